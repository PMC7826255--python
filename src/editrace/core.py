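"""Domain types and coordinate conventions shared by every pipeline stage.

Conventions
-----------
* All coordinates are 0-based; intervals are half-open ``[start, end)``.
* ``cut_site`` is an *inter-base* index into the stored reference: the
  nuclease cleaves between ``reference[cut_site - 1]`` and
  ``reference[cut_site]``.
* Events are stored in reference orientation.  Whenever a base identity is
  *reported* (inserted bases, the -4 base), it is converted to
  protospacer-strand orientation so that a "+T" means the same thing
  regardless of which genomic strand carries the guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "EditraceError",
    "ConfigError",
    "DataError",
    "revcomp",
    "complement",
    "Amplicon",
    "DonorSpec",
    "EditOp",
    "EditAllele",
    "SampleTable",
    "minus4_base",
    "apply_allele",
    "donor_edited_sequence",
    "op_signature",
    "allele_signature",
    "parse_signature",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"


class EditraceError(Exception):
    """Base class for package errors."""


class ConfigError(EditraceError):
    """Invalid configuration or schema violation (CLI exit code 2)."""


class DataError(EditraceError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves N, preserves case)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Amplicon geometry


@dataclass(frozen=True)
class Amplicon:
    """A reference amplicon with guide/PAM annotation.

    Parameters
    ----------
    id : str
        Amplicon identifier.
    reference_sequence : str
        Uppercase DNA (A/C/G/T/N), length >= 120.
    protospacer : str
        The 20-nt protospacer, given in protospacer-strand orientation.
    pam_start : int
        0-based reference index of the leftmost base of the 3-nt PAM
        region in the *stored* reference.
    strand : str
        ``"+"`` if the protospacer strand is the stored reference strand,
        ``"-"`` otherwise.

    The blunt cut site 3 nt 5' of the PAM is derived at construction and
    exposed as ``cut_site`` (an inter-base index).
    """

    id: str
    reference_sequence: str
    protospacer: str
    pam_start: int
    strand: str = "+"
    cut_site: int = field(init=False)

    MIN_LENGTH = 120

    def __post_init__(self) -> None:
        ref = self.reference_sequence
        if len(ref) < self.MIN_LENGTH:
            raise DataError(
                f"amplicon {self.id!r}: reference length {len(ref)} < "
                f"{self.MIN_LENGTH}"
            )
        if set(ref) - set("ACGTN"):
            raise DataError(f"amplicon {self.id!r}: non-DNA characters in reference")
        if self.strand not in "+-":
            raise DataError(f"amplicon {self.id!r}: strand must be '+' or '-'")
        if len(self.protospacer) != 20:
            raise DataError(f"amplicon {self.id!r}: protospacer must be 20 nt")

        if self.strand == "+":
            spacer = ref[self.pam_start - 20 : self.pam_start]
            pam = ref[self.pam_start : self.pam_start + 3]
            cut = self.pam_start - 3
        else:
            spacer = revcomp(ref[self.pam_start + 3 : self.pam_start + 23])
            pam = revcomp(ref[self.pam_start : self.pam_start + 3])
            cut = self.pam_start + 6
        if spacer != self.protospacer:
            raise DataError(
                f"amplicon {self.id!r}: protospacer does not match the "
                f"reference at pam_start={self.pam_start} ({self.strand})"
            )
        if not (len(pam) == 3 and pam[1:] == "GG"):
            raise DataError(f"amplicon {self.id!r}: PAM {pam!r} is not NGG")
        if not 0 < cut < len(ref):
            raise DataError(f"amplicon {self.id!r}: cut site {cut} out of range")
        object.__setattr__(self, "cut_site", cut)

    @property
    def pam(self) -> str:
        """The PAM trinucleotide in protospacer orientation."""
        pam = self.reference_sequence[self.pam_start : self.pam_start + 3]
        return pam if self.strand == "+" else revcomp(pam)

    def target_site(self) -> str:
        """Protospacer + PAM (23 nt) in protospacer orientation."""
        return self.protospacer + self.pam


def minus4_base(amplicon: Amplicon) -> str:
    """Base immediately 5' of the cut on the protospacer strand.

    This is position 17 (1-based) of the protospacer; its duplication is
    the signature +1 insertion event.

    Raises
    ------
    DataError
        If the reference carries an ambiguous base (N) at that position.
    """
    ref = amplicon.reference_sequence
    if amplicon.strand == "+":
        base = ref[amplicon.cut_site - 1]
    else:
        base = complement(ref[amplicon.cut_site])
    if base not in DNA_BASES:
        raise DataError(
            f"amplicon {amplicon.id!r}: ambiguous base {base!r} at the -4 position"
        )
    return base


# ---------------------------------------------------------------------------
# Edit operations and alleles


@dataclass(frozen=True, order=True)
class EditOp:
    """A single edit relative to the reference.

    ``ref_start == ref_end`` for insertions (the op sits between bases);
    deletions and substitutions cover ``[ref_start, ref_end)``.
    """

    ref_start: int
    ref_end: int
    kind: str  # insertion | deletion | substitution
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise DataError(f"unknown op kind {self.kind!r}")
        if self.ref_start > self.ref_end:
            raise DataError("ref_start > ref_end")
        if self.kind == "insertion":
            if self.ref_start != self.ref_end or not self.inserted_seq:
                raise DataError("insertion needs ref_start == ref_end and a sequence")
        elif self.kind == "deletion":
            if self.ref_end <= self.ref_start or self.inserted_seq:
                raise DataError("deletion needs ref_end > ref_start and no sequence")
        else:
            if self.ref_end <= self.ref_start or len(self.inserted_seq) != (
                self.ref_end - self.ref_start
            ):
                raise DataError("substitution length must match its interval")

    @property
    def length(self) -> int:
        if self.kind == "insertion":
            return len(self.inserted_seq)
        return self.ref_end - self.ref_start

    @property
    def net_size(self) -> int:
        """Signed length change caused by this op."""
        if self.kind == "insertion":
            return len(self.inserted_seq)
        if self.kind == "deletion":
            return -(self.ref_end - self.ref_start)
        return 0


def deletion(start: int, end: int) -> EditOp:
    return EditOp(start, end, "deletion")


def insertion(pos: int, seq: str) -> EditOp:
    return EditOp(pos, pos, "insertion", seq)


@dataclass
class EditAllele:
    """An aggregated editing outcome: an op list plus sample-level counts."""

    ops: tuple[EditOp, ...]
    read_count: int = 0
    frequency: float = 0.0
    repair_class: str = "unclassified"  # NHEJ | MMEJ | HDR | unedited | unclassified
    category: str = ""

    def __post_init__(self) -> None:
        self.ops = tuple(sorted(self.ops, key=lambda o: (o.ref_start, o.ref_end)))
        _check_non_overlapping(self.ops)

    @property
    def net_size(self) -> int:
        return sum(
            op.net_size for op in self.ops if op.kind in ("insertion", "deletion")
        )

    @property
    def indel_ops(self) -> tuple[EditOp, ...]:
        return tuple(op for op in self.ops if op.kind != "substitution")

    @property
    def signature(self) -> str:
        return allele_signature(self.indel_ops)

    def with_counts(self, read_count: int, frequency: float) -> "EditAllele":
        return replace(self, read_count=read_count, frequency=frequency)


def _check_non_overlapping(ops: tuple[EditOp, ...]) -> None:
    prev_end = -1
    prev_was_insertion = False
    prev_start = -1
    for op in ops:
        if op.ref_start < prev_end:
            raise DataError("overlapping edit operations")
        if op.kind == "insertion" and prev_was_insertion and op.ref_start == prev_start:
            raise DataError("two insertions at the same position")
        prev_end = op.ref_end
        prev_start = op.ref_start
        prev_was_insertion = op.kind == "insertion"


def apply_allele(amplicon: Amplicon | str, allele: EditAllele | tuple[EditOp, ...]) -> str:
    """Apply all ops of ``allele`` to the reference, left to right.

    Accepts either an :class:`Amplicon` or a raw reference string, and
    either an :class:`EditAllele` or a bare op tuple.  Substitution ops
    are applied too (they replace reference bases).
    """
    ref = amplicon.reference_sequence if isinstance(amplicon, Amplicon) else amplicon
    ops = allele.ops if isinstance(allele, EditAllele) else tuple(
        sorted(allele, key=lambda o: (o.ref_start, o.ref_end))
    )
    _check_non_overlapping(tuple(ops))
    pieces: list[str] = []
    pos = 0
    for op in ops:
        if op.ref_start < 0 or op.ref_end > len(ref):
            raise DataError(f"op {op} outside reference bounds")
        pieces.append(ref[pos : op.ref_start])
        if op.kind == "insertion":
            pieces.append(op.inserted_seq)
            pos = op.ref_start
        elif op.kind == "deletion":
            pos = op.ref_end
        else:  # substitution
            pieces.append(op.inserted_seq)
            pos = op.ref_end
    pieces.append(ref[pos:])
    return "".join(pieces)


# ---------------------------------------------------------------------------
# HDR donor


@dataclass(frozen=True)
class DonorSpec:
    """Short-insert HDR donor: insert placed exactly at the cut site."""

    insert_sequence: str
    insertion_point: int
    homology_arm_length: int = 600

    def __post_init__(self) -> None:
        if not self.insert_sequence:
            raise DataError("HDR donor insert must be non-empty")
        if set(self.insert_sequence) - set(DNA_BASES):
            raise DataError("HDR donor insert must be plain DNA")


def donor_edited_sequence(amplicon: Amplicon, donor: DonorSpec) -> str:
    """Reference with the donor insert placed at the cut site.

    Raises
    ------
    DataError
        If the insertion point is not the cut site, or if the edited
        sequence still contains the intact 23-nt protospacer+PAM on
        either strand (the donor must not be re-cuttable).
    """
    if donor.insertion_point != amplicon.cut_site:
        raise DataError(
            f"donor insertion point {donor.insertion_point} != cut site "
            f"{amplicon.cut_site}"
        )
    ref = amplicon.reference_sequence
    cut = amplicon.cut_site
    edited = ref[:cut] + donor.insert_sequence + ref[cut:]
    site = amplicon.target_site()
    if site in edited or revcomp(site) in edited:
        raise DataError(
            f"amplicon {amplicon.id!r}: donor insert recreates the intact "
            "protospacer+PAM target"
        )
    return edited


# ---------------------------------------------------------------------------
# Sample-level container


@dataclass
class SampleTable:
    """All called alleles of one sequencing sample.

    ``total_reads`` counts every read that entered allele calling
    (including unalignable reads); ``alleles`` carries only edited
    alleles that survived artifact filtering, so the unedited fraction is
    ``1 - sum(a.frequency for a in alleles) - unaligned/total``.
    """

    amplicon_id: str
    condition: str = "donor_absent"  # donor_absent | donor_present [+tag]
    timepoint_h: float = 48.0
    total_reads: int = 0
    alleles: list[EditAllele] = field(default_factory=list)
    unaligned_reads: int = 0

    def __post_init__(self) -> None:
        total = sum(a.frequency for a in self.alleles)
        if total > 1.0 + 1e-9:
            raise DataError(f"allele frequencies sum to {total} > 1")

    @property
    def edited_fraction(self) -> float:
        return sum(a.frequency for a in self.alleles)

    def allele_by_signature(self, signature: str) -> EditAllele | None:
        for allele in self.alleles:
            if allele.signature == signature:
                return allele
        return None


# ---------------------------------------------------------------------------
# Allele signatures (the inter-stage text representation)


def op_signature(op: EditOp) -> str:
    if op.kind == "deletion":
        return f"D{op.length}@{op.ref_start}"
    if op.kind == "insertion":
        return f"I{op.length}@{op.ref_start}:{op.inserted_seq}"
    return f"S{op.length}@{op.ref_start}:{op.inserted_seq}"


def allele_signature(ops: tuple[EditOp, ...]) -> str:
    """CIGAR-like signature, e.g. ``D4@103;I1@110:T``; ``WT`` if empty."""
    if not ops:
        return "WT"
    return ";".join(op_signature(op) for op in ops)


def parse_signature(signature: str) -> tuple[EditOp, ...]:
    """Inverse of :func:`allele_signature`."""
    if signature in ("", "WT"):
        return ()
    ops = []
    for token in signature.split(";"):
        kind_char = token[0]
        body = token[1:]
        if kind_char == "D":
            length, start = body.split("@")
            ops.append(EditOp(int(start), int(start) + int(length), "deletion"))
        elif kind_char in ("I", "S"):
            length_s, rest = body.split("@")
            pos_s, seq = rest.split(":")
            pos = int(pos_s)
            if kind_char == "I":
                ops.append(EditOp(pos, pos, "insertion", seq))
            else:
                ops.append(EditOp(pos, pos + int(length_s), "substitution", seq))
        else:
            raise DataError(f"cannot parse op token {token!r}")
    return tuple(ops)
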