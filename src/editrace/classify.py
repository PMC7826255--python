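"""NHEJ / MMEJ / HDR classification of edited alleles, plus binning.

MMEJ is recognized by junction microhomology: a deletion whose flanks
repeat 2-16 nt of sequence, making the junction placement ambiguous, or
a 1-nt G (C) deletion when the cut site lies between G|G (C|C).  HDR is
an exact donor insert at the cut with clean flanks.  Everything else
edited is NHEJ.

Microhomology is computed on the deletion's full placement-equivalence
class, not on any single reported placement, so equivalent deletions
always receive identical calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    Amplicon,
    ConfigError,
    DataError,
    DonorSpec,
    EditAllele,
    EditOp,
    complement,
    minus4_base,
)

__all__ = [
    "Microhomology",
    "RepairCall",
    "microhomology",
    "deletion_placements",
    "insertion_placements",
    "is_plus1_duplication",
    "classify",
    "categorize",
    "CATEGORY_SCHEMES",
]

MH_CAP = 16
MMEJ_MH_RANGE = (2, 16)
DEFAULT_FLANK_CHECK = 10


@dataclass(frozen=True)
class Microhomology:
    """Repeated junction sequence of a deletion.

    ``length`` is capped at :data:`MH_CAP`; ``placements`` lists every
    equivalent deletion interval (uncapped, ``raw_length + 1`` entries).
    """

    length: int
    sequence: str
    placements: tuple[tuple[int, int], ...]

    @property
    def raw_length(self) -> int:
        return len(self.placements) - 1


def deletion_placements(ref: str, del_start: int, del_end: int) -> tuple[tuple[int, int], ...]:
    """All deletion intervals of the same length yielding the same string."""
    d = del_end - del_start
    s, e = del_start, del_end
    while s > 0 and ref[s - 1] == ref[e - 1]:
        s -= 1
        e -= 1
    placements = [(s, e)]
    while e < len(ref) and ref[s] == ref[e]:
        s += 1
        e += 1
        placements.append((s, e))
    return tuple(placements)


def microhomology(
    reference: str, del_start: int, del_end: int, cap: int = MH_CAP
) -> Microhomology:
    """Microhomology of the deletion ``[del_start, del_end)``.

    The length equals the number of equivalent placements minus one,
    computed by flank-identity extension to both sides, then capped.
    The sequence is the repeated junction sequence itself.
    """
    if not 0 <= del_start < del_end <= len(reference):
        raise DataError("deletion interval out of bounds")
    placements = deletion_placements(reference, del_start, del_end)
    raw = len(placements) - 1
    leftmost_start = placements[0][0]
    seq = reference[leftmost_start : leftmost_start + raw]
    return Microhomology(length=min(raw, cap), sequence=seq, placements=placements)


def insertion_placements(ref: str, pos: int, seq: str) -> tuple[tuple[int, str], ...]:
    """All (position, rotated sequence) pairs equivalent to this insertion."""
    placements = [(pos, seq)]
    p, s = pos, seq
    while p > 0 and ref[p - 1] == s[-1]:
        s = s[-1] + s[:-1]
        p -= 1
        placements.append((p, s))
    p, s = pos, seq
    while p < len(ref) and ref[p] == s[0]:
        s = s[1:] + s[0]
        p += 1
        placements.append((p, s))
    return tuple(sorted(placements))


@dataclass(frozen=True)
class RepairCall:
    repair_class: str  # NHEJ | MMEJ | HDR
    subtype: str = ""
    microhomology: Microhomology | None = None

    def __post_init__(self) -> None:
        if self.repair_class not in ("NHEJ", "MMEJ", "HDR"):
            raise DataError(f"unknown repair class {self.repair_class!r}")


def is_plus1_duplication(allele: EditAllele, amplicon: Amplicon) -> str | None:
    """Return the duplicated base iff the allele is a -4-base duplication.

    The allele must be a single 1-nt insertion whose placement range
    includes the cut site and whose base equals the -4 base.  The base
    is reported in protospacer orientation.
    """
    ops = allele.indel_ops
    if len(ops) != 1 or ops[0].kind != "insertion" or len(ops[0].inserted_seq) != 1:
        return None
    op = ops[0]
    ref = amplicon.reference_sequence
    positions = {p for p, _ in insertion_placements(ref, op.ref_start, op.inserted_seq)}
    if amplicon.cut_site not in positions:
        return None
    base = op.inserted_seq
    reported = base if amplicon.strand == "+" else complement(base)
    if reported != minus4_base(amplicon):
        return None
    return reported


def _inserted_base_reported(op: EditOp, amplicon: Amplicon) -> str:
    base = op.inserted_seq
    return base if amplicon.strand == "+" else complement(base)


def classify(
    allele: EditAllele,
    amplicon: Amplicon,
    donor: DonorSpec | None = None,
    flank_check: int = DEFAULT_FLANK_CHECK,
) -> RepairCall:
    """Assign an edited allele to HDR, MMEJ, or NHEJ (ordered rules).

    1. HDR: a single insertion whose placement class puts exactly the
       donor insert at the cut site, with at least ``flank_check``
       unedited reference bases on each side.
    2. MMEJ: a single deletion of length >= 2 with microhomology length
       in [2, 16].
    3. MMEJ (1-nt rule): deletion of exactly one G (or C) where the
       bases flanking the cut are G|G (or C|C) and the deleted base is
       one of them.
    4. Everything else edited is NHEJ (insertions, 1-nt A/T deletions,
       no-microhomology deletions, complex alleles).
    """
    ops = allele.indel_ops
    if not ops:
        raise DataError("cannot classify an unedited allele")
    ref = amplicon.reference_sequence
    cut = amplicon.cut_site

    if donor is not None:
        if donor.insertion_point != cut:
            raise DataError("donor insertion point is not the cut site")
        if len(ops) == 1 and ops[0].kind == "insertion":
            op = ops[0]
            placements = insertion_placements(ref, op.ref_start, op.inserted_seq)
            at_cut = any(
                p == cut and seq == donor.insert_sequence for p, seq in placements
            )
            if at_cut and _clean_flanks(ops, cut, flank_check):
                return RepairCall(
                    "HDR", subtype=f"HDR +{len(donor.insert_sequence)}"
                )

    if len(ops) == 1 and ops[0].kind == "deletion":
        op = ops[0]
        mh = microhomology(ref, op.ref_start, op.ref_end)
        if op.length >= 2 and MMEJ_MH_RANGE[0] <= mh.length <= MMEJ_MH_RANGE[1]:
            return RepairCall(
                "MMEJ",
                subtype=f"MH={mh.length} del -{op.length}",
                microhomology=mh,
            )
        if op.length == 1:
            base = ref[op.ref_start]
            flank = ref[cut - 1 : cut + 1]
            if (
                base in "GC"
                and flank == base * 2
                and ((cut - 1, cut) in mh.placements or (cut, cut + 1) in mh.placements)
            ):
                reported = base if amplicon.strand == "+" else complement(base)
                return RepairCall(
                    "MMEJ",
                    subtype=f"-1 {reported}|{reported}",
                    microhomology=mh,
                )

    # NHEJ catch-all; give +1 insertions an informative subtype.
    if len(ops) == 1 and ops[0].kind == "insertion" and ops[0].length == 1:
        dup = is_plus1_duplication(allele, amplicon)
        if dup is not None:
            return RepairCall("NHEJ", subtype=f"+{dup} duplication")
        return RepairCall(
            "NHEJ", subtype=f"+{_inserted_base_reported(ops[0], amplicon)} insertion"
        )
    return RepairCall("NHEJ", subtype=f"net {allele.net_size:+d}")


def _clean_flanks(ops: tuple[EditOp, ...], cut: int, flank: int) -> bool:
    """True iff no op other than the cut-site op touches [cut-flank, cut+flank]."""
    for op in ops:
        if op.ref_start == op.ref_end == cut:
            continue
        if op.ref_start < cut + flank and max(op.ref_end, op.ref_start + 1) > cut - flank:
            return False
    return True


# ---------------------------------------------------------------------------
# Category schemes


def _insertion_base(allele: EditAllele, amplicon: Amplicon) -> str | None:
    ops = allele.indel_ops
    if len(ops) == 1 and ops[0].kind == "insertion" and ops[0].length == 1:
        return _inserted_base_reported(ops[0], amplicon)
    return None


def _seven_group(call, allele, amplicon):
    base = _insertion_base(allele, amplicon)
    if base is not None:
        return "+A/T" if base in "AT" else "+C/G"
    net = allele.net_size
    if net >= 0:
        return None
    return _deletion_bin(-net, [(1, 1, "-1"), (2, 2, "-2"), (3, 5, "-3 to -5"),
                                (6, 9, "-6 to -9"), (10, 30, "-10 to -30")])


def _eleven_cat(call, allele, amplicon):
    base = _insertion_base(allele, amplicon)
    if base is not None:
        return f"+{base}"
    net = allele.net_size
    if net < 0:
        label = _deletion_bin(
            -net,
            [(1, 1, "-1"), (2, 2, "-2"), (3, 5, "-3 to -5"), (6, 9, "-6 to -9"),
             (10, 23, "-10 to -23"), (24, 30, "-24 to -30")],
        )
        if label is not None:
            return label
    return "other"


def _t50_bins(call, allele, amplicon):
    base = _insertion_base(allele, amplicon)
    if base is not None:
        return f"+{base}"
    net = allele.net_size
    if net < 0:
        label = _deletion_bin(
            -net,
            [(1, 1, "-1"), (2, 2, "-2"), (3, 5, "-3 to -5"), (6, 9, "-6 to -9"),
             (10, 30, ">= -10")],
        )
        if label is not None:
            return label
    return "other"


def _competition_bins(call, allele, amplicon):
    if call.repair_class == "HDR":
        return "HDR"
    if _insertion_base(allele, amplicon) is not None:
        return "+1"
    net = allele.net_size
    if net < 0:
        return _deletion_bin(
            -net,
            [(1, 1, "-1"), (2, 5, "-2 to -5"), (6, 9, "-6 to -9"),
             (10, 30, "-10 to -30")],
        )
    return None


def _deletion_bin(size: int, bins: list[tuple[int, int, str]]) -> str | None:
    for lo, hi, label in bins:
        if lo <= size <= hi:
            return label
    return None


CATEGORY_SCHEMES = {
    "seven_group": _seven_group,
    "eleven_cat": _eleven_cat,
    "t50_bins": _t50_bins,
    "competition_bins": _competition_bins,
}


def categorize(
    call: RepairCall, allele: EditAllele, amplicon: Amplicon, scheme: str
) -> str | None:
    """Bin a classified allele under the requested scheme.

    Returns None when the allele falls outside the scheme's bins (e.g.
    a -40 deletion under ``seven_group``).  Net size (insertions minus
    deletions over all ops) drives the deletion bins.
    """
    try:
        fn = CATEGORY_SCHEMES[scheme]
    except KeyError:
        raise ConfigError(
            f"unknown category scheme {scheme!r}; valid: {sorted(CATEGORY_SCHEMES)}"
        ) from None
    return fn(call, allele, amplicon)
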