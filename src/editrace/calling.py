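"""Alignment of merged reads, edit-op extraction, and allele aggregation.

This stage plays the role of the usual web-tool + spreadsheet-script
combination: global affine alignment against the reference amplicon,
left-aligned indel extraction, a cut-site window filter that discards
distal artifacts, and count/frequency thresholds that suppress
sequencing-error alleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .core import (
    Amplicon,
    DataError,
    EditAllele,
    EditOp,
    SampleTable,
)

__all__ = [
    "AlignmentResult",
    "align_to_reference",
    "extract_operations",
    "call_allele",
    "call_read",
    "aggregate",
    "call_sample",
    "editing_efficiency",
    "top_n_patterns",
]

DEFAULT_WINDOW = 50
DEFAULT_MIN_COUNT = 2
DEFAULT_MIN_FREQ = 0.0005
MIN_IDENTITY = 0.60
LENGTH_RATIO_RANGE = (0.4, 1.6)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AlignmentResult:
    """Outcome of aligning one read: ops on success, a reason otherwise."""

    ok: bool
    ops: tuple[EditOp, ...] = ()
    identity: float = 0.0
    reason: str = ""


def align_to_reference(read: str, amplicon: Amplicon) -> AlignmentResult:
    """Globally align ``read`` to the amplicon and extract edit ops.

    Scoring: match +2, mismatch -4, gap open -10, gap extend -1.  Reads
    whose length falls outside 0.4-1.6x the reference, or whose
    alignment identity is below 60%, are flagged unalignable.  Indels
    are left-aligned within their repeat context after extraction, so
    the op placement is deterministic.
    """
    ref = amplicon.reference_sequence
    lo, hi = LENGTH_RATIO_RANGE
    if not lo * len(ref) <= len(read) <= hi * len(ref):
        return AlignmentResult(False, reason="length_ratio")

    # Fast path: equal length and few mismatches means substitutions only.
    if len(read) == len(ref):
        mismatches = [i for i, (a, b) in enumerate(zip(ref, read)) if a != b]
        if len(mismatches) <= 0.05 * len(ref):
            ops = _runs_to_substitutions(ref, read, mismatches)
            identity = 1.0 - len(mismatches) / len(ref)
            return AlignmentResult(True, ops, identity)

    alignment = _ALIGNER.align(ref, read)[0]
    ops = extract_operations(alignment, ref, read)
    n_match = sum(
        1
        for op_start, op_end in _matched_columns(alignment, ref, read)
        for _ in range(op_end - op_start)
    )
    identity = n_match / max(alignment.length, 1)
    if identity < MIN_IDENTITY:
        return AlignmentResult(False, reason="low_identity", identity=identity)
    return AlignmentResult(True, ops, identity)


def _matched_columns(alignment, ref: str, read: str):
    tblocks, qblocks = alignment.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        start = None
        for i in range(te - ts):
            if ref[ts + i] == read[qs + i]:
                if start is None:
                    start = i
            else:
                if start is not None:
                    yield (start, i)
                    start = None
        if start is not None:
            yield (start, te - ts)


def _runs_to_substitutions(
    ref: str, read: str, positions: Sequence[int]
) -> tuple[EditOp, ...]:
    """Coalesce adjacent mismatch positions into substitution ops."""
    ops: list[EditOp] = []
    run_start = None
    prev = None
    for pos in positions:
        if run_start is None:
            run_start = pos
        elif pos != prev + 1:
            ops.append(EditOp(run_start, prev + 1, "substitution", read[run_start : prev + 1]))
            run_start = pos
        prev = pos
    if run_start is not None:
        ops.append(EditOp(run_start, prev + 1, "substitution", read[run_start : prev + 1]))
    return tuple(ops)


def extract_operations(alignment, ref: str, read: str) -> tuple[EditOp, ...]:
    """Convert a pairwise alignment into a left-aligned op list.

    Adjacent gap columns are coalesced into single indel ops; each indel
    is then shifted to its leftmost equivalent placement (bounded by the
    previous op so ops never collide).  Substitutions are recorded as
    ops but are never treated as edits downstream.
    """
    tblocks, qblocks = alignment.aligned
    raw: list[EditOp] = []
    prev_t = 0
    prev_q = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if ts > prev_t:
            raw.append(EditOp(prev_t, ts, "deletion"))
        if qs > prev_q:
            raw.append(EditOp(ts, ts, "insertion", read[prev_q:qs]))
        # substitutions inside the aligned block
        i = 0
        while i < te - ts:
            if ref[ts + i] != read[qs + i]:
                j = i
                while j < te - ts and ref[ts + j] != read[qs + j]:
                    j += 1
                raw.append(EditOp(ts + i, ts + j, "substitution", read[qs + i : qs + j]))
                i = j
            else:
                i += 1
        prev_t, prev_q = te, qe
    if len(ref) > prev_t:
        raw.append(EditOp(prev_t, len(ref), "deletion"))
    if len(read) > prev_q:
        raw.append(EditOp(len(ref), len(ref), "insertion", read[prev_q:]))

    raw.sort(key=lambda o: (o.ref_start, o.ref_end))
    ops: list[EditOp] = []
    floor = 0
    for op in raw:
        if op.kind == "deletion":
            s, e = op.ref_start, op.ref_end
            while s > floor and ref[s - 1] == ref[e - 1]:
                s -= 1
                e -= 1
            op = EditOp(s, e, "deletion")
        elif op.kind == "insertion":
            pos, seq = op.ref_start, op.inserted_seq
            while pos > floor and ref[pos - 1] == seq[-1]:
                seq = seq[-1] + seq[:-1]
                pos -= 1
            op = EditOp(pos, pos, "insertion", seq)
        ops.append(op)
        floor = max(floor, op.ref_end if op.ref_end > op.ref_start else op.ref_start)
    ops.sort(key=lambda o: (o.ref_start, o.ref_end))
    return tuple(ops)


def call_allele(
    ops: Iterable[EditOp], amplicon: Amplicon, window: int = DEFAULT_WINDOW
) -> EditAllele | None:
    """Decide whether an op list is an edit; None means unedited.

    A read is edited iff at least one insertion/deletion overlaps
    ``[cut_site - window, cut_site + window]``.  In-window indels make up
    the allele; out-of-window indels and all substitutions are dropped
    as PCR/sequencing artifacts.
    """
    cut = amplicon.cut_site
    kept = []
    for op in ops:
        if op.kind == "substitution":
            continue
        if op.kind == "insertion":
            hit = cut - window <= op.ref_start <= cut + window
        else:
            hit = op.ref_start < cut + window and op.ref_end > cut - window
        if hit:
            kept.append(op)
    if not kept:
        return None
    return EditAllele(ops=tuple(kept))


def call_read(
    read: str, amplicon: Amplicon, window: int = DEFAULT_WINDOW
) -> EditAllele | None | str:
    """Align one read and call it; returns an allele, None, or 'unalignable'."""
    result = align_to_reference(read, amplicon)
    if not result.ok:
        return "unalignable"
    return call_allele(result.ops, amplicon, window)


def aggregate(
    called: Sequence[EditAllele | None],
    min_count: int = DEFAULT_MIN_COUNT,
    min_freq: float = DEFAULT_MIN_FREQ,
    n_unaligned: int = 0,
    amplicon_id: str = "",
    condition: str = "donor_absent",
    timepoint_h: float = 48.0,
) -> SampleTable:
    """Collapse per-read calls into a sample allele table.

    Alleles failing ``min_count`` or ``min_freq`` are removed from the
    edited set; their reads still count toward ``total_reads`` (they are
    folded back into the unedited mass), so the editing efficiency
    reflects the exclusion.
    """
    total = len(called) + n_unaligned
    if total == 0:
        raise DataError("cannot aggregate zero reads")
    counts: Counter[tuple[EditOp, ...]] = Counter()
    for allele in called:
        if allele is not None:
            counts[allele.indel_ops] += 1
    alleles = [
        EditAllele(ops=ops, read_count=count, frequency=count / total)
        for ops, count in counts.items()
        if count >= min_count and count / total >= min_freq
    ]
    alleles.sort(key=lambda a: (-a.frequency, _op_span(a), a.signature))
    return SampleTable(
        amplicon_id=amplicon_id,
        condition=condition,
        timepoint_h=timepoint_h,
        total_reads=total,
        alleles=alleles,
        unaligned_reads=n_unaligned,
    )


def call_sample(
    reads: Iterable[str],
    amplicon: Amplicon,
    window: int = DEFAULT_WINDOW,
    min_count: int = DEFAULT_MIN_COUNT,
    min_freq: float = DEFAULT_MIN_FREQ,
    condition: str = "donor_absent",
    timepoint_h: float = 48.0,
) -> SampleTable:
    """Align + call + aggregate a whole sample of merged reads.

    Unique sequences are aligned once and their calls reused, which makes
    deep amplicon samples cheap (most reads are exact duplicates).
    """
    seq_counts = Counter(reads)
    called: list[EditAllele | None] = []
    n_unaligned = 0
    for seq, count in seq_counts.items():
        call = call_read(seq, amplicon, window)
        if call == "unalignable":
            n_unaligned += count
        else:
            called.extend([call] * count)
    return aggregate(
        called,
        min_count=min_count,
        min_freq=min_freq,
        n_unaligned=n_unaligned,
        amplicon_id=amplicon.id,
        condition=condition,
        timepoint_h=timepoint_h,
    )


def editing_efficiency(sample: SampleTable) -> float:
    """Total edited fraction: the sum of edited allele frequencies."""
    return sum(a.frequency for a in sample.alleles)


def _op_span(allele: EditAllele) -> int:
    ops = allele.indel_ops
    if not ops:
        return 0
    return max(op.ref_end for op in ops) - min(op.ref_start for op in ops)


def top_n_patterns(sample: SampleTable, n: int = 10) -> list[EditAllele]:
    """Alleles ranked by frequency; ties go to the shorter op span, then
    the lexicographically smaller signature."""
    ranked = sorted(
        sample.alleles, key=lambda a: (-a.frequency, _op_span(a), a.signature)
    )
    return ranked[:n]
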