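"""Synthetic data: amplicons, outcome models, repair-race time courses,
and paired-end reads with sequencing error.

The generating model is a per-cell repair race.  Every editable cell
commits to one indel outcome with probability proportional to the
outcome propensities (so 48-h outcome shares match the propensity table
by construction), and completes it at a class-specific time

    t = delta + Exponential(mu)

whose marginal CDF reaches 0.5 at ``delta + mu * ln 2`` - the class T50.
When an HDR donor is present, every editable cell additionally draws an
independent HDR completion time and realizes whichever channel finishes
first.  Because HDR kinetics sit between the fast NHEJ classes and the
slow long-deletion MMEJ classes, the donor channel preferentially
pre-empts long MMEJ deletions while leaving +1 NHEJ nearly untouched.

Default calibration (propensities and class T50s) is documented on the
constants below; per-cell-type multipliers live in :data:`CELL_PROFILES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .classify import microhomology
from .core import (
    Amplicon,
    ConfigError,
    DataError,
    DonorSpec,
    EditOp,
    allele_signature,
    apply_allele,
    donor_edited_sequence,
    minus4_base,
    revcomp,
)
from .reads import ReadPair

__all__ = [
    "CellProfile",
    "CELL_PROFILES",
    "KineticClassParams",
    "SimOutcome",
    "OutcomeModel",
    "SimulationConfig",
    "random_amplicon",
    "build_outcome_model",
    "simulate_locus",
    "TrueTables",
    "reads_from_frequencies",
    "demo_timecourse_locus",
]

LN2 = math.log(2.0)

# +1 duplication propensity (share of edited events) by -4 base.
PLUS1_PROPENSITY = {"T": 0.27, "A": 0.10, "C": 0.05, "G": 0.03}
NONDUP_PROPENSITY = 0.05
DEL1_PROPENSITY = 0.05
MMEJ_MASS = 0.30  # total propensity of microhomology-mediated deletions

# Class T50s in hours (baseline profile; iPSC values for deletions).
PLUS1_T50 = {"T": 6.2, "A": 7.8, "C": 7.9, "G": 6.6}
DEL1_NHEJ_T50 = 8.5
FILLER_NHEJ_T50 = 10.0
GGCC_MMEJ_T50 = 12.0
MMEJ_SHORT_T50 = 18.4  # deletions of 2-5 nt
MMEJ_MID_T50 = 19.9  # 6-9 nt
MMEJ_LONG_T50 = 23.9  # >= 10 nt
HDR_T50 = 15.0

DELAY_FRACTION = 0.6  # delta = fraction * T50 for NHEJ/MMEJ classes
HDR_DELAY_FRACTION = 0.75  # HDR needs a longer minimum processing time
DEFAULT_DONOR_FRACTION = 0.8  # fraction of cells carrying an active donor channel

MMEJ_LENGTH_SCALE = 15.0  # propensity kernel: mh_len * exp(-d / scale)
MAX_MMEJ_OUTCOMES = 12
MAX_DELETION = 30


@dataclass(frozen=True)
class CellProfile:
    """Per-cell-type multipliers on the baseline calibration."""

    name: str
    nhej_t50_scale: float = 1.0
    mmej_t50_scale: float = 1.0
    plus1_propensity_scale: float = 1.0


CELL_PROFILES = {
    "iPSC": CellProfile("iPSC", 1.0, 1.0, 1.4),
    "T": CellProfile("T", 1.0, 0.85, 1.0),
    "K562": CellProfile("K562", 2.0, 1.0, 1.0),
    "U937": CellProfile("U937", 1.6, 1.0, 1.0),
}


@dataclass(frozen=True)
class KineticClassParams:
    """Shifted-exponential completion-time parameters."""

    delta: float
    mu: float

    @classmethod
    def from_t50(cls, t50: float, delay_fraction: float = DELAY_FRACTION):
        if t50 <= 0:
            raise ConfigError("T50 must be positive")
        delta = delay_fraction * t50
        return cls(delta=delta, mu=(t50 - delta) / LN2)

    @property
    def t50(self) -> float:
        return self.delta + self.mu * LN2


@dataclass(frozen=True)
class SimOutcome:
    ops: tuple[EditOp, ...]
    weight: float
    kinetic_class: str  # NHEJ | MMEJ_short | MMEJ_long | HDR
    kinetics: KineticClassParams
    label: str

    @property
    def signature(self) -> str:
        return allele_signature(self.ops)


@dataclass(frozen=True)
class OutcomeModel:
    """Indel outcome propensities plus an optional HDR channel."""

    outcomes: tuple[SimOutcome, ...]
    editable_fraction: float
    hdr: SimOutcome | None = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise DataError("outcome model has no candidate outcomes")
        if any(o.weight <= 0 or not math.isfinite(o.weight) for o in self.outcomes):
            raise DataError("outcome propensities must be positive and finite")
        if not 0.0 <= self.editable_fraction <= 1.0:
            raise DataError("editable fraction must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([o.weight for o in self.outcomes], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    cell_profile: str = "iPSC"
    depth: int = 50_000
    timepoints: tuple[float, ...] = (4.0, 8.0, 12.0, 24.0, 48.0)
    error_rate: float = 0.002
    read_length: int = 150
    phred: int = 37
    donor: DonorSpec | None = None
    hdr_propensity: float = 1.0
    donor_fraction: float = DEFAULT_DONOR_FRACTION
    nhej_scale: float = 1.0
    mmej_scale: float = 1.0
    editable_fraction: float | None = None  # None: draw Uniform(0.2, 0.6)
    mmej_mass: float = MMEJ_MASS
    amplicon_length: int = 240

    def __post_init__(self) -> None:
        if self.depth < 0 or self.error_rate < 0 or self.read_length <= 0:
            raise ConfigError("depth/error_rate/read_length must be non-negative")
        if self.cell_profile not in CELL_PROFILES:
            raise ConfigError(
                f"unknown cell profile {self.cell_profile!r}; "
                f"valid: {sorted(CELL_PROFILES)}"
            )
        if not all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ConfigError("timepoints must be strictly increasing")
        if self.hdr_propensity <= 0 or self.nhej_scale <= 0 or self.mmej_scale <= 0:
            raise ConfigError("propensity scales must be positive")
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ConfigError("donor_fraction must lie in [0, 1]")

    @property
    def profile(self) -> CellProfile:
        return CELL_PROFILES[self.cell_profile]


# ---------------------------------------------------------------------------
# Amplicon generation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_amplicon(
    seed: int | np.random.Generator,
    length: int = 240,
    minus4: str | None = None,
    planted_microhomologies: Sequence[tuple[int, int]] = (),
    amplicon_id: str | None = None,
) -> Amplicon:
    """Uniform-random amplicon with a central valid protospacer+NGG.

    Parameters
    ----------
    minus4 : str, optional
        Force this base immediately 5' of the cut (the +1-duplication
        driver); None leaves it random.
    planted_microhomologies : sequence of (mh_len, separation)
        For each pair, a repeat of ``mh_len`` nt is planted so that the
        deletion of ``separation`` nt straddling the cut carries at
        least that much junction microhomology.

    Raises
    ------
    DataError
        If the constraints cannot be satisfied within bounded retries.
    """
    if length < Amplicon.MIN_LENGTH:
        raise DataError(f"amplicon length must be >= {Amplicon.MIN_LENGTH}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cut = length // 2
    pam_start = cut + 3

    for attempt in range(200):
        arr = rng.choice(_BASES, size=length)
        seq = list(arr.tobytes().decode())
        for mh_len, separation in planted_microhomologies:
            if not 1 <= mh_len <= separation:
                raise DataError("planted mh_len must be in [1, separation]")
            s = cut - separation // 2
            e = s + separation
            if s - mh_len < 0 or e > length:
                raise DataError("planted microhomology does not fit the amplicon")
            seq[e - mh_len : e] = seq[s - mh_len : s]
        seq[pam_start + 1 : pam_start + 3] = "GG"
        if minus4 is not None:
            seq[cut - 1] = minus4
        ref = "".join(seq)

        ok = True
        for mh_len, separation in planted_microhomologies:
            s = cut - separation // 2
            if microhomology(ref, s, s + separation).raw_length < mh_len:
                ok = False
                break
        if not ok:
            continue
        try:
            return Amplicon(
                id=amplicon_id or f"sim_amplicon_{attempt}",
                reference_sequence=ref,
                protospacer=ref[pam_start - 20 : pam_start],
                pam_start=pam_start,
                strand="+",
            )
        except DataError:
            continue
    raise DataError("could not satisfy amplicon constraints in 200 attempts")


# ---------------------------------------------------------------------------
# Outcome model construction


def _kp(t50: float, delay_fraction: float = DELAY_FRACTION) -> KineticClassParams:
    return KineticClassParams.from_t50(t50, delay_fraction)


def _mmej_t50(d: int, profile: CellProfile) -> tuple[float, str]:
    if d <= 5:
        return MMEJ_SHORT_T50 * profile.mmej_t50_scale, "MMEJ_short"
    if d <= 9:
        return MMEJ_MID_T50 * profile.mmej_t50_scale, "MMEJ_long"
    return MMEJ_LONG_T50 * profile.mmej_t50_scale, "MMEJ_long"


def _filler_op(
    ref: str, cut: int, d: int, rng: np.random.Generator
) -> tuple[EditOp, str]:
    """A d-nt NHEJ remainder op near the cut.

    Prefers a deletion with microhomology < 2 (so it can never collide
    with - or be classified as - an MMEJ outcome); when the local
    sequence offers none, a d-nt insertion at the cut is used instead
    (insertions are NHEJ by definition).
    """
    for s in range(max(cut - d, 0), min(cut, len(ref) - d) + 1):
        if microhomology(ref, s, s + d).length < 2:
            return EditOp(s, s + d, "deletion"), f"-{d} NHEJ"
    seq = "".join(rng.choice(list("ACGT"), size=d))
    return EditOp(cut, cut, "insertion", seq), f"+{d} NHEJ"


def build_outcome_model(
    amplicon: Amplicon,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> OutcomeModel:
    """Derive the per-locus outcome propensity table.

    Propensities are shares of edited events at the 48-h endpoint
    (donor absent): the -4-base-dependent +1 duplication, small NHEJ
    baselines, microhomology-driven deletions weighted by
    ``mh_len * exp(-d / 15)`` within a fixed total MMEJ mass, and an
    unbiased NHEJ remainder.  Inhibitor knobs rescale whole classes;
    the iPSC profile boosts +1 insertion propensities by 1.4x.
    """
    rng = rng or np.random.default_rng(config.seed)
    profile = config.profile
    ref = amplicon.reference_sequence
    cut = amplicon.cut_site

    dup_base_ref = ref[cut - 1] if amplicon.strand == "+" else ref[cut]
    m4 = minus4_base(amplicon)

    outcomes: list[SimOutcome] = []

    p_dup = PLUS1_PROPENSITY[m4] * profile.plus1_propensity_scale
    outcomes.append(
        SimOutcome(
            ops=(EditOp(cut, cut, "insertion", dup_base_ref),),
            weight=p_dup,
            kinetic_class="NHEJ",
            kinetics=_kp(PLUS1_T50[m4] * profile.nhej_t50_scale),
            label=f"+{m4} duplication",
        )
    )

    other_bases = [b for b in "ACGT" if b != dup_base_ref]
    nondup_ref = other_bases[int(rng.integers(len(other_bases)))]
    nondup_reported = nondup_ref if amplicon.strand == "+" else revcomp(nondup_ref)
    outcomes.append(
        SimOutcome(
            ops=(EditOp(cut, cut, "insertion", nondup_ref),),
            weight=NONDUP_PROPENSITY * profile.plus1_propensity_scale,
            kinetic_class="NHEJ",
            kinetics=_kp(PLUS1_T50.get(nondup_reported, 7.5) * profile.nhej_t50_scale),
            label=f"+{nondup_reported} insertion",
        )
    )

    cut_flanks = ref[cut - 1 : cut + 1]
    ggcc = cut_flanks in ("GG", "CC")
    if not ggcc:
        outcomes.append(
            SimOutcome(
                ops=(EditOp(cut, cut + 1, "deletion"),),
                weight=DEL1_PROPENSITY,
                kinetic_class="NHEJ",
                kinetics=_kp(DEL1_NHEJ_T50 * profile.nhej_t50_scale),
                label="-1 NHEJ",
            )
        )

    # Microhomology-driven deletion candidates straddling the cut.
    mmej_candidates: dict[tuple[int, int], tuple[float, int]] = {}
    for d in range(2, MAX_DELETION + 1):
        for s in range(max(cut - d, 0), min(cut, len(ref) - d) + 1):
            mh = microhomology(ref, s, s + d)
            if not 2 <= mh.length <= 16:
                continue
            canonical = mh.placements[0]
            kernel = mh.length * math.exp(-d / MMEJ_LENGTH_SCALE)
            if canonical not in mmej_candidates:
                mmej_candidates[canonical] = (kernel, d)
    ranked = sorted(
        mmej_candidates.items(), key=lambda kv: (-kv[1][0], kv[0])
    )[:MAX_MMEJ_OUTCOMES]

    ggcc_candidates: list[tuple[EditOp, float]] = []
    if ggcc:
        ggcc_candidates.append(
            (EditOp(cut - 1, cut, "deletion"), math.exp(-1 / MMEJ_LENGTH_SCALE))
        )

    kernel_total = sum(k for _, (k, _) in ranked) + sum(k for _, k in ggcc_candidates)
    mmej_mass = config.mmej_mass if kernel_total > 0 else 0.0
    for (s, e), (kernel, d) in ranked:
        t50, kclass = _mmej_t50(d, profile)
        outcomes.append(
            SimOutcome(
                ops=(EditOp(s, e, "deletion"),),
                weight=mmej_mass * kernel / kernel_total,
                kinetic_class=kclass,
                kinetics=_kp(t50),
                label=f"MMEJ -{d}",
            )
        )
    for op, kernel in ggcc_candidates:
        outcomes.append(
            SimOutcome(
                ops=(op,),
                weight=mmej_mass * kernel / kernel_total,
                kinetic_class="MMEJ_short",
                kinetics=_kp(GGCC_MMEJ_T50 * profile.mmej_t50_scale),
                label=f"-1 {cut_flanks[0]}|{cut_flanks[0]}",
            )
        )

    filler_mass = 1.0 - sum(o.weight for o in outcomes)
    if filler_mass > 1e-9:
        for d, share in ((2, 0.6), (3, 0.4)):
            op, label = _filler_op(ref, cut, d, rng)
            outcomes.append(
                SimOutcome(
                    ops=(op,),
                    weight=filler_mass * share,
                    kinetic_class="NHEJ",
                    kinetics=_kp(FILLER_NHEJ_T50 * profile.nhej_t50_scale),
                    label=label,
                )
            )

    # Inhibitor knobs scale whole classes; shares renormalize in the draw.
    scaled = []
    for o in outcomes:
        scale = config.nhej_scale if o.kinetic_class == "NHEJ" else config.mmej_scale
        scaled.append(replace(o, weight=o.weight * scale))
    outcomes = scaled

    hdr = None
    if config.donor is not None:
        if config.donor.insertion_point != cut:
            raise DataError("donor insertion point must equal the cut site")
        donor_edited_sequence(amplicon, config.donor)  # validates recognizability
        kp = KineticClassParams.from_t50(HDR_T50, HDR_DELAY_FRACTION)
        hdr = SimOutcome(
            ops=(EditOp(cut, cut, "insertion", config.donor.insert_sequence),),
            weight=config.hdr_propensity,
            kinetic_class="HDR",
            # the propensity knob accelerates the exponential stage
            kinetics=KineticClassParams(kp.delta, kp.mu / config.hdr_propensity),
            label=f"HDR +{len(config.donor.insert_sequence)}",
        )

    if config.editable_fraction is not None:
        editable = config.editable_fraction
    else:
        editable = float(rng.uniform(0.2, 0.6))
    return OutcomeModel(tuple(outcomes), editable_fraction=editable, hdr=hdr)


# ---------------------------------------------------------------------------
# Repair-race simulation


@dataclass(frozen=True)
class TrueTables:
    """Per-timepoint generating allele-frequency tables."""

    timepoints: tuple[float, ...]
    tables: Mapping[float, Mapping[tuple[EditOp, ...], float]]
    labels: Mapping[tuple[EditOp, ...], str]
    editable_fraction: float

    def frequencies(self, t: float) -> dict[tuple[EditOp, ...], float]:
        return dict(self.tables[t])

    def unedited_fraction(self, t: float) -> float:
        return 1.0 - sum(self.tables[t].values())


def simulate_locus(
    model: OutcomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TrueTables:
    """Monte Carlo repair race over ``config.depth`` cells.

    Each editable cell commits to an indel outcome (propensity-weighted)
    with a shifted-exponential completion time; with a donor present the
    cell also draws an HDR completion time and realizes the earlier
    channel.  A cell observed at time t shows its winning allele iff the
    winning completion time is <= t.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.depth
    tables: dict[float, dict[tuple[EditOp, ...], float]] = {
        t: {} for t in config.timepoints
    }
    labels = {o.ops: o.label for o in model.outcomes}
    if model.hdr is not None:
        labels[model.hdr.ops] = model.hdr.label
    if n == 0:
        return TrueTables(config.timepoints, tables, labels, model.editable_fraction)

    editable = rng.random(n) < model.editable_fraction
    k = int(editable.sum())
    if k == 0:
        return TrueTables(config.timepoints, tables, labels, model.editable_fraction)

    deltas = np.array([o.kinetics.delta for o in model.outcomes])
    mus = np.array([o.kinetics.mu for o in model.outcomes])
    idx = rng.choice(len(model.outcomes), size=k, p=model.weights)
    t_indel = deltas[idx] + rng.exponential(mus[idx])

    if model.hdr is not None:
        t_hdr = model.hdr.kinetics.delta + rng.exponential(model.hdr.kinetics.mu, size=k)
        no_donor = rng.random(k) >= config.donor_fraction
        t_hdr[no_donor] = np.inf
        hdr_wins = t_hdr < t_indel
        t_win = np.where(hdr_wins, t_hdr, t_indel)
    else:
        hdr_wins = np.zeros(k, dtype=bool)
        t_win = t_indel

    for t in config.timepoints:
        done = t_win <= t
        counts: dict[tuple[EditOp, ...], int] = {}
        indel_done = done & ~hdr_wins
        for i, count in zip(*np.unique(idx[indel_done], return_counts=True)):
            counts[model.outcomes[int(i)].ops] = int(count)
        n_hdr = int((done & hdr_wins).sum())
        if n_hdr and model.hdr is not None:
            counts[model.hdr.ops] = counts.get(model.hdr.ops, 0) + n_hdr
        tables[t] = {ops: c / n for ops, c in counts.items()}
    return TrueTables(config.timepoints, tables, labels, model.editable_fraction)


# ---------------------------------------------------------------------------
# Read generation


def _mutate_reads(
    seq: str, count: int, rate: float, rng: np.random.Generator
) -> list[str]:
    """``count`` copies of ``seq`` with iid substitution errors."""
    if count == 0:
        return []
    base = np.frombuffer(seq.encode(), dtype=np.uint8)
    if rate <= 0:
        return [seq] * count
    arr = np.tile(base, (count, 1))
    mask = rng.random(arr.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        # map A/C/G/T to 0..3, shift by 1-3, map back: always a different base
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        codes = lut[arr[mask]]
        shifted = (codes + rng.integers(1, 4, size=n_err)) % 4
        arr[mask] = _BASES[shifted]
    return [row.tobytes().decode() for row in arr]


def reads_from_frequencies(
    amplicon: Amplicon,
    frequencies: Mapping[tuple[EditOp, ...], float],
    config: SimulationConfig,
    barcode: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Sample paired-end reads from a generating allele table.

    Returns the read pairs plus the ground-truth read counts keyed by
    allele signature (``WT`` for unedited).  Fragments are the edited
    amplicon with the sample barcode prepended; R1 is the fragment 5'
    prefix, R2 the reverse-complement 5' prefix, both ``read_length``
    long, with iid substitution errors at ``config.error_rate`` and a
    constant phred score.
    """
    rng = rng or np.random.default_rng(config.seed)
    allele_list = list(frequencies.items())
    probs = [f for _, f in allele_list]
    unedited = 1.0 - sum(probs)
    if unedited < -1e-9:
        raise DataError("allele frequencies sum to more than 1")
    counts = rng.multinomial(config.depth, probs + [max(unedited, 0.0)])

    truth: dict[str, int] = {}
    pairs: list[ReadPair] = []
    entries = [(ops, int(c)) for (ops, _), c in zip(allele_list, counts[:-1])]
    entries.append(((), int(counts[-1])))
    for ops, count in entries:
        if count == 0:
            continue
        sig = allele_signature(ops)
        truth[sig] = truth.get(sig, 0) + count
        fragment = barcode + apply_allele(amplicon, ops)
        if len(fragment) < config.read_length:
            raise DataError("fragment shorter than the read length")
        r1_t = fragment[: config.read_length]
        r2_t = revcomp(fragment)[: config.read_length]
        qual = tuple([config.phred] * config.read_length)
        r1s = _mutate_reads(r1_t, count, config.error_rate, rng)
        r2s = _mutate_reads(r2_t, count, config.error_rate, rng)
        pairs.extend(
            ReadPair(r1, r2, qual, qual) for r1, r2 in zip(r1s, r2s)
        )
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order], truth


# ---------------------------------------------------------------------------
# Worked-example locus


def demo_timecourse_locus(seed: int = 0, depth: int = 50_000):
    """A packaged one-locus time-course dataset for demos and smoke tests.

    The locus carries a T at the -4 position and a planted 3-nt
    microhomology around a 4-nt deletion; the +1 duplication and that
    deletion are pinned to T50 = 5 h and 16 h respectively (worked
    example calibration).  Returns ``(amplicon, config, model, truth)``.
    """
    rng = np.random.default_rng(seed)
    amplicon = random_amplicon(
        rng, minus4="T", planted_microhomologies=((3, 4),), amplicon_id="demo_locus"
    )
    config = SimulationConfig(seed=seed, cell_profile="iPSC", depth=depth)
    model = build_outcome_model(amplicon, config, rng)

    cut = amplicon.cut_site
    mh4 = microhomology(
        amplicon.reference_sequence, cut - 2, cut + 2
    ).placements[0]
    pinned = []
    for o in model.outcomes:
        if o.label.endswith("duplication"):
            o = replace(o, kinetics=_kp(5.0))
        elif o.ops == (EditOp(mh4[0], mh4[1], "deletion"),):
            o = replace(o, kinetics=_kp(16.0))
        pinned.append(o)
    model = replace(model, outcomes=tuple(pinned))
    truth = simulate_locus(model, config, rng)
    return amplicon, config, model, truth
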