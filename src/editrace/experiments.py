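"""Calibration-recovery experiments: multi-locus simulated runs measured
end-to-end (reads -> merge -> demux -> call -> classify -> stats/kinetics).

These are the workloads behind the package's headline checks: the
simulator's documented defaults encode the calibration values, and the
pipeline must recover them from raw reads.
"""

from __future__ import annotations

import numpy as np

from .core import DonorSpec, EditraceError
from .kinetics import CategoryT50Summary, summarize_t50
from .pipeline import (
    fit_sample_kinetics,
    plus1_duplication_share,
    simulate_and_call_locus,
)
from .simulate import SimulationConfig, random_amplicon
from .stats import CompetitionResult, competition_delta

__all__ = [
    "plus1_share_experiment",
    "competition_experiment",
    "t50_recovery_experiment",
    "T50_CALIBRATION_TARGETS",
]

# category -> generating class T50 (hours), iPSC profile
T50_CALIBRATION_TARGETS = {
    "+T|NHEJ": 6.2,
    "+A|NHEJ": 7.8,
    "+C|NHEJ": 7.9,
    "+G|NHEJ": 6.6,
    "-3 to -5|MMEJ": 18.4,
    "-6 to -9|MMEJ": 19.9,
    ">= -10|MMEJ": 23.9,
}

DEFAULT_PLANTED = ((3, 4), (4, 12))


def plus1_share_experiment(
    seed: int,
    n_loci: int = 50,
    depth: int = 20_000,
    cell_profile: str = "T",
    minus4: str = "T",
) -> tuple[float, list[float]]:
    """Mean +1-duplication share of edited events (percent) at 48 h.

    Each locus is an independent random amplicon with the requested -4
    base, simulated at a single 48-h timepoint (no donor) and pushed
    through the full read-level pipeline.
    """
    master = np.random.default_rng(seed)
    shares = []
    for _ in range(n_loci):
        locus_seed = int(master.integers(2**31))
        cfg = SimulationConfig(
            seed=locus_seed, cell_profile=cell_profile, depth=depth,
            timepoints=(48.0,),
        )
        run = simulate_and_call_locus(
            cfg, rng=np.random.default_rng(locus_seed), minus4=minus4
        )
        shares.append(100.0 * plus1_duplication_share(run.samples[48.0], run.amplicon))
    return float(np.mean(shares)), shares


def _random_donor(rng: np.random.Generator, amplicon, length: int = 8) -> DonorSpec:
    from .core import donor_edited_sequence

    for _ in range(50):
        insert = "".join(rng.choice(list("ACGT"), size=length))
        donor = DonorSpec(insert, amplicon.cut_site)
        try:
            donor_edited_sequence(amplicon, donor)
        except EditraceError:
            continue
        return donor
    raise EditraceError("could not design a non-recuttable donor insert")


def competition_experiment(
    seed: int,
    n_loci: int = 20,
    depth: int = 20_000,
    cell_profile: str = "iPSC",
    planted=DEFAULT_PLANTED,
) -> CompetitionResult:
    """Donor-present vs donor-absent 48-h competition over paired loci.

    Loci carry planted microhomologies (a short and a >=10 nt deletion
    candidate) so every locus exposes the long-MMEJ bin.  Each pair
    shares the amplicon and editable fraction; only the donor differs.
    """
    master = np.random.default_rng(seed)
    pairs, amplicons, donors = [], {}, {}
    for i in range(n_loci):
        locus_seed = int(master.integers(2**31))
        rng = np.random.default_rng(locus_seed)
        amplicon = random_amplicon(
            rng, planted_microhomologies=planted, amplicon_id=f"locus{i:03d}"
        )
        donor = _random_donor(rng, amplicon)
        editable = float(rng.uniform(0.2, 0.6))
        common = dict(
            cell_profile=cell_profile, depth=depth, timepoints=(48.0,),
            editable_fraction=editable,
        )
        run_nd = simulate_and_call_locus(
            SimulationConfig(seed=locus_seed, **common),
            rng=np.random.default_rng(locus_seed + 1),
            amplicon=amplicon,
        )
        run_d = simulate_and_call_locus(
            SimulationConfig(seed=locus_seed, donor=donor, **common),
            rng=np.random.default_rng(locus_seed + 2),
            amplicon=amplicon,
        )
        pairs.append((run_nd.samples[48.0], run_d.samples[48.0]))
        amplicons[amplicon.id] = amplicon
        donors[amplicon.id] = donor
    return competition_delta(pairs, amplicons, donors)


def t50_recovery_experiment(
    seed: int,
    n_loci: int = 8,
    depth: int = 20_000,
    minus4_cycle: tuple[str, ...] = ("T", "A", "C", "G"),
    planted=DEFAULT_PLANTED,
) -> list[CategoryT50Summary]:
    """Category-mean T50s recovered by the full pipeline (iPSC defaults).

    Loci cycle through the requested -4 bases so every +1 category is
    populated; summaries are keyed ``category|repair_class``.
    """
    master = np.random.default_rng(seed)
    fits = []
    for i in range(n_loci):
        locus_seed = int(master.integers(2**31))
        cfg = SimulationConfig(seed=locus_seed, cell_profile="iPSC", depth=depth)
        run = simulate_and_call_locus(
            cfg,
            rng=np.random.default_rng(locus_seed),
            minus4=minus4_cycle[i % len(minus4_cycle)],
            planted_microhomologies=planted,
        )
        for label, rclass, fit in fit_sample_kinetics(
            list(run.samples.values()), run.amplicon
        ):
            if label:
                fits.append((f"{label}|{rclass}", fit))
    return summarize_t50(fits)
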