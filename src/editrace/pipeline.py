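"""End-to-end orchestration: simulate -> merge -> demux -> call -> classify
-> kinetics -> stats, in memory.

These drivers tie the stage functions together for experiments that run
entirely on simulated data (each locus gets its own amplicon, outcome
model, and read set), and are what the CLI and the acceptance checks
call.  Every function threads a single seeded generator, so a run is
fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .calling import call_sample, editing_efficiency
from .classify import categorize, classify, is_plus1_duplication
from .core import Amplicon, DataError, DonorSpec, SampleTable
from .kinetics import KineticFit, TimeCourse, fit_t50
from .reads import BarcodeTable, demultiplex, merge_pairs
from .simulate import (
    OutcomeModel,
    SimulationConfig,
    TrueTables,
    build_outcome_model,
    random_amplicon,
    reads_from_frequencies,
    simulate_locus,
)
from .stats import relative_frequencies

__all__ = [
    "CallingParams",
    "LocusRun",
    "process_read_pairs",
    "simulate_and_call_locus",
    "classify_sample",
    "plus1_duplication_share",
    "timecourses_from_samples",
    "fit_sample_kinetics",
]

DEFAULT_BARCODE = "ACGTGTCA"


@dataclass(frozen=True)
class CallingParams:
    window: int = 50
    min_count: int = 2
    min_freq: float = 0.0005
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1


@dataclass
class LocusRun:
    """One simulated locus pushed through the full pipeline."""

    amplicon: Amplicon
    config: SimulationConfig
    model: OutcomeModel
    truth: TrueTables
    samples: dict[float, SampleTable]  # timepoint -> called sample
    n_unmerged: dict[float, int]
    read_truth: dict[float, dict[str, int]]  # timepoint -> signature -> reads


def process_read_pairs(
    pairs,
    amplicon: Amplicon,
    params: CallingParams = CallingParams(),
    barcode: str = DEFAULT_BARCODE,
    condition: str = "donor_absent",
    timepoint_h: float = 48.0,
) -> tuple[SampleTable, int]:
    """Merge, demultiplex (single-sample), and call one read set."""
    merged, n_unmerged = merge_pairs(
        pairs, min_overlap=params.min_overlap, max_mismatch_frac=params.max_mismatch_frac
    )
    table = BarcodeTable(samples=((f"{amplicon.id}_s", barcode, amplicon.id),))
    bins, unassigned = demultiplex(merged, table)
    reads = [m.seq for m in bins[f"{amplicon.id}_s"]]
    sample = call_sample(
        reads,
        amplicon,
        window=params.window,
        min_count=params.min_count,
        min_freq=params.min_freq,
        condition=condition,
        timepoint_h=timepoint_h,
    )
    return sample, n_unmerged + len(unassigned)


def simulate_and_call_locus(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    amplicon: Amplicon | None = None,
    minus4: str | None = None,
    planted_microhomologies: Sequence[tuple[int, int]] = (),
    params: CallingParams = CallingParams(),
) -> LocusRun:
    """Simulate one locus and run the read-level pipeline at every timepoint."""
    rng = rng or np.random.default_rng(config.seed)
    if amplicon is None:
        amplicon = random_amplicon(
            rng,
            length=config.amplicon_length,
            minus4=minus4,
            planted_microhomologies=planted_microhomologies,
        )
    model = build_outcome_model(amplicon, config, rng)
    truth = simulate_locus(model, config, rng)
    condition = "donor_present" if config.donor is not None else "donor_absent"

    samples: dict[float, SampleTable] = {}
    unmerged: dict[float, int] = {}
    read_truth: dict[float, dict[str, int]] = {}
    for t in config.timepoints:
        pairs, truth_counts = reads_from_frequencies(
            amplicon, truth.tables[t], config, barcode=DEFAULT_BARCODE, rng=rng
        )
        sample, n_dropped = process_read_pairs(
            pairs, amplicon, params=params, condition=condition, timepoint_h=t
        )
        samples[t] = sample
        unmerged[t] = n_dropped
        read_truth[t] = truth_counts
    return LocusRun(amplicon, config, model, truth, samples, unmerged, read_truth)


def classify_sample(
    sample: SampleTable,
    amplicon: Amplicon,
    donor: DonorSpec | None = None,
    scheme: str = "seven_group",
) -> SampleTable:
    """Attach repair classes and category labels to a called sample."""
    classified = []
    for allele in sample.alleles:
        call = classify(allele, amplicon, donor=donor)
        label = categorize(call, allele, amplicon, scheme)
        classified.append(
            replace(allele, repair_class=call.repair_class, category=label or "")
        )
    out = replace(sample)
    out.alleles = classified
    return out


def plus1_duplication_share(sample: SampleTable, amplicon: Amplicon) -> float:
    """Share of edited events that are -4-base +1 duplications."""
    shares = relative_frequencies(sample)
    total = 0.0
    for allele in sample.alleles:
        if is_plus1_duplication(allele, amplicon) is not None:
            total += shares[allele.signature]
    return total


def timecourses_from_samples(
    samples: Sequence[SampleTable], min_points: int = 4
) -> list[TimeCourse]:
    """Assemble per-pattern trajectories from one locus's timepoint samples.

    A pattern's frequency is taken as 0 at timepoints where it was not
    called.  ``total_indels_final`` is the total edited fraction of the
    final-timepoint sample.
    """
    ordered = sorted(samples, key=lambda s: s.timepoint_h)
    if len(ordered) < min_points:
        raise DataError(f"need at least {min_points} timepoints")
    times = [s.timepoint_h for s in ordered]
    if len(set(times)) != len(times):
        raise DataError("duplicate timepoints for one locus/condition")
    total_final = editing_efficiency(ordered[-1])
    signatures: dict[str, dict[float, float]] = {}
    for s in ordered:
        for a in s.alleles:
            signatures.setdefault(a.signature, {})[s.timepoint_h] = a.frequency
    return [
        TimeCourse(
            pattern_id=sig,
            points=tuple((t, freqs.get(t, 0.0)) for t in times),
            total_indels_final=total_final,
        )
        for sig, freqs in sorted(signatures.items())
    ]


def fit_sample_kinetics(
    samples: Sequence[SampleTable],
    amplicon: Amplicon,
    donor: DonorSpec | None = None,
    scheme: str = "t50_bins",
) -> list[tuple[str | None, str, KineticFit]]:
    """Fit T50 for every pattern of one locus.

    Returns (category label, repair class, fit) triples; patterns are
    classified from their final-timepoint allele.
    """
    final = max(samples, key=lambda s: s.timepoint_h)
    results = []
    for tc in timecourses_from_samples(samples):
        allele = final.allele_by_signature(tc.pattern_id)
        if allele is None:
            continue
        call = classify(allele, amplicon, donor=donor)
        label = categorize(call, allele, amplicon, scheme)
        results.append((label, call.repair_class, fit_t50(tc)))
    return results


# ---------------------------------------------------------------------------
# Config-driven full runs


def validate_run_config(config: dict) -> dict:
    """Validate a pipeline config mapping; returns it with defaults filled.

    Raises :class:`~editrace.core.ConfigError` naming the offending field.
    """
    from .core import ConfigError
    from .simulate import CELL_PROFILES

    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    out = dict(config)
    out.setdefault("seed", 0)
    if not isinstance(out["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    loci = out.get("loci")
    if not isinstance(loci, list) or not loci:
        raise ConfigError("field 'loci' must be a non-empty list")
    for i, locus in enumerate(loci):
        if not isinstance(locus, dict) or "id" not in locus:
            raise ConfigError(f"field 'loci[{i}].id' is required")
        m4 = locus.get("minus4")
        if m4 is not None and m4 not in "ACGT":
            raise ConfigError(f"field 'loci[{i}].minus4' must be one of A/C/G/T")
        donor = locus.get("donor_insert")
        if donor is not None and (not isinstance(donor, str) or set(donor) - set("ACGT")):
            raise ConfigError(f"field 'loci[{i}].donor_insert' must be a DNA string")
    sim = out.setdefault("simulation", {})
    if not isinstance(sim, dict):
        raise ConfigError("field 'simulation' must be a mapping")
    profile = sim.get("cell_profile", "iPSC")
    if profile not in CELL_PROFILES:
        raise ConfigError(
            f"field 'simulation.cell_profile' must be one of {sorted(CELL_PROFILES)}"
        )
    calling = out.setdefault("calling", {})
    if not isinstance(calling, dict):
        raise ConfigError("field 'calling' must be a mapping")
    for key in calling:
        if key not in ("window", "min_count", "min_freq", "min_overlap", "max_mismatch_frac"):
            raise ConfigError(f"unknown field 'calling.{key}'")
    return out


def run_pipeline(config: dict, output_dir) -> dict:
    """Simulate every configured locus and run all stages; write the bundle.

    Writes allele tables (classified), kinetics tables, a stats JSON and
    a run log carrying the package version, seed, and full parameter
    snapshot.  Returns a manifest of output paths.
    """
    import json
    from pathlib import Path

    from . import __version__
    from .core import DonorSpec
    from .io import config_hash, write_sample_tables, write_table
    from .kinetics import summarize_t50
    from .stats import gini_top_n

    import pandas as pd

    config = validate_run_config(config)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    sim_kwargs = dict(config.get("simulation", {}))
    calling = CallingParams(**config.get("calling", {}))
    master = np.random.default_rng(seed)

    all_samples = []
    kinetics_rows = []
    stats_summary = {}
    for locus in config["loci"]:
        locus_seed = int(master.integers(2**31))
        rng = np.random.default_rng(locus_seed)
        planted = [tuple(p) for p in locus.get("planted_microhomologies", [])]
        amplicon = random_amplicon(
            rng,
            length=int(sim_kwargs.get("amplicon_length", 240)),
            minus4=locus.get("minus4"),
            planted_microhomologies=planted,
            amplicon_id=locus["id"],
        )
        donor = None
        if locus.get("donor_insert"):
            donor = DonorSpec(locus["donor_insert"], amplicon.cut_site)
        cfg = SimulationConfig(
            seed=locus_seed,
            donor=donor,
            **{
                k: (tuple(v) if k == "timepoints" else v)
                for k, v in sim_kwargs.items()
                if k != "amplicon_length"
            },
        )
        run = simulate_and_call_locus(cfg, rng=rng, amplicon=amplicon, params=calling)
        samples = [
            classify_sample(s, amplicon, donor=donor)
            for _, s in sorted(run.samples.items())
        ]
        all_samples.extend(samples)
        if len(samples) >= 4:
            for label, rclass, fit in fit_sample_kinetics(
                list(run.samples.values()), amplicon, donor=donor
            ):
                kinetics_rows.append(
                    {
                        "amplicon_id": amplicon.id,
                        "condition": samples[0].condition,
                        "pattern": fit.pattern_id,
                        "repair_class": rclass,
                        "category": label or "",
                        "t50": fit.t50,
                        "f_max": fit.f_max,
                        "rss": fit.rss,
                        "method": fit.method,
                        "eligible": fit.eligible,
                    }
                )
        final = samples[-1]
        locus_stats = {"editing_efficiency": editing_efficiency(final)}
        if donor is None and final.alleles:
            locus_stats["gini_top5"] = gini_top_n(final)
        stats_summary[amplicon.id] = locus_stats

    manifest = {}
    alleles_path = output_dir / "alleles.tsv"
    write_sample_tables(all_samples, alleles_path, config=config)
    manifest["alleles"] = str(alleles_path)

    if kinetics_rows:
        kin_path = output_dir / "kinetics.tsv"
        write_table(pd.DataFrame(kinetics_rows), kin_path, config=config)
        manifest["kinetics"] = str(kin_path)
        summaries = summarize_t50(
            (f"{r['category']}|{r['repair_class']}", KineticFit(
                r["pattern"], r["t50"], r["f_max"], r["rss"], r["method"], r["eligible"]
            ))
            for r in kinetics_rows
            if r["category"]
        )
        summary_path = output_dir / "kinetics_summary.tsv"
        write_table(
            pd.DataFrame([s.__dict__ for s in summaries]), summary_path, config=config
        )
        manifest["kinetics_summary"] = str(summary_path)

    stats_path = output_dir / "stats.json"
    stats_path.write_text(json.dumps(stats_summary, indent=2, sort_keys=True))
    manifest["stats"] = str(stats_path)

    log_path = output_dir / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "editrace_version": __version__,
                "seed": seed,
                "config": config,
                "config_hash": config_hash(config),
                "outputs": manifest,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    manifest["run_log"] = str(log_path)
    return manifest
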