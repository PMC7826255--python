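"""Dispersion, competition, and concordance statistics over allele tables.

The Gini coefficient here is the plain relative mean absolute difference
over the top-n pattern percentages (zero-padded to n), quantifying how
concentrated editing is in a few dominant patterns.  Competition deltas
measure how each repair category's share of edited events responds to
the presence of an HDR donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .calling import editing_efficiency, top_n_patterns
from .classify import categorize, classify
from .core import Amplicon, DataError, DonorSpec, SampleTable

__all__ = [
    "gini_top_n",
    "gini_coefficient",
    "relative_frequencies",
    "category_shares",
    "competition_delta",
    "CompetitionResult",
    "pearson_r2",
    "compare_external_predictions",
]

COMPETITION_BIN_ORDER = ("+1", "-1", "-2 to -5", "-6 to -9", "-10 to -30", "HDR")


def gini_coefficient(values: Sequence[float]) -> float:
    """Relative mean absolute difference: sum|xi-xj| / (2 n^2 mean)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or x.sum() <= 0:
        raise DataError("Gini requires a non-empty, non-zero share vector")
    if (x < 0).any():
        raise DataError("Gini shares must be non-negative")
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2 * x.size ** 2 * x.mean()))


def gini_top_n(sample: SampleTable, n: int = 5) -> float:
    """Gini coefficient of the top-n edited pattern percentages.

    Fewer than n patterns are padded with zeros.  Defined on donor-absent
    editing patterns; HDR alleles are excluded if present.
    """
    alleles = [a for a in top_n_patterns(sample, n=len(sample.alleles) or 1)
               if a.repair_class != "HDR"][:n]
    if not alleles:
        raise DataError("Gini requires at least one edited allele")
    shares = [a.frequency * 100 for a in alleles]
    shares += [0.0] * (n - len(shares))
    return gini_coefficient(shares)


def relative_frequencies(sample: SampleTable) -> dict[str, float]:
    """Per-allele share of edited events (signature -> share, sums to 1)."""
    eff = editing_efficiency(sample)
    if eff <= 0:
        raise DataError("no edited alleles; relative frequencies undefined")
    return {a.signature: a.frequency / eff for a in sample.alleles}


def category_shares(
    sample: SampleTable,
    amplicon: Amplicon,
    donor: DonorSpec | None = None,
    scheme: str = "competition_bins",
) -> dict[str, float]:
    """Share of edited events per category bin (classifies on the fly)."""
    shares = relative_frequencies(sample)
    out: dict[str, float] = {}
    for allele in sample.alleles:
        call = classify(allele, amplicon, donor=donor)
        label = categorize(call, allele, amplicon, scheme)
        if label is None:
            continue
        out[label] = out.get(label, 0.0) + shares[allele.signature]
    return out


@dataclass(frozen=True)
class CompetitionResult:
    """Per-bin relative share change (donor present vs absent)."""

    deltas: dict[str, float]  # bin -> (share_donor - share_no_donor) / share_no_donor
    shares_absent: dict[str, float]
    shares_present: dict[str, float]
    t_statistics: dict[str, tuple[float, float]] | None = None  # bin -> (t, p)


def competition_delta(
    pairs: Sequence[tuple[SampleTable, SampleTable]],
    amplicons: Mapping[str, Amplicon],
    donors: Mapping[str, DonorSpec],
    scheme: str = "competition_bins",
) -> CompetitionResult:
    """Donor-present vs donor-absent share changes, averaged across loci.

    ``pairs`` holds (donor_absent, donor_present) sample pairs from the
    same amplicon.  Each bin's delta is computed per locus on shares of
    edited events and averaged; bins absent from a locus's no-donor
    sample are omitted for that locus.  With >= 2 loci a paired
    two-sided t statistic on the shares is reported per bin.
    """
    per_bin_deltas: dict[str, list[float]] = {}
    per_bin_absent: dict[str, list[float]] = {}
    per_bin_present: dict[str, list[float]] = {}
    paired_shares: dict[str, list[tuple[float, float]]] = {}

    for sample_nd, sample_d in pairs:
        if sample_nd.amplicon_id != sample_d.amplicon_id:
            raise DataError("competition pair spans different amplicons")
        amplicon = amplicons[sample_nd.amplicon_id]
        donor = donors[sample_nd.amplicon_id]
        shares_nd = category_shares(sample_nd, amplicon, donor=None, scheme=scheme)
        shares_d = category_shares(sample_d, amplicon, donor=donor, scheme=scheme)
        bins = set(shares_nd) | set(shares_d)
        for label in bins:
            a = shares_nd.get(label, 0.0)
            b = shares_d.get(label, 0.0)
            per_bin_absent.setdefault(label, []).append(a)
            per_bin_present.setdefault(label, []).append(b)
            paired_shares.setdefault(label, []).append((a, b))
            if a > 0:
                per_bin_deltas.setdefault(label, []).append((b - a) / a)

    if not per_bin_absent:
        raise DataError("no classified bins in competition input")

    deltas = {k: float(np.mean(v)) for k, v in per_bin_deltas.items()}
    shares_absent = {k: float(np.mean(v)) for k, v in per_bin_absent.items()}
    shares_present = {k: float(np.mean(v)) for k, v in per_bin_present.items()}

    t_statistics = None
    if len(pairs) >= 2:
        t_statistics = {}
        for label, values in paired_shares.items():
            if len(values) < 2:
                continue
            a, b = zip(*values)
            if np.allclose(a, b):
                continue
            t, p = sps.ttest_rel(b, a)
            t_statistics[label] = (float(t), float(p))
    return CompetitionResult(deltas, shares_absent, shares_present, t_statistics)


def pearson_r2(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("pearson_r2 needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("pearson_r2 is undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r**2), float(p)


def compare_external_predictions(
    observed: Mapping[str, float],
    predicted: Mapping[str, float],
    classes: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, float]]:
    """Concordance of observed vs externally predicted pattern shares.

    Parameters
    ----------
    observed, predicted : mapping
        Pattern signature -> frequency.  Signatures must already be in
        the package's canonical form (see :func:`editrace.core.op_signature`);
        adapters for external CSV dialects only rewrite signatures.
    classes : mapping
        Class name -> list of signatures belonging to that class (e.g.
        the +1 insertions, or the MMEJ deletions).

    Returns per class: ``r2``, ``p``, ``n`` (matched patterns) and
    ``unmatched_predicted_mass`` (total predicted frequency with no
    observed counterpart in that class).
    """
    out: dict[str, dict[str, float]] = {}
    for name, signatures in classes.items():
        obs, pred = [], []
        unmatched = 0.0
        for sig in signatures:
            if sig in observed and sig in predicted:
                obs.append(observed[sig])
                pred.append(predicted[sig])
            elif sig in predicted:
                unmatched += predicted[sig]
        if len(obs) < 3:
            raise DataError(
                f"class {name!r}: fewer than 3 common patterns between "
                "observed and predicted tables"
            )
        r2, p = pearson_r2(obs, pred)
        out[name] = {
            "r2": r2,
            "p": p,
            "n": len(obs),
            "unmatched_predicted_mass": unmatched,
        }
    return out
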