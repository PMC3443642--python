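"""Pearson correlation with two-tailed t significance, and the break/repair
vs crossing-over correlation suite.

Significance follows the product-moment convention: for n pairs,
``t = r * sqrt((n-2) / (1 - r^2))`` referred to a t distribution with n-2
degrees of freedom (two-tailed), where n is the number of deletion bins
entering the comparison.  Pairs with a missing value in either variable are
dropped before computing r (a bin lacking genetic-map coverage contributes
nothing to any comparison involving crossing-over frequency).

The suite pairs the per-bin metrics the way the analysis uses them:
BR vs CO frequency, each frequency vs distance from the centromere, number
of deletions vs their mean size, each frequency vs deletion number / mean
size / marker deletion frequency.  Because the metric used for "distance
from the centromere" is a convention, it is computed from fractional bin
midpoints and can be reported in Mb or as a bare arm fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import BinRecord
from .deletions import BinDeletionSummary
from .metrics import BinMetrics


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    t_stat: float
    p_two_tailed: float
    significant_at: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.significant_at is None:
            return None
        return self.p_two_tailed < self.significant_at


def pearson(
    x: Sequence[float | None],
    y: Sequence[float | None],
    *,
    alpha: float | None = None,
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t test at n-2
    degrees of freedom.  None/NaN pairs are dropped; fewer than 3 complete
    pairs or zero variance raise ``ValueError``."""
    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if a is not None and b is not None and np.isfinite(a) and np.isfinite(b)
    ]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(pairs)}")
    xa = np.array([p[0] for p in pairs])
    ya = np.array([p[1] for p in pairs])
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    n = len(pairs)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(
        r=r,
        n=n,
        df=df,
        t_stat=float(t),
        p_two_tailed=float(res.pvalue),
        significant_at=alpha,
    )


def centromere_distance(
    bin_record: BinRecord, arm_mb: float, *, units: str = "mb"
) -> float:
    """Distance of a bin from the centromere.

    The bin's fractional interval runs from the centromere (fraction 0) to
    the telomere (fraction 1) of its arm; the distance is the arm length
    scaled by the bin's fractional midpoint (or the bare midpoint with
    ``units='fraction'``).  Centromeric bins (named from fraction 0) follow
    the same rule.
    """
    mid = 0.5 * (bin_record.frac_start + bin_record.frac_end)
    if units == "fraction":
        return mid
    if units == "mb":
        return mid * arm_mb
    raise ValueError(f"units must be 'mb' or 'fraction', got {units!r}")


#: comparisons of the correlation suite: name -> (x attribute, y attribute)
SUITE_PAIRS = (
    ("br_vs_co", "br_freq", "co_freq"),
    ("co_vs_centromere_distance", "co_freq", "centromere_distance"),
    ("br_vs_centromere_distance", "br_freq", "centromere_distance"),
    ("n_deletions_vs_mean_size", "n_deletions", "mean_size_mb"),
    ("co_vs_n_deletions", "co_freq", "n_deletions"),
    ("br_vs_n_deletions", "br_freq", "n_deletions"),
    ("co_vs_mean_size", "co_freq", "mean_size_mb"),
    ("br_vs_mean_size", "br_freq", "mean_size_mb"),
    ("co_vs_deletion_frequency", "co_freq", "mean_deletion_frequency"),
    ("br_vs_deletion_frequency", "br_freq", "mean_deletion_frequency"),
)


def correlation_suite(
    bin_metrics: Sequence[BinMetrics],
    deletion_summaries: Mapping[str, BinDeletionSummary] | None = None,
    centromere_distances: Mapping[str, float] | None = None,
    *,
    alpha: float = 0.05,
) -> dict[str, CorrelationResult | None]:
    """Run every pairwise correlation of the suite over the deletion bins.

    Bins missing a variable are dropped pairwise; a comparison with fewer
    than 3 usable bins, or whose inputs were not supplied at all, reports
    None.  The output is keyed by comparison name and is invariant to the
    ordering of the input bins.
    """
    bins = sorted(bin_metrics, key=lambda m: m.bin_name)
    values: dict[str, list[float | None]] = {
        "br_freq": [m.br_freq for m in bins],
        "co_freq": [m.co_freq for m in bins],
    }
    if centromere_distances is not None:
        values["centromere_distance"] = [
            centromere_distances.get(m.bin_name) for m in bins
        ]
    if deletion_summaries is not None:
        summ = [deletion_summaries.get(m.bin_name) for m in bins]
        values["n_deletions"] = [
            float(s.n_deletions) if s is not None else None for s in summ
        ]
        values["mean_size_mb"] = [
            s.mean_size_mb if s is not None else None for s in summ
        ]
        values["mean_deletion_frequency"] = [
            s.mean_deletion_frequency if s is not None else None for s in summ
        ]
    out: dict[str, CorrelationResult | None] = {}
    for name, xk, yk in SUITE_PAIRS:
        if xk not in values or yk not in values:
            out[name] = None
            continue
        try:
            out[name] = pearson(values[xk], values[yk], alpha=alpha)
        except ValueError:
            out[name] = None
    return out


def deletion_frequency_uniformity(
    per_line_bin_freqs: np.ndarray,
) -> tuple[float, float]:
    """Heterogeneity test of per-bin marker deletion frequencies.

    ``per_line_bin_freqs`` is a lines x bins array: for each informative
    line, the fraction of each bin's markers scored DELETED.  Lines are the
    independent replication unit (markers within a bin share deletions, so
    marker-level counts are over-dispersed, and one deletion can straddle a
    bin border, correlating neighbouring bins).  The statistic is the
    chi-square-type Hotelling contrast form
    ``n * (C xbar)' (C S C')^{-1} (C xbar)`` for the bins-1 adjacent-
    difference contrasts C, with S the line-level covariance.  Because the
    per-line fractions are strongly zero-inflated, the asymptotic
    chi-square (or finite-sample F) reference over-rejects at these sample
    sizes; the p value is instead calibrated by a seeded centred bootstrap
    over lines, which is conservative under the null while still flagging
    gross non-uniformity.  p > alpha means no detectable difference in
    deletion frequency between bins.
    """
    x = np.asarray(per_line_bin_freqs, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a lines x bins array with >=2 bins")
    x = x[~np.isnan(x).any(axis=1)]
    n, b = x.shape
    if n < b + 2:
        raise ValueError("need more complete lines than bins to test uniformity")

    def _stat(d: np.ndarray) -> float:
        m = d.shape[0]
        dbar = d.mean(axis=0)
        cov = np.cov(d, rowvar=False, ddof=1)
        return float(m * dbar @ np.linalg.pinv(cov) @ dbar)

    diffs = np.diff(x, axis=1)               # adjacent-bin contrasts
    stat = _stat(diffs)
    centered = diffs - diffs.mean(axis=0)
    rng = np.random.default_rng(_UNIFORMITY_BOOT_SEED)
    exceed = sum(
        _stat(centered[rng.integers(0, n, n)]) >= stat
        for _ in range(_UNIFORMITY_N_BOOT)
    )
    p = float((exceed + 1) / (_UNIFORMITY_N_BOOT + 1))
    return stat, p


# resampling depth / seed of the uniformity test's null calibration
_UNIFORMITY_N_BOOT = 300
_UNIFORMITY_BOOT_SEED = 20120724
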