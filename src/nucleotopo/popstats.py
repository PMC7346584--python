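"""Nonparametric population comparisons of per-signal nuclear metrics.

Distributions of per-signal quantities (normalized radius r, area
fraction S_norm, inter-signal distance d and angle alpha, AgNOR metrics)
pooled over the cells of a population are compared between conditions
with the two-sample Kolmogorov-Smirnov statistic D (with its asymptotic
significance level) and the Mann-Whitney U test, both reported alongside
group medians; differences are called significant at p < 0.01.

The radius threshold r = 0.75 splits each sample into a peripheral
(r > 0.75) and an interior (r < 0.75) fraction; the ratio of median
signal-area fractions between the two groups is the size-disproportion
statistic: ~1 when signal size is independent of radial position, > 1
when only small signals occupy the interior.

Conventions: signals are pooled across nuclei by default (each signal
is an observation); ``aggregate="nucleus"`` switches to per-nucleus
medians for sensitivity analysis.  Ties at the split threshold go to
the peripheral group.  U is reported as min(U_x, U_y); its p-value is
exact by enumeration for small tie-free samples (n_x + n_y <= 16) and
uses the normal approximation with tie and continuity corrections
otherwise.  The KS significance uses the asymptotic Kolmogorov law at
the effective size n_x*n_y/(n_x+n_y) with the standard finite-n
argument (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "EmpiricalDistribution",
    "TwoSampleResult",
    "FractionSplit",
    "ks_two_sample",
    "mann_whitney",
    "two_sample_compare",
    "split_by_threshold",
    "compare_conditions",
    "extract_metric",
    "cumulative_histogram",
    "SIGNIFICANCE_LEVEL",
    "METRICS",
]

SIGNIFICANCE_LEVEL = 0.01
METRICS = (
    "r", "S_norm", "d_norm", "alpha_deg",
    "S_agnor", "r_agnor", "agnor_count", "nucleolus_dist",
)


class EmpiricalDistribution:
    """Sorted sample with ECDF evaluation and cumulative histogram."""

    def __init__(self, values):
        vals = np.asarray(values, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("empty sample")
        self.values = np.sort(vals)
        self.n = int(vals.size)

    def ecdf(self, x) -> np.ndarray | float:
        out = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right") / self.n
        return out if np.ndim(x) else float(out)

    def cumulative_histogram(self, bins: int = 20, upper: float | None = None):
        """Cumulative counts over equal bins on [0, upper]; the final
        bin count equals n."""
        hi = upper if upper is not None else max(1.0, float(self.values.max()))
        edges = np.linspace(0.0, hi, bins + 1)
        counts, _ = np.histogram(np.clip(self.values, 0.0, hi), bins=edges)
        return edges, np.cumsum(counts)

    def median(self) -> float:
        return float(np.median(self.values))


def cumulative_histogram(values, bins: int = 20, upper: float | None = None):
    return EmpiricalDistribution(values).cumulative_histogram(bins, upper)


@dataclass(frozen=True)
class TwoSampleResult:
    """KS + Mann-Whitney comparison of two pooled samples."""

    D: float
    ks_sig: float  # asymptotic KS significance level
    U: float  # min(U_x, U_y)
    p: float  # two-sided Mann-Whitney p
    median_x: float
    median_y: float
    n_x: int
    n_y: int

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        return dict(
            D=self.D, ks_sig=self.ks_sig, U=self.U, p=self.p,
            median_x=self.median_x, median_y=self.median_y,
            n_x=self.n_x, n_y=self.n_y, significant=self.significant,
        )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic D and its asymptotic significance.

    D is the exact sup over the pooled order statistics of
    |ECDF_x - ECDF_y| (both step functions are right-continuous, so the
    sup is attained at a pooled data point).
    """
    ex, ey = EmpiricalDistribution(x), EmpiricalDistribution(y)
    pooled = np.concatenate([ex.values, ey.values])
    d = float(np.max(np.abs(ex.ecdf(pooled) - ey.ecdf(pooled))))
    ne = ex.n * ey.n / (ex.n + ey.n)
    en = math.sqrt(ne)
    sig = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, min(max(sig, 0.0), 1.0)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (as min(U_x, U_y)) and two-sided p-value.

    Exact enumeration for tie-free samples with n_x + n_y <= 16, else
    normal approximation with midranks, tie correction and continuity
    correction.
    """
    ex, ey = EmpiricalDistribution(x), EmpiricalDistribution(y)
    pooled = np.concatenate([ex.values, ey.values])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and ex.n + ey.n <= 16) else "asymptotic"
    res = stats.mannwhitneyu(ex.values, ey.values, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u = min(u_x, ex.n * ey.n - u_x)
    return u, float(min(res.pvalue, 1.0))


def two_sample_compare(x, y) -> TwoSampleResult:
    """Run both tests and report medians and sizes."""
    ex, ey = EmpiricalDistribution(x), EmpiricalDistribution(y)
    d, sig = ks_two_sample(ex.values, ey.values)
    u, p = mann_whitney(ex.values, ey.values)
    return TwoSampleResult(d, sig, u, p, ex.median(), ey.median(), ex.n, ey.n)


@dataclass
class FractionSplit:
    """Peripheral/interior split of per-signal area fractions at a
    radius threshold (ties and r > 1 go peripheral)."""

    threshold: float
    peripheral: np.ndarray  # S_norm of signals with r >= threshold
    interior: np.ndarray  # S_norm of signals with r < threshold
    median_peripheral: float | None = None
    median_interior: float | None = None
    median_ratio: float | None = None
    ratio_ci: tuple[float, float] | None = None
    comparison: TwoSampleResult | None = None
    empty_group: bool = False
    extra: dict = field(default_factory=dict)


def split_by_threshold(
    r_values,
    s_values,
    threshold: float = 0.75,
    n_boot: int = 1000,
    seed: int = 0,
) -> FractionSplit:
    """Split signals at the radius threshold and compare the area
    fractions of the two groups.

    ``r_values`` and ``s_values`` are parallel per-signal arrays.  The
    median-area ratio peripheral/interior comes with a seeded bootstrap
    95% CI.  If either group is empty the comparison and ratio are
    reported missing and flagged.
    """
    r = np.asarray(r_values, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if r.size == 0 or r.shape != s.shape:
        raise ValueError("r and S_norm arrays must be non-empty and parallel")
    peri = s[r >= threshold]
    inter = s[r < threshold]
    out = FractionSplit(threshold=threshold, peripheral=peri, interior=inter)
    if peri.size == 0 or inter.size == 0:
        out.empty_group = True
        return out
    out.median_peripheral = float(np.median(peri))
    out.median_interior = float(np.median(inter))
    out.median_ratio = out.median_peripheral / out.median_interior
    out.comparison = two_sample_compare(peri, inter)
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        bp = np.median(rng.choice(peri, size=peri.size, replace=True))
        bi = np.median(rng.choice(inter, size=inter.size, replace=True))
        ratios[i] = bp / bi if bi > 0 else np.nan
    ratios = ratios[~np.isnan(ratios)]
    out.ratio_ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    return out


def extract_metric(records, metric: str, aggregate: str = "pooled") -> np.ndarray:
    """Pull one metric out of a list of NucleusRecord.

    Per-signal metrics (r, S_norm, r_agnor, nucleolus_dist) pool all
    signals; per-nucleus metrics (d_norm, alpha_deg, S_agnor,
    agnor_count) give one value per nucleus.  ``aggregate="nucleus"``
    reduces per-signal metrics to one median per nucleus.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    per_signal = {
        "r": lambda rec: [s.r for s in rec.fish],
        "S_norm": lambda rec: [s.S_norm for s in rec.fish],
        "r_agnor": lambda rec: [s.r for s in rec.agnor],
        "nucleolus_dist": lambda rec: [d for d in rec.nucleolus_dist_norm if d is not None],
    }
    per_nucleus = {
        "d_norm": lambda rec: rec.d_norm,
        "alpha_deg": lambda rec: rec.alpha_deg,
        "S_agnor": lambda rec: rec.S_agnor_total if rec.agnor else None,
        "agnor_count": lambda rec: rec.agnor_count,
    }
    vals: list[float] = []
    for rec in records:
        if rec.border_flag:
            continue
        if metric in per_signal:
            v = per_signal[metric](rec)
            if aggregate == "nucleus" and v:
                vals.append(float(np.median(v)))
            else:
                vals.extend(v)
        else:
            v = per_nucleus[metric](rec)
            if v is not None:
                vals.append(float(v))
    return np.asarray(vals, dtype=float)


def compare_conditions(
    records_a,
    records_b,
    metric: str = "r",
    aggregate: str = "pooled",
    min_group: int = 20,
) -> TwoSampleResult:
    """Compare one metric between two populations of nucleus records."""
    a = extract_metric(records_a, metric, aggregate)
    b = extract_metric(records_b, metric, aggregate)
    if a.size < min_group or b.size < min_group:
        raise ValueError(
            f"metric {metric!r}: group sizes {a.size}/{b.size} below minimum {min_group}"
        )
    return two_sample_compare(a, b)
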