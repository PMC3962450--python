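"""Test-retest reliability statistics: variance components, ICC, Bland-Altman.

The reliability model is the one-way random-effects ANOVA for n subjects
measured k = 2 times:

    x_ij = μ + b_i + e_ij,   b_i ~ (0, σ²_b),  e_ij ~ (0, σ²_w)

with method-of-moments estimators σ̂²_w = MSW and σ̂²_b = max(0, (MSB−MSW)/k),
and ICC(1,1) = σ²_b / (σ²_b + σ²_w) — between-subject variance as a fraction
of total.  Scans are exchangeable back-to-back repeats, so there is no
systematic "rater" structure and the one-way model is the natural choice.

The 95% CI uses the delta method with Fisher's large-sample variance

    V(ρ) = 2(1−ρ)²·(1+(k−1)ρ)² / (k(k−1)(n−1)).

By default the Wald interval is built on the variance-stabilized arctanh
scale (where, for k = 2, the delta-method standard error is exactly
1/sqrt(n−1)) and back-transformed; ``transform="identity"`` gives the plain
interval ρ̂ ± z·sqrt(V(ρ̂)).  Both are truncated to [0, 1].

Bland-Altman agreement reports the mean and SD of within-pair differences
and the 95% limits of agreement mean ± 1.96·SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PairedSeries",
    "ReliabilityResult",
    "BlandAltmanResult",
    "variance_components",
    "icc",
    "icc_ci_delta",
    "bland_altman",
    "reliability_result",
    "reliability_table",
    "reliability_summary",
    "voxelwise_icc",
    "outlier_sensitivity",
    "RELIABILITY_COLUMNS",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

RELIABILITY_COLUMNS = [
    "region",
    "metric",
    "group",
    "n",
    "icc",
    "ci_low",
    "ci_high",
    "var_within",
    "var_between",
]
SUMMARY_COLUMNS = [
    "metric",
    "group",
    "n_regions",
    "n_icc_ge_0.8",
    "pct_icc_ge_0.8",
    "mean_icc",
]


@dataclass(frozen=True)
class PairedSeries:
    """n subjects × 2 repeats of one measurement, with subject ids."""

    values: np.ndarray
    subject_ids: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"values must be (n, 2), got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(v)):
            raise ValueError("paired values contain missing/non-finite entries")
        ids = tuple(self.subject_ids)
        if len(ids) != v.shape[0]:
            raise ValueError("subject_ids length must match number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return 2

    def drop(self, subject_id) -> "PairedSeries":
        if subject_id not in self.subject_ids:
            raise KeyError(f"subject {subject_id!r} not in series")
        keep = [i for i, s in enumerate(self.subject_ids) if s != subject_id]
        return PairedSeries(
            self.values[keep], tuple(self.subject_ids[i] for i in keep)
        )


@dataclass
class ReliabilityResult:
    """ICC, its 95% CI, and the variance components for one analysis cell."""

    icc: float
    ci_low: float
    ci_high: float
    var_within: float
    var_between: float
    n: int
    undefined: bool = False


@dataclass
class BlandAltmanResult:
    """Agreement between repeats: bias, SD of differences, limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: pd.DataFrame = field(repr=False, default=None)


def _as_values(series) -> np.ndarray:
    if isinstance(series, PairedSeries):
        return series.values
    v = np.asarray(series, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) table, got {v.shape}")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(v)):
        raise ValueError("paired values contain missing/non-finite entries")
    return v


def variance_components(series) -> tuple[float, float]:
    """One-way random-effects ANOVA estimators ``(var_between, var_within)``.

    MSW = Σᵢⱼ (xᵢⱼ − x̄ᵢ)² / (n(k−1)); MSB = k·Σᵢ (x̄ᵢ − x̄)² / (n−1);
    σ̂²_w = MSW and σ̂²_b = max(0, (MSB − MSW)/k).
    """
    x = _as_values(series)
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = row_means.mean()
    # per-subject squared deviations first, then sum over subjects — the same
    # operation order as the vectorized voxelwise path, so both agree bitwise
    msw = float(((x - row_means[:, None]) ** 2).sum(axis=1).sum() / (n * (k - 1)))
    msb = float(k * ((row_means - grand) ** 2).sum() / (n - 1))
    var_between = max(0.0, (msb - msw) / k)
    return var_between, msw


def icc(var_between: float, var_within: float) -> float:
    """ICC(1,1) = σ²_b / (σ²_b + σ²_w); NaN (undefined) when both are zero."""
    if var_between < 0 or var_within < 0:
        raise ValueError("variance components must be non-negative")
    total = var_between + var_within
    if total == 0:
        # no variance at all: reliability is undefined, not 0 and not 1
        return float("nan")
    return var_between / total


def icc_ci_delta(
    icc_value: float,
    n: int,
    k: int = 2,
    alpha: float = 0.05,
    transform: str = "fisher-z",
) -> tuple[float, float]:
    """Delta-method (1−α) CI for the ICC, truncated to [0, 1].

    ``transform="fisher-z"`` (default) builds the Wald interval on the
    arctanh scale and back-transforms; ``"identity"`` is the plain interval
    ρ̂ ± z·sqrt(V(ρ̂)).  Requires n ≥ 3.
    """
    if not 0.0 <= icc_value <= 1.0:
        raise ValueError("icc_value must be in [0, 1]")
    if n < 3:
        raise ValueError("delta-method CI needs n >= 3")
    z = norm.ppf(1.0 - alpha / 2.0)
    V = 2.0 * (1 - icc_value) ** 2 * (1 + (k - 1) * icc_value) ** 2 / (
        k * (k - 1) * (n - 1)
    )
    if transform == "identity":
        half = z * math.sqrt(V)
        lo, hi = icc_value - half, icc_value + half
    elif transform == "fisher-z":
        if icc_value >= 1.0:
            return 1.0, 1.0
        se_z = math.sqrt(V) / (1.0 - icc_value**2)
        zc = math.atanh(icc_value)
        lo, hi = math.tanh(zc - z * se_z), math.tanh(zc + z * se_z)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return max(0.0, lo), min(1.0, hi)


def bland_altman(series) -> BlandAltmanResult:
    """Bland-Altman agreement of repeat 1 vs repeat 2.

    Differences are repeat1 − repeat2; SD uses the n−1 denominator; limits
    of agreement are mean ± 1.96·SD.  Per-pair (mean, diff) coordinates are
    returned for plotting.
    """
    x = _as_values(series)
    diffs = x[:, 0] - x[:, 1]
    means = x.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    ids = (
        list(series.subject_ids)
        if isinstance(series, PairedSeries)
        else list(range(len(diffs)))
    )
    pairs = pd.DataFrame({"subject_id": ids, "mean": means, "diff": diffs})
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pairs=pairs,
    )


def reliability_result(series, alpha: float = 0.05) -> ReliabilityResult:
    """Variance components, ICC and delta-method CI for one paired series.

    Groups with n < 3 get a point estimate but no CI (NaN bounds); an
    all-zero-variance series is flagged undefined.
    """
    x = _as_values(series)
    var_b, var_w = variance_components(x)
    rho = icc(var_b, var_w)
    n = x.shape[0]
    if math.isnan(rho):
        return ReliabilityResult(
            icc=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            var_within=var_w,
            var_between=var_b,
            n=n,
            undefined=True,
        )
    if n < 3:
        lo = hi = float("nan")
    else:
        lo, hi = icc_ci_delta(rho, n, alpha=alpha)
    return ReliabilityResult(
        icc=rho, ci_low=lo, ci_high=hi, var_within=var_w, var_between=var_b, n=n
    )


def _paired_from_table(cell: pd.DataFrame) -> PairedSeries:
    wide = cell.pivot(index="subject_id", columns="repeat", values="value")
    if set(wide.columns) != {1, 2} or wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete repeats for subjects {missing}")
    return PairedSeries(wide[[1, 2]].to_numpy(), tuple(wide.index))


def reliability_table(measurements: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One reliability row per (region, metric, group).

    Groups are analysed separately (never pooled).  Output columns are
    :data:`RELIABILITY_COLUMNS`; undefined ICCs and omitted CIs are NaN
    (written as "NA" in file output).
    """
    required = {"subject_id", "group", "repeat", "region", "metric", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    rows = []
    for (region, metric, group), cell in measurements.groupby(
        ["region", "metric", "group"], sort=True
    ):
        series = _paired_from_table(cell)
        res = reliability_result(series, alpha=alpha)
        rows.append(
            {
                "region": region,
                "metric": metric,
                "group": group,
                "n": res.n,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "var_within": res.var_within,
                "var_between": res.var_between,
            }
        )
    return pd.DataFrame(rows, columns=RELIABILITY_COLUMNS)


def reliability_summary(
    table: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Per (metric, group): number and share of regions with ICC ≥ threshold,
    and the unweighted mean ICC.  Undefined (NaN) ICCs count toward
    ``n_regions`` but not toward the threshold count or the mean."""
    rows = []
    for (metric, group), cell in table.groupby(["metric", "group"], sort=True):
        vals = cell["icc"]
        defined = vals.dropna()
        n_ge = int((defined >= threshold).sum())
        rows.append(
            {
                "metric": metric,
                "group": group,
                "n_regions": len(vals),
                "n_icc_ge_0.8": n_ge,
                "pct_icc_ge_0.8": 100.0 * n_ge / len(vals),
                "mean_icc": defined.mean() if len(defined) else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def voxelwise_icc(
    stream1_maps: np.ndarray,
    stream2_maps: np.ndarray,
    mask: np.ndarray | None = None,
    subject_ids1=None,
    subject_ids2=None,
) -> tuple[np.ndarray, int]:
    """Per-voxel ICC across subjects from two aligned map stacks.

    ``stream*_maps`` are (n_subjects, X, Y, Z) stacks in identical subject
    order (checked via the optional id lists).  Per masked voxel the n×2
    paired series across subjects feeds the variance-component ICC.
    Undefined voxels (zero total variance) are set to 0; their count is
    logged and returned.
    """
    a = np.asarray(stream1_maps, dtype=float)
    b = np.asarray(stream2_maps, dtype=float)
    if a.shape != b.shape or a.ndim != 4:
        raise ValueError("stacks must be matching (n, X, Y, Z) arrays")
    if subject_ids1 is not None or subject_ids2 is not None:
        if list(subject_ids1) != list(subject_ids2):
            raise ValueError("subject order differs between streams")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if mask is None:
        mask = np.ones(a.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape[1:]:
        raise ValueError("mask shape does not match map grid")

    x1 = a[:, mask]  # (n, V)
    x2 = b[:, mask]
    row_mean = 0.5 * (x1 + x2)
    grand = row_mean.mean(axis=0)
    k = 2
    msw = ((x1 - row_mean) ** 2 + (x2 - row_mean) ** 2).sum(axis=0) / (n * (k - 1))
    msb = k * ((row_mean - grand) ** 2).sum(axis=0) / (n - 1)
    var_b = np.maximum(0.0, (msb - msw) / k)
    total = var_b + msw
    defined = total > 0
    vals = np.zeros(x1.shape[1])
    vals[defined] = var_b[defined] / total[defined]
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info(
            "voxelwise_icc: %d of %d voxels undefined (zero total variance)",
            n_undefined,
            len(vals),
        )
    out = np.zeros(mask.shape)
    out[mask] = vals
    return out, n_undefined


def outlier_sensitivity(
    series: PairedSeries, drop
) -> tuple[ReliabilityResult, ReliabilityResult]:
    """Reliability before and after removing one subject.

    The dropped subject must leave n ≥ 3 so the CI remains estimable.
    """
    if not isinstance(series, PairedSeries):
        raise TypeError("outlier_sensitivity requires a PairedSeries with ids")
    if series.n < 4:
        raise ValueError("need n >= 4 so that n - 1 >= 3 after dropping")
    before = reliability_result(series)
    after = reliability_result(series.drop(drop))
    return before, after
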