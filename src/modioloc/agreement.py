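"""Method-comparison statistics: Bland-Altman, percentage error, Pearson, ICC.

The battery follows standard method-comparison practice: paired differences
between two measurement methods are summarised by their bias (mean difference)
and limits of agreement (bias +/- 1.96 sample SD), supplemented by the
percentage error (LoA width over the reference method's mean), the Pearson
correlation with a Fisher-z confidence interval, a two-way intraclass
correlation with absolute agreement, and a Lilliefors-corrected
Kolmogorov-Smirnov normality check of the differences. Subgroup bias tests
(rank-sum for two groups, one-way ANOVA for more) screen candidate
confounders such as voxel size or image-quality score.

Differences are pooled across arrays at the electrode level; within-array
clustering is deliberately ignored (the statistics describe the pooled
scatter, not a hierarchical model).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import (
    IncompleteMatrixError,
    InsufficientDataError,
    InvalidReferenceError,
    PairingError,
    UndefinedCorrelationError,
)
from .measurement import ElectrodeArrayMeasurement

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "KSNormality",
    "GroupBiasReport",
    "paired_differences",
    "bland_altman",
    "percentage_error",
    "pearson_with_ci",
    "icc_two_way_mixed_absolute",
    "ks_normality",
    "group_bias_tests",
    "build_agreement_report",
]

PARAMETER_COLUMNS = {"EMD": "emd", "aDOI": "adoi"}


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float

    @property
    def half_width(self) -> float:
        """Precision: 1.96 * SD, the half-width of the limits of agreement."""
        return 1.96 * self.sd


@dataclass(frozen=True)
class KSNormality:
    statistic: float
    p_value: float
    normal: bool
    degenerate: bool = False


@dataclass(frozen=True)
class GroupBiasReport:
    test: str
    statistic: float
    p_value: float
    group_sizes: dict
    group_means: dict
    exceeds_criterion: bool | None


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one spatial parameter (EMD or aDOI)."""

    parameter: str
    n_pairs: int
    bias: float
    loa_low: float
    loa_high: float
    percentage_error: float
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    icc: float
    ks_statistic: float
    ks_p: float
    ks_normal: bool

    def to_dict(self) -> dict:
        return asdict(self)


def paired_differences(set_a: Iterable[ElectrodeArrayMeasurement],
                       set_b: Iterable[ElectrodeArrayMeasurement],
                       parameter: str) -> pd.DataFrame:
    """Electrode-level paired values pooled across arrays.

    Returns a frame with columns array_id, electrode, value_a, value_b,
    mean ((a+b)/2) and diff (a - b). Raises :class:`PairingError` listing
    offending keys when (array, electrode) coverage differs.
    """
    col = PARAMETER_COLUMNS.get(parameter)
    if col is None:
        raise ValueError(f"parameter must be one of {sorted(PARAMETER_COLUMNS)}")

    def index(measurements):
        out = {}
        for m in measurements:
            values = getattr(m, col)
            for e, v in zip(m.electrode_numbers, values):
                out[(m.array_id, e)] = v
        return out

    a = index(set_a)
    b = index(set_b)
    if a.keys() != b.keys():
        offenders = sorted(a.keys() ^ b.keys())
        raise PairingError(f"unmatched (array, electrode) pairs: {offenders[:10]}"
                           + ("..." if len(offenders) > 10 else ""))
    keys = sorted(a.keys())
    va = np.array([a[k] for k in keys])
    vb = np.array([b[k] for k in keys])
    return pd.DataFrame({
        "array_id": [k[0] for k in keys],
        "electrode": [k[1] for k in keys],
        "value_a": va,
        "value_b": vb,
        "mean": (va + vb) / 2.0,
        "diff": va - vb,
    })


def bland_altman(differences: Sequence[float] | np.ndarray) -> BlandAltman:
    """Bias and 95% limits of agreement of paired differences.

    bias = mean(d); limits = bias +/- 1.96 * SD(d) with the sample (n-1)
    standard deviation.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd=sd)


def percentage_error(loa_low: float, loa_high: float,
                     reference_mean: float) -> float:
    """LoA width as a percentage of the reference (established) method's mean.

    100 * (loa_high - loa_low) / reference_mean; puts the limits of agreement
    in proportion to the magnitude of the quantity being measured.
    """
    if not reference_mean > 0:
        raise InvalidReferenceError("reference mean must be > 0")
    return 100.0 * (loa_high - loa_low) / reference_mean


def pearson_with_ci(x: Sequence[float], y: Sequence[float],
                    confidence: float = 0.95) -> tuple[float, float, float]:
    """Pearson product-moment r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("Pearson CI needs at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant input sequence")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(ci.low), float(ci.high)


def icc_two_way_mixed_absolute(ratings: np.ndarray | Sequence[Sequence[float]],
                               *, average: bool = True) -> float:
    """Intraclass correlation, two-way mixed-effects model, absolute agreement.

    ``ratings`` is a complete subjects x raters matrix. The coefficient is
    computed from the two-way ANOVA mean squares (rows = subjects,
    columns = raters):

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)
        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects and k raters. ``average=True`` (the default) returns the
    multiple-raters form ICC(A,k); ``average=False`` the single-measure form.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise IncompleteMatrixError("ratings must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if k < 2 or n < 5:
        raise InsufficientDataError("ICC needs >= 2 raters and >= 5 subjects")
    if not np.all(np.isfinite(m)):
        raise IncompleteMatrixError("ratings matrix has missing/non-finite cells")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if average:
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        # identical constant raters: perfect agreement by convention
        return 1.0
    return float((msr - mse) / denom)


def ks_normality(differences: Sequence[float] | np.ndarray,
                 alpha: float = 0.05) -> KSNormality:
    """Kolmogorov-Smirnov normality check with estimated mean and SD.

    Because the reference normal's parameters are fitted from the sample, the
    Lilliefors correction is used for the p-value. Constant data (zero SD) is
    degenerate — the empirical distribution is a point mass — and is flagged
    rather than tested.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 5:
        raise InsufficientDataError("normality test needs at least 5 values")
    if d.std(ddof=1) == 0.0:
        return KSNormality(statistic=0.0, p_value=float("nan"),
                           normal=False, degenerate=True)
    stat, p = lilliefors(d, dist="norm", pvalmethod="table")
    return KSNormality(statistic=float(stat), p_value=float(p),
                       normal=bool(p > alpha))


def group_bias_tests(per_array_bias: Sequence[float] | np.ndarray,
                     groups: Sequence,
                     criterion: float | None = None) -> GroupBiasReport:
    """Test whether per-array bias differs between covariate groups.

    Two groups: Wilcoxon rank-sum test. More than two: one-way ANOVA. Each
    group needs n >= 3. When ``criterion`` (the interrater precision for the
    parameter) is given, the report also flags whether the spread of group
    mean biases exceeds it.
    """
    values = np.asarray(per_array_bias, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("per_array_bias and groups must align")
    uniq = pd.unique(labels)
    samples = [values[labels == g] for g in uniq]
    if len(uniq) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g, s in zip(uniq, samples):
        if s.size < 3:
            raise InsufficientDataError(f"group {g!r} has n={s.size} < 3")
    if len(uniq) == 2:
        stat, p = stats.ranksums(samples[0], samples[1])
        test = "wilcoxon-rank-sum"
    else:
        stat, p = stats.f_oneway(*samples)
        test = "one-way-anova"
    means = {str(g): float(s.mean()) for g, s in zip(uniq, samples)}
    exceeds = None
    if criterion is not None:
        spread = max(means.values()) - min(means.values())
        exceeds = bool(spread > criterion)
    return GroupBiasReport(
        test=test, statistic=float(stat), p_value=float(p),
        group_sizes={str(g): int(s.size) for g, s in zip(uniq, samples)},
        group_means=means, exceeds_criterion=exceeds)


def build_agreement_report(set_a: Iterable[ElectrodeArrayMeasurement],
                           set_b: Iterable[ElectrodeArrayMeasurement],
                           parameter: str,
                           confidence: float = 0.95) -> AgreementReport:
    """Assemble the full battery for one parameter, A compared against B.

    ``set_b`` is treated as the reference (established) method: the percentage
    error divides the LoA width by B's grand mean. Differences are A - B.
    """
    set_a = list(set_a)
    set_b = list(set_b)
    pairs = paired_differences(set_a, set_b, parameter)
    ba = bland_altman(pairs["diff"].to_numpy())
    pe = percentage_error(ba.loa_low, ba.loa_high,
                          float(pairs["value_b"].mean()))
    r, lo, hi = pearson_with_ci(pairs["value_a"], pairs["value_b"],
                                confidence=confidence)
    icc = icc_two_way_mixed_absolute(
        np.column_stack([pairs["value_a"], pairs["value_b"]]))
    ks = ks_normality(pairs["diff"].to_numpy())
    return AgreementReport(
        parameter=parameter,
        n_pairs=int(len(pairs)),
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        percentage_error=pe,
        pearson_r=r,
        r_ci_low=lo,
        r_ci_high=hi,
        icc=icc,
        ks_statistic=ks.statistic,
        ks_p=ks.p_value,
        ks_normal=ks.normal,
    )
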