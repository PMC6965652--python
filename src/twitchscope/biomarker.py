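"""Per-mouse twitch summary metrics and ROC discrimination analysis.

The composite twitch time (CTT) summarizes a mouse's motor-unit pool at one
time point as

    CTT = harmonic mean of rise times + median of half-relaxation times,

a metric sensitive to the loss of the fastest units: the harmonic mean
weights short rise times heavily, so denervation of fast-fatigable units
moves it early, while the median half-relaxation time tracks the bulk
shift of the pool toward slow units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "MouseMetricRecord",
    "ROCResult",
    "composite_twitch_time",
    "candidate_metrics",
    "roc_auc",
]


@dataclass(frozen=True)
class MouseMetricRecord:
    """Composite twitch time and its two components for one mouse."""

    mouse_id: str
    genotype: str
    age_weeks: float
    n_units: int
    harmonic_mean_t_r: float
    median_t_hr: float
    ctt: float
    candidates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.ctt != self.harmonic_mean_t_r + self.median_t_hr:
            raise ValueError("ctt must equal harmonic_mean_t_r + median_t_hr")


def composite_twitch_time(
    t_r,
    t_hr,
    *,
    mouse_id: str = "",
    genotype: str = "",
    age_weeks: float = np.nan,
    with_candidates: bool = False,
) -> MouseMetricRecord:
    """Composite twitch time of one mouse from its motor-unit times.

    ``t_r`` and ``t_hr`` are the per-unit rise and half-relaxation times in
    ms (one entry per motor unit, paired).  The harmonic mean is
    n / sum(1/t_r); the median uses the mean of the central pair for even
    n.  Raises ``ValueError`` on empty input or nonpositive times.
    """
    t_r = np.asarray(t_r, dtype=float)
    t_hr = np.asarray(t_hr, dtype=float)
    if t_r.size == 0 or t_hr.size == 0:
        raise ValueError("need at least one motor unit")
    if t_r.size != t_hr.size:
        raise ValueError("t_r and t_hr must be paired per unit")
    if np.any(t_r <= 0) or np.any(t_hr <= 0):
        raise ValueError("all times must be > 0")
    hm = float(t_r.size / np.sum(1.0 / t_r))
    med = float(np.median(t_hr))
    cand = candidate_metrics(t_r, t_hr) if with_candidates and t_r.size >= 2 else {}
    return MouseMetricRecord(
        mouse_id=mouse_id,
        genotype=genotype,
        age_weeks=age_weeks,
        n_units=int(t_r.size),
        harmonic_mean_t_r=hm,
        median_t_hr=med,
        ctt=hm + med,
        candidates=cand,
    )


def candidate_metrics(t_r, t_hr) -> dict[str, float]:
    """Summary-statistic candidates for each time constant.

    Arithmetic mean, harmonic mean, median, quartiles (linear interpolation
    between order statistics, the type-7 convention), unbiased variance and
    adjusted Fisher-Pearson sample skewness, for rise and half-relaxation
    times.  Variance and skewness require n >= 2 and n >= 3 respectively.
    """
    out: dict[str, float] = {}
    for name, x in (("t_r", np.asarray(t_r, float)), ("t_hr", np.asarray(t_hr, float))):
        if x.size < 2:
            raise ValueError("need >= 2 units for moment-based candidates")
        out[f"mean_{name}"] = float(np.mean(x))
        out[f"harmonic_mean_{name}"] = float(x.size / np.sum(1.0 / x))
        out[f"median_{name}"] = float(np.median(x))
        out[f"q1_{name}"] = float(np.quantile(x, 0.25))  # type-7 linear
        out[f"q3_{name}"] = float(np.quantile(x, 0.75))
        out[f"var_{name}"] = float(np.var(x, ddof=1))
        out[f"skew_{name}"] = (
            float(sps.skew(x, bias=False)) if x.size >= 3 else np.nan
        )
    return out


@dataclass(frozen=True)
class ROCResult:
    """ROC curve, AUC and bootstrap confidence interval."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_bootstrap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        lo, hi = self.auc_ci
        if lo > hi:
            raise ValueError("ci_lower must be <= ci_upper")


def _auc_mann_whitney(disease: np.ndarray, control: np.ndarray) -> float:
    """P(disease > control) with ties counted half."""
    gt = (disease[:, None] > control[None, :]).sum()
    eq = (disease[:, None] == control[None, :]).sum()
    return float((gt + 0.5 * eq) / (disease.size * control.size))


def _roc_curve(disease: np.ndarray, control: np.ndarray):
    """Threshold sweep over pooled unique scores (rule: score >= threshold)."""
    pooled = np.unique(np.concatenate([disease, control]))
    thresholds = np.concatenate([[np.inf], pooled[::-1], [-np.inf]])
    tpr = np.array([(disease >= th).mean() for th in thresholds])
    fpr = np.array([(control >= th).mean() for th in thresholds])
    return thresholds, tpr, fpr


def roc_auc(
    scores_disease,
    scores_control,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ROCResult:
    """ROC analysis of a scalar score separating disease from control.

    The AUC is the Mann-Whitney probability that a random disease score
    exceeds a random control score (ties count half); it equals the
    trapezoidal area under the threshold-sweep curve.  The confidence
    interval is a percentile bootstrap over ``n_bootstrap`` resamples drawn
    within each group independently (resampling subjects).
    """
    disease = np.asarray(scores_disease, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if disease.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    auc = _auc_mann_whitney(disease, control)
    thresholds, tpr, fpr = _roc_curve(disease, control)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        d = rng.choice(disease, disease.size, replace=True)
        c = rng.choice(control, control.size, replace=True)
        boots[b] = _auc_mann_whitney(d, c)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        n_bootstrap=n_bootstrap,
    )
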