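"""Nonparametric test battery and trend fits for longitudinal cohorts.

The longitudinal design is a randomized block layout: mice are blocks,
time points are treatments, and each cell holds one or several motor-unit
measurements.  Two rank tests cover it:

* ``gore_test`` — Friedman-type test allowing multiple observations per
  cell (replicated blocks).  Observations are mid-ranked jointly within
  each block; the vector of centred cell rank sums is referred to its
  exact within-block permutation covariance via a Moore-Penrose inverse,
  giving a chi-squared statistic with k-1 degrees of freedom.  With equal
  replication c and no ties this reduces to the closed form
  12(k-1) sum_j (T_j - nc(N+1)/2)^2 / (k n c (N+1)(N-c)), N = kc, and to
  Friedman's statistic at c = 1.  A seeded within-block permutation
  p-value is available as a cross-check.
* ``skillings_mack_test`` — one observation per cell, cells may be
  missing (e.g. a mouse that died before the last time point).  Built on
  the same quadratic form; on complete data it equals the tie-corrected
  Friedman statistic exactly.

Alongside: Dunn's post-hoc z-tests with Bonferroni correction, two-sample
Kolmogorov-Smirnov and Wilcoxon rank-sum wrappers, a kernel density
estimator based on linear diffusion with automatic (fixed-point plug-in)
bandwidth selection, an exponential trend model y = A exp(Bx) + C with C
pinned to the first-time-point mean, and the pair of F-tests that asks
whether two datasets share one trend model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.fft import dct, idct
from scipy.optimize import brentq, least_squares

__all__ = [
    "BlockDesignData",
    "TestResult",
    "ExpTrendFit",
    "ExpTrendModel",
    "ExpTrendResults",
    "gore_test",
    "skillings_mack_test",
    "dunn_posthoc",
    "ks_two_sample",
    "rank_sum_test",
    "diffusion_kde",
    "fit_exp_trend",
    "f_test_model_equivalence",
    "pearson_r",
    "DesignError",
]


class DesignError(ValueError):
    """Block design does not meet the test's requirements."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None
    method: str
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


class BlockDesignData:
    """Observations indexed by (block, treatment); replicates allowed.

    Constructed from long-format arrays or a DataFrame with block,
    treatment and value columns.  Blocks with fewer than two observed
    treatments carry no within-block contrast and are dropped.
    """

    def __init__(self, blocks, treatments, values):
        blocks = np.asarray(blocks)
        treatments = np.asarray(treatments)
        values = np.asarray(values, dtype=float)
        if not (blocks.shape == treatments.shape == values.shape):
            raise ValueError("blocks, treatments, values must align")
        keep_blocks = []
        for b in pd.unique(blocks):
            if len(pd.unique(treatments[blocks == b])) >= 2:
                keep_blocks.append(b)
        mask = np.isin(blocks, keep_blocks)
        self.blocks = blocks[mask]
        self.treatments = treatments[mask]
        self.values = values[mask]
        self.block_ids = list(pd.unique(self.blocks))
        self.treatment_ids = list(pd.unique(treatments))  # keep all levels
        if len(self.treatment_ids) < 2:
            raise DesignError("need at least 2 treatments")
        if not self.block_ids:
            raise DesignError("every block needs >= 2 observed treatments")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, block: str, treatment: str, value: str
    ) -> "BlockDesignData":
        return cls(df[block].to_numpy(), df[treatment].to_numpy(), df[value].to_numpy())


def _block_rank_statistic(data: BlockDesignData) -> tuple[float, int, np.ndarray]:
    """Quadratic-form rank statistic over within-block permutations.

    Within each block all observations are mid-ranked jointly.  For cell
    (i, j) with c_ij observations and rank sum R_ij, the centred cell sum
    is R_ij - c_ij (N_i + 1)/2.  Under the null the cell assignments are a
    random partition of the block's rank multiset, with exact moments
    Var(R_ij) = c_ij s2_i (N_i - c_ij)/(N_i - 1) and
    Cov(R_ij, R_il) = -c_ij c_il s2_i/(N_i - 1), where s2_i is the
    population variance of the block's mid-ranks (ties enter here).  The
    statistic is d' Sigma^+ d on the treatment-total vector d.
    """
    k = len(data.treatment_ids)
    tindex = {t: j for j, t in enumerate(data.treatment_ids)}
    d = np.zeros(k)
    sigma = np.zeros((k, k))
    for b in data.block_ids:
        sel = data.blocks == b
        vals = data.values[sel]
        treats = data.treatments[sel]
        ranks = sps.rankdata(vals)  # mid-ranks
        N = ranks.size
        mean_r = (N + 1) / 2.0
        s2 = float(np.mean((ranks - mean_r) ** 2))  # population variance
        if s2 == 0.0 or N < 2:
            continue  # fully tied block carries no information
        cols = np.array([tindex[t] for t in treats])
        for j in np.unique(cols):
            c_j = int(np.sum(cols == j))
            d[j] += float(ranks[cols == j].sum()) - c_j * mean_r
            sigma[j, j] += c_j * s2 * (N - c_j) / (N - 1)
            for l in np.unique(cols):
                if l != j:
                    c_l = int(np.sum(cols == l))
                    sigma[j, l] -= c_j * c_l * s2 / (N - 1)
    stat = float(d @ np.linalg.pinv(sigma) @ d)
    return max(stat, 0.0), k - 1, d


def gore_test(
    data: BlockDesignData,
    *,
    method: str = "asymptotic",
    n_permutations: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Rank test for treatment effects in replicated block designs.

    Extends Friedman's test to c > 1 observations per cell: all
    observations within a block are mid-ranked jointly and treatment cell
    rank sums are referred to their exact within-block permutation
    covariance (see :func:`_block_rank_statistic`); the statistic is
    asymptotically chi-squared with k-1 degrees of freedom.  Unequal cell
    counts enter through the per-cell moments.

    ``method='permutation'`` replaces the asymptotic reference with a
    seeded within-block permutation distribution of the same statistic.
    """
    stat, df, _ = _block_rank_statistic(data)
    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, df))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perm_stats = np.empty(n_permutations)
        shuffled = BlockDesignData(data.blocks, data.treatments, data.values)
        vals = shuffled.values
        for r in range(n_permutations):
            for b in shuffled.block_ids:
                sel = shuffled.blocks == b
                vals[sel] = rng.permutation(vals[sel])
            perm_stats[r], _, _ = _block_rank_statistic(shuffled)
        p = float((1 + np.sum(perm_stats >= stat - 1e-12)) / (1 + n_permutations))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(stat, p, df, f"Gore replicated-block rank test ({method})",
                      int(data.values.size))


def skillings_mack_test(data: BlockDesignData) -> TestResult:
    """Friedman-type test for block designs with missing cells.

    One observation per (block, treatment) cell; cells may be absent.
    Uses the same permutation-moment quadratic form as :func:`gore_test`;
    on complete data the statistic equals the tie-corrected Friedman
    statistic exactly.
    """
    for b in data.block_ids:
        sel = data.blocks == b
        t = data.treatments[sel]
        if len(pd.unique(t)) != t.size:
            raise DesignError(
                "skillings_mack_test expects one observation per cell; "
                "use gore_test for replicated cells"
            )
    stat, df, _ = _block_rank_statistic(data)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, df, "Skillings-Mack test", int(data.values.size))


def dunn_posthoc(
    groups: list[np.ndarray],
    *,
    labels: list[str] | None = None,
    correction: str = "bonferroni",
) -> dict[tuple[str, str], TestResult]:
    """Dunn's pairwise z-tests on pooled mid-ranks, Bonferroni-adjusted.

    The tie correction subtracts sum(t^3 - t)/(12 (N - 1)) from the rank
    variance N(N+1)/12.  Adjusted p-values are multiplied by the number of
    pairs in this call and capped at 1.
    """
    if len(groups) < 3:
        raise DesignError("Dunn's test is a post hoc over >= 3 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term
    mean_ranks, sizes, pos = [], [], 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[pos : pos + g.size])))
        sizes.append(g.size)
        pos += g.size
    pairs = list(combinations(range(len(groups)), 2))
    multiplier = len(pairs) if correction == "bonferroni" else 1
    out: dict[tuple[str, str], TestResult] = {}
    for i, j in pairs:
        se = math.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))) * multiplier)
        out[(labels[i], labels[j])] = TestResult(
            z, p, None, "Dunn's test (Bonferroni)", sizes[i] + sizes[j]
        )
    return out


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), None,
                      "two-sample KS (asymptotic)", x.size + y.size)


def rank_sum_test(x, y) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney test, two-sided normal
    approximation with tie correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), None,
                      "Wilcoxon rank-sum (asymptotic)", x.size + y.size)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    r, _ = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r)


# ---------------------------------------------------------------------------
# Kernel density estimation by linear diffusion


def _fixed_point(t: float, N: int, I2: np.ndarray, a2: np.ndarray) -> float:
    """t - xi gamma^[l](t) for the plug-in bandwidth fixed point (l = 7)."""
    ell = 7
    f = 2.0 * np.pi ** (2 * ell) * np.sum(I2**ell * a2 * np.exp(-I2 * np.pi**2 * t))
    for s in range(ell - 1, 1, -1):
        K0 = np.prod(np.arange(1, 2 * s, 2)) / math.sqrt(2 * np.pi)
        const = (1 + (0.5) ** (s + 0.5)) / 3.0
        time = (2 * const * K0 / (N * f)) ** (2.0 / (3 + 2 * s))
        f = 2.0 * np.pi ** (2 * s) * np.sum(I2**s * a2 * np.exp(-I2 * np.pi**2 * time))
    return t - (2.0 * N * math.sqrt(np.pi) * f) ** (-0.4)


def diffusion_kde(sample, grid, *, n_mesh: int = 2**12) -> np.ndarray:
    """Density estimate by linear diffusion with automatic bandwidth.

    The sample is binned on a dyadic mesh spanning the requested grid, the
    discrete cosine transform of the empirical measure is damped by the
    Gaussian (heat) kernel, and the diffusion time is selected by the
    fixed-point plug-in rule t = xi gamma^[7](t), which estimates the
    functionals of the unknown density needed by the asymptotically
    optimal bandwidth from the data itself.  The smoothed transform is
    inverted and interpolated onto ``grid``; the result is clipped at zero
    and integrates to ~1 when the grid covers the sample with margin.
    """
    x = np.asarray(sample, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    lo = min(grid.min(), x.min())
    hi = max(grid.max(), x.max())
    span = hi - lo
    lo -= 0.0  # grid is required to carry its own margin
    mesh = np.linspace(lo, hi, n_mesh + 1)[:-1]
    delta = span / n_mesh
    hist, _ = np.histogram(x, bins=n_mesh, range=(lo, hi))
    N = int(np.sum(np.unique(x, return_counts=True)[1] > 0))
    p0 = hist / x.size
    a = dct(p0, type=2)
    I2 = np.arange(1, n_mesh, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2
    try:
        t_star = brentq(lambda t: _fixed_point(t, N, I2, a2), 1e-12, 0.1)
    except ValueError:
        # fall back to the Gaussian-reference diffusion time
        sigma = np.std(x, ddof=1) / span
        t_star = float((4.0 * sigma**5 / (3.0 * N)) ** (2.0 / 5.0))
    a_t = a * np.exp(-np.arange(n_mesh, dtype=float) ** 2 * np.pi**2 * t_star / 2.0)
    dens = idct(a_t, type=2) / (2.0 * span)
    dens = np.clip(dens, 0.0, None)
    # renormalize the mesh density before interpolation
    area = np.trapezoid(dens, mesh)
    if area > 0:
        dens = dens / area
    return np.interp(grid, mesh, dens, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# Exponential trend fits and model-equivalence F-tests


@dataclass(frozen=True)
class ExpTrendFit:
    """y = A exp(Bx) + C with C fixed to the first-time-point mean."""

    A: float
    B: float
    C: float
    rss: float
    red_chi2: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.A * np.exp(self.B * np.asarray(x, float)) + self.C


class ExpTrendModel:
    """Least-squares exponential trend of a time constant versus age.

    ``x`` is weeks since the first time point, ``y`` the per-mouse metric
    (ms).  The offset C is not free: it is pinned to the mean of ``y`` at
    the earliest ``x`` (the healthy baseline), so only the amplitude A and
    rate B are estimated, and the reduced chi-squared uses n - 2 degrees
    of freedom.
    """

    def __init__(self, x, y, C: float | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and aligned")
        if np.unique(x).size < 3:
            raise ValueError("need >= 3 distinct x values")
        self.x, self.y = x, y
        self.C = float(np.mean(y[x == x.min()])) if C is None else float(C)

    def fit(self) -> "ExpTrendResults":
        x, y, C = self.x, self.y, self.C
        r = y - C

        def amp_for(B: float) -> float:
            e = np.exp(B * x)
            denom = float(e @ e)
            return float(r @ e) / denom if denom > 0 else 0.0

        best = None
        for B0 in (-0.3, -0.1, -0.02, 0.01, 0.05, 0.15, 0.3, 0.6):
            A0 = amp_for(B0)
            sol = least_squares(
                lambda ab: ab[0] * np.exp(ab[1] * x) + C - y,
                x0=[A0 if A0 != 0 else 1e-3, B0],
                method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000,
            )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        rss, sol = best
        if not sol.success and not np.isfinite(rss):
            raise RuntimeError("exponential trend fit failed to converge")
        A, B = map(float, sol.x)
        n = x.size
        fit = ExpTrendFit(A, B, C, rss, rss / max(n - 2, 1), n)
        return ExpTrendResults(self, fit)


@dataclass(frozen=True)
class ExpTrendResults:
    model: ExpTrendModel
    fit: ExpTrendFit

    @property
    def params(self) -> dict[str, float]:
        return {"A": self.fit.A, "B": self.fit.B, "C": self.fit.C}

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.fit.predict(self.model.x)

    def summary(self) -> str:
        f = self.fit
        return (
            "Exponential trend fit: y = A exp(Bx) + C\n"
            f"A = {f.A:.4f}   B = {f.B:.4f} /week   C = {f.C:.4f} ms (fixed)\n"
            f"RSS = {f.rss:.4f}   reduced chi2 = {f.red_chi2:.4f}   n = {f.n}"
        )


def fit_exp_trend(x, y, C: float | None = None) -> ExpTrendFit:
    """Fit y = A exp(Bx) + C with C fixed (defaults to mean y at min x)."""
    return ExpTrendModel(x, y, C=C).fit().fit


def f_test_model_equivalence(
    fit_1: ExpTrendFit, data_1: tuple, fit_2: ExpTrendFit, data_2: tuple
) -> tuple[TestResult, TestResult]:
    """Do two datasets share one exponential trend?  Pair of F-tests.

    Each direction applies the other dataset's fitted model and compares
    its reduced chi-squared against the dataset's own fit:
    F = red_chi2(cross-applied model on data_j) / red_chi2(own fit of
    data_j), referred two-sided to F(n_j - 2, n_j - 2).  Identical
    datasets give F = 1 and the maximal p of 1.
    """
    results = []
    for own_fit, (x, y), other_fit in (
        (fit_1, data_1, fit_2),
        (fit_2, data_2, fit_1),
    ):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.size
        dof = n - 2
        if own_fit.red_chi2 <= 0:
            raise ZeroDivisionError(
                "own fit is exact (reduced chi-squared 0); F undefined"
            )
        rss_cross = float(np.sum((other_fit.predict(x) - y) ** 2))
        F = (rss_cross / dof) / own_fit.red_chi2
        p = 2.0 * float(min(sps.f.sf(F, dof, dof), sps.f.cdf(F, dof, dof)))
        results.append(
            TestResult(F, min(p, 1.0), dof, "model-equivalence F-test", n)
        )
    return results[0], results[1]
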