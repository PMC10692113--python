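"""Repeated-measures statistical battery for scores and gains.

Covers the inference used on prediction correlations and FS-S gains:
Shapiro-Wilk normality and Mauchly sphericity screening, one-way
repeated-measures ANOVA with Greenhouse-Geisser correction and partial
eta-squared, the Friedman test with Kendall's W, one-sample / paired
Wilcoxon signed-rank tests (exact 2^n enumeration for small n), BH-FDR
correction, and the bootstrap topography-similarity analysis.

Every function is a pure function of its inputs (plus an explicit seed for
the bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "wilcoxon_signed_rank",
    "rm_anova_oneway",
    "greenhouse_geisser_epsilon",
    "mauchly_test",
    "friedman_kendall",
    "fdr_bh",
    "assumption_screen",
    "bootstrap_topography_similarity",
    "EXACT_WILCOXON_MAX_N",
]

#: largest n for which the Wilcoxon null is enumerated exactly (2^n patterns)
EXACT_WILCOXON_MAX_N = 15


@dataclass
class StatResult:
    """One test's outcome: statistic, (possibly corrected) df, p, effect size."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_fdr: float | None = None
    effect_size: float | None = None
    effect_name: str = ""
    correction: str = "none"
    epsilon: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

def _exact_wilcoxon_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed p by enumerating all 2^n sign assignments.

    Ties in |d| are handled naturally through average ranks.  Returns
    (T_plus, p).
    """
    n = len(d)
    ranks = sstats.rankdata(np.abs(d))
    t_obs = float(ranks[d > 0].sum())
    # distribution of T+ over all sign patterns
    signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1   # (2^n, n) of 0/1
    t_null = signs @ ranks
    p_low = np.mean(t_null <= t_obs + 1e-9)
    p_high = np.mean(t_null >= t_obs - 1e-9)
    return t_obs, float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x: np.ndarray,
    mu: float = 0.0,
    y: np.ndarray | None = None,
) -> StatResult:
    """Two-tailed Wilcoxon signed-rank test (one-sample or paired).

    If ``y`` is given the test runs on the paired differences ``x - y``,
    otherwise on ``x - mu``.  Zeros are dropped before ranking (classic
    convention).  For n <= 15 nonzero differences the p-value is exact by
    full sign enumeration; beyond that a normal approximation with
    continuity and tie corrections is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x - mu
    d = d[d != 0.0]
    if len(d) == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if len(d) < 3:
        raise ValueError("need >= 3 nonzero differences")
    if len(d) <= EXACT_WILCOXON_MAX_N:
        t_obs, p = _exact_wilcoxon_p(d)
    else:
        res = sstats.wilcoxon(d, zero_method="wilcox", correction=True,
                              alternative="two-sided", method="approx")
        ranks = sstats.rankdata(np.abs(d))
        t_obs = float(ranks[d > 0].sum())
        p = float(res.pvalue)
    return StatResult(test="wilcoxon", statistic=t_obs, df=(), p=p, n=len(d))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA and sphericity
# ---------------------------------------------------------------------------

def _check_table(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = data.shape
    if k < 2 or n < 3:
        raise ValueError(f"need n >= 3 subjects and k >= 2 conditions, got {n}x{k}")
    return data


def rm_anova_oneway(data: np.ndarray, alpha_sphericity: float = 0.05) -> StatResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Uses the two-way (subject x condition) decomposition:
    F = MS_condition / MS_error with df (k-1, (n-1)(k-1)).  Mauchly's test
    screens sphericity; on rejection the df are multiplied by the
    Greenhouse-Geisser epsilon.  Partial eta-squared is
    SS_condition / (SS_condition + SS_error).
    """
    data = _check_table(data)
    n, k = data.shape
    grand = data.mean()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    F = 0.0 if ms_err == 0 and ms_cond == 0 else ms_cond / ms_err
    eta_p = 0.0 if (ss_cond + ss_err) == 0 else ss_cond / (ss_cond + ss_err)

    correction, eps = "none", None
    if k > 2:
        _, _, _, p_sph = mauchly_test(data)
        if p_sph < alpha_sphericity:
            eps = greenhouse_geisser_epsilon(data)
            correction = "Greenhouse-Geisser"
    if correction == "Greenhouse-Geisser":
        df_use = (eps * df_cond, eps * df_err)
    else:
        df_use = (float(df_cond), float(df_err))
    p = float(sstats.f.sf(F, df_use[0], df_use[1])) if F > 0 else 1.0
    return StatResult(test="rm_anova", statistic=float(F), df=df_use, p=p,
                      effect_size=float(eta_p), effect_name="partial_eta2",
                      correction=correction, epsilon=eps, n=n)


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity-violation factor, in [1/(k-1), 1].

    Computed from the double-centered sample covariance of the conditions:
    eps = tr(S_c)^2 / ((k-1) * sum(S_c^2)).
    """
    data = _check_table(data)
    n, k = data.shape
    S = np.cov(data, rowvar=False)
    Cmat = np.eye(k) - 1.0 / k
    Sc = Cmat @ S @ Cmat
    denom = (k - 1) * np.sum(Sc * Sc)
    if denom <= 0 or np.trace(Sc) <= 0:
        raise ValueError("degenerate condition covariance; epsilon undefined")
    eps = np.trace(Sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(data: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test: returns (W, chi2, df, p).

    Uses the covariance of k-1 orthonormal contrasts; for k = 2 sphericity
    holds trivially (W = 1, p = 1).
    """
    data = _check_table(data)
    n, k = data.shape
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    # orthonormal contrasts: the non-constant columns of a QR basis
    H = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[:-1]]).T)[0][:, 1:]
    S1 = H.T @ np.cov(data, rowvar=False) @ H
    d = k - 1
    det = np.linalg.det(S1)
    tr = np.trace(S1)
    if tr <= 0 or det <= 0:
        return 0.0, np.inf, (k * d) // 2 - 1, 0.0
    W = det / (tr / d) ** d
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = (k * d) // 2 - 1
    p = float(sstats.chi2.sf(chi2, df))
    return float(W), float(chi2), df, p


# ---------------------------------------------------------------------------
# Friedman / Kendall's W
# ---------------------------------------------------------------------------

def friedman_kendall(data: np.ndarray) -> StatResult:
    """Friedman test on a subjects x conditions table, with Kendall's W.

    Ranks within each subject (average ranks on ties); Kendall's W is
    chi2 / (n * (k - 1)).
    """
    data = _check_table(data)
    n, k = data.shape
    if all(np.ptp(row) == 0 for row in data):
        raise ValueError("all rows constant; ranks are undefined")
    chi2, p = sstats.friedmanchisquare(*(data[:, j] for j in range(k)))
    W = float(chi2) / (n * (k - 1))
    return StatResult(test="friedman", statistic=float(chi2), df=(float(k - 1),),
                      p=float(p), effect_size=W, effect_name="kendall_w", n=n)


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D vector")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# assumption screening
# ---------------------------------------------------------------------------

def assumption_screen(data: np.ndarray, alpha: float = 0.05) -> str:
    """Recommend 'rmANOVA', 'rmANOVA+GG' or 'Friedman' for a data table.

    Shapiro-Wilk normality is tested per condition level; any failure sends
    the analysis to the Friedman test.  Otherwise Mauchly's test decides
    whether the Greenhouse-Geisser correction is needed.
    """
    data = _check_table(data)
    for j in range(data.shape[1]):
        col = data[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"condition {j} is constant; screening undefined")
        if sstats.shapiro(col).pvalue < alpha:
            return "Friedman"
    if data.shape[1] > 2 and mauchly_test(data)[3] < alpha:
        return "rmANOVA+GG"
    return "rmANOVA"


# ---------------------------------------------------------------------------
# bootstrap topography similarity
# ---------------------------------------------------------------------------

def bootstrap_topography_similarity(
    topographies: np.ndarray,
    reference: np.ndarray,
    group_size: int = 17,
    iterations: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Bootstrap similarity of per-participant topographies to a reference map.

    Each iteration resamples ``group_size`` participants with replacement,
    averages their channel-wise maps, and Pearson-correlates the average
    with the reference topography.  Returns (mean r, all draws); fully
    reproducible for a fixed seed.
    """
    topographies = np.asarray(topographies, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if topographies.ndim != 2 or topographies.shape[1] != reference.shape[0]:
        raise ValueError(
            f"channel mismatch: topographies {topographies.shape} vs "
            f"reference {reference.shape}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = topographies.shape[0]
    draws = np.empty(iterations)
    ref_c = reference - reference.mean()
    ref_norm = np.sqrt((ref_c ** 2).sum())
    if ref_norm == 0:
        raise ValueError("reference topography has zero variance")
    for it in range(iterations):
        idx = rng.integers(0, n, size=group_size)
        avg = topographies[idx].mean(axis=0)
        avg_c = avg - avg.mean()
        denom = np.sqrt((avg_c ** 2).sum()) * ref_norm
        draws[it] = (avg_c @ ref_c) / denom if denom > 0 else np.nan
    return float(np.nanmean(draws)), draws
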