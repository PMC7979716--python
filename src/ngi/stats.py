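"""Cohort statistics: rank tests, paired CIs, logistic odds ratios,
housekeeping normalisation and quantitative SAM.

Small samples get exact enumeration p-values (Spearman permutation, Wilcoxon
sign-flip, Mann–Whitney labelling enumeration); larger samples fall back on
the standard approximations with tie corrections.  All tests are two-sided
unless stated.  The Mann–Whitney normal approximation omits the continuity
correction so that its p-value coincides algebraically with the two-group
Kruskal–Wallis chi-square p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

_EPS = 1e-12


@dataclass
class TestResult:
    method: str
    statistic: float | None
    p_value: float | None
    n: int | tuple
    exact: bool = False
    estimate: float | None = None
    flag: str | None = None


@dataclass
class PairedDifferenceResult:
    n_pairs: int
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float | None
    level: float = 0.95


@dataclass
class OddsRatioResult:
    or_per_unit: float | None
    ci_low: float | None
    ci_high: float | None
    unit_scale: float
    n: int
    converged: bool
    flag: str | None = None


@dataclass
class ExpressionMatrix:
    """Gene x sample grid of log2 housekeeping-normalised values."""

    values: pd.DataFrame
    housekeeping: tuple
    offsets: pd.Series  # per-sample additive normalisation constant


@dataclass
class SamResult:
    table: pd.DataFrame  # gene, d, q, significant
    s0: float
    n_permutations: int
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])


# ---------------------------------------------------------------------------
# rank-based tests


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = math.sqrt(float((rx * rx).sum() * (ry * ry).sum()))
    if den == 0:
        return math.nan
    return float((rx * ry).sum() / den)


def spearman(x, y, exact_max_n: int = 8) -> TestResult:
    """Spearman rank correlation with midranks for ties.

    p is exact (full permutation enumeration) for n <= ``exact_max_n``, else
    the t-distribution approximation.  Pairs with missing values are dropped;
    a constant input yields a flagged null result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", None, None, n, flag="constant input")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - _EPS
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho_from_ranks(rx, np.array(perm))) >= target:
                count += 1
        return TestResult("spearman", rho, count / total, n, exact=True, estimate=rho)

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult("spearman", rho, float(p), n, estimate=rho)


def _signed_rank_statistic(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive ranks) and the doubled integer ranks of |diff|."""
    ranks2 = np.rint(2.0 * _midranks(np.abs(diff))).astype(np.int64)
    w2 = int(ranks2[diff > 0].sum())
    return w2 / 2.0, ranks2


def paired_wilcoxon(x, y, alternative: str = "two-sided",
                    exact_max_n: int = 12) -> TestResult:
    """Paired Wilcoxon signed-rank test on differences y - x.

    Zero differences are dropped.  Exact sign-flip enumeration for effective
    n <= ``exact_max_n``; otherwise normal approximation with continuity and
    tie corrections.  All-zero differences yield a flagged null result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    diff = y - x
    diff = diff[~np.isnan(diff)]
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        return TestResult("wilcoxon_signed_rank", None, None, 0,
                          flag="all differences zero")
    w, ranks2 = _signed_rank_statistic(diff)
    w2 = int(round(2 * w))
    total2 = int(ranks2.sum())

    if n <= exact_max_n:
        # Distribution of 2*W+ over all 2^n sign assignments by convolution.
        counts = np.zeros(total2 + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:len(counts) - r]
            counts = counts + shifted
        denom = counts.sum()
        lower = counts[:w2 + 1].sum() / denom
        upper = counts[w2:].sum() / denom
        if alternative == "greater":
            p = upper
        elif alternative == "less":
            p = lower
        else:
            p = min(1.0, 2.0 * min(lower, upper))
        return TestResult("wilcoxon_signed_rank", w, float(p), n, exact=True)

    mean = total2 / 2.0 / 2.0
    # variance of W+ under sign flips, tie-corrected: sum(r_i^2) / 4
    var = float(((ranks2 / 2.0) ** 2).sum()) / 4.0
    if var == 0:
        return TestResult("wilcoxon_signed_rank", w, None, n, flag="zero variance")
    if alternative == "greater":
        z = (w - mean - 0.5) / math.sqrt(var)
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w - mean + 0.5) / math.sqrt(var)
        p = sps.norm.cdf(z)
    else:
        cc = 0.5 * np.sign(w - mean)
        z = (w - mean - cc) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("wilcoxon_signed_rank", w, float(min(1.0, p)), n)


def _mann_whitney_u(pooled_ranks2: np.ndarray, n1: int) -> float:
    r1_2 = int(pooled_ranks2[:n1].sum())
    return (r1_2 / 2.0) - n1 * (n1 + 1) / 2.0


def mann_whitney(g1, g2, exact_max_total: int = 12) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact by enumeration of all group labellings when n1 + n2 <=
    ``exact_max_total``; otherwise normal approximation with tie correction
    (no continuity correction; see module docstring).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks2 = np.rint(2.0 * _midranks(pooled)).astype(np.int64)
    u = _mann_whitney_u(ranks2, n1)
    nn = n1 + n2

    if nn <= exact_max_total:
        us = []
        for combo in itertools.combinations(range(nn), n1):
            r1_2 = int(ranks2[list(combo)].sum())
            us.append(r1_2 / 2.0 - n1 * (n1 + 1) / 2.0)
        us = np.array(us)
        lower = float((us <= u + _EPS).mean())
        upper = float((us >= u - _EPS).mean())
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult("mann_whitney", u, p, (n1, n2), exact=True)

    mean = n1 * n2 / 2.0
    ranks = ranks2 / 2.0
    tie_adj = 0.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_adj = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_adj / (nn * (nn - 1)))
    if var == 0:
        return TestResult("mann_whitney", u, None, (n1, n2), flag="zero variance")
    z = (u - mean) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("mann_whitney", u, float(min(1.0, p)), (n1, n2))


def rank_group_test(groups) -> TestResult:
    """Two groups: Mann–Whitney U; more: Kruskal–Wallis with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        return mann_whitney(groups[0], groups[1])
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p),
                      tuple(len(g) for g in groups))


def paired_mean_difference_ci(x, y, level: float = 0.95) -> PairedDifferenceResult:
    """Mean of (y - x) with a t-distribution CI; p from the paired Wilcoxon.

    Mirrors cohort tables that pair a parametric mean difference with a
    nonparametric p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = y - x
    mean = float(d.mean())
    se = float(d.std(ddof=1)) / math.sqrt(n)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, n - 1))
    wil = paired_wilcoxon(x, y)
    return PairedDifferenceResult(
        n_pairs=n, mean_difference=mean,
        ci_low=mean - tcrit * se, ci_high=mean + tcrit * se,
        p_value=wil.p_value, level=level,
    )


# ---------------------------------------------------------------------------
# logistic odds ratios


def logistic_or_pcr(outcome, predictor, unit_scale: float = 1.0,
                    level: float = 0.95) -> OddsRatioResult:
    """Univariate logistic regression odds ratio for a binary outcome.

    OR per ``unit_scale`` predictor units = exp(slope * unit_scale), with the
    Wald CI on the same scale.  Separation / non-convergence is flagged
    rather than raised.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and predictor must have equal length")
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if np.all(x == x[0]):
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:
        return OddsRatioResult(None, None, None, unit_scale, n, False,
                               flag="fit failed")
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3 * max(1.0, abs(beta)):
        return OddsRatioResult(None, None, None, unit_scale, n, False,
                               flag="separation")
    zcrit = float(sps.norm.ppf(0.5 + level / 2.0))
    return OddsRatioResult(
        or_per_unit=math.exp(beta * unit_scale),
        ci_low=math.exp((beta - zcrit * se) * unit_scale),
        ci_high=math.exp((beta + zcrit * se) * unit_scale),
        unit_scale=unit_scale, n=n, converged=converged,
    )


# ---------------------------------------------------------------------------
# expression normalisation and quantitative SAM


def normalize_expression(raw_counts: pd.DataFrame, housekeeping) -> ExpressionMatrix:
    """log2(count + 1), then per-sample housekeeping centring.

    Each sample's values are shifted so its housekeeping-gene mean equals the
    grand housekeeping mean over all samples.
    """
    housekeeping = tuple(housekeeping)
    missing = [g for g in housekeeping if g not in raw_counts.index]
    if missing:
        raise ValueError(f"housekeeping genes missing from matrix: {missing}")
    logged = np.log2(raw_counts.astype(float) + 1.0)
    hk = logged.loc[list(housekeeping)]
    grand = float(hk.to_numpy().mean())
    offsets = grand - hk.mean(axis=0)
    values = logged.add(offsets, axis=1)
    return ExpressionMatrix(values=values, housekeeping=housekeeping, offsets=offsets)


def _regression_d(X: np.ndarray, y: np.ndarray, s0: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene slope of expression on y, its SE, and d = slope/(SE + s0)."""
    n = len(y)
    yc = y - y.mean()
    sxx = float((yc * yc).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    slopes = (Xc @ yc) / sxx
    rss = (Xc * Xc).sum(axis=1) - slopes ** 2 * sxx
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(se + s0 > 0, slopes / (se + s0), 0.0)
    return slopes, se, d


def _choose_s0(slopes: np.ndarray, se: np.ndarray, n_bins: int = 10) -> float:
    """SAM fudge factor: the s-percentile minimising the coefficient of
    variation of the spread of d across s-quantile windows."""
    candidates = np.percentile(se, np.arange(0, 101, 5))
    # bin genes by se quantile once
    order = np.argsort(se, kind="stable")
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = float(np.median(se)), np.inf
    for s0 in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(se + s0 > 0, slopes / (se + s0), 0.0)
        mads = np.array([sps.median_abs_deviation(d[b]) for b in bins if len(b) > 1])
        mu = mads.mean()
        if mu <= 0:
            continue
        cv = mads.std(ddof=0) / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_til_association(expr: ExpressionMatrix | pd.DataFrame, stils,
                        fdr_threshold: float = 0.01, n_permutations: int = 1000,
                        seed: int = 0) -> SamResult:
    """Quantitative SAM: which genes track a continuous response (sTILs).

    Per gene, d_i = r_i / (s_i + s0) with r_i the least-squares slope of
    expression on the response and s_i its standard error; s0 regularises
    low-variance genes.  The null |d| distribution comes from seeded
    permutations of the response; q-values are median-false-call FDRs,
    monotone non-increasing in |d| (pi0 = 1, conservative).
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    y = np.asarray(stils, dtype=float)
    if values.shape[1] != len(y):
        raise ValueError("sample counts of expression matrix and sTILs differ")
    X = values.to_numpy(dtype=float)
    genes = list(values.index)

    slopes, se, _ = _regression_d(X, y, 0.0)
    s0 = max(_choose_s0(slopes, se), 1e-12)
    d = slopes / (se + s0)
    absd = np.abs(d)

    rng = np.random.default_rng(seed)
    m = len(genes)
    # Null counts: for each observed |d| threshold, #{null |d*| >= t} per perm.
    thresholds = np.sort(absd)
    exceed = np.empty((n_permutations, m), dtype=np.int32)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        _, _, dp = _regression_d(X, yp, s0)
        null_sorted = np.sort(np.abs(dp))
        exceed[b] = m - np.searchsorted(null_sorted, thresholds, side="left")
    med_false = np.median(exceed, axis=0)

    n_called = m - np.arange(m)  # #{|d| >= t} at each sorted threshold
    fdr = np.minimum(1.0, med_false / n_called)
    # q at threshold t = min FDR over all rejection regions containing t.
    q_sorted = np.minimum.accumulate(fdr)
    # map back to genes: gene with sorted position k gets q_sorted[k]
    order = np.argsort(absd, kind="stable")
    q = np.empty(m)
    q[order] = q_sorted

    table = pd.DataFrame({
        "gene": genes, "slope": slopes, "se": se, "d": d, "q": q,
        "significant": q < fdr_threshold,
    })
    table = table.sort_values("q", kind="stable").reset_index(drop=True)
    return SamResult(table=table, s0=s0, n_permutations=n_permutations,
                     fdr_threshold=fdr_threshold)
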