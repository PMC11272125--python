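"""Distributional statistics of TIL proportion across cohorts.

Nonparametric comparisons (Kruskal–Wallis, Wilcoxon rank-sum, Pearson
chi-square, Spearman) with Bonferroni correction, and the multivariable
linear model of TIL % on clinical covariates with standardised
coefficients — the statistics used to characterise how lymphocyte
infiltration differs by demographics and cancer type.

Scipy/statsmodels back the computations; this module fixes conventions
(tie handling, reference levels, complete-case analysis) and the result
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class DegenerateDataError(ValueError):
    """The data carry no information for the requested test."""


class CollinearityError(ValueError):
    """The regression design is rank-deficient."""


@dataclass
class TestResult:
    """One hypothesis test: statistic, df, p, optional adjusted p and summaries."""

    statistic: float
    df: Optional[float]
    p: float
    adjusted_p: Optional[float] = None
    group_summaries: list[dict] = field(default_factory=list)


@dataclass
class RegressionFit:
    """OLS fit: per-term B, SE, CI, standardised Beta, p; R2 and adjusted R2."""

    terms: list[str]
    B: np.ndarray
    SE: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    beta_std: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "B": self.B,
                "SE": self.SE,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "Beta": self.beta_std,
                "p": self.p,
            }
        )


def _summaries(groups: Sequence[np.ndarray]) -> list[dict]:
    out = []
    for g in groups:
        out.append(
            {
                "n": len(g),
                "median": float(np.median(g)),
                "iqr": (float(np.quantile(g, 0.25)), float(np.quantile(g, 0.75))),
            }
        )
    return out


def _kw_exact_p(gs: list[np.ndarray], observed: float) -> float:
    """P(H >= observed) by full enumeration of group assignments."""
    import itertools

    sizes = [len(g) for g in gs]
    pooled = np.concatenate(gs)
    count = total = 0

    def _h(arranged):
        return stats.kruskal(*arranged).statistic

    def recurse(remaining, gi, chosen):
        nonlocal count, total
        if gi == len(sizes) - 1:
            total += 1
            count += _h(chosen + [pooled[remaining]]) >= observed - 1e-12
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [r for r in remaining if r not in comb]
            recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    recurse(list(range(len(pooled))), 0, [])
    return count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]], exact_max_n: int = 12
) -> TestResult:
    """Tie-corrected Kruskal–Wallis H.

    The p-value comes from the chi-square approximation with g-1 df, except
    for tiny pooled samples (n <= ``exact_max_n``), where the exact
    permutation distribution of H is enumerated — the chi-square
    approximation is unreliable at such sizes.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations tied across all groups")
    h, p = stats.kruskal(*gs)
    if len(pooled) <= exact_max_n:
        p = _kw_exact_p(gs, float(h))
    return TestResult(
        statistic=float(h), df=len(gs) - 1, p=float(p), group_summaries=_summaries(gs)
    )


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney U with tie correction).

    Exact null distribution when the smaller sample has <= 8 observations
    and there are no ties; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        group_summaries=_summaries([a, b]),
    )


def chi_square_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r x c contingency table (no Yates correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise DegenerateDataError("expected count of zero")
    return TestResult(statistic=float(chi2), df=float(dof), p=float(p))


def bonferroni_adjust(pvals: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """min(1, m * p) for each p; m defaults to the number of comparisons."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise DegenerateDataError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fit_linear_model(
    design: pd.DataFrame,
    y: Sequence[float],
    categorical: Optional[dict[str, str]] = None,
) -> RegressionFit:
    """OLS of TIL % on a covariate table, with standardised coefficients.

    ``categorical`` maps column names to their reference level; those
    columns are dummy-coded with the stated reference dropped.  Rows with
    any missing value are excluded (complete-case).  Standardised Beta for
    each term is B * SD(x_term) / SD(y).  CIs are B +/- 1.96 * SE.

    Raises
    ------
    CollinearityError
        If the dummy-coded design is rank-deficient, naming the terms.
    """
    design = design.copy()
    y = pd.Series(np.asarray(y, dtype=float), index=design.index, name="y")
    cc = design.notna().all(axis=1) & y.notna()
    design, y = design.loc[cc], y.loc[cc]

    cols = []
    for name in design.columns:
        col = design[name]
        if categorical and name in categorical:
            ref = categorical[name]
            levels = [l for l in pd.unique(col) if l != ref]
            for lev in sorted(map(str, levels)):
                cols.append(pd.Series((col.astype(str) == lev).astype(float),
                                      name=f"{name}[{lev}]"))
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, pd.unique(col)))
            for lev in levels[1:]:  # first level is the reference
                cols.append(pd.Series((col.astype(str) == lev).astype(float),
                                      name=f"{name}[{lev}]"))
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1)
    Xc = sm.add_constant(X, has_constant="add")

    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending terms: columns whose removal restores full rank
        bad = []
        arr = Xc.to_numpy()
        for i, name in enumerate(Xc.columns):
            if name == "const":
                continue
            sub = np.delete(arr, i, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise CollinearityError(f"rank-deficient design; involved terms: {bad}")

    fit = sm.OLS(y.to_numpy(), Xc).fit()
    terms = [c for c in Xc.columns if c != "const"]
    B = np.array([fit.params[t] for t in terms])
    SE = np.array([fit.bse[t] for t in terms])
    pvals = np.array([fit.pvalues[t] for t in terms])
    z = 1.959963984540054
    sd_y = float(y.std(ddof=1))
    beta_std = np.array(
        [fit.params[t] * float(X[t].std(ddof=1)) / sd_y for t in terms]
    )
    return RegressionFit(
        terms=terms,
        B=B,
        SE=SE,
        ci_low=B - z * SE,
        ci_high=B + z * SE,
        beta_std=beta_std,
        p=pvals,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
    )
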