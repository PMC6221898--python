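"""Statistical battery for the rating and band-power analyses.

Covers: paired-samples t tests with effect sizes, the χ² goodness-of-fit
frequency test, 2×2 fully-within-subject interaction contrasts (univariate
F and the two-response Hotelling T² / Wilks λ form), partial correlation
with Benjamini–Hochberg FDR control, and forward/backward stepwise
multiple linear regression.

With two two-level within factors, the interaction test reduces exactly
to a one-sample test on the per-subject double difference
g_i = (A1 − A2) − (B1 − B2): univariately F = t², and with p responses a
Hotelling T² on the double-difference vectors, with Wilks
λ = 1/(1 + T²/(n−1)) and F = ((n−p)/p)·T²/(n−1) on (p, n−p) degrees of
freedom.  Sphericity corrections are no-ops for two-level factors.

Effect sizes for paired designs: d_z = mean(diff)/sd(diff) (reported by
default) and d_av = mean(diff)/((sd_x + sd_y)/2); both are attached to
every paired result because published values are frequently computed
either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    label: str = ""
    kind: str = ""                  # "t", "chi2", "F", "T2", "r"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")

    def as_row(self) -> dict:
        row = {"label": self.label, "kind": self.kind,
               "statistic": self.statistic, "p": self.p,
               "effect_size": self.effect_size}
        for i, d in enumerate(self.df, start=1):
            row[f"df{i}"] = d
        row.update(self.extra)
        return row


def paired_t(x, y, label: str = "") -> StatResult:
    """Paired-samples t test, two-sided, with d_z and d_av effect sizes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t, p = scipy.stats.ttest_rel(x, y)
    d_z = 0.0 if sd == 0 and mean == 0 else (np.inf * np.sign(mean) if sd == 0
                                             else mean / sd)
    denom_av = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    d_av = mean / denom_av if denom_av > 0 else np.nan
    return StatResult(statistic=float(t), df=(n - 1,), p=float(p),
                      effect_size=float(abs(d_z)), label=label, kind="t",
                      extra={"mean_diff": mean, "sd_diff": sd,
                             "d_z": float(d_z),
                             "d_av": float(d_av) if np.isfinite(d_av) else np.nan})


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int,
                          label: str = "") -> StatResult:
    """Paired t reconstructed from the summary of the differences."""
    if n < 2 or sd_diff <= 0:
        raise ValueError("need n >= 2 and sd_diff > 0")
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return StatResult(statistic=float(t), df=(n - 1,), p=float(p),
                      effect_size=float(abs(mean_diff / sd_diff)),
                      label=label, kind="t")


def chi_square_gof(observed_counts, expected_counts, label: str = "") -> StatResult:
    """χ² goodness-of-fit: Σ (O−E)²/E with k−1 degrees of freedom."""
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_counts, dtype=float)
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive")
    stat, p = scipy.stats.chisquare(obs, exp)
    n = obs.sum()
    w = np.sqrt(stat / n) if n > 0 else np.nan   # Cohen's w
    return StatResult(statistic=float(stat), df=(obs.size - 1,), p=float(p),
                      effect_size=float(w), label=label, kind="chi2")


def _double_difference(cells: np.ndarray) -> np.ndarray:
    if cells.ndim < 3 or cells.shape[1:3] != (2, 2):
        raise ValueError("expect a subjects × 2 × 2 (× p) array")
    return (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])


def within_interaction_univariate(cells, label: str = "") -> StatResult:
    """2×2 fully-within interaction F test on one response.

    ``cells`` is subjects × factor-A levels × factor-B levels.  F equals
    the squared one-sample t on the double difference; partial η² is
    t²/(t² + n − 1).
    """
    g = _double_difference(np.asarray(cells, dtype=float))
    n = g.size
    sd = g.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if g.mean() == 0.0 else np.inf
    else:
        t = g.mean() / (sd / np.sqrt(n))
    F = t ** 2
    p = float(scipy.stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
    eta = F / (F + n - 1) if np.isfinite(F) else 1.0
    return StatResult(statistic=float(F), df=(1, n - 1), p=p,
                      effect_size=float(eta), label=label, kind="F")


def within_interaction_multivariate(cells, label: str = "") -> StatResult:
    """2×2 within-subject interaction on p responses jointly.

    ``cells`` is subjects × 2 × 2 × p.  A one-sample Hotelling T² on the
    p-vector of double differences; reported as Wilks λ and its exact F.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expect subjects × 2 × 2 × p array")
    G = _double_difference(arr)                     # n × p
    n, p = G.shape
    if n <= p:
        raise ValueError("need more subjects than response variables")
    mean = G.mean(axis=0)
    cov = np.cov(G, rowvar=False, ddof=1)
    if not G.any():                         # double differences identically zero
        T2 = 0.0
    else:
        try:
            sol = np.linalg.solve(np.atleast_2d(cov), mean)
        except np.linalg.LinAlgError:
            raise ValueError("singular covariance of double differences") from None
        T2 = float(n * mean @ sol)
    lam = 1.0 / (1.0 + T2 / (n - 1))
    F = (n - p) / p * T2 / (n - 1)
    pval = float(scipy.stats.f.sf(F, p, n - p))
    eta = 1.0 - lam
    return StatResult(statistic=float(F), df=(p, n - p), p=pval,
                      effect_size=float(eta), label=label, kind="F",
                      extra={"wilks_lambda": lam, "hotelling_T2": T2})


def partial_correlation(x, y, covariates=None, label: str = "") -> StatResult:
    """Pearson correlation of x and y after partialling out covariates.

    Both variables are residualized on the covariates (plus intercept) by
    least squares; the t-based p uses n − #covariates − 2 degrees of
    freedom.  With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r ** 2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=df)
    return StatResult(statistic=r, df=(df,), p=float(p), effect_size=abs(r),
                      label=label, kind="r", extra={"t": float(t)})


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≥ raw)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RegressionModel:
    """Final stepwise model: selected predictors and their coefficients."""

    predictors: list[str]
    coef: pd.Series                 # unstandardized B, incl. intercept "const"
    stderr: pd.Series
    beta: pd.Series                 # standardized coefficients (no intercept)
    adj_r2: float
    f_stat: float
    f_p: float
    n: int

    def __post_init__(self) -> None:
        if self.adj_r2 > 1.0 + 1e-12:
            raise ValueError("adjusted R² cannot exceed 1")


def stepwise_regression(candidates: pd.DataFrame, y, p_enter: float = 0.05,
                        p_remove: float = 0.10) -> RegressionModel:
    """Forward/backward stepwise OLS selection by partial-F p-values.

    At each step the not-yet-included candidate with the smallest
    coefficient p-value enters if that p < ``p_enter``; then any included
    predictor whose p exceeds ``p_remove`` leaves (worst first).  Stops
    at a fixed point; a guard of 4 × #candidates iterations prevents
    cycling (and ``p_enter > p_remove`` is rejected outright, which is
    the classical cycling hazard).
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must not exceed p_remove (risk of cycling)")
    y = np.asarray(y, dtype=float)
    X = candidates.astype(float)
    if len(y) != len(X):
        raise ValueError("y and candidate matrix length mismatch")

    def fit(cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, design).fit()

    included: list[str] = []
    if y.std(ddof=0) == 0:          # degenerate: nothing to explain
        res = fit(included)
        return RegressionModel(predictors=[], coef=res.params, stderr=res.bse,
                               beta=pd.Series(dtype=float), adj_r2=0.0,
                               f_stat=0.0, f_p=1.0, n=len(y))
    for _ in range(4 * max(1, X.shape[1])):
        changed = False
        trials = {}
        for col in X.columns:
            if col in included:
                continue
            res = fit(included + [col])
            trials[col] = res.pvalues[col]
        if trials:
            best = min(trials, key=trials.get)
            if trials[best] < p_enter:
                included.append(best)
                changed = True
        while included:
            res = fit(included)
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise RuntimeError("stepwise selection failed to stabilize")

    res = fit(included)
    sd_y = y.std(ddof=1)
    beta = pd.Series(
        {c: res.params[c] * X[c].std(ddof=1) / sd_y for c in included}
        if sd_y > 0 else {c: 0.0 for c in included})
    return RegressionModel(
        predictors=included,
        coef=res.params,
        stderr=res.bse,
        beta=beta,
        adj_r2=float(res.rsquared_adj) if included else 0.0,
        f_stat=float(res.fvalue) if included else 0.0,
        f_p=float(res.f_pvalue) if included else 1.0,
        n=len(y),
    )
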