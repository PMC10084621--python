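"""Canonical correlation analysis between a phenotypic and an environmental
variable set, with loadings, cross-loadings, per-individual canonical scores,
and the Wilks'-lambda significance ladder under Rao's F approximation.

Model
-----
Given standardized trait matrix X (N x p) and coded environment matrix Y
(N x q), CCA finds weight vectors a_k, b_k maximizing corr(X a_k, Y b_k)
subject to successive score pairs being uncorrelated within each set. The
m = min(p, q) canonical correlations rho_1 >= ... >= rho_m are the singular
values of the whitened cross-covariance Sxx^{-1/2} Sxy Syy^{-1/2}.

The significance of correlations k..m is tested with Wilks' lambda
Lambda_k = prod_{i>=k} (1 - rho_i^2) and Rao's F approximation. With
p' = p - k + 1, q' = q - k + 1:

    s   = sqrt((p'^2 q'^2 - 4) / (p'^2 + q'^2 - 5))   (s = 1 if p'q' <= 3
                                                       or the denominator is 0)
    t   = (N - 1) - (p + q + 1) / 2                    (original p, q for all k)
    df1 = p' q'
    df2 = s * t - p' q' / 2 + 1
    F   = ((1 - Lambda_k^{1/s}) / Lambda_k^{1/s}) * (df2 / df1)

Signs of canonical axes are mathematically arbitrary; each axis is oriented
so that the environment weight of largest magnitude is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

#: binary environment coding, recorded in result metadata
ENVIRONMENT_CODING = {
    "latitude": {"high": 0, "central": 1},
    "temperature": {20: 0, 24: 1},
    "predator": {"absent": 0, "present": 1},
}


def code_environment(pheno: pd.DataFrame) -> pd.DataFrame:
    """Code latitude/temperature/predator as 0/1 columns indexed by individual."""
    coded = pd.DataFrame(
        {
            "latitude": pheno["latitude"].map(ENVIRONMENT_CODING["latitude"]).to_numpy(),
            "temperature": pheno["temperature"].map(ENVIRONMENT_CODING["temperature"]).to_numpy(),
            "predator": pheno["predator"].map(ENVIRONMENT_CODING["predator"]).to_numpy(),
        },
        index=pd.Index(pheno["individual_id"], name="individual_id"),
    )
    if coded.isna().any().any():
        raise ValidationError("unrecognized environment level during coding")
    return coded.astype(float)


@dataclass
class WilksTest:
    """One rung of the ladder: test of correlations k..m jointly."""

    k: int
    lambda_: float
    s: float
    df1: float
    df2: float
    F: float
    p_value: float


@dataclass
class CcaResult:
    rho: np.ndarray                 # canonical correlations, descending
    x_weights: pd.DataFrame         # trait -> axis coefficients (standardized scale)
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame          # CCp: individual x axis
    y_scores: pd.DataFrame          # CCe
    x_loadings: pd.DataFrame        # corr(trait, CCp axis)
    y_loadings: pd.DataFrame
    x_cross_loadings: pd.DataFrame  # corr(trait, CCe axis)
    y_cross_loadings: pd.DataFrame
    n: int
    p: int
    q: int
    coding: dict

    @property
    def m(self) -> int:
        return len(self.rho)


def _standardize(df: pd.DataFrame, what: str) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        col = df.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValidationError(f"{what} column {col!r} is constant")
    return (arr - arr.mean(axis=0)) / sd


def _inv_sqrt(mat: np.ndarray, cols, what: str) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    tol = 1e-10 * vals.max()
    if vals.min() < tol:
        # name the offending column: the one with the largest weight in the
        # null-space eigenvector
        null_vec = vecs[:, int(np.argmin(vals))]
        col = cols[int(np.argmax(np.abs(null_vec)))]
        raise ValidationError(
            f"{what} set is rank-deficient; column {col!r} is linearly dependent"
        )
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def fit_cca(X: pd.DataFrame, Y: pd.DataFrame) -> CcaResult:
    """Fit CCA between trait matrix X and coded environment Y.

    Both sets are standardized internally; rows must align one-to-one.
    """
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValidationError(f"need N > p + q (got N={n}, p={p}, q={q})")
    Xs = _standardize(X, "trait")
    Ys = _standardize(Y, "environment")
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    Kx = _inv_sqrt(Sxx, list(X.columns), "trait")
    Ky = _inv_sqrt(Syy, list(Y.columns), "environment")
    U, d, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    m = min(p, q)
    rho = np.clip(d[:m], 0.0, 1.0)
    a = Kx @ U[:, :m]     # x weights on standardized scale
    b = Ky @ Vt.T[:, :m]  # y weights

    # orient: environment weight of largest magnitude positive per axis
    for j in range(m):
        lead = int(np.argmax(np.abs(b[:, j])))
        if b[lead, j] < 0:
            a[:, j] *= -1
            b[:, j] *= -1

    axes = [f"axis{j + 1}" for j in range(m)]
    x_scores = Xs @ a
    y_scores = Ys @ b

    def corr_with(scores: np.ndarray, block: np.ndarray) -> np.ndarray:
        sc = (scores - scores.mean(0)) / scores.std(0, ddof=1)
        return block.T @ sc / (n - 1)

    res = CcaResult(
        rho=rho,
        x_weights=pd.DataFrame(a, index=X.columns, columns=axes),
        y_weights=pd.DataFrame(b, index=Y.columns, columns=axes),
        x_scores=pd.DataFrame(x_scores, index=X.index, columns=axes),
        y_scores=pd.DataFrame(y_scores, index=Y.index, columns=axes),
        x_loadings=pd.DataFrame(corr_with(x_scores, Xs), index=X.columns, columns=axes),
        y_loadings=pd.DataFrame(corr_with(y_scores, Ys), index=Y.columns, columns=axes),
        x_cross_loadings=pd.DataFrame(corr_with(y_scores, Xs), index=X.columns, columns=axes),
        y_cross_loadings=pd.DataFrame(corr_with(x_scores, Ys), index=Y.columns, columns=axes),
        n=n, p=p, q=q, coding=ENVIRONMENT_CODING,
    )
    return res


def wilks_ladder(rho: np.ndarray, n: int, p: int, q: int) -> list[WilksTest]:
    """Test correlations k..m for k = 1..m via Wilks' lambda and Rao's F."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho >= 1)):
        raise ValidationError("canonical correlations must lie in [0, 1)")
    if np.any(np.diff(rho) > 1e-12):
        raise ValidationError("canonical correlations must be non-increasing")
    if n <= p + q:
        raise ValidationError("need N > p + q")
    m = len(rho)
    t = (n - 1) - (p + q + 1) / 2.0
    out: list[WilksTest] = []
    for k in range(1, m + 1):
        pp = p - k + 1
        qq = q - k + 1
        lam = float(np.prod(1.0 - rho[k - 1:] ** 2))
        denom = pp**2 + qq**2 - 5
        if pp * qq <= 3 or denom == 0:
            s = 1.0
        else:
            s = np.sqrt((pp**2 * qq**2 - 4.0) / denom)
        df1 = float(pp * qq)
        df2 = s * t - pp * qq / 2.0 + 1.0
        lam_s = lam ** (1.0 / s)
        F = (1.0 - lam_s) / lam_s * (df2 / df1)
        pval = float(stats.f.sf(F, df1, df2))
        out.append(WilksTest(k=k, lambda_=lam, s=float(s), df1=df1, df2=float(df2),
                             F=float(F), p_value=pval))
    return out


def wilks_table(tests: list[WilksTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [t.k for t in tests],
            "wilks_lambda": [t.lambda_ for t in tests],
            "df1": [t.df1 for t in tests],
            "df2": [t.df2 for t in tests],
            "F": [t.F for t in tests],
            "p_value": [t.p_value for t in tests],
        }
    ).set_index("k")


def significant_loadings(res: CcaResult, threshold: float = 0.30) -> pd.DataFrame:
    """Flag variables whose |loading| strictly exceeds the threshold.

    Returns a long table (set, variable, axis, loading, cross_loading,
    significant) covering both variable sets.
    """
    rows = []
    for set_name, load, cross in (
        ("phenotype", res.x_loadings, res.x_cross_loadings),
        ("environment", res.y_loadings, res.y_cross_loadings),
    ):
        for var in load.index:
            for axis in load.columns:
                val = float(load.loc[var, axis])
                rows.append({
                    "set": set_name, "variable": var, "axis": axis,
                    "loading": val, "cross_loading": float(cross.loc[var, axis]),
                    "significant": abs(val) > threshold,
                })
    return pd.DataFrame(rows)


def canonical_scores(res: CcaResult) -> pd.DataFrame:
    """Per-individual CCp/CCe scores, one row per individual, 2m columns."""
    ccp = res.x_scores.rename(columns=lambda a: "CCp" + a.removeprefix("axis"))
    cce = res.y_scores.rename(columns=lambda a: "CCe" + a.removeprefix("axis"))
    return pd.concat([ccp, cce], axis=1)
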