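"""Negative-binomial differential expression for a two-group contrast.

The route mirrors the classic exact-test workflow for simple two-group
RNA-seq designs: low-expression filtering on CPM, TMM (trimmed mean of
M-values) composition normalization, conditional-maximum-likelihood
dispersion estimation with empirical-Bayes shrinkage toward a common value,
an exact conditional NB test per gene, and Benjamini-Hochberg FDR control.

Counts for gene g in sample j are modeled NB with mean proportional to the
effective library size (library size x TMM factor) and gene dispersion
phi_g, so that var = mu + phi_g mu^2. Before dispersion estimation and
testing, counts are rescaled ("pseudo-counts") to the geometric mean of the
effective library sizes and rounded, which makes samples exchangeable within
a group and the conditional likelihood/test applicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

_PHI_MIN, _PHI_MAX = 1e-4, 10.0
_PRIOR_COUNT = 0.125  # per-sample logFC prior, per million reads of common library


@dataclass
class NormalizationFactors:
    lib_size: pd.Series       # raw column sums
    tmm: pd.Series            # TMM factors, geometric mean 1

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.tmm


@dataclass
class DispersionModel:
    common: float
    tagwise: pd.Series        # per-gene dispersions, indexed like the counts
    prior_df: float


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_size: pd.Series | None = None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if lib_size is None else lib_size
    return counts / lib * 1e6


def filter_low_expression(counts: pd.DataFrame, groups: pd.Series | None = None,
                          min_cpm: float = 1.0,
                          min_samples: int | None = None) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in at least min_samples samples
    (default: the smaller group size, which requires ``groups``)."""
    if min_samples is None:
        if groups is None:
            raise ValidationError("need either groups or an explicit min_samples")
        sizes = groups.value_counts()
        if len(sizes) != 2:
            raise ValidationError("filtering expects exactly two groups")
        min_samples = int(sizes.min())
    keep = (cpm(counts) > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "no gene passes the expression filter; lower min_cpm or min_samples"
        )
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile. Per sample, M (log2 ratio) and A (mean log2
    abundance) values are computed over genes with nonzero counts in both the
    sample and the reference; the M tails (``trim_m`` each side) and A tails
    (``trim_a``) are trimmed, and the factor is 2**(precision-weighted mean M).
    Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        empty = lib.index[int(np.flatnonzero(lib.to_numpy() == 0)[0])]
        raise ValidationError(f"sample {empty!r} has zero library size")
    rel = counts.to_numpy(dtype=float) / lib.to_numpy()
    uq = np.quantile(np.where(rel > 0, rel, np.nan), 0.75, axis=0)
    uq = np.nan_to_num(uq)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    ref = rel[:, ref_idx]
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs = rel[:, j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            continue
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        # asymptotic (delta-method) variance of M
        nj, nr = lib.iloc[j], lib.iloc[ref_idx]
        yj, yr = counts.iloc[:, j].to_numpy(float)[ok], counts.iloc[:, ref_idx].to_numpy(float)[ok]
        w = (nj - yj) / (nj * yj) + (nr - yr) / (nr * yr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(w[keep]).all():
            continue
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(lib_size=lib, tmm=pd.Series(factors, index=counts.columns))


def pseudo_counts(counts: pd.DataFrame, norm: NormalizationFactors,
                  round_: bool = True) -> tuple[pd.DataFrame, float]:
    """Rescale counts to the geometric mean of the effective library sizes
    (rounded to integers unless ``round_`` is False). Returns (pseudo matrix,
    common library size)."""
    eff = norm.effective_lib_size.reindex(counts.columns)
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts * (common / eff)
    if round_:
        pseudo = pseudo.round().astype(np.int64)
    return pseudo, common


# ---------------------------------------------------------------------------
# dispersion estimation (conditional likelihood + weighted shrinkage)
# ---------------------------------------------------------------------------

def _cond_loglik_profile(pseudo: np.ndarray, group_masks: list[np.ndarray],
                         log_phi_grid: np.ndarray) -> np.ndarray:
    """Per-gene NB conditional log-likelihood evaluated on a dispersion grid.

    For a group of n exchangeable NB(mu, phi) counts y_i with sum z, the
    likelihood conditional on z depends only on r = 1/phi:

        l(r) = sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(z + n r) - n lgamma(r)

    Returns a (genes x grid) matrix summed over the two groups.
    """
    G = pseudo.shape[0]
    out = np.zeros((G, len(log_phi_grid)))
    for mask in group_masks:
        y = pseudo[:, mask]                      # G x n
        n = int(mask.sum())
        z = y.sum(axis=1)                        # G
        for k, lphi in enumerate(log_phi_grid):
            r = np.exp(-lphi)
            out[:, k] += (gammaln(y + r).sum(axis=1) + gammaln(n * r)
                          - gammaln(z + n * r) - n * gammaln(r))
    return out


def _refine(grid: np.ndarray, vals: np.ndarray, idx: int) -> float:
    """Parabolic interpolation of the maximum around grid point ``idx``."""
    if idx == 0 or idx == len(grid) - 1:
        return grid[idx]
    h = grid[idx] - grid[idx - 1]
    y0, y1, y2 = vals[idx - 1], vals[idx], vals[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return grid[idx]
    return grid[idx] + 0.5 * h * (y0 - y2) / denom


def estimate_dispersions(counts: pd.DataFrame, groups: pd.Series,
                         norm: NormalizationFactors, prior_df: float = 10.0,
                         n_grid: int = 61) -> DispersionModel:
    """Common + tagwise NB dispersions via conditional maximum likelihood.

    The common dispersion maximizes the summed per-gene conditional
    log-likelihood; tagwise dispersions maximize the per-gene likelihood plus
    ``prior_df`` times the average (per-gene) common profile, i.e. weighted
    -likelihood shrinkage. ``prior_df = inf`` collapses every gene to the
    common value. Optimization is over a log-dispersion grid on
    [1e-4, 10] with parabolic refinement.
    """
    groups = groups.reindex(counts.columns)
    levels = groups.unique()
    if len(levels) != 2:
        raise ValidationError("dispersion estimation expects exactly two groups")
    masks = [(groups == lv).to_numpy() for lv in levels]
    if min(m.sum() for m in masks) < 2:
        raise ValidationError("each group needs >= 2 samples to identify dispersion")
    pseudo, _ = pseudo_counts(counts, norm)
    grid = np.linspace(np.log(_PHI_MIN), np.log(_PHI_MAX), n_grid)
    L = _cond_loglik_profile(pseudo.to_numpy(), masks, grid)

    common_prof = L.sum(axis=0)
    ci = int(np.argmax(common_prof))
    common = float(np.exp(_refine(grid, common_prof, ci)))

    if np.isinf(prior_df):
        tag = np.full(counts.shape[0], common)
    else:
        shared = prior_df * (L.mean(axis=0))
        W = L + shared[None, :]
        idx = W.argmax(axis=1)
        tag = np.empty(counts.shape[0])
        for g in range(counts.shape[0]):
            tag[g] = np.exp(_refine(grid, W[g], int(idx[g])))
    return DispersionModel(common=common,
                           tagwise=pd.Series(tag, index=counts.index),
                           prior_df=prior_df)


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def _nb_params(mean: float, phi: float) -> tuple[float, float]:
    """scipy nbinom (n, p) for a given mean and dispersion."""
    r = 1.0 / max(phi, 1e-8)
    return r, r / (r + mean)


def exact_nb_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional NB p-value for a two-group split.

    Conditions the group-1 sum on the total; the per-sample mean is the
    pooled estimate total/(n1+n2). Two-sided by summing the probabilities of
    all outcomes no more likely than the observed one.
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    k = np.arange(t + 1)
    logp = (nbinom.logpmf(k, *_nb_params(n1 * mu, phi / n1))
            + nbinom.logpmf(t - k, *_nb_params(n2 * mu, phi / n2)))
    logp -= np.logaddexp.reduce(logp)   # renormalize to the conditional law
    obs = logp[y1]
    p = np.exp(np.logaddexp.reduce(logp[logp <= obs + 1e-10]))
    return float(min(p, 1.0))


def exact_test(counts: pd.DataFrame, high_ids: list[str], low_ids: list[str],
               norm: NormalizationFactors, model: DispersionModel) -> pd.DataFrame:
    """Per-gene exact NB test of high vs low group.

    Returns a DataFrame indexed by gene with columns ``logFC`` (log2, high
    over low), ``p_value``, ``fdr`` (Benjamini-Hochberg) and ``avg_log2cpm``.
    """
    missing = [s for s in list(high_ids) + list(low_ids) if s not in counts.columns]
    if missing:
        raise ValidationError(f"samples absent from counts: {missing}")
    sub = counts[list(high_ids) + list(low_ids)]
    pseudo, common = pseudo_counts(sub, NormalizationFactors(
        lib_size=norm.lib_size.reindex(sub.columns),
        tmm=norm.tmm.reindex(sub.columns)), round_=False)
    n1, n2 = len(high_ids), len(low_ids)
    # exact group sums for logFC; rounded sums for the discrete conditional test
    y1f = pseudo[list(high_ids)].sum(axis=1).to_numpy()
    y2f = pseudo[list(low_ids)].sum(axis=1).to_numpy()
    y1 = np.round(y1f).astype(np.int64)
    y2 = np.round(y2f).astype(np.int64)
    phi = model.tagwise.reindex(counts.index).to_numpy()

    pvals = np.array([
        exact_nb_pvalue(int(a), int(b), n1, n2, float(f))
        for a, b, f in zip(y1, y2, phi)
    ])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    # prior scales with the common library so logFC is depth-invariant
    prior = _PRIOR_COUNT * common / 1e6
    logfc = np.log2((y1f / n1 + prior) / (y2f / n2 + prior))
    eff = norm.effective_lib_size.reindex(sub.columns).to_numpy()
    avg = np.log2(((sub.to_numpy() + 0.5) / (eff + 1.0) * 1e6)).mean(axis=1)
    return pd.DataFrame(
        {"logFC": logfc, "p_value": pvals, "fdr": fdr, "avg_log2cpm": avg},
        index=counts.index,
    )


def run_de(counts: pd.DataFrame, high_ids: list[str], low_ids: list[str],
           min_cpm: float = 1.0, prior_df: float = 10.0) -> pd.DataFrame:
    """Filter -> TMM -> dispersions -> exact test for one contrast."""
    ids = list(high_ids) + list(low_ids)
    sub = counts[ids]
    groups = pd.Series(["high"] * len(high_ids) + ["low"] * len(low_ids), index=ids)
    filtered = filter_low_expression(sub, groups, min_cpm=min_cpm)
    norm = tmm_factors(filtered)
    model = estimate_dispersions(filtered, groups, norm, prior_df=prior_df)
    return exact_test(filtered, list(high_ids), list(low_ids), norm, model)
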