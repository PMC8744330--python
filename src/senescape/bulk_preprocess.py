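"""Filtering, TMM normalization, log2 transform and covariate adjustment.

The residual expression produced here is the substrate for network
construction and age correlation.  The steps mirror the standard bulk
RNA-seq recipe: keep genes above 1 log2CPM in more than 25% of samples,
scale libraries by trimmed-mean-of-M-values (TMM) factors, log2-transform
CPM with a +1 pseudocount, and take per-gene OLS residuals against the
sample covariates (collection site, RIN, ischemic time, exonic/rRNA/
intergenic rates, sex, and optionally age).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizedExpression:
    """Residualized log2 expression (gene x sample) with provenance flags."""

    values: pd.DataFrame
    tmm_applied: bool = False
    covariates_adjusted: bool = False
    age_adjusted: bool = False


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    libs = mat.sum(axis=0)
    zero = np.where(libs == 0)[0]
    if zero.size:
        bad = list(counts.columns[zero])
        raise ValueError(f"samples with zero library size: {bad}")
    return mat


def filter_genes(counts: pd.DataFrame, log2cpm_threshold: float = 1.0,
                 sample_fraction: float = 0.25) -> pd.Index:
    """Genes with log2(CPM) > threshold in strictly more than the given
    fraction of samples.  CPM uses raw library sizes (no TMM offset)."""
    mat = _check_counts(counts)
    libs = mat.sum(axis=0)
    cpm = mat / libs[None, :] * 1e6
    with np.errstate(divide="ignore"):
        log2cpm = np.log2(cpm)
    n_pass = (log2cpm > log2cpm_threshold).sum(axis=1)
    keep = n_pass > sample_fraction * counts.shape[1]
    return counts.index[keep]


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors.

    Reference sample: the one whose upper-quartile CPM is closest to the
    mean upper-quartile.  For each sample, M (log2 ratio vs reference) and
    A (mean log2 abundance) are computed on genes expressed in both; the
    most extreme 30% of M and 5% of A are trimmed and the factor is the
    precision-weighted mean of the remaining M values (binomial delta-
    method weights).  Factors are normalized so their log-mean is zero.
    """
    mat = _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libs = mat.sum(axis=0)
    cpm = mat / libs[None, :] * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    ref_lib = libs[ref_idx]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs, obs_lib = mat[:, j], libs[j]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            continue
        p_obs = obs[mask] / obs_lib
        p_ref = ref[mask] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (obs_lib - obs[mask]) / (obs_lib * obs[mask]) \
            + (ref_lib - ref[mask]) / (ref_lib * ref[mask])
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not keep.any():
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float,
                      trim_a: float) -> np.ndarray:
    """Keep values inside the central (1-2*trim) rank band of both M and A."""
    n = m.size
    rank_m = m.argsort().argsort()
    rank_a = a.argsort().argsort()
    lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m)) - 1
    lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a)) - 1
    return ((rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a))


def normalize_log2(counts: pd.DataFrame, factors: pd.Series | None = None,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) with TMM-adjusted effective library sizes."""
    mat = _check_counts(counts)
    libs = mat.sum(axis=0)
    if factors is None:
        eff = libs
    else:
        f = factors.reindex(counts.columns).to_numpy(dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("TMM factors must be positive and aligned to samples")
        eff = libs * f
    cpm = mat / eff[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + pseudocount), index=counts.index,
                        columns=counts.columns)


def build_design(covars: pd.DataFrame, include_age: bool) -> pd.DataFrame:
    """One-hot design matrix (reference level dropped) with intercept."""
    if covars.isna().any().any():
        bad = covars.columns[covars.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns: {bad}")
    cols = {"intercept": pd.Series(1.0, index=covars.index)}
    for name in covars.columns:
        if name == "age" and not include_age:
            continue
        col = covars[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol].astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=covars.index)


def adjust_covariates(expr: pd.DataFrame, covars: pd.DataFrame,
                      include_age: bool = False) -> NormalizedExpression:
    """Per-gene OLS residuals of expression against the covariate design.

    Residuals are exactly orthogonal to the design column space.  A rank-
    deficient design is rejected, naming the collinear columns.
    """
    covars = covars.loc[expr.columns]
    design = build_design(covars, include_age)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _find_collinear(design)
        raise ValueError(f"rank-deficient covariate design; collinear columns: "
                         f"{collinear}")
    q, _ = np.linalg.qr(X)
    y = expr.to_numpy(dtype=float).T  # samples x genes
    resid = y - q @ (q.T @ y)
    values = pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
    return NormalizedExpression(values=values, tmm_applied=True,
                                covariates_adjusted=True, age_adjusted=include_age)


def _find_collinear(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    kept: list[int] = []
    X = design.to_numpy(dtype=float)
    collinear = []
    for j in range(X.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            kept.append(j)
        else:
            collinear.append(cols[j])
    return collinear


def preprocess_tissue(counts: pd.DataFrame, covars: pd.DataFrame,
                      include_age_adjustment: bool = False,
                      log2cpm_threshold: float = 1.0,
                      sample_fraction: float = 0.25) -> NormalizedExpression:
    """Full per-tissue pipeline: filter -> TMM -> log2 CPM -> residuals."""
    kept = filter_genes(counts, log2cpm_threshold, sample_fraction)
    sub = counts.loc[kept]
    factors = tmm_factors(sub)
    logexpr = normalize_log2(sub, factors)
    return adjust_covariates(logexpr, covars, include_age=include_age_adjustment)
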