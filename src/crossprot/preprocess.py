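"""Rank-based inverse normal transformation, residualization and PCA.

Protein measures on incommensurable raw scales (RFU vs. NPX) are mapped to
normal scores before any comparison; QTL scans run on measures residualized
for age, sex, recruitment site, plate, genotype PCs and protein PCs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .io import ProteinMatrix


def rank_int(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform with a Blom-type offset.

    Non-missing entries are replaced by ``ndtri((rank - c) / (m - 2c + 1))``
    with ``c = offset`` (default 0.5) and ``m`` the non-missing count; ties
    receive average ranks; missing values stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("rank_int: all values missing")
    if m < 3:
        raise ValueError(f"rank_int: need >= 3 non-missing values, got {m}")
    ranks = rankdata(x[mask], method="average")
    out[mask] = ndtri((ranks - offset) / (m - 2 * offset + 1))
    return out


def transform_matrix(matrix: ProteinMatrix, offset: float = 0.5) -> ProteinMatrix:
    """Apply :func:`rank_int` per probe; returns the ``transformed`` layer."""
    if matrix.layer != "raw":
        raise ValueError(f"expected raw layer, got {matrix.layer!r}")
    values = matrix.values.apply(lambda col: rank_int(col.to_numpy(), offset), axis=0)
    return ProteinMatrix(matrix.platform, values, layer="transformed")


def build_covariates(samples: pd.DataFrame,
                     continuous=("age",),
                     categorical=("sex", "site", "plate"),
                     extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble a full-rank covariate matrix with intercept.

    Continuous covariates enter as given; categorical ones are one-hot
    encoded dropping the first level.  ``extra`` (e.g. genotype or protein
    PC scores) is concatenated sample-aligned.
    """
    parts = [pd.Series(1.0, index=samples.index, name="intercept")]
    for c in continuous:
        parts.append(samples[c].astype(float))
    for c in categorical:
        dummies = pd.get_dummies(samples[c], prefix=c, drop_first=True, dtype=float)
        parts.append(dummies)
    x = pd.concat(parts, axis=1)
    if extra is not None:
        if not x.index.equals(extra.index):
            raise ValueError("extra covariates not sample-aligned")
        x = pd.concat([x, extra], axis=1)
    _check_full_rank(x)
    return x


def _check_full_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify a minimal offending column by greedy elimination
        bad = []
        keep: list[int] = []
        for j in range(arr.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(x.columns[j])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")


def residualize(y, x: pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Replace each column of ``y`` by its OLS residual on ``x``.

    Missing entries of a column are preserved; the fit for that column uses
    complete cases only.  Residuals are orthogonal to every covariate column
    over the fitted cases.
    """
    x_arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    _check_full_rank(pd.DataFrame(x_arr, columns=getattr(x, "columns", None)))
    y_in = y
    y_arr = np.asarray(y, dtype=float)
    squeeze = y_arr.ndim == 1
    if squeeze:
        y_arr = y_arr[:, None]
    if y_arr.shape[0] != x_arr.shape[0]:
        raise ValueError("residualize: y and x rows are not aligned")
    out = np.full(y_arr.shape, np.nan)
    full = ~np.isnan(y_arr).any(axis=1)
    if full.all():
        coef, *_ = np.linalg.lstsq(x_arr, y_arr, rcond=None)
        out = y_arr - x_arr @ coef
    else:
        for j in range(y_arr.shape[1]):
            mask = ~np.isnan(y_arr[:, j])
            coef, *_ = np.linalg.lstsq(x_arr[mask], y_arr[mask, j], rcond=None)
            out[mask, j] = y_arr[mask, j] - x_arr[mask] @ coef
    if squeeze:
        out = out[:, 0]
    if isinstance(y_in, pd.DataFrame):
        return pd.DataFrame(out, index=y_in.index, columns=y_in.columns)
    return out


def residualize_matrix(matrix: ProteinMatrix, x: pd.DataFrame) -> ProteinMatrix:
    if list(matrix.values.index) != list(x.index):
        raise ValueError("residualize_matrix: samples not aligned with covariates")
    return ProteinMatrix(matrix.platform, residualize(matrix.values, x), layer="residualized")


def principal_components(m, n_components: int | None = None,
                         variance_target: float | None = None):
    """Centered PCA by SVD with column-mean imputation of missing values.

    Returns ``(scores, variance_explained, n_for_target)`` where
    ``variance_explained`` sums to 1 over all components and
    ``n_for_target`` is the smallest k whose cumulative fraction reaches
    ``variance_target`` (None when no target given).
    """
    arr = np.asarray(m, dtype=float).copy()
    if arr.shape[0] < 2:
        raise ValueError("principal_components: need at least 2 samples")
    if np.isnan(arr).any():
        col_means = np.nanmean(arr, axis=0)
        idx = np.where(np.isnan(arr))
        arr[idx] = np.take(col_means, idx[1])
    arr -= arr.mean(axis=0)
    u, s, _ = np.linalg.svd(arr, full_matrices=False)
    var = s**2
    total = var.sum()
    varexp = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    n_for_target = None
    if variance_target is not None:
        cum = np.cumsum(varexp)
        n_for_target = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    if n_components is not None:
        scores = scores[:, :n_components]
        varexp_out = varexp[:n_components]
    else:
        varexp_out = varexp
    return scores, varexp_out, n_for_target


def pc_scores(values: pd.DataFrame, n_components: int, prefix: str) -> pd.DataFrame:
    """Convenience: top-k PC score DataFrame aligned to the input index."""
    k = min(n_components, values.shape[1], values.shape[0] - 1)
    scores, _, _ = principal_components(values.to_numpy(dtype=float), n_components=k)
    return pd.DataFrame(scores, index=values.index,
                        columns=[f"{prefix}{i + 1}" for i in range(k)])
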