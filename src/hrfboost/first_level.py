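"""Voxelwise OLS GLM estimation, T-statistics and contrast images.

Estimation is plain least squares per voxel (no prewhitening; synthetic
noise is white by default), vectorized over voxels.  Volumes are passed as
``(x, y, z, t)`` arrays with a 3-D boolean mask; single time series as 1-D
arrays.  R-squared is computed against mean-removed data so the constant
column never counts as explained signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from hrfboost.design import DesignMatrix

__all__ = ["GLMFit", "ContrastImage", "fit_ols", "t_statistic", "contrast_image"]


@dataclass
class GLMFit:
    """Per-voxel GLM estimates.

    ``betas`` has shape ``(n_columns, n_voxels)`` (``n_voxels`` is 1 for a
    single series); ``residual_variance`` and ``r_squared`` have shape
    ``(n_voxels,)``.  ``shape``/``mask`` record volume geometry when the
    input was 4-D.
    """

    betas: np.ndarray
    residual_variance: np.ndarray
    df: int
    design: DesignMatrix
    r_squared: np.ndarray
    shape: tuple | None = None
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.design.index(label)]

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into volume geometry."""
        if self.shape is None:
            return values
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def sidecar(self) -> dict:
        return {
            "df": self.df,
            "columns": list(self.design.labels),
            "basis": self.design.meta.get("basis"),
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


@dataclass
class ContrastImage:
    """Linear combination of parameter estimates, one value per voxel."""

    values: np.ndarray
    contrast_weights: np.ndarray
    model_tag: str  # {"canonical", "informed", "boost_constrained", "boost_full"}
    shape: tuple | None = None
    mask: np.ndarray | None = None

    def volume(self, fill: float = 0.0) -> np.ndarray:
        if self.shape is None:
            return self.values
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = self.values
        return out


def _as_voxel_matrix(y: np.ndarray, n_scans: int, mask: np.ndarray | None):
    """Reshape input data to (n_scans, n_voxels); return geometry info."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        if y.size != n_scans:
            raise ValueError("series length does not match n_scans")
        return y[:, None], None, None
    if y.ndim == 2:
        if y.shape[0] != n_scans:
            raise ValueError("data rows must equal n_scans")
        return y, None, None
    if y.ndim == 4:
        if y.shape[-1] != n_scans:
            raise ValueError("time axis (last) must equal n_scans")
        if mask is None:
            raise ValueError("a 3-D mask is required for volume input")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != y.shape[:3]:
            raise ValueError("mask shape must match the volume grid")
        return y[mask].T, y.shape[:3], mask
    raise ValueError("y must be 1-D, 2-D (time x voxels) or 4-D (x, y, z, t)")


def fit_ols(y, X: DesignMatrix, mask: np.ndarray | None = None) -> GLMFit:
    """Ordinary least-squares fit of the design to the data, per voxel."""
    Y, shape, mask = _as_voxel_matrix(y, X.n_scans, mask)
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contain non-finite values")
    M = X.matrix
    rank = int(np.linalg.matrix_rank(M))
    if rank < M.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df = X.n_scans - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    betas, _, _, _ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ betas
    rss = np.sum(resid**2, axis=0)
    residual_variance = rss / df
    # an exact (noiseless) fit leaves only rounding error; flag it as zero
    data_ssq = np.sum(Y**2, axis=0)
    exact = rss <= 1e-20 * np.maximum(data_ssq, 1e-300)
    residual_variance = np.where(exact, 0.0, residual_variance)

    centered = Y - Y.mean(axis=0, keepdims=True)
    ss_tot = np.sum(centered**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - rss / ss_tot
    r2 = np.where(ss_tot > 0, r2, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    return GLMFit(
        betas=betas,
        residual_variance=residual_variance,
        df=df,
        design=X,
        r_squared=r2,
        shape=shape,
        mask=mask,
    )


def _check_weights(fit: GLMFit, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != fit.design.n_columns:
        raise ValueError(
            f"contrast length {w.size} does not match design with {fit.design.n_columns} columns"
        )
    if not np.all(np.isfinite(w)):
        raise ValueError("contrast weights must be finite")
    return w


def t_statistic(fit: GLMFit, weights) -> np.ndarray:
    """Contrast T-statistic: (w'b) / sqrt(sigma^2 * w'(X'X)^-1 w).

    Voxels with zero estimated residual variance (and a nonzero contrast)
    are reported as +/-inf with a warning; a zero weight vector yields 0.
    """
    w = _check_weights(fit, weights)
    M = fit.design.matrix
    xtx_inv = np.linalg.inv(M.T @ M)
    var_factor = float(w @ xtx_inv @ w)
    effect = w @ fit.betas
    if var_factor == 0.0:
        return np.zeros_like(effect)
    se = np.sqrt(fit.residual_variance * var_factor)
    zero = se == 0
    if np.any(zero):
        warnings.warn(
            f"{int(np.sum(zero))} voxel(s) with zero residual variance; T set to +/-inf",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    t[zero & (effect > 0)] = np.inf
    t[zero & (effect < 0)] = -np.inf
    t[zero & (effect == 0)] = 0.0
    return t


def contrast_image(fit: GLMFit, weights, model_tag: str | None = None) -> ContrastImage:
    """Per-voxel contrast of parameter estimates."""
    w = _check_weights(fit, weights)
    if model_tag is None:
        model_tag = fit.design.meta.get("basis", "canonical")
    return ContrastImage(
        values=w @ fit.betas,
        contrast_weights=w,
        model_tag=model_tag,
        shape=fit.shape,
        mask=fit.mask,
    )
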