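"""Second-level summary-statistics random-effects inference.

First-level contrast (or boosted) images from N subjects are pooled
voxelwise: the group mean is related to the unbiased between-subject
variance through t = mean / sqrt(var / N) with N - 1 degrees of freedom.
Paired tests reduce to a one-sample test on subject-wise differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroupStatMap", "one_sample_t", "paired_t", "variance_map"]


@dataclass
class GroupStatMap:
    """Voxelwise group mean, between-subject variance, t and df."""

    group_mean: np.ndarray
    between_subject_variance: np.ndarray
    t_values: np.ndarray
    df: int
    n_subjects: int
    n_zero_variance: int = 0
    meta: dict = field(default_factory=dict)

    def sidecar(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "df": self.df,
            "n_zero_variance": int(self.n_zero_variance),
        }


def _stack(images) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim < 2:
        raise ValueError("need a stack of at least two co-dimensioned images")
    return arr


def one_sample_t(images, model_tag: str | None = None) -> GroupStatMap:
    """One-sample t-test across subjects (first axis of ``images``).

    Voxels where all subjects agree exactly get an infinite-t sentinel
    (NaN when the common value is zero) and are counted in
    ``n_zero_variance``.
    """
    data = _stack(images)
    n = data.shape[0]
    if n < 2:
        raise ValueError("at least two subjects are required")
    mean = data.mean(axis=0)
    var = data.var(axis=0, ddof=1)
    zero = var == 0
    n_zero = int(np.sum(zero))
    if n_zero:
        warnings.warn(
            f"{n_zero} voxel(s) with zero between-subject variance; t set to sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.asarray(t, dtype=float)
    if t.ndim == 0:
        t = t[None]
        scalar = True
    else:
        scalar = False
    zt = np.broadcast_to(zero, t.shape)
    mt = np.broadcast_to(mean, t.shape)
    t[zt & (mt > 0)] = np.inf
    t[zt & (mt < 0)] = -np.inf
    t[zt & (mt == 0)] = np.nan
    if scalar:
        t = t[0]
    return GroupStatMap(
        group_mean=mean,
        between_subject_variance=var,
        t_values=t,
        df=n - 1,
        n_subjects=n,
        n_zero_variance=n_zero,
        meta={"model_tag": model_tag} if model_tag else {},
    )


def paired_t(images_a, images_b, model_tag: str | None = None) -> GroupStatMap:
    """Paired t-test: one-sample test on subject-matched differences a - b."""
    a = _stack(images_a)
    b = _stack(images_b)
    if a.shape != b.shape:
        raise ValueError("paired image stacks must have identical shapes")
    return one_sample_t(a - b, model_tag=model_tag)


def variance_map(images) -> np.ndarray:
    """Unbiased voxelwise between-subject variance."""
    data = _stack(images)
    if data.shape[0] < 2:
        raise ValueError("at least two subjects are required")
    return data.var(axis=0, ddof=1)
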