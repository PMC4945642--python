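"""Scan-resolution GLM design construction.

Event timelines are rasterized to the microtime grid as boxcars, convolved
with basis kernels, sampled at scan acquisition times (t = scan_index * TR),
and assembled into a labeled design matrix together with nuisance columns
(constant, discrete-cosine drift basis, optional motion covariates).  For a
condition modeled with the informed basis set, the derivative column is
orthogonalized against that condition's canonical column and the constant,
so the canonical estimate is unchanged by the added regressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hrfboost.hrf import HRFParameters, SampledKernel, informed_basis

__all__ = [
    "EventTimeline",
    "DesignMatrix",
    "boxcar",
    "convolve_to_scans",
    "orthogonalize",
    "drift_basis",
    "build_design",
    "read_events_tsv",
]


@dataclass(frozen=True)
class EventTimeline:
    """Onsets/durations/amplitudes of one experimental condition."""

    onsets: np.ndarray
    durations: np.ndarray
    amplitudes: np.ndarray
    condition: str = "task"

    def __post_init__(self) -> None:
        onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "amplitudes", amplitudes)
        if not (onsets.size == durations.size == amplitudes.size):
            raise ValueError("onsets, durations, amplitudes must have equal length")
        if onsets.size and np.any(onsets < 0):
            raise ValueError("onsets must be non-negative")
        if onsets.size and np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted")
        if durations.size and np.any(durations < 0):
            raise ValueError("durations must be >= 0")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def end_time(self) -> float:
        if self.n_events == 0:
            return 0.0
        return float(np.max(self.onsets + self.durations))

    def scaled(self, factor: float) -> "EventTimeline":
        return EventTimeline(self.onsets, self.durations, self.amplitudes * factor, self.condition)


def read_events_tsv(path, condition: str | None = None) -> list[EventTimeline]:
    """Read a BIDS-style ``events.tsv`` into one timeline per trial_type.

    Expected columns: ``onset``, ``duration``, optional ``trial_type`` and
    ``amplitude`` (defaulting to one condition named "task" and amplitude 1).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"events file missing required column {col!r}")
    if "trial_type" not in df.columns:
        df["trial_type"] = "task"
    if "amplitude" not in df.columns:
        df["amplitude"] = 1.0
    timelines = []
    for name, grp in df.groupby("trial_type", sort=True):
        if condition is not None and name != condition:
            continue
        grp = grp.sort_values("onset")
        timelines.append(
            EventTimeline(
                onsets=grp["onset"].to_numpy(float),
                durations=grp["duration"].to_numpy(float),
                amplitudes=grp["amplitude"].to_numpy(float),
                condition=str(name),
            )
        )
    return timelines


def boxcar(events: EventTimeline, dt: float, total_duration: float) -> np.ndarray:
    """Rasterize events to a microtime stimulus series.

    Samples inside an event carry its amplitude; zero-duration events become
    single-sample sticks.  Overlapping events within the timeline are
    rejected.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if events.n_events and events.end_time() > total_duration + 1e-9:
        raise ValueError("total_duration does not cover all events")
    n = int(math.ceil(total_duration / dt))
    u = np.zeros(n)
    filled = np.zeros(n, dtype=bool)
    for onset, dur, amp in zip(events.onsets, events.durations, events.amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(int(round((onset + dur) / dt)), i0 + 1)
        i1 = min(i1, n)
        i0 = min(i0, n - 1)
        if np.any(filled[i0:i1]):
            raise ValueError(f"overlapping events in condition {events.condition!r}")
        u[i0:i1] = amp
        filled[i0:i1] = True
    return u


def convolve_to_scans(
    u: np.ndarray, kernel: SampledKernel, tr: float, n_scans: int
) -> np.ndarray:
    """Convolve a microtime stimulus with a kernel and sample at scan times.

    The discrete convolution is scaled by the microtime step so it
    approximates the continuous convolution integral; scan samples are taken
    at t = k * TR.
    """
    u = np.asarray(u, dtype=float)
    dt = kernel.dt
    full = np.convolve(u, kernel.values)[: u.size] * dt
    idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    if idx[-1] >= u.size:
        raise ValueError("stimulus series too short for the requested number of scans")
    return full[idx]


def orthogonalize(x2: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Residualize ``x2`` against ``x1`` (or against several columns).

    ``x1`` may be a single regressor or a 2-D array whose columns span the
    space to project out; the result is orthogonal to every column.
    """
    x2 = np.asarray(x2, dtype=float)
    X = np.asarray(x1, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot orthogonalize against a zero-norm regressor")
    coef, *_ = np.linalg.lstsq(X, x2, rcond=None)
    return x2 - X @ coef


def drift_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift columns plus a constant column.

    Returns an ``(n_scans, 1 + k_max)`` array: a constant column followed by
    unit-norm cosines of period longer than ``cutoff`` seconds.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff period must exceed 2 * TR")
    n = np.arange(n_scans)
    k_max = int(np.floor(2.0 * n_scans * tr / cutoff))
    cols = [np.ones(n_scans)]
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_scans))
        cols.append(c * np.sqrt(2.0 / n_scans))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Labeled scan-resolution design matrix.

    Column order is deterministic: per condition the canonical column then
    (informed set only) the orthogonalized derivative column, followed by
    nuisance columns (constant, drift, motion), encoded in the labels.
    """

    labels: list
    matrix: np.ndarray
    tr: float
    n_scans: int
    microtime_dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape != (self.n_scans, len(self.labels)):
            raise ValueError("matrix shape does not match n_scans / labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def column_ssq(self) -> np.ndarray:
        """Per-column sum of squares, recomputed on demand."""
        return np.sum(self.matrix**2, axis=0)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.index(label)]

    def ssq(self, label: str) -> float:
        return float(np.sum(self.column(label) ** 2))

    def has_derivative(self) -> bool:
        return any(lbl.endswith("_derivative") for lbl in self.labels)

    def condition_names(self) -> list:
        return [lbl[: -len("_canonical")] for lbl in self.labels if lbl.endswith("_canonical")]

    def contrast_for(self, weights_by_condition: dict) -> np.ndarray:
        """Full-length weight vector with weights on canonical columns."""
        w = np.zeros(self.n_columns)
        for cond, weight in weights_by_condition.items():
            w[self.index(f"{cond}_canonical")] = weight
        return w

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.labels).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float, microtime_dt: float) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=list(df.columns),
            matrix=df.to_numpy(float),
            tr=tr,
            n_scans=len(df),
            microtime_dt=microtime_dt,
        )


def build_design(
    events,
    tr: float,
    n_scans: int,
    params: HRFParameters | None = None,
    basis: str = "informed",
    drift_cutoff: float | None = None,
    motion: np.ndarray | None = None,
    orthogonalize_derivative: bool = True,
) -> DesignMatrix:
    """Assemble a design matrix from one or more event timelines.

    ``basis`` selects the model: ``"canonical"`` (HRF alone) or
    ``"informed"`` (HRF plus its orthogonalized temporal derivative).  The
    derivative is residualized against its own condition's canonical column
    and the constant, which leaves the canonical estimate invariant to its
    inclusion.
    """
    if params is None:
        params = HRFParameters()
    if basis not in ("canonical", "informed"):
        raise ValueError(f"unknown basis {basis!r}")
    if isinstance(events, EventTimeline):
        events = [events]
    can, der = informed_basis(params)
    total = n_scans * tr + params.kernel_length
    constant = np.ones(n_scans)

    labels: list = []
    cols: list = []
    for ev in events:
        u = boxcar(ev, params.microtime_dt, total)
        x1 = convolve_to_scans(u, can, tr, n_scans)
        labels.append(f"{ev.condition}_canonical")
        cols.append(x1)
        if basis == "informed":
            x2 = convolve_to_scans(u, der, tr, n_scans)
            if orthogonalize_derivative:
                x2 = orthogonalize(x2, np.column_stack([x1, constant]))
            labels.append(f"{ev.condition}_derivative")
            cols.append(x2)

    if drift_cutoff is not None:
        nuis = drift_basis(n_scans, tr, drift_cutoff)
        labels.append("constant")
        cols.append(nuis[:, 0])
        for k in range(1, nuis.shape[1]):
            labels.append(f"drift_{k}")
            cols.append(nuis[:, k])
    else:
        labels.append("constant")
        cols.append(constant)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ValueError("motion covariates must have n_scans rows")
        for k in range(motion.shape[1]):
            labels.append(f"motion_{k + 1}")
            cols.append(motion[:, k])

    meta = {"basis": basis, "hrf_params": params.to_dict(), "drift_cutoff": drift_cutoff}
    return DesignMatrix(
        labels=labels,
        matrix=np.column_stack(cols),
        tr=tr,
        n_scans=n_scans,
        microtime_dt=params.microtime_dt,
        meta=meta,
    )
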