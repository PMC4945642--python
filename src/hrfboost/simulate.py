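"""Synthetic BOLD data with ground truth.

Two generators back every downstream test:

* a single-voxel slow event-related simulation — 10 s events alternating
  with 10 s rests (0.05 Hz presentation), convolved at fine time resolution
  with a latency-shifted HRF and sampled at scan times; and
* multi-subject 4-D cohorts in which each subject draws a response latency
  and amplitude from configurable distributions, active voxels carry the
  shifted response, and volumes are optionally smoothed spatially.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from hrfboost.design import EventTimeline, boxcar, convolve_to_scans
from hrfboost.hrf import HRFParameters, shifted_hrf

__all__ = [
    "VoxelSimSpec",
    "CohortSpec",
    "CohortSample",
    "periodic_event_timeline",
    "simulate_voxel_series",
    "simulate_cohort",
    "simulate_smooth_field",
    "fwhm_to_sigma",
]

#: default event presentation period (s) -> 0.05 Hz
DEFAULT_PERIOD_S = 20.0
#: latency bound keeping subjects inside the basis set's representable range
LATENCY_BOUND_S = 2.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM to standard deviation."""
    return fwhm / np.sqrt(8.0 * np.log(2.0))


def periodic_event_timeline(
    n_events: int = 10,
    period: float = DEFAULT_PERIOD_S,
    duration: float = 10.0,
    amplitude: float = 1.0,
    condition: str = "task",
) -> EventTimeline:
    """Periodic event train: ``duration``-s events every ``period`` seconds.

    Defaults reproduce the slow event-related design used throughout: 10 s
    events interspersed with 10 s rests, i.e. a 0.05 Hz presentation rate.
    """
    onsets = np.arange(n_events) * period
    return EventTimeline(
        onsets=onsets,
        durations=np.full(n_events, float(duration)),
        amplitudes=np.full(n_events, float(amplitude)),
        condition=condition,
    )


@dataclass(frozen=True)
class VoxelSimSpec:
    """Spec for the single-voxel shifted-response simulation."""

    shift: float = 0.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    events: EventTimeline | None = None
    tr: float = 0.5
    n_scans: int = 400
    hrf_params: HRFParameters = field(default_factory=HRFParameters)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.shift) > 2.0 * LATENCY_BOUND_S:
            raise ValueError("shift outside the generator's sanity bound")
        if self.events is None:
            total = self.n_scans * self.tr
            n_events = int(np.floor((total - 10.0) / DEFAULT_PERIOD_S)) + 1
            object.__setattr__(self, "events", periodic_event_timeline(n_events=max(n_events, 1)))


def simulate_voxel_series(spec: VoxelSimSpec):
    """Simulate one voxel's scan-resolution BOLD series.

    Returns ``(series, truth)`` where ``truth`` records the imposed shift
    and amplitude plus the noiseless signal.
    """
    params = spec.hrf_params
    kernel = shifted_hrf(params, spec.shift)
    total = spec.n_scans * spec.tr + params.kernel_length
    u = boxcar(spec.events, params.microtime_dt, total)
    signal = spec.amplitude * convolve_to_scans(u, kernel, spec.tr, spec.n_scans)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_scans) if spec.noise_sd > 0 else 0.0
    truth = {"shift": spec.shift, "amplitude": spec.amplitude, "signal": signal}
    return signal + noise, truth


@dataclass(frozen=True)
class CohortSpec:
    """Spec for a multi-subject 4-D cohort with latency heterogeneity.

    Presets are pure configuration: a "child-like" cohort uses a larger
    ``latency_mean``/``latency_sd`` and ``noise_sd``; an "adult-like" cohort
    centers latency near zero.  Default group sizes elsewhere in the
    pipeline echo typical developmental samples (19 and 17) but any
    ``n_subjects >= 2`` is accepted.
    """

    n_subjects: int = 17
    volume_shape: tuple = (12, 12, 6)
    voxel_size: float = 3.0
    active_mask: np.ndarray | None = None
    latency_mean: float = 0.0
    latency_sd: float = 0.5
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.1
    noise_sd: float = 0.5
    smoothing_fwhm: float = 0.0
    seed: int = 0
    events: EventTimeline | None = None
    tr: float = 2.0
    n_scans: int = 100
    hrf_params: HRFParameters = field(default_factory=HRFParameters)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("latency_sd", "amplitude_sd", "noise_sd", "smoothing_fwhm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        shape = tuple(int(s) for s in self.volume_shape)
        object.__setattr__(self, "volume_shape", shape)
        if self.active_mask is None:
            mask = np.zeros(shape, dtype=bool)
            sl = tuple(slice(s // 4, max(s // 4 + 1, (3 * s) // 4)) for s in shape)
            mask[sl] = True
            object.__setattr__(self, "active_mask", mask)
        else:
            mask = np.asarray(self.active_mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("active_mask shape must equal volume_shape")
            object.__setattr__(self, "active_mask", mask)
        if not np.any(self.active_mask):
            raise ValueError("active_mask must contain at least one voxel")
        if self.events is None:
            total = self.n_scans * self.tr
            n_events = int(np.floor((total - 10.0) / DEFAULT_PERIOD_S)) + 1
            object.__setattr__(self, "events", periodic_event_timeline(n_events=max(n_events, 1)))

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["active_mask"] = None  # stored separately; shape captured below
        d["n_active_voxels"] = int(np.sum(self.active_mask))
        d["events"] = {
            "onsets": self.events.onsets.tolist(),
            "durations": self.events.durations.tolist(),
            "amplitudes": self.events.amplitudes.tolist(),
            "condition": self.events.condition,
        }
        d["hrf_params"] = self.hrf_params.to_dict()
        return d


@dataclass
class CohortSample:
    """Simulated cohort: per-subject 4-D data plus the ground-truth table."""

    spec: CohortSpec
    data: list  # list of (x, y, z, t) arrays
    truth: pd.DataFrame  # columns: subject, latency_s, amplitude

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def write(self, out_dir) -> None:
        """Write per-subject NIfTI volumes, the truth TSV and the spec JSON."""
        import os

        import nibabel as nib

        os.makedirs(out_dir, exist_ok=True)
        affine = np.diag([self.spec.voxel_size] * 3 + [1.0])
        for i, vol in enumerate(self.data):
            img = nib.Nifti1Image(vol.astype(np.float32), affine)
            img.header["pixdim"][4] = self.spec.tr
            nib.save(img, os.path.join(out_dir, f"sub-{i + 1:02d}_bold.nii"))
        self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "cohort_spec.json"), "w") as fh:
            json.dump(self.spec.to_json_dict(), fh, indent=2)


def _truncated_normal(rng, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, low, high)))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: CohortSpec) -> CohortSample:
    """Simulate a cohort of subjects with heterogeneous response latency.

    Each subject draws latency ~ Normal(latency_mean, latency_sd) truncated
    to +/-2 s and amplitude ~ Normal(amplitude_mean, amplitude_sd).  Active
    voxels carry the subject's shifted response plus white noise; inactive
    voxels carry noise only; each time frame is then smoothed spatially
    with ``smoothing_fwhm``.
    """
    rng = np.random.default_rng(spec.seed)
    latencies = _truncated_normal(
        rng, spec.latency_mean, spec.latency_sd, -LATENCY_BOUND_S, LATENCY_BOUND_S, spec.n_subjects
    )
    amplitudes = rng.normal(spec.amplitude_mean, spec.amplitude_sd, size=spec.n_subjects)

    params = spec.hrf_params
    total = spec.n_scans * spec.tr + params.kernel_length
    u = boxcar(spec.events, params.microtime_dt, total)
    sigma_vox = fwhm_to_sigma(spec.smoothing_fwhm) / spec.voxel_size if spec.smoothing_fwhm > 0 else 0.0

    data = []
    for i in range(spec.n_subjects):
        kernel = shifted_hrf(params, float(latencies[i]))
        signal = amplitudes[i] * convolve_to_scans(u, kernel, spec.tr, spec.n_scans)
        vol = rng.normal(0.0, spec.noise_sd, size=spec.volume_shape + (spec.n_scans,))
        vol[spec.active_mask] += signal
        if sigma_vox > 0:
            vol = ndimage.gaussian_filter(vol, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))
        data.append(vol)

    truth = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(spec.n_subjects)],
            "latency_s": latencies,
            "amplitude": amplitudes,
        }
    )
    return CohortSample(spec=spec, data=data, truth=truth)


def simulate_smooth_field(
    shape, voxel_size: float = 1.0, fwhm: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Unit-variance Gaussian random field with known smoothness.

    White Gaussian noise is convolved with a Gaussian kernel of the given
    FWHM (in mm; ``voxel_size`` converts to voxels) and re-standardized to
    zero mean and unit variance.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    rng = np.random.default_rng(seed)
    field_ = rng.standard_normal(tuple(int(s) for s in shape))
    if fwhm > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=fwhm_to_sigma(fwhm) / voxel_size)
    field_ = field_ - field_.mean()
    sd = field_.std()
    if sd == 0:
        raise ValueError("degenerate field")
    return field_ / sd
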