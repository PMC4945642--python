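"""Canonical double-gamma HRF, temporal derivative, and shifted variants.

The canonical hemodynamic response function is modeled as the difference of
two gamma densities — a positive peak followed by a scaled undershoot — and
is scaled to unit peak so that fitted amplitudes read directly in signal
units.  The companion basis function is the first temporal derivative,
computed from the closed form of the gamma density and rescaled so its
peak-to-peak amplitude matches the conventional 1-s finite-difference
construction.  All kernels live on a shared uniform microtime grid starting
at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "HRFParameters",
    "SampledKernel",
    "canonical_hrf",
    "temporal_derivative",
    "shifted_hrf",
]

#: largest |shift| accepted by :func:`shifted_hrf` (generator sanity bound)
MAX_SHIFT_S = 4.0


@dataclass(frozen=True)
class HRFParameters:
    """Parameterization of the double-gamma HRF.

    Delays and dispersions are in seconds; the gamma shape parameters are
    ``delay / dispersion`` with scale ``dispersion``, so with the defaults
    the positive lobe is a gamma density with shape 6 and unit scale, whose
    mode sits at 5 s post stimulus.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    microtime_dt: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
            "microtime_dt",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.microtime_dt > 0.5:
            raise ValueError(
                f"microtime_dt must be <= 0.5 s to resolve 0.5 s shifts, got {self.microtime_dt}"
            )

    def grid(self) -> np.ndarray:
        """Microtime sample points covering [0, kernel_length]."""
        n = int(np.floor(self.kernel_length / self.microtime_dt)) + 1
        return np.arange(n) * self.microtime_dt

    def to_dict(self) -> dict:
        return {
            "peak_delay": self.peak_delay,
            "undershoot_delay": self.undershoot_delay,
            "peak_dispersion": self.peak_dispersion,
            "undershoot_dispersion": self.undershoot_dispersion,
            "undershoot_ratio": self.undershoot_ratio,
            "kernel_length": self.kernel_length,
            "microtime_dt": self.microtime_dt,
        }


@dataclass(frozen=True)
class SampledKernel:
    """A response kernel sampled on a uniform microtime grid starting at 0."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # one of {"canonical", "derivative", "shifted"}
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("kernel needs at least two samples")
        if abs(times[0]) > 1e-12:
            raise ValueError("first sample must be at t = 0")
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("times must be strictly increasing with uniform spacing")
        if not np.all(np.isfinite(values)):
            raise ValueError("kernel values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def same_grid(self, other: "SampledKernel") -> bool:
        return self.times.size == other.times.size and np.allclose(
            self.times, other.times, rtol=0, atol=1e-9
        )

    def peak_time(self) -> float:
        """Grid time of the maximum value."""
        return float(self.times[int(np.argmax(self.values))])

    # -- plain-text round trip (two columns: time_s, value) ------------------

    def to_text(self, path) -> None:
        header = f"kind={self.kind}"
        np.savetxt(path, np.column_stack([self.times, self.values]), header=header)

    @classmethod
    def from_text(cls, path, kind: str | None = None) -> "SampledKernel":
        data = np.loadtxt(path)
        if kind is None:
            kind = "canonical"
            try:
                with open(path) as fh:
                    first = fh.readline()
                if "kind=" in first:
                    kind = first.split("kind=")[1].strip()
            except OSError:
                pass
        return cls(times=data[:, 0], values=data[:, 1], kind=kind)


def _double_gamma(t: np.ndarray, params: HRFParameters) -> np.ndarray:
    """Unnormalized double-gamma HRF values."""
    pos = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    neg = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    return pos - params.undershoot_ratio * neg


def _double_gamma_derivative(t: np.ndarray, params: HRFParameters) -> np.ndarray:
    """Closed-form time derivative of the unnormalized double-gamma HRF.

    For a gamma density g with shape a and scale s, g'(t) = g(t)((a-1)/t - 1/s);
    the limit at t = 0 is 0 whenever a > 1.
    """

    def gpdf_prime(a: float, s: float) -> np.ndarray:
        g = stats.gamma.pdf(t, a, scale=s)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = g * ((a - 1.0) / t - 1.0 / s)
        out[~np.isfinite(out)] = 0.0
        return out

    d_pos = gpdf_prime(params.peak_delay / params.peak_dispersion, params.peak_dispersion)
    d_neg = gpdf_prime(
        params.undershoot_delay / params.undershoot_dispersion,
        params.undershoot_dispersion,
    )
    return d_pos - params.undershoot_ratio * d_neg


def canonical_hrf(params: HRFParameters | None = None) -> SampledKernel:
    """Construct the unit-peak canonical double-gamma HRF.

    Parameters default to the widely used double-gamma parameterization
    (positive lobe peaking at 5 s, undershoot scaled by 1/6); the
    parameterization is recorded in the kernel metadata.
    """
    if params is None:
        params = HRFParameters()
    t = params.grid()
    raw = _double_gamma(t, params)
    peak = float(np.max(raw))
    if peak <= 0:
        raise ValueError("degenerate parameters: HRF has no positive peak")
    meta = {"params": params.to_dict(), "scale_factor": 1.0 / peak}
    return SampledKernel(times=t, values=raw / peak, kind="canonical", meta=meta)


def temporal_derivative(
    kernel: SampledKernel, params: HRFParameters | None = None
) -> SampledKernel:
    """First temporal derivative basis function of the canonical HRF.

    Computed analytically from the gamma closed form (grid independent), then
    rescaled so its peak-to-peak amplitude equals that of the 1-s-lag finite
    difference ``h(t) - h(t - 1)`` of the unit-peak canonical kernel, the
    conventional construction.  The result shares the canonical grid: a
    positive lobe before the canonical peak, a negative lobe after.
    """
    if params is None:
        params = HRFParameters(**kernel.meta["params"]) if "params" in kernel.meta else HRFParameters()
    t = params.grid()
    if kernel.times.size != t.size or not np.allclose(kernel.times, t, rtol=0, atol=1e-9):
        raise ValueError("kernel grid does not match the supplied parameters")

    scale = kernel.meta.get("scale_factor")
    if scale is None:
        raw_peak = float(np.max(_double_gamma(t, params)))
        scale = 1.0 / raw_peak
    analytic = scale * _double_gamma_derivative(t, params)

    # finite-difference reference: unit-peak canonical minus its 1 s delayed copy
    delayed = np.interp(t - 1.0, t, kernel.values, left=0.0, right=0.0)
    fd = kernel.values - delayed
    ptp_fd = float(np.ptp(fd))
    ptp_an = float(np.ptp(analytic))
    if ptp_an <= 0:
        raise ValueError("degenerate derivative")
    values = analytic * (ptp_fd / ptp_an)
    meta = dict(kernel.meta)
    meta["ptp_match_factor"] = ptp_fd / ptp_an
    return SampledKernel(times=t, values=values, kind="derivative", meta=meta)


def shifted_hrf(params: HRFParameters | None = None, delta: float = 0.0) -> SampledKernel:
    """Canonical HRF translated in time by ``delta`` seconds.

    Positive ``delta`` delays the response (later peak).  The shift is
    realized on the microtime grid by rounding ``delta`` to the nearest
    grid step and zero-padding at the edge.
    """
    if params is None:
        params = HRFParameters()
    if not np.isfinite(delta) or abs(delta) > MAX_SHIFT_S:
        raise ValueError(f"|delta| must be <= {MAX_SHIFT_S} s, got {delta!r}")
    base = canonical_hrf(params)
    k = int(round(delta / params.microtime_dt))
    values = np.zeros_like(base.values)
    if k == 0:
        values[:] = base.values
    elif k > 0:
        values[k:] = base.values[:-k]
    else:
        values[:k] = base.values[-k:]
    meta = dict(base.meta)
    meta["shift_s"] = k * params.microtime_dt
    return SampledKernel(times=base.times, values=values, kind="shifted", meta=meta)


def informed_basis(params: HRFParameters | None = None) -> tuple[SampledKernel, SampledKernel]:
    """The K=2 informed basis set: (canonical, temporal derivative)."""
    if params is None:
        params = HRFParameters()
    can = canonical_hrf(params)
    return can, temporal_derivative(can, params)
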