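"""Free-concentration forcing profiles.

A :class:`ConcentrationProfile` is the model's driving input: free plasma
glucocorticoid concentration (nM) as a function of time (minutes).  This
module provides constant and step profiles, periodic piecewise-polynomial
interpolants for tabulated data, and a deterministic synthetic diurnal
cortisol curve that emulates the published 24-hour free-cortisol
microdialysis measurements (whose raw samples are not available): the curve
is pinned to the printed nadir (1.45 nM at 03:00) and its two free constants
— peak height and post-peak decay width — were calibrated once, by
``scripts/calibrate_cortisol.py``, so that the full time-dependent receptor
model reproduces the published peak relative activity (0.39) and daily
transcription quotient (0.17) for endogenous cortisol.

Clock convention: minutes since midnight; a day is exactly 1440 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "MINUTES_PER_DAY",
    "ConcentrationProfile",
    "constant_profile",
    "step_profile",
    "piecewise_poly_profile",
    "from_samples",
    "DiurnalCortisolSpec",
    "synthetic_cortisol",
    "profile_from_csv",
    "profile_to_csv",
]

MINUTES_PER_DAY = 1440.0

# Frozen output of scripts/calibrate_cortisol.py (see module docstring).
CALIBRATED_PEAK_NM = 29.96
CALIBRATED_DECAY_TAU_MIN = 224.5


@dataclass(frozen=True)
class ConcentrationProfile:
    """Free concentration vs time.

    evaluator : vectorized callable, time (min) -> nM.
    domain : closed interval on which the profile is defined; periodic
        profiles are defined for all t by periodic extension.
    period : optional period in minutes.
    breakpoints : times (within the domain/period) where the profile is not
        smooth; ODE integration restarts there.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    period: float | None = None
    breakpoints: tuple[float, ...] = ()
    description: str = ""

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.period is not None:
            tt = self.domain[0] + np.mod(t - self.domain[0], self.period)
        else:
            tt = t
            if np.any(tt < self.domain[0] - 1e-9) or np.any(tt > self.domain[1] + 1e-9):
                raise ValueError(
                    f"time outside profile domain {self.domain}: {t}")
        out = np.maximum(np.asarray(self.evaluator(tt), dtype=float), 0.0)
        return float(out) if out.ndim == 0 else out

    def segment_edges(self, t0: float, t1: float) -> np.ndarray:
        """Sorted integration restart times in [t0, t1] (incl. endpoints)."""
        edges = {t0, t1}
        if self.period is None:
            edges.update(b for b in self.breakpoints if t0 < b < t1)
        else:
            n0 = int(np.floor((t0 - self.domain[0]) / self.period)) - 1
            n1 = int(np.ceil((t1 - self.domain[0]) / self.period)) + 1
            for n in range(n0, n1 + 1):
                for b in self.breakpoints:
                    tb = b + n * self.period
                    if t0 < tb < t1:
                        edges.add(tb)
        return np.array(sorted(edges))


def constant_profile(level: float) -> ConcentrationProfile:
    if level < 0:
        raise ValueError("concentration must be >= 0")
    return ConcentrationProfile(lambda t: np.full_like(np.asarray(t, float), level),
                                domain=(-np.inf, np.inf),
                                description=f"constant {level} nM")


def step_profile(levels: Sequence[tuple[float, float]]) -> ConcentrationProfile:
    """Right-continuous piecewise-constant profile.

    ``levels`` is a list of (start_min, nM); the first entry must start at
    t = 0 and starts must be strictly increasing.
    """
    if not levels:
        raise ValueError("need at least one (start, level) pair")
    starts = np.array([s for s, _ in levels], dtype=float)
    vals = np.array([v for _, v in levels], dtype=float)
    if starts[0] != 0:
        raise ValueError("step profile must start at t = 0")
    if np.any(np.diff(starts) <= 0):
        raise ValueError("step starts must be strictly increasing (no zero-"
                         "duration segments)")
    if np.any(vals < 0):
        raise ValueError("concentrations must be >= 0")

    def ev(t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]

    return ConcentrationProfile(ev, domain=(0.0, np.inf),
                                breakpoints=tuple(starts[1:]),
                                description="step profile")


def piecewise_poly_profile(samples: Sequence[tuple[float, float]],
                           period: float = MINUTES_PER_DAY) -> ConcentrationProfile:
    """Smooth periodic interpolant through tabulated (time, nM) samples.

    Uses a periodic cubic spline; the curve passes through the samples
    exactly and is clipped at zero.  Intended for user-digitized daily
    curves.
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 samples")
    t = np.array([s[0] for s in samples], dtype=float)
    v = np.array([s[1] for s in samples], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if t[0] < 0 or t[-1] >= t[0] + period:
        raise ValueError("sample times must lie within one period")
    if np.any(v < 0):
        raise ValueError("concentrations must be >= 0")
    tt = np.append(t, t[0] + period)
    vv = np.append(v, v[0])
    spl = CubicSpline(tt, vv, bc_type="periodic")

    def ev(x: np.ndarray) -> np.ndarray:
        return spl(t[0] + np.mod(x - t[0], period))

    return ConcentrationProfile(ev, domain=(t[0], t[0] + period), period=period,
                                description="piecewise polynomial fit")


def from_samples(t: np.ndarray, values: np.ndarray,
                 period: float | None = None,
                 breakpoints: Sequence[float] = ()) -> ConcentrationProfile:
    """Linear-interpolation profile over a dense sample grid (PK output)."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)

    def ev(x: np.ndarray) -> np.ndarray:
        return np.interp(x, t, values)

    return ConcentrationProfile(ev, domain=(float(t[0]), float(t[-1])),
                                period=period, breakpoints=tuple(breakpoints),
                                description="tabulated profile")


@dataclass(frozen=True)
class DiurnalCortisolSpec:
    """Shape parameters of the synthetic daily free-cortisol curve.

    The curve rises from the nadir to the peak along a half-cosine ramp and
    relaxes back along an exponential of width ``decay_tau_min``, closing
    exactly at the next day's nadir; it is 24 h periodic and deterministic.
    Defaults are the calibrated package values.
    """

    nadir_nM: float = 1.45
    nadir_time_min: float = 180.0          # 03:00
    peak_nM: float = CALIBRATED_PEAK_NM
    peak_time_min: float = 480.0           # 08:00
    decay_tau_min: float = CALIBRATED_DECAY_TAU_MIN

    def __post_init__(self) -> None:
        if not 0 <= self.nadir_nM < self.peak_nM:
            raise ValueError("need 0 <= nadir < peak")
        if not 0 < self.decay_tau_min:
            raise ValueError("decay width must be positive")
        if not 0 <= self.nadir_time_min < self.peak_time_min < MINUTES_PER_DAY:
            raise ValueError("expect nadir before peak within one day")


def synthetic_cortisol(spec: DiurnalCortisolSpec | None = None) -> ConcentrationProfile:
    """Deterministic 24 h-periodic synthetic free-cortisol profile (nM)."""
    spec = spec or DiurnalCortisolSpec()
    t_n, t_p = spec.nadir_time_min, spec.peak_time_min
    rise = t_p - t_n
    fall = MINUTES_PER_DAY - rise           # peak back to next nadir
    amp = spec.peak_nM - spec.nadir_nM
    E = np.exp(-fall / spec.decay_tau_min)

    def ev(t: np.ndarray) -> np.ndarray:
        # phase in [0, 1440) measured from the nadir
        ph = np.mod(np.asarray(t, float) - t_n, MINUTES_PER_DAY)
        s = np.where(
            ph <= rise,
            0.5 * (1.0 - np.cos(np.pi * ph / rise)),
            (np.exp(-(ph - rise) / spec.decay_tau_min) - E) / (1.0 - E),
        )
        return spec.nadir_nM + amp * s

    return ConcentrationProfile(ev, domain=(0.0, MINUTES_PER_DAY),
                                period=MINUTES_PER_DAY,
                                breakpoints=(t_n, t_p),
                                description="synthetic diurnal cortisol")


def profile_from_csv(path, period: float | None = MINUTES_PER_DAY,
                     interpolate: bool = True) -> ConcentrationProfile:
    """Load a tabulated profile from a two-column CSV (time_min, nM).

    With ``interpolate=True`` and a period, returns the smooth periodic
    interpolant of :func:`piecewise_poly_profile`; otherwise a linear
    interpolation over the sampled domain.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError("expected a two-column CSV (time_min, nM)")
    if interpolate and period is not None:
        return piecewise_poly_profile([(t, v) for t, v in data], period=period)
    return from_samples(data[:, 0], data[:, 1], period=period)


def profile_to_csv(profile: ConcentrationProfile, path, t0: float, t1: float,
                   step: float = 1.0) -> None:
    """Sample a profile on a regular grid and write it as two-column CSV."""
    t = np.arange(t0, t1 + step / 2, step)
    np.savetxt(path, np.column_stack([t, profile(t)]), delimiter=",",
               header="time_min,nM", comments="", fmt="%.10g")
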