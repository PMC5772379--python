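"""Forward kinetic models for L-[1-(11)C]leucine PET.

The homogeneous tissue model describes the total decay-corrected (11)C
concentration in a voxel or region as the sum of an irreversibly trapped
component (labeled protein), a single equilibrating component (free labeled
leucine in tissue), and a blood contribution::

    CT*(t) = (1-Vb) * K1*k4/beta * int_0^t Cp*(tau) dtau
           + (1-Vb) * K1*(k2+k3)/beta * int_0^t Cp*(tau) exp(-beta (t-tau)) dtau
           + Vb * [Cb*(t) - VD*Cc*(t)] + VD*Cc*(t)

with ``beta = k2 + k3 + k4``.  A kinetically heterogeneous volume is a
weighted mixture of such homogeneous subregions sharing one blood term; its
tissue part is a spectrum of exponential-convolution components with a single
trapping amplitude ``theta0`` and equilibrating amplitudes ``theta_i`` at
rates ``beta_i``.

Physiological outputs:

* ``lambda = (k2+k3)/(k2+k3+k4)`` -- fraction of the tissue precursor pool
  for protein synthesis derived from arterial plasma.
* ``rCPS = K1*k4/(k2+k3) * Cp`` -- regional rate of cerebral protein
  synthesis (nmol/g/min), with ``Cp`` the unlabeled plasma leucine
  concentration (nmol/mL).

All rates are per minute and all times are minutes internally; file readers
convert from seconds at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "CO2_DISTRIBUTION_VOLUME",
    "FrameSchedule",
    "InputFunctionSet",
    "HomogeneousParams",
    "SubregionMixture",
    "SpectralRepresentation",
    "TissueTAC",
    "MacroParams",
    "lambda_from_rates",
    "rcps_from_rates",
    "exp_conv",
    "frame_average",
    "basis_curve",
    "homogeneous_tac",
    "heterogeneous_tac",
    "spectrum_from_params",
    "spectrum_from_mixture",
    "macros_from_spectrum",
]

#: Blood:brain equilibrium distribution volume of (11)CO2 (unitless).
CO2_DISTRIBUTION_VOLUME = 0.41

# 42-frame 90-min acquisition protocol, durations in seconds.
_DEFAULT_FRAME_DURATIONS_S = (16 * (15,)) + (4 * (30,)) + (4 * (60,)) + (4 * (150,)) + (14 * (300,))


class DegenerateKineticsError(ValueError):
    """Raised when rate constants make the requested quantity undefined."""


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame grid: start times and durations in minutes."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_times and durations must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        ends = start + dur
        if np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "durations", dur)

    @classmethod
    def default_protocol(cls) -> "FrameSchedule":
        """The standard 42-frame leucine protocol (16x15, 4x30, 4x60, 4x150,
        14x300 s), 90 min total, converted to minutes."""
        dur = np.asarray(_DEFAULT_FRAME_DURATIONS_S, dtype=float) / 60.0
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    @classmethod
    def from_seconds(cls, start_s, dur_s) -> "FrameSchedule":
        return cls(np.asarray(start_s, float) / 60.0, np.asarray(dur_s, float) / 60.0)

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + 0.5 * self.durations

    @property
    def total_duration(self) -> float:
        return float(self.end_times[-1])


@dataclass(frozen=True)
class InputFunctionSet:
    """Arterial input curves on a fine time grid (minutes).

    ``cp_star``: labeled leucine in arterial plasma; ``cb_star``: total (11)C
    in whole blood; ``cc_star``: (11)CO2 in whole blood (all decay-corrected
    activity concentrations); ``cp_unlabeled``: unlabeled plasma leucine
    (nmol/mL), constant over the study.
    """

    time: np.ndarray
    cp_star: np.ndarray
    cb_star: np.ndarray
    cc_star: np.ndarray
    cp_unlabeled: float

    def __post_init__(self):
        t = np.asarray(self.time, float)
        curves = {}
        for name in ("cp_star", "cb_star", "cc_star"):
            c = np.asarray(getattr(self, name), float)
            if c.shape != t.shape:
                raise ValueError(f"{name} must match the time grid")
            if np.any(c < 0):
                raise ValueError(f"{name} must be non-negative")
            curves[name] = c
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        if abs(t[0]) > 1e-12:
            raise ValueError("time grid must start at t=0")
        if np.max(np.diff(t)) > 1.0 / 60.0 + 1e-9:
            raise ValueError("input curves must be sampled at least every 1 s")
        for name in ("cp_star", "cb_star", "cc_star"):
            if curves[name][0] != 0.0:
                raise ValueError(f"{name} must be zero at t=0")
        if self.cp_unlabeled < 0:
            raise ValueError("cp_unlabeled must be non-negative")
        object.__setattr__(self, "time", t)
        for name, c in curves.items():
            object.__setattr__(self, name, c)

    def shifted(self, delay_min: float) -> "InputFunctionSet":
        """Return a copy with every blood curve arriving ``delay_min`` later
        (curves are zero before the delay)."""
        if delay_min == 0.0:
            return self

        def shift(c):
            out = np.interp(self.time - delay_min, self.time, c, left=0.0)
            out[self.time < delay_min] = 0.0
            return out

        return replace(
            self,
            cp_star=shift(self.cp_star),
            cb_star=shift(self.cb_star),
            cc_star=shift(self.cc_star),
        )


@dataclass(frozen=True)
class HomogeneousParams:
    """Rate constants of one kinetically uniform tissue.

    ``K1`` mL/g/min, ``k2k3`` = k2+k3 (1/min), ``k4`` (1/min), ``Vb`` blood
    volume fraction.
    """

    K1: float
    k2k3: float
    k4: float
    Vb: float = 0.05

    def __post_init__(self):
        if min(self.K1, self.k2k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.Vb <= 1.0:
            raise ValueError("Vb must lie in [0, 1]")

    @property
    def beta(self) -> float:
        """Lumped rate constant k2+k3+k4 (1/min)."""
        return self.k2k3 + self.k4

    @property
    def lam(self) -> float:
        return lambda_from_rates(self.k2k3, self.k4)

    def rcps(self, cp: float) -> float:
        return rcps_from_rates(self.K1, self.k2k3, self.k4, cp)


@dataclass(frozen=True)
class SubregionMixture:
    """Weighted set of homogeneous subregions sharing one blood term."""

    subregions: Sequence[HomogeneousParams]
    weights: np.ndarray
    Vb: float = 0.05

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if len(self.subregions) < 1 or w.size != len(self.subregions):
            raise ValueError("need one weight per subregion, n >= 1")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if not 0.0 <= self.Vb <= 1.0:
            raise ValueError("Vb must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "subregions", tuple(self.subregions))

    @property
    def K1(self) -> float:
        """Weighted average influx rate constant."""
        return float(np.dot(self.weights, [s.K1 for s in self.subregions]))

    def rcps(self, cp: float) -> float:
        """Weighted average rCPS of the mixture."""
        return float(np.dot(self.weights, [s.rcps(cp) for s in self.subregions]))


@dataclass(frozen=True)
class SpectralRepresentation:
    """Spectrum of a (possibly heterogeneous) tissue: trapping amplitude
    ``theta0``, equilibrating amplitudes ``thetas`` at rates ``betas``."""

    theta0: float
    thetas: np.ndarray
    betas: np.ndarray
    Vb: float = 0.05
    VD: float = CO2_DISTRIBUTION_VOLUME

    def __post_init__(self):
        th = np.atleast_1d(np.asarray(self.thetas, float))
        be = np.atleast_1d(np.asarray(self.betas, float))
        if th.shape != be.shape:
            raise ValueError("thetas and betas must have equal length")
        if self.theta0 < 0 or np.any(th < 0):
            raise ValueError("spectral amplitudes must be non-negative")
        if np.any(be <= 0):
            raise ValueError("equilibrating rates must be positive")
        object.__setattr__(self, "thetas", th)
        object.__setattr__(self, "betas", be)


@dataclass(frozen=True)
class TissueTAC:
    """Frame-averaged decay-corrected tissue time-activity curve."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (self.schedule.n_frames,):
            raise ValueError("one value per frame required")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MacroParams:
    """Macro parameters recovered from a spectrum."""

    K1: float
    lam: float
    rcps: float
    degenerate: bool = False


def lambda_from_rates(k2k3: float, k4: float) -> float:
    """Fraction of the precursor leucine pool derived from arterial plasma,
    ``(k2+k3)/(k2+k3+k4)``."""
    if k2k3 < 0 or k4 < 0:
        raise ValueError("rates must be non-negative")
    if k2k3 + k4 == 0:
        raise DegenerateKineticsError("lambda undefined when k2+k3 and k4 are both zero")
    return k2k3 / (k2k3 + k4)


def rcps_from_rates(K1: float, k2k3: float, k4: float, cp: float) -> float:
    """Rate of cerebral protein synthesis ``K1*k4/(k2+k3) * Cp`` (nmol/g/min)."""
    if min(K1, k2k3, k4, cp) < 0:
        raise ValueError("all inputs must be non-negative")
    if k2k3 == 0:
        raise DegenerateKineticsError("rCPS undefined for k2+k3 = 0 (pure trapping)")
    return K1 * k4 / k2k3 * cp


def exp_conv(time: np.ndarray, curve: np.ndarray, beta: float) -> np.ndarray:
    """Convolution ``int_0^t curve(tau) exp(-beta (t-tau)) dtau`` on the grid.

    Uses the piecewise-analytic recurrence that is exact for piecewise-linear
    inputs, which keeps large ``beta`` (stiff) components accurate on a 1-s
    grid.  ``beta = 0`` returns the running integral.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta == 0.0:
        return cumulative_trapezoid(curve, time, initial=0.0)
    dt = np.diff(time)
    a = curve[:-1]
    m = np.diff(curve) / dt
    e = np.exp(-beta * dt)
    one_m_e = -np.expm1(-beta * dt)
    # segment integral of (a + m*u) * exp(-beta*(dt-u)) over u in [0, dt]
    g = a * one_m_e / beta + m * (dt * beta - one_m_e) / beta**2
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        # uniform grid: the recurrence y[k] = e*y[k-1] + g[k-1] is an IIR filter
        y_tail = lfilter([1.0], [1.0, -e[0]], g)
    else:
        y_tail = np.empty_like(g)
        acc = 0.0
        for k in range(g.size):
            acc = e[k] * acc + g[k]
            y_tail[k] = acc
    return np.concatenate([[0.0], y_tail])


def frame_average(time: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Mean of a continuous curve within each frame (trapezoidal)."""
    if schedule.end_times[-1] > time[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the input time grid")
    integral = cumulative_trapezoid(curve, time, initial=0.0)
    hi = np.interp(schedule.end_times, time, integral)
    lo = np.interp(schedule.start_times, time, integral)
    return (hi - lo) / schedule.durations


def basis_curve(beta: float, inputs: InputFunctionSet, schedule: FrameSchedule) -> TissueTAC:
    """Frame-averaged exponential-convolution basis function of ``cp_star``."""
    conv = exp_conv(inputs.time, inputs.cp_star, beta)
    return TissueTAC(schedule, frame_average(inputs.time, conv, schedule))


def _blood_curve(inputs: InputFunctionSet, Vb: float, VD: float) -> np.ndarray:
    """Blood contribution Vb*[Cb* - VD*Cc*] + VD*Cc* on the fine grid.

    With ``cc_star = 0`` (simulation mode) this reduces to ``Vb*Cb*``.
    """
    return Vb * (inputs.cb_star - VD * inputs.cc_star) + VD * inputs.cc_star


def _spectral_fine_curve(spec: SpectralRepresentation, inputs: InputFunctionSet) -> np.ndarray:
    tissue = spec.theta0 * exp_conv(inputs.time, inputs.cp_star, 0.0)
    for th, be in zip(spec.thetas, spec.betas):
        if th != 0.0:
            tissue = tissue + th * exp_conv(inputs.time, inputs.cp_star, be)
    return tissue + _blood_curve(inputs, spec.Vb, spec.VD)


def spectrum_from_params(
    params: HomogeneousParams, VD: float = CO2_DISTRIBUTION_VOLUME
) -> SpectralRepresentation:
    """Spectral (theta, beta) representation of one homogeneous tissue."""
    beta = params.beta
    if beta == 0.0:
        raise DegenerateKineticsError("spectrum undefined for beta = 0")
    scale = (1.0 - params.Vb) * params.K1 / beta
    return SpectralRepresentation(
        theta0=scale * params.k4,
        thetas=np.array([scale * params.k2k3]),
        betas=np.array([beta]),
        Vb=params.Vb,
        VD=VD,
    )


def spectrum_from_mixture(
    mix: SubregionMixture, VD: float = CO2_DISTRIBUTION_VOLUME
) -> SpectralRepresentation:
    """Spectrum of a weighted mixture: summed trapping amplitude and one
    equilibrating component per subregion."""
    theta0 = 0.0
    thetas, betas = [], []
    for w, sub in zip(mix.weights, mix.subregions):
        beta = sub.beta
        if beta == 0.0:
            raise DegenerateKineticsError("subregion with beta = 0 not representable")
        scale = (1.0 - mix.Vb) * w * sub.K1 / beta
        theta0 += scale * sub.k4
        thetas.append(scale * sub.k2k3)
        betas.append(beta)
    return SpectralRepresentation(theta0, np.array(thetas), np.array(betas), mix.Vb, VD)


def homogeneous_tac(
    params: HomogeneousParams,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    VD: float = CO2_DISTRIBUTION_VOLUME,
) -> TissueTAC:
    """Noise-free frame-averaged TAC of a kinetically homogeneous tissue."""
    if params.beta == 0.0:
        # no efflux or incorporation: everything delivered is trapped
        tissue = (1.0 - params.Vb) * params.K1 * exp_conv(inputs.time, inputs.cp_star, 0.0)
        fine = tissue + _blood_curve(inputs, params.Vb, VD)
        return TissueTAC(schedule, frame_average(inputs.time, fine, schedule))
    spec = spectrum_from_params(params, VD)
    fine = _spectral_fine_curve(spec, inputs)
    return TissueTAC(schedule, frame_average(inputs.time, fine, schedule))


def heterogeneous_tac(
    mix: SubregionMixture,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    VD: float = CO2_DISTRIBUTION_VOLUME,
) -> TissueTAC:
    """Noise-free frame-averaged TAC of a mixture of homogeneous subregions
    sharing a single blood term."""
    spec = spectrum_from_mixture(mix, VD)
    fine = _spectral_fine_curve(spec, inputs)
    return TissueTAC(schedule, frame_average(inputs.time, fine, schedule))


def macros_from_spectrum(spec: SpectralRepresentation, cp: float) -> MacroParams:
    """Macro parameters (K1, lambda, rCPS) from a fitted or constructed
    spectrum::

        K1     = (theta0 + sum theta_i) / (1 - Vb)
        lambda = sum theta_i / (theta0 + sum theta_i)
        rCPS   = K1 * (1 - lambda)/lambda * Cp

    A spectrum with no equilibrating mass (sum theta_i = 0) cannot separate
    transport from incorporation; it is flagged degenerate and rCPS falls
    back to the net-uptake form ``theta0/(1-Vb) * Cp``.
    """
    if spec.Vb >= 1.0:
        raise ValueError("Vb must be < 1 to recover tissue parameters")
    theta_sum = float(np.sum(spec.thetas))
    total = spec.theta0 + theta_sum
    if total == 0.0:
        return MacroParams(0.0, 0.0, 0.0, degenerate=True)
    K1 = total / (1.0 - spec.Vb)
    lam = theta_sum / total
    if theta_sum == 0.0:
        # pure trapping: lambda formally 0, report net uptake as rCPS
        return MacroParams(K1, 0.0, spec.theta0 / (1.0 - spec.Vb) * cp, degenerate=True)
    if spec.theta0 == 0.0:
        return MacroParams(K1, 1.0, 0.0, degenerate=False)
    rcps = K1 * (1.0 - lam) / lam * cp
    return MacroParams(K1, lam, rcps, degenerate=False)
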