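"""Synthetic study inputs: arterial input functions, the 19-entry reference
parameter library, heterogeneous counterparts, frame-level Gaussian noise, and
a 3D brain-like phantom.

The noise model assigns each frame an independent zero-mean Gaussian error
with variance proportional to the (decay-uncorrected) count rate::

    Var[CT*(t_i)] = alpha * exp(gamma * t_i) * CT*(t_i) / dt_i

where ``gamma`` is the (11)C decay constant, ``dt_i`` the frame duration and
``alpha`` a proportionality coefficient calibrated to either voxel-level or
region-of-interest (ROI) level data quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import (
    FrameSchedule,
    HomogeneousParams,
    InputFunctionSet,
    SubregionMixture,
    TissueTAC,
    homogeneous_tac,
)

__all__ = [
    "C11_HALF_LIFE_MIN",
    "C11_DECAY_CONSTANT",
    "NoiseModel",
    "PhantomSpec",
    "Phantom",
    "make_input_functions",
    "reference_library",
    "derive_heterogeneous",
    "add_noise",
    "calibrate_alpha",
    "noise_model_for_level",
    "build_phantom",
]

#: (11)C half-life in minutes and the corresponding decay constant (1/min).
C11_HALF_LIFE_MIN = 20.34
C11_DECAY_CONSTANT = math.log(2.0) / C11_HALF_LIFE_MIN

# Printed ranges of the regional reference rate constants.
_K1_RANGE = (0.025, 0.062)      # mL/g/min
_K2K3_RANGE = (0.054, 0.157)    # 1/min
_K4_RANGE = (0.027, 0.053)      # 1/min
_REFERENCE_VB = 0.05

#: Target relative SD at the peak frame of the mid-library TAC per noise
#: level.  The anchors were calibrated once so that the Monte Carlo estimator
#: dispersion (RMSE% of K1, lambda and rCPS in the noise-dominated regime)
#: reproduces the dispersion reported for voxel-level and ROI-level leucine
#: PET data; see the methods note.
NOISE_LEVEL_REL_SD = {"voxel": 0.07, "roi": 0.012}


@dataclass(frozen=True)
class NoiseModel:
    """Frame-wise Gaussian noise with count-statistics-shaped variance.

    ``alpha`` scales the variance; ``gamma`` is the isotope decay constant
    (1/min).  ``alpha = 0`` produces noise-free realizations.
    """

    alpha: float
    gamma: float = C11_DECAY_CONSTANT
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def variance(self, tac: TissueTAC) -> np.ndarray:
        """Per-frame error variance evaluated at frame mid-times, using the
        noise-free TAC (available by construction in simulation)."""
        t = tac.schedule.mid_times
        ct = np.clip(tac.values, 0.0, None)
        return self.alpha * np.exp(self.gamma * t) * ct / tac.schedule.durations

    def sd_scale(self, tac: TissueTAC) -> np.ndarray:
        """The per-frame scale s_i = sqrt(exp(gamma t_i) CT_i / dt_i), i.e. the
        error SD for alpha = 1 (used to normalize residuals)."""
        t = tac.schedule.mid_times
        ct = np.clip(tac.values, 0.0, None)
        return np.sqrt(np.exp(self.gamma * t) * ct / tac.schedule.durations)


def make_input_functions(
    infusion_min: float = 2.0,
    peak: float = 100.0,
    tail_halftimes: Sequence[float] = (1.5, 8.0, 45.0),
    tail_fractions: Sequence[float] = (0.6, 0.3, 0.1),
    cp_unlabeled: float = 120.0,
    blood_plasma_ratio: float = 0.8,
    total_min: float = 90.0,
    dt_s: float = 1.0,
) -> InputFunctionSet:
    """Synthetic arterial input set for a 2-min tracer infusion.

    Labeled plasma leucine ``cp_star`` ramps linearly from zero to ``peak``
    over the infusion, then decays as a sum of exponentials with the given
    half-times and amplitude fractions (fractions must sum to 1 so the curve
    is continuous at the end of infusion).  Whole-blood activity is a constant
    multiple of plasma activity; whole-blood (11)CO2 is zero (simulation
    mode).  Deterministic given its arguments.
    """
    if infusion_min <= 0:
        raise ValueError("infusion duration must be positive")
    if peak <= 0:
        raise ValueError("peak activity must be positive")
    fr = np.asarray(tail_fractions, float)
    ht = np.asarray(tail_halftimes, float)
    if fr.shape != ht.shape or np.any(fr < 0) or np.any(ht <= 0):
        raise ValueError("tail fractions/half-times must be matched, valid sequences")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("tail fractions must sum to 1")
    dt = dt_s / 60.0
    n = int(round(total_min / dt))
    time = np.linspace(0.0, total_min, n + 1)
    cp = np.where(time <= infusion_min, peak * time / infusion_min, 0.0)
    tail_mask = time > infusion_min
    tau = time[tail_mask] - infusion_min
    decay = np.zeros_like(tau)
    for f, h in zip(fr, ht):
        decay += f * np.exp(-math.log(2.0) * tau / h)
    cp[tail_mask] = peak * decay
    return InputFunctionSet(
        time=time,
        cp_star=cp,
        cb_star=blood_plasma_ratio * cp,
        cc_star=np.zeros_like(cp),
        cp_unlabeled=cp_unlabeled,
    )


def reference_library() -> list[HomogeneousParams]:
    """The 19 regional reference parameter sets.

    Each rate constant spans its physiological range inclusive of both
    endpoints; the three rates are laid out by deterministic stratified
    interpolation with fixed decorrelating permutations (multiplicative
    orderings mod 19), so the joint spread is not a single monotone sweep.
    ``Vb`` is 0.05 in every set.
    """
    n = 19
    out = []
    for i in range(n):
        u1 = i / (n - 1)
        u2 = ((i * 7) % n) / (n - 1)
        u4 = ((i * 11) % n) / (n - 1)
        out.append(
            HomogeneousParams(
                K1=_K1_RANGE[0] + u1 * (_K1_RANGE[1] - _K1_RANGE[0]),
                k2k3=_K2K3_RANGE[0] + u2 * (_K2K3_RANGE[1] - _K2K3_RANGE[0]),
                k4=_K4_RANGE[0] + u4 * (_K4_RANGE[1] - _K4_RANGE[0]),
                Vb=_REFERENCE_VB,
            )
        )
    return out


def derive_heterogeneous(h: HomogeneousParams) -> SubregionMixture:
    """Two-subregion heterogeneous counterpart of a homogeneous tissue.

    Construction: equal weights; equal ``lambda`` in both subregions; the
    weighted average K1 equals the homogeneous K1; the lumped rate
    ``beta = k2+k3+k4`` in the first subregion is five times that in the
    second; the product ``K1*(k2+k3)`` in the first is 25 times that in the
    second.  The constraints fix K1a = 5*K1/3 and K1b = K1/3; the absolute
    scale of the betas is anchored so the weighted mean beta equals the
    homogeneous beta (beta_a = 5*beta/3, beta_b = beta/3).  The construction
    preserves the weighted average rCPS exactly.
    """
    if h.k2k3 <= 0 or h.k4 <= 0:
        raise ValueError("heterogeneous construction requires k2+k3 > 0 and k4 > 0")
    lam = h.lam
    k1a, k1b = 5.0 * h.K1 / 3.0, h.K1 / 3.0
    beta_a, beta_b = 5.0 * h.beta / 3.0, h.beta / 3.0
    sub_a = HomogeneousParams(k1a, lam * beta_a, (1.0 - lam) * beta_a, h.Vb)
    sub_b = HomogeneousParams(k1b, lam * beta_b, (1.0 - lam) * beta_b, h.Vb)
    return SubregionMixture((sub_a, sub_b), np.array([0.5, 0.5]), Vb=h.Vb)


def add_noise(
    tac: TissueTAC,
    model: NoiseModel,
    n_reps: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``n_reps`` independent noisy realizations of a TAC, shape
    ``(n_reps, n_frames)``.  Gaussian per frame; negative values are allowed.
    Reproducible from ``model.seed`` when no generator is passed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    sd = np.sqrt(model.variance(tac))
    return tac.values[None, :] + rng.standard_normal((n_reps, tac.schedule.n_frames)) * sd[None, :]


def calibrate_alpha(
    tac: TissueTAC, target_rel_sd: float, gamma: float = C11_DECAY_CONSTANT
) -> float:
    """Alpha such that the relative SD at the frame of peak activity of
    ``tac`` equals ``target_rel_sd``."""
    p = int(np.argmax(tac.values))
    ct = tac.values[p]
    if ct <= 0:
        raise ValueError("calibration TAC has non-positive peak")
    t = tac.schedule.mid_times[p]
    dt = tac.schedule.durations[p]
    return target_rel_sd**2 * ct * dt * math.exp(-gamma * t)


def noise_model_for_level(
    level: str,
    inputs: InputFunctionSet | None = None,
    schedule: FrameSchedule | None = None,
    seed: int = 0,
    gamma: float = C11_DECAY_CONSTANT,
) -> NoiseModel:
    """Noise model calibrated to 'voxel' (25% peak relative SD) or 'roi'
    (5%) data quality, against the mid-library homogeneous TAC."""
    level = level.lower()
    if level not in NOISE_LEVEL_REL_SD:
        raise ValueError(f"unknown noise level {level!r}; use 'roi' or 'voxel'")
    if inputs is None:
        inputs = make_input_functions()
    if schedule is None:
        schedule = FrameSchedule.default_protocol()
    mid = reference_library()[9]
    tac = homogeneous_tac(mid, inputs, schedule)
    alpha = calibrate_alpha(tac, NOISE_LEVEL_REL_SD[level], gamma)
    return NoiseModel(alpha=alpha, gamma=gamma, seed=seed)


# default phantom tissue classes at the reference-library extremes: gray
# matter takes the fast/well-perfused endpoint of every rate range, white
# matter the slow endpoint, maximizing the gray/white kinetic contrast
_GRAY = HomogeneousParams(K1=_K1_RANGE[1], k2k3=_K2K3_RANGE[1], k4=_K4_RANGE[1], Vb=0.05)
_WHITE = HomogeneousParams(K1=_K1_RANGE[0], k2k3=_K2K3_RANGE[0], k4=_K4_RANGE[0], Vb=0.05)

BACKGROUND, WHITE, GRAY = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue classes of the 3D brain-like phantom."""

    shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.2)
    class_params: dict = field(
        default_factory=lambda: {GRAY: _GRAY, WHITE: _WHITE}
    )

    def label_map(self) -> np.ndarray:
        """Ellipsoidal brain: gray-matter shell around a white-matter core,
        zero-activity background."""
        nx, ny, nz = self.shape
        x, y, z = np.meshgrid(
            np.arange(nx) - (nx - 1) / 2,
            np.arange(ny) - (ny - 1) / 2,
            np.arange(nz) - (nz - 1) / 2,
            indexing="ij",
        )
        outer = (x / (0.42 * nx)) ** 2 + (y / (0.42 * ny)) ** 2 + (z / (0.42 * nz)) ** 2
        inner = (x / (0.26 * nx)) ** 2 + (y / (0.26 * ny)) ** 2 + (z / (0.26 * nz)) ** 2
        labels = np.full(self.shape, BACKGROUND, dtype=np.int16)
        labels[outer <= 1.0] = GRAY
        labels[inner <= 1.0] = WHITE
        return labels


@dataclass(frozen=True)
class Phantom:
    """4D dynamic image plus per-voxel ground truth."""

    spec: PhantomSpec
    schedule: FrameSchedule
    labels: np.ndarray
    image: np.ndarray            # (nx, ny, nz, n_frames)
    truth: dict                  # maps 'K1', 'lam', 'rcps' -> 3D arrays

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spec.voxel_size_mm
        return aff

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


def build_phantom(
    spec: PhantomSpec,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    noise: NoiseModel | None = None,
) -> Phantom:
    """Dynamic phantom whose voxels are each kinetically homogeneous before
    any smoothing: every in-brain voxel carries the noise-free TAC of its
    tissue class, plus optional frame-wise Gaussian noise."""
    labels = spec.label_map()
    n_frames = schedule.n_frames
    image = np.zeros(spec.shape + (n_frames,), dtype=np.float64)
    truth = {k: np.zeros(spec.shape) for k in ("K1", "lam", "rcps")}
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    present = set(np.unique(labels)) - {BACKGROUND}
    if not present <= set(spec.class_params):
        raise ValueError(f"no parameters for class labels {present - set(spec.class_params)}")
    for lab in sorted(present):
        params = spec.class_params[lab]
        tac = homogeneous_tac(params, inputs, schedule)
        mask = labels == lab
        image[mask] = tac.values
        truth["K1"][mask] = params.K1
        truth["lam"][mask] = params.lam
        truth["rcps"][mask] = params.rcps(inputs.cp_unlabeled)
        if rng is not None and noise.alpha > 0:
            sd = np.sqrt(noise.variance(tac))
            nvox = int(mask.sum())
            image[mask] += rng.standard_normal((nvox, n_frames)) * sd[None, :]
    return Phantom(spec, schedule, labels, image, truth)
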