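"""PRFS MR encoding: temperature -> phase -> complex images -> subsampled
segmented-EPI k-space.

The proton resonance frequency of water shifts by alpha = -0.01 ppm/degC, so
a temperature rise dT appears in a gradient-echo image as a phase change
dphi = gamma * alpha * B0 * TE * dT (Eq. form dT = dphi/(gamma*alpha*B0*TE)).
Acquisition is modelled as a snapshot centered 3D Fourier transform at the
k-space-center time of each dynamic, with a Cartesian variable-density mask
over (ky, kz): the readout kx is always fully sampled, a small fully sampled
central kz band anchors the contrast, and the outer kz lines are equally
spaced with a frame-dependent offset so that consecutive dynamics interleave
complementarily.  No phase unwrapping is performed anywhere: protocols in
scope keep |dphi| < pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PRFSConstants",
    "SamplingMask",
    "KSpaceFrame",
    "temp_to_phase",
    "phase_to_temp",
    "synth_image",
    "build_mask",
    "acquire_frame",
    "frame_times",
    "fft3c",
    "ifft3c",
    "synthetic_baseline",
]

GAMMA_RAD_PER_S_T = 2.0 * np.pi * 42.576e6  # proton gyromagnetic ratio


@dataclass(frozen=True)
class PRFSConstants:
    """Constants of the PRFS temperature-to-phase mapping."""

    gamma: float = GAMMA_RAD_PER_S_T   # rad/(s*T)
    alpha_prfs: float = -0.01          # ppm/degC (negative for aqueous tissue)
    b0: float = 3.0                    # T
    te: float = 11e-3                  # s

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.b0 <= 0 or self.te <= 0:
            raise ValueError("gamma, b0 and te must be positive")
        if self.alpha_prfs >= 0:
            warnings.warn("alpha_prfs >= 0 is unphysical for aqueous tissue",
                          stacklevel=2)

    @property
    def rad_per_degc(self) -> float:
        return self.gamma * (self.alpha_prfs * 1e-6) * self.b0 * self.te


def temp_to_phase(dT, consts: PRFSConstants):
    """Phase change (rad) for a temperature rise dT (degC)."""
    return np.asarray(dT) * consts.rad_per_degc


def phase_to_temp(dPhi, consts: PRFSConstants):
    """Temperature rise (degC) for a phase change dPhi (rad); exact inverse
    of :func:`temp_to_phase`.  No unwrapping is applied."""
    scale = consts.rad_per_degc
    if scale == 0:
        raise ValueError("degenerate PRFS constants: zero rad/degC scale")
    return np.asarray(dPhi) / scale


def synth_image(magnitude: np.ndarray, baseline_phase: np.ndarray, dT,
                consts: PRFSConstants) -> np.ndarray:
    """Complex image magnitude*exp(i*(baseline_phase + dphi(dT)))."""
    magnitude = np.asarray(magnitude)
    if np.any(magnitude < 0):
        raise ValueError("magnitude must be non-negative")
    dphi = temp_to_phase(dT, consts)
    if np.max(np.abs(dphi)) >= np.pi:
        warnings.warn("|dphi| >= pi: PRFS phase would wrap; temperature "
                      "range exceeds the protocol's unambiguous range",
                      stacklevel=2)
    return magnitude * np.exp(1j * (np.asarray(baseline_phase) + dphi))


# ---------------------------------------------------------------------------
# sampling masks
# ---------------------------------------------------------------------------

@dataclass
class SamplingMask:
    """Variable-density Cartesian (ky, kz) acquisition pattern.

    ``pattern`` is boolean over (ny, nz); kx (readout) is always full.
    ``shots`` lists the kz indices of each echo train (constant echo spacing
    within a shot).  ``frame_index`` selects the complementary interleave.
    """

    pattern: np.ndarray
    R: float
    etl: int
    frame_index: int
    shots: list[np.ndarray] = field(default_factory=list)

    @property
    def sampled_fraction(self) -> float:
        return float(self.pattern.mean())

    def sampled_kz(self) -> np.ndarray:
        return np.flatnonzero(self.pattern[self.pattern.shape[0] // 2, :])


def _chunk_shots(indices: np.ndarray, etl: int) -> list[np.ndarray]:
    return [indices[i:i + etl] for i in range(0, len(indices), etl)]


def build_mask(ny: int, nz: int, R: float, etl: int = 7,
               frame_index: int = 0, center_frac: float = 0.2) -> SamplingMask:
    """Two-tier variable-density kz sampling at reduction factor R.

    A fully sampled central band takes ~``center_frac`` of the line budget
    round(nz/R); the remaining budget is spent on equally spaced outer kz
    lines whose offset rotates with ``frame_index`` (complementary
    interleaving for sliding-window reconstruction).  Within each echo train
    the kz indices form an arithmetic progression (constant echo spacing).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > nz:
        raise ValueError("R exceeds the number of kz lines")
    if etl < 1 or etl > ny:
        raise ValueError("invalid echo train length")
    budget = max(1, int(round(nz / R)))
    n_center = max(1, int(round(center_frac * budget)))
    n_center = min(n_center, nz)
    c0 = nz // 2 - n_center // 2
    center_lines = np.arange(c0, c0 + n_center)
    sampled = set(center_lines.tolist())
    shots: list[np.ndarray] = _chunk_shots(center_lines, etl)
    n_outer = budget - n_center
    if n_outer > 0 and n_center < nz:
        n_remaining = nz - n_center
        stride = max(1, n_remaining // n_outer)
        offset = int(frame_index) % stride
        below = np.arange(0, c0)[offset::stride]
        above = np.arange(c0 + n_center, nz)[offset::stride]
        # the floor stride over-produces; trim the outermost picks (the ends
        # of each arithmetic run) so the line budget is met exactly
        excess = below.size + above.size - n_outer
        while excess > 0 and (below.size or above.size):
            d_below = c0 - below[0] if below.size else -1
            d_above = above[-1] - (c0 + n_center) if above.size else -1
            if d_below >= d_above:
                below = below[1:]
            else:
                above = above[:-1]
            excess -= 1
        for pick in (below, above):
            sampled.update(pick.tolist())
            shots.extend(_chunk_shots(pick, etl))
    pattern = np.zeros((ny, nz), dtype=bool)
    pattern[:, sorted(sampled)] = True
    return SamplingMask(pattern=pattern, R=float(R), etl=etl,
                        frame_index=int(frame_index), shots=shots)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def fft3c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 3D Fourier transform (image -> k-space)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def ifft3c(k: np.ndarray) -> np.ndarray:
    """Centered orthonormal inverse 3D Fourier transform."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k), norm="ortho"))


@dataclass
class KSpaceFrame:
    """One dynamic's k-space samples (zeros where unsampled) plus timing."""

    data: np.ndarray              # (nx, ny, nz) complex, zero off-mask
    mask: SamplingMask
    t_start: float
    t_acq: float

    @property
    def t_center(self) -> float:
        """Acquisition is assigned to the k-space-center time."""
        return self.t_start + self.t_acq / 2.0

    @property
    def fully_sampled(self) -> bool:
        return bool(self.mask.pattern.all())


def acquire_frame(volume: np.ndarray, mask: SamplingMask, noise_sd: float = 0.0,
                  seed: int | None = None, t_start: float = 0.0,
                  t_acq: float = 2.4) -> KSpaceFrame:
    """Encode a complex volume into masked k-space with complex white
    Gaussian noise (sd per real/imaginary channel) on sampled points only."""
    volume = np.asarray(volume, dtype=complex)
    if volume.ndim != 3 or volume.shape[1:] != mask.pattern.shape:
        raise ValueError(f"volume shape {volume.shape} does not match mask "
                         f"{mask.pattern.shape} over (ky, kz)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    k = fft3c(volume)
    k[:, ~mask.pattern] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sel = np.broadcast_to(mask.pattern, k.shape)
        n = int(sel.sum())
        noise = rng.normal(0.0, noise_sd, n) + 1j * rng.normal(0.0, noise_sd, n)
        k[sel] += noise
    return KSpaceFrame(data=k, mask=mask, t_start=float(t_start),
                       t_acq=float(t_acq))


def frame_times(n_frames: int, t_acq: float, t0: float = 0.0) -> list[tuple[float, float]]:
    """(start, k-space-center) times of back-to-back dynamics; the center of
    k-space is sampled halfway through each acquisition."""
    if t_acq <= 0:
        raise ValueError("t_acq must be positive")
    return [(t0 + i * t_acq, t0 + i * t_acq + t_acq / 2.0) for i in range(n_frames)]


# ---------------------------------------------------------------------------
# synthetic baseline images
# ---------------------------------------------------------------------------

_COMPARTMENT_SIGNAL = {0: 0.85, 1: 1.0, 2: 0.05}   # water / gel / PVC


def synthetic_baseline(labels: np.ndarray, seed: int = 0,
                       shading: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic baseline magnitude and phase for the complex MR pipeline.

    Magnitude: compartment signal levels (PVC is nearly signal-free)
    modulated by a smooth radial coil-shading profile; phase: a seeded
    low-order polynomial background.  Emulates the spatial structure of a
    gradient-echo baseline without modelling relaxation.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = labels.shape
    sig = np.ones(labels.shape)
    for lab, s in _COMPARTMENT_SIGNAL.items():
        sig[labels == lab] = s
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    r2 = x ** 2 + y ** 2 + z ** 2
    shade = 1.0 - shading * r2 / r2.max()
    coeffs = rng.uniform(-0.5, 0.5, size=7)
    phase = (coeffs[0] + coeffs[1] * x + coeffs[2] * y + coeffs[3] * z
             + coeffs[4] * x * y + coeffs[5] * x * z + coeffs[6] * y * z)
    return (sig * shade).astype(float), (phase + np.zeros_like(sig)).astype(float)
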