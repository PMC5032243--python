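"""Phased-array modelling and hybrid angular-spectrum (HAS) beam simulation.

The continuous-wave field of a spherically curved phased array is marched
plane-by-plane along +z through a voxelized medium, alternating between the
space domain (per-voxel attenuation and speed-of-sound phase deviation,
normal-incidence interface transmission) and the spatial-frequency domain
(exact homogeneous diffraction at a per-slab reference speed).  Power
deposition density Q = alpha*|p|^2/(rho*c) feeds the bioheat solver, and
per-element single-shot simulations provide phase-aberration correction for
focusing through the skull shell.

Conventions: time dependence exp(-i*omega*t), forward propagation phase
exp(+i*k*z); the marched field is the envelope with the carrier exp(i*kbar*z)
removed (a global per-plane phase, irrelevant to magnitudes and to relative
element phases).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .phantoms import MediumGrid

__all__ = [
    "TransducerArray",
    "SourcePlane",
    "PressureField",
    "QField",
    "build_array",
    "geometric_steer",
    "source_plane",
    "has_propagate",
    "compute_q",
    "aberration_correct",
    "oneil_axial_oracle",
    "calibrate_aperture",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class TransducerArray:
    """Spherically curved phased array of point-like elements.

    Elements lie on the sphere of radius ``roc`` about ``focus_center`` (the
    geometric focus), inside the aperture cone.  ``drive`` holds the complex
    per-element excitation (unit amplitude, zero phase by default); absolute
    source strength is fixed later by normalizing the source plane to the
    requested acoustic power.
    """

    n_elements: int
    element_positions: np.ndarray      # (N, 3) m
    element_normals: np.ndarray        # (N, 3) unit, toward focus
    frequency: float                   # Hz
    roc: float                         # m
    aperture_diameter: float           # m
    focus_center: tuple[float, float, float]
    drive: np.ndarray                  # (N,) complex
    total_acoustic_power: float = 0.0  # W, set at source-plane normalization
    element_radius: float = 0.0        # m; > 0 adds piston-like directivity

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.drive)

    def with_phases(self, phases: np.ndarray) -> "TransducerArray":
        amp = np.abs(self.drive)
        return replace(self, drive=amp * np.exp(1j * np.asarray(phases)))


def build_array(n_elements: int = 256, roc: float = 0.13, frequency: float = 1.0e6,
                aperture_diameter: float = 0.11, layout_seed: int | None = None,
                apex=(0.0, 0.0, 0.0), element_radius: float | None = None) -> TransducerArray:
    """Quasi-uniform (Fibonacci-spiral) element layout on a spherical cap.

    The apex of the bowl sits at ``apex`` and the geometric focus at
    ``apex + (0, 0, roc)``.  A ``layout_seed`` adds a small seeded jitter to
    the deterministic spiral, standing in for the unpublished layout of the
    commercial array.

    Each element radiates a spherical wave weighted by a piston-like Gaussian
    directivity of effective radius ``element_radius`` (default: the radius
    of a disc tiling the cap area among the elements).  A sparse set of
    isotropic point sources at several-wavelength pitch would throw most of
    its power into grating lobes that the real contiguous-element array does
    not have; the directivity keeps the radiated power in the focusing cone
    so that the source-plane power normalization is physically meaningful.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if not (0 < aperture_diameter < 2 * roc):
        raise ValueError("aperture_diameter must be in (0, 2*roc)")
    a = aperture_diameter / 2.0
    theta_max = np.arcsin(a / roc)
    cos_max = np.cos(theta_max)
    i = np.arange(n_elements)
    if n_elements == 1:
        cos_t = np.array([1.0])      # single element on axis
        phi = np.array([0.0])
    else:
        # area-uniform in cos(theta) over the cap
        cos_t = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_elements
        phi = i * _GOLDEN_ANGLE
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    if layout_seed is not None and n_elements > 1:
        rng = np.random.default_rng(layout_seed)
        dtheta = theta_max / max(np.sqrt(n_elements), 1.0)
        theta = np.clip(theta + rng.normal(0, 0.15 * dtheta, n_elements), 0, theta_max)
        phi = phi + rng.normal(0, 0.15 * dtheta, n_elements)
    center = np.asarray(apex, dtype=float) + np.array([0.0, 0.0, roc])
    # elements below the focus center, on the sphere of radius roc
    dirs = np.stack([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     -np.cos(theta)], axis=1)
    positions = center + roc * dirs
    normals = (center - positions) / roc
    if element_radius is None:
        cap_area = 2.0 * np.pi * roc * (roc - np.sqrt(roc * roc - a * a))
        element_radius = float(np.sqrt(cap_area / (np.pi * n_elements)))
    return TransducerArray(
        n_elements=n_elements, element_positions=positions, element_normals=normals,
        frequency=frequency, roc=roc, aperture_diameter=aperture_diameter,
        focus_center=tuple(center), drive=np.ones(n_elements, dtype=complex),
        element_radius=element_radius)


def geometric_steer(array: TransducerArray, focus_point, c_ref: float) -> np.ndarray:
    """Per-element phases focusing all waves in phase at ``focus_point``.

    phase_i = -(2*pi*f/c_ref) * (|focus - pos_i| - roc); at the geometric
    center of curvature all path lengths equal roc and all phases are zero.
    """
    if c_ref <= 0:
        raise ValueError("c_ref must be positive")
    d = np.linalg.norm(np.asarray(focus_point, dtype=float)
                       - array.element_positions, axis=1)
    return -(2.0 * np.pi * array.frequency / c_ref) * (d - array.roc)


# ---------------------------------------------------------------------------
# source plane and direct (Rayleigh-like point-source) summation
# ---------------------------------------------------------------------------

def field_at_points(array: TransducerArray, points: np.ndarray, c: float,
                    per_element: bool = False, chunk: int = 64) -> np.ndarray:
    """Free-field pressure of the array at arbitrary points in a homogeneous
    medium of sound speed ``c``: sum of spherically spreading contributions
    a_i * exp(i*(phase_i + k*r))/r.  Brute-force; used for source planes,
    aperture calibration and as a validation oracle."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    k = 2.0 * np.pi * array.frequency / c
    out_shape = (array.n_elements, pts.shape[0]) if per_element else (pts.shape[0],)
    out = np.zeros(out_shape, dtype=complex)
    # piston pattern 2J1(x)/x ~= exp(-x^2/8), x = k*a_e*sin(psi)
    gauss_scale = (k * array.element_radius) ** 2 / 8.0
    for lo in range(0, array.n_elements, chunk):
        hi = min(lo + chunk, array.n_elements)
        dvec = pts[None, :, :] - array.element_positions[lo:hi, None, :]
        r = np.linalg.norm(dvec, axis=2)
        if np.any(r <= 0):
            raise ValueError("field point coincides with an element")
        contrib = array.drive[lo:hi, None] * np.exp(1j * k * r) / r
        if gauss_scale > 0:
            cos_psi = np.einsum("epk,ek->ep", dvec,
                                array.element_normals[lo:hi]) / r
            sin2 = np.clip(1.0 - cos_psi ** 2, 0.0, None)
            contrib = contrib * np.exp(-gauss_scale * sin2)
        if per_element:
            out[lo:hi] = contrib
        else:
            out += contrib.sum(axis=0)
    return out


@dataclass
class SourcePlane:
    """Complex pressure on one z grid plane, the HAS starting condition."""

    p: np.ndarray                # (nx, ny) or (batch, nx, ny) complex
    z_index: int
    z: float
    spacing: tuple[float, float]
    watts: float | None = None


def source_plane(array: TransducerArray, plane_z: float, medium: MediumGrid,
                 watts: float | None = None, c_water: float | None = None,
                 per_element: bool = False) -> SourcePlane:
    """Evaluate the array's free field on the grid plane nearest ``plane_z``.

    The plane must lie between the array surface and the phantom, in the
    homogeneous water bath, where the point-source summation is exact.  When
    ``watts`` is given the plane is scaled so its integrated intensity
    sum(|p|^2/(2*rho*c))*dA equals ``watts``.
    """
    zi = int(round((plane_z - medium.origin[2]) / medium.spacing[2]))
    if not (0 <= zi < medium.shape[2]):
        raise ValueError(f"plane_z {plane_z} outside the grid")
    z = medium.origin[2] + zi * medium.spacing[2]
    if z <= array.element_positions[:, 2].max():
        raise ValueError("source plane intersects the array surface")
    if c_water is None:
        labs = medium.labels[:, :, zi]
        c_water = float(np.median(medium.c[:, :, zi][labs == labs.flat[0]]))
    xs = medium.axis_coords(0)
    ys = medium.axis_coords(1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=1)
    p = field_at_points(array, pts, c_water, per_element=per_element)
    if per_element:
        p = p.reshape(array.n_elements, *X.shape)
    else:
        p = p.reshape(X.shape)
    dA = medium.spacing[0] * medium.spacing[1]
    if watts is not None:
        if watts <= 0:
            raise ValueError("watts must be positive")
        rho_c = (medium.rho[:, :, zi] * medium.c[:, :, zi])
        total = np.sum(np.abs(p) ** 2 / (2.0 * rho_c)) * dA
        if per_element:
            total = float(total)  # power of the summed field is not meaningful
            raise ValueError("power normalization is undefined per element")
        p = p * np.sqrt(watts / total)
        array.total_acoustic_power = float(watts)
    return SourcePlane(p=p, z_index=zi, z=z,
                       spacing=(medium.spacing[0], medium.spacing[1]), watts=watts)


# ---------------------------------------------------------------------------
# HAS marching
# ---------------------------------------------------------------------------

@dataclass
class PressureField:
    """Complex steady-state pressure amplitude per voxel (Pa)."""

    p: np.ndarray
    frequency: float
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]


@dataclass
class QField:
    """Ultrasound power deposition density per voxel (W/m^3)."""

    q: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def total_power(self) -> float:
        return float(self.q.sum()) * self.spacing[0] * self.spacing[1] * self.spacing[2]


def _slab_reference_speed(medium: MediumGrid) -> np.ndarray:
    """c_ref per z slab = sound speed of the dominant compartment there."""
    nz = medium.shape[2]
    c_ref = np.empty(nz)
    for j in range(nz):
        labs = medium.labels[:, :, j]
        vals, counts = np.unique(labs, return_counts=True)
        dom = vals[np.argmax(counts)]
        c_ref[j] = np.median(medium.c[:, :, j][labs == dom])
    return c_ref


def _check_spacing(medium: MediumGrid, frequency: float, mode: str) -> None:
    lam_min = float(medium.c.min()) / frequency
    if max(medium.spacing[0], medium.spacing[1]) > lam_min / 2 + 1e-12:
        msg = (f"lateral spacing {medium.spacing[:2]} exceeds lambda_min/2 "
               f"= {lam_min / 2:.4g} m; angular-spectrum sampling is inadequate")
        if mode == "raise":
            raise ValueError(msg)
        if mode == "warn":
            import warnings
            warnings.warn(msg, stacklevel=3)


def _propagator(nx, ny, dx, dy, kbar, dz):
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, dy)
    k2 = kx[:, None] ** 2 + ky[None, :] ** 2
    kz2 = kbar * kbar - k2
    prop = kz2 > 0
    H = np.zeros((nx, ny), dtype=complex)
    H[prop] = np.exp(1j * dz * (np.sqrt(kz2[prop]) - kbar))
    return H  # evanescent components zeroed


def _march(p0: np.ndarray, medium: MediumGrid, frequency: float, source_index: int,
           stop_index: int, collect: bool, include_transmission: bool = True):
    """Core plane-to-plane forward march.  ``p0`` may carry leading batch axes.

    Returns (volume or None, final_plane, forward_planes_list_if_collect).
    """
    nx, ny, nz = medium.shape
    dx, dy, dz = medium.spacing
    omega = 2.0 * np.pi * frequency
    c_ref = _slab_reference_speed(medium)
    Z = medium.rho * medium.c
    vol = None
    if collect:
        vol = np.zeros(p0.shape[:-2] + (nx, ny, nz), dtype=complex)
        vol[..., source_index] = p0
    p = p0.astype(complex)
    H_cache: dict[float, np.ndarray] = {}
    for j in range(source_index, stop_index):
        cr = c_ref[j + 1]
        kbar = omega / cr
        H = H_cache.get(cr)
        if H is None:
            H = _propagator(nx, ny, dx, dy, kbar, dz)
            H_cache[cr] = H
        if include_transmission:
            t = 2.0 * Z[:, :, j + 1] / (Z[:, :, j] + Z[:, :, j + 1])
            p = p * t
        P = np.fft.fft2(p, axes=(-2, -1))
        p = np.fft.ifft2(P * H, axes=(-2, -1))
        # local absorption and phase-speed deviation of layer j+1
        k0 = kbar
        m = np.exp(-medium.alpha[:, :, j + 1] * dz) \
            * np.exp(1j * k0 * (cr / medium.c[:, :, j + 1] - 1.0) * dz)
        p = p * m
        if collect:
            vol[..., j + 1] = p
    return vol, p


def has_propagate(source: SourcePlane, medium: MediumGrid,
                  frequency: float | None = None, include_reflection: bool = False,
                  spacing_check: str = "raise") -> PressureField:
    """Propagate a source plane through the medium with the hybrid
    angular-spectrum method.

    Per dz step the field is (i) multiplied in the space domain by the local
    attenuation exp(-alpha*dz) and speed-deviation phase
    exp(i*k0*(c_ref/c - 1)*dz), with normal-incidence pressure transmission
    applied at impedance interfaces, and (ii) diffracted in the spatial-
    frequency domain by the exact homogeneous propagator at the slab's
    reference speed, evanescent components zeroed.  With
    ``include_reflection`` a single backward sweep accumulates first-order
    reflections r = (Z2 - Z1)/(Z2 + Z1) generated at z interfaces.
    """
    if frequency is None:
        frequency = medium.frequency
    if source.p.shape[-2:] != medium.shape[:2]:
        raise ValueError(f"source plane shape {source.p.shape[-2:]} does not "
                         f"match grid {medium.shape[:2]}")
    _check_spacing(medium, frequency, spacing_check)
    nz = medium.shape[2]
    vol, _ = _march(source.p, medium, frequency, source.z_index, nz - 1,
                    collect=True)
    if include_reflection:
        _add_first_order_reflection(vol, medium, frequency, source.z_index)
    return PressureField(p=vol, frequency=frequency,
                         spacing=medium.spacing, origin=medium.origin)


def _add_first_order_reflection(vol: np.ndarray, medium: MediumGrid,
                                frequency: float, source_index: int) -> None:
    """Single backward sweep adding first-order interface reflections."""
    nx, ny, nz = medium.shape
    dx, dy, dz = medium.spacing
    omega = 2.0 * np.pi * frequency
    c_ref = _slab_reference_speed(medium)
    Z = medium.rho * medium.c
    b = np.zeros((nx, ny), dtype=complex)
    H_cache: dict[float, np.ndarray] = {}
    fwd = vol.copy()
    for j in range(nz - 2, source_index - 1, -1):
        # backward-propagate b through layer j+1 -> plane j
        cr = c_ref[j + 1]
        kbar = omega / cr
        H = H_cache.get(cr)
        if H is None:
            H = _propagator(nx, ny, dx, dy, kbar, dz)
            H_cache[cr] = H
        m = np.exp(-medium.alpha[:, :, j + 1] * dz) \
            * np.exp(1j * kbar * (cr / medium.c[:, :, j + 1] - 1.0) * dz)
        b = np.fft.ifft2(np.fft.fft2(b * m, axes=(-2, -1)) * H, axes=(-2, -1))
        r = (Z[:, :, j + 1] - Z[:, :, j]) / (Z[:, :, j + 1] + Z[:, :, j])
        b = b + r * fwd[..., j]
        vol[..., j] = vol[..., j] + b


def compute_q(pressure: PressureField, medium: MediumGrid) -> QField:
    """Power deposition density Q = alpha*|p|^2/(rho*c) (all attenuation
    treated as absorption; scattering is not modelled)."""
    if pressure.p.shape != medium.shape:
        raise ValueError("pressure and medium grids do not match")
    q = medium.alpha * np.abs(pressure.p) ** 2 / (medium.rho * medium.c)
    return QField(q=q, spacing=medium.spacing, origin=medium.origin)


# ---------------------------------------------------------------------------
# aberration correction
# ---------------------------------------------------------------------------

def aberration_correct(array: TransducerArray, medium: MediumGrid, focus_point,
                       source_plane_z: float | None = None, chunk: int = 32,
                       return_diagnostics: bool = False):
    """Per-element phase correction maximizing |sum_i p_i(focus)|.

    Each element is simulated alone (zero phase, unit amplitude) through the
    medium; the corrected phase is -arg(p_i(focus)), cancelling the arrival
    phase offsets caused by the heterogeneous path.  Elements whose field is
    numerically zero at the focus are reported and left at zero phase.
    """
    fi = medium.index_of(focus_point)
    if source_plane_z is None:
        source_plane_z = medium.origin[2]
    unit = replace(array, drive=np.ones(array.n_elements, dtype=complex))
    p_focus = np.zeros(array.n_elements, dtype=complex)
    zi = int(round((source_plane_z - medium.origin[2]) / medium.spacing[2]))
    for lo in range(0, array.n_elements, chunk):
        hi = min(lo + chunk, array.n_elements)
        sub = replace(unit,
                      n_elements=hi - lo,
                      element_positions=unit.element_positions[lo:hi],
                      element_normals=unit.element_normals[lo:hi],
                      drive=unit.drive[lo:hi])
        sp = source_plane(sub, source_plane_z, medium, per_element=True)
        _, final = _march(sp.p, medium, array.frequency, zi, fi[2], collect=False)
        p_focus[lo:hi] = final[:, fi[0], fi[1]]
    scale = np.abs(p_focus).max()
    dead = np.abs(p_focus) < 1e-12 * max(scale, 1e-300)
    phases = np.where(dead, 0.0, -np.angle(p_focus))
    if return_diagnostics:
        return phases, {"p_focus": p_focus, "disabled_elements": np.flatnonzero(dead)}
    return phases


# ---------------------------------------------------------------------------
# closed-form oracle and aperture calibration
# ---------------------------------------------------------------------------

def oneil_axial_oracle(roc: float, aperture_diameter: float, frequency: float,
                       c: float, rho: float, z, u0: float = 1.0) -> np.ndarray:
    """O'Neil's closed-form on-axis pressure magnitude of a uniformly
    vibrating spherical-cap source in a lossless homogeneous medium.

    |p(z)| = 2*rho*c*u0 * |A/(A-z)| * |sin(k*(r_e - z)/2)| with
    r_e(z) = sqrt(z^2 + 2*A*(A-z)*(1-cos(theta_max))) the distance from the
    axial point to the bowl rim; the z -> A singularity is removed by its
    finite limit rho*c*u0*k*A*(1-cos(theta_max)) (= rho*c*u0*k*h, h the cap
    depth).  The bowl apex is at z = 0, the focus at z = A = roc.
    """
    a = aperture_diameter / 2.0
    if not (0 < a < roc):
        raise ValueError("need 0 < aperture/2 < roc")
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("z must be positive")
    A = roc
    k = 2.0 * np.pi * frequency / c
    one_minus_cos = 1.0 - np.sqrt(1.0 - (a / A) ** 2)
    delta = A - z
    r_e = np.sqrt(z * z + 2.0 * A * delta * one_minus_cos)
    phase = 0.5 * k * (r_e - z)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = 2.0 * rho * c * u0 * np.abs(A / delta) * np.abs(np.sin(phase))
    limit = rho * c * u0 * k * A * one_minus_cos
    near = np.abs(delta) < 1e-9 * A
    if np.ndim(mag) == 0:
        return float(limit) if near else float(mag)
    mag = np.where(near, limit, mag)
    return mag


def _lateral_fwhm_direct(array: TransducerArray, c: float,
                         half_extent: float = 25e-3, n: int = 2501) -> float:
    """Lateral pressure-amplitude FWHM at the geometric focus from the exact
    free-field summation (homogeneous water path)."""
    fx, fy, fz = array.focus_center
    x = np.linspace(0.0, half_extent, n)
    pts = np.stack([fx + x, np.full(n, fy), np.full(n, fz)], axis=1)
    prof = np.abs(field_at_points(array, pts, c))
    half = prof[0] / 2.0
    below = np.flatnonzero(prof < half)
    if below.size == 0:
        raise ValueError("half maximum not reached within the profile extent")
    j = below[0]
    # linear interpolation between the bracketing samples
    x_half = x[j - 1] + (half - prof[j - 1]) / (prof[j] - prof[j - 1]) * (x[j] - x[j - 1])
    return 2.0 * x_half


def calibrate_aperture(target_lateral_fwhm: float = 2.0e-3,
                       target_axial_fwhm: float | None = None,
                       frequency: float = 1.0e6, roc: float = 0.13,
                       c_water: float = 1482.0, n_elements: int = 256,
                       layout_seed: int | None = None,
                       bracket=(0.02, None)) -> float:
    """Find the aperture diameter whose water-path focal spot matches the
    transducer's specified lateral pressure FWHM (2 mm for the default
    therapy array).

    The search is a deterministic 1D root find on the exact free-field focal
    profile; the axial FWHM, if requested, is reported for information only
    (the geometry has one free parameter).
    """
    if target_lateral_fwhm <= 0:
        raise ValueError("target FWHM must be positive")
    lo, hi = bracket
    if hi is None:
        hi = 1.96 * roc / 2 * 2 * 0.99  # just below the hemisphere limit
        hi = min(hi, 1.98 * roc)

    def f(diam: float) -> float:
        arr = build_array(n_elements, roc, frequency, diam, layout_seed)
        return _lateral_fwhm_direct(arr, c_water) - target_lateral_fwhm

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("no bracketing aperture in the search interval")
    return float(brentq(f, lo, hi, xtol=1e-5))
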