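"""Digital phantoms for focused-ultrasound heating experiments.

A phantom is a voxelized :class:`MediumGrid` holding the acoustic maps the
angular-spectrum beam simulation needs (speed of sound, amplitude attenuation,
density) and the thermal maps the Pennes bioheat solver needs (conductivity,
specific heat, perfusion).  Two experiment geometries are provided: a
homogeneous gelatin block coupled through a water bath, and the same block
with an embedded spherical-cap shell of PVC "skull" of varying thickness.

Coordinate convention: 0-based voxel indices, voxel centers at
``origin + index * spacing``, and the z axis is the ultrasound propagation
axis with the transducer at low z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialProperties",
    "MediumGrid",
    "ShellSpec",
    "GELATIN",
    "PVC_SKULL",
    "WATER",
    "LABEL_WATER",
    "LABEL_GEL",
    "LABEL_SKULL",
    "attenuation_np_per_m",
    "build_homogeneous_phantom",
    "build_skull_phantom",
    "segment_magnitude",
]

LABEL_WATER = 0
LABEL_GEL = 1
LABEL_SKULL = 2


@dataclass(frozen=True)
class MaterialProperties:
    """Acoustic and thermal properties of one compartment.

    Attenuation is stored in the tabular unit Np/(cm*MHz) and converted to
    Np/m at the operating frequency when a grid is built.  Thermal fields may
    be None, in which case the builder substitutes the gelatin values (heating
    is only evaluated in gel; water/PVC thermal behaviour is not modelled
    distinctly).
    """

    c: float                      # speed of sound, m/s
    attenuation: float            # amplitude attenuation, Np/(cm*MHz)
    rho: float                    # density, kg/m^3
    c_t: float | None = None      # specific heat, J/(kg*degC)
    k_th: float | None = None     # thermal conductivity, W/(m*degC)
    w_perf: float = 0.0           # Pennes perfusion, kg/(m^3*s)


# 250-bloom gelatin, PVC skull and water-bath tabular values.
GELATIN = MaterialProperties(c=1553.0, attenuation=0.06, rho=1057.0,
                             c_t=3635.0, k_th=0.55, w_perf=0.0)
PVC_SKULL = MaterialProperties(c=2376.0, attenuation=1.50, rho=1200.0)
WATER = MaterialProperties(c=1482.0, attenuation=0.0, rho=1000.0)


def attenuation_np_per_m(att_np_per_cm_mhz: float, frequency_hz: float) -> float:
    """Convert tabular Np/(cm*MHz) attenuation to Np/m at ``frequency_hz``."""
    return att_np_per_cm_mhz * (frequency_hz / 1e6) * 100.0


@dataclass
class MediumGrid:
    """Voxelized 3D property maps on a regular grid.

    All property arrays share ``shape``; spacing/origin are in meters.
    ``labels`` assigns each voxel to exactly one compartment
    (0 water / 1 gelatin / 2 skull).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    c: np.ndarray
    alpha: np.ndarray            # amplitude attenuation, Np/m at frequency
    rho: np.ndarray
    k_th: np.ndarray
    c_t: np.ndarray
    w_perf: np.ndarray
    labels: np.ndarray
    c_b: float = 3600.0          # blood specific heat, J/(kg*degC)
    t_blood: float = 0.0         # arterial blood temperature rise, degC
    frequency: float = 1.0e6     # frequency alpha was evaluated at, Hz

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if any(d <= 0 for d in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        for name in ("c", "alpha", "rho", "k_th", "c_t", "w_perf", "labels"):
            arr = getattr(self, name)
            if arr.shape != self.shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {self.shape}")
        if np.any(self.c <= 0) or np.any(self.rho <= 0) or np.any(self.c_t <= 0):
            raise ValueError("c, rho and c_t must be strictly positive")
        if np.any(self.alpha < 0) or np.any(self.k_th < 0) or np.any(self.w_perf < 0):
            raise ValueError("alpha, k_th and w_perf must be non-negative")

    # -- geometry helpers -------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center physical coordinates along one axis (m)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_of(self, point) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point (m)."""
        idx = tuple(
            int(round((point[a] - self.origin[a]) / self.spacing[a])) for a in range(3)
        )
        for a in range(3):
            if not (0 <= idx[a] < self.shape[a]):
                raise ValueError(f"point {point} outside grid on axis {a}")
        return idx

    @property
    def rho_ct(self) -> np.ndarray:
        """Volumetric heat capacity rho*C_t, J/(m^3*degC)."""
        return self.rho * self.c_t

    def impedance(self) -> np.ndarray:
        """Acoustic impedance Z = rho*c per voxel (Rayl)."""
        return self.rho * self.c


def _thermal_defaults(props: MaterialProperties, reference: MaterialProperties,
                      rho: float) -> tuple[float, float]:
    """Return (c_t, k_th) for ``props``; missing values fall back so that
    rho*c_t and k match the reference (gelatin) compartment."""
    if reference.c_t is None or reference.k_th is None:
        reference = GELATIN
    ref_rho_ct = reference.rho * reference.c_t
    c_t = props.c_t if props.c_t is not None else ref_rho_ct / rho
    k_th = props.k_th if props.k_th is not None else reference.k_th
    return c_t, k_th


def _grid_from_labels(shape, spacing, origin, labels, materials: dict[int, MaterialProperties],
                      frequency: float, thermal_reference: MaterialProperties) -> MediumGrid:
    shape = tuple(int(n) for n in shape)
    c = np.empty(shape)
    alpha = np.empty(shape)
    rho = np.empty(shape)
    k_th = np.empty(shape)
    c_t = np.empty(shape)
    w = np.empty(shape)
    for lab, props in materials.items():
        m = labels == lab
        c[m] = props.c
        alpha[m] = attenuation_np_per_m(props.attenuation, frequency)
        rho[m] = props.rho
        ct_v, kth_v = _thermal_defaults(props, thermal_reference, props.rho)
        c_t[m] = ct_v
        k_th[m] = kth_v
        w[m] = props.w_perf
    return MediumGrid(shape=shape, spacing=tuple(float(s) for s in spacing),
                      origin=tuple(float(o) for o in origin),
                      c=c, alpha=alpha, rho=rho, k_th=k_th, c_t=c_t, w_perf=w,
                      labels=labels.astype(np.int8), frequency=frequency)


def build_homogeneous_phantom(shape, spacing, gel_props: MaterialProperties = GELATIN,
                              water_props: MaterialProperties = WATER,
                              gel_z_extent: tuple[float, float] | float = 0.06,
                              origin=(0.0, 0.0, 0.0),
                              frequency: float = 1.0e6) -> MediumGrid:
    """Homogeneous gelatin block coupled through a water bath.

    ``gel_z_extent`` is either the z coordinate (m) of the water/gel interface
    (gel occupies everything above it, i.e. away from the transducer) or a
    (z_lo, z_hi) pair bounding the gel slab.  Voxels whose centers fall inside
    the extent are gelatin; the remainder is water.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape) or any(d <= 0 for d in spacing):
        raise ValueError("shape and spacing must be strictly positive")
    z = origin[2] + np.arange(shape[2]) * spacing[2]
    if np.isscalar(gel_z_extent):
        z_lo, z_hi = float(gel_z_extent), np.inf
    else:
        z_lo, z_hi = map(float, gel_z_extent)
    if z_lo >= z[-1] + spacing[2] / 2 or z_hi <= z[0] - spacing[2] / 2:
        raise ValueError(f"gel_z_extent {gel_z_extent} lies outside the grid "
                         f"z range [{z[0]:.4g}, {z[-1]:.4g}] m")
    gel_planes = (z >= z_lo) & (z < z_hi)
    labels = np.full(shape, LABEL_WATER, dtype=np.int8)
    labels[:, :, gel_planes] = LABEL_GEL
    return _grid_from_labels(shape, spacing, origin, labels,
                             {LABEL_WATER: water_props, LABEL_GEL: gel_props},
                             frequency, thermal_reference=gel_props)


@dataclass(frozen=True)
class ShellSpec:
    """Spherical-cap shell of varying thickness embedded in the gel.

    The shell is a piece of a sphere centered at ``center`` (typically the
    intended focus, so the therapy beam crosses it near normal incidence).
    Inner radius ``inner_radius``; local thickness varies between
    ``t_min`` and ``t_max`` as a smooth deterministic function of polar angle
    theta (from the -z beam axis) and azimuth phi, emulating the varying
    thickness of a plastic skull.  Only the cap with theta <= ``half_angle``
    is materialized.
    """

    center: tuple[float, float, float]
    inner_radius: float
    t_min: float
    t_max: float
    half_angle: float = np.deg2rad(50.0)

    def thickness(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")
        frac = 0.5 * np.clip(theta / self.half_angle, 0.0, 1.0) \
            + 0.25 * (1.0 + np.sin(2.0 * phi))
        return self.t_min + (self.t_max - self.t_min) * np.clip(frac, 0.0, 1.0)


def build_skull_phantom(shape, spacing, gel_props: MaterialProperties = GELATIN,
                        skull_props: MaterialProperties = PVC_SKULL,
                        shell_spec: ShellSpec | None = None,
                        water_props: MaterialProperties = WATER,
                        gel_z_extent: tuple[float, float] | float = 0.06,
                        origin=(0.0, 0.0, 0.0),
                        frequency: float = 1.0e6) -> MediumGrid:
    """Gelatin phantom with an embedded PVC skull-shell.

    Degenerate shells (t_min == t_max == 0) reproduce the homogeneous phantom.
    """
    grid = build_homogeneous_phantom(shape, spacing, gel_props, water_props,
                                     gel_z_extent, origin, frequency)
    if shell_spec is None or (shell_spec.t_min == 0 and shell_spec.t_max == 0):
        return grid
    if shell_spec.t_min > shell_spec.t_max:
        raise ValueError("t_min must not exceed t_max")
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    cx, cy, cz = shell_spec.center
    dx, dy, dz = xs - cx, ys - cy, zs - cz
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore"):
        # polar angle measured from the -z direction (toward the transducer)
        theta = np.arccos(np.clip(-dz / np.maximum(r, 1e-30), -1.0, 1.0))
    phi = np.arctan2(dy, dx) + np.zeros_like(r)
    t = shell_spec.thickness(theta, phi)
    shell = (r >= shell_spec.inner_radius) & (r <= shell_spec.inner_radius + t) \
        & (theta <= shell_spec.half_angle)
    if shell.any():
        idx = np.argwhere(shell)
        edge = ((idx == 0).any() or
                (idx[:, 0] == shape[0] - 1).any() or
                (idx[:, 1] == shape[1] - 1).any() or
                (idx[:, 2] == shape[2] - 1).any())
        if edge:
            raise ValueError("skull shell protrudes outside the grid")
    # shell must sit inside the gel, not in the water bath
    shell &= grid.labels == LABEL_GEL
    labels = grid.labels.copy()
    labels[shell] = LABEL_SKULL
    return _grid_from_labels(shape, spacing, origin, labels,
                             {LABEL_WATER: water_props, LABEL_GEL: gel_props,
                              LABEL_SKULL: skull_props},
                             frequency, thermal_reference=gel_props)


def segment_magnitude(volume: np.ndarray, thresholds) -> np.ndarray:
    """Threshold a magnitude volume into compartment labels.

    ``thresholds`` must be strictly increasing; voxels are assigned the index
    of the intensity bin they fall in (label i for
    thresholds[i-1] <= v < thresholds[i]), giving len(thresholds)+1 labels.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1D sequence")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    volume = np.asarray(volume)
    if np.any(volume < 0):
        raise ValueError("magnitude volume must be non-negative")
    return np.digitize(volume, thresholds).astype(np.int8)
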