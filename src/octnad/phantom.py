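"""Synthetic SS-OCT phantoms with known attenuation fields and ground truth.

The forward model is single-scattering Beer-Lambert decay: along each
A-line the intensity below the sample surface is

    I(z) = I0 * exp(-2 * integral of mu over the path from the surface to z)

with the factor 2 for the round trip of the probe light.  The attenuation
field ``mu`` is piecewise constant per voxel, so the optical path is an
exact cumulative sum and a windowed log-linear fit recovers ``mu`` to
machine precision on noiseless homogeneous segments.  Speckle is modelled
as independent per-voxel multiplicative unit-mean exponential factors
(fully developed speckle after square-law detection); an optional additive
noise floor fills the region above the surface as well.

Every phantom carries its analytic ground truth (attenuation field,
surface height, en-face inclusion boundary radius per depth) so each
downstream stage can be validated without real specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .octio import OCTVolume, ValidationError


@dataclass
class Surface:
    """Smooth surface height z(x, y) in µm from the top of the window.

    z(x, y) = z0 + slope_x * x_um + slope_y * y_um
              + bump_amp * exp(-((x-cx)^2 + (y-cy)^2) / (2 * bump_sigma^2))
    """

    z0_um: float = 0.0
    slope_x: float = 0.0  # µm depth per µm lateral
    slope_y: float = 0.0
    bump_amp_um: float = 0.0
    bump_sigma_um: float = 1.0
    bump_center_um: tuple[float, float] = (0.0, 0.0)

    def __call__(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        z = self.z0_um + self.slope_x * x_um + self.slope_y * y_um
        if self.bump_amp_um != 0.0:
            cx, cy = self.bump_center_um
            r2 = (x_um - cx) ** 2 + (y_um - cy) ** 2
            z = z + self.bump_amp_um * np.exp(-r2 / (2.0 * self.bump_sigma_um**2))
        return np.asarray(z, dtype=float)


@dataclass
class Inclusion:
    """A region of distinct attenuation embedded below the surface.

    ``center`` is (x_um, y_um, z_below_surface_um); depth is measured from
    the local surface so inclusions follow surface topography, matching
    how en-face maps are extracted at constant depth below the surface.
    """

    shape: Literal["ellipsoid", "cylinder", "slab"]
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]  # (a_x, a_y, c_z) µm; slab uses c_z
    mu: float  # mm^-1

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("inclusion semi-axes must be positive")
        if self.mu < 0:
            raise ValidationError("inclusion mu must be >= 0")

    def boundary_radius_um(self, depth_um: float) -> float:
        """Analytic en-face boundary radius at a depth below the surface.

        For an ellipsoid with lateral semi-axis a and axial semi-axis c
        centred z_c below the surface, radius(d) = a*sqrt(1-((d-z_c)/c)^2)
        where the root is real; NaN where the inclusion has no cross
        section.  Cylinders and slabs are constant over their axial span.
        """
        ax, ay, cz = self.semi_axes
        a = 0.5 * (ax + ay)
        zc = self.center[2]
        if self.shape == "ellipsoid":
            t = (depth_um - zc) / cz
            if abs(t) > 1.0:
                return float("nan")
            return a * float(np.sqrt(1.0 - t * t))
        if self.shape == "cylinder":
            return a if abs(depth_um - zc) <= cz else float("nan")
        return float("nan")  # slabs have no closed lateral boundary

    def contains(
        self,
        x_um: np.ndarray,
        y_um: np.ndarray,
        depth_um: np.ndarray,
    ) -> np.ndarray:
        """Boolean membership on broadcastable (x, y, depth-below-surface)."""
        ax, ay, cz = self.semi_axes
        cx, cy, zc = self.center
        if self.shape == "ellipsoid":
            return (
                ((x_um - cx) / ax) ** 2
                + ((y_um - cy) / ay) ** 2
                + ((depth_um - zc) / cz) ** 2
            ) <= 1.0
        if self.shape == "cylinder":
            lateral = ((x_um - cx) / ax) ** 2 + ((y_um - cy) / ay) ** 2 <= 1.0
            return lateral & (np.abs(depth_um - zc) <= cz)
        # slab: a horizontal band at constant depth below the surface
        return np.abs(depth_um - zc) <= cz


@dataclass
class NoiseSpec:
    """Speckle and noise-floor model.

    ``speckle`` multiplies each voxel by an independent unit-mean
    exponential draw; ``floor`` adds a constant-scale non-negative offset
    (exponential with the given mean) everywhere, including above the
    surface.
    """

    kind: Literal["none", "speckle"] = "speckle"
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValidationError("noise floor must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry, optics and noise defining a synthetic volume."""

    nz: int
    nx: int
    ny: int
    dz_um: float = 9.375
    dx_um: float = 30.0
    dy_um: float = 30.0
    surface: Surface = field(default_factory=Surface)
    mu_background: float = 2.0  # mm^-1
    inclusions: list[Inclusion] = field(default_factory=list)
    i0: float = 1.0
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(kind="none"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_background < 0:
            raise ValidationError("mu_background must be >= 0")
        z = self.surface(*self._lateral_grids())
        if z.min() < 0 or z.max() >= self.nz * self.dz_um:
            raise ValidationError("surface must lie inside the axial window")

    def _lateral_grids(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.arange(self.nx, dtype=float)[:, None] * self.dx_um
        y = np.arange(self.ny, dtype=float)[None, :] * self.dy_um
        return x, y


@dataclass
class GroundTruth:
    """Analytic truth accompanying a rendered phantom."""

    mu_field: np.ndarray  # (nz, nx, ny) mm^-1, 0 above surface
    surface_z_um: np.ndarray  # (nx, ny)
    surface_index: np.ndarray  # (nx, ny) int, first voxel at/below surface
    spec: PhantomSpec

    def boundary_radius_um(self, depth_um: float, inclusion: int = 0) -> float:
        return self.spec.inclusions[inclusion].boundary_radius_um(depth_um)


def build_mu_field(spec: PhantomSpec) -> GroundTruth:
    """Voxelize the attenuation field of a phantom.

    Background attenuation everywhere below the surface, inclusion values
    inside each inclusion (later inclusions override earlier ones), zero
    above the surface.
    """
    x_um, y_um = spec._lateral_grids()
    surface_z = spec.surface(x_um, y_um)  # (nx, ny)
    z_um = np.arange(spec.nz, dtype=float)[:, None, None] * spec.dz_um
    depth = z_um - surface_z[None, :, :]  # depth below local surface
    below = depth >= 0.0

    mu = np.where(below, spec.mu_background, 0.0)
    for inc in spec.inclusions:
        inside = inc.contains(x_um[None], y_um[None], depth) & below
        if not inside.any():
            warnings.warn(
                f"inclusion {inc.shape} at {inc.center} lies entirely outside "
                "the sampled volume below the surface",
                stacklevel=2,
            )
        mu = np.where(inside, inc.mu, mu)

    surface_index = np.ceil(surface_z / spec.dz_um - 1e-9).astype(int)
    return GroundTruth(
        mu_field=mu.astype(np.float64),
        surface_z_um=surface_z,
        surface_index=surface_index,
        spec=spec,
    )


def render_volume(
    spec: PhantomSpec, truth: Optional[GroundTruth] = None
) -> OCTVolume:
    """Render a phantom to an intensity volume; deterministic given seed.

    Below the surface the noiseless signal is
    ``i0 * exp(-2 * dz * cumulative-sum of mu down to the previous voxel)``
    (in mm), so the first in-tissue voxel carries ``i0`` exactly; above the
    surface the signal is zero.  Speckle multiplies, the noise floor adds.
    """
    if truth is None:
        truth = build_mu_field(spec)
    mu = truth.mu_field  # mm^-1
    dz_mm = spec.dz_um / 1000.0
    # optical path to voxel k excludes voxel k itself: exact on homogeneous
    # segments, exactly invertible by an OLS fit of ln I vs z
    path = np.cumsum(mu, axis=0) * dz_mm
    path = np.concatenate([np.zeros_like(path[:1]), path[:-1]], axis=0)
    # mu may be 0 below the surface (mu_background=0), so the below-surface
    # mask comes from geometry, not the mu field
    z_um = np.arange(spec.nz, dtype=float)[:, None, None] * spec.dz_um
    below = z_um >= truth.surface_z_um[None, :, :]

    signal = np.where(below, spec.i0 * np.exp(-2.0 * path), 0.0)

    rng = np.random.default_rng(spec.seed)
    if spec.noise.kind == "speckle":
        signal = signal * rng.exponential(1.0, size=signal.shape)
    if spec.noise.floor > 0:
        signal = signal + rng.exponential(spec.noise.floor, size=signal.shape)

    return OCTVolume(
        intensity=signal,
        dz=spec.dz_um,
        dx=spec.dx_um,
        dy=spec.dy_um,
        log_domain=False,
    )


# ---------------------------------------------------------------------------
# presets


def glioma_preset(small: bool = True, seed: int = 7) -> PhantomSpec:
    """A glioma-specimen-like phantom at test scale.

    A flat-ish surface, strongly attenuating background (brain-like,
    2 mm^-1), one ellipsoidal low-attenuation tumor (1 mm^-1, so the tumor
    signal decays more slowly than normal tissue), one thin high-attenuation
    slab emulating the corpus-callosum band (4 mm^-1), speckle on.  The
    axial spacing is 9.375 µm so a 40-pixel fit window spans 375 µm.

    ``small=True`` returns a <=128^3 grid for fast test runs.
    """
    if small:
        nx = ny = 96
        nz = 160
        dx = dy = 40.0
    else:
        nx = ny = 192
        nz = 256
        dx = dy = 22.5
    extent_x = nx * dx
    tumor = Inclusion(
        shape="ellipsoid",
        center=(0.42 * extent_x, 0.45 * extent_x, 350.0),
        semi_axes=(1000.0, 1000.0, 600.0),
        mu=1.0,
    )
    callosum = Inclusion(
        shape="slab",
        center=(0.0, 0.0, 1050.0),
        semi_axes=(1.0, 1.0, 50.0),  # 100 µm thick band
        mu=4.0,
    )
    return PhantomSpec(
        nz=nz,
        nx=nx,
        ny=ny,
        dz_um=9.375,
        dx_um=dx,
        dy_um=dy,
        surface=Surface(z0_um=150.0, slope_x=0.005),
        mu_background=2.0,
        inclusions=[tumor, callosum],
        i0=1.0,
        noise=NoiseSpec(kind="speckle", floor=0.0),
        seed=seed,
    )


def homogeneous_preset(
    mu: float,
    n: int = 128,
    noise: str = "none",
    seed: int = 0,
    surface_z_um: float = 75.0,
) -> PhantomSpec:
    """Homogeneous half-space phantom, flat surface, n^3 grid."""
    return PhantomSpec(
        nz=n,
        nx=n,
        ny=n,
        dz_um=9.375,
        dx_um=30.0,
        dy_um=30.0,
        surface=Surface(z0_um=surface_z_um),
        mu_background=mu,
        noise=NoiseSpec(kind=noise),  # type: ignore[arg-type]
        seed=seed,
    )


def cylinder_preset(
    radius_um: float = 300.0,
    mu_inside: float = 1.0,
    mu_outside: float = 2.0,
    seed: int = 11,
    noise: str = "speckle",
) -> PhantomSpec:
    """Vertical low-attenuation cylinder in a homogeneous background.

    The cylinder spans all depths, so its en-face boundary radius is
    constant: the oracle for boundary-localization checks.
    """
    nx = ny = 96
    nz = 160
    dx = dy = 25.0
    extent = nx * dx
    cyl = Inclusion(
        shape="cylinder",
        center=(0.5 * extent, 0.5 * extent, 750.0),
        semi_axes=(radius_um, radius_um, 750.0),
        mu=mu_inside,
    )
    return PhantomSpec(
        nz=nz,
        nx=nx,
        ny=ny,
        dz_um=9.375,
        dx_um=dx,
        dy_um=dy,
        surface=Surface(z0_um=75.0),
        mu_background=mu_outside,
        inclusions=[cyl],
        noise=NoiseSpec(kind=noise),  # type: ignore[arg-type]
        seed=seed,
    )


def ellipsoid_preset(
    a_um: float = 1150.0,
    c_um: float = 900.0,
    center_depth_um: float = 450.0,
    mu_inside: float = 1.0,
    mu_outside: float = 2.0,
    seed: int = 13,
    noise: str = "speckle",
) -> PhantomSpec:
    """Single low-attenuation ellipsoid: the tumor-geometry oracle.

    Sized so the lower hemisphere spans many fit-window depths: the
    en-face boundary radius shrinks by several lateral pixels per 100 µm
    of depth, well above the ridge-localization noise.
    """
    nx = ny = 160
    nz = 200
    dx = dy = 20.0
    extent = nx * dx
    tumor = Inclusion(
        shape="ellipsoid",
        center=(0.5 * extent, 0.5 * extent, center_depth_um),
        semi_axes=(a_um, a_um, c_um),
        mu=mu_inside,
    )
    return PhantomSpec(
        nz=nz,
        nx=nx,
        ny=ny,
        dz_um=9.375,
        dx_um=dx,
        dy_um=dy,
        surface=Surface(z0_um=75.0),
        mu_background=mu_outside,
        inclusions=[tumor],
        noise=NoiseSpec(kind=noise),  # type: ignore[arg-type]
        seed=seed,
    )
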