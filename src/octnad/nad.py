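"""Normalized-absolute-difference (NAD) mapping.

Each en-face OAC map is min-max normalized against a fixed tumor ROI --
NOAC(x, y) = (OAC(x, y) - min_ROI) / (max_ROI - min_ROI) -- so the tumor
region spans [0, 1] at every depth regardless of the depth-wise loss of
signal.  Values outside the ROI may leave [0, 1] and are deliberately not
clipped: clipping would erase gradients at bright structures such as the
corpus-callosum band.  After Gaussian low-pass filtering in x and y, the
nearest-neighbour differences ΔNOAC_x and ΔNOAC_y are combined pointwise
into NAD = sqrt(ΔNOAC_x² + ΔNOAC_y²), which is large wherever the
attenuation changes abruptly -- i.e. at tissue boundaries.  Stacking NAD
maps over depth yields the volumetric margin map.

The two difference fields live on staggered half-pixel grids; NAD is
assembled on the shared (nx-1) x (ny-1) corner grid by pairing
Δx(i, j) with Δy(i, j), so NAD pixel (i, j) sits at en-face position
(i + 1/2, j + 1/2) in map pixels.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .oac import OACMap, enface_oac_map
from .octio import EnfaceROI, OCTVolume, PipelineConfig, ValidationError


class DegenerateNormalizationError(ValueError):
    """ROI min equals ROI max (or ROI fully masked); Eq.-style min-max
    normalization is undefined."""


@dataclass
class NOACMap:
    """ROI-normalized en-face OAC map (dimensionless)."""

    value: np.ndarray  # (nx, ny), NaN = missing
    depth_um: float
    roi: EnfaceROI
    min_roi: float  # mm^-1
    max_roi: float  # mm^-1

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.value)


@dataclass
class NADMap:
    """Gradient-magnitude map on the (nx-1) x (ny-1) corner grid."""

    value: np.ndarray  # >= 0, NaN = missing
    depth_um: float

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.value)


@dataclass
class NADVolume:
    """Stack of NAD maps over an increasing depth axis, with provenance."""

    maps: list[NADMap]
    roi: EnfaceROI
    config_hash: str
    roi_minmax: list[tuple[float, float]]  # (min_roi, max_roi) per depth

    def __post_init__(self) -> None:
        depths = self.depths_um
        if np.any(np.diff(depths) <= 0):
            raise ValidationError("depth axis must be strictly increasing")
        shapes = {m.value.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValidationError("all NAD maps must share extents")

    @property
    def depths_um(self) -> np.ndarray:
        return np.array([m.depth_um for m in self.maps])

    def as_array(self) -> np.ndarray:
        """(ndepth, nx-1, ny-1) stack."""
        return np.stack([m.value for m in self.maps])


def normalize_map(oac_map: OACMap, roi: EnfaceROI) -> NOACMap:
    """Min-max normalize an OAC map against its ROI.

    value = (OAC - min_ROI) / (max_ROI - min_ROI); within the ROI the
    unmasked output spans exactly [0, 1], outside it values may exceed
    that range.
    """
    roi.check_within(*oac_map.value.shape)
    sx, sy = roi.slices()
    roi_vals = oac_map.value[sx, sy]
    finite = roi_vals[np.isfinite(roi_vals)]
    if finite.size < 4:
        raise DegenerateNormalizationError(
            f"ROI has only {finite.size} unmasked pixels (need >= 4)"
        )
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise DegenerateNormalizationError(
            f"ROI min equals ROI max ({lo} mm^-1); cannot normalize"
        )
    return NOACMap(
        value=(oac_map.value - lo) / (hi - lo),
        depth_um=oac_map.depth_um,
        roi=roi,
        min_roi=lo,
        max_roi=hi,
    )


def lowpass_filter(noac_map: NOACMap, sigma_px: float) -> NOACMap:
    """Separable Gaussian smoothing in x and y; sigma 0 is the identity.

    Missing pixels are excluded by normalized convolution: the kernel
    weights are renormalized over the unmasked support, and originally
    missing pixels stay missing.
    """
    if sigma_px < 0:
        raise ValidationError("sigma_px must be >= 0")
    if sigma_px == 0:
        smoothed = noac_map.value.copy()
    else:
        ok = np.isfinite(noac_map.value)
        filled = np.where(ok, noac_map.value, 0.0)
        num = ndimage.gaussian_filter(filled, sigma=sigma_px, mode="constant")
        den = ndimage.gaussian_filter(ok.astype(float), sigma=sigma_px, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(ok & (den > 0), num / den, np.nan)
    return NOACMap(
        value=smoothed,
        depth_um=noac_map.depth_um,
        roi=noac_map.roi,
        min_roi=noac_map.min_roi,
        max_roi=noac_map.max_roi,
    )


def directional_differences(noac_map: NOACMap) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour NOAC differences along x and y.

    ΔNOAC_x(i, j) = NOAC(i+1, j) - NOAC(i, j) and analogously in y, both
    cropped to the common (nx-1) x (ny-1) corner grid.  A difference
    touching a missing pixel is missing.
    """
    v = noac_map.value
    nx, ny = v.shape
    if nx < 2 or ny < 2:
        raise ValidationError("need at least 2 pixels along each axis")
    dx = (v[1:, :] - v[:-1, :])[:, : ny - 1]
    dy = (v[:, 1:] - v[:, :-1])[: nx - 1, :]
    return dx, dy


def nad_map(dx: np.ndarray, dy: np.ndarray, depth_um: float = float("nan")) -> NADMap:
    """Pointwise RMS of the two directional differences.

    NAD(i, j) = sqrt(ΔNOAC_x(i, j)² + ΔNOAC_y(i, j)²); missing wherever
    either input is missing.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValidationError(f"shape mismatch: {dx.shape} vs {dy.shape}")
    return NADMap(value=np.sqrt(dx * dx + dy * dy), depth_um=depth_um)


def _config_hash(cfg: PipelineConfig, roi: EnfaceROI) -> str:
    payload = json.dumps(
        {"config": cfg.model_dump(), "roi": roi.model_dump()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def nad_volume(
    volume: OCTVolume,
    roi: EnfaceROI,
    depths_um: Optional[Sequence[float]] = None,
    config: Optional[PipelineConfig] = None,
) -> NADVolume:
    """Full per-depth pipeline: OAC map -> normalize -> filter -> NAD.

    ``volume`` must be flattened.  When ``depths_um`` is omitted, every
    window-start index from the surface down to the deepest depth where at
    least half the map is unmasked is used.  A depth whose OAC map is
    fully masked yields a fully masked NAD slice with a warning rather
    than a hard failure.
    """
    cfg = config or PipelineConfig()
    roi.check_within(volume.nx, volume.ny)
    if depths_um is None:
        depths_um = _default_depths(volume, cfg)
    depths_um = list(depths_um)
    if not depths_um or np.any(np.diff(depths_um) <= 0):
        raise ValidationError("depths_um must be non-empty and strictly increasing")

    maps: list[NADMap] = []
    minmax: list[tuple[float, float]] = []
    shape = (volume.nx - 1, volume.ny - 1)
    for d in depths_um:
        oac = enface_oac_map(volume, d, cfg)
        if not np.isfinite(oac.value).any():
            warnings.warn(f"depth {d} µm fully masked; NAD slice masked", stacklevel=2)
            maps.append(NADMap(value=np.full(shape, np.nan), depth_um=oac.depth_um))
            minmax.append((float("nan"), float("nan")))
            continue
        noac = normalize_map(oac, roi)
        noac = lowpass_filter(noac, cfg.lowpass_sigma_px)
        dx, dy = directional_differences(noac)
        maps.append(nad_map(dx, dy, depth_um=oac.depth_um))
        minmax.append((noac.min_roi, noac.max_roi))
    return NADVolume(
        maps=maps, roi=roi, config_hash=_config_hash(cfg, roi), roi_minmax=minmax
    )


def _default_depths(volume: OCTVolume, cfg: PipelineConfig) -> list[float]:
    """Window-start depths from the surface to the last mostly-valid one."""
    w = cfg.fit_window_px
    aline_len = np.isfinite(volume.intensity).sum(axis=0)  # valid run per A-line
    depths = []
    for k0 in range(volume.nz - w + 1):
        frac = (aline_len >= k0 + w).mean()
        if frac < 0.5:
            break
        depths.append(k0 * volume.dz)
    return depths


# ---------------------------------------------------------------------------
# boundary extraction (convenience; the maps themselves are the product)


def extract_boundary(
    nadm: NADMap,
    method: Literal["threshold", "ridge"] = "threshold",
    level: float = 0.95,
    seed_px: Optional[tuple[float, float]] = None,
    n_angles: int = 180,
) -> np.ndarray:
    """Binary boundary mask from a NAD map.

    ``threshold``: pixels at or above the ``level`` quantile of unmasked
    values.  ``ridge``: per-radial-ray argmax from ``seed_px``
    (en-face pixel coordinates of the presumed inclusion centre).
    A convenience for downstream consumers, not a validated segmentation.
    """
    v = nadm.value
    ok = np.isfinite(v)
    mask = np.zeros(v.shape, dtype=bool)
    if not ok.any():
        warnings.warn("NAD map fully masked; empty boundary", stacklevel=2)
        return mask
    if method == "threshold":
        vals = v[ok]
        if np.all(vals == 0):
            warnings.warn("NAD map is identically zero; empty boundary", stacklevel=2)
            return mask
        thr = np.quantile(vals, level)
        if thr <= 0:
            thr = np.nextafter(0.0, 1.0)
        mask[ok] = v[ok] >= thr
        return mask
    if method == "ridge":
        if seed_px is None:
            raise ValidationError("ridge method requires seed_px")
        radii, angles = ridge_radii(nadm, seed_px, n_angles=n_angles)
        good = np.isfinite(radii)
        ii = np.round(seed_px[0] - 0.5 + radii[good] * np.cos(angles[good])).astype(int)
        jj = np.round(seed_px[1] - 0.5 + radii[good] * np.sin(angles[good])).astype(int)
        keep = (ii >= 0) & (ii < v.shape[0]) & (jj >= 0) & (jj < v.shape[1])
        mask[ii[keep], jj[keep]] = True
        if not mask.any():
            warnings.warn("ridge produced an empty boundary", stacklevel=2)
        return mask
    raise ValidationError(f"unknown method {method!r}")


def ridge_radii(
    nadm: NADMap,
    center_px: tuple[float, float],
    n_angles: int = 180,
    r_max_px: Optional[float] = None,
    dr_px: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius of maximal NAD along radial rays from a centre.

    ``center_px`` is in en-face map pixels; NAD corner-grid pixel (i, j)
    sits at map position (i + 1/2, j + 1/2), which the sampling accounts
    for.  Returns (radii_px, angles_rad); a ray whose samples are all
    missing yields NaN.
    """
    v = nadm.value
    cx = center_px[0] - 0.5  # corner-grid coordinates
    cy = center_px[1] - 0.5
    if r_max_px is None:
        r_max_px = min(
            cx, cy, v.shape[0] - 1 - cx, v.shape[1] - 1 - cy
        )
    r = np.arange(dr_px, r_max_px, dr_px)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    xi = cx + r[None, :] * np.cos(angles[:, None])
    yj = cy + r[None, :] * np.sin(angles[:, None])
    # missing pixels get a large negative sentinel so interpolation never
    # produces NaN and argmax never lands on a masked sample
    sentinel = -1e30
    filled = np.where(np.isfinite(v), v, sentinel)
    samples = ndimage.map_coordinates(
        filled, [xi, yj], order=1, mode="constant", cval=sentinel
    )
    best = np.argmax(samples, axis=1)
    radii = r[best]
    bad = samples[np.arange(n_angles), best] <= sentinel * 1e-2
    radii = radii.astype(float)
    radii[bad] = np.nan
    return radii, angles


def ridge_radius_um(
    nadm: NADMap,
    center_px: tuple[float, float],
    dx_um: float,
    n_angles: int = 180,
) -> float:
    """Ridge radius in µm: the median over rays.

    The median is robust to the occasional ray whose argmax locks onto a
    residual speckle blob instead of the boundary ring (assumes isotropic
    lateral spacing).
    """
    radii, _ = ridge_radii(nadm, center_px, n_angles=n_angles)
    good = np.isfinite(radii)
    if not good.any():
        return float("nan")
    return float(np.median(radii[good]) * dx_um)
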