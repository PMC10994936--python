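"""Sample-surface detection and depth-below-surface re-indexing.

The surface on each A-line is taken as the position of the greatest axial
intensity variation: the argmax of the first forward difference of the
axially smoothed log-compressed profile.  Intensities are normalized by
the volume maximum before log compression, which makes detection exactly
invariant to a global positive rescaling of the data; the prominence
criterion is relative to each A-line's own axial variability and is
therefore scale-free as well.

A-lines whose strongest edge is not prominent enough are marked invalid
and stay masked downstream -- holes are never interpolated away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .octio import OCTVolume, ValidationError


class SurfaceDetectionError(RuntimeError):
    """No A-line produced a usable surface."""


@dataclass
class SurfaceMap:
    """Per-(x, y) axial index of the sample surface."""

    z_index: np.ndarray  # (nx, ny) int
    valid: np.ndarray  # (nx, ny) bool

    def __post_init__(self) -> None:
        if self.z_index.shape != self.valid.shape:
            raise ValidationError("z_index and valid must share shape")

    @property
    def nx(self) -> int:
        return self.z_index.shape[0]

    @property
    def ny(self) -> int:
        return self.z_index.shape[1]

    def to_csv(self, path) -> None:
        out = np.where(self.valid, self.z_index, -1)
        np.savetxt(path, out, delimiter=",", fmt="%d")

    def to_png(self, path) -> None:
        """16-bit heightmap; invalid pixels = 65535."""
        from PIL import Image

        img = np.where(self.valid, self.z_index, 65535).astype(np.uint16)
        Image.fromarray(img.T, mode="I;16").save(path)


def detect_surface(
    volume: OCTVolume,
    axial_presmooth_px: int = 3,
    lateral_presmooth_px: int = 3,
    min_prominence: Optional[float] = None,
    median_regularize: bool = True,
) -> SurfaceMap:
    """Locate the surface on every A-line of a linear-domain volume.

    Parameters
    ----------
    axial_presmooth_px : int
        Width of the axial boxcar applied to the log-compressed profile
        before differencing (1 = none).
    lateral_presmooth_px : int
        Width of the lateral (x and y) boxcar applied alongside -- the
        same speckle-suppression-by-neighbour-averaging idea the OAC
        stage uses.  1 disables it; use 1 for strictly per-A-line
        detection on noiseless data.
    min_prominence : float, optional
        Minimum value of the winning forward difference for an A-line to
        count as detected.  Default: 5x that A-line's median absolute
        axial difference, a scale-free threshold.
    median_regularize : bool
        Apply a 3x3 median filter over the detected indices (valid pixels
        only) to suppress isolated speckle-driven outliers.
    """
    if volume.log_domain:
        raise ValidationError("detect_surface expects a linear-domain volume")
    inten = volume.intensity
    # normalize by a scale-equivariant statistic so detection is exactly
    # invariant to global positive rescaling; the mean (not the max) keeps
    # log1p genuinely compressive against speckle spikes
    scale = np.nanmean(inten)
    if not np.isfinite(scale) or scale <= 0:
        raise SurfaceDetectionError("volume carries no signal")
    prof = np.log1p(inten / scale)
    if axial_presmooth_px > 1:
        prof = ndimage.uniform_filter1d(
            prof, size=axial_presmooth_px, axis=0, mode="nearest"
        )
    if lateral_presmooth_px > 1:
        prof = ndimage.uniform_filter(
            prof, size=(1, lateral_presmooth_px, lateral_presmooth_px),
            mode="nearest",
        )
    diff = np.diff(prof, axis=0)  # (nz-1, nx, ny)

    # argmax returns the first (shallowest) maximiser; the physical surface
    # is the first large rise
    z_index = np.argmax(diff, axis=0) + 1  # edge between k and k+1 -> k+1
    best = np.take_along_axis(diff, (z_index - 1)[None], axis=0)[0]

    if min_prominence is None:
        mad = np.median(np.abs(diff), axis=0)
        thresh = 5.0 * mad
    else:
        thresh = np.full(best.shape, float(min_prominence))
    valid = best > np.maximum(thresh, 0.0)
    if not valid.any():
        raise SurfaceDetectionError("surface not detected on any A-line")

    if median_regularize and valid.sum() > 1:
        filled = np.where(valid, z_index, int(np.median(z_index[valid])))
        z_index = ndimage.median_filter(filled, size=3, mode="nearest")

    return SurfaceMap(z_index=z_index.astype(int), valid=valid)


def flatten(volume: OCTVolume, surface: SurfaceMap) -> OCTVolume:
    """Shift each A-line so its surface sits at output index 0.

    Samples shifted beyond the axial window become NaN; invalid A-lines
    are fully masked.  Every non-masked output sample equals exactly one
    input sample (a per-A-line shift, no resampling).
    """
    if surface.z_index.shape != volume.intensity.shape[1:]:
        raise ValidationError("surface map does not match volume extents")
    if surface.valid.mean() < 0.5:
        raise ValidationError(
            "surface invalid on more than half the A-lines; refusing to flatten"
        )
    nz, nx, ny = volume.shape
    out = np.full((nz, nx, ny), np.nan, dtype=float)
    z = np.arange(nz)[:, None, None]
    src = z + surface.z_index[None, :, :]
    ok = (src < nz) & surface.valid[None, :, :]
    src_c = np.clip(src, 0, nz - 1)
    gathered = np.take_along_axis(volume.intensity.astype(float), src_c, axis=0)
    out[ok] = gathered[ok]
    return OCTVolume(
        intensity=out,
        dz=volume.dz,
        dx=volume.dx,
        dy=volume.dy,
        log_domain=volume.log_domain,
    )
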