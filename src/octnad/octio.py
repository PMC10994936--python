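"""Volume and map I/O with physical metadata, plus pipeline configuration.

An OCT volume is stored as a non-negative scalar field indexed ``(z, x, y)``:
``z`` runs along the A-line (index 0 = shallowest sample of the acquisition
window), ``x`` across A-lines within a B-scan, ``y`` across B-scan frames.
All spacings are in micrometres, in tissue.  On disk a volume is a multi-page
TIFF (one page per B-scan frame, page rows = z, page cols = x) or a raw
binary blob, either accompanied by a JSON sidecar carrying dtype, extents
and voxel spacing.

Missing samples anywhere in the pipeline are carried as NaN, never
interpolated away.
"""

from __future__ import annotations

import json

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class FormatError(ValueError):
    """File contents inconsistent with the declared layout."""


class ValidationError(ValueError):
    """Metadata or configuration violates an invariant."""


# ---------------------------------------------------------------------------
# volume container


@dataclass
class OCTVolume:
    """3-D OCT intensity volume with voxel spacing.

    Parameters
    ----------
    intensity : ndarray, shape (nz, nx, ny)
        Linear-domain intensity (>= 0) or log-intensity depending on
        ``log_domain``.  NaN marks missing samples (e.g. after flattening).
    dz, dx, dy : float
        Voxel spacing in micrometres; ``dz`` is the axial spacing in tissue.
    log_domain : bool
        True when values are log-intensity.
    """

    intensity: np.ndarray
    dz: float
    dx: float
    dy: float
    log_domain: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValidationError(
                f"intensity must be 3-D (z, x, y), got ndim={self.intensity.ndim}"
            )
        if min(self.intensity.shape) < 1:
            raise ValidationError("all extents must be >= 1")
        for name, v in (("dz", self.dz), ("dx", self.dx), ("dy", self.dy)):
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if not self.log_domain:
            finite = self.intensity[np.isfinite(self.intensity)]
            if finite.size and finite.min() < 0:
                raise ValidationError("linear-domain intensity must be non-negative")

    @property
    def nz(self) -> int:
        return self.intensity.shape[0]

    @property
    def nx(self) -> int:
        return self.intensity.shape[1]

    @property
    def ny(self) -> int:
        return self.intensity.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def z_um(self) -> np.ndarray:
        """Axial coordinate of each sample, micrometres from index 0."""
        return np.arange(self.nz, dtype=float) * self.dz


# ---------------------------------------------------------------------------
# configuration


class EnfaceROI(BaseModel):
    """Inclusive rectangular region in en-face (x, y) pixel coordinates.

    Mirrors the fixed red-box tumor region against which every depth's
    OAC map is normalized.
    """

    x0: int = Field(ge=0)
    x1: int = Field(ge=0)
    y0: int = Field(ge=0)
    y1: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered_and_big_enough(self) -> "EnfaceROI":
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError("ROI bounds must satisfy x0 <= x1 and y0 <= y1")
        if (self.x1 - self.x0 + 1) * (self.y1 - self.y0 + 1) < 4:
            raise ValueError("ROI area must be at least 4 pixels")
        return self

    def check_within(self, nx: int, ny: int) -> None:
        if self.x1 >= nx or self.y1 >= ny:
            raise ValidationError(
                f"ROI {self} exceeds en-face extents ({nx}, {ny})"
            )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.x0, self.x1 + 1), slice(self.y0, self.y1 + 1)


class PipelineConfig(BaseModel):
    """Parameters of the OAC/NAD pipeline.

    Defaults: a 40-pixel depth fit window and
    lateral averaging of ~20 A-lines per B-scan (21 here, the nearest odd
    width, so the window has a centre; set 20 for the literal, left-biased
    variant).
    """

    lateral_avg_width: int = Field(default=21, ge=1)
    fit_window_px: int = Field(default=40, ge=3)
    lowpass_sigma_px: float = Field(default=2.0, ge=0.0)
    roi: Optional[EnfaceROI] = None
    depths_um: list[float] = Field(default_factory=list)
    refractive_index: float = Field(default=1.0, gt=0.0)
    axial_presmooth_px: int = Field(default=3, ge=1)

    @field_validator("depths_um")
    @classmethod
    def _depths_nonneg(cls, v: list[float]) -> list[float]:
        if any(d < 0 for d in v):
            raise ValueError("depths_um must be non-negative")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration.

    An empty document yields all defaults.  Raises a validation error
    naming the offending field otherwise.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config root must be a mapping, got {type(data)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# volume I/O

_SIDECAR_KEYS = ("dtype", "nz", "nx", "ny", "dz_um", "dx_um", "dy_um")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    Pages are B-scan frames (y), page rows z, page cols x.
    """
    path = Path(path)
    pages = np.ascontiguousarray(np.moveaxis(volume.intensity, 2, 0))
    tifffile.imwrite(
        path,
        pages.astype(np.float32, copy=False),
        photometric="minisblack",
        planarconfig="contig",
    )
    meta = {
        "dtype": "float32",
        "nz": volume.nz,
        "nx": volume.nx,
        "ny": volume.ny,
        "dz_um": volume.dz,
        "dx_um": volume.dx,
        "dy_um": volume.dy,
        "log_domain": volume.log_domain,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(
    path: str | Path,
    spacing_override: Optional[tuple[float, float, float]] = None,
    refractive_index: float = 1.0,
) -> OCTVolume:
    """Read a volume from multi-page TIFF or raw binary + JSON sidecar.

    Parameters
    ----------
    spacing_override : (dz, dx, dy) in µm, optional
        Overrides sidecar spacings.
    refractive_index : float
        Sidecar axial spacing is treated as air-path and divided by this
        to obtain in-tissue spacing (default 1.0 = no conversion).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            pages = tifffile.imread(path)
        except Exception as exc:  # corrupt file
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        intensity = np.moveaxis(pages, 0, 2)  # (z, x, y)
    else:
        if not meta:
            raise FormatError(f"raw binary volume {path} requires a JSON sidecar")
        missing = [k for k in _SIDECAR_KEYS if k not in meta]
        if missing:
            raise FormatError(f"sidecar {sidecar} missing keys: {missing}")
        dtype = np.dtype(meta["dtype"])
        nz, nx, ny = int(meta["nz"]), int(meta["nx"]), int(meta["ny"])
        expected = nz * nx * ny * dtype.itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise FormatError(
                f"{path}: file size {actual} != {expected} for "
                f"{nz}x{nx}x{ny} {dtype}"
            )
        flat = np.fromfile(path, dtype=dtype)
        intensity = np.moveaxis(flat.reshape(ny, nz, nx), 0, 2)

    if meta:
        for k in ("nz", "nx", "ny"):
            if k in meta and int(meta[k]) != intensity.shape[("nz", "nx", "ny").index(k)]:
                raise FormatError(
                    f"sidecar extent {k}={meta[k]} inconsistent with file "
                    f"shape {intensity.shape}"
                )
    dz = float(meta.get("dz_um", 1.0))
    dx = float(meta.get("dx_um", 1.0))
    dy = float(meta.get("dy_um", 1.0))
    if spacing_override is not None:
        dz, dx, dy = map(float, spacing_override)
    else:
        dz = dz / refractive_index
    log_domain = bool(meta.get("log_domain", False))
    return OCTVolume(intensity=intensity, dz=dz, dx=dx, dy=dy, log_domain=log_domain)


# ---------------------------------------------------------------------------
# 2-D map export


def write_map(
    map2d: np.ndarray,
    path: str | Path,
    colormap: str = "viridis",
    vmin: Optional[float] = None,
    vmax: Optional[float] = None,
) -> None:
    """Export an en-face map losslessly (CSV) and as an 8-bit PNG render.

    ``path`` is the stem; ``<stem>.csv`` holds the raw values (NaN for
    missing) and ``<stem>.png`` an 8-bit colormapped render with missing
    pixels transparent.  The render clips the display range to
    [vmin, vmax] when given; the CSV always preserves raw values so no
    test or downstream step ever reads numbers off a picture.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import colormaps, colors

    map2d = np.asarray(map2d, dtype=float)
    if map2d.ndim != 2:
        raise ValidationError("write_map expects a 2-D array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path.with_suffix(".csv"), map2d, delimiter=",", fmt="%.17g")

    finite = np.isfinite(map2d)
    lo = vmin if vmin is not None else (map2d[finite].min() if finite.any() else 0.0)
    hi = vmax if vmax is not None else (map2d[finite].max() if finite.any() else 1.0)
    if hi <= lo:
        hi = lo + 1.0
    norm = colors.Normalize(vmin=lo, vmax=hi, clip=True)
    rgba = colormaps[colormap](norm(np.where(finite, map2d, lo)))
    rgba[..., 3] = np.where(finite, 1.0, 0.0)
    # en-face maps are indexed (x, y); render with y as image rows
    img = (rgba.transpose(1, 0, 2) * 255).astype(np.uint8)
    from PIL import Image

    Image.fromarray(img, mode="RGBA").save(path.with_suffix(".png"))


def read_map_csv(path: str | Path) -> np.ndarray:
    """Read back a map written by :func:`write_map` (lossless CSV)."""
    return np.atleast_2d(np.loadtxt(Path(path), delimiter=","))
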