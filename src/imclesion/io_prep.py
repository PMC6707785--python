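"""Image reconstruction, cleanup and limit-of-detection normalization.

The preprocessing chain mirrors how raw ion-count acquisitions become
analysis-ready channels: shots are laid out line scan by line scan into a
pixel grid, a region of interest is outlined (with gray matter excluded),
single-pixel speckle artifacts are removed by a gray-level morphological
opening, and every channel is scaled by its limit-of-detection reference

    I_zs = I / (mu + 3 * sigma)

where mu and sigma are the mean and population standard deviation of the
in-mask pixel intensities. A channel at its detection limit therefore maps
to ~1.0, making positivity thresholds comparable across markers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon
from skimage.morphology import opening, disk, footprint_rectangle

from .image import LineScanStack, MultichannelImage

__all__ = [
    "ROIAnnotation",
    "NormalizationStats",
    "DespeckleConfig",
    "reconstruct_image",
    "despeckle_channel",
    "normalize_channel",
    "apply_roi_mask",
    "read_multichannel_tiff",
    "write_multichannel_tiff",
    "read_panel_config",
    "read_linescan_text",
    "read_roi_json",
    "write_roi_json",
]

#: Lesion-stage vocabulary (control white matter through mixed-lesion core).
LESION_STAGES = (
    "WMC",
    "NAWM",
    "PPWM",
    "preactive",
    "active_center",
    "mixed_edge",
    "mixed_core",
)


@dataclass
class ROIAnnotation:
    """Polygonal region of interest with a lesion-stage label.

    Vertices are (x=column, y=row) pixel coordinates. ``excluded_polygons``
    carves out sub-regions (typically gray matter) from the analysis mask.
    """

    polygon: list[tuple[float, float]]
    lesion_stage: str
    excluded_polygons: list[list[tuple[float, float]]] = field(default_factory=list)
    name: str = "ROI"

    def __post_init__(self) -> None:
        if self.lesion_stage not in LESION_STAGES:
            raise ValueError(
                f"unknown lesion stage {self.lesion_stage!r}; expected one of {LESION_STAGES}"
            )
        poly = Polygon(self.polygon)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("ROI polygon must be simple with positive area")

    def shapely_polygon(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class NormalizationStats:
    """Limit-of-detection statistics for one marker channel."""

    marker: str
    mu: float
    sigma: float
    denom: float
    n_pixels: int
    degenerate: bool = False


@dataclass
class DespeckleConfig:
    """Structuring element for the speckle-removal opening filter.

    ``kernel_shape`` is "disk" (radius-1 disk = 4-connected cross, the
    default) or "square" (a (2r+1)² box).
    """

    kernel_radius: int = 1
    kernel_shape: str = "disk"

    def footprint(self) -> np.ndarray:
        if self.kernel_radius < 1:
            raise ValueError("kernel_radius must be >= 1")
        if self.kernel_shape == "disk":
            return disk(self.kernel_radius)
        if self.kernel_shape == "square":
            n = 2 * self.kernel_radius + 1
            return footprint_rectangle((n, n))
        raise ValueError(f"unknown kernel_shape {self.kernel_shape!r}")


def reconstruct_image(
    stack: LineScanStack,
    markers: list[str],
    pixel_size_um: float = 1.0,
    *,
    pad_policy: str = "zero",
) -> MultichannelImage:
    """Lay out laser shots into pixel grids, line scan by line scan.

    Shot ``i`` of each channel becomes pixel ``(i // row_width,
    i % row_width)`` — row-major order, exactly the order the signals were
    recorded.

    Parameters
    ----------
    pad_policy
        "zero" pads a truncated final line with zeros (with a warning);
        "strict" raises instead.
    """
    if len(markers) != stack.n_channels:
        raise ValueError(
            f"marker list has {len(markers)} names but stack has "
            f"{stack.n_channels} channels per shot"
        )
    values = stack.values
    n, w = stack.n_shots, stack.row_width
    rem = n % w
    if rem != 0:
        if pad_policy == "strict":
            raise ValueError(
                f"{n} shots is not a multiple of row_width {w} (strict mode)"
            )
        if pad_policy != "zero":
            raise ValueError(f"unknown pad_policy {pad_policy!r}")
        warnings.warn(
            f"final line truncated ({rem}/{w} shots); padding with zeros",
            stacklevel=2,
        )
        pad = np.zeros((w - rem, stack.n_channels))
        values = np.vstack([values, pad])
    height = values.shape[0] // w
    channels = {
        name: values[:, j].reshape(height, w).copy()
        for j, name in enumerate(markers)
    }
    return MultichannelImage(channels, pixel_size_um=pixel_size_um)


def despeckle_channel(channel: np.ndarray, cfg: DespeckleConfig | None = None) -> np.ndarray:
    """Remove single-pixel speckle by gray-level morphological opening.

    Opening (erosion then dilation) deletes bright features smaller than
    the structuring element while leaving larger structures' interiors
    untouched; the result is pixelwise <= the input.
    """
    cfg = cfg or DespeckleConfig()
    channel = np.asarray(channel, dtype=np.float64)
    if np.any(channel < 0):
        raise ValueError("channel must be non-negative")
    fp = cfg.footprint()
    if fp.shape[0] > channel.shape[0] or fp.shape[1] > channel.shape[1]:
        raise ValueError(
            f"structuring element {fp.shape} larger than image {channel.shape}"
        )
    return opening(channel, footprint=fp)


def normalize_channel(
    channel: np.ndarray,
    mask: np.ndarray,
    marker: str = "",
) -> tuple[np.ndarray, NormalizationStats]:
    """Scale a channel by its limit-of-detection reference mu + 3*sigma.

    mu and sigma are the mean and *population* standard deviation of the
    pixels inside ``mask`` (the channel is treated as the full population
    of shots, not a sample). Out-of-mask pixels are zeroed. An all-zero
    channel cannot define a detection limit; it is returned as zeros with
    ``stats.degenerate`` set so gating treats it as uniformly negative.
    """
    channel = np.asarray(channel, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    vals = channel[mask]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (ddof=0)
    denom = mu + 3.0 * sigma
    out = np.zeros_like(channel)
    if denom == 0.0:
        stats = NormalizationStats(marker, mu, sigma, denom, int(mask.sum()), degenerate=True)
        return out, stats
    out[mask] = channel[mask] / denom
    stats = NormalizationStats(marker, mu, sigma, denom, int(mask.sum()))
    return out, stats


def normalize_image(
    image: MultichannelImage, mask: np.ndarray
) -> tuple[MultichannelImage, dict[str, NormalizationStats]]:
    """Apply :func:`normalize_channel` to every channel of an image."""
    channels: dict[str, np.ndarray] = {}
    stats: dict[str, NormalizationStats] = {}
    for name, chan in image.channels.items():
        channels[name], stats[name] = normalize_channel(chan, mask, marker=name)
    return MultichannelImage(channels, pixel_size_um=image.pixel_size_um), stats


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers fall inside ``poly`` (center-in convention)."""
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return shapely.contains_xy(poly, cols.ravel(), rows.ravel()).reshape(shape)


def apply_roi_mask(
    image: MultichannelImage, roi: ROIAnnotation
) -> tuple[MultichannelImage, np.ndarray, float]:
    """Mask an image to the ROI polygon minus its exclusion polygons.

    Returns the masked image (out-of-mask pixels zeroed), the boolean
    mask, and the mask area in mm². A pixel belongs to the mask when its
    center (col + 0 offset: integer indices are the centers) lies inside
    the ROI polygon and outside every exclusion polygon.
    """
    poly = roi.shapely_polygon()
    h, w = image.shape
    frame = Polygon([(-0.5, -0.5), (w - 0.5, -0.5), (w - 0.5, h - 0.5), (-0.5, h - 0.5)])
    if not frame.contains(poly):
        warnings.warn("ROI polygon extends beyond image bounds; clipping", stacklevel=2)
    mask = _rasterize(poly, image.shape)
    for excl in roi.excluded_polygons:
        epoly = Polygon(excl)
        if epoly.area <= 0:
            raise ValueError("degenerate exclusion polygon (zero area)")
        mask &= ~_rasterize(epoly, image.shape)
    if not mask.any():
        raise ValueError("ROI mask is empty after rasterization/exclusion")
    area_mm2 = float(mask.sum()) * image.pixel_size_um**2 / 1e6
    masked = MultichannelImage(
        {k: np.where(mask, v, 0.0) for k, v in image.channels.items()},
        pixel_size_um=image.pixel_size_um,
    )
    return masked, mask, area_mm2


# ---------------------------------------------------------------------------
# file formats


def write_multichannel_tiff(image: MultichannelImage, path: str | Path) -> None:
    """Write one 32-bit float page per marker, names in page metadata."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, chan in image.channels.items():
            meta = json.dumps({"marker": name, "pixel_size_um": image.pixel_size_um})
            tif.write(chan.astype(np.float32), description=meta, photometric="minisblack")


def read_multichannel_tiff(path: str | Path) -> MultichannelImage:
    """Read a multi-page float TIFF back into a :class:`MultichannelImage`."""
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    pixel_size = 1.0
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = f"channel_{i}"
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    name = meta["marker"]
                    pixel_size = float(meta.get("pixel_size_um", pixel_size))
                except (json.JSONDecodeError, KeyError, TypeError):
                    warnings.warn(
                        f"page {i} of {path.name} lacks marker metadata; "
                        f"using positional name {name!r}",
                        stacklevel=2,
                    )
            else:
                warnings.warn(
                    f"page {i} of {path.name} has no description tag; "
                    f"using positional name {name!r}",
                    stacklevel=2,
                )
            channels[name] = page.asarray().astype(np.float64)
    return MultichannelImage(channels, pixel_size_um=pixel_size)


def read_linescan_text(path: str | Path, row_width: int) -> tuple[LineScanStack, list[str]]:
    """Parse a delimited text export: header of marker names, one row per shot."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed line-scan export {path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise ValueError(f"malformed row at line {bad} of {path}")
    markers = [str(c) for c in df.columns]
    return LineScanStack(df.to_numpy(dtype=np.float64), row_width=row_width), markers


def read_roi_json(path: str | Path) -> list[ROIAnnotation]:
    with open(path) as fh:
        data = json.load(fh)
    rois = data["rois"] if isinstance(data, dict) else data
    return [
        ROIAnnotation(
            polygon=[tuple(v) for v in r["polygon"]],
            lesion_stage=r["lesion_stage"],
            excluded_polygons=[[tuple(v) for v in p] for p in r.get("excluded_polygons", [])],
            name=r.get("name", f"ROI_{i}"),
        )
        for i, r in enumerate(rois)
    ]


def write_roi_json(rois: list[ROIAnnotation], path: str | Path) -> None:
    payload = {
        "rois": [
            {
                "name": r.name,
                "lesion_stage": r.lesion_stage,
                "polygon": [list(v) for v in r.polygon],
                "excluded_polygons": [[list(v) for v in p] for p in r.excluded_polygons],
            }
            for r in rois
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_panel_config(path: str | Path) -> dict:
    """Load the panel/pipeline YAML: marker list, gate thresholds, despeckle
    and segmentation parameters. Returns a plain dict; typed configs are
    constructed by the modules that consume each section."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "markers" not in cfg:
        raise ValueError(f"panel config {path} must define a 'markers' list")
    markers = cfg["markers"]
    if len(markers) != len(set(markers)):
        raise ValueError("panel config contains duplicate marker names")
    return cfg
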