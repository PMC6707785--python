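"""Cell-density and cell-to-vessel distance morphometry.

Two descriptive summaries per region of interest: the density of every
phenotype class (cells/mm² of analysis mask), and each class's mean
distance to the nearest collagen+ perivascular region. Vessel candidates
are connected collagen-positive components; only regions *strictly*
exceeding 10 µm equivalent diameter and 800 µm² area count as vessels
(smaller fragments are collagen debris, not perfused vessels). Distance is
measured from the cell centroid to the nearest pixel of the retained
regions' border; cells inside a region score 0. A class absent from an ROI
has no mean distance — those entries are n/a, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "VesselFilterConfig",
    "VesselMap",
    "detect_vessels",
    "cell_vessel_distances",
    "density_matrix",
    "distance_matrix",
    "render_heatmaps",
    "export_matrix",
]


@dataclass
class VesselFilterConfig:
    """Collagen positivity and the two strict size filters."""

    collagen_threshold: float = 0.5  # normalized intensity
    min_equivalent_diameter_um: float = 10.0
    min_area_um2: float = 800.0
    diameter_definition: str = "equivalent"  # or "min_feret"

    def __post_init__(self) -> None:
        if self.collagen_threshold <= 0:
            raise ValueError("collagen_threshold must be > 0")
        if self.diameter_definition not in ("equivalent", "min_feret"):
            raise ValueError(f"unknown diameter definition {self.diameter_definition!r}")


@dataclass
class VesselMap:
    """Retained perivascular regions: union mask plus per-region geometry."""

    mask: np.ndarray
    regions: pd.DataFrame  # region_id, area_um2, equivalent_diameter_um
    pixel_size_um: float


def detect_vessels(
    collagen: np.ndarray,
    cfg: VesselFilterConfig | None = None,
    pixel_size_um: float = 1.0,
) -> VesselMap:
    """Segment collagen+ perivascular regions and apply the size filters.

    Threshold -> 8-connected components -> per-component area (px count x
    pixel area) and equivalent circular diameter 2*sqrt(area/pi) -> keep
    components with diameter > 10 µm AND area > 800 µm² (both strict).
    No retained region is a valid outcome.
    """
    cfg = cfg or VesselFilterConfig()
    binary = np.asarray(collagen, dtype=float) >= cfg.collagen_threshold
    labels = cc_label(binary, connectivity=2)
    mask = np.zeros(binary.shape, dtype=bool)
    rows = []
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size_um**2
        eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
        if cfg.diameter_definition == "min_feret":
            # minor-axis length of the fitted ellipse approximates min-Feret
            diam = prop.axis_minor_length * pixel_size_um
        else:
            diam = eq_diam
        if area_um2 > cfg.min_area_um2 and diam > cfg.min_equivalent_diameter_um:
            mask |= labels == prop.label
            rows.append(
                {
                    "region_id": prop.label,
                    "area_um2": float(area_um2),
                    "equivalent_diameter_um": float(eq_diam),
                }
            )
    regions = pd.DataFrame(rows, columns=["region_id", "area_um2", "equivalent_diameter_um"])
    return VesselMap(mask=mask, regions=regions, pixel_size_um=pixel_size_um)


def vessel_border(mask: np.ndarray) -> np.ndarray:
    """Pixels of the vessel mask adjacent to non-vessel tissue."""
    if not mask.any():
        return np.zeros_like(mask)
    return mask & ~binary_erosion(mask, border_value=1)


def cell_vessel_distances(
    cells: pd.DataFrame,
    vessels: VesselMap,
    *,
    reference: str = "centroid",
) -> pd.DataFrame:
    """Append per-cell Euclidean distance (µm) to the nearest vessel border.

    Cells whose centroid lies inside a retained region get 0. With no
    retained vessel in frame the distance is undefined: NaN with
    ``vessel_distance_defined`` False, and such cells are excluded from
    class means downstream.
    """
    if reference != "centroid":
        raise NotImplementedError("only centroid reference is implemented")
    out = cells.copy()
    n = len(cells)
    if not vessels.mask.any():
        out["distance_to_vessel_um"] = np.nan
        out["vessel_distance_defined"] = False
        return out
    border = vessel_border(vessels.mask)
    coords = np.argwhere(border)  # (row, col)
    tree = cKDTree(coords)
    cy = cells["y_px"].to_numpy(dtype=float)
    cx = cells["x_px"].to_numpy(dtype=float)
    dist_px, _ = tree.query(np.column_stack([cy, cx]))
    h, w = vessels.mask.shape
    ri = np.clip(np.rint(cy).astype(int), 0, h - 1)
    ci = np.clip(np.rint(cx).astype(int), 0, w - 1)
    inside = vessels.mask[ri, ci]
    dist_um = dist_px * vessels.pixel_size_um
    dist_um[inside] = 0.0
    out["distance_to_vessel_um"] = dist_um
    out["vessel_distance_defined"] = True
    return out


def density_matrix(
    cells: pd.DataFrame,
    roi_areas_mm2: dict[str, float],
    class_names: list[str] | None = None,
    *,
    roi_column: str = "roi",
) -> pd.DataFrame:
    """Cells per mm² for every (class, ROI) pair.

    ``cells`` must carry ``cell_class`` and an ROI assignment column;
    classes absent from an ROI get density 0 (a zero density is data —
    the n/a convention applies to distances only).
    """
    for roi, area in roi_areas_mm2.items():
        if area <= 0:
            raise ValueError(f"ROI {roi!r} has non-positive area")
    unknown_roi = set(cells[roi_column]) - set(roi_areas_mm2)
    if unknown_roi:
        raise ValueError(f"cells assigned to ROIs with no area: {sorted(unknown_roi)}")
    counts = cells.groupby([roi_column, "cell_class"]).size()
    classes = class_names or sorted(cells["cell_class"].unique())
    rois = list(roi_areas_mm2)
    data = {
        roi: [
            counts.get((roi, cls), 0) / roi_areas_mm2[roi] for cls in classes
        ]
        for roi in rois
    }
    return pd.DataFrame(data, index=pd.Index(classes, name="cell_class"))


def distance_matrix(
    cells: pd.DataFrame,
    class_names: list[str] | None = None,
    *,
    roi_column: str = "roi",
) -> pd.DataFrame:
    """Mean vessel distance (µm) per class per ROI; NaN marks n/a.

    Cells with undefined distances (no retained vessel in their ROI) are
    excluded; a (class, ROI) pair with zero contributing cells is NaN,
    serialized as the literal "n/a" by :func:`export_matrix`.
    """
    usable = cells
    if "vessel_distance_defined" in cells.columns:
        usable = cells[cells["vessel_distance_defined"]]
    classes = class_names or sorted(cells["cell_class"].unique())
    rois = sorted(cells[roi_column].unique())
    means = usable.groupby([roi_column, "cell_class"])["distance_to_vessel_um"].mean()
    data = {
        roi: [means.get((roi, cls), np.nan) for cls in classes] for roi in rois
    }
    return pd.DataFrame(data, index=pd.Index(classes, name="cell_class"))


def export_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a class × ROI matrix as TSV, NaN entries as literal 'n/a'."""
    matrix.to_csv(path, sep="\t", na_rep="n/a")


def render_heatmaps(
    density: pd.DataFrame,
    distance: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Render the two class × ROI heat maps to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mat, fmt, cbar in (
        ("density_heatmap.png", density, ".1f", "cells / mm²"),
        ("distance_heatmap.png", distance, ".0f", "mean distance to vessel (µm)"),
    ):
        fig, ax = plt.subplots(
            figsize=(2 + 1.1 * mat.shape[1], 1 + 0.4 * mat.shape[0])
        )
        sns.heatmap(mat, annot=True, fmt=fmt, cmap="viridis",
                    cbar_kws={"label": cbar}, ax=ax)
        ax.set_xlabel("region of interest")
        fig.tight_layout()
        p = out / name
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
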