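"""End-to-end quantification of one ROI.

Chains the stages in their canonical order: outline the ROI (gray matter
excluded) -> despeckle every channel -> limit-of-detection normalization
over the analysis mask -> DNA-guided segmentation with marker refinement
-> hierarchical gating -> vessel detection and per-cell distances ->
density and distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import GateConfig, ClassRuleSet, classify_cells, load_rules
from .image import MultichannelImage
from .io_prep import (
    DespeckleConfig,
    NormalizationStats,
    ROIAnnotation,
    apply_roi_mask,
    despeckle_channel,
    normalize_image,
)
from .morphometry import (
    VesselFilterConfig,
    VesselMap,
    cell_vessel_distances,
    density_matrix,
    detect_vessels,
    distance_matrix,
)
from .segmentation import SegmentationParams, segment_and_measure

__all__ = ["ROIResult", "preprocess_roi", "quantify_roi", "summarize_rois"]


@dataclass
class ROIResult:
    """Everything computed for one ROI."""

    cells: pd.DataFrame
    area_mm2: float
    mask: np.ndarray
    norm_stats: dict[str, NormalizationStats]
    vessels: VesselMap
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    normalized: MultichannelImage
    despeckled: MultichannelImage


def preprocess_roi(
    image: MultichannelImage,
    roi: ROIAnnotation,
    despeckle_cfg: DespeckleConfig | None = None,
) -> tuple[MultichannelImage, MultichannelImage, np.ndarray, float, dict[str, NormalizationStats]]:
    """Mask -> despeckle -> normalize. Returns (despeckled, normalized,
    mask, area_mm2, per-channel stats)."""
    despeckle_cfg = despeckle_cfg or DespeckleConfig()
    masked, mask, area_mm2 = apply_roi_mask(image, roi)
    despeckled = MultichannelImage(
        {m: despeckle_channel(chan, despeckle_cfg) for m, chan in masked.channels.items()},
        pixel_size_um=image.pixel_size_um,
    )
    normalized, stats = normalize_image(despeckled, mask)
    return despeckled, normalized, mask, area_mm2, stats


def quantify_roi(
    image: MultichannelImage,
    roi: ROIAnnotation,
    gates: GateConfig,
    *,
    seg_params: SegmentationParams | None = None,
    vessel_cfg: VesselFilterConfig | None = None,
    despeckle_cfg: DespeckleConfig | None = None,
    rules: ClassRuleSet | None = None,
) -> ROIResult:
    """Run the full single-ROI pipeline and return the classified table."""
    rules = rules or load_rules()
    seg_params = seg_params or SegmentationParams()
    despeckled, normalized, mask, area_mm2, stats = preprocess_roi(
        image, roi, despeckle_cfg
    )
    cells, nuclei, cell_labels = segment_and_measure(despeckled, normalized, seg_params)
    cells = classify_cells(
        cells, gates, rules, min_nucleus_area_px=seg_params.min_nucleus_area_px
    )
    vcfg = vessel_cfg or VesselFilterConfig(collagen_threshold=gates.threshold("Collagen"))
    vessels = detect_vessels(normalized["Collagen"], vcfg, image.pixel_size_um)
    cells = cell_vessel_distances(cells, vessels)
    cells["roi"] = roi.name
    cells["lesion_stage"] = roi.lesion_stage
    return ROIResult(
        cells=cells,
        area_mm2=area_mm2,
        mask=mask,
        norm_stats=stats,
        vessels=vessels,
        nucleus_labels=nuclei,
        cell_labels=cell_labels,
        normalized=normalized,
        despeckled=despeckled,
    )


def summarize_rois(
    results: dict[str, ROIResult],
    class_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-ROI tables into the density and distance matrices."""
    cells = pd.concat([r.cells for r in results.values()], ignore_index=True)
    areas = {name: r.area_mm2 for name, r in results.items()}
    density = density_matrix(cells, areas, class_names)
    distance = distance_matrix(cells, class_names)
    return density, distance
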