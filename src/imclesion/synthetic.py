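"""Synthetic multiplexed scenes with known ground truth.

Real acquisitions of staged demyelinating lesions are not publicly
deposited, so every downstream stage is exercised on simulated tissue:
a DNA-intercalator channel of nucleated cells, class-specific marker
expression following the shipped phenotype table (including the two-level
CD45 and HLA gates), collagen+/CD31+ vessel tubes, lesion-stage-dependent
class composition and ambient myelin, Poisson shot noise, and isolated
single-pixel speckle artifacts.

The model is deliberately simple where the detector physics does not
matter for testing the pipeline: each cell draws one log-normal expression
level per marker (cell-to-cell variation) and paints it uniformly over its
footprint; Poisson resampling then adds per-pixel shot noise. Positive and
negative levels are separated widely enough that gates placed at the
geometric midpoint of the generating means recover every class on
noiseless scenes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gating import GateConfig, load_rules
from .image import MultichannelImage
from .io_prep import (
    NormalizationStats,
    ROIAnnotation,
    write_multichannel_tiff,
    write_roi_json,
    read_multichannel_tiff,
)

__all__ = [
    "SceneConfig",
    "SceneGroundTruth",
    "generate_scene",
    "render_vessels",
    "write_scene",
    "load_scene_config",
    "gates_from_intensity_model",
    "default_composition",
]

#: full panel rendered by the generator
PANEL = (
    "DNA", "CD45", "CD3", "CD4", "CD8a", "CD68", "TMEM119", "HLA", "PLP",
    "Igk", "Igl", "IgM", "CD38", "Ki67", "NFAT1", "Collagen", "CD31",
)

#: per-marker (positive_mean, negative_mean) on the raw ion-count scale
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, float]] = {
    m: {"positive_mean": 20.0, "negative_mean": 0.2}
    for m in PANEL
}
DEFAULT_INTENSITY_MODEL["DNA"] = {"positive_mean": 30.0, "negative_mean": 0.05}
DEFAULT_INTENSITY_MODEL["Collagen"] = {"positive_mean": 25.0, "negative_mean": 0.1}
DEFAULT_INTENSITY_MODEL["CD31"] = {"positive_mean": 20.0, "negative_mean": 0.1}
DEFAULT_INTENSITY_MODEL["PLP"] = {"positive_mean": 25.0, "negative_mean": 0.2}

#: lesion-stage class mixes (cells per 0.25 mm² scene); chosen once to
#: echo the qualitative picture of staged lesions — microglia dominate
#: control tissue, demyelinating phagocytes and lymphocytes fill active
#: lesion centers and mixed-lesion edges.
STAGE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "WMC": {"microglia": 70, "macrophage": 6, "CD8 T cell": 3, "CD4 T cell": 2, "other": 40},
    "NAWM": {"microglia": 65, "activated microglia": 10, "macrophage": 8,
             "CD8 T cell": 4, "CD4 T cell": 3, "other": 38},
    "PPWM": {"microglia": 55, "activated microglia": 20, "macrophage": 10,
             "CD8 T cell": 6, "CD4 T cell": 4, "other": 35},
    "preactive": {"microglia": 40, "activated microglia": 35, "macrophage": 12,
                  "CD8 T cell": 8, "CD4 T cell": 5, "naive B cell": 3, "other": 30},
    "active_center": {
        "demyelinating microglia": 60, "demyelinating macrophage": 40,
        "activated microglia": 30, "microglia": 25, "macrophage": 25,
        "activated macrophage": 20, "CD8 T cell": 25, "CD4 T cell": 20,
        "chronically activated CD8 T cell": 8, "proliferating CD8 T cell": 6,
        "activated CD4 T cell": 6, "unclassified T cell": 10,
        "naive B cell": 8, "IgM memory B cell": 5, "switched memory B cell": 4,
        "other": 8,
    },
    "mixed_edge": {
        "demyelinating microglia": 45, "demyelinating macrophage": 30,
        "activated microglia": 35, "microglia": 20, "macrophage": 20,
        "CD8 T cell": 30, "CD4 T cell": 22, "unclassified T cell": 18,
        "chronically activated CD8 T cell": 10, "naive B cell": 6, "other": 14,
    },
    "mixed_core": {
        "microglia": 15, "macrophage": 30, "activated macrophage": 15,
        "CD8 T cell": 12, "CD4 T cell": 8, "unclassified T cell": 6, "other": 60,
    },
}

#: stages whose white matter retains ambient myelin (PLP background)
_MYELINATED_STAGES = {"WMC", "NAWM", "PPWM", "preactive"}
_AMBIENT_PLP_MEAN = 8.0


def default_composition(lesion_stage: str) -> dict[str, int]:
    """Cell-class mix emulating one lesion stage (copy; edit freely)."""
    return dict(STAGE_COMPOSITIONS[lesion_stage])


@dataclass
class SceneConfig:
    """Everything needed to reproduce one synthetic scene.

    A 500 × 500 px frame at 1 µm/px is 0.25 mm² of tissue. Intensities are
    mean ion counts; ``dispersion`` is the log-normal sigma (natural log)
    of cell-to-cell expression variation. ``speckle_rate`` is the expected
    number of isolated hot pixels per 10⁴ pixels per channel.
    ``touching_pairs`` places that many cell pairs at 1.2 × radius center
    spacing to stress watershed splitting.
    """

    height: int = 500
    width: int = 500
    pixel_size_um: float = 1.0
    lesion_stage: str = "active_center"
    class_composition: dict[str, int] | None = None
    nucleus_radius_range: tuple[int, int] = (3, 5)
    min_center_spacing_px: float = 17.0
    cytoplasm_paint_px: int = 4
    intensity_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MODEL.items()}
    )
    cd45_levels: dict[str, float] = field(
        default_factory=lambda: {"low_mean": 6.0, "high_mean": 30.0}
    )
    hla_levels: dict[str, float] = field(
        default_factory=lambda: {"activation_mean": 5.0, "myeloid_mean": 25.0}
    )
    dispersion: float = 0.12
    vessels: list[tuple[tuple[float, float], tuple[float, float], float]] = field(
        default_factory=lambda: [
            ((60.0, 100.0), (440.0, 140.0), 8.0),
            ((380.0, 420.0), (120.0, 380.0), 12.0),
        ]
    )
    speckle_rate: float = 2.0
    speckle_amplitude: float = 120.0
    poisson_noise: bool = True
    touching_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_composition is None:
            self.class_composition = default_composition(self.lesion_stage)
        if any(c < 0 for c in self.class_composition.values()):
            raise ValueError("class counts must be >= 0")
        for m, mdl in self.intensity_model.items():
            if not mdl["positive_mean"] > mdl["negative_mean"] >= 0:
                raise ValueError(
                    f"intensity model for {m!r} needs positive_mean > negative_mean >= 0"
                )

    def n_cells(self) -> int:
        return sum(self.class_composition.values())


@dataclass
class SceneGroundTruth:
    """What the generator actually placed, for recovery tests."""

    cells: pd.DataFrame  # cell_id, true_class, y_px, x_px, nucleus_radius_px
    vessel_mask: np.ndarray
    roi: ROIAnnotation
    speckles: dict[str, np.ndarray]  # channel -> (n, 2) row/col coordinates
    config: SceneConfig


def render_vessels(
    cfg: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize vessel tubes: collagen fill, CD31 endothelial rim, mask.

    Each vessel is the set of pixels within ``radius_um`` of its
    centerline segment; CD31 is painted on the innermost ~2 px rim.
    Returns noiseless (collagen, cd31, vessel_mask) grids.
    """
    from scipy.ndimage import binary_erosion

    h, w, psz = cfg.height, cfg.width, cfg.pixel_size_um
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    mask = np.zeros((h, w), dtype=bool)
    for (x0, y0), (x1, y1), radius_um in cfg.vessels:
        if radius_um <= 0:
            raise ValueError("vessel radius must be > 0")
        if not (0 <= x0 < w and 0 <= y0 < h and 0 <= x1 < w and 0 <= y1 < h):
            warnings.warn("vessel centerline extends beyond frame; clipping", stacklevel=2)
        dx, dy = x1 - x0, y1 - y0
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            t = np.zeros_like(cols)
        else:
            t = np.clip(((cols - x0) * dx + (rows - y0) * dy) / seg2, 0.0, 1.0)
        px, py = x0 + t * dx, y0 + t * dy
        dist_um = np.hypot(cols - px, rows - py) * psz
        mask |= dist_um <= radius_um
    collagen = np.where(mask, cfg.intensity_model["Collagen"]["positive_mean"], 0.0)
    rim = mask & ~binary_erosion(mask, iterations=2)
    cd31 = np.where(rim, cfg.intensity_model["CD31"]["positive_mean"], 0.0)
    return collagen, cd31, mask


def _class_marker_levels(cls: str, cfg: SceneConfig, rules, cell_index: int) -> dict[str, float]:
    """Mean expression per marker for one cell of class ``cls``."""
    sig = next(r["signature"] for r in rules.rules if r["name"] == cls)
    levels = {m: cfg.intensity_model[m]["negative_mean"] for m in PANEL if m not in ("Collagen", "CD31")}
    levels["DNA"] = cfg.intensity_model["DNA"]["positive_mean"]
    levels["Collagen"] = cfg.intensity_model["Collagen"]["negative_mean"]
    levels["CD31"] = cfg.intensity_model["CD31"]["negative_mean"]
    for marker, sign in sig.items():
        if marker == "CD45":
            levels["CD45"] = (
                cfg.cd45_levels["high_mean"] if sign == "high" else cfg.cd45_levels["low_mean"]
            )
        elif marker == "HLA":
            levels["HLA"] = (
                cfg.hla_levels["activation_mean"] if sign == "act"
                else cfg.hla_levels["myeloid_mean"] if sign == "+"
                else cfg.intensity_model["HLA"]["negative_mean"]
            )
        elif marker == "Igk/Igl":
            if sign == "+":
                levels["Igk"] = cfg.intensity_model["Igk"]["positive_mean"]
        elif sign == "+":
            levels[marker] = cfg.intensity_model[marker]["positive_mean"]
    if cls == "unclassified T cell":
        # alternate double-positive / double-negative CD3+ cells
        if cell_index % 2 == 0:
            levels["CD4"] = cfg.intensity_model["CD4"]["positive_mean"]
            levels["CD8a"] = cfg.intensity_model["CD8a"]["positive_mean"]
        else:
            levels["CD4"] = cfg.intensity_model["CD4"]["negative_mean"]
            levels["CD8a"] = cfg.intensity_model["CD8a"]["negative_mean"]
    return levels


def _place_centers(
    cfg: SceneConfig, rng: np.random.Generator, forbidden: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Rejection-sample cell centers with a minimum pairwise spacing."""
    n = len(radii)
    margin = cfg.nucleus_radius_range[1] + cfg.cytoplasm_paint_px + 1
    centers: list[tuple[float, float]] = []
    spacing = cfg.min_center_spacing_px
    pair_budget = cfg.touching_pairs
    attempts, max_attempts = 0, 400 * max(n, 1)
    i = 0
    while i < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} cells at spacing {spacing} px in a "
                f"{cfg.height}x{cfg.width} frame; enlarge the frame or reduce counts"
            )
        attempts += 1
        y = rng.uniform(margin, cfg.height - margin)
        x = rng.uniform(margin, cfg.width - margin)
        if forbidden[int(round(y)), int(round(x))]:
            continue
        if centers:
            d = np.hypot(np.array([c[0] for c in centers]) - y,
                         np.array([c[1] for c in centers]) - x)
            if d.min() < spacing:
                continue
        centers.append((y, x))
        i += 1
        if pair_budget > 0 and i < n:
            # partner nucleus at 1.2 x radius: a touching pair for watershed
            ang = rng.uniform(0, 2 * np.pi)
            gap = 1.2 * float(radii[i - 1] + radii[i])  # center distance
            yy, xx = y + gap * np.sin(ang), x + gap * np.cos(ang)
            if (margin <= yy < cfg.height - margin and margin <= xx < cfg.width - margin
                    and not forbidden[int(round(yy)), int(round(xx))]):
                centers.append((yy, xx))
                i += 1
                pair_budget -= 1
    return np.array(centers)


def generate_scene(cfg: SceneConfig) -> tuple[MultichannelImage, SceneGroundTruth]:
    """Render one scene and its ground truth; identical seeds reproduce it."""
    rng = np.random.default_rng(cfg.seed)
    rules = load_rules()
    unknown = set(cfg.class_composition) - set(rules.class_names)
    if unknown:
        raise ValueError(f"composition names unknown classes: {sorted(unknown)}")
    h, w = cfg.height, cfg.width

    collagen, cd31, vessel_mask = render_vessels(cfg)
    from scipy.ndimage import binary_dilation

    keepout = binary_dilation(
        vessel_mask, iterations=cfg.nucleus_radius_range[1] + cfg.cytoplasm_paint_px
    )

    class_list = [
        cls for cls, count in cfg.class_composition.items() for _ in range(count)
    ]
    n = len(class_list)
    radii = rng.integers(
        cfg.nucleus_radius_range[0], cfg.nucleus_radius_range[1] + 1, size=n
    )
    centers = _place_centers(cfg, rng, keepout, radii) if n else np.zeros((0, 2))

    channels = {
        m: np.full((h, w), cfg.intensity_model[m]["negative_mean"])
        for m in PANEL
    }
    channels["Collagen"] = np.where(
        vessel_mask, collagen, cfg.intensity_model["Collagen"]["negative_mean"]
    )
    channels["CD31"] = np.where(
        cd31 > 0, cd31, cfg.intensity_model["CD31"]["negative_mean"]
    )
    cols_grid, rows_grid = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    footprint_any = np.zeros((h, w), dtype=bool)
    records = []
    for i, cls in enumerate(class_list):
        cy, cx = centers[i]
        r = int(radii[i])
        dist = np.hypot(cols_grid - cx, rows_grid - cy)
        nucleus = dist <= r
        footprint = dist <= r + cfg.cytoplasm_paint_px
        footprint_any |= footprint
        levels = _class_marker_levels(cls, cfg, rules, i)
        for m, mean in levels.items():
            if m == "DNA":
                continue
            lvl = mean * float(np.exp(rng.normal(0.0, cfg.dispersion)))
            channels[m][footprint] = np.maximum(channels[m][footprint], lvl)
        dna_lvl = levels["DNA"] * float(np.exp(rng.normal(0.0, cfg.dispersion)))
        channels["DNA"][nucleus] = np.maximum(channels["DNA"][nucleus], dna_lvl)
        records.append(
            {"cell_id": i + 1, "true_class": cls, "y_px": cy, "x_px": cx,
             "nucleus_radius_px": r}
        )

    # ambient myelin texture fills intact white matter, but only outside
    # cell footprints (cells displace the myelin they sit on) and vessels
    if cfg.lesion_stage in _MYELINATED_STAGES:
        ambient = ~footprint_any & ~vessel_mask
        channels["PLP"][ambient] = np.maximum(
            channels["PLP"][ambient], _AMBIENT_PLP_MEAN
        )

    if cfg.poisson_noise:
        for m in PANEL:
            channels[m] = rng.poisson(channels[m]).astype(np.float64)

    speckles: dict[str, np.ndarray] = {}
    n_speckles = int(round(cfg.speckle_rate * h * w / 1e4))
    if cfg.speckle_rate > 0 and n_speckles > 0:
        for m in PANEL:
            taken = np.zeros((h, w), dtype=bool)
            coords = []
            guard = 0
            while len(coords) < n_speckles and guard < 100 * n_speckles:
                guard += 1
                r_, c_ = int(rng.integers(1, h - 1)), int(rng.integers(1, w - 1))
                if taken[max(r_ - 2, 0):r_ + 3, max(c_ - 2, 0):c_ + 3].any():
                    continue
                coords.append((r_, c_))
                taken[r_, c_] = True
                channels[m][r_, c_] = cfg.speckle_amplitude
            speckles[m] = np.array(coords, dtype=int).reshape(-1, 2)
    else:
        speckles = {m: np.zeros((0, 2), dtype=int) for m in PANEL}

    image = MultichannelImage(channels, pixel_size_um=cfg.pixel_size_um)
    roi = ROIAnnotation(
        polygon=[(-0.49, -0.49), (w - 0.51, -0.49), (w - 0.51, h - 0.51), (-0.49, h - 0.51)],
        lesion_stage=cfg.lesion_stage,
        name=f"synthetic_{cfg.lesion_stage}",
    )
    truth = SceneGroundTruth(
        cells=pd.DataFrame(
            records,
            columns=["cell_id", "true_class", "y_px", "x_px", "nucleus_radius_px"],
        ),
        vessel_mask=vessel_mask,
        roi=roi,
        speckles=speckles,
        config=cfg,
    )
    return image, truth


def gates_from_intensity_model(
    cfg: SceneConfig, norm_stats: dict[str, NormalizationStats]
) -> GateConfig:
    """Gate thresholds matched to the generating intensity model.

    Each threshold is the geometric midpoint between a marker's negative
    and positive generating means (two-level markers use midpoints between
    adjacent levels), divided by that channel's limit-of-detection
    denominator so the gates live on the normalized scale the cell table
    reports.
    """
    def denom(m: str) -> float:
        s = norm_stats[m]
        return s.denom if not s.degenerate else float("inf")

    def mid(lo: float, hi: float) -> float:
        return float(np.sqrt(max(lo, 1e-2) * hi))

    thresholds = {}
    for m in PANEL:
        if m in ("DNA",):
            continue
        mdl = cfg.intensity_model[m]
        thresholds[m] = mid(mdl["negative_mean"], mdl["positive_mean"]) / denom(m)
    neg_cd45 = cfg.intensity_model["CD45"]["negative_mean"]
    cd45_low = mid(neg_cd45, cfg.cd45_levels["low_mean"]) / denom("CD45")
    cd45_high = mid(cfg.cd45_levels["low_mean"], cfg.cd45_levels["high_mean"]) / denom("CD45")
    thresholds["CD45"] = cd45_low
    neg_hla = cfg.intensity_model["HLA"]["negative_mean"]
    hla_act = mid(neg_hla, cfg.hla_levels["activation_mean"]) / denom("HLA")
    hla_my = mid(cfg.hla_levels["activation_mean"], cfg.hla_levels["myeloid_mean"]) / denom("HLA")
    thresholds["HLA"] = hla_act
    return GateConfig(
        thresholds=thresholds,
        cd45_low=cd45_low,
        cd45_high=cd45_high,
        hla_myeloid=hla_my,
        hla_activation=hla_act,
        provenance="manual",
    )


# ---------------------------------------------------------------------------
# provenance round trip


def _config_to_dict(cfg: SceneConfig) -> dict:
    d = asdict(cfg)
    d["nucleus_radius_range"] = list(cfg.nucleus_radius_range)
    d["vessels"] = [
        {"start": list(v[0]), "end": list(v[1]), "radius_um": v[2]} for v in cfg.vessels
    ]
    return d


def load_scene_config(path: str | Path) -> SceneConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["nucleus_radius_range"] = tuple(d["nucleus_radius_range"])
    d["vessels"] = [
        ((v["start"][0], v["start"][1]), (v["end"][0], v["end"][1]), v["radius_um"])
        for v in d["vessels"]
    ]
    return SceneConfig(**d)


def write_scene(
    image: MultichannelImage, truth: SceneGroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Persist the four scene artifacts: TIFF, truth table, ROI, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "scene.tiff",
        "truth": out / "ground_truth.csv",
        "roi": out / "roi.json",
        "config": out / "scene_config.yaml",
    }
    write_multichannel_tiff(image, paths["image"])
    truth.cells.to_csv(paths["truth"], index=False)
    write_roi_json([truth.roi], paths["roi"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(truth.config), fh, sort_keys=False)
    return paths


def read_scene(scene_dir: str | Path) -> tuple[MultichannelImage, pd.DataFrame, SceneConfig]:
    """Re-load a written scene (image, truth table, config)."""
    scene_dir = Path(scene_dir)
    image = read_multichannel_tiff(scene_dir / "scene.tiff")
    cells = pd.read_csv(scene_dir / "ground_truth.csv")
    cfg = load_scene_config(scene_dir / "scene_config.yaml")
    return image, cells, cfg
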