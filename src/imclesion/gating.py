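"""Hierarchical positive/negative gating of segmented cells.

Every nucleated cell is pushed through three mutually exclusive lineage
branches, in order B -> T -> myeloid, each opened by an exclusion gate on
markers the lineage does not express:

* **B branch** — cells negative for CD3/CD4/CD8a/CD68, CD45-high, and
  positive for exactly one immunoglobulin light chain (Igk xor Igl;
  double-positives are artifactual since the two allelic variants cannot
  coexist on one cell). Subsets from the IgM x CD38 quadrant: naive
  (IgM+CD38-), IgM memory (IgM+CD38+), switched memory (IgM-CD38+); the
  IgM-CD38- remainder is kept as "B cell unresolved".
* **T branch** — cells negative for Igk/Igl/IgM/CD68 and below the
  myeloid-level HLA gate, CD45-high and CD3+. The CD4 x CD8a quadrant
  yields CD4 and CD8 T cells; double-positive and double-negative cells
  are "unclassified T cell". Functional modifiers: Ki67+ (proliferating),
  NFAT1+ (activated), CD38+HLA+ at the activation-level HLA gate
  (chronically activated).
* **Myeloid branch** — cells negative for CD3/CD4/CD8a/Igk/Igl/IgM,
  placed on the TMEM119 x CD45 plane: TMEM119+ CD45-low/+ microglia,
  TMEM119- CD45-high macrophages; both-low cells are "other"
  (astrocytes, oligodendrocytes, ...). CD68/PLP split each into
  activated (CD68+PLP-) and demyelinating (CD68+PLP+) subsets.

Cells matching no branch are "other" — the partition is total.

HLA is used at two distinct levels because it serves two roles: a high
"myeloid-level" cutoff excludes antigen-presenting myeloid cells from the
T branch, while a lower "activation-level" cutoff detects HLA as a T-cell
activation antigen. A single cutoff cannot serve both.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GateConfig",
    "ClassRuleSet",
    "SeedAnnotation",
    "load_rules",
    "fit_gates_from_seeds",
    "classify_cells",
    "classify_vector",
    "biaxial_summary",
]

#: markers every gating run must be able to threshold
CORE_MARKERS = (
    "CD45", "CD3", "CD4", "CD8a", "CD68", "TMEM119", "HLA", "PLP",
    "Igk", "Igl", "IgM", "CD38", "Ki67", "NFAT1",
)

T_BASE_CLASSES = ("CD4 T cell", "CD8 T cell", "unclassified T cell")

#: log-transform offset, as a fraction of each channel's normalized scale
LOG_EPS_FRACTION = 1e-3


@dataclass
class GateConfig:
    """Per-marker positivity thresholds on mean normalized intensity.

    ``cd45_low``/``cd45_high`` form the two-level CD45 gate separating
    background / microglia (low/+) / macrophages-and-lymphocytes (high).
    ``hla_myeloid``/``hla_activation`` form the analogous two-level HLA
    gate (lineage exclusion vs activation modifier).
    """

    thresholds: dict[str, float]
    cd45_low: float
    cd45_high: float
    hla_myeloid: float
    hla_activation: float
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.cd45_high < self.cd45_low:
            raise ValueError("cd45_high must be >= cd45_low")
        if self.hla_myeloid < self.hla_activation:
            raise ValueError("hla_myeloid must be >= hla_activation")
        bad = [m for m, t in self.thresholds.items() if t < 0]
        if bad or min(self.cd45_low, self.hla_activation) < 0:
            raise ValueError(f"negative thresholds: {bad}")

    def threshold(self, marker: str) -> float:
        try:
            return self.thresholds[marker]
        except KeyError:
            raise KeyError(f"no gate threshold configured for marker {marker!r}") from None


@dataclass
class ClassRuleSet:
    """Ordered phenotype rules (class name, marker signs, lineage)."""

    rules: list[dict]

    def __post_init__(self) -> None:
        names = [r["name"] for r in self.rules]
        if len(names) != len(set(names)):
            dup = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate class names in rule set: {dup}")
        sigs: dict[tuple, str] = {}
        for r in self.rules:
            key = (r["lineage"], tuple(sorted(r["signature"].items())))
            if key in sigs:
                raise ValueError(
                    f"classes {sigs[key]!r} and {r['name']!r} share one signature"
                )
            sigs[key] = r["name"]

    @property
    def class_names(self) -> list[str]:
        return [r["name"] for r in self.rules]

    def validate_panel(self, markers: list[str]) -> None:
        panel = set(markers)
        for r in self.rules:
            for m in r["signature"]:
                wanted = {"Igk", "Igl"} if m == "Igk/Igl" else {m}
                missing = wanted - panel
                if missing:
                    raise ValueError(
                        f"rule {r['name']!r} requires markers {sorted(missing)} "
                        "absent from the panel"
                    )


def load_rules(path: str | Path | None = None) -> ClassRuleSet:
    """Load the shipped phenotype table (or a user-edited copy)."""
    if path is None:
        ref = importlib.resources.files("imclesion") / "rules" / "table2.yaml"
        data = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return ClassRuleSet(rules=data["classes"])


@dataclass
class SeedAnnotation:
    """Pathologist-style seed labels used to fit quadrant gates.

    ``positive``/``negative`` map a marker name to lists of cell ids
    verified positive / negative for it. ``cd45_high_ids``/``cd45_low_ids``
    carry macrophage-or-lymphocyte vs microglia seeds for the two-level
    CD45 gate (and analogously ``hla_myeloid_ids``/``hla_activation_ids``).
    """

    positive: dict[str, list] = field(default_factory=dict)
    negative: dict[str, list] = field(default_factory=dict)
    cd45_high_ids: list = field(default_factory=list)
    cd45_low_ids: list = field(default_factory=list)
    hla_myeloid_ids: list = field(default_factory=list)
    hla_activation_ids: list = field(default_factory=list)


def _log_midpoint(lo: np.ndarray, hi: np.ndarray, eps: float) -> float:
    """Geometric midpoint between max(lo) and min(hi) on the log scale."""
    a, b = float(np.max(lo)), float(np.min(hi))
    return math.exp(0.5 * (math.log(a + eps) + math.log(b + eps))) - eps


def fit_gates_from_seeds(
    cells: pd.DataFrame,
    seeds: SeedAnnotation,
    *,
    overlap_tolerance: float = 0.0,
) -> GateConfig:
    """Fit positivity thresholds from annotated seed cells.

    For each marker with both positive and negative seeds the threshold is
    the midpoint, on log10(x + eps) intensity, between the largest negative
    seed and the smallest positive seed (eps = 1e-3 of the channel scale).
    Seed ranges that invert or overlap beyond ``overlap_tolerance`` raise,
    naming the conflicting cells. The two-level CD45 (and HLA) gates are
    fitted the same way from microglia-labeled (low) vs
    macrophage/lymphocyte-labeled (high) seeds.
    """
    idx = cells.set_index("cell_id")

    def values(marker: str, ids: list) -> np.ndarray:
        missing = [i for i in ids if i not in idx.index]
        if missing:
            raise KeyError(f"seed cell ids not in table: {missing}")
        return idx.loc[ids, f"norm_{marker}"].to_numpy(dtype=float)

    def fit_one(marker: str, neg_ids: list, pos_ids: list) -> float:
        neg, pos = values(marker, neg_ids), values(marker, pos_ids)
        scale = float(max(np.max(neg), np.max(pos)))
        eps = LOG_EPS_FRACTION * (scale if scale > 0 else 1.0)
        if np.max(neg) > np.min(pos) + overlap_tolerance:
            bad_n = [i for i, v in zip(neg_ids, neg) if v > np.min(pos)]
            bad_p = [i for i, v in zip(pos_ids, pos) if v < np.max(neg)]
            raise ValueError(
                f"seed intensity ranges for {marker!r} overlap: negative ids "
                f"{bad_n} exceed positive ids {bad_p}"
            )
        return _log_midpoint(neg, pos, eps)

    thresholds: dict[str, float] = {}
    for marker, pos_ids in seeds.positive.items():
        if marker not in seeds.negative:
            continue  # no negatives: manual threshold required for this marker
        thresholds[marker] = fit_one(marker, seeds.negative[marker], pos_ids)

    if seeds.cd45_high_ids and seeds.cd45_low_ids:
        cd45_high = fit_one("CD45", seeds.cd45_low_ids, seeds.cd45_high_ids)
        if "CD45" in thresholds:
            cd45_low = thresholds["CD45"]
        else:
            # without CD45-negative seeds, anchor the low gate below the
            # dimmest microglia seed
            cd45_low = float(np.min(values("CD45", seeds.cd45_low_ids))) / 2.0
        thresholds["CD45"] = cd45_low
    else:
        raise ValueError("CD45 two-level gate requires both low and high seed ids")

    if seeds.hla_myeloid_ids and seeds.hla_activation_ids:
        hla_myeloid = fit_one("HLA", seeds.hla_activation_ids, seeds.hla_myeloid_ids)
        if "HLA" in thresholds:
            hla_activation = thresholds["HLA"]
        else:
            hla_activation = float(np.min(values("HLA", seeds.hla_activation_ids))) / 2.0
        thresholds["HLA"] = hla_activation
    else:
        raise ValueError("HLA two-level gate requires activation and myeloid seed ids")

    return GateConfig(
        thresholds=thresholds,
        cd45_low=cd45_low,
        cd45_high=cd45_high,
        hla_myeloid=hla_myeloid,
        hla_activation=hla_activation,
        provenance="fitted-from-seeds",
    )


# ---------------------------------------------------------------------------
# classification


def classify_vector(values: dict[str, float], gates: GateConfig) -> tuple[str, str, str]:
    """Classify one cell's mean normalized intensities.

    Returns ``(class_name, lineage, modifiers)`` where ``modifiers`` is a
    "+"-joined string of functional flags (T cells only). This is the
    single canonical decision procedure; :func:`classify_cells` applies it
    row-wise.
    """
    def pos(m: str) -> bool:
        return values[m] >= gates.threshold(m)

    cd45 = values["CD45"]
    cd45_level = "high" if cd45 >= gates.cd45_high else ("low" if cd45 >= gates.cd45_low else "neg")
    hla_myeloid = values["HLA"] >= gates.hla_myeloid
    hla_act = values["HLA"] >= gates.hla_activation

    # --- B branch ---
    if (
        not pos("CD3") and not pos("CD4") and not pos("CD8a") and not pos("CD68")
        and cd45_level == "high" and (pos("Igk") or pos("Igl"))
    ):
        if pos("Igk") and pos("Igl"):
            return "B cell artifact", "B", ""
        igm, cd38 = pos("IgM"), pos("CD38")
        if igm and not cd38:
            return "naive B cell", "B", ""
        if igm and cd38:
            return "IgM memory B cell", "B", ""
        if cd38:
            return "switched memory B cell", "B", ""
        return "B cell unresolved", "B", ""

    # --- T branch ---
    if (
        not pos("Igk") and not pos("Igl") and not pos("IgM") and not pos("CD68")
        and not hla_myeloid and cd45_level == "high" and pos("CD3")
    ):
        cd4, cd8 = pos("CD4"), pos("CD8a")
        if cd8 and not cd4:
            base = "CD8 T cell"
        elif cd4 and not cd8:
            base = "CD4 T cell"
        else:
            base = "unclassified T cell"
        mods = []
        if pos("Ki67"):
            mods.append("Ki67+")
        if pos("NFAT1"):
            mods.append("NFAT1+")
        chron = pos("CD38") and hla_act
        if chron:
            mods.append("CD38+HLA+")
        modifiers = "+".join(mods)
        if base == "unclassified T cell":
            return base, "T", modifiers
        if chron:
            return f"chronically activated {base}", "T", modifiers
        if pos("Ki67") and pos("NFAT1"):
            return f"activated and proliferating {base}", "T", modifiers
        if pos("Ki67"):
            return f"proliferating {base}", "T", modifiers
        if pos("NFAT1"):
            return f"activated {base}", "T", modifiers
        return base, "T", modifiers

    # --- myeloid branch ---
    if (
        not pos("CD3") and not pos("CD4") and not pos("CD8a")
        and not pos("Igk") and not pos("Igl") and not pos("IgM")
    ):
        if pos("TMEM119") and cd45_level != "neg":
            base = "microglia"
        elif not pos("TMEM119") and cd45_level == "high":
            base = "macrophage"
        else:
            return "other", "none", ""
        if pos("CD68") and pos("PLP"):
            return f"demyelinating {base}", "myeloid", ""
        if pos("CD68"):
            return f"activated {base}", "myeloid", ""
        return base, "myeloid", ""

    return "other", "none", ""


def classify_cells(
    cells: pd.DataFrame,
    gates: GateConfig,
    rules: ClassRuleSet | None = None,
    *,
    min_nucleus_area_px: int = 1,
) -> pd.DataFrame:
    """Assign every cell exactly one phenotype class plus modifier flags.

    ``cells`` is the segmentation export (one ``norm_<marker>`` column per
    marker). Cells whose nucleus falls below ``min_nucleus_area_px`` fail
    the "nucleated" requirement and go to "other". Returns a copy with
    ``cell_class``, ``lineage`` and ``modifiers`` columns appended.
    """
    rules = rules or load_rules()
    markers = [c[5:] for c in cells.columns if c.startswith("norm_")]
    missing = [m for m in CORE_MARKERS if m not in markers]
    if missing:
        raise ValueError(f"cell table lacks normalized intensities for {missing}")
    rules.validate_panel(markers)

    out = cells.copy()
    classes, lineages, mods = [], [], []
    cols = {m: cells[f"norm_{m}"].to_numpy(dtype=float) for m in markers}
    nuc_area = (
        cells["nucleus_area_px"].to_numpy()
        if "nucleus_area_px" in cells.columns
        else np.full(len(cells), np.inf)
    )
    for i in range(len(cells)):
        if nuc_area[i] < min_nucleus_area_px:
            cls, lin, mod = "other", "none", ""
        else:
            vec = {m: cols[m][i] for m in markers}
            cls, lin, mod = classify_vector(vec, gates)
        classes.append(cls)
        lineages.append(lin)
        mods.append(mod)
    out["cell_class"] = classes
    out["lineage"] = lineages
    out["modifiers"] = mods
    unknown = set(classes) - set(rules.class_names)
    if unknown:
        raise RuntimeError(f"classifier produced classes absent from rule set: {unknown}")
    return out


def biaxial_summary(
    cells: pd.DataFrame,
    marker_x: str,
    marker_y: str,
    gates: GateConfig,
    *,
    ax=None,
) -> dict[str, int]:
    """Quadrant counts of cells on a log-log biaxial plot of two markers.

    Returns counts keyed ``"--"`` (double negative), ``"+-"`` (x positive
    only), ``"-+"``, ``"++"``. If ``ax`` is given, a log-log scatter with
    the two gate lines is drawn onto it.
    """
    for m in (marker_x, marker_y):
        if f"norm_{m}" not in cells.columns:
            raise KeyError(f"marker {m!r} not measured in cell table")
    x = cells[f"norm_{marker_x}"].to_numpy(dtype=float)
    y = cells[f"norm_{marker_y}"].to_numpy(dtype=float)
    tx, ty = gates.threshold(marker_x), gates.threshold(marker_y)
    px_, py_ = x >= tx, y >= ty
    counts = {
        "--": int(np.sum(~px_ & ~py_)),
        "+-": int(np.sum(px_ & ~py_)),
        "-+": int(np.sum(~px_ & py_)),
        "++": int(np.sum(px_ & py_)),
    }
    if ax is not None:
        eps_x = LOG_EPS_FRACTION * max(x.max(), 1e-12)
        eps_y = LOG_EPS_FRACTION * max(y.max(), 1e-12)
        ax.scatter(x + eps_x, y + eps_y, s=4, alpha=0.6)
        ax.axvline(tx + eps_x, color="k", lw=0.8)
        ax.axhline(ty + eps_y, color="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(marker_x)
        ax.set_ylabel(marker_y)
    return counts
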