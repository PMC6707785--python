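"""Fit gate thresholds from pathologist-style seed annotations.

Instead of deriving gates from the generator's intensity model, this
mimics the manual workflow: a handful of cells are "annotated" (here taken
from ground truth) as positive/negative for Ki67 and NFAT1 and as
CD45-high (macrophage/lymphocyte) vs CD45-low (microglia); thresholds are
the log-scale midpoints of the seed gaps.
"""

from imclesion.gating import SeedAnnotation, fit_gates_from_seeds
from imclesion.pipeline import preprocess_roi, quantify_roi
from imclesion.synthetic import SceneConfig, gates_from_intensity_model, generate_scene
from imclesion.validation import classification_accuracy, match_to_truth

cfg = SceneConfig(seed=31)
image, truth = generate_scene(cfg)
_, _, _, _, stats = preprocess_roi(image, truth.roi)
# first pass with model-derived gates, only to obtain a measured cell table
result = quantify_roi(image, truth.roi, gates_from_intensity_model(cfg, stats))

matched = match_to_truth(truth.cells, result.cells).dropna(subset=["matched_cell_id"])
by_class = {
    cls: matched.loc[matched.true_class == cls, "matched_cell_id"].astype(int).tolist()
    for cls in matched.true_class.unique()
}
ki67_pos = by_class["proliferating CD8 T cell"][:3]
ki67_neg = by_class["CD8 T cell"][:3]
nfat_pos = by_class["activated CD4 T cell"][:3]
nfat_neg = by_class["CD4 T cell"][:3]
cd45_high = by_class["macrophage"][:4] + by_class["CD8 T cell"][3:6]
cd45_low = by_class["microglia"][:6]
hla_myeloid = by_class["macrophage"][:4]
hla_act = by_class["chronically activated CD8 T cell"][:3]

seeds = SeedAnnotation(
    positive={"Ki67": ki67_pos, "NFAT1": nfat_pos},
    negative={"Ki67": ki67_neg, "NFAT1": nfat_neg},
    cd45_high_ids=cd45_high, cd45_low_ids=cd45_low,
    hla_myeloid_ids=hla_myeloid, hla_activation_ids=hla_act,
)
fitted = fit_gates_from_seeds(result.cells, seeds)
print(f"provenance: {fitted.provenance}")
print(f"Ki67 threshold : {fitted.thresholds['Ki67']:.3f} (normalized)")
print(f"NFAT1 threshold: {fitted.thresholds['NFAT1']:.3f}")
print(f"CD45 gate      : low {fitted.cd45_low:.3f} / high {fitted.cd45_high:.3f}")
print(f"HLA gate       : activation {fitted.hla_activation:.3f} / myeloid {fitted.hla_myeloid:.3f}")
# Seed-fitted thresholds land between the generating populations, so
# reclassifying with them reproduces the functional T subsets.
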