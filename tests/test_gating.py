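"""Hierarchical gating: seed-fitted thresholds, classification, quadrants."""

import math

import numpy as np
import pandas as pd
import pytest

from imclesion.gating import (
    GateConfig,
    SeedAnnotation,
    biaxial_summary,
    classify_cells,
    classify_vector,
    fit_gates_from_seeds,
    load_rules,
)
from imclesion.validation import classification_accuracy

MARKERS = (
    "CD45", "CD3", "CD4", "CD8a", "CD68", "TMEM119", "HLA", "PLP",
    "Igk", "Igl", "IgM", "CD38", "Ki67", "NFAT1",
)


def simple_gates(**kw):
    thr = {m: 0.5 for m in MARKERS}
    thr.update({"CD45": 0.2, "HLA": 0.3})
    defaults = dict(thresholds=thr, cd45_low=0.2, cd45_high=0.6,
                    hla_myeloid=0.7, hla_activation=0.3)
    defaults.update(kw)
    return GateConfig(**defaults)


def oracle_classify(v: dict, g: GateConfig) -> str:
    """Independent flat re-statement of the lineage decision table."""
    p = {m: v[m] >= g.thresholds[m] for m in MARKERS}
    cd45_high = v["CD45"] >= g.cd45_high
    cd45_any = v["CD45"] >= g.cd45_low
    hla_my = v["HLA"] >= g.hla_myeloid
    hla_act = v["HLA"] >= g.hla_activation

    b_ok = (not p["CD3"] and not p["CD4"] and not p["CD8a"] and not p["CD68"]
            and cd45_high and (p["Igk"] or p["Igl"]))
    if b_ok:
        if p["Igk"] and p["Igl"]:
            return "B cell artifact"
        if p["IgM"] and not p["CD38"]:
            return "naive B cell"
        if p["IgM"] and p["CD38"]:
            return "IgM memory B cell"
        if p["CD38"]:
            return "switched memory B cell"
        return "B cell unresolved"

    t_ok = (not p["Igk"] and not p["Igl"] and not p["IgM"] and not p["CD68"]
            and not hla_my and cd45_high and p["CD3"])
    if t_ok:
        if p["CD8a"] and not p["CD4"]:
            base = "CD8 T cell"
        elif p["CD4"] and not p["CD8a"]:
            base = "CD4 T cell"
        else:
            return "unclassified T cell"
        if p["CD38"] and hla_act:
            return "chronically activated " + base
        if p["Ki67"] and p["NFAT1"]:
            return "activated and proliferating " + base
        if p["Ki67"]:
            return "proliferating " + base
        if p["NFAT1"]:
            return "activated " + base
        return base

    m_ok = (not p["CD3"] and not p["CD4"] and not p["CD8a"]
            and not p["Igk"] and not p["Igl"] and not p["IgM"])
    if m_ok:
        if p["TMEM119"] and cd45_any:
            base = "microglia"
        elif not p["TMEM119"] and cd45_high:
            base = "macrophage"
        else:
            return "other"
        if p["CD68"] and p["PLP"]:
            return "demyelinating " + base
        if p["CD68"]:
            return "activated " + base
        return base
    return "other"


def cells_from_vectors(vectors: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(vectors, columns=[f"norm_{m}" for m in MARKERS])
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    df["nucleus_area_px"] = 30
    return df


class TestFitGates:
    def test_geometric_midpoint_of_seed_gap(self):
        cells = cells_from_vectors(np.zeros((4, len(MARKERS))))
        cells.loc[:, "norm_Ki67"] = [0.1, 0.2, 0.8, 1.0]
        cells.loc[:, "norm_CD45"] = [0.05, 0.05, 1.0, 1.0]
        cells.loc[:, "norm_HLA"] = [0.05, 0.05, 1.0, 1.0]
        seeds = SeedAnnotation(
            positive={"Ki67": [3, 4]},
            negative={"Ki67": [1, 2]},
            cd45_low_ids=[1, 2],
            cd45_high_ids=[3, 4],
            hla_activation_ids=[1, 2],
            hla_myeloid_ids=[3, 4],
        )
        gates = fit_gates_from_seeds(cells, seeds)
        eps = 1e-3
        expected = math.exp(0.5 * (math.log(0.2 + eps) + math.log(0.8 + eps))) - eps
        assert gates.thresholds["Ki67"] == pytest.approx(expected)
        assert gates.thresholds["Ki67"] == pytest.approx(math.sqrt(0.16), rel=0.02)
        assert gates.provenance == "fitted-from-seeds"

    def test_inverted_seed_ranges_error_with_ids(self):
        cells = cells_from_vectors(np.zeros((2, len(MARKERS))))
        cells.loc[:, "norm_Ki67"] = [0.5, 0.4]  # negative above positive
        seeds = SeedAnnotation(
            positive={"Ki67": [2]}, negative={"Ki67": [1]},
            cd45_low_ids=[1], cd45_high_ids=[2],
            hla_activation_ids=[1], hla_myeloid_ids=[2],
        )
        cells.loc[:, "norm_CD45"] = [0.1, 1.0]
        cells.loc[:, "norm_HLA"] = [0.1, 1.0]
        with pytest.raises(ValueError, match="overlap"):
            fit_gates_from_seeds(cells, seeds)

    def test_generated_seed_populations_separate_cleanly(self, rng):
        # two log-normal populations as the scene generator draws them
        neg = 0.2 * np.exp(rng.normal(0, 0.12, 25))
        pos = 20.0 * np.exp(rng.normal(0, 0.12, 25))
        vals = np.concatenate([neg, pos])
        cells = cells_from_vectors(np.zeros((50, len(MARKERS))))
        cells["norm_NFAT1"] = vals
        cells["norm_CD45"] = np.concatenate([0.2 * np.ones(25), 30 * np.ones(25)])
        cells["norm_HLA"] = np.concatenate([0.2 * np.ones(25), 25 * np.ones(25)])
        ids = cells.cell_id.tolist()
        seeds = SeedAnnotation(
            positive={"NFAT1": ids[25:]}, negative={"NFAT1": ids[:25]},
            cd45_low_ids=ids[:25], cd45_high_ids=ids[25:],
            hla_activation_ids=ids[:25], hla_myeloid_ids=ids[25:],
        )
        gates = fit_gates_from_seeds(cells, seeds)
        thr = gates.thresholds["NFAT1"]
        assert (neg < thr).all() and (pos >= thr).all()  # zero training error


class TestClassify:
    def test_cd8_t_cell_signature(self):
        g = simple_gates()
        v = {m: 0.0 for m in MARKERS}
        v.update({"CD45": 1.0, "CD3": 1.0, "CD8a": 1.0})
        assert classify_vector(v, g)[0] == "CD8 T cell"

    def test_all_zero_vector_is_other(self):
        g = simple_gates()
        v = {m: 0.0 for m in MARKERS}
        assert classify_vector(v, g)[0] == "other"

    def test_double_positive_light_chains_are_artifact(self):
        g = simple_gates()
        v = {m: 0.0 for m in MARKERS}
        v.update({"CD45": 1.0, "Igk": 1.0, "Igl": 1.0})
        assert classify_vector(v, g)[0] == "B cell artifact"

    def test_agrees_with_rule_table_oracle_on_random_vectors(self, rng):
        g = simple_gates()
        n = 10_000
        vectors = 10 ** rng.uniform(-3, 0.5, size=(n, len(MARKERS)))
        cells = classify_cells(cells_from_vectors(vectors), g)
        mismatches = 0
        for i in range(n):
            v = dict(zip(MARKERS, vectors[i]))
            if oracle_classify(v, g) != cells["cell_class"].iat[i]:
                mismatches += 1
        assert mismatches == 0

    def test_partition_is_total(self, rng):
        g = simple_gates()
        vectors = 10 ** rng.uniform(-3, 0.5, size=(500, len(MARKERS)))
        cells = classify_cells(cells_from_vectors(vectors), g)
        assert cells["cell_class"].notna().all()
        assert cells["cell_class"].value_counts().sum() == 500

    def test_raising_threshold_is_monotone(self, rng):
        g = simple_gates()
        vectors = 10 ** rng.uniform(-3, 0.5, size=(2000, len(MARKERS)))
        table = cells_from_vectors(vectors)
        t_classes = [c for c in load_rules().class_names if "T cell" in c and c != "unclassified T cell"]

        def count_t(gates):
            out = classify_cells(table, gates)
            return out["cell_class"].isin(t_classes).sum()

        low = count_t(g)
        thr = dict(g.thresholds)
        thr["CD3"] = thr["CD3"] * 4
        high = count_t(simple_gates(thresholds=thr))
        assert high <= low

    def test_noiseless_scene_recovers_all_classes(self, noiseless_scene, noiseless_result):
        _, _, truth = noiseless_scene
        _, _, result, _ = noiseless_result
        assert classification_accuracy(truth.cells, result.cells) == 1.0

    def test_noisy_scene_accuracy_and_zero_artifact_rate(self, default_scene, default_result):
        _, _, truth = default_scene
        _, _, result, _ = default_result
        assert classification_accuracy(truth.cells, result.cells) >= 0.95
        # generator emitted no double-positive B cells
        assert (result.cells["cell_class"] == "B cell artifact").sum() == 0

    def test_contradictory_rule_set_rejected(self):
        from imclesion.gating import ClassRuleSet

        with pytest.raises(ValueError, match="share"):
            ClassRuleSet(rules=[
                {"name": "a", "lineage": "T", "signature": {"CD3": "+"}},
                {"name": "b", "lineage": "T", "signature": {"CD3": "+"}},
            ])


class TestBiaxial:
    def test_one_cell_per_quadrant(self):
        g = simple_gates()
        cells = cells_from_vectors(np.zeros((4, len(MARKERS))))
        cells["norm_CD4"] = [0.1, 1.0, 0.1, 1.0]
        cells["norm_CD8a"] = [0.1, 0.1, 1.0, 1.0]
        counts = biaxial_summary(cells, "CD4", "CD8a", g)
        assert counts == {"--": 1, "+-": 1, "-+": 1, "++": 1}

    def test_all_double_negative(self):
        g = simple_gates()
        cells = cells_from_vectors(np.zeros((7, len(MARKERS))))
        counts = biaxial_summary(cells, "CD4", "CD8a", g)
        assert counts == {"--": 7, "+-": 0, "-+": 0, "++": 0}

    def test_synthetic_t_mixture_counts(self, noiseless_result):
        cfg, truth, result, gates = noiseless_result
        t = result.cells[result.cells["lineage"] == "T"]
        counts = biaxial_summary(t, "CD4", "CD8a", gates)
        comp = cfg.class_composition
        cd4_true = sum(v for k, v in comp.items() if "CD4 T cell" in k)
        cd8_true = sum(v for k, v in comp.items() if "CD8 T cell" in k)
        assert counts["+-"] == cd4_true
        assert counts["-+"] == cd8_true
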