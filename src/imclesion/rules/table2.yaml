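# Phenotype signatures for hierarchical gating of brain immune cells.
# Sign conventions: "+" positive, "-" negative, "high"/"low" the two-level
# CD45 gate (low = above the low threshold but below the high one, i.e.
# CD45^low/+ microglia vs CD45^high macrophages and lymphocytes), and
# "act" the activation-level (sub-myeloid) HLA gate.
# Users may edit signatures; classify_cells validates them against the panel.
classes:
  # -- macrophages and microglia ------------------------------------------
  - name: macrophage
    lineage: myeloid
    signature: {CD45: high, HLA: "+", TMEM119: "-"}
  - name: activated macrophage
    lineage: myeloid
    signature: {CD45: high, HLA: "+", TMEM119: "-", CD68: "+", PLP: "-"}
  - name: demyelinating macrophage
    lineage: myeloid
    signature: {CD45: high, HLA: "+", TMEM119: "-", CD68: "+", PLP: "+"}
  - name: microglia
    lineage: myeloid
    signature: {CD45: low, HLA: "+", TMEM119: "+"}
  - name: activated microglia
    lineage: myeloid
    signature: {CD45: low, HLA: "+", TMEM119: "+", CD68: "+", PLP: "-"}
  - name: demyelinating microglia
    lineage: myeloid
    signature: {CD45: low, HLA: "+", TMEM119: "+", CD68: "+", PLP: "+"}
  # -- T cells -------------------------------------------------------------
  - name: CD8 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "+", CD4: "-"}
  - name: proliferating CD8 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "+", CD4: "-", Ki67: "+"}
  - name: activated CD8 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "+", CD4: "-", NFAT1: "+"}
  - name: activated and proliferating CD8 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "+", CD4: "-", NFAT1: "+", Ki67: "+"}
  - name: chronically activated CD8 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "+", CD4: "-", CD38: "+", HLA: act}
  - name: CD4 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "-", CD4: "+"}
  - name: proliferating CD4 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "-", CD4: "+", Ki67: "+"}
  - name: activated CD4 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "-", CD4: "+", NFAT1: "+"}
  - name: activated and proliferating CD4 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "-", CD4: "+", NFAT1: "+", Ki67: "+"}
  - name: chronically activated CD4 T cell
    lineage: T
    signature: {CD45: high, CD3: "+", CD8a: "-", CD4: "+", CD38: "+", HLA: act}
  # -- B cells -------------------------------------------------------------
  - name: naive B cell
    lineage: B
    signature: {CD45: high, Igk/Igl: "+", IgM: "+", CD38: "-"}
  - name: IgM memory B cell
    lineage: B
    signature: {CD45: high, Igk/Igl: "+", IgM: "+", CD38: "+"}
  - name: switched memory B cell
    lineage: B
    signature: {CD45: high, Igk/Igl: "+", IgM: "-", CD38: "+"}
  # -- catch-alls (not phenotype rows; required by the branch logic) -------
  - name: unclassified T cell
    lineage: T
    signature: {CD45: high, CD3: "+"}
    catch_all: true
  - name: B cell unresolved
    lineage: B
    signature: {CD45: high, Igk/Igl: "+", IgM: "-", CD38: "-"}
    catch_all: true
  - name: B cell artifact
    lineage: B
    signature: {Igk: "+", Igl: "+"}
    catch_all: true
  - name: other
    lineage: none
    signature: {}
    catch_all: true
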