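# Methods

This note documents the models, parameter choices and numerical conventions
behind `imclesion`, and what the synthetic-scene tests do and do not show
about real tissue.

## Image model and preprocessing

An acquisition is a set of per-marker ion-count grids on a shared pixel
lattice with physical pixel size `pixel_size_um` (default 1.0 µm, the laser
spot size). Line-scan exports are reconstructed row-major: shot *i* maps to
pixel `(i // row_width, i % row_width)`. A truncated final line is padded
with zeros (with a warning) by default; strict mode errors instead, since
acquisition truncation is common but should be visible.

**Despeckling.** Isolated hot pixels — a known detector artifact — are
removed by gray-level morphological opening. The "radius 1" structuring
element is the 4-connected cross (a digital disk of radius 1); a 3×3 square
is selectable. Opening is anti-extensive and idempotent: it deletes any
bright feature that cannot contain the element (single pixels, 1-px tips of
rasterized disks, ribbons thinner than 3 px) and leaves larger interiors
exactly unchanged.

**Limit-of-detection normalization.** Each channel is divided by
`μ + 3σ` computed over the analysis mask. The *population* standard
deviation (divide by N) is used: the masked image is the entire population
of shots, not a sample. Statistics are computed after ROI outlining,
gray-matter exclusion and despeckling, in that order, and include
zero-valued (unablated) pixels — the formula references the whole image. An
all-zero channel has no detection limit; it is returned as zeros with a
`degenerate` flag so gating treats it as uniformly negative rather than
producing NaNs.

**ROI masks.** Polygons use (x=column, y=row) coordinates, 0-based; a pixel
belongs to the mask when its center lies inside the ROI polygon and outside
every exclusion polygon. Mask area in mm² is the true-pixel count times
`pixel_size_um² / 10⁶`.

## Segmentation

Nuclei: Gaussian blur (`gaussian_sigma_px`, default 1.5), threshold (Otsu on
the blurred channel by default; a fixed value can be supplied — the
appropriate value depends on staining intensity and is deliberately
configuration, not a constant), then a watershed seeded at local maxima of
the blurred image with minimum separation `peak_min_distance_px` (≈ one
nucleus radius, default 4). Components under `min_nucleus_area_px`
(default 9 px) are dropped.

Cytoplasm: nuclei are expanded by `expansion_radius_px` (default 3 px ≈
3 µm, a typical thin cytoplasmic rim at this resolution); contested pixels
join the nearest nucleus, so cells stay disjoint and nuclei never shrink.

Marker refinement: for each configured rule (marker set, threshold on mean
normalized intensity), a positive cell's footprint is replaced by the
connected marker-positive components touching its nucleus, clipped to
pixels not owned by other cells and always retaining the nucleus. Rules are
applied in order and a cell is refined at most once (first-listed set
wins); refinement is territory-preserving by construction, which resolves
conflicts the acquisition itself cannot.

Cells touching the frame border are kept and flagged (`on_border`);
densities use all kept cells.

## Gating

Classification runs through three mutually exclusive branches in the order
B → T → myeloid; since each branch's entry condition excludes the defining
markers of the others, the order cannot change assignments for
rule-consistent cells. Every cell receives exactly one class; anything
matching no branch is "other".

- *B*: CD3⁻CD4⁻CD8α⁻CD68⁻, CD45 above the high gate, and at least one Ig
  light chain positive. Igκ⁺Igλ⁺ cells are artifacts (allelic exclusion
  forbids co-expression). Subsets by IgM × CD38: naive (IgM⁺CD38⁻), IgM
  memory (IgM⁺CD38⁺), switched memory (IgM⁻CD38⁺); IgM⁻CD38⁻ B-lineage
  cells are retained as "B cell unresolved" rather than dropped.
- *T*: Igκ⁻Igλ⁻IgM⁻CD68⁻, below the *myeloid-level* HLA gate, CD45-high,
  CD3⁺. CD4 × CD8α quadrants give CD4/CD8 T cells; double-positive and
  double-negative cells are "unclassified T cell". Functional subsets:
  chronically activated (CD38⁺ and HLA above the *activation-level* gate)
  takes precedence, then activated-and-proliferating, proliferating
  (Ki67⁺), activated (NFAT1⁺).
- *Myeloid*: CD3⁻CD4⁻CD8α⁻Igκ⁻Igλ⁻IgM⁻ cells on the TMEM119 × CD45 plane:
  TMEM119⁺ with any CD45 → microglia; TMEM119⁻CD45-high → macrophage;
  both-low → "other" (parenchymal cells). CD68⁺PLP⁻ marks activated and
  CD68⁺PLP⁺ demyelinating subsets (ingested myelin protein inside the
  phagocytic compartment).

HLA carries two distinct thresholds because it plays two roles: a high
"myeloid-level" cutoff excludes professional antigen-presenting cells from
the T branch, while a lower "activation-level" cutoff scores HLA as a T-cell
activation antigen. A single cutoff cannot satisfy both uses, so
`GateConfig` holds both, analogous to the two-level CD45 gate.

Seed-based fitting places each threshold at the midpoint on
`log10(x + ε)` intensity between the largest negative and smallest positive
seed (ε = 10⁻³ of the channel scale, handling zeros); overlapping seed
ranges raise an error naming the conflicting cells. Markers without seeds
require manual thresholds.

The phenotype signatures ship as an editable YAML rule table
(`imclesion/rules/table2.yaml`); `classify_cells` validates it against the
measured panel and rejects duplicate signatures at load time.

## Morphometry

Vessels are 8-connected collagen-positive components retained only when
area > 800 µm² **and** diameter > 10 µm, both strict — the printed bounds
use ">", and the boundary case (exactly 800 µm²) is rejected. "Diameter"
defaults to the equivalent circular diameter `2√(area/π)`; a minor-axis
(min-Feret-like) definition is available via config since the quantity is
otherwise underdetermined for elongated vessels.

Distance is measured from the cell *centroid* to the nearest pixel of the
retained regions' border (exact nearest-neighbor search over border pixels,
so it agrees with exhaustive search to machine precision); centroids inside
a region score 0. Cell-boundary reference is left as a config extension
point. Cells in frames with no retained vessel have undefined distance and
are excluded from class means. Density matrices put 0 for absent classes
(zero is data); distance matrices put n/a (a mean over nothing), serialized
literally as `n/a`.

## Validation statistics and embedding

Spearman correlation ranks both vectors (average ranks on ties) and takes
their Pearson correlation. The p-value uses the t-approximation with n − 2
degrees of freedom by default; for n ≤ 7 the exact two-sided permutation p
over all n! orderings is computed automatically (available on request up to
n = 9, where enumeration is still feasible but slow). Constant vectors
leave r undefined and are flagged rather than raising.

Embedding features (CD3, CD4, CD8α, CD38, CD45, HLA, Ki67, NFAT1, vessel
distance) are mapped through `log10(x + ε)` (ε = 10⁻³ of each column's
scale) and z-scored per column; zero-variance columns are dropped with a
warning. The embedding itself is an adapter: the default backend is a
deterministic diffusion map — Gaussian kernel on the k-nearest-neighbor
graph (k = 100 by default, matching the workflow's neighborhood size;
adaptive bandwidth at the k/3-th neighbor), symmetrically normalized,
eigendecomposed, coordinates from the top two non-trivial eigenvectors
scaled by eigenvalue^t (t = 8), with a fixed sign convention so repeated
runs are bit-identical. Any diffusion-geometry embedding honoring the
(k, determinism) contract — e.g. a PHATE implementation — can be swapped in
through the `backend` hook. Cluster naming/annotation is manual and out of
scope.

## Synthetic scenes

The generator emulates what the pipeline consumes, not detector physics.
Each cell is a disk nucleus (radius 3–5 px) with a painted cytoplasmic
footprint (nucleus + 4 px); each marker level is one log-normal draw per
cell (σ = 0.12 cell-to-cell dispersion) around class-specific means taken
from the rule table: positives at 20 counts, negatives at 0.2, DNA at 30,
CD45 at 6/30 (low/high), HLA at 5/25 (activation/myeloid). Vessels are
tubes of configurable radius with collagen fill (25) and a ~2 px CD31
endothelial rim; ambient myelin (PLP = 8) fills non-lesion stages outside
cell footprints. Poisson resampling adds shot noise; speckles are isolated
pixels set to 120 counts at 2 per 10⁴ pixels per channel. Default frames
are 500×500 px (0.25 mm²) with per-stage compositions of ~120–300 cells
chosen to echo the qualitative picture of lesion staging (microglia
dominate control white matter; demyelinating phagocytes and lymphocytes
fill active lesions). Centers are rejection-sampled at ≥ 17 px spacing
(≥ 2.5× the largest nucleus radius, and wide enough that painted
footprints of neighbors cannot contaminate measured means); an optional
touching-pairs mode places centers at 1.2× the summed radii to stress
watershed splitting. Gates can be derived from the generating means
(geometric midpoints between adjacent levels divided by each channel's
limit-of-detection denominator) or fitted from seeds.

Because positive/negative levels are separated by ~100× and cells are
spatially isolated, a passing pipeline demonstrates *correctness of the
computational chain* — index bookkeeping, threshold logic, geometry — not
robustness to the hard parts of real tissue: overlapping and irregular
cells, marker spillover between neighbors, autofluorescence-like
background structure, channel crosstalk, or antibody-performance
variation. Those failure modes require real acquisitions and are exactly
why the thresholds stay configuration rather than constants.

## Problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own study design: 0.25 mm² scenes of ~300 cells (one per
lesion stage for the cross-stage correlation, n = 7), 10,000 random marker
vectors for the gating oracle, 20-cell/2-vessel distance fixtures, and a
~150-cell pooled T table for the embedding. All randomness flows from
explicit seeds.

## Known limitations

- The vendor's binary MCD container is not parsed; inputs are text exports
  or TIFF.
- No channel spillover / isotope-impurity correction (none is applied in
  the emulated workflow either).
- Segmentation is 2D and intensity-based; no membrane models or learned
  segmentation.
- Densities are reported descriptively; no inferential comparison across
  lesions is provided.
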