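# Methods

## Scope and design

`lungplex` reimplements, as a tested pipeline, the single-cell analysis of
cyclic multiplex immunofluorescence of mouse lung: image alignment across
staining rounds, autofluorescence subtraction, DAPI-based nuclear
segmentation, per-cell marker quantification, graph-based phenoclustering,
signature-driven cell typing, composition and transporter statistics, and
virtual tissue-microarray (TMA) core-size validation.  Because no real image
data ships with the package, a first-class synthetic generator produces
multi-round image stacks with per-cell ground truth; every quality gate in
the test suite is phrased against that ground truth.

## The marker panel

The packaged panel (`lungplex/data/table1_panel.yaml`) encodes the
24-antibody, 11-round staining design: per marker a staining round, a
fluorescence channel (FITC / TRITC / FARRED; DAPI is the implicit
counterstain in every round), the host species/isotype as metadata, and the
cell types the marker labels.  Channel assignments per round are consistent
with the secondary-antibody set of the design (one fluor per marker per
round); their only functional role is that FITC and TRITC receive
autofluorescence subtraction.

23 of the 24 markers form the classification set used for clustering and
typing; BCRP is carried as measured-only.  P-gP, the multidrug transporter,
is *in* the classification set — it is constitutively expressed and so
carries clustering information — but has no lineage signature (ANY in every
row of the signature matrix), so it never contributes to type scores.

The signature matrix is derived mechanically from the panel's target lists:
POS where the marker labels the type, ANY for measured-only markers, NEG
otherwise.  The transitional AT phenotype is POS for both the AT1-only set
(AQP5, PDPN, RAGE, HOP) and the AT2-only set (SPD, NKX2-1, ABCA3), plus the
pan-epithelial PanCK.

## Synthetic tissue model

The generator is the package's study-condition definition; its defaults are
fixed and the tests run against them.

**Geometry.** Nuclei are placed by hard-core dart throwing (minimum spacing
9 µm) inside a circular core or rectangular section at 1 µm/px.  The default
2 mm-core preset places 6,100 cells, chosen so that the expected *segmented*
count matches the ~6,000 cells-per-core scale of the study design (observed:
6,006 at seed 1).  A configurable fraction (default 5%) of nuclei is placed
deliberately touching a neighbour to exercise the watershed split and the
hybrid-signature artifact path.  Vasculature and myofibroblast/smooth-muscle
cells lie on random Bezier tubes (endothelium on the centerline, mural cells
offset ~5 µm), bronchial/goblet cells line larger tubes, and all other types
are uniform.  Stromal and myofibroblast nuclei are 3:1 ellipses (area
preserved), reproducing the known weakness of nucleus-based segmentation for
elongated cells; everything else is round.  Nuclear radii are normal
(3.5 ± 0.45 µm, clipped).

**Composition.** The normal-lung preset uses the published composition
(AT1 22, AT2 14, transitional 32, bronchial/goblet 7, endothelium 3,
myofibroblast/SMC 2, other stromal 0.7, T 7, B 3, macrophage 4,
neutrophil 1 — in percent).  Those values sum to 96.7, so the preset
normalizes them to fractions summing to 1; the normalized values stay well
inside each type's published between-animal SD.  Cell types are drawn
i.i.d. from the composition, so single-section fluctuations are binomial.
For multi-animal experiments, per-animal composition is a Dirichlet draw
around the preset (concentration 60, giving a 3–5 percentage-point SD for a
20–30% type — the scale of the published between-mouse spread).

**Intensities.** Per (type, marker): truncated normal on [0, 255].  POS
pairs use 140 ± 45 (a ~32% CV, typical of immunofluorescence mean
intensities); NEG pairs 12 ± 8; DAPI 185 ± 25.  Transitional AT expresses
both alveolar marker sets at a reduced 0.7× level, mirroring a
continuum-like intermediate phenotype while keeping a discrete oracle
label.  P-gP is painted in every cell at 60 ± 20, scaled by the treatment
multiplier.  Each cell carries a log-normal staining factor (σ = 0.12)
shared across its markers, emulating cell-to-cell staining variability and
correlating marker brightness within a cell.

**Rendering.** Nuclei are anti-aliased ellipses on a per-channel float
canvas; marker signal covers the nucleus plus a 2 px perinuclear ring.
Autofluorescence is a low-frequency texture plus constant (FITC 26 + 12,
TRITC 14 + 7, none in far red), also emitted as a blank reference round.
Each round is warped by a random rigid motion (≤ 10 px translation, ≤ 2°
rotation; round 1 is the reference), then camera noise (σ = 3) is added and
the image is quantized to 8 bit.  Identical parameters and seed give
bit-identical stacks.

**Tabular fast path.** `cell_table_from_truth` emits a measured-like cell
table directly from ground truth (measured = 0.88·true + 0.12·background +
noise), skipping pixels.  The large sampling experiments (whole-section TMA
validation, the 25-sample time course) use this path at problem sizes of
~17k–52k cells; pixel-level fidelity (registration, segmentation, feature
extraction) is validated separately on rendered cores, where the measured
AT1 AQP5 means track the per-cell generative values with a median ratio of
1.00.

**Treatment presets.** Composition weights per time point encode the
fibrosis course qualitatively: transient AT1 dip, progressive AT2 +
transitional decline to day 21, monotone stromal rise with a late
myofibroblast component, late decrease of macrophages / neutrophils / B
cells, near-recovery at day 28.  P-gP multipliers rise in every type after
treatment (1.35/1.65/1.8/1.25 at d7/d14/d21/d28) except bronchial/goblet
(1.0 throughout); the mesenchymal compartment (stromal and
myofibroblast/SMC, which merge into the major "stromal" class) starts one
week late (1.0 at d7).

## Registration

Rigid model (rotation + translation), matching what a slide re-mount
produces.  Both images are band-limited (Gaussian, σ = 1) so the rotation
score is comparable between the un-warped θ = 0 candidate and interpolated
ones.  Rotation: coarse search (±3°, 0.25° steps) on a 4× downsampled pair,
fine search (0.05° steps) at 2× with parabolic sub-step refinement, scoring
by the un-normalized phase-correlation residual (the phase-whitened variant
saturates under broadband noise).  Translation: phase correlation at 20×
subpixel upsampling on the rotation-corrected pair.  On rendered stacks the
planted motion is recovered to ≲ 0.02° and ≲ 0.1 px, against acceptance
bounds of 0.1° and 0.5 px.  Resampling is bilinear with zero fill and
round-half-up back to 8 bit.  AF subtraction is pixel-wise
max(marker − AF, 0) on the aligned stack, FITC and TRITC only.

## Segmentation

Global isodata threshold (the closest documented equivalent of the ImageJ
"Default" method; Otsu and fixed cutoffs are exposed), Euclidean distance
transform, watershed seeded at h-maxima of the distance map (h = 1), size
filter (min 20 px², max 10× the median nucleus area).  Pseudo-cells are
nuclei expanded by 2 px with nearest-label tie-breaking, so expanded regions
partition the grown foreground and never merge.  On well-separated round
nuclei the detector exceeds 0.95 precision and recall; recall on the
elongated stromal preset is lower by design and only the ordering is
asserted.

## Phenoclustering

Directed kNN (k = 30, Euclidean on the 0–1 rescaled classification markers,
no PCA — 23 dimensions is small), symmetrized; edge weight is the Jaccard
index of the two endpoints' neighbour sets, where a cell's set is itself
plus its k neighbours (so identical neighbourhoods give weight exactly 1);
zero-weight edges are dropped.  Louvain modularity optimization runs on
igraph's C implementation; nodes are visited in a seed-derived permutation
and igraph's RNG is pinned to the same seed, so a (matrix, seed) pair always
yields the identical partition.  Clusters are relabelled by decreasing
size.  tSNE/UMAP embeddings call the standard implementations and are
visualization-only.

## Classification

Marker positivity per cluster is decided from the across-cluster
distribution of cluster means.  Two rules are implemented:

* `z` — positive above mean + z·SD of the cluster means (z = 1): simple,
  but biased when a marker is genuinely positive in many clusters.  With
  ~half of all clusters alveolar, the alveolar markers' cutoffs climb above
  the transitional-AT level and mid-level clusters get miscalled; we
  observed a whole T-cell cluster discarded this way.
* `kmeans` (default) — exact 1-D two-means split of the cluster means,
  positive class above the boundary, guarded by a minimum between-class
  contrast of 0.08 (below it, the marker is called negative everywhere).
  This tracks bimodality regardless of how many clusters are positive.

Cluster scores are `#POS matched − #POS missed − penalty·#NEG violated`
(penalty 1), argmax with ties broken by a fixed type-priority order; a
cluster positive for both AT1-only and AT2-only markers is transitional AT.
Discards: positives spanning ≥ 2 exclusive lineage compartments
(epithelial / hematopoietic / stromal / vascular) — the hybrid signatures
juxtaposed elongated cells produce — and clusters with no positive lineage
marker ("null phenotype", standing in for the unpublished
"uninterpretable" criterion).  Major types: alveolar (AT1 / AT2 /
transitional retained as sub-labels), bronchial/goblet, vasculature,
stromal (incl. myofibroblast/SMC sub-label), T, B, macrophage, neutrophil.

End to end on the default rendered core, ≥ 85% of centroid-matched cells
are correctly typed at the major level and the discard fraction stays below
10% (observed ~98% and ~0%).

## Quantification and TMA adequacy

Composition percentages are over classified cells only (artifact clusters
excluded from all denominators); group statistics are unweighted mean ± SD
(two-pass, ddof = 1) across samples.  Transporter summaries are Tukey
boxplots (1.5×IQR whiskers) of rescaled 0–1 intensities per (type, group).
Time-course similarity uses the L1 distance between composition vectors.

A virtual core is the set of cells strictly inside a circle; core layouts
are packed greedily, largest first.  "Population rediscovered" is
operationalized as: after independently re-clustering and re-classifying
the core with the whole-section configuration, some cluster is assigned
that population with ≥ 20 cells and ≥ 0.6 per-cell signature purity
(fraction of members whose nearest POS/NEG template, by cosine similarity,
matches the assigned type).  A core is adequate when nothing identified on
the whole section is missing.  In the packaged 4 + 4 design on the default
5.2 mm synthetic section, 2 mm cores are adequate and 1 mm cores are not:
at ~1,500 cells per 1 mm core the rarest population (neutrophil, 1% → ~15
cells) drops below the identifiability threshold.  Note the marginal
population under these clean synthetic conditions is the 1% type, not the
4% macrophage that is marginal in real-data noise; only the core-size
direction, not the identity of the failing population, generalizes.

## Reproducibility

Every stochastic stage consumes a sub-seed derived from one master seed
(`SeedSequence`); the pipeline writes a config hash, per-stage timings and
counts next to its outputs, and identical config + seed reproduces
byte-identical tables on the same platform.

## Problem sizes

Defaults used by the experiment protocols: one rendered 2 mm core of 6,100
cells for the full-pipeline composition recovery; a 5.2 mm tabular section
(~52k cells) with four 2 mm and four 1 mm cores for TMA validation; five
time points × 3 animals × 2,500 cells, jointly clustered (~37k cells), for
the treatment course.

## Limitations

* The generator draws marker intensities independently per cell given type
  (plus one shared staining factor); it does not model spatial intensity
  gradients, bleed-through between channels, stripping artifacts, or focus
  variation.
* Misalignment is rigid; real slides can deform non-rigidly.  Elastic
  registration is out of scope.
* Segmentation is nucleus-based by design; signals from adjacent cells can
  leak into a pseudo-cell.  The hybrid-discard rule handles the cluster-level
  consequence, but per-cell leakage remains in the feature table.
* Passing tests show the analysis recovers the generative structure under
  these conditions; they cannot show robustness to real-microscopy artifacts
  the generator does not emulate.
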