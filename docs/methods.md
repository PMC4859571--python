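# Methods

## The screen as a ranking device

The screen contrasts expression energy between two voxel sets of an
annotated volume — a vulnerable anterior region of interest (lobules
II/III) and a resistant posterior one (lobule X), both restricted to
|ML| ≤ 1400 µm from the midline — treating every selected voxel as a
replicate observation of its region. Voxels within one sagittal plane of
an in-situ-hybridization atlas derive from the same experiment and are
not independent samples, so on real atlas data the p-, q- and adjusted
p-values are ordering devices, not calibrated inference; the calibration
results below hold under the independence the synthetic generator
actually provides. This is why the pipeline narrows by rank (top N per
route) and then by absolute expression criteria rather than by a
significance cutoff.

## Statistical routes

**Student's t.** Classical pooled-variance two-sample t with
n₁ + n₂ − 2 degrees of freedom, two-sided, signed as
mean(resistant) − mean(vulnerable); Bonferroni adjustment multiplies by
the number of *tested* genes and caps at 1. Pooled variance (not Welch)
is the default because the screen's reference analysis used the plain
Student test; a Welch variant would be a one-line change in
`diffexpr.t_screen` but is deliberately not a config knob. Degenerate
input conventions: both groups constant and equal → (t, p) = (0, 1);
constant but unequal → signed infinity with p = 0, flagged rather than
silently dropped.

**SAM.** Relative difference d(i) = (x̄₂ − x̄₁)/(s(i) + s₀) with
s(i) = pooled SD × √(1/n₁ + 1/n₂), so d with s₀ = 0 *is* the t statistic
(an identity the tests assert exactly). The fudge factor s₀ is chosen
from the percentiles 0, 5, …, 100 of the per-gene scatters, minimizing
the coefficient of variation of the median absolute deviation of d
across 10 contiguous s-quantile windows; zero-scatter genes are excluded
from the windows, ties resolve to the smallest candidate, and fewer than
10 usable genes fall back to median(s). Ten windows (rather than the 100
sometimes used at microarray scale) keep the window MADs stable at the
few-thousand-gene sizes this package targets.

The permutation null uses balanced (group-size-preserving) label
assignments: all C(n, n₁) of them when that count is ≤ 10 000, otherwise
B = 1000 sampled assignments (seeded). Expected order statistics d̄(i)
are means of the sorted permuted d. For a threshold Δ the calling
cutoffs are asymmetric: scanning outward from the d closest to zero, the
first sorted position whose observed-minus-expected deviation reaches +Δ
sets the upper cutoff, symmetrically below; the FDR estimate is the
median permuted count of d beyond the cutoffs divided by the observed
called count, capped at 1 (no null-proportion correction). A gene's q is
the smallest estimated FDR at which it is called, then forced monotone
non-increasing in |d|. On all-null data the observed d distribution
matches the permutation null, so the procedure is conservative: at the Δ
targeting FDR 0.05 it typically calls nothing, and the realized pooled
false-call rate measured by `evaluation.sam_null_false_call_fraction`
sits far below the target.

**Top-N union.** Each route contributes its best N genes (ascending p
with |t| then gene_id tie-breaks; descending |d| with gene_id
tie-breaks); the default N = 1000 matches the screen's full-scale
setting, and the union — not an intersection — advances, since the two
routes are known to disagree at the margin.

## Curation surrogates

The original narrowing was human image review. Two reproducible
surrogates stand in:

* **Detectability in exactly one ROI** — detect fraction = share of ROI
  voxels with energy > `threshold` (default 0: any positive energy);
  detectable when that share ≥ `min_fraction` (default 0.1). Both knobs
  are exposed because the by-eye criterion has no unique numeric
  translation; the defaults make "undetectable" mean essentially no
  signal while tolerating a few artifactual positive voxels.
* **Survival-pattern concordance** — Pearson correlation (affine
  invariant, hence the min–max rescale is presentational) between the
  gene's per-lobule mean-energy profile inside the midline corridor and
  the reference survival pattern, requiring |r| ≥ 0.7. The reference
  pattern maps lobule X → 1, II/III → 0 and graded intermediate values
  VI = 0.4, VII = 0.45, VIII = 0.3, IX = 0.6 — "patchy" survival is not
  quantified anywhere, so these are modeling choices: IX above VIII
  encodes the spared caudal aspect of lobule IX, VII slightly above VI
  the spared VI/VII boundary region. All values are configurable. At 7
  segments the null probability of |r| ≥ 0.7 is ≈ 8%, which is
  acceptable because the detectability filter removes broadly expressed
  null genes first; a planted lobule-X-restricted gene scores ≈ +0.77
  against the default pattern, an anterior-restricted one ≈ −0.77.

Classification follows the detectability direction — posterior-restricted
genes are candidate neuroprotective, anterior-restricted candidate
susceptibility — and a concordance sign contradicting the region raises a
conflict flag instead of dropping the gene. Candidates are clustered with
average linkage (1 − Pearson correlation across genes, Euclidean across
voxels), the standard choice for expression heatmaps; leaf order is
deterministic given identical input. Term over-representation uses the
hypergeometric upper tail on a user-supplied gene→term table with
α = 0.01 and, matching the screen's original report, no multiplicity
correction by default (Bonferroni across terms behind a flag). The
enrichment universe defaults to the tested genes, not all atlas genes.

## Synthetic atlas

The generator emulates only the statistical structure the screen
consumes:

* **Geometry** — an axis-aligned block partition of a
  (anterior-posterior × dorsal-ventral × medio-lateral) grid into seven
  lobule segments II, III, VI, VII, VIII, IX, X inside a cortical slab,
  rest background; default 40×20×29 voxels at 200 µm, one hemisphere with
  the midline at ML index 0. The screen reads only labels and ML
  coordinates, so curved cortical geometry would add nothing testable.
* **Noise model** — energy = Bernoulli(detected) × LogNormal(µ, σ), with
  (µ, σ) moment-matched to a target mean and coefficient of variation
  (default cv 0.3): non-negative, zero-inflated, right-skewed, matching
  "expression energy" semantics. Null genes express everywhere with mean
  `background_energy` (default = `effect_energy` = 2.0) and per-voxel
  dropout `zero_inflation` (default 0.3); planted genes express only
  inside their lobule set (X, or II∪III) with mean `effect_energy` and no
  dropout, zero elsewhere.
* **Plane batches** — optional per-gene, per-sagittal-plane log-normal
  factor (`plane_batch_sd`) shared by all voxels of a plane, reproducing
  the same-plane dependence of real hybridization data; with it enabled,
  within-plane correlation of log-energies across genes exceeds
  across-plane correlation (property-tested by permutation).

What the generator does **not** emulate: expression restricted to the
Purkinje-cell layer within a lobule, signal bleed from neighboring cell
types, imaging artifacts, parasagittal stripe patterns, and graded (as
opposed to all-or-none) regional differences. Consequently, passing
recovery tests show the pipeline's machinery is correct and calibrated
under its own assumptions — they do not show that a real atlas screen
would achieve similar sensitivity, which at full scale was limited
precisely by the artifacts the generator omits (hence the original
reliance on manual curation).

## Problem sizes and numerical choices

Null-calibration experiments run many seeds, so they use a reduced
14×5×3 grid (~54 ROI voxels per gene) with the same noise model; the
planted-recovery experiment uses the full default geometry (2000 genes,
20 + 20 planted, 20 seeds). The tiny-instance SAM check (20 genes, 3 + 3
voxels) enumerates all 20 balanced permutations and is compared exactly
against a loop-written oracle.

Determinism: one global seed fans out through a `SeedSequence` to the
atlas and permutation streams; gene order is lexicographic, voxel order
is raster order, every ranking has a total tie-break (statistic, then
gene_id), and output tables are written with fixed float formatting, so
identical (config, seed) reproduce outputs byte for byte. Missing voxel
values are excluded pairwise per gene; genes with fewer than two usable
voxels in either group are reported untested. The ROI lateral bound is
inclusive (≤ 1400 µm), voxel physical positions are voxel centers, and
the bound applies to |ML| so mirrored hemispheres select identically.

Volumes are stored either as one minimal ASCII-encoded NRRD per gene or
as a single long-format TSV (gene_id, x, y, z, energy); both routes are
round-trip tested to produce identical matrices. The NRRD codec is
intentionally small (NRRD0004, ascii encoding, C-order data) — enough for
lossless self-interchange of these grids, not a general NRRD reader.

## Known limitations

* The curation surrogates approximate a human judgment; on real data the
  posterior/anterior split they produce can only approximate curated
  lists.
* SAM's FDR estimate omits the null-proportion factor; with many true
  positives it is conservative.
* The screen's headline full-scale gene counts depend on the external
  atlas and human review and are out of scope here by design.
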