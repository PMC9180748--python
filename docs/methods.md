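# Methods

## Differential-expression calling

The DEP caller treats the quantitation table as the unit of analysis:
peptide-to-protein roll-up, DIA spectral processing and batch
correction are out of scope — the table is assumed to carry one
normalized (or normalizable) intensity per protein per sample plus the
search engine's unique-peptide count and identification FDR.

Four filters are applied per protein, in order:

1. **unique peptides ≥ 2** — quantitation reliability;
2. **identification FDR < 0.01** — this is a *search-engine
   identification confidence* carried in the input table, not a
   multiple-testing correction of the ANOVA p-values. The two cannot
   be the same quantity: a 1% FDR correction of the p-values would
   make the separate raw p ≤ 0.05 gate vacuous. A Benjamini–Hochberg
   adjustment of the ANOVA p-values is nevertheless available behind
   `DEPParams(bh_correct=True)` for sensitivity analysis (via
   `scipy.stats.false_discovery_control`);
3. **fold-change magnitude ≥ min_fc** — `fc_signed` is the ratio of
   arithmetic means of normalized *linear* intensities (matching the
   "averaged, normalized intensities" convention; geometric/log means
   would be the natural alternative but change the meaning of the FC
   gate), `fc_magnitude = max(r, 1/r)`. The gate is inclusive (≥).
   Defaults: 1.5 for cell-line comparisons, 1.3 recommended for
   mouse-brain datasets;
4. **one-way ANOVA p ≤ 0.05** — `scipy.stats.f_oneway` on the two
   compared groups, on linear intensities by default with a log2
   option (`log_scale=True`); with two groups this is exactly the
   pooled-variance two-sample t-test (F = t²), which the tests verify
   numerically to 1e-10.

**Normalization.** The default `median-scale` rescales every sample so
its median over the proteins observed in *all* samples equals the
grand median of those proteins; this is scale-equivalent, which is all
that ratio statistics require. `none` passes data through for
pre-normalized tables.

**Missing data.** Cells absent from the input stay missing — they are
excluded from means and ANOVA, never imputed or zero-filled. A protein
with fewer than two observed replicates in either compared group is
*untestable*: it is excluded from calling and reported with a reason.

**Degenerate inputs.** All-equal values within and across groups give
F = 0 and p = 1 (scipy returns NaN for the 0/0 case; the package maps
it to 1). Zero or negative group means abort fold-change computation
with an error rather than emitting ±inf.

## Lysosomal-confidence scoring

The scheme is a weighted union of seven evidence sources in three
layers (see README for the award table). Numerical choices worth
recording:

* The **UniProt-keyword award is 2 points by inference**: the source
  text enumerates awards for every other criterion and a 14-point
  ceiling; 2 is the only value consistent with that ceiling
  (2+2 layer 1, 2+2+2+2 layer 2, 2 layer 3). It is configurable in
  `ScoringScheme.membership_points`.
* **hLGDB and mLGDB form one combined 2-point criterion** (presence in
  either database), again the only reading consistent with the
  ceiling. Multiple catalogs may be registered under the `lgdb`
  source; membership in any of them counts.
* **Compartments bands**: confidence ≤ 2 → 0 points, strictly between
  2 and 4 → 1, in [4, 5] → 2. Values outside [0, 5] are input errors,
  not clipped, because the source resource is bounded at 5. When
  several Compartments entries match one protein the highest
  confidence wins.
* **Tier bands overlap at 6** in the printed definition ("3–6" high
  vs "6–14" very high); 6 is assigned to the higher tier (vHC),
  configurable via `vhc_min`.
* **Conflicting layer-1 categories** (a protein listed both SwissProt
  and TrEMBL in the bovine source, or EL and Misc in the rat source)
  resolve to the higher-scoring category with a logged warning; inside
  a single scoring call they are rejected as contradictory.
* **Cross-species matching is by uppercased gene symbol** (accessions
  are tried first for same-species catalogs). Orthology mapping would
  be more precise but requires an external service; symbol matching is
  the only offline option and its limitation — paralog collapse,
  unmatched renamed genes — is accepted and documented here.

Scoring is monotone by construction: adding any positive observation
never decreases the total or the tier. The test suite verifies the
total against an independent hard-coded award table over all 432
combinations of distinct-scoring observations.

## Cross-model overlap

`common_deps` is a plain harmonized set intersection across model DEP
lists. `build_overlap_matrix` restricts this study's scored proteins
to tiers HC ∪ vHC (the tiers shown in cross-study comparisons),
matches them by symbol/accession against external NCL-study gene
lists, and keeps rows with at least one external hit. Direction of
dysregulation is carried when available but never affects matching —
layer-3 evidence is presence-based. No third-party gene lists are
bundled; the external sets are user-supplied files (or synthetic ones
from the generators).

## Lipid-droplet quantification

The chain re-implements the classic particle-analysis recipe rather
than wrapping an external GUI tool:

1. **Denoising** — Gaussian smoothing, σ = 1 px by default
   (`smooth_sigma_px`, 0 disables). Pixel noise roughens the
   thresholded boundary, inflating perimeter estimates and biasing
   circularity low (a noisy in-focus droplet can fall from ≈0.9 to
   below the 0.6 gate); light smoothing restores the underlying shape
   while leaving geometry tests on clean masks untouched.
2. **Local thresholding** — foreground iff intensity > mean of a
   square window (default 51 px, odd, reflective borders) + offset.
   The local-threshold family has many variants; windowed
   mean-plus-offset is the simplest reproducible one. The offset is in
   image intensity units (default 0.4, suited to the unit-amplitude
   synthetic images; rescale for 8/16-bit data). Objects approaching
   the window size hollow out — a known property of local
   thresholding; the window must be chosen larger than the largest
   droplet diameter.
3. **Particle analysis** — 8-connected components
   (`skimage.measure.label`); area = pixel count × pixel size²;
   perimeter = marching-squares sub-pixel contour length
   (`skimage.measure.find_contours` at level 0.5), summed over all
   contours of the component. This weighted boundary-segment estimate
   was chosen over chain-code and Crofton formulas because it is the
   only one of the three that keeps digitized polygons near their
   analytic circularity (square → 0.809 vs π/4 ≈ 0.785; 4:1 rectangle
   → 0.515 vs 0.503) while giving disks values that rise with
   digitization fineness (0.79 at r = 5 px to ≈0.90 at r = 200 px).
   No single perimeter estimator is simultaneously exact for
   axis-aligned polygons and asymptotically exact for smooth curves;
   this one brackets the 0.6 gate correctly from both sides, which is
   what the classification needs. Circularity 4πA/P² is clipped at 1,
   mirroring common particle-analysis tools.
4. **Gating** — kept iff circularity > 0.6 *and* area > 3 µm², both
   strict inequalities (an object of exactly 3 µm² is discarded).
5. **Nucleus counting** — Gaussian smoothing (σ = 1 px), global Otsu
   threshold, 8-connected components, discard below
   `min_nucleus_area_um2` (default 10 µm²). Otsu always returns *some*
   threshold, including on signal-free noise where the foreground
   would percolate into spurious giant components; a robust guard
   therefore requires the threshold to exceed the background level
   (median + 3 × MAD-based SD) and reports 0 otherwise. Touching
   nuclei are not split (no watershed) — a documented limitation;
   planted-nucleus tests use non-overlapping geometry, and overlaps
   are flagged in the simulation truth.

`droplets_per_cell = droplet_count / nucleus_count`; with zero nuclei
the droplet count is still reported and the ratio is `None`
(undefined), never 0 or inf. All counts are invariant to uniform
intensity scaling with proportionally scaled offset.

## Synthetic data

The generators emulate the statistical structure each stage assumes —
and only that structure:

* **Quantitation matrices**: per-protein baseline log2 intensity
  uniform on [18, 30] (spanning a realistic precursor-ion dynamic
  range; the value itself cancels in ratio statistics), group effect
  ±`effect_log2` in every non-reference group for a planted fraction
  `frac_dep` of proteins (sign random per protein so up- and
  down-regulation are both exercised), i.i.d. Gaussian noise on the
  log2 scale. Default conditions: 1000 proteins, two groups × 3
  replicates, 10% planted DEPs, 2-fold effects, σ = 0.1 log2 units.
  Unique-peptide counts are uniform on {1..10} and identification FDRs
  uniform on [0, 0.05], *independent of the planted effect* — so the
  static gates remove ≈10% and ≈80% of proteins respectively
  regardless of truth. Caller performance against planted truth is
  therefore evaluated *conditional on the identification filters*
  (among proteins passing the peptide/FDR gates and testable), the
  usual notion of differential-expression power. What the generator
  does **not** model: missing-value mechanisms of data-independent
  acquisition, peptide-level roll-up, intensity-dependent variance,
  batch effects — a passing planted-recovery test shows filter logic
  and power under idealized noise, not robustness to real MS
  pathology.
* **Annotation catalogs**: a latent lysosomal label (probability
  `p_lyso`, default 0.3) drives per-source membership
  (sensitivity 0.9 / false-positive rate 0.05 by default). Categorical
  sources pick SwissProt/TrEMBL or EL/Misc uniformly among positives;
  Compartments confidences are uniform on [2.5, 5] for members and
  [0, 2] for non-members (the [2, 2.5] gap keeps the synthetic bands
  away from the 2-point boundary). Real annotation sources are
  correlated with each other; the generator's conditional independence
  makes the scored separation cleaner than reality.
* **Images**: anti-aliased unit-amplitude disks (boundary pixels
  weighted by approximate coverage, avoiding degenerate perimeters for
  small disks) plus additive Gaussian noise; `1/noise_sigma` is the
  per-pixel SNR. 512×512 px at 0.1 µm/px by default. No point-spread
  function, no uneven illumination, no autofluorescence background.

All generators are pure functions of their parameters and seed
(NumPy `default_rng`), giving byte-identical outputs for identical
inputs — the basis of the end-to-end determinism tests.

## Problem sizes

Statistical checks run at sizes where their expected behavior is
sharp: null and planted DEP simulations at 2000 proteins (binomial
fluctuation of the null call rate ≈ 0.5%), p-value uniformity at
10,000 simulated ANOVAs, planted-fraction convergence at 10,000
proteins, droplet recovery over 20 seeded 512×512 px fields with 3–12
droplets of radius 1.2–1.8 µm at SNR 5 — droplets comfortably inside
the threshold window, the regime the gates are designed for.

## Known limitations

* Symbol-based cross-species matching (see above).
* No watershed splitting of touching nuclei or droplets.
* Local thresholding hollows out objects comparable to the window.
* ANOVA on linear intensities inherits log-normal skew; the log2
  option is provided where normality matters more than the FC
  convention.
* The scoring scheme's award values are faithful to their published
  definition; the package deliberately does not re-derive the
  underlying resources' own confidence calls.
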