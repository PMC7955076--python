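# Methods

This note documents the models and procedures implemented in `msntx`, the
assumptions behind them, the parameters that matter, and what the synthetic
data generator does and does not emulate.

## Morphometric similarity networks

For one subject, let `M` be the region × feature matrix of multimodal
morphometric measurements (defaults: surface area, cortical thickness, gray
matter volume, Gaussian curvature, mean curvature, fractional anisotropy,
mean diffusivity). Each feature column is z-normalized across regions
(sample SD, `ddof=1`; the choice of denominator is documented because field
usage varies) so that features with different native units contribute
equally. The MSN is the region × region matrix of Pearson correlations
between regions' z-scored feature vectors, diagonal set to zero. The
per-region statistic is the **regional strength**: the signed sum of a
region's correlation weights to all other regions — negative weights are
included, with no normalization.

Optional density thresholding keeps the top `d` fraction of off-diagonal
entries. Ranking is by **signed** value by default (largest correlations
kept): the strength statistic sums signed weights and its interpretation
depends on negative entries, so discarding the most negative edges first is
the consistent convention; ranking by absolute value is available via
`rank_by="absolute"`. Ties break by (row, column) lexicographic order of the
upper-triangle entry. Kept-edge sets are nested across densities.

Pearson correlation over only 7 feature points is noisy by construction;
no per-edge significance filtering is applied, matching standard MSN
practice.

## Case-control regional statistics

Per region, ordinary least squares of strength on an intercept, a case
indicator, and covariates (age in years, sex coded 0/1, education in years;
total intracranial volume can be added for a sensitivity model):

    strength_i = β0 + βg·group + β1·age + β2·sex + β3·education

The t-map is the per-region two-sided t statistic of βg (contrast =
case − control), residual df = n − k with k the number of design columns.
Sex coding affects only the intercept. Multiple comparisons across regions
use Benjamini–Hochberg FDR; every FDR call states its family (regions,
systems, genes) in its output. The implementation is a vectorized
normal-equations solve shared across regions; `statsmodels.OLS` serves as
the independent oracle in the tests.

Quadrant classification combines the sign of the regional t with the sign
of the control-group mean strength: negative t with positive mean strength
is *decoupling*; positive t with negative mean strength is
*dedifferentiation*; the two remaining strict-sign quadrants are labelled
`coupled_increase` and `differentiated_decrease`; exact zeros map to
`null` because the two named quadrants leave boundaries undefined.

System-level aggregation averages each subject's strengths within each
labelled system (functional networks or cytoarchitectonic classes) and
refits the same contrast per system, with FDR across systems.

Symptom correlations are per-region Pearson correlations of strength with a
clinical score, case subjects only by default (pooled mode available; the
case-only default reflects that symptom scales are meaningful in patients).

## Spatial permutation (spin) nulls

Parcel centroids live on the unit sphere. A spin draws a uniform random
rotation of SO(3) (quaternion method), applies it to the left-hemisphere
centroids (and its x-mirrored twin to the right hemisphere in two-hemisphere
scope), and reassigns each parcel to a rotated parcel by greedy one-to-one
matching in ascending distance order, ties broken by lower region index.
Each permutation is a bijection within each hemisphere's index block, so
spun maps preserve the value multiset and the spatial autocorrelation
structure.

Permutation p-values are +1-corrected: p = (1 + #{null at least as
extreme}) / (n + 1). This can never be exactly zero, remains valid input to
FDR, and reproduces the raw percentile rule in the limit. Two-sided p is
2·min(one-sided) capped at 1.

By convention the engine spins the first map argument, and callers pass the
MSN-derived map; gene expression stays fixed.

## Expression preprocessing (six steps)

The multi-donor microarray bundle (per-donor expression, detection calls,
sample coordinates, probe annotations, plus an RNA-seq-like reference) is
reduced to a left-hemisphere region × gene matrix:

1. **Re-annotation** — probes with missing, ambiguous (multi-gene) or
   contradicted gene annotations (against an independent mapping) are
   dropped.
2. **Intensity filtering** — a probe is kept if its detection-call rate,
   pooled across all donors' samples, is ≥ 0.5 (per-donor mode available;
   pooling is the default reading of "across participants").
3. **Probe selection** — one probe per gene: the probe whose region-averaged
   profile has the highest Spearman correlation with the reference profile;
   genes missing from the reference fall back to highest mean intensity;
   ties go to the lowest probe id. (Regional profiles require the sample
   assignment of step 4, which is a pure function computed once and shared;
   the *filtering* order of the steps is unchanged.)
4. **Sample assignment** — each sample maps to the nearest region
   representative point if within `max_distance` (default 2.0 distance
   units); right-hemisphere samples are excluded in the default left-only
   mode, since expression coverage of the right hemisphere is too sparse to
   analyze.
5. **SRS normalization** — per gene within each donor, the scaled robust
   sigmoid x′ = 1/(1+exp(−(x−median)/IQR)) followed by min–max rescaling to
   [0, 1]; genes with zero IQR become the constant 0.5 and are flagged, not
   fatal.
6. **Differential stability (DS)** — per gene, the mean over donor pairs of
   the Spearman correlation between the two donors' regional profiles over
   shared regions (≥ 3 required; Spearman is invariant to the monotone SRS,
   so filtering after normalization is equivalent to filtering before).
   Retention is by top DS fraction (default mode) or a DS minimum
   (`ds_min`, e.g. the 0.1 convention); the exact cut-off that real studies
   used is not derivable, so it is configuration, never hard-coded.

Donor aggregation normalizes per donor first, then averages donors within
region; regions with no donor coverage are dropped and logged. Full
provenance counts (probes in/out per step, samples assigned, genes
surviving DS) are recorded.

## PLS1 imaging-transcriptomics regression

With X the region × gene matrix (columns z-scored by default — SRS outputs
live on [0, 1] with unequal variances) and y the t-map restricted to the
covered left-hemisphere regions, the first PLS component has the closed
form w = X_c′y_c / ‖X_c′y_c‖ for a univariate response, identical to the
first NIPALS component (verified against scikit-learn's `PLSRegression` in
the tests). Regional scores are X_c·w; variance explained is the squared
Pearson correlation of scores with y (the response-variance reading;
the fraction of predictor-block variance captured is reported alongside,
since "variance explained" is ambiguous for PLS). The component's sign is
fixed so scores correlate positively with y, making "PLS1−" reproducibly
mean "expression high where t is low".

Significance of the variance explained comes from refitting against spun
versions of y (default 5000 spins). Per-gene uncertainty comes from
bootstrap resampling of **regions** — the observational units of this
regression; subjects are already collapsed into the t-map — with each
replicate's weights sign-aligned to the original (global flip when the dot
product is negative); Z = weight / bootstrap SE, two-sided normal p, BH-FDR
across genes. Gene lists apply both |Z| > 5 and q < 0.005; with a large
bootstrap the two nearly coincide, and both are applied because both
conventions exist. Degenerate bootstrap resamples (constant response) are
redrawn.

Per-gene map correlations (for prior disease-gene panels) use Pearson r
against y with a two-sided spin p and FDR across the supplied panel.

## Gene-list statistics

- **DGE correlation** — Spearman correlation between PLS gene weights (or
  Z) and differential-expression values over the genes shared with the
  direction-filtered DGE set (≥ 3 required). The permutation null shuffles
  which gene carries which (value, direction) pair — "relabelling the
  dysregulated sets across all DE genes" with values travelling with their
  labels. This preserves per-direction counts and, critically, the
  label–value coupling: direction is typically the sign of the value, and
  relabelling directions against their own values is measurably
  anticonservative (~11% rejection at α = 0.05 in our null calibration),
  whereas the gene-assignment shuffle is exactly exchangeable under the
  null (~5%, verified).
- **Cell-type overlap** — observed overlap of a gene list with each of the
  seven canonical cortical cell classes (astrocytes, endothelial cells,
  excitatory neurons, inhibitory neurons, microglia, OPCs,
  oligodendrocytes); the null redraws size-matched gene sets from the
  background universe (resampling the *cell set*, per the procedure's
  wording; resampling the list instead is available behind a flag);
  p = (1 + #{null ≥ obs})/(n+1), FDR across the seven classes. The
  permutation p converges to the hypergeometric upper tail (tested at
  n_perm = 50,000). The background universe defaults to the post-DS gene
  universe and is explicitly configurable, because overlap statistics are
  background-sensitive.
- **Cell-type maps** — per class, the mean regional expression over the
  genes shared between the list and the class set.
- **List overlap OR** — 2×2 table over the background (both, a-only,
  b-only, neither); OR with Haldane 0.5 correction when a cell is zero;
  two-sided Fisher exact p (scipy), cross-checked against full
  enumeration of tables with small margins.

## Synthetic data generator

The generator exists so every downstream stage can be tested against known
ground truth; its defaults mirror the study conditions the analysis is
designed for (308 parcels, 154 per hemisphere; 7 features; age/sex/education
covariates; 6 donors; 3 probes per gene; 50% detection threshold; 2.0
assignment distance).

- **Atlas** — a deterministic quasi-uniform (Fibonacci) lattice over the
  x < 0 hemisphere, mirrored to the right; system labels by contiguous
  latitude bands (a 7-band functional scheme and a 5-band cytoarchitectonic
  scheme).
- **Spatial autocorrelation** — every regional field is a Gaussian process
  with squared-exponential covariance exp(−d²/2ℓ²) on great-circle distance
  d; `smoothness` = ℓ in radians (default 0.4–0.5). Spin tests are only
  meaningful on autocorrelated maps. The true autocorrelation structure of
  real MSN maps is unknown; the kernel is a stand-in, not an inference.
- **Cohort** — subject matrices are a shared smooth profile (features mixed
  through a random loading matrix with a decaying spectrum, so profiles
  share a dominant subspace as multimodal morphometry does) plus smooth
  covariate-effect fields scaled by standardized covariates plus i.i.d.
  subject noise (`noise_sd`, default 1 latent unit). Features are then
  mapped to native units (mm², mm, mm³, …) by fixed affine transforms so
  the z-scoring step does real work. Participant tables carry group, age,
  sex, education, TIV, and HAMD/HAMA scores (cases high, controls low).
- **Planted group effect** — in each effect region, a case subject's
  feature profile is *rotated* toward (direction +1) or away from (−1) the
  sum of all other regions' standardized profiles, by a step of
  `effect_size · noise_sd / √F` in the column-standardized domain. Because
  a region's strength equals the inner product of its standardized profile
  with that sum, the strength change is an emergent, sign-controlled
  consequence of the MSN computation — strengths are never shifted
  directly. Modifying an effect region also perturbs every other region's
  strength through their shared edges; a diffuse secondary group contrast
  across the cortex is therefore an expected, realistic feature of the
  planted data, not a defect.
- **Expression bundle** — per-gene regional profiles are smooth fields;
  planted genes instead mix in the planted contrast map with weight
  |loading| and the loading's sign. Each gene's probe 0 reproduces its
  profile with highest fidelity; other probes are degraded by mixing in an
  independent field plus bias and noise, so reference-based probe selection
  has a true answer. Samples sit at donor-jittered positions near the left
  centroids on a brain-sized sphere (radius 75 distance units, so the
  2.0-unit assignment threshold, the 0.6-unit jitter and the deliberately
  far samples are all meaningful); small fractions of far and
  right-hemisphere samples exercise the distance and left-only filters.
  Detection calls are absent below the donor-specific 20th-percentile
  intensity (configurable; any monotone rule suffices for testing the
  50% filter). Optional probes with missing/ambiguous/contradicted
  annotations and background-level probes exercise steps (i) and (ii); the
  generator records bookkeeping counts from its own artifacts so pipeline
  provenance can be checked exactly.
- **DGE table** — planted genes receive values c·loading + √(1−c²)·noise
  (c = `corr_strength`; c = 1 is an exact monotone map), background genes
  pure noise; direction is the value's sign.
- **Cell sets** — seven classes by default, sizes configurable, optional
  enrichment fraction drawn from the planted genes; classes may overlap, as
  real cell classes do.

What the generator does **not** emulate: realistic cortical geometry or
surface meshes, image-level artifacts, realistic gene co-expression
topology beyond smooth fields plus planted signal, batch structure between
donors beyond probe bias, or site effects between cohorts. Passing tests
therefore demonstrate the correctness and calibration of the *procedures*,
not performance claims about real MRI or microarray data.

## Strong-signal study conditions

`strong_signal_settings()` ships the documented conditions used by the
recovery tests and the acceptance script: 60+60 subjects, 154 regions per
hemisphere, 7 features, 16 effect regions at effect size 3.5, 2000 genes
with 100 planted (5%) at loadings 0.75–0.95, 6 donors, 200 samples per
donor, 30 bad-annotation and 60 background probes, 999 spins, 1000
bootstrap replicates, Z threshold 5. The loading floor and effect footprint
were chosen while designing the fixture so that the planted signal
genuinely dominates the smooth background field: lower loadings put
correct-signed genes in the |Z| ≈ 3–5 range, and a smaller footprint lets
the rotation-based planting saturate in regions whose baseline profile
already points away from the consensus. Under these conditions the study
recovers ≥ 90% of effect regions at FDR < 0.05 and ≥ 80% of planted genes
in the correct PLS1 list across seeds.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] after the matrix product; MSN
  matrices are symmetrized by averaging before the diagonal is zeroed.
- Constant feature columns, constant region profiles, constant symptom
  scores, zero-variance responses and rank-deficient designs raise named
  errors rather than propagating NaNs.
- Thresholding keeps ⌈d·P⌉ of the P upper-triangle pairs (so the kept-edge
  count is always even over the full matrix and nested across densities).
- Greedy spin matching breaks distance ties by lower region index; the
  cited rotation-matching approach leaves ties unspecified.
- All generators and permutation engines draw from
  `numpy.random.default_rng` with explicit seeds; identical (seed,
  parameters) give bit-identical outputs, and the pipeline manifest
  records config hash, seeds and output checksums (and deliberately no
  wallclock timestamp, so reruns are byte-identical).
- Pipeline problem sizes in the shipped demo config (40 parcels per
  hemisphere, 40+40 subjects, 400 genes, 4 donors) are chosen so a full
  end-to-end run completes in seconds; the strong-signal study (above) runs
  in about a minute on one CPU.

## Known limitations

- The analysis is parcel-level throughout; vertex-level spinning and
  variogram-matched nulls are out of scope.
- Only the first PLS component is estimated and tested; multi-component or
  sparse variants are not implemented.
- The DS cut-off reproducing any particular real study's gene count cannot
  be derived from first principles and must be supplied.
- Graph-topological MSN metrics (modularity, degree distributions) are
  deliberately absent; the strength statistic is the analysis target.
- Pathway/GO enrichment depends on an external knowledge-base service and
  is not reproduced; only the list-overlap odds-ratio component of the
  validation analysis is.
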