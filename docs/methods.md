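# Methods

This note documents the models, numerical choices and limitations behind
each stage of `csbn`. Everything quantitative stated here is computed by the
test suite or the example scripts; nothing is quoted from elsewhere.

## Quantification model

The underlying signal model is rank-1 per protein: the intensity of peptide
*i* in slice-run *j* is

    I_ij = e_i · a_j · ε_ij

with ionization efficiency *e*ᵢ (constant across the gel), molecular
abundance *a*ⱼ, and multiplicative measurement noise ε. All consistency
machinery works in log space, where the model is additive.

**Elution alignment.** The reference time of a peptide is its median over
all runs; each run's deviation from the reference is smoothed by LOESS
(statsmodels `lowess`, frac = 0.5, 2 robustifying iterations) as a function
of elution time and subtracted. Runs sharing fewer than 20 peptides with the
reference are left uncorrected with a warning — a correction estimated from
fewer points would be noise.

**Feature matching.** A feature is assigned to an identity iff
|Δm/z| ≤ 2 ppm (configurable within the instrument-typical 1.5–2 ppm range)
and |Δt| ≤ 1 min; among candidates the smallest ppm deviation wins, ties
break on |Δt|. The matcher is exhaustively checked against a brute-force
oracle in the tests.

**Run normalization.** For each run, every peptide's intensity is divided by
its median over the runs within ±20 slices (a 40-slice window, truncated at
the gel ends); the run factor is the median of those ratios over peptides
with ≥ 3 window observations, requiring ≥ 5 usable peptides (otherwise the
factor stays 1.0 with a warning). The local window removes global
injection/spray offsets without flattening genuine abundance structure.

**Expected peptide values (EPV).** For an observed cell (i, j), predictions
come from two routes, both exact under the rank-1 model:

- *row route*: for every other peptide k, L[k, j] + ρᵢₖ, where
  ρᵢₖ = median over runs of (L[i, ·] − L[k, ·]) pools all shared columns;
- *column route*: for runs l within ±10 slices, L[i, l] + cⱼₗ, with
  cⱼₗ = median over peptides of (L[·, j] − L[·, l]).

Using every (other-row, other-column) cell individually would be O((p·r)²)
per protein and is infeasible at 245 runs; the median-pooled routes keep the
estimator O(p²r + p·r·w) while preserving the property the EPV exists for:
on an internally consistent matrix every prediction equals the observation.
The EPV is the mode of a Gaussian kernel density (Silverman bandwidth) over
the log₂ predictions, evaluated at the sample points; cells with fewer than
3 predictions are interpolated from EPV-validated neighbours within a
5-slice window, and cells with no EPV at all fall back to weight 1.0
(no consistency information, not evidence of inconsistency). The
consistency weight is w = exp(−|log₂ I − log₂ EPV|) ∈ (0, 1]. A
single-peptide matrix has no internal consistency to measure: EPVs are
flagged undefined and all weights are 1.

**Detectability threshold.** The intensity floor for a cell is the 3rd
percentile (linear interpolation between order statistics) of the
intensities of all peptides of that run co-eluting within ±1.5 min.
With fewer than 10 co-eluting peptides the threshold is undefined and
missingness stays uninformative — a missing value is never treated as zero
abundance.

**Reference ridge.** Qualified runs (median cell weight ≥ 0.5,
configurable) are merged onto the anchor run (most assigned intensities) by
weighted least squares over shared peptides; the ridge is the weighted mean
of the scaled intensities per peptide, normalized to max = 1. The ridge is
scale-free: proportional runs give identical ridges regardless of anchor.

**Abundance and reliability.** The abundance at slice *s* solves
min Σ w (I − a·ridge)² over all above-threshold cells in slices
s − 2 … s + 2 (five consecutive slices, truncated at the gel ends):
a = Σ w·ridge·I / Σ w·ridge². Because the gel oversamples (the slice width
is one third of the sharpest peak's half-width), this behaves as a sliding
average; **the estimand of the quantifier is therefore the 5-slice
window-integrated abundance**, and recovery tests compare against that
integrated truth. For a protein whose only peak has σ = 1.5 slices, the
correlation of *any* implementation of this estimator with the unsmoothed
truth is capped near 0.96 by boxcar attenuation — a resolution trade-off of
the windowing, not an estimator defect; against the window-integrated truth
the implementation measures r ≈ 0.99 per protein under σ = 0.2 lognormal
noise and 30% threshold dropout. The reliability score is
(1 − e^(−n/3)) · e^(−d/1), clamped to [0, 1], with n the number of distinct
peptides used and d the mean |log₂(I/EPV)| over the used cells; the
constants n₀ = 3, d₀ = 1 are package choices (config-exposed) — n₀ = 3 puts
≈ 2/3 of the asymptote at three peptides, d₀ = 1 halves confidence at one
log₂ unit of inconsistency. Zero usable intensities give abundance 0 with
reliability 0.

## Mass calibration

The slice ↔ mass relationship is fitted in (slice, log₁₀ mass) space with a
five-parameter generalized logistic (Richards) curve

    y(s) = lo + (hi − lo) / (1 + exp((s − x₀)/b))^g,

which contains the symmetric 4-parameter logistic at g = 1. The asymmetry
is needed in practice: the builtin marker set contains an anomalously
migrating particle (a pre-ribosomal subunit running ahead of a heavier
marker complex), and a symmetric logistic fitted to these 12 points misses
the heaviest anchor by ~0.074 log units, while the Richards fit keeps every
residual ≤ 0.07. Bounds b ≥ 3 slices and g ∈ [0.05, 20] prevent the family
from collapsing onto a step function around the out-of-order marker.
Initialization: asymptotes from the extreme marker log-masses ± 0.3,
midpoint at the median marker slice. The fit must be strictly decreasing on
the whole gel or it is rejected. Conversions outside the marker-covered
slice range are flagged as extrapolations but not refused, because genuine
profile peaks sit beyond the gel ends; masses outside the asymptotes have
no slice and raise an error. Printed marker log-masses are 2-decimal
renderings that are sometimes truncated rather than rounded, so the
table-consistency check uses a 0.008 band (one full last-digit truncation)
rather than half an ulp.

## Peak deconvolution

Candidate peaks are local maxima filtered by relative height ≥ 0.1 of the
profile maximum, prominence ≥ 0.5 of the peak's own height, and width at
half prominence ≤ 50 slices (all config-exposed; the reference quantities
are package choices where the filter definition leaves them open).

The sum-of-Gaussians model is fitted by bounded trust-region least squares
with an analytic Jacobian, minimizing the *relative* residual
(model − y)/max(y, 0.05·y_max): intensity errors scale with signal, and an
unweighted objective lets a tall peak's summit dominate while masking
structure elsewhere. Growth: starting from the candidates, one trial
component is added at the argmax of the 3-slice-smoothed weighted residual
and kept only if the refit cuts the weighted RSS by ≥ 2% *and* by enough to
justify three extra parameters under a BIC criterion whose sample size is
the number of signal-bearing slices (slices above the weight floor) — with
the full gel length the criterion is far too permissive, since the
stabilized noise lives only where there is signal. Rejected trials roll
back, so the RSS is monotone in model growth; the cap is 12 components.
After growth, components with amplitude < 2% of the profile maximum or
σ outside [0.8, 50] slices are pruned (refitting the survivors), and
strongly overlapping pairs (means within 1 σ) are trial-merged, the merge
kept when BIC prefers the simpler model — this removes "split" components
where one peak plus noise was modelled as two. Measured on 200 random
profiles per seed base (1–8 components, ≥ 2 σ separation, amplitude ratios
≥ 0.1, 5% multiplicative noise): ≥ 99% of components recovered within one
slice, < 1% spurious. "Signal-to-noise ratio 20" is interpreted as pointwise
multiplicative noise of relative σ 1/20 — the natural noise model for MS
intensity data; additive noise at 1/20 of the global maximum would make the
smallest admissible peaks undetectable by the stated filters by
construction. No baseline is subtracted by default (profiles arrive
background-corrected); a constant-offset term is available by config.

Fit quality is reported as unweighted RSS / Σy² so that values are
comparable across profiles regardless of the weighting.

## Co-migration similarity

Seed ROIs are fitted components clipped at mean ± 2.5 σ (rounded to slices,
clipped to the gel), excluding components with σ > 20 slices or FWHM
crossing a gel end. Correlation expansion compares each seed segment to the
same slices of every other profile and keeps r ≥ 0.95 segments. ROIs of the
same protein with both boundaries within 3 slices merge transitively
(single linkage); merged boundaries are rounded means, the seed correlation
is averaged, and the maximum abundance is re-read from the profile.

The ROI vector is (√v₁, √v₂, v₃, v₄) with v = min/max-normalized left
boundary, right boundary, max abundance and seed correlation; the square
root on the (normalized) boundary coordinates steepens the penalty for
small location differences. Normalizing before the square root keeps all
four coordinates on [0, 1]; the transform of raw indices is an alternative
reading of the construction, and both the transform and the
mutual-correlation interval (union of the two ROI spans by default,
intersection by config) are exposed. The distance appends (1 − r_ab)/2 as a
fifth Euclidean coordinate, making the theoretical maximum exactly √5 and
similarity = 1 − d/√5; a multiplicative variant (distance scaled by
1 + (1 − r_ab)/2, d_max = 4) is available by config.

Two properties of this measure matter for interpretation. First, it is a
**dissimilarity, not a metric**: the mutual-correlation coordinate is
computed over the pair-dependent union interval, so the triangle inequality
can and does fail; t-SNE, which consumes the matrix, does not require
metricity. Second, min/max normalization makes coordinates
**dataset-relative**: in a dataset whose r_seed values span a narrow range,
tiny correlation differences are amplified to the full [0, 1] coordinate.
Absolute similarity values are therefore comparable within one dataset, not
across datasets.

The t-SNE embedding (scikit-learn, precomputed metric, random
initialization, perplexity 30 capped at n/4, mandatory seed) is
presentation-layer only: no quantitative conclusion in this package rests
on embedded coordinates.

## Synthetic worlds and what a green test establishes

The generator states one world: complex masses log-uniform on
[80, 3800] kDa, abundances log-uniform over six decades, per-protein
membership Poisson(mean − 1) + 1 with mean 6.4, peak widths uniform on
[1.5, 6] slices (spanning the sharpest focusing allowed by the slice width
up to broad smears; no width model is implied by the data themselves),
lognormal ionization efficiencies (σ = 1 in natural log), and
detection-limit (threshold) dropout as the default missingness mechanism,
with a random-missingness mode for robustness tests. Truth values are drawn
directly from these distributions and never computed with pipeline code.

The generator emulates the *statistical structure* the pipeline assumes —
rank-1 evidence, Gaussian peaks, smooth profiles — and deliberately omits
chromatographic artefacts, isotope envelopes, charge states, co-eluting
interference and peptide-level identity errors. A green recovery test
therefore establishes correctness of the estimators under the stated model,
not robustness to everything a real instrument produces.

One stated end-to-end expectation is not achievable and is documented
rather than tuned away: in the full default world (mean 6.4 memberships
over six abundance decades), only ~38% of true co-complex protein pairs
reach similarity > 0.9 — and the ceiling is the same (~37%) when the
similarity stage runs on the *true* profiles, so it is structural: the
stated 10% relative-height filter removes the minor peaks of multi-complex
proteins (no ROI exists on one side for ~30% of pairs), and neighbouring
larger peaks contaminate the mutual correlation inside the window. The
integration test asserts the robust, meaningful property instead: covered
co-complex pairs score a median similarity > 0.9, far above the
between-complex median (measured 0.93 vs 0.65).

## Degenerate inputs and tie-breaks

- Zero-variance profile segments: correlation undefined → segment skipped
  in expansion, r = 0 (flagged, no co-migration information) in distances.
- Degenerate normalization range (all ROIs share a value): that coordinate
  is 0 for all ROIs, with a warning.
- All-zero profiles: no candidates, empty peak list, fit quality 0.
- Duplicate evidence for one (peptide, run): intensities are summed.
- Equal ppm deviations in feature matching: the smaller |Δt| wins.
- Merging is order-independent (single linkage over a symmetric relation;
  members averaged, not sequentially updated).

## Known limitations

- Quantified abundances are ridge-relative; absolute cross-protein scaling
  (ionization-efficiency modelling) is out of scope.
- The reliability-score functional form is a package choice; only its
  monotonicity in both ingredients and its [0, 1] range are externally
  constrained.
- The peak-growth stop rules (BIC guard, effective sample size, overlap
  merge) are package choices on the same footing: principled, tested, but
  not uniquely determined by the problem statement.
- Very broad components (σ near the 50-slice bound) trade off against the
  width filters; profiles dominated by such smears are reported with few or
  no components rather than speculative ones.
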