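# Methods

`floromics` reimplements, as a tested library, the computational core of a
stage-resolved multi-omics analysis of Arabidopsis flower opening: isotope
tracer quantification (¹⁴C label partitioning and ¹³C mass-isotopologue
correction), stage-profile statistics, thresholded correlation networks,
and the RNA-seq count funnel, together with a synthetic-data generator that
stands in for the raw measurements.

## Developmental staging

Florets are sampled at eight stages spanning roughly eight days of
development; anthesis — the bud-to-open-flower transition — occurs at
stage S13, 11.50 days. Ages are 7.25, 9.25, 10.25, 11.50, 13.25, 13.50,
14.25 and 15.25 days; three stages precede anthesis and four follow it.
The standard flower-staging nomenclature offers only three labels after
anthesis, so the two young-open-flower samples taken six hours apart are
distinguished as S14a and S14b. The age of the youngest stage is reported
ambiguously in the source material (7.25 vs 7.29 days); it is plain
metadata here, defaulting to 7.25 d, and no computation depends on the
choice.

## ¹³C mass-isotopologue correction (`isotopes`)

A measured MID `m` (fractions of M+0..M+n, n = tracer carbons) is modelled
as `m = C x`, where `x` is the tracer-labelling distribution and column `j`
of `C` is the natural-abundance mass-shift distribution of the species with
`j` tracer-derived carbons: the remaining `C_total - j` carbons and all
heteroatoms sit at natural isotope abundance, and each tracer carbon is
heavy with probability equal to the tracer purity (default 1.0,
configurable). Mass shifts beyond M+n fall outside the measured window, so
columns sum to at most one.

The correction solves `min ||C x - m||` subject to `x >= 0` (non-negative
least squares) and renormalizes `x` to sum to one. Non-negativity inside
the fit, rather than inverting and clipping, preserves the sum-to-one
guarantee under noise. Mean fractional enrichment is
`E = sum_j j x_j / n`, and the tracer-derived amount of a metabolite pool
is `pool_amount * E` (ng·mg⁻¹ FW when the pool is in those units). This
product definition of the labelled amount is this package's declared
convention for "total ¹³C accumulation".

Default natural abundances: ¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364,
¹⁷O/¹⁸O 0.00038/0.00205, ²⁹Si/³⁰Si 0.04685/0.03092, ³³S/³⁴S 0.0075/0.0425;
P is treated as monoisotopic. All are configurable. Correction uses the
full fragment formula when it is known (GC-MS derivatization adds Si-rich
groups whose isotopes matter); when only the carbon backbone is known, a
carbon-only formula does a backbone-only correction.

Numerical notes: the matrix construction is exact convolution arithmetic
(no series truncation other than the M+n window), NNLS is deterministic,
and for abundances below 0.5 per isotope the matrix is well conditioned.
Noiseless forward-simulation/correction round trips recover `E` to ~1e-15.
Re-analysing a MID with extra trailing-zero label positions perturbs the
leading corrected fractions by ~1e-4 — the price of the M+n window — which
is why tests pin that stability at 1e-3 rather than machine precision.

## ¹⁴C label partitioning and fluxes (`flux`)

Per replicate, the redistribution fraction of compound class `c` is
`100 * Bq_c / metabolized`. The absolute synthesis flux over a feeding of
`t` hours is `(fraction/100 * metabolized) / (SA * t)` in nmol hexose
equivalents gFW⁻¹ h⁻¹. The biologically correct `SA` is the specific
activity of the internal hexose-phosphate pool; when only the
feeding-solution value is available (7 Bq/nmol here: 7 MBq per mmol
glucose), isotopic dilution is ignored and the fluxes are lower bounds —
recomputing the published fluxes this way lands 8–16% low, consistent with
that bias. No factor-of-two hexose-equivalent accounting is applied to
sucrose: the label already measures hexose-equivalent carbon.

Fluxes are computed per replicate and then averaged (mean of ratios),
matching how replicate feedings are reported; the ratio of means is
reported alongside because the two differ whenever replicates differ.
Label conservation (class Bq summing to the metabolized total) is checked
to a configurable 1% relative tolerance and violations warn rather than
silently renormalize. The fractionation recovery is a measured
pass-through quantity: it is never recomputed from uptake and metabolized
label, whose ratio measures something else.

## Stage-profile statistics (`profiles`)

Abundances are normalized per sample by fresh weight × internal-standard
response. Heatmap matrices are log₂ of the per-stage replicate mean (log of
the mean, not mean of logs), optionally z-scored per compound; ratio tables
divide every replicate value by the compound's reference-stage mean.

Group comparisons use two-sided Welch t-tests on the raw scale, from
replicate data or directly from (mean, se, n) summaries, with
Welch–Satterthwaite degrees of freedom. Welch was chosen because the
published phase summaries show strongly unequal standard errors (e.g. one
phase with se 25 next to one with se 213). Letters come from an
insert-and-absorb compact letter display at α = 0.05: groups sharing no
letter differ significantly; a bold flag marks significance at α = 0.01 in
at least one pairwise comparison. No multiple-testing correction is
applied across compounds, matching the raw 0.05/0.01 convention of such
tables.

A caveat found while validating: of the published letter patterns we
cross-check, the fructose and succinate rows reproduce exactly from the
printed summaries, but three rows (fumarate, glucose, citrate) print three
distinct letters where no standard two-sided t-test variant on the printed
(mean, se, n=3) values yields significance for one of the pairs (e.g.
citrate pre- vs postanthesis: p ≈ 0.16–0.22 depending on the variant).
Those checks are left failing rather than bending the test to match.

## Correlation networks (`networks`)

Pearson correlations are computed over pairwise-complete observations;
two-sided p-values use `t = r sqrt(n-2)/sqrt(1-r²)` on `n-2` df. Pairs
with fewer than `min_pairs` (default 3) shared samples are undefined.
Edges enter a network when the raw p-value passes 0.05 and |r| strictly
exceeds the threshold — 0.65 for metabolite–metabolite, 0.80 for
transcript–metabolite, 0.82 for transcript–transcript networks; ties at
the threshold are excluded. Thresholds written elsewhere as "r² > 0.65"
and "r² < −0.65" are interpreted as signed r, the only reading that admits
negative values. Benjamini–Hochberg correction is available but off by
default, matching the raw-P convention. Correlations run across all
stage × replicate samples by default (configurable to stage means; the
source material does not state which was used, and counts are sensitive to
the choice). Node statistics are degree and unnormalized shortest-path
betweenness centrality; isolated nodes are dropped. Networks export to
GraphML (typed attributes) and edge-list CSV.

## RNA-seq count funnel (`transcripts`)

Genes with fewer than 10 total counts across all samples are removed
("fewer than" is strict; a per-sample mode exists behind a flag).
Normalization is log₂ CPM with a pseudo-count of 0.5 per million — the
pseudo-count scales with library size so the transform is exactly invariant
under joint rescaling of counts and libraries. The smooth-trend filter
regresses each gene's log-CPM on a 3-df orthogonal polynomial basis of
floret age and F-tests it against the intercept-only model, with BH
correction across genes at FDR 0.05. The basis resolves a contradiction in
the source description ("second degree quadratic polynomial, df = 3" —
degree two has only two non-intercept df): a 3-df smooth polynomial keeps
the stated df and the smooth-and-gradual assumption, and the basis is
configurable. Stage contrasts are per-gene Welch t-tests with BH within
each contrast. Empirical-Bayes variance moderation is deliberately not
layered on top: the funnel's structure is what this module implements, and
with n = 3 per stage the unmoderated tests have full raw-p power for
4-fold changes but only partial recall at FDR 0.05 — a documented
difference from moderated pipelines. K-means (default k = 6, seeded, 10
restarts) clusters z-scored stage profiles and reports each cluster's
centroid step across the S12→S13 (anthesis) boundary, whose sign
identifies the clusters switching on or off at flower opening.

## Synthetic data (`simulate`)

The generators produce inputs with the structure the analyses assume, plus
the ground truth, so every stage is testable end to end; at zero noise each
generator is the exact inverse of its analysis counterpart.

* **Metabolite tables**: 8 stages × 3 replicates, default 130 compounds.
  Trend archetypes `up`, `down`, `peak_at_anthesis` (Gaussian bump at
  11.50 d, 1-day sd), `flat`, with log₂ fold ranges drawn U(1, 3);
  abundance = baseline × exp(trend) × lognormal noise. The default CV of
  0.2 reflects typical between-replicate variation of pooled-floret GC-MS
  measurements. Fresh weight ~30 mg and internal standard ~1.0, both at
  10% CV.
* **Count matrices**: negative binomial with mean
  `lib_size × exp(quadratic(age))` and variance `mean + φ·mean²`
  (default φ = 0.1, libraries 10⁶); a fraction of genes (default 5%) are
  planted at expected totals below the 10-count filter, and `frac_null`
  genes are flat.
* **MIDs**: binomial i.i.d. labelling per tracer carbon at enrichment E*,
  convolved with the natural-abundance signature, truncated-normal noise,
  renormalized.
* **¹⁴C partitions**: per class, `J* × SA × t × lognormal(cv)` with
  default n = 5 replicates at 30% CV; the default true fluxes are the ones
  implied by the published partitioning summary. Uptake is metabolized
  label divided by the observed metabolized-to-uptake ratio (0.95), and
  the fractionation recovery is an independent pass-through draw
  (0.58 ± 0.04).

What the generators do **not** emulate: chromatography and batch effects,
organ-level (within-floret) resolution, correlated noise between compounds,
and library-composition balance. The last one matters: because CPM divides
by the column sum, planting many strongly trending genes induces a residual
age trend in flat genes' log-CPM (the classic composition bias that
TMM-style normalization addresses). Calibration tests therefore normalize
by the nominal sequencing depth; analyses of real data with strong global
shifts should use a composition-robust library-size estimate. Passing
tests on these simulations show the estimators are correct under their
stated models, not that real floral data meet those models.

## Determinism and problem sizes

All randomness flows through explicit integer seeds into
`numpy.random.default_rng`; identical seeds give byte-identical outputs.
Calibration checks run at the study's own design sizes (24 samples; 129
compounds; 2,000 null genes; 500 replicate feeding simulations), which the
whole suite completes in seconds.
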