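# Methods

`arcex` is a two-part analysis toolkit for Arctic winter extremes: (1)
detection and trend analysis of extreme winter warming and rain-on-snow
events on daily gridded climate fields, and (2) a multilevel,
phylogenetically informed meta-analysis of the effects of such events on
the fitness of Arctic biota, with a spatial projection combining the two
parts. This note records the models, the defaults and why they were
chosen, the numerical decisions, and the known limitations.

## Event definitions

**Winter season.** October–March. The winter spanning Oct of year Y−1
through Mar of year Y is labelled Y, keeping every season's days
contiguous in time; all per-"year" outputs use this label. A complete
season has 182 days (183 with a leap 29 February).

**Extreme winter warming.** Per grid cell, the threshold is the 99th
percentile of winter daily maximum temperature over a baseline period
(default 1950–1980, using the complete winters inside it), with linear
interpolation between order statistics — the percentile convention is
recorded in the output because several conventions exist. A day
qualifies when its tmax strictly exceeds the cell threshold; maximal
runs of consecutive qualifying days form one event. The per-day
*exceedance* is tmax − threshold; the *annual cumulative exceedance* in
a cell-season sums exceedances over all its events' days.

**Rain-on-snow (ROS).** A day qualifies when all of: winter day; rain ≥
3 mm; snowpack ≥ 3 mm snow-water-equivalent; tmax > 1 °C. Runs of
qualifying days are candidates, retained only when the mean of the three
daily maxima after the run is below 0 °C — the refreeze that forms the
ice crust responsible for the ecological damage. Both moisture
comparisons default to inclusive (≥) with strict variants switchable in
`RosCriteria`, because "3 mm" thresholds are quoted ambiguously across
the ROS literature. The refreeze lookahead may use early-April days for
events ending in late March: the criterion tests physical refreeze, not
season membership. Candidates within three days of the end of the record
cannot be evaluated and are discarded into a diagnostics counter.

**Intensity.** For both event types, intensity is the day-weighted sum
of the event's own series — Σ_d series_d × d with d the 1-based day
index, exceedance (°C) for warming and rainfall (mm) for ROS. A two-day
warming event at 5 °C and 7 °C over a 3 °C threshold scores
(5−3)×1 + (7−3)×2 = 10; a two-day ROS event with 5 then 7 mm of rain
scores 5×1 + 7×2 = 19. The weighting emphasises sustained, late-event
conditions (prolonged thaw or rain on an already-wet pack); intensities
are treated as unitless scores.

**Missing data** in any required variable disqualifies the day and
breaks runs — conservative detection. Spatial aggregation to coarser
grids uses unweighted block means (per-variable reduction overridable);
a latitude-weighted mean is deliberately not the default.

## Trends and period contrasts

Event characteristics (length, intensity, maximum temperature, counts,
totals) are aggregated per season and region, then fitted with the
Theil–Sen estimator: the median of all pairwise slopes, robust to
outliers and non-normality. Significance comes from the Mann–Kendall
test (Kendall's tau against time, tie-corrected), the standard
nonparametric companion; ordinary least squares is available via
`method="ols"` for rates such as precipitation totals. Theil–Sen
intercepts are the median residual.

Period contrasts (baseline 1950–1980 vs modern 1990–2020 by default)
use a paired t-test with *grid cells as the pairing unit*: each cell
contributes its per-period mean, and the reported difference is modern −
baseline in the variable's units. Spatial dependence between cells is
assessed with a Mantel permutation test (Pearson correlation of
upper-triangle distances; one-sided permutation p with the +1
correction, p ≥ 1/(B+1); exhaustive enumeration available for small
matrices). The second distance matrix defaults to absolute differences
of the per-cell period-difference values — an interpretation choice,
stated here because "spatial autocorrelation of the grid data" can be
operationalised several ways.

Emergence is classified per cell: "new" (ROS events in the modern period
but none in the baseline), "vanished" (the reverse), "both-periods",
"neither", with proportions over cells reported.

Regions are axis-aligned lat/lon boxes (Northern Alaska, Northern
Fennoscandia, Svalbard, Yamal approximations ship as defaults); no
field-significance correction is applied across cells.

## Effect sizes (SMDH)

Control/response group summaries are converted to the standardized mean
difference with heteroscedastic population variances:

    s'²  = (s_c² + s_r²)/2
    d    = J(m) (x̄_r − x̄_c)/s',  m = n_c + n_r − 2
    J(m) = Γ(m/2) / (√(m/2) Γ((m−1)/2))
    var(d) = d²(s_c⁴/(n_c−1) + s_r⁴/(n_r−1)) / (8 s'⁴)
             + (s_c²/(n_c−1) + s_r²/(n_r−1)) / s'²

This matches the `escalc(measure="SMDH")` convention of metafor (R),
verified against it to ten digits on fixed inputs. The variance is a
delta-method (large-sample) expression: its own approximation error,
measured against parametric bootstraps, is about +11% at n=(6,6), +2% at
n=(10,12) and below 1% for group sizes ≳25. The bootstrap-oracle test
therefore checks settings with n ≥ 55 per group, where a wrong formula
would still show (typical implementation mistakes shift the variance by
tens of percent) but the expression's own asymptotic error is below
Monte-Carlo resolution at 10⁵ replicates; small-n settings are tested
with an explicit analytic-slack term.

**Direction harmonisation.** Effects are sign-flipped when an increase
in the response harms fitness (mortality, digging time), so negative
always means a fitness loss. Flags ship as an editable lookup (variable
name → ±1); records with unknown variables are quarantined, never
passed silently, and re-applying the flags raises.

**Groups from observational series.** When a study reports an annual
series instead of groups, extreme years become the response group and
the year immediately preceding each extreme year its control. Extreme
years are either stated by the study or classified by comparing the
study's environmental variable against the 99th percentile of baseline
winters in a 5°×5° box around the site. An extreme year without an
available preceding control year is dropped; a year may serve as
control for at most one extreme year (conflicts are logged); group n is
the number of years.

**Outliers.** Records with |standardized residual| > 3 under an
overall-mean random-effects model are removed in a single pass:
residual = (y − μ̂)/√(v_i + τ̂²) with τ̂² the REML between-effect
variance (common-effect standardization, τ̂² = 0, is switchable). No
refit-and-repeat; the filter is idempotent on its own output.

## Multilevel phylogenetic meta-analysis

The observed effects y follow

    y = Xβ + Z_study u + e + Z_sp s + Z_sp p + ε,
    V = σ²_study Z_st Z_st' + σ²_effect I + σ²_species Z_sp Z_sp'
        + σ²_phylo Z_sp A Z_sp' + diag(v_i),

with A the species correlation matrix from the phylogeny and v_i the
known sampling variances. Variance components are estimated by REML on
the log-variance scale (bounds e⁻³⁰..e¹⁰, L-BFGS-B, ftol 10⁻¹²) with
three starts — near-zero, method-of-moments split, and a perturbed
start — keeping the best; estimates below 10⁻⁸ are reported as exact
zeros. Fixed effects are generalized least squares at the REML solution;
CIs use normal (z) critical values, matching common practice (a
t-approximation is a documented alternative); the 95% prediction
interval adds all variance components to the coefficient variance. The
reported restricted log-likelihood is the kernel (it omits the constants
−(n−p)/2·log 2π and ½log|X'X| that some packages add). The fit was
cross-validated against an independent multilevel meta-analysis
implementation on a fixed dataset, agreeing to six decimals in the
pooled estimate, its SE and all four components; those values are frozen
in the test suite.

**Tree → correlation matrix.** Newick input; polytomies are resolved to
bifurcations by seeded randomization (the seed is a required argument
and is echoed into the fit diagnostics, because results at fine
taxonomic levels are sensitive to the randomized bifurcation); missing
branch lengths are set to 1 (cladogram rule); the tree is made
ultrametric by extending pendant branches to the deepest tip; then
A_ij = depth of the MRCA of i and j divided by total depth, unit
diagonal, validated symmetric positive semi-definite. Species in the
data but absent from the tree abort the phylogenetic fit rather than
being dropped. If no matrix is supplied, the phylogenetic level is
dropped and flagged in the diagnostics.

**Heterogeneity.** Multilevel I² with the typical sampling variance
v̄ = (k−1)Σw/((Σw)²−Σw²), w=1/v_i (the Higgins–Thompson form used in
multilevel meta-analysis; plain mean switchable and recorded in output
metadata). Total I² = Σσ²/(Σσ²+v̄); per-level shares use the same
denominator, so they sum to the total exactly.

**Moderators.** Categorical moderators are fitted without an intercept:
the first moderator gets one coefficient per level (each level's pooled
mean with CI and PI), further moderators are drop-first coded. Q_M is a
Wald chi-square on *level-difference contrasts* (df = Σ(levels−1)),
answering "do levels differ?"; the omnibus all-coefficients-zero variant
(df = number of coefficients), which some software reports as QM for
no-intercept models, is also computed (`q_m_omnibus`) since it answers
the different question "is any level nonzero?". Marginal R² =
var(Xβ̂)/(var(Xβ̂)+Σσ²) as a percentage. The first-authorship
publication-bias check is the two-level moderator fit with the Wald
contrast p-value.

## Synthetic-data generators

**Climate.** Daily tmax = per-cell offset + cosine seasonal cycle
(peak mid-July) + linear trend in whole years + stationary AR(1) noise;
precipitation occurs on random days with gamma amounts and falls as snow
below 0.5 °C; the snowpack is a bucket (accumulate snowfall, melt at 2
mm SWE per degree-day above freezing). Defaults emulate a maritime
low-Arctic cell: mean −6 °C, amplitude 14 °C, AR(1) 0.65 with 3.5 °C
innovations — enough winter variability that above-freezing rainy days
on snowpack occur a few times per decade per cell, followed usually by
refreezing. Daily values are generated directly (no hourly step)
because all analysis consumes daily aggregates; fields draw from
per-field seed substreams so adding a field never perturbs existing
ones. What it does *not* emulate: orography, ocean/sea-ice coupling,
spatially correlated weather systems, or precipitation seasonality —
so passing detection tests demonstrates correctness of the algorithms,
not realism of Arctic climatology.

**Effect sizes.** True per-record effects compose an overall effect,
moderator offsets, study and record-level normal effects, and
species-level effects drawn with covariance σ²_phylo·A + σ²_species·I
from a simulated tree. Defaults mirror a compilation of 17 studies × 11
effects across 49 species with a strongly negative overall effect
(−0.9). Two observation modes: `"groups"` emits control/response
summaries from exact normal sampling distributions (group mean ~
N(μ, σ²/n), group variance ~ σ²χ²_{n−1}/(n−1)) for end-to-end pipeline
tests; `"direct"` emits d_i = θ_i + N(0, v_i) with known v_i ~
U(v_range) — the exact generative counterpart of the fitted model —
for estimator-recovery studies. The distinction matters: SMDH-estimated
sampling variances contain d², which inflates under between-record
heterogeneity, so recovery through the `"groups"` route attenuates the
REML components; that attenuation is a property of the standard SMDH
pipeline, not of the estimator.

**Trees.** `tree_shape="random"` draws a coalescent-style tree (uniform
pair merges at rate-n waiting times). `tree_shape="balanced"` builds the
deterministic balanced binary tree with evenly spaced split depths
(graded shared-ancestry fractions). `tree_shape="paired"` builds the
deterministic "cherries" tree — sister pairs splitting at half depth, a
root polytomy above — which gives the phylogenetic variance the largest
number of independent contrasts (one per pair) and keeps the pooled
mean from being dominated by a few deep clade draws. Species can also be
assigned to records evenly (`species_assignment="stratified"`) instead
of uniformly at random.

## Validation study sizes

Chosen as the package's own verification design: detection equivalence
on 100 simulated cubes of 10×10 cells × 5 winters against per-day
brute-force oracles; SMDH variance against 10⁵-replicate parametric
bootstraps at ten settings; estimator recovery on 200 replicates of 50
studies × 4 effects over 64 species (paired tree, components
0.4/0.3/0.2/0.3, v ~ U(0.05, 0.3)), checking 95% CI coverage within a
three-sigma binomial band and median components against truth;
end-to-end pipeline on a 3°×3°, 50-year cube. The demonstration pipeline
completes in seconds; the full suite in a few minutes on one CPU.

The recovery study deserves a candid note. With known variance
components, the GLS interval for the overall effect is exactly
calibrated (an oracle control in the design phase measured coverage
0.95); the plug-in z-interval at this problem size measures 0.92, inside
a three-sigma binomial band of the nominal rate. Medians of the study,
effect-level and phylogenetic components land within 2% of their truths.
The *independent species* component does not: same-species covariance
informs σ²_species + σ²_phylo jointly, their split rests on weaker
cross-species contrasts, and across every tree shape and species count
piloted (16–64 species; coalescent, clade-structured, balanced and
paired trees; stratified assignment) the residual species component was
biased toward the REML boundary, with a median 12–46% below truth —
while the species+phylo sum recovered. The package reports both
components but documents them, and phylum-level contrasts, as weakly
separated at compilations of a few hundred effects; analyses of real
data of this size should interpret the two species-level components
jointly and re-run the fit under several tree-randomization seeds. The
corresponding recovery test asserts the 10% clause for all four
components and is expected to fail on the species component; this is a
recorded property of the estimator at this problem size, not a defect
being hidden.

## Reproducing reanalysis-scale results

Desk-scale synthetic runs cannot reproduce numbers derived from a full
reanalysis archive. Users with access to ERA5 Hourly Data on Single
Levels can run the identical pipeline at scale:

1. Download hourly 2-m temperature, total precipitation/rainfall and
   snow-depth (water-equivalent) fields, 1950–present, for latitudes ≥
   60° N.
2. Aggregate to daily values — daily maximum temperature, daily total
   rainfall, daily mean snow depth — and to 1°×1° cells with
   `aggregate_grid` (unweighted block means; convert snow metres of
   water equivalent to mm in the reader, `io.read_climate` does this
   from the units attribute).
3. Write the cube as NetCDF with variables `tasmax`, `pr`, `swe`
   (plus `prsn` for precipitation-phase trends) and run
   `arcex run --config <yaml>` with baseline 1950–1980, modern
   1990–2020, 99th percentile, and the regional boxes of interest.
4. For the meta-analysis, supply the effect-size table (CSV with the
   documented group-summary schema) and the species tree (newick) in
   the config; the tree-randomization seed is recorded in every fit.

## Known limitations

- Detection is cell-local: no spatial pooling of events that straddle
  cells, and reanalysis biases at kilometre scales pass through.
- The SMDH sampling variance is asymptotic; below ~15 observations per
  group it is biased upward by several percent (quantified above).
- The species/phylogeny variance split is weakly identified in
  compilations of a few hundred effects; treat those two components
  (and phylum-level contrasts) as sensitive to the tree and its
  randomized bifurcation.
- Projection maps multiply one pooled effect by the per-cell change —
  relative magnitudes for prioritisation, not predictions; the output
  metadata carries this caveat.
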