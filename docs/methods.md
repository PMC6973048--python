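# Methods

## Data model and conventions

A flowering record is one individual's (for herbs, one flowering shoot's)
observed interval: the first and last census dates on which it was in
flower, within one year's weekly census calendar (1 March – 31 July by
default).  All dates are ISO-8601; all arithmetic is in integer days.
Records missing either date are rejected rather than imputed — analyses use
complete individual intervals only.

**Length convention.** Individual flowering length is inclusive,
(end − onset) + 1, so a flower seen on a single census has length 1.  The
alternative (exclusive) convention shifts every length by the same
constant, leaving all comparisons unchanged.

**Species filters.** A species is retained when (a) its pooled set of
census dates with at least one flowering individual is strictly larger
than `min_flowering_days` (default 2), and (b) it has at least
`min_individuals` (default 5) individuals — per year in every year when
`require_both_years` is set, else pooled.  The flowering-days filter is
species-level: the individual-level alternative is not distinguishable
from the protocol's description of the data, and species-level is the
reading under which a two-census species is excluded.

## Species-level variables

For a species-year with individual lengths L₁…Lₙ:

* TFL = (max end − min onset) + 1; MFL = mean Lᵢ; VFL = sample variance
  (n−1 denominator, as are all variances here).
* Skewness m₃/m₂^{3/2} and kurtosis m₄/m₂² use raw moment estimators
  without small-sample bias correction; kurtosis is non-excess (normal
  = 3) by default, with an `excess` flag.  Skewness needs n ≥ 3, kurtosis
  n ≥ 4 and non-zero m₂; otherwise the value is NaN (flagged undefined).
* Onset variance is computed on offsets from the first-blooming
  individual (day 0); it is shift-invariant by construction.

**Morisita's Iδ.** Counts nᵢ are individuals in flower at census i (an
individual contributes to every census inside its interval), and
Iδ = q Σ nᵢ(nᵢ−1)/(N(N−1)) over q bins.  The default bin set is the **full
season calendar** (zeros included): this is what one obtains by handing
the census-date × species community table to a dispersion-index routine,
and it is the convention under which synchronous species score high
(concentration in few of many bins → Iδ up to q) and asynchronous species
score low.  Restricting bins to the species' own first-onset→last-end
window (`bins="window"`) is available for sensitivity analysis, but note
it *inverts* the ranking for highly synchronous species: within its own
short window a synchronous species is near-uniform (Iδ ≲ 1) while a
spread-out species shows a central hump (Iδ > 1).

## Community-wide synchrony

φ = Var_t[x_T(t)] / (Σᵢ SD_t[xᵢ(t)])², the Loreau–de Mazancourt (2008)
definition, with sample (T−1) variances used consistently in numerator and
denominator (the ratio is invariant to that choice).  φ ∈ [0, 1] by
Cauchy–Schwarz; φ = 1 iff all series are perfectly correlated, and
E[φ] ≈ 1/S for S independent equal-SD series.  The literal
sum-of-variances denominator is exposed as `denominator="sum_var"` for
sensitivity checks only.

Species-level onset is the earliest individual onset of the year.
Onset-date skewness uses the moment estimator and is tested with the
D'Agostino–Pearson omnibus K² (χ², 2 df); n ≥ 8 is enforced for the
validity of the z-transformations.

**Species bootstrap.** Group CIs (for φ and onset skewness) resample
species with replacement at the group's own size, B = 1000 by default,
percentile 95% bounds; replicates with undefined statistics are dropped
and the effective B reported.  A caveat worth knowing: resampled
duplicates of a species are perfectly correlated copies, so for weakly
synchronous communities the bootstrap distribution of φ sits above the
plug-in value (for S independent series, around (2S−1)/S² rather than
1/S).  This is intrinsic to species resampling of a synchrony index; the
CIs are comparable across groups, which is how they are used, but they
are not centred on the plug-in φ.

## Rarefaction–extrapolation

For each species and variable, the expected statistic at sample size j is
estimated by drawing j individuals with replacement B times (B = 1000
default) and averaging the defined replicates; j runs from the statistic's
minimum n up to the species' own sample size.  Model selection pools all
species' curves for one variable after rescaling each by its own maximum,
fits y = a+bj, y = a+bj+cj², y = a+b·ln j and y = a/(1+e^{−b(j−c)}) by
least squares, and picks the minimum BIC = m·ln(RSS/m) + k·ln m with
k = parameters + 1.  Exact fits are clamped to a common RSS floor
(m·(10⁻⁹·scale)²) so parsimony, not rounding noise, breaks ties; remaining
ties go to fewer parameters, then the fixed order linear < logarithmic <
quadratic < logistic.  Logistic fits start from a₀ = max y, c₀ = j at
half-max, b₀ = 1, with |b| ≤ 50 and a > 0; a non-convergent logistic is
excluded with a warning.  The selected form is then fitted to each
species' **raw** curve (standardization is only for pooled selection) and
evaluated at n ∈ {5, 7, 12, 18, 22}; when a per-species fit fails, the
bootstrap mean at the nearest available j is used instead.

Reproducibility: every curve's RNG substream is derived from
(master seed, species, year, variable) via CRC32-keyed SeedSequence, so
results are independent of evaluation order.

## Two-sample testing and mixed models

Test selection: Shapiro–Wilk normality on each group and median-centred
Levene homogeneity, both at α = 0.05 (configurable) → *t* (both normal),
Wilcoxon rank-sum (non-normal, homogeneous), Fligner–Policello
(non-normal, heterogeneous).  The Fligner–Policello statistic uses
placement counts with half-weight ties and the large-sample normal
reference — group sizes in this design are ~13–20, where the normal
approximation is standard; complete separation with zero placement
variance returns an infinite statistic with p = 0.  Holm's step-down
adjustment is applied within each family of comparisons and returns
values in input order.

The gamma GLMM (log link — the natural reading of a multiplicative,
positive-response model — with a genus random intercept) is fitted by
Laplace-approximated ML: the 1-d conditional mode per genus by Newton's
method, the marginal likelihood in the cancellation form
−½·log(1 + σ²·αSe^{−û}) that stays exact as σ² → 0, and joint L-BFGS-B
optimization of (β, log shape, σ²) with σ² ≥ 0, initialized from the
plain gamma GLM.  Wald p values come from the numeric Hessian of the
Laplace deviance.  A fit with σ² at zero is returned (flagged singular)
rather than failed.  Gaussian LMMs use statsmodels MixedLM with full ML
and best-of-two optimizer restarts (keeping the higher log-likelihood):
single-optimizer fits occasionally under-fit the null model, which
inflates downstream likelihood-ratio tests.  The skewness model ladder
(random-intercept-only vs +year vs +individuals) is compared by LRT
against χ²(1).

## Phylogenetic signal

Trees are consumed, never estimated.  Newick input requires branch
lengths and unique tips; polytomies are resolved to zero-length binary
splits and zero-length branches perturbed by 10⁻⁸ × tree depth.
Contrasts follow the standard pruning recursion ((x₁−x₂)/√(b₁+b₂),
inverse-branch-weighted ancestral values, parent branch extended by
b₁b₂/(b₁+b₂)); internally each contrast is kept as a linear functional of
the tip values, which makes the permutation null a single matrix product.
Blomberg's K is the observed MSE₀/MSE over its Brownian expectation
(tr V − n/(1ᵀV⁻¹1))/(n−1).  The permutation test shuffles tip labels
(default statistic: mean squared contrast, "≤ observed" counted as
extreme since low contrast variance indicates signal; a K-based variant
is available) and uses the add-one p estimator, so p ∈ (0, 1].

## Synthetic data

The generator emulates the weekly census: species peak onsets ~
Normal(peak mean, between-species SD); individual true onsets ~
Normal(species peak, within-species SD — the synchrony dial); true
durations ~ Gamma parameterized by (MFL mean, VFL variance), truncated at
1 day; the *observed* record is the first/last covered census date, and
individuals covering no census are censored out (so observed intervals
are never longer than true ones, and observed lengths are quantized to
the weekly grid).  Genus labels are assigned round-robin over species
ordered by peak onset, at most 3 species per genus, to exercise the
random-intercept machinery with realistic imbalance.  Defaults encode the
study community: 13 tree / 15 perennial / 20 annual species observed in
2016 and 2017, 5–69 individuals per species, trees with small
within-species onset SD (3 d) and duration variance (9 d²), annuals large
(12 d, 100 d²), perennials intermediate.

A consequence of the census-resolution observation model worth knowing:
two groups with *equal* generating mean duration but different duration
variances do **not** have equal observed mean flowering length.  Short
flowers in the high-variance group are disproportionately censored out
(they can fall entirely between censuses), and week-grid quantization of
a skewed length distribution adds a further upward shift — about 1.7 days
in total for variance 100 vs 4 at mean 14 d.  This is a property of
weekly recording itself, not of the estimators, and it applies equally to
real field data collected under this protocol.

What the generator does **not** emulate: spatial plot structure, weather
covariates, between-year climate shifts, flower abundance within
individuals, and observation error in onset/end calls.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
life-form contrasts under the stated generative model, not robustness to
those real-data features.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to give stable Monte-Carlo
estimates at desk scale: 500 replicates for the φ independence law and
the type-I-error checks, 200 Brownian replicates for the K calibration,
100 replicates for model-family recovery and the end-to-end life-form
contrast study (two 15-species × 15-individual communities, B = 200
bootstrap replicates per curve; B = 1000 remains the analysis default).

## Known limitations

* The Laplace approximation can shrink the genus variance estimate for
  small per-genus samples; fixed effects are accurate (checked against
  GLM in the degenerate case and by parameter recovery).
* Percentile bootstrap CIs inherit the species-duplication bias described
  above.
* Rarefaction extrapolation beyond a species' own n trusts the selected
  parametric form; curves are reliable interpolants but extrapolants only
  as far as the form holds.
* Pooled ("both years") summaries average per-year values; raw records
  are never pooled across calendar years, since TFL across years is not
  meaningful.
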