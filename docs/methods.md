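# Methods

This note documents the models implemented in `fishdemog`, their
assumptions, the default parameter values and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Ageing validation

**Increment periodicity.** An OTC-injected fish time-stamps its otolith: the
distance `x` (mm) from the fluorescent mark to the edge spans `x/y` increment
cycles, where `y` (mm) is the width of the last complete increment laid down
before death. Over a known growth period `G` (days), the formation period is

    P = G · y / x   [days per annulus].

`P` is strictly decreasing in `x` and increasing in `y` and `G`; `P ≈ 365 d`
validates annual deposition. We label the quantity days-per-annulus
throughout (the reciprocal, annuli per day, carries the same information).
The summary reports the mean together with both the sample (ddof = 1) and
population (ddof = 0) standard deviations, because with the very small fish
counts typical of tank experiments (n ≈ 6) the two conventions differ
visibly; the mean is the headline number.

**Seasonality.** Marginal-increment analysis averages the otolith growth
beyond the last complete annulus per capture month (restricted to one or two
well-sampled age classes so increment widths are comparable); a single annual
minimum — the season when most fish have just completed an annulus — is the
signature of yearly deposition. Edge-type analysis tabulates the monthly
percentage of translucent margins, excluding indeterminate edges before
computing; a single winter maximum corresponds to the slow-growth season.
Months come straight from the capture date; no smoothing is applied.

**Reader precision.** The index of average percent error over fish `j` with
reads `x_ij` and mean read `x̄_j`:

    IAPE = (100/N) Σ_j (1/R_j) Σ_i |x_ij − x̄_j| / x̄_j .

The reference age is the arithmetic mean of the reads; fish whose reads
average zero are excluded (their relative error is undefined). IAPE is
invariant to fish order, read order and common rescaling, and is zero iff
all retained reads agree. Percent agreement at tolerance `t` is the share of
fish whose reads span at most `t` years. Reader confidence codes
(G/FG/F/FP/P) are tabulated but never modelled.

**Otolith–fish allometry.** Linear models of otolith weight (mg) on age and
of otolith length (mm) on fish TL (cm), with candidate morph and sex main
effects and a covariate×morph interaction. Reference levels are the plain
morph and males. Model selection computes the Gaussian AIC
`n·ln(RSS/n) + 2p` for each candidate and then applies the standard
parsimony convention: among models within 2 AIC units of the minimum, the
one with the fewest parameters is selected. (Raw minimum-AIC keeps a
spurious 1-df term with probability ≈ 0.16; the 2-unit rule brings the
false-inclusion rate down to ≈ 5% while never discarding a strongly
supported term.) The RSS is floored at `n·10⁻²⁰` so that noiseless data —
used in exact-recovery tests — does not produce infinite log-likelihoods.

## Growth

The von Bertalanffy growth function (VBGF)

    L_t = L_inf (1 − e^(−K (t − t0)))

is fitted by nonlinear least squares (trust-region reflective) with
multi-start initialisation: `L_inf` starts at 1.05× the largest observed
fish and `K` on the grid {0.1, 0.3, 0.6} (for the unconstrained fit, `t0` in
{−0.5, 0}); the best converged start wins. The default **constrained** mode
fixes `t0 = 0`, the appropriate choice when the sampled age range lacks
small/young fish and the parameters would otherwise trade off freely against
an unidentified intercept. At least three distinct age classes are required
for identifiability. AIC uses the same Gaussian formula as above and is
meaningful only for ranking models on the same data.

**Bootstrap.** Fish are resampled with replacement and the model refitted
per replicate, warm-started at the full-data estimates (falling back to the
multi-start grid if the warm start fails). Replicates that still fail are
dropped and counted; more than 50% failures aborts. Percentile 95% CIs are
the default; basic (reflected) intervals are available via
`ci_method="basic"` since the flavour used in published tables is rarely
stated. The bootstrap cloud of `(L_inf, K)` pairs drives group comparison.

**Confidence ellipses.** The cloud is summarised by its mean and sample
covariance; the 95% region is the ellipse
`(p − c)ᵀ Σ⁻¹ (p − c) ≤ χ²₂(0.95) ≈ 5.991` — a bivariate-Gaussian
approximation of the bootstrap distribution. Overlap of two elliptical disks
is decided numerically: mutual centre containment plus membership of each
ellipse's boundary (sampled at 1440 points) in the other; the discretisation
resolves overlaps far finer than bootstrap noise. A convex-hull region was
considered and rejected: at 1000 replicates the hull's coverage is noisy and
its overlap test is much more expensive, while the Gaussian approximation is
what the ellipse-plot convention in the growth literature depicts.

**Francis reparametrisation.** The same curve expressed through mean lengths
`(l₁, l₂, l₃)` at reference ages `τ₁ < (τ₁+τ₃)/2 < τ₃`:

    L(t) = l₁ + (l₃ − l₁) (1 − r^(2(t−τ₁)/(τ₃−τ₁))) / (1 − r²),
    r = (l₃ − l₂)/(l₂ − l₁),

with back-transformation `K = −2 ln r/(τ₃ − τ₁)`,
`L_inf = l₁ + (l₃ − l₁)/(1 − r²)`, `t0 = τ₁ + ln(1 − l₁/L_inf)/K`. Defaults
`τ₁ = 2, τ₃ = 10` span the well-sampled ages of a moderately long-lived
reef fish; reference ages outside the observed range are recorded as
warnings on the result rather than errors, since extrapolated mean lengths
are still well-defined curve values. CIs for the `l` parameters come from
the least-squares Jacobian (Gaussian approximation).

## Age–length keys and mortality

**Keys.** 1-cm, left-closed/right-open length bins (matching 1-cm observer
measurements; the bin width is configurable), stratified pooled, by sex, by
morph, or both. Row proportions are counts over row totals. Keys are only
ever built from directly aged (or simulated-truth) fish — never from
key-assigned ages, which would compound assignment error.

**Assignment.** Stochastic mode draws each fish's age from its bin's row
with an explicit seed. Fish in an empty bin borrow the nearest populated bin
up to 2 bins away; beyond that they are left unaged and reported. The
deterministic *fractional* mode allocates fish within each bin to ages by
largest-remainder rounding of the row proportions (ages ascending with
length within the bin), for pipelines that must be reproducible without a
seed. Assignment changes only the age fields.

**Catch curves.** Under equilibrium (stable recruitment, constant mortality
and selectivity over the analysed ages), `ln N_a` declines linearly in age
at rate `Z`. The descending limb runs from one year older than the modal age
(full selectivity; modal ties resolve to the *oldest* mode, the conservative
choice) to the oldest age preceded by at most two consecutive
zero-frequency classes. Interior zeros inside the limb are dropped from the
regression (their log is undefined) but kept in the plot data; they are
never replaced by constants. The fit is unweighted OLS; `Z = −slope`,
`A = (1 − e^(−Z))·100` %. At least three positive-count limb ages are
required to fit. An ascending limb returns a flagged result rather than an
error. A Chapman–Robson survival estimator over the same limb is provided
as an independent cross-check.

**Comparisons.** Group differences in `Z` are tested in the pooled model
`ln(count) ~ age * group` over each group's own limb; the age×group
interaction F-test assesses slope homogeneity, and with full interaction
coding the per-group slopes equal the separate single-group fits. Cohort
curves pool each birth-year's counts across sampling years
(cohort = capture year − age); cohorts with fewer than 4 positive age
classes are skipped with a reason.

**Known limitation.** When length carries little age information near the
asymptote, key-assigned ages share the key's sampling noise across many
fish; the catch-curve regression SE, which assumes independent counts, then
understates the true uncertainty of `Z` from assigned ages (in our
simulations, by roughly a third at a 58% directly-aged fraction). Estimates
remain unbiased; intervals from assigned-age curves should be read as
optimistic.

## Population summaries

Length–weight uses natural logs: `ln TW = ln a + b ln TL`, with candidate
sex/morph effects and a `ln TL × sex` interaction, selected by the same
AIC-parsimony rule; plain/male are reference levels, and `b = 3` is
isometry. Longevity and mean maximum size are the mean age and mean TL of
the `ceil(n/10)` oldest fish, ties broken by length (longer first) then id —
computed within group by default when groups are compared (a pooled subset
conflates group size structures). Group tests are Welch's unequal-variance
t (fractional df) and the rank-sum test.

## Synthetic populations

The generator draws, per fish: a colour morph (default 70% plain / 30%
spotted — market samples of this population are predominantly plain);
an integer age from a truncated exponential (geometric) distribution at the
morph's total mortality `z` on ages 1–22 (the equilibrium age structure the
catch curve assumes; 22 yr is the oldest observed age); a length from the
morph's VBGF plus Gaussian noise with sd `1.0 + 0.2·age` cm (size
variability grows with age; the growth rate of the variance is not
quantified in published sources, so the slope is a package choice); sex by
an irreversible female→male logistic in length (midpoints 36.0 / 47.2 cm
for plain/spotted, slope 0.45 /cm — sharp enough that sex change completes
within ±5 cm); weight from the log-log allometry (intercept −4.488, slope
3.122 in natural logs, lognormal error sd 0.06); and otolith weight/length
from the linear allometry models with morph/sex effects. Knife-edge gear
selectivity removes fish under 15 cm (gillnets do not retain smaller
individuals). Default growth/mortality values are the plain
(36.60 cm, 0.44 /yr, Z = 0.42) and spotted (49.32 cm, 0.26 /yr, Z = 0.28)
estimates.

The OTC-experiment generator reproduces the measurement structure
(`x/y = G/P` with multiplicative noise of a given CV); the double-read
generator adds rounded Gaussian reader error to true ages; the seasonal
generator gives each fish an annulus-completion month in the four months
from the opaque-zone onset (March by default), a marginal increment growing
at 0.05 mm/month since completion, and a translucent edge with probability
0.80 in the configured peak months versus 0.10 otherwise (5% indeterminate).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: individual growth trajectories (sampling is
cross-sectional; there is no persistent individual growth deviation),
dome-shaped or gradual gear selectivity, recruitment trends or
year-structure (ages are drawn from the stationary distribution, so cohort
analyses see an idealised steady state), ageing error in the "true" ages
fed to keys and catch curves (reader error exists only where explicitly
simulated), spatial structure, and any age-dependence of sex change beyond
its length dependence. Length-based knife-edge selection does interact with
growth exactly as in real catches: the few young fish that enter the sample
are the large ones, which biases growth fits from selected samples — growth
recovery checks therefore use length-unselected size-at-age samples.

## Numerical conventions and problem sizes

Seeds are explicit everywhere; no global random state is touched. Missing
values are `None` in memory and empty CSV cells on disk, never sentinels.
Dates are ISO-8601; fish lengths cm, weights g; otolith lengths mm, weights
mg. Lengths are recorded to 0.1 cm (market dialect) or 1 cm (observer
dialect). The test suite exercises recovery experiments at the study's
scales (n = 500 growth samples, 10⁴-fish mortality comparisons over 20
replicates, a 5000-fish end-to-end key pipeline, 100-dataset coverage
checks at reduced bootstrap counts), chosen so the whole suite completes in
well under a minute per module while keeping Monte-Carlo error small
relative to the asserted tolerances.
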