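# Methods

`cagepheno` reimplements an end-to-end analysis stack for automated
metabolic-cage phenotyping of aging mice. The study design it models is a
staggered-enrollment longitudinal cohort: each animal is monitored for one
7-day "run" per 28-day cycle in a respirometry cage that reports 14 base
measurement channels at 3-minute cadence (body mass, food and water intake,
wheel and pedestrian distance, total movement, X/Y/Z photobeam breaks, VO2,
VCO2, energy expenditure, RQ, VH2O) under a 12 h light / 12 h dark cycle.
Because the original cohort's data are not required, a synthetic-cohort
generator with full ground truth sits at the front of the pipeline; every
downstream stage is validated by recovering what the generator planted.

## Synthetic cohort generator

The generator draws, per animal: an enrollment age from a staggered
schedule; a lifespan from a Gumbel distribution on log-months (left
truncation at enrollment by resampling, right censoring at
enrollment + study length); a latent aging rate `beta_j ~ N(1, sigma_beta^2)`
(default SD 0.2) that multiplies all age effects; a body mass; and, when
genetics are enabled, per-channel mouse-level shifts composed of a genetic
value (variance `h2`) plus permanent environmental individuality (variance
`1 − h2`).

Runs are sampled from a six-state Markov chain (Sleep, Rest, Eat,
Eat&Drink, Run, Active) with separate light- and dark-phase transition
matrices; the dark matrix boosts the high-activity states, which is what
produces circadian structure in every channel. Emissions are Gaussian per
state and channel, with structural zeros where a state does not express a
behavior (no food intake while asleep). Aging acts additively on emission
means (wheel, gas and intake decline; pedestrian movement rises) and on the
log-odds of entering each state (occupancy shifts toward low-activity
states), both scaled by `age x beta_j`. Analyzer (cage) identity adds a
per-analyzer offset to the five gas channels, centered to zero mean across
analyzers. Sensor faults are injected per cell: spurious zeros (cell set to
exactly 0) and heavy-tailed bursts (t3-distributed displacement scaled by
the channel SD), with the fault mask and clean values kept as truth.
Everything is driven by `numpy` generators seeded from a single
`SeedSequence`, so a fixed seed fixes every output bit.

What the generator does *not* emulate: 1-second raw sensor physics, body
composition, sex or strain differences, and realistic within-state emission
shapes (real channels are mixtures; the generator uses zero-inflated
Gaussians). Passing tests therefore demonstrate that the *algorithms*
recover planted structure under realistic noise — not that the defaults
match any real cohort's effect sizes.

## Quality control

Per run and channel, in order:

1. **Acclimation truncation** — the first 24 h are dropped; runs left with
   less than one full day are rejected (`too_short`). The comparison is
   strict: a 48 h run keeps exactly its second day.
2. **Range checks** — closed permissive intervals (gas 0–10, body mass
   5–80 g, beam breaks 0–2000; distances bounded below at 0 only). Both
   endpoints are kept.
3. **Robust circadian decomposition** (gas channels) — an authored
   seasonal-trend decomposition with a 24 h period: the trend is a centered
   rolling median over one full period with periodic edge padding; the
   seasonal profile is the per-circadian-bin *mean* across days, smoothed
   by a circular Savitzky–Golay filter (window 9 bins, quadratic). Cells
   whose leave-one-day-out residual exceeds 4.5 robust SDs are excluded
   from the components and the pass repeats. Design rationale: a per-bin
   *median* profile is robust but, at 3–6 days per run, distorts the
   residual distribution enough to inflate the outlier test's false-positive
   rate several-fold; the mean profile keeps clean residuals calibrated,
   the smoothing removes the profile's own-cell weight (so moderate bursts
   are not absorbed), and the leave-one-day-out exclusion rejects gross
   spikes. The decomposition is exact for noiseless periodic signals
   (sinusoid residual ~1e-8 of amplitude) and a single spike of 10x the
   seasonal amplitude moves the seasonal estimate by <5%.
4. **Generalized ESD** (Rosner's test) on the residual at significance
   0.05, capped at 30% of points. On clean Gaussian input its family-wise
   flag rate is ~0.05; planted bursts of 6 channel-noise SDs (~7 residual
   SDs) are recovered with sensitivity >0.9.
5. **Run rejection** — a run is dropped if >=30% of checked cells are
   flagged, or if any gas channel is >=30% exact zeros (massive dropout
   violates the ESD's contamination bound: the zeros would mask
   themselves, so the flag-fraction rule could never fire).

Flagged cells are censored (masked), never modified; there is no
imputation anywhere.

## Robust behavioral-state HMM

A discrete-state HMM over 13 channels (body mass excluded) segments each
3-minute bin. Count-like channels are log1p-transformed. Emissions are
zero-inflated Gaussians: a learned point mass at exactly zero plus a
Gaussian for nonzero values — structural zeros (no wheel turns while
asleep) are therefore first-class rather than outliers. Two robustness
states extend the chain: a *censored* state (zero mass held near 0.9 by a
Beta pseudo-count prior, narrow emission at zero) that absorbs spurious
all-zero readings, and a *noise* state (fixed dispersion of 5x the pooled
channel SD) that absorbs implausible bursts. A per-analyzer additive
offset on each gas channel is learned in the M-step jointly with the other
parameters; offsets are identifiable only up to a constant and are
centered to zero mean across analyzers (the behavioral means absorb the
centering shift, leaving the likelihood unchanged).

Fitting is EM with k-means-initialized restarts; forward–backward runs in
scaled linear space with numba kernels; masked cells contribute nothing to
emission likelihoods; the training log-likelihood is non-decreasing every
iteration (the offset update is a coordinate-ascent step inside the
M-step, so the algorithm is a generalized EM). Decoding is per-bin
posterior argmax. The state count is selected by the one-standard-error
rule on held-out per-run log-likelihood: smallest k whose mean is within
one SE (taken across validation runs at the argmax k) of the best. Six
states are labeled deterministically from the expected emissions: Run has
the largest wheel emission, Eat&Drink the largest food+water among the
rest, Eat the largest food, Sleep and Rest the two lowest activity levels,
Active the remainder; other state counts get generic labels.

## Feature engineering

Sixteen base measurements (14 channels + WheelSpeed and PedSpeed, distance
per bin over bin duration) and six states yield exactly 309 features in
five families: overall run means + state occupancies (22), state-
conditioned means (96), six 4-hour bins aligned to lights-on (132),
pre/post light-transition ratios with 2-hour windows on both transitions
(44), and bout statistics — count, mean/max duration, mean/max inter-bout
interval for feeding, exercise and sleep (15). Bouts are detected on raw
3-minute streams (feeding: food > 0.01 g/bin; exercise: wheel > 1 m/bin;
sleep: zero beam breaks and wheel), merging gaps of <=1 bin and dropping
bouts shorter than 2 bins. Only complete 24 h days enter aggregation;
masked cells and robustness-state bins are excluded from means; a state
never occupied yields a missing value, never zero. On fully observed runs
the occupancy-weighted state-conditioned means reproduce the overall mean
to 1e-9, as do coverage-weighted 4-hour-bin means.

Two corrections precede extraction. Cage-exposure correction regresses
each measurement on run number with run-number-by-state interactions (the
saturated model reduces to a per-state slope in run number) and adjusts
all values to the first exposure. Body-mass normalization regresses each
gas measurement except RQ (a ratio) on body mass with mass-by-state
interactions and adjusts to the 31 g reference; after adjustment the
correlation of run-mean gas values with mass is ~0.

Age trends use the Kendall-tau test per feature against age with
Bonferroni correction over tested features. Age bins are half-open
3-month intervals from age 0, pooling ages >=33 months into a terminal
bin.

Per-mouse trend filtering (mice with >=4 runs) standardizes each feature
across the mouse's runs, solves
`min 1/2||X−Y||^2 + lambda * sum_t ||(D2 Y)_t||_2`
(second differences along run index, l2 across features) by ADMM, and
rescales. The group penalty makes the fits piecewise-linear with kink
locations shared across features; when the penalty zeroes every second
difference, the exact solution (per-feature least-squares line) is
returned. The default lambda = 2 on standardized features was chosen from
validation curves on synthetic cohorts — small enough to keep planted
kinks, large enough to suppress run-level noise.

## Phenotype networks and resilience

Per 3-month age bin, the feature correlation matrix is estimated
nonparanormally: Spearman rank correlation mapped through
`2 sin(pi rho / 6)` and projected to the nearest positive-definite
correlation matrix (eigenvalue clipping + diagonal renormalization). This
is invariant to monotone marginal transforms.

Sparse precision matrices across ordered bins come from a time-varying
graphical lasso solved by ADMM: an l1 penalty on off-diagonals within bins
and a column-group ("perturbed node") penalty on differences between
adjacent bins, symmetrized after the group shrinkage. With zero smoothing
each bin reduces to an independent graphical lasso (agreement with
scikit-learn's solver to <1e-4 at convergence); increasing the smoothing
penalty monotonically shrinks between-bin differences. The returned
precision is the l1 consensus variable, so reported supports contain exact
zeros. The sparsity penalty is chosen by extended BIC by default for real
use; benchmarks tune it on a small grid against planted support.

Features are grouped by bootstrap consensus clustering: each bootstrap
resample of runs re-estimates the nonparanormal correlation, converts it
to an absolute partial-correlation affinity (ridge-stabilized inverse),
and is spectrally clustered at every candidate k; the consensus matrix is
the co-clustering frequency. k is chosen by the delta-area criterion on
the consensus CDF (largest k whose relative area increase exceeds 0.05).
Each cluster's exemplar is the member with maximal median consensus to its
cluster. The default bootstrap count is 1000; benchmarks use 30–100,
which is already stable on planted-block problems.

**Resilience** is `1/2 log det R` of a correlation matrix R — the negative
multivariate mutual information of the Gaussian copula. It is 0 exactly
when features are independent and decreases as dependence grows, so a
falling curve across age bins means tightening coupling and a loss of
resilience. (The "negative copula entropy" phrasing would have the
opposite sign; this package follows the mutual-information convention,
where lower = more coupled, throughout.) When the feature count approaches
the per-bin run count, the per-bin curve applies one common linear
shrinkage toward the identity — the smallest intensity that makes every
bin comfortably positive definite — which compresses values toward 0 but
preserves the bins' ordering. Cluster summaries: inter-cluster
connectivity is the summed absolute partial correlation over edges
crossing a cluster's boundary (each crossing edge counts from both sides,
so the total over clusters is twice the crossing weight); intra-cluster
resilience is the resilience of the cluster's sub-correlation matrix.

## CASPAR: combined age and survival prediction of aging rate

A reference lifespan distribution — Gumbel on log lifespan — is fitted by
maximum likelihood on left-truncated, right-censored records (deaths
contribute `log f(log y) − log S(log a_enroll)`, censored records
`log S(log y_c) − log S(log a_enroll)`). The remaining-life density of a
reference mouse at age `a` is the total-lifespan density conditioned on
survival past `a`, with the change-of-variable terms to the (log-)
remaining-life scale; it integrates to 1 and its expectation decreases
with age.

The model: F(X) maps a run's features to a predicted biological age; the
observed per-run aging rate is `b_ij = F(X_ij)/A_ij`; each mouse has a
latent rate `b_j ~ N(1, sigma_beta^2)` with `b_ij ~ N(b_j, sigma_eps^2)`
(default `sigma_eps^2 = 1`). Training maximizes, over mice that died, a
survival term plus the closed-form Gaussian marginal of each mouse's rates
(covariance `sigma_eps^2 I + sigma_beta^2 11'`, evaluated by
Sherman–Morrison; verified against Gauss–Hermite quadrature to 1e-8).

Two modeling decisions matter and are deliberate:

- **T convention.** The default scores `T = log Y + log b` against the
  log-remaining-life density at age F — the accelerated-failure-time
  reading in which a mouse aging at rate b at predicted age F = bA has
  reference remaining life `Z = bY`. This matches the model's verbal
  premise (a 12-month-old with b = 1.5 has the remaining lifespan of an
  18-month-old reference). Two variants are available behind
  `t_convention` (`literal`: `T = log Y − b`; `log_ratio`:
  `T = log Y − log b`); in benchmarks neither produces the age-vs-survival
  regime structure that is the model's point, which is why they are not
  the default.
- **Survival weighting.** The survival term is averaged over a mouse's
  runs rather than summed: each animal dies once, and summing the death
  term per run pseudo-replicates the event, drowning out the Gaussian
  rate-consistency factor and flattening the sigma_beta dial.

With these choices sigma_beta behaves as designed: small values
(sigma_beta = 0.1) give an age clock (high correlation with chronological
age, weak with time to death), large values (sigma_beta = 100) strengthen
the time-to-death association at the cost of the age association, and the
per-mouse mean rates recover the generative latent rates. Note the
predicted biological age *anti*-correlates with remaining life — an older
biological age means less time left — so survival performance is read from
the magnitude of the (negative) correlation.

F is a LightGBM tree ensemble (depth 3, learning rate 0.05, deterministic
single-threaded training) on the raw score `g` with `F = exp(g)` (keeps
F > 0) and the negative marginal log-likelihood as a custom objective;
gradients and Hessian diagonals come from central finite differences of
the per-mouse objective, evaluated for one run position of every mouse
simultaneously (2 x max-runs + 1 vectorized sweeps per boosting round).
Non-finite or non-positive curvature falls back to a damped unit Hessian.
A linear learner (L-BFGS on the same objective) is available for small
tests. Evaluation uses full-animal holdout splits (all runs of a held-out
mouse are in the same test set), reporting Pearson correlations and R^2
(squared correlation) of predictions against chronological age and time to
death, with SEM across splits and p-values as twice the median across
splits.

## Heritability and genetic correlations

Kinship is the centered-scaled dosage cross-product over markers,
PSD-projected if needed. Heritability (PVE) of a feature uses the
spectral mixed model: per draw, one representative run per mouse is
sampled, the feature is quantile-normalized to a standard normal, and
`y = Xb + g + e` with `g ~ N(0, sg^2 K)`, `e ~ N(0, se^2 I)` is fitted by
a 1-D likelihood search over `delta = se^2/sg^2` after one
eigendecomposition; fixed effects are age and cohort. The likelihood is
the *fixed-effect-projected* (restricted) one: the dosage-centered kinship
is singular along the intercept direction, and an unprojected ML profile
diverges there (every PVE estimate saturates at 1), so the projection is a
correctness requirement, not a taste choice. The median and IQR over
draws are reported; significance is a likelihood-ratio test against
`sg^2 = 0` using the boundary mixture `(chi2_0 + chi2_1)/2`, Bonferroni
over features.

Pairwise genetic correlation uses a bivariate mixed model in the eigenbasis
of K (2x2 covariance `lambda_i G + E` per eigen-direction, closed-form and
vectorized), fitted by multi-start Nelder–Mead on log-variance/atanh-
correlation coordinates with fixed effects profiled by GLS; `rG` is the
genetic correlation, and the partial phenotypic correlation is the Pearson
correlation of covariate-residualized features. The generator gives the
kinship hierarchical (subpopulation -> family) structure because
variance-component separation is unidentifiable at a few hundred animals
without relatedness contrast.

## Problem sizes and benchmarks

The benchmark experiments (`cagepheno.experiments`, driven by both the
test suite and `scripts/acceptance.py`) run at desk scale, chosen once:
QC calibration on 500 clean 6-day gas series (6 days = a 7-day run after
acclimation truncation) with bursts planted at 6x the channel noise SD;
HMM recovery on 40 mice x 3 one-day runs with >=4-SD state separation and
state-count selection over k in 4–8 on 10 replicate cohorts; lifespan MLE
at n = 2000; CASPAR regimes on 200 dead mice x ~3 runs over 10 replicate
cohorts; network benchmarks at p = 15–32 features; heritability at n = 400
mice x 1500 markers with 100 representative-run draws; and a 40-mouse
end-to-end demo (3-day runs, 6-month follow-up) that is run twice to
verify bit-identical artifact checksums.

## Known limitations

- The HMM's censored/noise states are chain states over whole timepoints;
  single-channel dropout inside an otherwise normal bin is handled by the
  zero-inflation mass, not by the censored state.
- The ESD stage assumes <30% contamination per channel; heavier dropout is
  caught by the explicit zero-fraction guard rather than the test itself.
- The demo cohort (40 mice) is deliberately small; its CASPAR holdout
  correlations are noisy (2–4 test mice per split) and meaningful regime
  curves come from the 200-mouse benchmark cohort instead.
- rG estimates are noisy at a few hundred animals even with family
  structure; medians over replicates are stable, single fits are not.
- Bout thresholds are calibrated qualitatively; sleep-bout durations land
  near the 0.6–1.1 h scale on the default generator, but real-data
  thresholds would need revisiting.
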