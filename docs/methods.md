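# Methods

## Model

`koaprog` fits a mixture of linear z-score event-based progression models
to a single cross-sectional visit of a knee-osteoarthritis cohort.

**Events and stages.** Each biomarker is referenced to a control group:
z = direction × (x − mean)/sd, with direction −1 for measures that fall
with disease (joint space width, cartilage thickness) so that z always
rises with severity. Control statistics use the sample mean and the n−1
standard deviation; zero-variance control columns are rejected by name.
A z-score event is a biomarker crossing a threshold z ∈ {1, 2, 3, 5}.
An event is retained when **strictly more than** the threshold value is
observed in at least `min_count = 10` subjects (ties at the threshold do
not count). The biomarker's trajectory endpoint ("maximum z-score") is
derived from its largest retained event by the fixed mapping 1→2, 2→3,
3→5, 5→7. The S retained events define discrete stages 0..S; stage k
means the first k events of a subtype's ordering have occurred.

**Trajectories and likelihood.** Under ordering σ, biomarker i's expected
z at stage k linearly interpolates the knots (0,0), (p₁,z₁), …, (p_m,z_m),
(S, max-z); the final knot is dropped when the last event already sits at
position S. Observations are Gaussian with per-biomarker scale σ_i, fixed
at 1 by default because inputs are control-referenced z-scores (the scale
is configurable). Stages carry a discrete uniform prior over the S+1
stages; subject likelihoods marginalize the stage in log space
(log-sum-exp throughout), and the dataset likelihood is the f-weighted
mixture over subtypes.

**Fitting.** Sequences are optimized by greedy coordinate ascent: remove
one event, re-insert it at the (responsibility-weighted) likelihood-
maximizing valid position, sweep all events until a sweep changes nothing;
exact ties resolve to the lowest position. All candidate positions of one
event are scored in a single broadcasted evaluation. The c-subtype model
alternates this sequence step with EM updates (responsibilities from
stage-marginal likelihoods; fractions = mean responsibilities); each outer
iteration first runs the cheap fraction/responsibility cycle to
convergence with sequences fixed, then one sequence sweep per subtype.
Both steps increase the observed-data likelihood, so the trace is monotone
and asserted so on every fit (tolerance 1e-6). EM stops at absolute
log-likelihood change < `tol = 1e-6` or `max_iter = 100` outer iterations.

**Growing the mixture.** The (c+1)-subtype model is seeded from the
c-subtype model with several candidate families: (i) duplicate one subtype
and halve its fraction — this reproduces the parent likelihood exactly, so
a larger model can never fit worse than its parent; (ii) split one
subtype's hard-assigned subjects into two random halves and greedily refit
each half (from the parent sequence and from random restarts); (iii)
append a freshly drawn random sequence; (iv) full restart with all-random
sequences; (v) a "worst-fit" seed in which the new subtype's sequence is
fitted to the fifth of subjects with the lowest current likelihood.
Candidates are explored with a loose EM (tol 1e-3), and the `polish_top`
best are polished at full tolerance. The worst-fit and restart families
were added because split-only seeding reproducibly converged several nats
below the optimum reached from a truth-informed start on simulated
mixtures; with them, fits reach or exceed that reference on most draws.
Single-subtype fits take the best of `n_starts = 25` greedy ascents from
uniform random valid orderings (tests and the acceptance script use
smaller search budgets, stated below).

**Sequence uncertainty.** Per-subtype Metropolis–Hastings over orderings:
propose moving a uniformly chosen event to a uniformly chosen position
(symmetric proposal; moves violating within-biomarker z-order are rejected
before evaluation), accept on the mixture-likelihood ratio with the other
subtypes fixed. Defaults 10,000 iterations with 1,000 burn-in; the
reported matrices are event × position frequencies (rows sum to 1) and the
reported sequence estimate is the maximum-likelihood sample.

**Model selection.** CVIC = −2 · log P(X|M), with log P(X|M) the sum over
10 cross-validation folds of the log probability of the held-out subjects
under the model fitted on the remaining folds; folds are stratified by
severity grade when labels are given (so each training fold spans the
stage range) and the chosen c is the argmin, smallest c on ties. The
held-out probability is estimated by averaging the likelihood over MCMC
samples of the training fold's sequences (default 1,500 iterations, 500
burn-in, 20 evenly thinned samples; fractions from the fold fit, σ never
refit). Evaluating only the point-estimated sequences systematically
favours larger c — an extra mixture component mimics the hedging over
sequence-estimation uncertainty that posterior averaging gives every
candidate — and measurably over-selects on single-subtype data;
``mcmc_iter=0`` still provides that point-estimate evaluation. Within
each fold the candidate subtype counts are fitted hierarchically (c = 1,
then grown), which is also how a direct fit at larger c is built.

**Assignment.** Subtype posterior ∝ f_c × stage-marginal likelihood; stage
posteriors per subtype and marginalized over subtypes; every posterior's
normalization is asserted at construction. Most-likely stage ties resolve
to the earlier stage. "Strong assignment" means the top subtype
probability is ≥ 1.5 × each other subtype's probability (the literal
per-competitor reading, not 1.5 × their sum); the uniform vector is not
strong, and a single-subtype model is trivially strong (logged).

**Three-way comparison.** Subtypes-only baseline: diagonal-covariance
Gaussian mixture fitted to grade ≥ 2 subjects (scikit-learn, stepped one
EM iteration at a time so the monotone trace is recorded; best of
`n_starts` initializations; all subjects then assigned to the
highest-responsibility component). Stages-only baseline: the progression
model with c = 1. The arms are compared by logistic regression
(statsmodels, Newton/IRLS, Wald 95% CIs) on separating grade 0/1 from
grade ≥ 2, with predictors most-likely stage and/or integer-coded subtype
plus injury, gender, age, BMI. Subtype enters as a single integer-coded
predictor so each arm reports one coefficient per construct (dummy coding
can be performed by the caller). LR statistic = 2(llₐ − ll_b) against
chi-square with df = parameter-count difference; the compared models are
not nested and the result metadata flags this. Reported p-values are raw
(unadjusted) Wald / chi-square values. Perfect separation raises an error
naming the separating predictor when one predictor alone separates.

## Biomarker selection

Backward deletion removes, at each step, the biomarker whose removal most
improves a per-biomarker-normalized criterion, stopping when no removal
improves it by more than `min_gain` (default 1e-3). The default criterion
is the held-out log likelihood per subject per biomarker from a 3-fold CV
single-subtype fit: raw likelihoods of panels with different biomarker
counts are not comparable, and the per-biomarker normalization makes the
deletion well-posed.

## Synthetic cohort generator

The generator emulates the statistical structure of the OAI-derived
678-knee baseline cohort the method was designed for:

- 13 biomarkers carrying 32 z-score events (the published panel is shipped
  in `koaprog.reference`; one published row lists maximum z-score 2 with 2
  events, which the stated mapping cannot produce — the mapping's value 3
  is used, leaving the 32-event total unchanged);
- subtype ~ categorical(fractions), stage ~ uniform{0..S}; z = expected
  trajectory + N(0, noise_sd), default noise_sd = 1 (unit-variance z-scale
  noise); raw value = control_mean + direction × z × control_sd, so
  control-referenced z-scoring recovers z exactly when the true control
  parameters are used;
- control groups Gaussian per biomarker — z-scoring, their only downstream
  use, is exact for location-scale families;
- an ordinal severity grade 0..4 (Kellgren–Lawrence analog) thresholded on
  the true stage (default cutpoints (1, 3, 14, 27) for S = 32, scaled for
  other S, giving grade shares near the published 7.5/34/41/18%), with an
  optional probability of flipping to an adjacent grade; the grade derives
  from the stage, not the subtype, because the severity grade plays the
  role of a temporal, not phenotypic, marker;
- demographics independent of subtype by default — age ~ N(62, 9) years,
  BMI ~ N(29, 4.7) kg/m², 55% female, 21% injury — with optional
  subtype-linked shifts for power studies. (The source cohort's published
  summary BMI of 23.1 conflicts with its per-subtype means of 28–30; the
  generator follows the per-subtype table.)

Ground-truth sequences can be drawn uniformly at random (with a pairwise
Kendall-tau separation cap, default 0.3 — within-biomarker order
constraints put a positive floor under pairwise tau, so 0.3 still forces
strong cross-biomarker disagreement), as a *reversed pair* (two subtypes
progressing biomarkers one at a time in opposite orders — the maximally
separated two-subtype configuration; a naive position reversal is largely
undone by the within-biomarker constraint), or as *blocked* archetypes
(each subtype progresses biomarkers fully one at a time in its own random
order).

What the generator does **not** emulate: longitudinal follow-up, missing
data, non-Gaussian measurement error, ordinal/semi-quantitative readout
discreteness, correlated noise between anatomically adjacent biomarkers,
and demographic–subtype confounding. Tests passing on this generator
therefore show correctness of the inference machinery under the model's
own assumptions, not robustness to real-data violations of them.

## Problem sizes used in tests and the acceptance script

Simulation-based tests use a 5-biomarker, 10-event panel with n = 400–800
subjects and 5 replicate seeds for recovery, selection, and comparison
checks, and the full 13-biomarker, 32-event panel where stage resolution
matters (staging consistency); search budgets are scaled to these sizes
(n_starts 2–6, split_starts 1–8, polish_top 1–4; CVIC per-fold chains 800
iterations, 300 burn-in, 15 samples). Sequence-recovery and selection
cohorts carry two reversed-pair subtypes; model-comparison cohorts carry
three blocked archetypes at a 15/61/24% mix with severity cutpoints
(1, 4, 7, 9) — the mid-course grade 0/1 vs ≥ 2 boundary keeps all three
logistic arms estimable (with the boundary at the very first stages the
subtypes-only mixture component separates the outcome completely and its
coefficient diverges) — plus a 5% adjacent-grade flip emulating
severity-reading noise. The acceptance script uses the same sizes.
Enumeration-oracle checks run on all valid orderings of panels with
S ≤ 6.

## Known limitations

- Greedy-ascent-within-EM finds local optima; the multi-family seeding
  makes global recovery reliable on well-separated mixtures but the fitted
  likelihood can remain a few nats below the truth-seeded optimum on hard
  draws, and at n ≈ 600, σ = 1 even the exact ML ordering may differ from
  the generating one by a few adjacent transpositions.
- Cross-validated selection has a weak penalty: on single-subtype data a
  two-subtype model occasionally generalizes marginally better (a few nats
  in ~10⁴) because mixing two orderings hedges over sequence-estimation
  uncertainty, so the argmin occasionally selects c = 2 on null data.
- The LR comparison between non-nested logistic models uses the
  conventional chi-square reference; it is flagged as non-nested rather
  than corrected.
- σ = 1 is assumed, not estimated; misspecified noise scales distort stage
  posteriors.
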