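# Methods

## Task and generative model

The task is a probabilistic instrumental learning paradigm with three
stimulus-pair conditions — gain (win £1 / nothing), loss (lose £1 /
nothing) and neutral (no monetary consequence) — at reciprocal outcome
probabilities (0.8 / 0.2 by default). A session has 3 runs; each run
introduces one fresh pair per condition, presented 30 times in shuffled
order with left/right placement counterbalanced to within one trial. Both
options' Bernoulli outcome draws are realized at schedule time, so
simulation, refitting and counterfactual analyses are exactly reproducible
from the seed. The number of trials per pair is a convention (the task
length is otherwise under-determined); it is configuration, never
hard-coded downstream.

Choices come from a Rescorla–Wagner + softmax agent. Values start at zero;
only the chosen option updates, by α·δ with δ = R·1{outcome drawn} − Q;
choice probability is the softmax of (Q_A − Q_B)/β (temperature convention:
larger β = more random). Nil outcomes contribute reinforcement 0 — the δ
definition implies this and the alternative (skipping nil trials) would
make avoidance learning impossible. The neutral condition is simulated for
task fidelity (as an R = 0 agent) but excluded from fitting: there is no
monetary outcome to learn. During simulation β is floored at 1e−3 to avoid
division blow-ups; the near-greedy limit is otherwise exact.

## Identifiability and the estimator

A structural fact dictates the estimator design: the value recursion is
homogeneous of degree one in R (all Q values scale linearly with R) and
behaviour depends on values only through Q/β. The likelihood is therefore
*exactly* invariant under (R, β) → (cR, cβ): choices identify only the
learning rate α and the sensitivity ratio ρ = R/β. Naive three-parameter
maximum likelihood drifts arbitrarily along this flat ridge and, for
near-deterministic responders (separable choice data), diverges to the
parameter bounds.

`RescorlaWagnerML` therefore:

1. maximizes the likelihood over the identified coordinates
   (logit α ∈ [−12, 12], ln|ρ| ∈ [ln 1e−4, ln 1e4]) with L-BFGS-B from 10
   seeded restarts (one fixed start at α = 0.3, ρ = 1/0.3; the rest drawn
   uniformly over plausible ranges), with the sign of ρ set by the cell's
   valence (gain ≥ 0, loss ≤ 0 by default; a free-sign mode optimizes both
   branches);
2. adds weak MAP penalties — logit α ~ N(logit 0.35, 1.0²) and
   ln|ρ| ~ N(ln 3, 1.0²) — the standard regularization against the α–ρ
   error trade-off and against the ρ divergence of separable data. In
   internal simulations these penalties cut the log-ratio estimation error
   from 0.82 to 0.33 (close to the 0.31 achievable with α known) without
   materially biasing well-identified cells. Setting
   `alpha_prior=None, rho_prior=None` recovers pure maximum likelihood;
3. reports (β, R) by a deterministic ridge convention: the point on
   R = ρ̂·β minimizing 9·(ln β − ln 0.3)² + (ln|R| − ln 1)², in closed
   form. This is a tie-break along an exactly likelihood-flat direction —
   it fixes the reported scale (β near conventional temperature magnitudes,
   |R| near the £1 stake) without touching α, ρ̂ or the likelihood. Any
   statistic of β or |R| alone should be read with this convention in mind;
   rank-based statistics are unaffected by its single tunable exponent;
4. reports the data-term NLL at the optimum, and falls back to the
   no-learning boundary solution (α = 0, R = 0, β at its anchor,
   NLL = n·ln 2) whenever the regularized optimum fits worse than the
   random-choice model — a fit is never reported as worse than chance.

Cells pool the three runs' pairs of one condition, with Q reset to zero at
each run boundary (each run uses new stimuli, so no value carries over).
`mean_log_likelihood_per_pair` is the total log-likelihood divided by the
number of pairs — a reporting convention, flagged as such. Probabilities
are clipped at 1e−12 inside the log only; the chosen option's softmax
probability is evaluated directly from the signed value difference, so no
cancellation occurs even at |Q|/β ~ 1e4. The likelihood inner loop is
JIT-compiled (numba) with a pure-Python fallback; an independent brute-force
recursion verifies it to 1e−10 over all choice sequences of length ≤ 6 and
a 27-point parameter grid.

## Crossover inference

The design is 2 × 2 within-subject (treatment: placebo/vaccine × valence:
gain/loss). With one numerator degree of freedom the repeated-measures
ANOVA is computed exactly via per-subject difference scores; the
interaction F equals the squared paired t on the difference-of-differences
(asserted to 1e−8 against an independent computation, and cross-checked
against `statsmodels.AnovaRM`). Sphericity is moot for 2 × 2 within
designs. Tests are two-sided at α = .05 with no multiple-testing
correction in the behavioural family.

The headline ANOVA on subjective value uses the **valence-aligned
magnitude** |R| (`r_magnitude`), not signed R. Gain and loss cells measure
"how much the outcome matters" on scales of opposite sign; aligning them
makes the two valence levels commensurable, and an
increased punishment sensitivity plus decreased reward sensitivity then
*add* in the interaction contrast instead of partially cancelling. Post hoc
paired t tests per valence are reported on signed R (so "more negative
R_loss under vaccine" appears as a negative t), alongside engagement
(go-rate) and session-order checks. Plateau accuracy is the correct-choice
proportion over the final ⌈n/2⌉ trials pooled over pairs ("correct" =
approach the high-probability win option, avoid the high-probability loss
option); learning curves are trailing moving averages (default window 5
trials, configurable) of the per-trial-index accuracy averaged over pairs.
Whole-sequence accuracy is available where plateau is the default.

## Model-based ROI analysis

Event timing is a desk-scale convention: cues every 8 s (inter-trial
interval; not empirically constrained), outcome 4 s after each cue, 10 s
lead-in, TR 3.3 s. Regressors are delta functions at event onsets on a
microtime grid (16 bins per TR), scaled by the mean-centered modulator
(mean-centering per series is standard parametric-modulation practice),
convolved with the canonical double-gamma HRF (response gamma shape 6,
undershoot shape 16, unit dispersions, undershoot ratio 1/6, 32 s kernel,
normalized to peak 1; shape verified against nilearn's SPM HRF) and
downsampled to the TR grid. The session design holds intercept, linear
drift, an unmodulated outcome-onset regressor, condition-specific
outcome-phase δ modulators (reward PE on gain trials, punishment PE on loss
trials) and a pooled Q-modulated cue regressor. A modulator that is
identically zero (the δ series of a no-learning fallback fit) is dropped
and its encoding beta reported as 0.

Subject-level GLMs are ordinary least squares with Gaussian log-likelihood;
BIC = k·ln n − 2·logLik with k = regressors + 1 (noise variance).
Rank-deficient designs are rejected naming the collinear columns. Group
inference is the paired t of each headline beta across treatments
(vaccine − placebo), on the signed beta: reduced reward-PE encoding in
ventral striatum appears as vaccine < placebo, and enhanced
punishment-PE encoding in anterior insula — which follows the negative-
correlation convention — also appears as vaccine < placebo on the signed
(negative) beta, with the magnitude reported alongside.

The prediction-error vs outcome-value comparison fits, per scan, two
designs differing only in the outcome-phase modulators (fitted δ vs
objective ±1/0 outcome), condition-specific on both sides and pruned in
matched pairs so the candidate complexities stay equal. The group
fixed-effects log Bayes factor is ½·Σ(BIC_outcome − BIC_PE) (positive
favours the PE family), with the proportion of scans favouring PE as a
random-effects-flavoured summary. This is a BIC approximation in the
spirit of formal Bayesian model selection, not a replication of any
specific procedure.

## The synthetic cohort generator

The generator defines the study conditions: 24 subjects, two sessions 
(vaccine/placebo) in randomized order with exactly half vaccine-first, 18
subjects "scanned" (contributing ROI data), full task per session.
Population priors — chosen once as field-plausible values, not fitted to
any data — are: α ~ Beta(2.2, 3.3) (mean ≈ 0.40), β ~ LogNormal(ln 0.3,
0.35), |R| ~ N(1.0, 0.25) truncated at 0.2 (units of the £1 stake), with
small within-subject cell jitter (SD 0.03 on α, 10 % on β, 0.05 on R). The
planted inflammation × valence effect shifts vaccine-session R by −0.4
(loss; the headline effect) and −0.15 (gain; deliberately sub-threshold).
These defaults place the detection power of the interaction well above
chance but below certainty, in keeping with the modest effect the design
emulates.

IL-6 (pmol/L, following the emulated study's printed unit) is lognormal at
baseline (median 0.8, σ 0.5) with treatment fold-changes 2.4 (vaccine) and
1.2 (placebo) at the 3.5 h sample, multiplicative noise (σ 0.3), and
left-censoring at the assay limit 0.039. ROI signals are built from the
generative (true-parameter) δ/Q series with planted weights — striatum
reward-PE 1.0 (placebo) vs 0.5 (vaccine); insula punishment-PE −0.6 vs
−1.1 — plus subject-level weight jitter (SD 0.2), linear drift and white
Gaussian noise (SD 1.0). Analysis pipelines rebuild regressors from
*fitted* series, so generative and analytic quantities never collude.

What the generator does **not** emulate — hence what passing tests do not
show about real data: response times and omissions, attentional lapses or
exploration bonuses beyond softmax noise, session-to-session parameter
drift, fMRI preprocessing artifacts, temporally autocorrelated or
non-Gaussian noise, motion, subject dropout, and any mood or temperature
physiology. Detection rates measured here are upper bounds relative to
real acquisitions with these nuisances.

## Validation harnesses and problem sizes

The package's evidence that the pipeline works, all reseeded from a single
master seed:

- **Likelihood exactness** — exhaustive comparison with an independent
  recursion (all 4^L sequences, L ≤ 6, 27 parameter triples, tol 1e−10).
- **Parameter recovery** — 200 independent prior-drawn cells at the default
  90 trials/cell (and 30/300 for the trial-count sweep), scored by Spearman
  correlation of α, β, pooled signed R, and ρ = R/β, plus the median
  absolute error of α. Given the exact ridge, β is recoverable only through
  ρ; its rank correlation has an information ceiling near 0.6–0.65 at 90
  trials, which the threshold sits against.
- **Planted-effect detection** — 100 full cohorts (generate → fit → 2×2
  ANOVA on |R|) for power and 100 null cohorts (all planted effects
  removed) for type-I control; the acceptance script uses 60 + 60.
- **ANOVA identity** — 1000 fuzzed complete tables, max |F − t²|.
- **Neural double dissociation** — 30 cohorts (25 in the script) through
  fit → simulate ROI from fitted series → GLM → paired contrasts, plus the
  BIC family-selection rate.
- **IL-6** — 50 cohorts for the post-vaccine group mean and interaction
  detection rate.

These sizes were chosen so the whole suite runs in minutes on one CPU while
keeping the binomial error of each rate a few percent.

## Known limitations

Separate point estimates of β and |R| are convention-dependent (exact
ridge); only α and R/β are data-identified, and analyses that need a scale
should use R/β or the aligned magnitude with the convention stated. MAP
regularization slightly shrinks extreme cells; pure-ML mode exists but
inherits the divergence pathology. The GLM assumes white noise (no AR
modelling) and fixed event timing; the BIC comparison is fixed-effects at
the group level. The generator's priors and planted effects are
configuration, and all downstream "power" statements are conditional on
them.
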