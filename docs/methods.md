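# Methods

`sociometer` implements trial-by-trial generative models of momentary
self-esteem under social approval feedback, a synthetic task generator that
stands in for (non-public) participant data, and the estimation machinery —
joint maximum likelihood, BIC comparison, parameter and model recovery —
needed to arbitrate between the models. This note records the models, the
numerical choices, and what the synthetic experiments do and do not show.

## The task

A session presents a sequence of raters drawn from `M = 4` groups with
approval probabilities 15/30/70/85%, chosen so overall feedback is exactly
50% approvals. On each trial the participant sees the group cue, predicts
approval or disapproval (binary choice), and receives the outcome. Every
2–3 trials a probe collects a momentary self-esteem rating on a
visual-analogue scale, mapped to the unit interval and clamped to
`[1e-4, 1 - 1e-4]` (densities on (0,1) diverge at the bounds). The default
design uses 48 raters per group (192 total); a scanner configuration adds
24 no-feedback trials. Approval counts are realised exactly: per-group
counts are rate x raters rounded half-up, with the largest group absorbing
a ±1 correction so the 50% overall balance survives rounding (e.g. 20
raters per group gives 3/6/14/17 approvals = 40/80). Group interleaving,
within-group outcome order, no-feedback placement and probe gaps are seeded
draws, so a schedule is a pure function of its design.

Because the interleaving of groups and the modelled effect of no-feedback
trials are not externally fixed, both are design choices here: interleaving
is a uniform seeded shuffle, and no-feedback trials (off by default)
advance the trial counter and apply every leak/decay but deliver no
outcome and trigger no update.

## Associative (Rescorla–Wagner) family

Hub: each group carries an expected social value `ESV_g ∈ [0,1]`
(initialised at the uninformative 0.5), updated after outcome `R ∈ {0,1}`
by `SPE = R − ESV_g` and `ESV_g += η·SPE`. The dual-learning-rate (2LR)
variants split η into `η+`/`η−` by the sign of the SPE.

Self-esteem spoke: a probe after trial t reads out

    SE_t = w0 + w1 · Σ_j γ^(t−j) SPE_j + ε,   ε ~ N(0, σ²),

maintained by the equivalent recursion `X ← γX + SPE` (the identity is
property-tested to 1e-10). Variants: a separate expectation term
`w_EV · Σ γ^(t−j) ESV_j` (pre-update ESV; the post-update alternative is a
flagged open choice), a competence mixture
`w1·(w3·ΣγSPE + (1−w3)·ΣγCPE)` where `CPE = 1[prediction correct] − Q_a`
with `Q_accept = ESV`, `Q_reject = 1 − ESV`, and a sigmoid readout
`SE = σ((X + B)·m)` replacing the affine one. The kernel sum at a probe
includes every feedback trial up to and including the trial immediately
preceding the probe.

Choice spoke: two-action softmax over `Q_accept = ESV + B` and
`Q_reject = 1 − ESV` at temperature τ; the reject value follows the
competence convention, making the published accept-only rule a proper
two-action softmax. The fixed-bias variant pins `B = 0`.

Free parameter counts: baseline 7; 2LR 8; 2LR+expectation 9;
2LR+fixed-bias 7; competence 8; sigmoid 7.

## Belief model

Beliefs about each group's approval rate are beta distributions whose α/β
act as approval/disapproval pseudo-counts ("1 in 4 will like me" is
Beta(1,3)). Each trial every group belief leaks toward the uniform (1,1):
`α' = (1−λ_acc)α + λ_acc` (same for β); the encountered group then adds
the outcome to its counts. Initial group alphas interpolate linearly from
`α0_min` to `α0_max` with every total count fixed at `n0 = 2 + 1/λ_acc`
(tying prior strength to retention, and removing `n0` as a free
parameter); validation requires `α0_max ≤ n0 − 1` so no initial β drops
below 1.

The prediction error `δ = o − α'/n'` (post-decay, pre-increment values)
feeds a second beta-belief about the *momentum* of approval:

    α_S ← (α_S − 1)·ς + 1 + w·max(δ, 0)
    β_S ← (β_S − 1)·ς + 1 + w·max(−δ, 0)

so wins and losses accumulate separately, both counts stay ≥ 1, and with
no evidence the belief decays to the uniform fixed point. The source
equations print `max(δ, 0)` on both lines; that form (under which the
self-belief mean can never fall) is taken to be typographical and is kept
available behind `config.LITERAL_SELF_UPDATE`. The self-belief starts at
(1,1); the initial point of the deterministic expected-SE trajectory uses
the pooled expectation `Σα_i / Σn_i` through the readout. Probes never
precede trial 2, so this initial condition does not enter likelihoods for
generated schedules.

A rating is generated by drawing `P_acc ~ Beta(α_S, β_S)` and applying the
sigmoid readout

    SE = 1 / (1 + ((1 − P_acc)/(P_acc·B))^m),

which is affine in log-odds: `logit(SE) = m·(logit(P_acc) + ln B)`. That
form makes the map strictly monotone and analytically invertible, so the
rating likelihood is the *exact* pushforward density (change of
variables), not a Monte-Carlo estimate — deterministic and
optimiser-friendly, and equal in distribution to the sampling scheme. The
density simplifies to
`exp(α_S·log σ(z) + β_S·log σ(−z) − B(α_S, β_S)) / (m·r·(1−r))` with
`z = logit(r)/m − ln B`; it is property-tested to integrate to 1 (1e-6).
The expected rating uses 256-node Gauss–Legendre quadrature over the beta
density (cross-checked against Monte Carlo).

Choice: `π = σ((G_acc − 0.5 + B_choice)/T)` with `G_acc = α/n`. The −0.5
centering implements the stated indifference point at 0.5; the literal
uncentred form is available behind `config.LITERAL_CHOICE_RULE` (the two
are equivalent up to a reparameterisation of the bias).

Per-trial order of operations: decay → choice probability → prediction
error (primed values) → count update → self-belief update → readout at
probes. 9 free parameters; the initial-belief pair is fitted in
unit-interval coordinates (`a0_lo_u`, `a0_span_u`) that keep every initial
pseudo-count ≥ 1 for any λ_acc.

## Fitting and comparison

The joint negative log-likelihood sums the log choice probabilities over
all prediction trials and the log rating densities over all probes; the
discrete likelihood and continuous density enter on equal footing, and
`n_obs` for BIC counts both streams. Optimisation runs in an unconstrained
space (scaled logit of each box bound), with L-BFGS-B restarted from the
bounds' midpoint plus a seeded scrambled Sobol design — 129 starts by
default. Non-finite evaluations return a large finite penalty (1e10); ties
between optima break by lower negative log-likelihood, then lower
transformed-parameter norm. BIC is `ln(n)k − 2lnL`; mean squared error
over probe ratings is provided as a secondary diagnostic. The belief
likelihood is evaluated by an IIR-filter formulation (the leaky
accumulations are linear recursions and the belief dynamics do not depend
on the participant's responses); it is tested against the trial-stepped
reference to 1e-9.

Box bounds (fitting): unit-interval parameters (learning rates, decays,
kernel weights) on (1e-3, 1−1e-3); scale parameters (σ, τ, T, m) on
(1e-3, 20); additive biases on (−1, 1); the multiplicative readout bias
B_se on (1e-2, 100). These are deliberately loose and live in one place
(`config.py`).

## Recovery experiments and the synthetic generator

Recovery cohorts are the package's acceptance surface: 30 participants on
200-trial sessions (50 raters per group, ~78 probes), generated with
parameters drawn uniformly from declared ranges, re-fitted with a reduced
12-start grid (the documented fast mode; start-count sweeps show the
optima are unchanged from 129 starts at these problem sizes, the grid
exists to escape local optima in the 7–9-dimensional likelihoods).

Generation ranges are the interior 10–90% of the fitting bound for every
natively-unit-interval parameter. Scale parameters instead use
behaviourally plausible intervals (σ ∈ (0.05, 0.2), τ ∈ (0.1, 0.4),
m ∈ (0.5, 3), …): 10–90% of a (1e-3, 20) bound would put most cohorts in
a pure-noise regime that carries no information about any dynamic
parameter. Two degeneracy guards apply. For the Gaussian-readout
associative variants, draws with `w1 > 1 − γ` are rejected: the leaky PE
sum is bounded by 1/(1−γ), so such draws emit rating means far outside the
scale, pile ratings at the clamp bounds, and break the
generative/likelihood correspondence (the Gaussian likelihood is not
censored). For the belief model the ranges themselves exclude
unidentifiable corners (w ≈ 0, near-memoryless ς).

What the synthetic generator does not emulate: real participants'
heavy-tailed response noise, lapses, scale-use idiosyncrasies (anchoring,
coarse rounding of the VAS), and any drift in attention. Passing recovery
therefore shows the *pipeline* is consistent — the estimator identifies
the parameters and the BIC comparison identifies the generating model
under the models' own assumptions — not that the models are correct for
human data, and not that empirical BIC tables from participant data are
reproduced (those require the original data).

Measured at these conditions: rank correlations for the associative
η, γ, w1 are ≈ 0.84–0.98; belief ς ≈ 0.73 and m_se ≈ 0.83. The belief PE
gain w is the weakest-identified key parameter: across cohort draws its
rank correlation spans ≈ 0.6–0.75 (it partially trades off against the
readout parameters), and more optimizer starts do not change this — a
genuine identifiability limit at 30 participants, not an optimisation
failure. Group-belief initial conditions (α0_min, α0_max) and λ_acc are
weakly recovered, as found in the original development of such models
(hence `n0` being tied to λ_acc in the first place). Model recovery is
strongly directional: belief-generated cohorts are BIC-won by the belief
model in ~97% of participants, associative-generated cohorts by the
associative model in ~60% (the belief model's flexible heteroscedastic
readout lets it shadow associative data fairly well; the BIC penalty for
its two extra parameters is what keeps the direction correct).

## Known limitations

- Per-participant MLE only; no hierarchical pooling (matching the original
  analysis strategy).
- The likelihood treats clamped boundary ratings as interior observations
  rather than censored ones.
- Open modelling questions carried as flagged choices: pre- vs post-update
  ESV in the expectation kernel; whether ς applies on no-feedback trials
  (it does here when such trials are enabled); the printed vs sign-corrected
  self-belief update and the choice-rule centering (both switchable).
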