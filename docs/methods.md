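# Methods

`faceconn` re-implements, as a tested pipeline over synthetic data, an
effective-connectivity analysis of the core face-perception network:
three right-hemisphere regions — occipital face area (OFA), fusiform
face area (FFA) and posterior superior temporal sulcus (STS) — coupled
by a bilinear dynamic causal model (DCM), inverted per subject-session
over a 24-model space, compared by random-effects Bayesian model
selection (BMS), averaged by Bayesian model averaging (BMA), and pooled
across heterogeneous studies with a contrast-coded hierarchical linear
model (HLM).

## The generative model

Neural dynamics follow the deterministic bilinear state equation

    dz/dt = (A_eff + Σ_j u_j(t) B(j)) z + C u(t)

with z the three regional activations (Hz), u the sampled experimental
inputs, A the endogenous couplings, B(j) the change in coupling induced
by context u_j, and C the driving influence (entering at the OFA only).
Self-connections are parameterized in log-scale: region r's recurrent
rate is −0.5·exp(a_r), negative by construction; a_r = 0 corresponds to
−0.5 Hz. Modulatory inputs are not mean-centered: B entries read as
coupling *added while the condition is on*.

Each region's activity drives a balloon/Windkessel hemodynamic model —
vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q —

    s' = ε z − κ s − γ (f − 1)
    f' = s
    τ v' = f − v^(1/α)
    τ q' = f (1 − (1−E0)^(1/f))/E0 − v^(1/α) q/v

with the static BOLD observation
y = V0 (k1 (1−q) + k2 (1−q/v) + k3 (1−v)), k1 = 7E0, k2 = 2,
k3 = 2E0 − 0.2. Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32,
E0 = 0.4, V0 = 0.04; all overridable. Per-region log-deviations of ε and
τ are free parameters of the inversion.

Numerical choices:

* f, v, q are integrated as logarithms, so they stay positive by
  construction; a log state beyond ±8 (flow or volume changed by e⁸)
  marks model breakdown and raises an instability error carrying the
  offending time index.
* The integrator is fixed-step classical Runge–Kutta (RK4) on a
  microtime grid of `tr/16` by default, with explicit Euler available.
  RK4 is the default because at the default step it reproduces the
  matrix-exponential closed form of the linear regime to better than
  1e−3 relative RMS, which explicit Euler at that step does not.
* At dt = 0.5 s (microtime ratio 4, used in some scaled experiments) the
  volume equation becomes RK4-stiff when inflow is very high; parameter
  draws whose trajectories breach the admissible band are rejected and
  redrawn by the cohort generator, and the benchmark for undamped
  (feedforward-only) dynamics uses the finer `tr/8` grid.
* BOLD is sampled at scan onsets and mean-centered per region;
  observation noise is i.i.d. Gaussian per scan.

## The candidate model space

Structures differ in which of the six directed inter-regional couplings
exist. Three rules define admissibility: the driving input enters at the
OFA only; FFA and STS must be reachable from the OFA; a backward edge
onto the OFA requires the matching forward edge. Exactly 24 of the 64
edge subsets qualify (verified in the tests against an independent
brute-force BFS oracle). Every admitted edge is open to modulation by
each modulatory input; self-connections are never modulated. Ids are
assigned by ascending edge-set bitmask, so the fully interconnected
structure is always #24; `ModelSpace.forward_only_model` and
`.full_model` provide order-independent access to the two landmark
structures.

## Inversion: variational Laplace

`DCM.fit()` maximizes the variational free energy
F = accuracy − complexity over a fixed-form Gaussian posterior:
accuracy is the expected Gaussian log-likelihood (per-region noise
log-precisions h_r with Gaussian hyperpriors, updated by Newton steps
inside each iteration, capped at |h| bounds so exactly noise-free data
cannot overflow), and complexity is the KL divergence from prior to
posterior (θ and h), non-negative by construction. The ascent is damped
Gauss–Newton with a Levenberg-style multiplicative damping: a step is
accepted only if it raises F, so the recorded F trace is non-decreasing;
damping beyond a ceiling terminates the run. Jacobians are one-sided
finite differences reusing the current prediction (a central-difference
Jacobian refines the Laplace curvature once at the optimum).

The free-energy surface is multimodal (verified: fits from different
starts reach optima 20–40 nats apart), so `fit()` uses a small
deterministic multi-start — the prior mean plus perturbed coupling
starts from a fixed, data-independent seed — and returns the best run.
`fit_model_space` inverts the fully parameterized structure first and
offers its masked posterior to every sparser structure as a warm start.

Shrinkage priors (zero mean): variance 1/16 on A off-diagonals, 1/64 on
log-scale self-connections, 1 on B, 1 on C, 1/64 on the hemodynamic
log-deviations — the endogenous backbone is constrained much more
tightly than the condition effects. Convergence: ΔF < 1e−3 on three
consecutive accepted steps, at most 96 iterations; non-convergence is
flagged in the results, never silently dropped.

AIC and BIC are computed from the posterior-mode log-likelihood on the
log-evidence scale (AIC = lnL − k; BIC = lnL − (k/2) ln n_scans); the
three criteria need not agree on ranking and are reported without
reconciliation.

## Group statistics

Random-effects BMS runs the variational Dirichlet scheme over the
log-evidence matrix; expected model probabilities are α/Σα and
exceedance probabilities are Monte-Carlo frequencies of the argmax under
Dirichlet(α) (default 1e5 draws, fixed seed, validated against the K=2
Beta closed form to 0.01). The Dirichlet prior is uniform (α0 = 1). BMA
averages posterior means over the *full* model space with softmax(F)
weights — no Occam's window, so no model is dropped; parameters a model
excludes contribute zero under its weight.

Per-study inference: two-sided one-sample t-tests per inter-regional
connection, Bonferroni-corrected within each matrix (α/n, n = number of
inter-regional tests in that matrix; 6 for full A or B, 1 for C);
self-connections are excluded (negative by construction) and
hormone-manipulation studies are reported per session. Zero-variance
cells carry the exact limiting p with a `degenerate` flag rather than
NaN.

Cross-study pooling fits, per connection and matrix, a random-intercept
HLM with contrast-coded fixed effects: AvsB (+0.5/−0.5), ABvsC
(+0.25/+0.25/−0.5), ABCvsD (+1/6 each vs −0.5; the exact fraction keeps
the codes zero-sum) and the hormone contrast MvsP (+0.5 mid-luteal /
−0.5 early-follicular). With zero-sum codes the fixed intercept is the
average effect across studies — the pooled estimate. The emotion matrix
drops the hormone term and any contrast involving studies that did not
manipulate emotion; the fame matrix is intercept-only; on partial
cohorts, constant or collinear contrast columns are dropped
sequentially. The fitter is an exact profiled REML: for any variance
ratio ψ = σu²/σε² the fixed effects are the closed-form GLS solution,
and the REML criterion is minimized over log ψ in one dimension
(cross-checked in the tests against statsmodels MixedLM). Intercept
p-values use a t reference with between-within residual degrees of
freedom n_obs − n_fixed − n_participants + 1 (switchable to a normal
reference). The HLM consumes BMA point estimates only, discarding their
posterior variances — a deliberate simplification, shared with the
analysis it re-implements, that understates uncertainty.

## The synthetic cohort

The generator emulates a four-study corpus: A (23 participants × 1
block-design session, four face-block types of which three are
emotional), B (27 × 1, two block types), C (17 × 2, all female, one
mid-luteal and one early-follicular session per participant, neutral
faces only), D (16 × 5–9 event-related famous/non-famous sessions).
Block layout: 16 s face blocks and 16 s control blocks alternating with
4 s gaps; the "emotion" input covers an exactly-shuffled 3/4 of face
blocks. Event layout: 0.6 s face events, inter-stimulus intervals
jittered 3–6 s, an exactly-shuffled half famous.

Population model: participant parameters are Gaussian around the pooled
cross-study means (face modulation +0.92 OFA→FFA, +0.77 OFA→STS, −1.13
FFA→OFA, −0.31 FFA→STS, −0.4 STS→FFA; emotion +0.35 OFA→STS, −0.19
FFA→STS; endogenous +0.08 OFA→FFA, −0.19 FFA→OFA; drive +1.42; fame all
zero) with between-participant SDs of 0.1 on endogenous and 0.25 on
modulatory/driving entries — chosen to make recovery nontrivial but
feasible at the default signal-to-noise ratio. Draws are truncated to
stability twice over: an eigenvalue screen on every modulated coupling
matrix, then an attempted forward simulation (which also catches
transient, non-normal excursions that break the hemodynamic model).
Noise SD is calibrated per study so that signal SD / noise SD ≈ 1 for
the population mean. Every random stream is keyed by
(seed, study, participant, session), so any subset regenerates
identically.

What the generator does *not* emulate: voxel-level images and ROI
extraction, physiological noise and its autocorrelation, scanner drift,
head motion, session-to-session hemodynamic variability, and
hemispheric asymmetries. Passing recovery tests therefore demonstrate
the estimation machinery under the model's own assumptions, not
robustness to real fMRI artifacts.

## Recovery benchmarks and problem sizes

Parameter recovery simulates one subject from the pooled means on a
dedicated on/off benchmark design (16 s faces / 4 s rest: the high duty
cycle keeps the face-modulated state observable for most of the run
while the short rests expose return-to-baseline dynamics) at SNR ≈ 1
with 400 scans, inverts the fully connected structure, and scores the
Spearman rank correlation over the 16 connectivity parameters (A
off-diagonal, log-scale self, B, C). The six hemodynamic log-deviations
are nuisance and excluded from the score: their generating values are
identically zero, and a rank statistic over a vector dominated by tied
zeros measures tie-breaking noise rather than recovery. At these
conditions the benchmark recovers ρ > 0.8 in 10/10 seeds (Pearson
0.91–0.99).

Model recovery asks whether RFX-BMS identifies the generating structure.
Two generating truths are used. The forward-only truth (edges OFA→FFA,
OFA→STS only; drive reduced to +0.6 Hz to keep the undamped feedforward
cascade inside the balloon model's validity range) is recovered exactly
at small scale. The fully connected truth sets the three weak or null
lateral/backward entries of the pooled estimates to ±0.8 Hz (signs
chosen by a stability search): under the pooled means themselves, one
edge carries *no* effect at the population level, so the statistically
correct selection there is the sparser model — structure recovery is
only well-posed when every edge of the generating structure is
individually detectable. Even then, a single session must be long
(≥600–800 scans) before the evidence for each weak edge outweighs its
complexity cost (≈4–6 nats per edge under these priors), and driving the
group exceedance of the full model above 0.9 against 23 competitors
additionally needs six or more consistently confident subjects. The
corresponding acceptance experiment is therefore run at a reduced scale
(10 seeds × 3 subjects × 200 scans) chosen to fit a desk-scale test
budget; at that scale the full model is *not* reliably selected, and the
test documents this as a measured limitation rather than relaxing its
threshold. The companion experiments (forward-only recovery, exceedance
calibration, symmetry) pass at full fidelity.

The end-to-end experiment pushes a scaled four-study cohort (5/5/4/4
participants, 30 sessions in all, 100-scan sessions, microtime ratio 4)
through
simulate → 24-model inversion → BMS/BMA → t-tests → HLM and checks the
qualitative pooled pattern: significant positive face modulation of
OFA→FFA and OFA→STS, significant negative FFA→OFA, and no significant
fame modulation when fame effects are generated as zero.

## Known limitations

* Posterior uncertainty is Laplace-approximated around a local optimum;
  multimodality is handled by multi-start, not marginalized.
* The HLM pools point estimates, ignoring first-level posterior
  variance.
* Model-evidence comparisons at desk-scale session lengths
  systematically favor structures sparser than the generating one when
  edge effects are weak or collinear — an instance of the general
  complexity/absorption behavior of nested dynamic models, quantified
  above.
* Inputs are aligned to scan onsets; no slice-timing offsets inside the
  microtime grid.
* Exact numerical parity with any specific SPM release is a non-goal;
  the contracts validated here are internal consistency, closed-form
  oracles, and recovery behavior.
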