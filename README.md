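# faceconn

Effective connectivity of the core face-perception network — a tested,
reusable pipeline for simulating, inverting and pooling dynamic causal
models (DCMs) of the three-region system formed by the occipital face
area (OFA), the fusiform face area (FFA) and the posterior superior
temporal sulcus (STS).

The package is aimed at researchers who want to study the *behavior* of
this analysis chain — parameter and model recovery, selection
calibration, cross-study pooling — without access to fMRI data: a
synthetic-cohort generator stands in for the multi-study corpus, so
every downstream stage is exercised end to end with known ground truth.

## What it computes

**Generative model.** Region activity follows the bilinear neural state
equation

    dz/dt = (A + Σ_j u_j B(j)) z + C u

with endogenous couplings A (self-connections −0.5·exp(a) Hz, negative
by construction), context-induced coupling changes B(j), and a driving
input C entering at the OFA. A balloon/Windkessel hemodynamic model per
region maps z to the BOLD signal.

**Model space.** All 24 admissible patterns of the six inter-regional
couplings (driving input at OFA only; FFA and STS reachable from OFA;
backward edges onto OFA require the matching forward edge), each with
every admitted edge open to modulation.

**Inversion.** `DCM(data, design, structure).fit()` maximizes the
variational free energy F (accuracy − complexity) by damped Gauss–Newton
with deterministic multi-start, returning a `DCMResults` with posterior
means/covariance, F, AIC, BIC and a convergence record.

**Group level.** Random-effects Bayesian model selection
(`rfx_bms`: Dirichlet posterior over model frequencies, expected and
exceedance probabilities), Bayesian model averaging per subject-session
(`subject_bma`, full-space softmax(F) weights), per-study one-sample
t-tests with per-matrix Bonferroni correction, and a contrast-coded
random-intercept hierarchical linear model (`RandomInterceptHLM`,
profiled REML) whose fixed intercept pools each connection across
studies.

## Worked example

```python
import numpy as np
from faceconn import (enumerate_model_space, default_ground_truth,
                      recovery_design, sample_bold, DCM)
from faceconn.cohort import calibrate_noise_sd, _restrict_modulators

space = enumerate_model_space(["faces"])
print(len(space), space.full_model.id)          # 24 24

truth = _restrict_modulators(default_ground_truth().mean, ())
design = recovery_design(tr=2.0, n_scans=400)
noise = calibrate_noise_sd(truth, design, tr=2.0, n_scans=400)
data = sample_bold(truth, design, tr=2.0, noise_sd=noise, seed=0)

results = DCM(data, design, space.full_model).fit()
print(results.summary())
```

```
DCM inversion, model #24
  free energy F = 3472.232   AIC = 3491.049   BIC = 3447.143
  free parameters: 22, scans: 400, iterations: 39, converged: True
  parameter                         mean        sd
  A OFA->FFA                      0.1862    0.2124
  A OFA->STS                      0.0391    0.2203
  A FFA->OFA                     -0.1614    0.0863
  ...
  B OFA->FFA [faces]              0.9146    0.3959
  B OFA->STS [faces]              0.7212    0.2967
  B FFA->OFA [faces]             -0.8721    0.3768
  ...
  C input->OFA                    1.3765    0.3204
```

The generating face modulations (+0.92 OFA→FFA, +0.77 OFA→STS, −1.13
FFA→OFA) and drive (+1.42) are recovered within about one posterior
standard deviation at a signal-to-noise ratio of 1.

A full synthetic four-study analysis — cohort simulation, 24-model
inversion per session, per-study BMS/BMA, t-tests and the pooled HLM —
runs from the command line:

```
faceconn pipeline --config config.yaml --out results/run1
```

which writes the cohort, per-session inversions, BMS/BMA tables, the
cohort table, the pooled HLM report and a checksummed run manifest.
Individual stages (`simulate`, `invert`, `bms`, `bma`, `study-stats`,
`hlm`) operate on the same on-disk formats.

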