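# crossconn

Whole-brain functional and effective connectivity analysis for
two-condition (drug vs placebo) cross-over resting-state fMRI studies —
with a synthetic-study generator that makes every stage testable against
known ground truth.

## The scientific problem

Pharmacological resting-state studies ask how a compound reorganises
brain-wide communication. Functional connectivity (FC) — the Pearson
correlation r_ij between the BOLD time series of regions i and j — is
undirected and blind to two organisational features of cortex: the
asymmetry of directed influences, and within-region gain ("self-
connections"). Effective connectivity (EC) under a linear dynamic causal
model supplies both: neuronal states follow

    dx/dt = A x + w,

where the off-diagonal entries a_ij (Hz) are directed influences of region
j on region i, and the strictly negative diagonal entries a_ii are decay
rates — the region's self-inhibition, a per-region summary of
excitation/inhibition balance. Regression DCM (rDCM) makes whole-brain
estimation tractable by rewriting the state equation, region by region, as
a Bayesian linear regression in the frequency domain:

    d(m) · Y_i(m) = Σ_j a_ij · Y_j(m) + ε(m),   d(m) = (e^{2πim/T} − 1)/TR,

inverted with conjugate Gaussian–Gamma variational updates. A 132-region
parcellation gives 8,646 unique FC coefficients and 17,424 EC parameters
per session.

On top of the connectomes the package provides the full inference chain of
a paired cross-over design: physiological-covariate residualization,
mass-univariate paired t-tests with Benjamini–Hochberg FDR control,
directed-asymmetry tests (forward vs backward coupling per pair, plus the
drug-by-asymmetry interaction), mean-centred task PLSC and behavioural
PLSC with permutation and bootstrap inference, and random-forest condition
decoding with leakage-safe group-aware cross-validation, permutation
significance, McNemar model comparison and out-of-bag feature importance.

Because real pharmaco-fMRI datasets are rarely shareable, the
`simulate` module generates complete cross-over studies from a known
stochastic network model — drug effects that strengthen coupling and
reduce self-inhibition except in an "occipital-like" subset where both
reverse, physiological covariates, and a behavioural score wired to each
subject's true connectivity change — so parameter recovery, type-I error
and decoding power are all verifiable.

## Worked example

```python
import numpy as np
from crossconn import (SimulationConfig, sample_ground_truth,
                       simulate_bold, invert_rdcm)

cfg = SimulationConfig(n_subjects=1, n_regions=10, n_timepoints=600,
                       tr=2.0, obs_snr=3.0, seed=1, subject_sd=0.0,
                       effect_offdiag=0.0, effect_self=0.0)
rng = np.random.default_rng(1)
truth = sample_ground_truth(cfg, rng)[0].a_placebo
ts = simulate_bold(truth, cfg, rng)       # 600 volumes of 10-region BOLD
ec = invert_rdcm(ts)                      # whole-brain rDCM inversion

off = ~np.eye(10, dtype=bool)
print(np.corrcoef(ec.a[off], truth[off])[0, 1])
```

prints

```
off-diagonal recovery correlation: 0.866
estimated self-connections (Hz): [-0.24 -0.19 -0.2  -0.19 -0.22 -0.26 -0.21 -0.24 -0.2  -0.28]
```

i.e. the directed couplings of the generating network are recovered with
r ≈ 0.87 from 20 minutes of simulated scan at realistic noise, and every
self-connection is negative (the system decays back to baseline), though
shrunk toward zero relative to the true −0.45 Hz — correlation, not scale,
is the meaningful recovery metric after per-region signal normalisation.

Group-level, on a 20-subject synthetic study (`examples/03`, `04`):

```
FC edges significant at FDR 0.05: 42/45
task PLSC singular values: [0.234 0.   ]
LV1 permutation p: 0.0005 (LV2 p: 1.000)
behavioural PLSC latent correlation: 0.946
decoding balanced accuracy: 0.850 (permutation p 0.010)
```

The second task-PLSC singular value is identically zero — with two
conditions the mean-centred rows are exact negatives, so only one latent
variable can exist and its permutation p is 1 by construction.

Each script in `examples/` is a narrative demo of one capability:
simulation and I/O, effective-connectivity recovery, group inference, and
behaviour/decoding. A thin CLI (`crossconn simulate|fc|rdcm|stats|plsc|
classify|asymmetry|run-all`) wraps the same functions for shell use;
`run-all --seed N --out DIR` produces a deterministic results directory
with a machine-readable `summary.json`.

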