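# Methods

## Generative model

Neuronal dynamics per subject and condition follow a linear stochastic
(Ornstein–Uhlenbeck) network

    dx/dt = A x + w,

with coupling matrix A (Hz) and white state noise w of standard deviation
`state_noise_sd` per √s. Stability requires every eigenvalue of A to have
real part ≤ −0.05 Hz; the generator enforces this by diagonal shifts and
treats a shift below −10 Hz as a configuration error. BOLD is obtained by
convolving each region's state with a canonical double-gamma haemodynamic
response (peak 6 s, undershoot 16 s, undershoot ratio 1/6, 32 s support),
sampling every TR seconds after a lead-in equal to the state burn-in
(30 s) plus the HRF support — so the first retained volume is free of both
the initial-condition transient and the convolution edge — z-scaling per
region, and adding white observation noise with standard deviation
1/`obs_snr`. Because the signal is z-scaled first, `obs_snr` has a fixed
meaning as the signal-to-noise standard-deviation ratio.

Euler–Maruyama integration uses `integration_dt` (default 0.1 s). No
nonlinear (balloon-type) haemodynamics and no volumetric images are
simulated; region-level series are the unit of analysis.

## The synthetic cross-over study

A study consists of `n_subjects` (default 45, the reference paired-design
size) with one placebo and one drug session each. The group-mean network
has a fixed in-degree: every region receives 3 inbound couplings of
magnitude 0.2 Hz (jittered U(0.7, 1.3), random sign), self-connections
−0.45 Hz. Fixed in-degree keeps the stationary variances comparable across
regions; since each region's signal is z-scaled, heterogeneous variances
would otherwise be folded silently into the effective couplings (the
estimable quantity is S⁻¹AS with S the per-region signal scales). The
coupling magnitudes are free parameters of the testbed, chosen so that the
reference desk-scale recovery experiment is informative; they are not
estimates of any empirical effect size.

The drug condition adds a shared increment: a random quarter of the
ordered region pairs receive +`effect_offdiag` (default 0.06 Hz), flipped
to negative when both regions belong to the designated "occipital-like"
subset (by default the last ~12% of regions, matching the occipital share
of a whole-brain anatomical parcellation); self-connections shift toward
zero by `effect_self` (default 0.1 Hz) outside that subset and away from
zero inside it — i.e. widespread disinhibition with occipital
hyper-inhibition. Per-subject placebo matrices scatter around the group
mean with sd `subject_sd` (default 0.02 Hz), and an independent jitter of
the same size perturbs each subject's drug increment, so subjects genuinely
differ in how strongly the drug reshapes their connectome.

The behavioural score emulates a global subjective-effect rating:
`behav_offset + behav_scale × readout + noise`, where the readout projects
the subject's true increment (a_drug − a_placebo) onto the sign pattern of
the group effect template. With `behav_noise_sd = 0` the score is exactly
collinear with the readout — the noise-free limit used in tests. Baseline
physiology (heart rate, diastolic/systolic blood pressure, body
temperature) is drawn from plausible resting adult ranges; when
`covariate_effect` ≠ 0 the standardized covariates additively perturb a
fixed random subset of couplings in both conditions, giving downstream
residualization real signal to remove.

What the generator does not emulate: head motion and scanner drift,
spatially correlated physiological noise, haemodynamic variability across
regions and subjects, non-stationarity within a session, and sampling from
a nonlinear neurovascular cascade. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that real LSD-scale effects would be detected with these sample sizes.

## Effective connectivity estimation

`invert_rdcm` implements the resting-state regression-DCM scheme. The
discrete Fourier transform of each mean-removed (optionally z-scored)
region series gives spectra Y_j(m); the temporal-derivative spectrum of a
target region, formed with the exact transfer function of the first-order
forward difference, d(m) = (e^{2πim/T} − 1)/TR, is regressed on all source
spectra. Complex rows are split into stacked real and imaginary parts,
doubling the row count; the Gamma precision update uses that stacked
count, which must be kept in mind when comparing free-energy values across
implementations. There are no driving inputs; the stochastic drive is
absorbed into the regression residual. Confound handling beyond mean
removal is unnecessary for the synthetic data; the DC bin is always
excluded.

Two estimation details matter in practice:

* **Haemodynamic whitening.** The stochastic drive reaches the data
  through the HRF, so the regression residual carries the HRF's spectrum
  |H(ω)|². Because H multiplies both sides of the coupling relation it
  cancels from the regression identity, but leaving the residual coloured
  makes it strongly correlated with the regressors (the HRF spreads each
  innovation over ~16 TRs) and biases least squares badly. Dividing every
  spectrum by H(ω) — the canonical HRF's transfer function at the TR grid
  — whitens the residual; the noise-free identity is untouched.
* **Noise roll-off.** Observation noise is spectrally flat, so after
  whitening it dominates wherever |H| is small. Each bin is therefore
  weighted by 1/√(1 + (γ/|H_n(ω)|)²) with |H_n| the peak-normalised HRF
  gain and γ (`rolloff`, default 0.8) the assumed noise-to-signal ratio at
  the HRF peak. With the roll-off in place the full band up to Nyquist is
  retained by default; a hard low-pass mask ([1/(T·TR), 0.12 Hz]) remains
  available via `whiten_hrf=False` for the conventional band-limited
  variant. The soft weighting was adopted after the hard mask alone left
  recovery correlations near 0.45 at the reference conditions: restricting
  bins re-introduces a per-bin correlation between residual and regressor
  that cancels only when (nearly) all bins are summed.

Each region's regression is inverted independently (regions share the
design, so results are order-independent) with conjugate Gaussian–Gamma
coordinate updates: Σ = (P₀ + E[τ]XᵀX)⁻¹, μ = Σ(P₀μ₀ + E[τ]Xᵀy), then
shape = a₀ + n/2, rate = b₀ + ½(‖y − Xμ‖² + tr(XᵀX Σ)). The variational
free energy is computed after each sweep and is non-decreasing; iteration
stops when it changes by < 1e−6 (cap 500 iterations, non-convergence
flagged rather than raised). Default priors — couplings N(0, 1),
self-connections N(−0.5, 0.25), τ ~ Gamma(2, 1) — target unit-scale
z-scored data and are fully configurable. Priors this weak are effectively
inactive at the reference data sizes; they matter for short or noisy
sessions.

Estimates are shrunk toward zero relative to the generating A (finite-TR
discretisation maps A to (e^{A·TR} − I)/TR, and per-region normalisation
absorbs scale), so recovery is assessed by correlation over off-diagonal
entries, not by absolute error. At the reference desk-scale conditions
(10 regions, T = 600, TR = 2 s, obs_snr = 3) the mean recovery
correlation over 10 networks is ≈ 0.86, rising monotonically with scan
duration (≈ 0.72 at T = 150, ≈ 0.81 at T = 300). An explicit
errors-in-variables correction of the sufficient statistics (estimating
the observation-noise floor from the near-Nyquist spectral plateau) was
evaluated and rejected: it destabilised the inversion and degraded
recovery.

## Functional connectivity and feature conventions

FC is the plain product-moment correlation; raw r is the default feature
(a Fisher-z helper exists for downstream normality). Vectorization orders
are canonical and shared package-wide: FC takes the upper triangle
row-major (R(R−1)/2 features), EC all ordered pairs row-major (R(R−1)),
self-connections the diagonal (R). Feature identifiers are
(source, target, kind) triples; for EC, matrix entry (i, j) is the
influence of j on i, hence source j → target i. For classification and
whole-matrix PLSC the EC feature set concatenates off-diagonal and self
families (R² features; 17,424 at R = 132), while self-connections are also
analysed as their own R-length family.

## Group statistics

Residualization regresses each feature on [1, heart rate, dbp, sbp,
temperature] by OLS and keeps the (mean-zero) residuals; the design is
checked for rank and collinear columns are named in the error. A
fit/transform variant (`CovariateResidualizer`) exists for use inside
cross-validation. Paired t-tests run per feature with Benjamini–Hochberg
FDR over each family separately (FC; full EC; self-connections); features
with zero within-pair variance are excluded from the family rather than
assigned a pseudo p-value, keeping the FDR denominator honest. The
asymmetry analysis tests a_ij vs a_ji across subjects within each
condition for every unordered pair, plus the condition difference of the
asymmetry (drug-by-asymmetry interaction); counts at p < 0.05 are reported
uncorrected by default — the convention for this analysis — with a flag
for BH within each family. All statistics are antisymmetric under
direction swap by construction.

## PLSC

Task mode: SVD of the condition-mean matrix centred on the grand mean.
With two conditions the centred rows are exact negatives, so the second
singular value is identically zero and its permutation p is 1 —
a structural fact, not a finding. Salience signs are fixed so the drug
condition weighs positively, making outputs reproducible across
linear-algebra backends. Permutation inference flips condition labels
within subject — the exchangeable transformation of a cross-over design,
rather than free row shuffling — and enumerates all 2ⁿ flip patterns
exhaustively when they fit within `n_perm` (default 2000); p-values use
the add-one convention (1 + #{null ≥ observed})/(1 + n_perm). Bootstrap
resampling keeps subjects (both sessions together) as the unit; bootstrap
saliences are aligned to the original by orthogonal Procrustes (a sign
flip for one component) before the standard error is taken, and zero
bootstrap variance yields a capped sentinel (±1e6, 0 where the salience is
itself 0). Σσ² equals the squared Frobenius norm of the centred matrix on
every run — asserted, not assumed.

Behavioural mode: features and behaviour are z-scored; the cross-block
vector of feature–behaviour correlations is the (rank-one) matrix whose
SVD gives the single LV. The latent brain score's correlation with
behaviour is reported with its sign fixed non-negative. The per-subject
feature table defaults to drug-condition features, with a
condition-difference option; the difference features are the natural
choice when behaviour reflects the drug-induced change, and the
signal-recovery tests use them.

## Decoding

Random forests (500 trees, √F features per split by default) decode drug
vs placebo. Folds are group-aware — both sessions of a subject share a
fold, enforced by a hard error — and all preprocessing (near-zero-variance
pruning, greedy correlation pruning at |r| > 0.95, covariate
residualization) is fitted on the training fold only and applied to the
held-out fold. Out-of-fold predictions pool into one balanced accuracy.
The permutation null flips labels within subject and re-runs the entire
embedded pipeline per permutation (lighter forests are configurable for
the null, since its purpose is rank, not accuracy); exhaustive enumeration
replaces sampling when 2ⁿ patterns fit the budget. Classifier pairs are
compared with McNemar's test on pooled out-of-fold predictions: exact
binomial when the discordant count is below 25, continuity-corrected
chi-square otherwise. Feature importance is the mean decrease in accuracy
on permuted out-of-bag samples per tree, averaged across trees and folds,
with the across-fold standard deviation; features pruned in every fold are
flagged rather than scored.

## Pipeline, determinism, problem sizes

`run_pipeline` executes load → FC → rDCM → paired stats → asymmetry →
PLSC → decoding and writes a deterministic directory layout with a
versioned `summary.json`; two runs with the same seed are byte-identical.
The single global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence.spawn` in a fixed documented order. All
configuration lives in one dataclass tree with unknown-key rejection;
plain TSV/CSV/JSON are the only file formats (extracting region series
from volumetric images is a pre-step outside the package).

Validation experiments run at desk scale by the package's own choice of
problem size: 6–16 regions and 10–45 subjects for study-level checks, 10
regions for recovery, with null calibrations (paired-t type-I, permutation
uniformity, asymmetry under symmetric truth) drawing features directly
from the ground-truth connectome stage — under all-zero effects the BOLD
forward model adds cost but no structure relevant to the null being
calibrated. The 132-region full-scale configuration is exercised for the
feature-count identities and a single-session inversion.

## Known limitations

* Recovery correlation ≈ 0.86 at the reference conditions is limited
  jointly by finite scan length, the finite-TR discretisation, per-region
  scale absorption, and aliasing of supra-Nyquist state power through the
  sampling step; it is not a numerical-convergence issue.
* The estimator assumes the canonical HRF; regionally variable
  haemodynamics would leave un-whitened residual colour and bias couplings
  into the apparent direction of haemodynamic lag differences.
* The sparsity-inducing rDCM variant, task/driving-input DCM, nonlinear
  terms and haemodynamic-parameter estimation are out of scope, as are
  partial-correlation or tangent-space FC variants and any volumetric
  processing.
* Behavioural PLSC power depends strongly on how concentrated the planted
  coupling is; diffuse weak coupling across many features can leave the
  singular-value permutation test underpowered even when the latent
  correlation is high.
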