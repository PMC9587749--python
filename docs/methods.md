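# Methods note

This note records the modeling assumptions, default parameters and numerical
choices behind `tdmom`, in the package's own terms. It is the reference for
"why is this number what it is" questions that the API docstrings answer only
locally.

## 1. DTOF moments and their noise

For a histogram with counts `N_i` at bin times `t_i` and `N = Σ N_i`:

- `M0 = −log N`
- `M1 = Σ t_i N_i / N`
- `M2 = Σ (t_i − M1)² N_i / N`

Treating the bins as independent Poisson counts and linearizing the moment
map around the expected histogram (delta method) gives the shot-noise
covariance implemented in `shot_noise_covariance`:

```
Var(M0) = 1/N            Cov(M0, M1) = Cov(M0, M2) = 0
Var(M1) = μ2/N           Cov(M1, M2) = μ3/N
Var(M2) = (μ4 − μ2²)/N
```

with `μk` the k-th central moment of the normalized DTOF. The zero
M0-cross-covariances are exact at first order, not an approximation we chose:
the M0 gradient is constant across bins while the M1/M2 gradients are
centered. The tests validate the full matrix against brute-force Poisson
resampling (4000 replicates, 5% on the diagonal) and against closed-form
moments of an exponential DTOF.

Moment vectors are always stacked **moment-major** — all M0 rows, then all
M1 rows, then all M2 rows — and the scale constants `MOMENT_SCALES = (1,
1e12, 1e24)` convert the three moments to comparable magnitudes (seconds and
seconds² are small numbers).

## 2. Photon transport

`tdmom.transport` implements a layered semi-infinite slab Monte Carlo:

- 20 layers: 19 × 1 mm plus a terminal layer extending to 100 mm depth;
- scattering 10 mm⁻¹, Henyey-Greenstein anisotropy g = 0.9 (reduced
  scattering 1 mm⁻¹), refractive index 1.4 with Fresnel reflection at the
  top surface; lateral termination at 50 mm radius, DTOF support 5 ns;
- absorption applied by **reweighting**: photons propagate absorption-free
  and each detected photon stores per-layer partial pathlengths `l_j`, so one
  run serves every absorption vector via `w = exp(−Σ μa_j l_j)`;
- detection in **annular rings** (ρ ± 1 mm): the slab is laterally
  symmetric, so a single run yields every source-detector separation at once.

Weighted statistics of the records give moments and their absorption
derivatives *exactly on the sample*:

```
S0j = ⟨l_j⟩w        S1j = −Cov_w(t, l_j)        S2j = −Cov_w((t − M1)², l_j)
```

which is why the finite-difference oracle agrees to ~1e−6 rather than just
the 1% tolerance. The homogeneous-medium mean time of flight is additionally
checked against the extrapolated-boundary diffusion-theory reflectance
(agreement ~3% at 30 mm, 10% tolerance — diffusion theory itself is
approximate here).

### Lookup table

`build_lookup_table` tabulates layer sensitivities and DTOF central moments
on a grid of separations (6–34 mm, step 2) × homogeneous absorptions
(0.009–0.030 mm⁻¹, step 0.001), bilinearly interpolated and never
extrapolated. Defaults: 400 000 photons, seed 12345, ≥ 50 detected photons
per ring for validity; one CPU build takes ~20 s. The absorption grid covers
the baseline used throughout: 80% water plus 30 μM HbO and 20 μM HbR (60%
oxygen saturation), which lands at ≈ 0.012 mm⁻¹ at 690 nm and ≈ 0.014 mm⁻¹
at 850 nm.

`interp_two_layer` collapses the 20 layers into scalp (first 13 mm by
default) and brain (the rest). The brain share of the M0/M1/M2 sensitivity at
30 mm is ≈ 0.08 / 0.30 / 0.48 — the strictly increasing depth selectivity
that motivates the whole approach.

### Performance note

The numba kernel writes per-layer pathlengths into a caller-provided buffer.
That buffer **must be float64**: passing a float32 buffer makes the whole
kernel several times slower (mixed-precision stores defeat the JIT's
vectorization). `run_mc` therefore accumulates in float64 and downcasts to
float32 for storage afterwards.

## 3. Synthetic sessions

`simulate_session` produces a resting series plus an HRF-augmented copy with
complete ground truth (`augmented = resting + added` holds bit-exactly).

**Canonical HRF** (`make_hrf`): difference of two gamma densities (shape 6
and 16, unit timescale, undershoot ratio 0.1), zero for t ≤ 0,
peak-normalized on the evaluation grid so that at scale 1 the HbO peak is
exactly 0.6 μM and the HbR trough (same shape, amplitude ratio −1/3) exactly
−0.2 μM. The curve returns to within 5% of its peak by t = 18 s.

**Stimulus trains** (`make_stimulus_train`): inter-stimulus intervals are
normal(21 s, 3 s) truncated at zero, first onset uniform in [5 s, 21 s]; a
300 s train carries 14 onsets on average (rounded mean over 1000 seeds).

**Resting physiology**: scalp HbO per detector is cardiac (1.1 Hz, 0.7 μM)
plus respiratory (0.25 Hz, 0.3 μM) plus low-frequency (0.1 Hz, 0.5 μM)
oscillations with random phases and slowly wandering amplitudes, plus a
random-walk drift; scalp HbR tracks HbO with ratio −0.3 plus an independent
component. Each detector's SS and LS channel mix a shared scalp process with
a channel-specific one (`shared_fraction = 0.98`, variance-preserving), which
puts the SS-LS M0 correlation in the 0.7–0.9 range by construction. The brain
layer gets small independent fluctuations (0.08 μM LF + 0.02 μM white). The
amplitudes are chosen so that on long-separation channels scalp physiology
clearly dominates a scale-1 HRF in M0 — the regime in which short-separation
regression and moments matter.

Concentrations become absorption via Beer-Lambert, absorption becomes
moments via the two-layer sensitivities, and per-sample shot noise is drawn
from the theoretical covariance at the channel photon budgets (10⁶/sample at
8 mm, 10⁵/sample at 30 mm).

**Augmentation** (`augment`): the HRF convolved with each channel's onset
train is injected through the *brain* rows of the same forward model. SS
channels are augmented by default (the brain response is global);
`augment_ss=False` keeps them response-free. Channels at ≥ 34 mm are never
augmented; channels outside the lookup table are skipped and listed in
`failures`.

## 4. Recovery methods

All methods output an HRF on a [−2, 18] s epoch base, baseline-adjusted over
[−2, 0] s.

- **CW-BA / CW-SS**: low-pass (0.7 Hz, zero-phase 4th-order Butterworth) the
  channel's M0, convert to concentration with the homogeneous effective
  pathlength (total M0 sensitivity) and two-wavelength Beer-Lambert
  inversion, block-average over onsets. The homogeneous pathlength
  underestimates focal brain amplitudes (partial volume) — inherent to CW.
- **CW-GLM**: per-wavelength OLS of the LS M0 on onset-locked Gaussian
  temporal bases (spacing = std = 1 s, centers −2..18 s) plus the SS M0 as a
  scalp regressor; coefficients are reassembled into the epoch-domain
  response and converted like the block average.
- **TD-SS / TD-LS / TD-LS+SS**: per-sample scaled WLS separation of stacked
  channel moments into scalp and brain absorption, then Beer-Lambert
  unmixing of the brain traces and block averaging.
- **TD-GLM**: joint GLM over six row blocks (3 moments × 2 wavelengths) with
  columns [scalp(λ1), scalp(λ2), basis × {HbO, HbR}]; the scalp regressor
  for moment n is the SS M0 series scaled by
  `Sn_scalp(λ, ρLS) / S0_scalp(λ, ρSS)`; brain columns carry the brain
  sensitivities times molar absorption so coefficients are in μM.

### Numerical choices that matter

- **Covariance scaling.** Moment variances span ~48 orders of magnitude
  (Var(M0) ~ 1e−5, Var(M2) ~ 1e−49 s⁴). A pseudo-inverse with a relative
  eigenvalue cutoff silently truncates the M1/M2 blocks, reducing any
  "weighted" fit to an M0-only fit. All covariance inversions therefore use
  the exact identity `Z⁻¹ = k (k Z k)⁻¹ k` with `k` the per-moment scales;
  tests pin the estimators to extended-precision plain-WLS oracles.
- **PSD clipping.** Interpolated theoretical covariances can be indefinite
  at round-off level (eigenvalues ~ −1e−43 at M2 scale); a plain
  pseudo-inverse would invert the negative direction with its sign, so
  symmetric eigendecomposition with negative-eigenvalue clipping is used.
- **Kronecker structure.** The GLM noise model is `C = Z ⊗ I(Nt)`; the
  normal equations are assembled as `Σ_ab Z⁻¹[a,b] U_aᵀU_b` without ever
  materializing the 6·Nt square matrix. A dense path exists solely as a test
  oracle for small Nt.
- **Demeaned regressors.** Data blocks are mean-subtracted, so all design
  columns are demeaned too (equivalent to fitting an intercept); otherwise
  the missing intercept biases the basis coefficients.
- **Covariance sources.** "ZT" is the shot-noise model at the session photon
  budgets; "ZE" is the sample covariance of the series being fit. ZE
  down-weights physiology-dominated moments and empirically yields lower
  RMSE, which the benchmark asserts directionally.

## 5. Evaluation and benchmark

Recovered curves are scored against the generating truth with RMSE and the
Fisher z of the Pearson correlation (|r| clipped at 1 − 1e−12 so noise-free
tests stay finite). Methods are compared with two-sided paired t-tests on
channels matched by (group, channel, chromophore, scale); a
Bonferroni-adjusted p-value column is reported as an extension alongside the
plain p-values. Identical arms return a zero mean difference with an
undefined t statistic; constant non-zero differences raise (a paired t-test
is meaningless there).

The default benchmark (`BenchmarkConfig`): 6 independent seed groups
("subjects") × 20 SS/LS detector pairs × 300 s at 7 Hz, HRF scale 1, base
seed 2024, deterministic given the config. CW methods ignore the moment
covariance and run once even when several covariance sources are requested.
On one CPU the full benchmark takes well under a minute after the table is
built.

## 6. Known limitations

- The slab geometry has no curvature, no CSF layer, and homogeneous
  scattering; sensitivities are desk-scale (400k photons), so absolute
  values at 30+ mm carry a few percent Monte Carlo noise (correlated between
  forward and inverse use, which is why exact-recovery tests still pass).
- The physiology generator is stationary and sinusoid-based; it reproduces
  amplitude ratios and the scalp-dominance regime, not real spectra.
- The default 7 Hz sampling resolves the 1.1 Hz cardiac line (Nyquist
  3.5 Hz); a warning is raised only if a configured rate actually aliases it.
- The CW conversion deliberately uses the homogeneous pathlength; its
  partial-volume amplitude error is part of what the benchmark measures, not
  a bug to fix.
- No SNIRF I/O; sessions and tables persist as plain HDF5 with explicit
  schemas.
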