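# Methods

## Model and conventions

**Axis convention.** All volumes use a fixed voxel-index frame:
x = left–right (the perivascular / medullary-vein direction),
y = anterior–posterior (association-fiber axis),
z = inferior–superior (projection-fiber axis). The convention is recorded
in every `DWIVolume`/`TensorField` and in the NIfTI `descrip` header. The
ALPS construction is meaningless without a fixed frame, so it is not
configurable; the axis-permutation invariance (swapping the y and z roles
of the two fibers leaves the index unchanged) is instead verified by
test.

**Units.** Tensors are stored in mm²/s; user-facing profiles and report
columns use 10⁻³ mm²/s, the usual DTI scale.

**Phantom.** A rectangular grid (default 12 × 12 × 6 voxels) holds three
disjoint rectangular fiber regions that share a range of x indices —
projection (principal axis z), association (y), subcortical (x) — in an
isotropic background (0.8 · 10⁻³ mm²/s). Each fiber voxel carries a
diagonal tensor built from three principal diffusivities: axial λ_ax
along the fiber, perivascular λ_pv along x (for the subcortical fiber,
whose own axis is x, λ_pv is just the larger radial component, kept for
QC), and radial λ_rd on the remaining axis. For any profile the
noise-free phantom satisfies the calibration identity

    ALPS = mean(λ_pv^proj, λ_pv^assoc) / mean(λ_rd^proj, λ_rd^assoc)

exactly, which is what makes end-to-end recovery testable.

**Default profiles.** Both arms use λ_ax = 1.40 and λ_rd = 0.50
(10⁻³ mm²/s), physiologic values for coherent periventricular white
matter. λ_pv is the group-defining parameter, solved from the identity
so the analytic index equals each arm's published group mean:
λ_pv = 1.460 × 0.50 = 0.730 (ESRD) and 1.632 × 0.50 = 0.816 (control).

**Signal simulation.** Stejskal–Tanner single-tensor forward model
S = S0 · exp(−b gᵀ D g). Noise is Rician — the magnitude-image
distribution of MRI — applied per measurement as
√((S + ε₁)² + ε₂²), ε₁, ε₂ ~ N(0, S0/SNR), i.e. SNR is referenced to the
b = 0 amplitude. The default protocol is one b = 0 plus 32 unique
directions at b = 1000 s/mm², matching a standard single-shell clinical
acquisition; the direction set is an electrostatic-repulsion
(antipodally symmetric Coulomb-energy-minimised) point set generated once
and shipped as `alpsim/data/gradients32.txt` (minimum angular separation
24.8°).

**Tensor estimation.** Ordinary least squares on log-signals against the
standard b-matrix design (row i: 1, −b gₓ², −b g_y², −b g_z², −2b gₓg_y,
−2b gₓg_z, −2b g_y g_z). OLS inverts noise-free data exactly, which is
the package's primary verification surface; a single WLS refinement pass
(weights = squared predicted signal) is available behind
`fit_tensor(..., weighted=True)` for noisy data. Signals ≤ 10⁻⁶·S0 are
clamped before the log; a voxel is flagged invalid — never raised — when
more than 20 % of its measurements were clamped, any signal is
non-finite, the voxel is all-zero, or a fitted eigenvalue is ≤ 0.
Negative eigenvalues are not clipped: clipping would silently bias the
diffusivities, whereas flagging removes the voxel from ALPS selection.

**Voxel selection.** "Maximum orientation" is scored as
|e₁ · axis_f|, the absolute dot product of the principal eigenvector with
the fiber's expected axis. Voxels whose tensor is too close to isotropic
for e₁ to be meaningful — Westin linearity (λ₁−λ₂)/λ₁ < 0.05 — score 0,
so an ROI dropped onto isotropic tissue yields a *flagged* measurement
(all alignments below the 0.5 floor) rather than an arbitrary one. For
each x index present in all three regions the best valid voxel per fiber
is taken; the x maximising the summed alignment wins. Ties between
voxels break toward the lowest linear (C-order) index, ties between x
indices toward the lowest x. One voxel per fiber is used (no ROI
averaging); an ROI-mean variant was considered and deliberately left
out of the default path to keep the measurement definition single-valued.

**Index.** ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc),
where each denominator term is, in general, the diffusivity perpendicular
to both x and that fiber's axis (which reduces to Dyy for the projection
and Dzz for the association fiber under the default convention — this
generalisation is what makes the y/z-permutation invariance hold). The
subcortical voxel's diffusivities are carried for QC and group
comparisons but enter no formula term.

## Cohort generator

Each subject is driven by an independent deterministic substream,
`SeedSequence(entropy=(master_seed, arm_index, subject_index))`, so
cohorts are bit-reproducible and any subject can be regenerated in
isolation.

- **Perivascular jitter.** Subject λ_pv = profile λ_pv + N(0, σ_subj),
  σ_subj = 0.04 · 10⁻³ mm²/s in both arms (clipped to keep
  λ_rd < λ_pv < λ_ax; at 4 σ from either bound the clip is essentially
  never active). Group-level ALPS dispersion is not a published quantity,
  so σ_subj is a free parameter of the generator: 0.04 maps to an ALPS SD
  of ≈ 0.08, which makes the two-arm comparison at n = 49/38
  (Cohen's d ≈ 2) significant in essentially every seed while keeping
  individual subjects visibly variable.
- **PTH copula.** A latent bivariate normal (z₁, z₂) with correlation ρ
  drives λ_pv (via z₁) and PTH (via z₂). PTH = max(1, μ₀ + σ₀·z₂) with
  (μ₀, σ₀) = (281.7237, 315.0978), solved so that the *floored* variable
  has mean 313.9 and SD 265.9 pg/mL — the observed marginal, not the
  latent one, matches the published group summary. By Stein's lemma the
  floor attenuates the observable correlation by
  σ₀·P(PTH > 1)/SD = 0.964, so the default ρ = 0.3703 makes the
  expected ALPS–PTH Pearson correlation 0.357. A plain Gaussian floored
  at 1 pg/mL was chosen over a lognormal marginal: it keeps the copula
  linear (Pearson r is the target statistic) at the cost of a mild,
  quantified attenuation.
- **Other covariates.** Age ~ N(60.0, 8.1²) (ESRD) / N(61.1, 7.5²)
  (control); sex Bernoulli(28/49) / Bernoulli(21/38); dialysis duration
  N(38.6, 48.4²) months floored at 3 (the enrolment criterion); the 14
  remaining labs independent normals at their published mean/SD, floored
  at 0. Controls carry demographics only — the source table reports no
  control labs.
- **Fidelities.** `fast` skips imaging: each subject's ALPS measurement
  is the analytic readout of their jittered profile (used for
  statistics-heavy Monte Carlo). `full` simulates a personal phantom DWI
  volume at the configured SNR and leaves ALPS to the imaging pipeline.

**Cognitive screening.** `cerad_screen` implements the enrolment-style
exclusion: a domain is impaired iff its adjusted z-score is strictly more
than 1.5 SD below the norm (z < −1.5; the boundary itself does not
count), and a subject is excluded when ≥ 2 domains are impaired.

## Statistics

Pooled-variance (Student) two-sample t-tests for continuous variables —
the classical default when only "independent samples t-test" is
specified; Welch is available behind a flag. Pearson chi-square without
continuity correction for 2 × 2 tables: on the sex table (28/21 men,
21/17 women) this reproduces the published p = 0.861, which is the
deciding evidence for omitting the Yates correction. Pearson correlation
with the Fisher t-based two-tailed p. Bonferroni correction is applied
only to the nine per-axis fiber diffusivities (3 axes × 3 fibers),
m = 9, threshold 0.05/9 displayed as 0.0055 (truncated, not rounded, to
four decimals); ALPS itself and demographics are judged at two-tailed
α = 0.05. The kernels delegate to scipy.stats; the degenerate-case
contracts (zero pooled variance, zero marginals, constant samples) are
handled above it, and the suite cross-checks t and Pearson p against
closed-form textbook implementations to 10⁻⁶.

## Numerical and design notes

- **SNR default 40** (b0-referenced). High enough that Rician bias plus
  selection effects shift the grand-mean ALPS by well under 0.01
  (measured ≈ +0.005 over 20 seeds), so cohort calibration rests on the
  profiles, not on a noise-bias cancellation.
- **Phantom grid 12 × 12 × 6** with 8 shared x indices: small enough that
  a 20-seed, 87-subjects-per-seed full-pipeline run takes seconds, large
  enough that voxel selection is a genuine search.
- **Determinism.** Identical seeds give bit-identical volumes, cohorts
  and reports; all randomness flows from `numpy.random.Generator`
  seeded via `SeedSequence`.
- **Exit codes.** CLI: 0 success, 2 input/format/parameter error,
  3 computation/selection error.

## What the synthetic data does and does not show

The generator reproduces the *measurement chain* (tensor geometry,
acquisition, noise, voxel selection, statistics) and the published
summary statistics, but not real anatomy: no partial-volume mixing at
region borders, no eddy-current/susceptibility/motion artifacts (the
pipeline assumes preprocessed DWI), no T1/T2 relaxation, no spatially
varying noise, manually supplied ROIs rather than atlas or
susceptibility-weighted placement, and a linear latent ALPS–PTH
association imposed by construction (whether the real association is
linear is unknowable from group summaries). Passing tests therefore
demonstrate that the pipeline *recovers what was put in* under realistic
acquisition noise — parameter recovery, not clinical replication.
Per-group ALPS variances and the per-axis diffusivity group differences
are not published quantities; σ_subj and the subcortical profile are
generator choices flagged as such.
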