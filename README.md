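# alpsim

Simulation and analysis of the **DTI-ALPS index** — a non-invasive
diffusion-MRI proxy for glymphatic (perivascular fluid transport)
function — with a fully synthetic validation pipeline.

## The problem

The glymphatic system clears interstitial solutes from the brain through
perivascular spaces. At the level of the lateral-ventricle body, the
medullary veins (and their perivascular spaces) run left–right (**x**),
while the neighbouring white-matter tracts run inferior–superior
(projection fibers, **z**) and anterior–posterior (association fibers,
**y**). Because the perivascular direction is orthogonal to both fiber
axes there, water diffusivity measured *along x inside those fibers* is
sensitive to perivascular fluid transport rather than to the fibers
themselves. The ALPS index condenses this into a dimensionless ratio of
scanner-frame diffusion-tensor diagonal elements:

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

with one voxel per fiber (projection, association, and a subcortical
QC voxel) selected on a shared x index by maximal alignment between the
principal eigenvector and the expected fiber axis. Values near 1 indicate
no preferential perivascular diffusion; higher values indicate better
presumed glymphatic function. Lower ALPS has been reported in end-stage
renal disease (ESRD): group means of 1.460 (49 dialysis patients) versus
1.632 (38 healthy controls), and a positive correlation between ALPS and
serum parathyroid hormone (PTH, r = 0.357) within the ESRD arm.

Clinical DWI of such cohorts is not publicly available, so `alpsim`
provides the entire chain as testable code:

- **`phantom`** — three-fiber tensor phantoms whose analytic ALPS is known
  exactly, plus Stejskal–Tanner forward simulation
  (`S = S0·exp(−b·gᵀDg)`) with Rician noise;
- **`tensor`** — log-linear least-squares tensor estimation,
  eigendecomposition, axis diffusivities;
- **`alps`** — the ROI voxel-selection procedure and the index formula;
- **`cohort`** — two-arm synthetic cohorts with clinical covariates
  (Gaussian copula linking perivascular diffusivity to PTH) and the
  CERAD-style cognitive-screening rule;
- **`stats`** — pooled-variance t-tests, chi-square, Pearson
  correlations, Bonferroni correction (0.05/9 → displayed 0.0055);
- **`pipeline` / `cli`** — end-to-end runs and NIfTI + FSL
  bval/bvec I/O.

## Worked example

One synthetic subject, end to end:

```python
import numpy as np
from alpsim import (PhantomGeometry, FiberROI, build_phantom, esrd_profile,
                    default_protocol, simulate_dwi, subject_alps)

geometry = PhantomGeometry()                      # 12 x 12 x 6 voxel grid
roi = FiberROI.from_geometry(geometry)
field = build_phantom(geometry, esrd_profile())   # analytic ALPS = 1.460
dwi = simulate_dwi(field, default_protocol(), snr=40, seed=7)
result = subject_alps(dwi, roi)                   # fit -> select -> index
print(f"ALPS index: {result.index:.4f}")
```

prints

```
ALPS index: 1.4872
```

with the four formula diffusivities `Dxx_proj = 0.7513`,
`Dxx_assoc = 0.7167`, `Dyy_proj = 0.4821`, `Dzz_assoc = 0.5050`
(·10⁻³ mm²/s): at SNR 40 a single subject scatters around the phantom's
ground-truth 1.460 with an SD of about 0.06 from measurement noise alone.

A full two-arm study (49 ESRD at the ESRD profile, 38 controls at the
control profile, SNR 40, full imaging pipeline, then the statistics
battery):

```python
from alpsim.pipeline import PipelineConfig, run_pipeline
report, subjects = run_pipeline(PipelineConfig(seed=0, fidelity="full"))
```

yields (seed 0) group means **1.456 (SD 0.113)** vs **1.649 (SD 0.107)**,
t = −8.12, p = 3.3·10⁻¹², and an ALPS–PTH Pearson r = 0.189 (p = 0.19)
in the ESRD arm. A single cohort's correlation is noisy (its sampling SD
at n = 49 is ≈ 0.13); averaged over 50 seeds the pipeline recovers the
calibrated r ≈ 0.357 (see the acceptance script and
`tests/test_acceptance.py`). The same run is available from the shell:

```bash
alpsim run --seed 0 --out results/demo
alpsim simulate --profile control --snr 40 --seed 1 --out /tmp/phantom
alpsim alps /tmp/phantom.nii.gz /tmp/phantom.bval /tmp/phantom.bvec --roi /tmp/phantom.roi.json
```

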