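# xmlaa — emission-based estimation of flexible hardware attenuation in PET

Accurate PET quantification requires correcting for the attenuation of
everything between the annihilation photons and the detectors — including
hardware that standard MR-based attenuation maps cannot see.  Flexible
components such as MR-safe headphones and RF surface coils move from scan to
scan, so fixed CT templates do not apply, and ignoring them biases regional
activity by up to 10–25%.

`xmlaa` implements *external MLAA*: a joint maximum-likelihood reconstruction
of the activity image λ and the attenuation map μ from non-TOF emission data,
in which the attenuation update is restricted to a *hardware mask* strictly
outside the patient/phantom outline.  The patient attenuation map is taken as
known and never modified; only the attenuation of external, possibly cold
(zero-uptake) hardware is estimated.  The package is aimed at researchers in
PET/MR attenuation correction who want a compact, fully testable desk-scale
implementation of the algorithm, a matching phantom simulator, and the
evaluation machinery (region errors, plane profiles, hardware-only ACF
statistics).

## Model

Expected prompts on a line of response (LOR) *j*:

    p̂_j = (1 / (a_j n_j)) Σ_i M_ij λ_i + s_j / n_j + r_j,
    a_j = exp(Σ_i μ_i l_ij)                (attenuation correction factor)

with system-matrix weights `M_ij = l_ij` from a matched Joseph projector,
normalization `n_j`, scatter `s_j` and randoms `r_j`.  The objective is the
penalized Poisson log-likelihood

    Q(λ, μ) = Σ_j (p_j ln p̂_j − p̂_j) + β_S L_S(μ) + β_I L_I(μ),

where `L_S` is a Gibbs smoothing log-prior with the Geman-McClure potential
ψ(t) = t²/(δ² + t²) and `L_I` is a bi-modal intensity log-prior pulling mask
voxels toward the expected attenuation of air (0.0 ± 0.0001 mm⁻¹) or of
hardware material (0.01 ± 0.0020 mm⁻¹).  Each outer iteration performs one
OP-MLEM activity update on the whole FOV, then one relaxed gradient
attenuation update (relaxation α) on the hardware mask only, with negative
values truncated to zero.  Defaults: 50 iterations, α = 4.0, β_S = 5.0,
β_I = 0.01, no subsets in the joint loop; final images via OSEM (3 iterations
× 21 subsets) plus a 5 mm FWHM Gaussian filter.

## Worked example

A synthetic headphone experiment: a warm 150 mm water cylinder (λ = 1 a.u.)
wearing cold headphones (two earpad ellipsoids and a light headband), scanned
with the default desk-scale geometry (128×128 grid, 2 mm voxels, 120 views ×
128 radial bins, noiseless data).

```python
import numpy as np
from xmlaa import *

geom = ScannerGeometry()
ph = make_hp_phantom(geom)
blank = SinogramSet(np.zeros(geom.sino_shape))
sino = SinogramSet(expected_counts(ph.lambda_true, compute_acf(ph.mu_true, geom), blank, geom))

lam, mu, trace = run_xmlaa(sino, ph.mu_body, ph.hardware_mask, PriorConfig(),
                           ReconConfig(n_xmlaa_iters=150), geom, ph.body_mask)

support = mask_sinogram_support(ph.hardware_mask, geom)
for label, m in (("uncorrected", ph.mu_body), ("xMLAA", mu), ("ground truth", ph.mu_true)):
    s = AcfStats.from_acf(hardware_acf(m, ph.mu_body, geom), support)
    print(f"{label:12s} mean {s.mean:.3f}  sd {s.sd:.3f}  min {s.min:.3f}  max {s.max:.3f}")
print("region error after xMLAA: %+.2f%%"
      % region_mean_error(lam, ph.lambda_true, ph.evaluation_mask))
```

Output:

```
uncorrected  mean 1.000  sd 0.000  min 1.000  max 1.000
xMLAA        mean 1.141  sd 0.068  min 1.000  max 1.428
ground truth mean 1.133  sd 0.175  min 1.000  max 2.160
region error after xMLAA: +0.64%
```

Read it like a hardware-ACF table: without correction all hardware ACFs are
exactly one (the hardware is invisible to the reconstruction, which here
under-estimates the central activity by −8.3%).  The joint estimate cannot
reproduce the exact physical shape — its maximum ACF (1.43) is well below
the truth (2.16) — but the *mean* hardware ACF over the relevant LORs
matches the truth within ~1%, which is what PET quantification needs: the
central activity error shrinks from −8.3% to +0.6%.

## Command line

```sh
xmlaa simulate --phantom simulation --seed 1 --out runs/sim
xmlaa xmlaa --sinograms runs/sim/sinograms.h5 --mu-init runs/sim/mu_body.nii.gz \
      --hardware-mask runs/sim/hardware_mask.nii.gz --body-mask runs/sim/body_mask.nii.gz \
      --out runs/fit
xmlaa recon --sinograms runs/sim/sinograms.h5 --mu-map runs/fit/mu_est.nii.gz \
      --override recon.n_subsets=20 --out runs/rec
xmlaa evaluate --lambda-test runs/fit/lambda_est.nii.gz \
      --lambda-ref runs/sim/lambda_true.nii.gz \
      --region runs/sim/evaluation_mask.nii.gz --out runs/eval
```

All parameters live in one YAML configuration (see `xmlaa.io.RunConfig`);
`--override section.key=value` changes single entries, and every run writes
its resolved configuration next to its outputs.

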