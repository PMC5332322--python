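# Methods

## Problem and model

PET quantification needs attenuation correction factors (ACFs) for every
line of response (LOR).  In PET/MR, flexible hardware (MR-safe headphones,
RF surface coils) is invisible to the MR-derived attenuation map and moves
between scans, so its attenuation must be estimated per scan.  This package
estimates it directly from the emission data by joint maximum-likelihood
reconstruction of activity and attenuation, with the attenuation update
confined to a *hardware mask* outside the body outline — the body attenuation
map is trusted and never modified.

The forward model, likelihood and both update equations are given in the
README.  Two structural facts shape everything else:

* **Cold objects are only seen in silhouette.**  Hardware carries no
  activity, so a hardware voxel is informed only by LORs that also cross the
  emission region.  The angular information is therefore incomplete, and the
  estimated attenuation map cannot reproduce the exact physical shape of the
  hardware.  What the method does recover — and what quantification needs —
  is the *overall* attenuation: the mean hardware-only ACF over the emission
  sinogram support.
* **The "background trick"** (forcing μ = 0 along LORs without measured
  counts) is deliberately not used: LORs crossing only cold hardware have
  zero counts, and the trick would erase exactly the attenuation this method
  must find.

## Geometry and projector

The scanner is a parallel-bin sampler: `n_views` azimuthal angles over
[0, π) × `n_radial` radial bins spanning the transaxial FOV; a 3D acquisition
is stacked independent 2D planes.  The default desk-scale geometry is a
128×128 grid of 2 mm voxels, 120 views × 128 radial bins, one plane — chosen
so a full 50-iteration joint run completes in seconds while keeping the
phantom at physical scale (lengths in mm, μ in mm⁻¹ at 511 keV).

The projector is a Joseph-type single-beam interpolator: per LOR the driving
axis is the grid axis most aligned with the ray; the ray is sampled at every
voxel plane along that axis with linear interpolation transversally and a
step length of voxel spacing divided by the direction cosine.  The weights
are assembled once per geometry into a sparse matrix whose transpose is the
backprojector, so the forward/backprojection pair is adjoint to machine
precision — the property the update equations silently rely on.  The same
weights serve as the intersection lengths `l_ij` in the ACF exponent, making
a forward projection of a 0/1 support a chord length in mm.

## Priors

* **Smoothing (`L_S`)**: Gibbs log-prior with Geman-McClure potential
  ψ(t) = t²/(δ² + t²), 8-connected in-plane neighbourhoods with weights 1 and
  1/√2 (no axial neighbours in stacked-2D mode).  ψ is redescending, so
  object edges taller than δ are not penalized into oblivion.  δ defaults to
  0.005 mm⁻¹ — half the hardware mode — the main free scale of the prior.
* **Intensity (`L_I`)**: a bi-modal pull defined directly through its
  piecewise-linear gradient.  Below the midpoint between the modes a voxel is
  pulled toward μ_air = 0.0 with σ_air = 10⁻⁴ mm⁻¹ (strong: background must
  stay air); above it, toward μ_hardware = 0.01 with σ_hardware = 2×10⁻³
  mm⁻¹ (wide: many hardware materials).  Each branch is the Gaussian score
  −(μ−mode)/σ², clipped beyond k = 3 standard deviations so far outliers feel
  a bounded pull.  The gradient vanishes exactly at both modes.
* **Curvature surrogates.**  The attenuation-update denominator needs a
  non-negative diagonal curvature for each prior.  We use conservative upper
  bounds — Σ_k w_ik·2/δ² for the smoothing term and basin-wide 1/σ² for the
  intensity term — rather than the exact (locally zero or negative)
  curvatures.  The exact variants enlarge the steps and let the poorly
  determined limited-angle modes of the external problem grow before the
  priors can suppress them; the bounds damp precisely those modes.  The
  fixed point is unchanged (the numerator is untouched); only the path to it
  is.

Weights default to β_S = 5.0 and β_I = 0.01, the operating point used for
all experiments here.

## Update loop

Each of the (default 50) outer iterations runs one OP-MLEM activity update
over the whole FOV on all LORs (no subsets), then recomputes the expected
data with the just-updated activity and takes one relaxed gradient step
(α = 4.0) of the attenuation inside the hardware mask.  Voxels outside the
mask are returned bit-identical; negative values are truncated to zero;
voxels whose denominator is not safely positive skip the iteration.  The
chord term Σ_k l_kj in the denominator runs over the full image grid; the
mask-restricted alternative takes larger steps but was found to overshoot to
a worse solution.  Activity starts as a uniform disc filling the scanner
FOV.  Final images for human consumption come from OSEM (interleaved view
subsets; 1 subset reduces exactly to MLEM) with a sum-preserving Gaussian
post-filter specified by FWHM in mm.

## Synthetic data

The phantom factory emulates three setups at desk scale:

* **Warm/cold simulation phantom**: 150 mm cylinder (μ = 0.01 mm⁻¹,
  λ = 1 a.u.) flanked left/right by two earpad ellipsoids (μ = 0.01 mm⁻¹),
  one warm (λ = 1), one cold (λ = 0).  Earpad semi-axes default to
  10×35×45 mm: the 20 mm pad thickness is calibrated so the ground-truth
  mean hardware-only ACF over the hardware-mask sinogram support is ≈1.10,
  the magnitude measured for real headphones with CT-derived templates.
  The hardware mask is an annulus from 2 mm outside the body to r = 106 mm —
  as tight around the pads (r ≤ 95 mm) as a compensation margin allows; the
  evaluation region is a central 80×40 mm box between the pads.  Emission
  data are noiseless with n = 1, s = r = 0.
* **Headphone (HP) phantom**: water cylinder (0.0096 mm⁻¹), cold pads plus a
  light 6 mm headband strap at 0.005 mm⁻¹; hardware mask = interior of a
  head-coil annulus (r 77–118 mm), mirroring the physical boundary a head
  coil imposes.
* **RF-coil phantom**: elliptical water body with an arc-shell coil above it
  containing three small high-μ inclusions (0.05 mm⁻¹); elliptical-annulus
  hardware mask.

MRAC-style corruptions are provided as operators: a spherical air cavity
(default 3 cm) zeroed into the attenuation map, and a fat/water inversion
scaling the body attenuation by 0.85.  A voxel belongs to a shape iff its
centre is inside, so phantoms are bit-reproducible from their parameters;
Poisson noise (optional — the simulation study itself is noiseless) uses a
named substream of the global seed and can rescale to a fixed prompt budget.

What the generator does *not* emulate: scatter and randoms backgrounds,
detector normalization structure, resolution/positron-range blur, oblique 3D
LORs, and noise-matched clinical count densities.  Passing tests therefore
demonstrate the mathematics and the cold-object estimation behaviour, not
clinical robustness.

## Desk-scale study conditions and known limitations

All defaults are the values printed above; the deliberate desk-scale
choices and their measured consequences:

* With ~1.5×10⁴ LORs instead of ~10⁸, the per-voxel prior-to-likelihood
  ratio is roughly two orders of magnitude larger than at clinical scale at
  the same β values.  The joint estimate therefore converges more slowly per
  iteration: on the simulation phantom the evaluation-region activity error
  is about −1.1% after the default 50 iterations and settles at −0.05% by
  ~150–300 iterations.  Runs that evaluate converged behaviour (e.g. the HP
  recovery study) use 150 iterations.
* Scaling the noiseless data to a clinical prompt budget is *not* a fix: it
  weakens the priors relative to the likelihood and the ill-posed
  limited-angle modes inflate the estimate (~+15% activity error).  The
  prior weights and the data scale belong together.
* The hardware mask matters, as the method's own guidance says: too tight an
  annulus leaves no room to compensate for pad voxels hidden by the
  body-adjacency margin (net under-correction); too loose an annulus
  accumulates spurious attenuation (over-correction).  The defaults sit at
  the fidelity optimum of that trade-off for the simulation phantom.
* The "manually segmented" emission sinogram support of real studies is
  replaced by a thresholded forward projection of the body outline (default
  threshold: 1 mm of path length).
* Degenerate inputs: divisions and logs use an epsilon floor (10⁻¹²) without
  modifying stored sinograms; zero-sensitivity voxels freeze rather than
  divide; LORs with p = p̂ = 0 contribute zero likelihood; an all-zero
  attenuation map yields an empty body outline with a warning.

## Units

Lengths in mm, attenuation in mm⁻¹ at 511 keV (water 0.0096, generic
hardware 0.01), activity in arbitrary units; ACFs and normalization are
dimensionless.  Sinogram files store prompts/norm/scatter/randoms as HDF5
datasets with the geometry as attributes; volumes are NIfTI with the voxel
spacing in the affine.
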