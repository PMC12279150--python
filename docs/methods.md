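# Methods

`tavimorph` analyses the morphology of the aortic root / left
ventricular outflow tract (LVOT) and the spatial distribution of valve
calcification in cohorts of aortic-stenosis patients assessed for
transcatheter aortic valve implantation (TAVI).  This note documents the
models, their assumptions, the defaults, and the choices made where the
design was genuinely open.

## Deformation model

Shapes are compared through smooth invertible deformations of a common
template.  A deformation is parametrised by momenta `a_k` — one 3D
vector per control point `c_k` of a regular lattice — through a
reproducing-kernel velocity field with Gaussian kernel
`K(x,y) = exp(-|x-y|^2 / lambda_V^2)`.  Geodesic paths follow the
Hamiltonian landmark equations

    dc_k/dt =  sum_l K(c_k, c_l) a_l
    da_k/dt = -sum_l (a_k . a_l) grad_1 K(c_k, c_l)

integrated with fixed-step RK4 over `t in [0, 1]` (default 10 steps;
the generator uses 8).  The Hamiltonian `0.5 a' K(c) a` is conserved to
well below 1% at these step counts, and the inverse map is obtained by
reverse-time integration of the same field — the exact inverse of the
discrete flow, rather than shooting with negated momenta.

* `lambda_V` (deformation scale, mm): stiffness of the deformations;
  default 11 mm, with control-point spacing equal to `lambda_V` and a
  1 mm margin around the joint bounding box.
* A linearised "small-deformation" map `x -> x + sum K(x,c_k) a_k` is
  available; it shares the momenta parametrization, is linear in the
  momenta, and is the transport used *inside* registration (below).
  All statistics consume momenta regardless of which transport produced
  them.

Units are millimetres throughout, right-handed axes, with the template
long axis on +z and the valve plane at z = 0.

## Currents metric and atlas estimation

Surfaces are compared without point correspondence through the currents
inner product `<S,S'> = sum_f sum_g K_W(c_f, c_g) N_f . N_g`, where
`c_f` are face barycentres and `N_f` area-weighted face normals, with a
Gaussian kernel of width `lambda_W` (default 7 mm for the aortic root,
5 mm for the LVOT).  The single-subject objective balances the squared
currents distance against the RKHS norm of the momenta,

    J(a) = d_W(phi_a . T, S)^2 / (2 lambda^2) + |a|_K^2,

with the noise level `lambda` defaulting to 2.0.

Momenta are fitted by L-BFGS with an **analytic gradient under the
linearised transport**: the template-to-vertex map is then linear in the
momenta, so the chain rule needs only the exact gradient of the currents
distance with respect to the deformed vertices (kernel and cross-product
terms differentiated in closed form; verified against finite
differences).  An adjoint pass through the RK4 geodesic flow would buy
little at this problem scale and is not implemented; a finite-difference
shooting mode exists for very small problems.  Fits that fail to improve
on zero momenta return the zero field with a warning, which makes the
optimiser contract (`J(a_fit) <= J(0)`) unconditional.

Atlas estimation alternates:

1. initial template = vertex-wise mean of a subject subset (default 5)
   after rigid alignment (Kabsch);
2. per-subject momenta fits with the template fixed;
3. re-centering: the template is deformed along the mean momenta and the
   next round of fits warm-starts from the centred momenta;
4. repeat, at most 3 rounds, with rollback if a round fails to improve
   the cohort objective — the reported objective trace is therefore
   non-increasing by construction.  A final exact centering in momenta
   space leaves the mean momenta at zero for downstream statistics.

The template is *not* remeshed between rounds: no isotropic remesher is
available in the dependency set, and the synthetic cohorts share a
uniform topology with the template, so remeshing would only add a
non-reproducible step.  External cohorts with heterogeneous meshing
should be remeshed upstream.

Diagnostics: per-subject symmetric mean surface distance (exhaustive
point-to-triangle), relative enclosed-volume error for watertight
meshes, the average per-vertex standard deviation of the reconstructions
("modelled variability", population SD convention — divide by n, so the
two-subject `+t / -t` case gives exactly `|t|`), and PCA of the centred
momenta with mode renders at +/-3 SD.

**Hyperparameter selection.** `lambda_W` is chosen to minimise the mean
reconstruction error; `lambda_V` by AIC with the effective parameter
count `3 x #{control points with mean |a_k| > 1e-6}`.  A known
limitation of that count: smooth fits leave (numerically) non-zero
momenta almost everywhere, so the penalty is essentially proportional to
the lattice size, which grows as `lambda_V^-3`; at desk scale the
penalty dominates the data-term differences and AIC prefers the coarser
widths.  The selection is deterministic and seed-stable, and is tested
as such; treat the AIC ranking as a tie-breaker between widths with
comparable reconstruction error, not as an oracle for the generative
width.  Tests exercise the width grid {11, 15} mm: lattices below
~8 mm spacing cost minutes per fit at our bounding boxes, and the
conclusion (penalty-dominated ordering) is unchanged.

## Shape statistics

Momenta are treated as Euclidean coordinates (raw components, not
kernel-metric products).  Available analyses:

* subgroup mean shapes (mean momenta, rendered by shooting);
* OLS of all momenta coordinates on a shared design matrix, with
  `r^2 (%) = 100 (1 - RSS/TSS)` summed over *all* coordinates — when the
  covariate is a PCA mode score this reduces exactly to that mode's
  variance fraction;
* effect renders at the mean +/- k covariate SDs along a coefficient
  field;
* per-control-point statistics: two-sample Hotelling T^2 on the 3D
  momenta (pooled covariance with a `1e-6 x trace/3` ridge), and a
  Wilks-type likelihood ratio `n log(det S0 / det S1)` for linear
  effects.  The LR ridge is one shared absolute value per control point
  (taken from the null-model scale) so degenerate coordinates cancel
  exactly in the determinant ratio; a trace-proportional ridge applied
  separately to S0 and S1 would inflate the statistic threefold in the
  rank-one case.
* family-wise inference by max-statistic permutation: B label
  permutations (default 1000), `p = (1 + #{perm max >= observed}) /
  (B + 1)` (never exactly zero), one-hot coding for categorical
  variables (tested with the LR statistic);
* covariate adjustment by residualising the momenta on the co-regressors
  and permuting the variable of interest (Freedman-Lane style); with an
  empty co-regressor set this is bitwise the unadjusted test.

Missing covariates are handled by listwise deletion per analysis; no
imputation anywhere.

## Calcification model

Calcium segmentations are normalised to template space by pushing every
template voxel centre (1 mm grid) through the subject's *forward*
deformation and sampling the native volume there — equivalent to
applying the inverse deformation to the segmentation.  Nearest-neighbour
sampling for binary/label inputs; linear sampling re-thresholds binary
data at 0.5.  Local volume is deliberately not preserved (the
normalization acts as a local density correction).

Summaries: per-voxel calcification rate maps; slab averages — slab A is
the 10 mm slab centred on the valve plane (z in [-5, 5)), slab B the
20 mm slab directly above (z in [5, 25)); exceedance volumes (voxels
with rate above a threshold); cylindrical cusp quantification.  The
valve cylinder (default radius 15.5 mm, z in [-5, 10)) is split into
three 120-degree sectors bounded by the commissure azimuths 90/210/330
degrees, labelled NCC (330-90], LCC (90-210], RCC (210-330]; calcium
above the cylinder is reported as aortic wall.

Per-location group comparison uses a zero-inflated Gamma model: the
quantification is zero with probability `1 - p` and otherwise
Gamma(k, theta) with the scale fixed cohort-wide (`theta = 2.2`;
a sensitivity-sweep utility exposes other values).  Estimators are
explicit — `p_hat = 1 - n0/n`, `k_hat = mean(positive x) / theta` —
and the two-group statistic is `z = L(Ga) + L(Gb) - L(Ga u Gb)` with
each log-likelihood evaluated at its own group's fit, the conventions
`0 log 0 = 0`, and the Gamma term dropped for all-zero samples.  The
explicit `k_hat` is the moment estimator at fixed scale, *not* the exact
MLE (which solves `digamma(k) = mean(log x) - log theta`); both are
implemented, the explicit formula is the default, and `z >= 0` is
guaranteed only under `estimator='exact_mle'` (nested likelihoods).
Vectorised z-maps over 2D slices use the closed forms.  Median splits of
continuous covariates put ties in the lower group.

## Synthetic cohort generator

The generator defines the study conditions and closes the loop for every
recovery test.  It emulates:

* an idealised aortic root — a tube with three sinus bulges (cusp
  centres at azimuths 30/150/270 degrees), valve plane at z = 0, total
  length 1.5 x the root diameter, radii inflated by the inscribed-
  polygon factor so plane-section equivalent-circle diameters read their
  nominal values at any mesh resolution (annulus 27.0 mm);
* covariate-linked momenta: a size mode calibrated so a unit coefficient
  adds 1 mm of measured annulus diameter (male-female gap 2.2 mm,
  residual SD 1.9 mm), an ascending-aorta curvature mode (males
  straighter), an LCC-sinus-elongation and a narrow-root mode carrying
  the PVL group structure — deliberately non-monotone, with a distinct
  'trivial' phenotype — plus smooth random modes and noise;
* calcium painted per-voxel in template space as Bernoulli(p) x
  Gamma(k, theta = 2.2) with crescent-shaped elevated-p regions on the
  three cusps (NCC > LCC > RCC), wall calcification higher on the RCC
  side, a male bump at the LCC/RCC commissure, a size effect on the LCC,
  an age effect on the wall, and a per-subject lognormal severity
  multiplier (sigma = 0.4) that produces the between-subject spread of
  total calcium (cohort mean ~2100-2600 mm^3);
* a clinical table with the documented multicollinearity (sex-diameter-
  calcium, pressure gradient vs calcium, EF vs Euroscore, BMI vs
  frailty), Table-1-like marginals truncated to realistic ranges,
  missingness at realistic per-variable rates, and a device-choice
  mechanism in which high calcification weighs towards the smaller
  device and self-expanding devices appear in low-calcium cases.

Native-space calcium volumes are materialised on demand on a CT-like
0.5 mm grid by pulling each native voxel back through the inverse
deformation (exact integration on a 3 mm lattice, trilinear
interpolation of the displacement — the velocity field is smooth at the
11 mm kernel scale, so the interpolation error is far below the voxel
size) and sampling the template map nearest-neighbour.  Because calcium
is painted in template space and pushed forward, the normalization round
trip has an exact target; at these grids the support round trip is
essentially lossless.

What the generator does **not** emulate: anatomically realistic leaflet
geometry, bicuspid valves, image intensities and segmentation error,
connected calcium aggregates (voxels are drawn independently given the
p-field), scanner/operator variability, and longitudinal change.
Passing recovery tests therefore demonstrate the correctness and
calibration of the estimators under the assumed generative structure,
not clinical validity on real cohorts.

## Problem sizes

Unit and property tests run on meshes of 66-300 vertices, cohorts of
3-10 subjects, and permutation counts of 100-500; the calibration suite
uses 200 null cohorts at n = 60 with 50 control points and B = 200, and
the generator-calibration suite 5 cohorts of n = 130 at coarse mesh
resolution.  The acceptance script uses one n = 130 cohort, an 8-subject
atlas round trip, 100 null calibration cohorts and 10 power replicates.
These sizes were chosen so the full suite runs comfortably on a single
CPU while every statistical check retains clear resolution margins.

## Known limitations

* The AIC effective-parameter convention makes the lambda_V selection
  penalty-dominated (see above).
* Momenta are non-identifiable across kernel widths and lattice layouts;
  cross-model comparisons should be made on induced displacement fields,
  which is also how the generative-recovery test is phrased.
* The currents metric is orientation-sensitive: inconsistently wound
  input meshes must be repaired upstream.
* The moment estimator `k_hat` can make `z` marginally negative; use
  `exact_mle` where non-negativity matters.
* `select_hyperparameters` refits whole atlases per grid point and is
  the slowest path in the package.
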