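# tavimorph

Statistical shape modelling and calcification mapping of the aortic
root and left ventricular outflow tract (LVOT) for TAVI cohorts.

Patients with calcific aortic stenosis who are assessed for
transcatheter aortic valve implantation (TAVI) differ in the 3D shape of
the implantation site and in where calcium has accumulated on the valve
— and both influence procedural outcomes such as paravalvular leakage
(PVL).  Classical analyses reduce this to a handful of diameters and a
global calcium score.  `tavimorph` implements the full 3D alternative
for researchers in cardiovascular morphometry:

* **Shape atlases** — a template surface plus per-subject diffeomorphic
  deformations parametrised by momenta `a_k` on a control-point lattice
  through a Gaussian reproducing-kernel velocity field
  (`K(x,y) = exp(-|x-y|^2/lambda_V^2)`, geodesic shooting of the
  Hamiltonian landmark equations).  Template-to-subject registration
  uses the correspondence-free **currents metric**
  `<S,S'> = sum_{f,g} K_W(c_f,c_g) N_f . N_g` on area-weighted face
  normals, balanced against the RKHS norm of the momenta by a noise
  level `lambda`.
* **Shape statistics on momenta** — subgroup means, OLS with `r^2` as
  percent of total momenta variance, per-control-point Hotelling `T^2`
  and likelihood-ratio statistics, and family-wise inference by
  **max-statistic permutation tests** (with Freedman–Lane style
  co-regressor adjustment).
* **Calcium in template space** — segmentations normalised by the
  inverse subject deformation onto a common 1 mm grid; rate maps, slab
  averages around the valve, cusp-sector quantification (NCC/LCC/RCC),
  and a voxelwise **Bernoulli x Gamma** (zero-inflated Gamma) model with
  fixed scale `theta = 2.2`, explicit estimators
  `p_hat = 1 - n0/n`, `k_hat = mean(x>0)/theta`, and the two-group
  statistic `z = L(Ga) + L(Gb) - L(Ga u Gb)`.
* **Clinical table statistics** — pairwise association screens
  (chi-squared / Welch t / Pearson), Bonferroni thresholds, PVL grade
  encodings, and the device-choice logistic model.
* **A synthetic cohort generator** — an idealised aortic root deformed
  by covariate-linked momenta with crescent-shaped cusp calcification,
  standing in for (non-public) patient data and providing ground truth
  for every recovery test.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import numpy as np
from tavimorph.synthetic import GeneratorConfig, sample_cohort
from tavimorph.atlas import AtlasConfig, estimate_atlas
from tavimorph.shape_stats import max_stat_permutation_test
from tavimorph.calcium_model import cusp_quantify, slab_average, z_map

cohort = sample_cohort(GeneratorConfig(n=30, n_rings=14, n_azimuth=12),
                       seed=7)
print(f"annulus {cohort.covariates['annulus_mm'].mean():.1f} mm, "
      f"calcium {cohort.covariates['calcium_volume_mm3'].mean():.0f} mm3")

atlas, report = estimate_atlas(cohort.meshes[:8],
                               AtlasConfig(lambda_v=11, lambda_w=7, noise=2))
print(f"reconstruction error {report.reconstruction_errors.mean():.2f} mm, "
      f"variability {report.variability:.2f} mm")

sex = (cohort.covariates['sex'] == 'male').astype(int).to_numpy()
res = max_stat_permutation_test(cohort.momenta, sex,
                                statistic='hotelling', B=500, seed=1)
print(f"sex vs shape: p = {res.p_value:.3f}, r2 = {res.r2:.1f}%")

vols = {lab: np.mean([cusp_quantify(m, cohort.frame)[lab]['volume_mm3']
                      for m in cohort.calcium_maps])
        for lab in ('NCC', 'LCC', 'RCC')}
print("cusp calcium mm3:", {k: round(v) for k, v in vols.items()})

slabs = [slab_average(m, 'A') for m in cohort.calcium_maps]
z, diff = z_map(slabs, sex, theta=2.2)
print(f"sex z-map max {z.max():.1f}")
```

prints (seed 7):

```
annulus 26.5 mm, calcium 2591 mm3
reconstruction error 0.09 mm, variability 1.69 mm
sex vs shape: p = 0.004, r2 = 19.0%
cusp calcium mm3: {'NCC': 712, 'LCC': 534, 'RCC': 487}
sex z-map max 7.9
```

The annulus diameter sits at the cohort calibration (27 mm), the atlas
reconstructs subjects to a tenth of a millimetre while modelling ~1.7 mm
of anatomical variability (a ~19x ratio), the injected sexual dimorphism
is detected by the family-wise permutation test, the non-coronary cusp
carries the most calcium, and the z-map flags the commissural region
where the generator placed the male-specific calcification.

A full pipeline run (simulate -> atlas -> shape stats -> calcium ->
clinical -> JSON report) is one command:

```bash
tavimorph run-all --out out/ --n 30 --seed 7
```

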