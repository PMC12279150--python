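"""Synthetic TAVI cohort generator.

Stands in for the (non-public) patient data: an idealised aortic-root
template — a tube with three sinus bulges, valve plane at z = 0, total
length 1.5 x the root diameter — deformed per subject by covariate-
linked momenta, plus per-subject calcium maps painted in template space
from a voxelwise Bernoulli(p) x Gamma(k, theta) field with crescent-
shaped elevated-p regions on the three cusps (NCC highest), and a
clinical covariate table with the multicollinearity the analysis has to
cope with (sex - diameter - calcium, PVL group effects, non-monotone
'trivial' phenotype).

Default parameters emulate the cohort the analysis pipeline expects:
n = 130, annulus diameter centred on 27.0 mm with ~2.4 mm SD, male
anatomies larger, calcium totals around 2000 mm^3 with the NCC the most
calcified cusp.  Calcium is painted in template space and pushed forward
to native space so that the spatial-normalization round trip has an
exact target.

Every random draw goes through one :class:`numpy.random.Generator`, so
a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .calcium_model import CalciumMap, ValveFrame
from .deformation import (ControlPointGrid, DeformationKernel, MomentaField,
                          build_control_grid, deform_mesh, flow_points,
                          shoot, small_deform)
from .mesh import SurfaceMesh

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticCohort",
           "make_template_mesh", "sample_cohort", "measure_diameters"]


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n: int = 130
    # template geometry (mm)
    annulus_radius: float = 13.5
    sinus_bulge: float = 3.0
    length_factor: float = 1.5          # total length = factor x root diameter
    skirt: float = 5.0                  # below-annulus extension
    n_rings: int = 26
    n_azimuth: int = 24
    # deformation model
    lambda_v: float = 11.0
    grid_margin: float = 1.0
    shoot_steps: int = 8
    # momenta structure (coefficients in mm of peak displacement)
    sex_size_diff: float = 2.2          # male-female annulus diameter gap
    size_sd: float = 1.9
    curve_sd: float = 0.8
    sex_curve_diff: float = -0.7        # males straighter
    lcc_sd: float = 0.4
    narrow_sd: float = 0.4
    n_random_modes: int = 2
    random_mode_sd: float = 1.0
    noise_sd: float = 0.35
    # PVL group shifts on the LCC-elongation / narrow-root fields
    pvl_proportions: tuple = (0.26, 0.20, 0.43, 0.10, 0.01)
    pvl_lcc_shift: tuple = (0.0, -0.2, 0.5, 0.7, 0.8)
    pvl_narrow_shift: tuple = (0.0, 0.8, 0.0, 0.0, 0.0)
    # calcium field
    theta: float = 2.2
    p_cusp: tuple = (0.30, 0.22, 0.18)  # NCC, LCC, RCC
    k_cusp: float = 1.0
    severity_sigma: float = 0.4         # per-subject lognormal p multiplier
    p_wall: float = 0.035
    p_wall_rcc_extra: float = 0.02
    p_base: float = 0.003
    k_wall: float = 1.0
    p_sex_commissure: float = 0.12      # male bump at the LCC/RCC commissure
    p_size_lcc: float = 0.04            # per-SD-of-size bump on the LCC
    p_age_wall: float = 0.03            # younger patients: more wall calcium
    calcium_origin: tuple = (-22.0, -22.0, -6.0)
    calcium_shape: tuple = (45, 45, 32)
    native_spacing: float = 0.5         # CT-like native voxel size (mm)
    # covariate missingness (count out of n, scaled for other n)
    missingness: bool = True

    @property
    def root_diameter(self) -> float:
        return 2.0 * self.annulus_radius

    @property
    def length(self) -> float:
        return self.length_factor * self.root_diameter


def _radius_profile(cfg: GeneratorConfig):
    """Base tube radius r(z) through anatomically ordered anchors."""
    from scipy.interpolate import PchipInterpolator
    top = cfg.length - cfg.skirt
    z_anchor = [-cfg.skirt, 0.0, 8.0, 0.5 * top, top]
    r_ann = cfg.annulus_radius
    r_anchor = [0.98 * r_ann, r_ann, 1.04 * r_ann, 1.06 * r_ann,
                1.27 * r_ann]
    return PchipInterpolator(z_anchor, r_anchor)


def _petal(azimuth_rad: np.ndarray) -> np.ndarray:
    """Three-fold sinus modulation peaking at the cusp centres.

    Commissures sit at 90/210/330 deg so cusp centres are 30/150/270.
    """
    w = 0.5 * (1.0 + np.cos(3.0 * (azimuth_rad - np.radians(30.0))))
    return w ** 1.5


def make_template_mesh(config: GeneratorConfig | None = None
                       ) -> tuple[SurfaceMesh, ValveFrame]:
    """Idealised aortic root: closed tube with three sinus bulges."""
    cfg = config or GeneratorConfig()
    if cfg.annulus_radius <= 0 or cfg.n_rings < 4 or cfg.n_azimuth < 6:
        raise ValueError("degenerate template parameters")
    prof = _radius_profile(cfg)
    zs = np.linspace(-cfg.skirt, cfg.length - cfg.skirt, cfg.n_rings)
    phis = np.linspace(0.0, 2.0 * np.pi, cfg.n_azimuth, endpoint=False)
    # inflate radii so the inscribed-polygon cross-section area matches
    # the nominal circle (equivalent-circle diameters read true)
    poly = np.sqrt(2.0 * np.pi / cfg.n_azimuth
                   / np.sin(2.0 * np.pi / cfg.n_azimuth))
    bulge_env = cfg.sinus_bulge * np.exp(-((zs - 8.0) / 5.0) ** 2)
    verts = []
    for z, env in zip(zs, bulge_env):
        r = poly * (prof(z) + env * _petal(phis))
        verts.append(np.column_stack([r * np.cos(phis), r * np.sin(phis),
                                      np.full_like(phis, z)]))
    verts = np.concatenate(verts)
    nA = cfg.n_azimuth
    faces = []
    for i in range(cfg.n_rings - 1):
        for j in range(nA):
            a = i * nA + j
            b = i * nA + (j + 1) % nA
            c = (i + 1) * nA + j
            d = (i + 1) * nA + (j + 1) % nA
            faces += [[a, b, d], [a, d, c]]
    bot = len(verts)
    top = bot + 1
    verts = np.vstack([verts, [0.0, 0.0, zs[0]], [0.0, 0.0, zs[-1]]])
    for j in range(nA):                     # caps (watertight)
        faces.append([bot, (j + 1) % nA, j])
        base = (cfg.n_rings - 1) * nA
        faces.append([top, base + j, base + (j + 1) % nA])
    mesh = SurfaceMesh(verts, np.array(faces, dtype=int), name="template")
    frame = ValveFrame(center=np.zeros(3), radius=1.15 * cfg.annulus_radius,
                       height=(-5.0, 10.0))
    return mesh, frame


# -- diameter measurement ------------------------------------------------

MEASUREMENT_HEIGHTS = {"annulus": 0.0, "sov": 8.0, "stj": 20.0, "aao": 30.0}


def _section_area(mesh: SurfaceMesh, z: float) -> float:
    """Cross-section area at height z (star-shaped sections assumed)."""
    segments = trimesh.intersections.mesh_plane(
        mesh.to_trimesh(), plane_normal=[0.0, 0.0, 1.0],
        plane_origin=[0.0, 0.0, z])
    if len(segments) == 0:
        raise ValueError(f"plane z={z} misses the mesh")
    pts = segments.reshape(-1, 3)[:, :2]
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - center[1],
                                  pts[:, 0] - center[0]))
    poly = pts[order]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def measure_diameters(mesh: SurfaceMesh, frame: ValveFrame,
                      heights: dict | None = None,
                      markers: np.ndarray | None = None) -> dict:
    """Equivalent-circle diameters ``2 sqrt(area/pi)`` at frame heights.

    ``markers`` are optional transported coronary-ostium stand-in points
    whose z (above the valve plane) is reported as the coronary height.
    """
    heights = heights or MEASUREMENT_HEIGHTS
    out = {}
    for name, z in heights.items():
        area = _section_area(mesh, frame.center[2] + z)
        out[f"{name}_mm"] = 2.0 * np.sqrt(area / np.pi)
    if markers is not None:
        out["rca_height_mm"] = float(markers[0, 2] - frame.center[2])
        out["lca_height_mm"] = float(markers[1, 2] - frame.center[2])
    return out


# -- momenta mode fields -------------------------------------------------


def _normalize_field(raw: np.ndarray, grid: ControlPointGrid,
                     kernel: DeformationKernel,
                     template: SurfaceMesh) -> np.ndarray:
    """Scale a momenta field so unit coefficient = 1 mm peak displacement."""
    disp = small_deform(template.vertices, grid, MomentaField(raw), kernel) \
        - template.vertices
    peak = np.linalg.norm(disp, axis=1).max()
    if peak < 1e-12:
        raise ValueError("null mode field")
    return raw / peak


def _mode_fields(grid: ControlPointGrid, kernel: DeformationKernel,
                 template: SurfaceMesh, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    c = grid.points
    r = np.hypot(c[:, 0], c[:, 1])
    az = np.arctan2(c[:, 1], c[:, 0])
    rad_hat = np.where(r[:, None] > 1e-9,
                       np.column_stack([c[:, 0], c[:, 1], np.zeros(len(c))])
                       / np.maximum(r, 1e-9)[:, None], 0.0)
    fields = {}

    # isotropic size: radial expansion + mild vertical stretch
    scale = np.column_stack([c[:, 0], c[:, 1], 0.4 * (c[:, 2] - 12.0)])
    fields["scale"] = _normalize_field(scale, grid, kernel, template)
    # unit = +1 mm measured annulus diameter instead of peak displacement
    base = measure_diameters(template, ValveFrame())["annulus_mm"]
    probe = deform_mesh(template, shoot(grid,
                                        MomentaField(fields["scale"]),
                                        kernel, steps=cfg.shoot_steps))
    gain = measure_diameters(probe, ValveFrame())["annulus_mm"] - base
    fields["scale"] = fields["scale"] / gain

    # ascending-aorta curvature: lateral push growing above the sinuses
    curve = np.column_stack([np.clip(c[:, 2] - 15.0, 0.0, None),
                             np.zeros(len(c)), np.zeros(len(c))])
    fields["curve"] = _normalize_field(curve, grid, kernel, template)

    # LCC sinus elongation: radial bump in the LCC sector near the sinuses
    w_lcc = (np.exp(-((np.degrees(az) % 360.0 - 150.0) / 40.0) ** 2)
             * np.exp(-((c[:, 2] - 8.0) / 6.0) ** 2))
    fields["lcc"] = _normalize_field(w_lcc[:, None] * rad_hat, grid, kernel,
                                     template)

    # narrow root: inward radial below the sinotubular junction
    w_nar = np.exp(-((c[:, 2] - 4.0) / 8.0) ** 2)
    fields["narrow"] = _normalize_field(-w_nar[:, None] * rad_hat, grid,
                                        kernel, template)

    # smooth random modes: white momenta smoothed by the kernel Gram matrix
    K = kernel(c, c)
    for m in range(cfg.n_random_modes):
        raw = K @ rng.normal(size=(len(c), 3))
        fields[f"random{m}"] = _normalize_field(raw, grid, kernel, template)
    return fields


# -- calcium fields ------------------------------------------------------


def _calcium_grids(cfg: GeneratorConfig):
    origin = np.asarray(cfg.calcium_origin)
    ax = [origin[d] + np.arange(cfg.calcium_shape[d]) for d in range(3)]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    return origin, xs, ys, zs


def _calcium_pk_fields(cfg: GeneratorConfig, frame: ValveFrame):
    """Cohort-level Bernoulli-p and Gamma-k fields plus effect masks."""
    origin, xs, ys, zs = _calcium_grids(cfg)
    r = np.hypot(xs, ys)
    az = np.degrees(np.arctan2(ys, xs)) % 360.0
    prof = _radius_profile(cfg)
    wall_r = prof(np.clip(zs, -cfg.skirt, cfg.length - cfg.skirt))

    p = np.full(cfg.calcium_shape, cfg.p_base)
    k = np.full(cfg.calcium_shape, cfg.k_wall)

    cusp_band = (zs >= -2.0) & (zs < 6.0) & (r >= 7.0) & (r <= 13.5)
    sector = frame.sector_of(az)
    # crescent: heavier towards the commissures within each cusp
    crescent = 0.6 + 0.4 * np.abs(np.sin(np.radians(1.5 * (az - 30.0))))
    for i, p_i in enumerate(cfg.p_cusp):
        m = cusp_band & (sector == i)
        p[m] = p_i * crescent[m]
        k[m] = cfg.k_cusp

    wall_band = (zs >= 8.0) & (zs < 26.0) & (r >= wall_r - 2.0) \
        & (r <= wall_r + 1.0)
    p[wall_band] = cfg.p_wall
    rcc_side = wall_band & (sector == 2)
    p[rcc_side] += cfg.p_wall_rcc_extra

    sex_mask = (cusp_band
                & (np.abs((az - 210.0 + 180.0) % 360.0 - 180.0) < 35.0))
    lcc_mask = cusp_band & (sector == 1)
    return {"p": p, "k": k, "cusp_band": cusp_band, "wall_band": wall_band,
            "sex_mask": sex_mask, "lcc_mask": lcc_mask, "origin": origin}


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    template: SurfaceMesh
    frame: ValveFrame
    grid: ControlPointGrid
    kernel: DeformationKernel
    momenta: np.ndarray                  # (n, K, 3)
    mode_fields: dict
    coefficients: pd.DataFrame
    p_field: np.ndarray
    k_field: np.ndarray
    labels: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    covariates: pd.DataFrame
    meshes: list
    momenta: np.ndarray
    calcium_maps: list
    ground_truth: GroundTruth
    frame: ValveFrame

    def trajectory(self, i: int):
        gt = self.ground_truth
        return shoot(gt.grid, MomentaField(gt.momenta[i]), gt.kernel,
                     steps=self.config.shoot_steps)

    def native_calcium(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Materialise subject i's native-space calcium volume.

        The template-space map is pushed forward: each native voxel
        centre is pulled back through the inverse deformation and the
        template map is sampled nearest-neighbour.  The native grid is
        CT-like (``native_spacing``, default 0.5 mm).  The inverse
        deformation is integrated exactly on a coarse 3 mm lattice and
        interpolated to the native voxels — the velocity field is smooth
        at the kernel scale (lambda_V ~ 11 mm), so the interpolation
        error is far below the voxel size.  Returns ``(volume, affine)``.
        """
        from scipy.ndimage import map_coordinates

        cfg = self.config
        cmap = self.calcium_maps[i]
        h = cfg.native_spacing
        origin = cmap.origin - 4.0
        extent = np.array(cmap.data.shape) + 8.0
        shape = tuple(int(np.ceil(e / h)) for e in extent)
        traj = self.trajectory(i)

        # exact inverse flow on a coarse lattice spanning the native grid
        coarse = 3.0
        n_c = [int(np.ceil(extent[d] / coarse)) + 1 for d in range(3)]
        ax_c = [origin[d] + coarse * np.arange(n_c[d]) for d in range(3)]
        xs, ys, zs = np.meshgrid(*ax_c, indexing="ij")
        lattice = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        disp = (flow_points(lattice, traj, direction="inverse")
                - lattice).reshape(n_c + [3])

        ax = [origin[d] + h * np.arange(shape[d]) for d in range(3)]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        centers = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        frac = ((centers - origin) / coarse).T
        back = centers + np.column_stack(
            [map_coordinates(disp[..., d], frac, order=1, mode="nearest")
             for d in range(3)])
        idx = np.round(back - cmap.origin).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(cmap.data.shape)), axis=1)
        vals = np.zeros(len(centers))
        vals[ok] = cmap.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        affine = np.diag([h, h, h, 1.0])
        affine[:3, 3] = origin
        return vals.reshape(shape), affine


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def sample_cohort(config: GeneratorConfig | None = None,
                  seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort (deterministic in ``seed``)."""
    cfg = config or GeneratorConfig()
    if cfg.n < 2:
        raise ValueError("need n >= 2 subjects")
    rng = np.random.default_rng(seed)
    template, frame = make_template_mesh(cfg)
    kernel = DeformationKernel(cfg.lambda_v)
    grid = build_control_grid([template], spacing=cfg.lambda_v,
                              margin=cfg.grid_margin)
    fields = _mode_fields(grid, kernel, template, cfg, rng)

    n = cfg.n
    male = rng.random(n) < 63.0 / 130.0
    male_c = male - male.mean()

    coef = pd.DataFrame(index=range(n))
    coef["scale"] = cfg.sex_size_diff * male_c + rng.normal(0, cfg.size_sd, n)
    coef["curve"] = cfg.sex_curve_diff * male_c + rng.normal(0, cfg.curve_sd, n)

    # PVL grades: driven by size (smaller -> worse) plus noise
    latent = -0.7 * (coef["scale"] / max(coef["scale"].std(), 1e-9)) \
        + rng.normal(0, 1, n)
    edges = np.quantile(latent, np.cumsum(cfg.pvl_proportions)[:-1])
    pvl_idx = np.searchsorted(edges, latent)
    pvl = np.array(["none", "trivial", "mild", "moderate", "severe"])[pvl_idx]

    coef["lcc"] = rng.normal(0, cfg.lcc_sd, n) \
        + np.asarray(cfg.pvl_lcc_shift)[pvl_idx]
    coef["narrow"] = rng.normal(0, cfg.narrow_sd, n) \
        + np.asarray(cfg.pvl_narrow_shift)[pvl_idx]
    for m in range(cfg.n_random_modes):
        coef[f"random{m}"] = rng.normal(0, cfg.random_mode_sd, n)

    K = kernel(grid.points, grid.points)
    momenta = np.zeros((n, grid.n_points, 3))
    for name, f in fields.items():
        momenta += coef[name].to_numpy()[:, None, None] * f
    noise_raw = K @ rng.normal(size=(n, grid.n_points, 3))
    peak = np.abs(noise_raw).max() or 1.0
    momenta += cfg.noise_sd * noise_raw / peak * 3.0

    # subject meshes: template shot along each momenta field
    markers_t = np.array([
        [10.0 * np.cos(np.radians(270)), 10.0 * np.sin(np.radians(270)), 14.7],
        [10.0 * np.cos(np.radians(150)), 10.0 * np.sin(np.radians(150)), 13.1],
    ])
    meshes, rows = [], []
    for i in range(n):
        traj = shoot(grid, MomentaField(momenta[i]), kernel,
                     steps=cfg.shoot_steps)
        mesh = deform_mesh(template, traj)
        mesh.name = f"s{i:03d}"
        meshes.append(mesh)
        markers = flow_points(markers_t, traj)
        rows.append(measure_diameters(mesh, frame, markers=markers))
    diam = pd.DataFrame(rows)

    # calcium in template space
    pk = _calcium_pk_fields(cfg, frame)
    age = _truncnorm(rng, 82.0, 7.9, 54.0, 97.0, n)
    z_size = (coef["scale"] / max(coef["scale"].std(), 1e-9)).to_numpy()
    z_age = (age - age.mean()) / age.std()
    severity = rng.lognormal(-0.5 * cfg.severity_sigma ** 2,
                             cfg.severity_sigma, n)    # mean 1 multiplier
    maps, calc_vol = [], np.zeros(n)
    for i in range(n):
        p_i = pk["p"] * severity[i]
        if male[i]:
            p_i[pk["sex_mask"]] += cfg.p_sex_commissure
        p_i[pk["lcc_mask"]] += cfg.p_size_lcc * z_size[i]
        if z_age[i] < 0:
            p_i[pk["wall_band"]] += cfg.p_age_wall
        p_i = np.clip(p_i, 0.0, 0.95)
        occupied = rng.random(p_i.shape) < p_i
        amount = np.where(
            occupied, rng.gamma(np.maximum(pk["k"], 1e-6), cfg.theta,
                                size=p_i.shape), 0.0)
        maps.append(CalciumMap(amount, pk["origin"].copy(),
                               subject_id=f"s{i:03d}"))
        calc_vol[i] = amount.sum()

    # clinical covariates with the documented correlation structure
    pg = np.clip(43.6 + 4.5 * (calc_vol - calc_vol.mean())
                 / max(calc_vol.std(), 1e-9)
                 + rng.normal(0, 12.1, n), 19.0, 90.0)
    ef = _truncnorm(rng, 54.4, 11.3, 12.0, 77.0, n)
    z_ef = (ef - ef.mean()) / ef.std()
    euroscore = np.clip(3.9 - 0.45 * 6.8 * z_ef
                        + rng.gamma(1.5, 2.0, n) - 3.0, 0.8, 61.0)
    sv = np.clip(70.8 + 0.26 * 22.4 * z_ef + rng.normal(0, 21.6, n),
                 28.0, 153.0)
    bsa = np.clip(1.81 + 0.10 * male_c * 2 + rng.normal(0, 0.17, n),
                  1.39, 2.35)
    bmi = np.clip(27.8 + 8.0 * (bsa - bsa.mean()) + rng.normal(0, 6.0, n),
                  14.9, 54.4)
    z_bmi = (bmi - bmi.mean()) / bmi.std()
    frailty = np.clip(np.round(3.79 - 0.4 * male_c * 2 - 0.25 * 1.67 * z_bmi
                               + rng.normal(0, 1.4, n)), 1, 7)
    hypertension = (rng.random(n) < 0.80).astype(int)
    coronary = (rng.random(n) < np.where(male, 0.65, 0.36)).astype(int)

    # device choice: annulus-driven sizing, high calcium weighs towards
    # the smaller device; self-expanding devices in low-calcium cases
    z_calc = (calc_vol - calc_vol.mean()) / max(calc_vol.std(), 1e-9)
    score = diam["annulus_mm"].to_numpy() + rng.normal(0, 0.8, n) \
        - 0.9 * z_calc
    device_size = np.select([score < 23.0, score < 25.8, score < 28.6],
                            [20.0, 23.0, 26.0], default=29.0)
    p_self = 1.0 / (1.0 + np.exp(1.9 + 0.8 * z_calc))
    device_type = np.where(rng.random(n) < p_self, "self_expanding",
                           "balloon")

    table = pd.DataFrame({
        "subject": [f"s{i:03d}" for i in range(n)],
        "age": age, "sex": np.where(male, "male", "female"),
        "bsa": bsa, "bmi": bmi, "hypertension": hypertension,
        "coronary_disease": coronary, "euroscore": euroscore,
        "frailty": frailty,
        **{k: diam[k].to_numpy() for k in diam.columns},
        "calcium_volume_mm3": calc_vol, "stroke_volume": sv,
        "ejection_fraction": ef, "pressure_gradient": pg,
        "pvl": pvl, "device_type": device_type,
        "device_size": device_size,
    })

    if cfg.missingness:
        for col, miss in [("bsa", 23), ("bmi", 23), ("euroscore", 12),
                          ("ejection_fraction", 34), ("stroke_volume", 46),
                          ("pvl", 15), ("device_type", 3),
                          ("device_size", 3)]:
            k_miss = int(round(miss * n / 130.0))
            if k_miss > 0:
                idx = rng.choice(n, size=k_miss, replace=False)
                table.loc[idx, col] = np.nan

    labels = pd.DataFrame({"male": male, "pvl": pvl})
    gt = GroundTruth(template=template, frame=frame, grid=grid,
                     kernel=kernel, momenta=momenta, mode_fields=fields,
                     coefficients=coef, p_field=pk["p"], k_field=pk["k"],
                     labels=labels)
    return SyntheticCohort(config=cfg, covariates=table, meshes=meshes,
                           momenta=momenta, calcium_maps=maps,
                           ground_truth=gt, frame=frame)
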