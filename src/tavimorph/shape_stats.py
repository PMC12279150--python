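"""Statistics on atlas momenta.

The momenta of a fitted atlas live in a linear space, so subgroup means,
ordinary least squares against clinical covariates, and PCA all apply
directly.  Hypothesis testing uses a per-control-point statistic —
two-sample Hotelling T^2 on the 3D momenta for group comparisons, a
Wilks-type likelihood-ratio statistic for linear effects of continuous
covariates — combined with the *maximum* over control points and a
label-permutation scheme, which controls the family-wise error without
distributional assumptions on the momenta.

Effect size is reported as the percentage of total momenta variance
explained by the covariate(s) in an OLS fit with a shared design matrix
(r^2 summed over all momenta coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasModel
from .deformation import MomentaField, kernel_matrix
from .mesh import SurfaceMesh

__all__ = [
    "ShapeTestResult", "group_mean_shape", "regress_momenta",
    "render_effect", "hotelling_t2_map", "lr_stat_map",
    "max_stat_permutation_test", "adjusted_test", "momenta_stat_maps_export",
]

_RIDGE = 1e-6


@dataclass
class ShapeTestResult:
    """Outcome of a max-statistic permutation test on momenta."""

    stat_map: np.ndarray          # (K,) per-control-point statistic
    max_stat: float
    p_value: float
    n_permutations: int
    statistic: str
    r2: float | None = None       # % of momenta variance explained
    effect: MomentaField | None = None


def _as_array(momenta) -> np.ndarray:
    if isinstance(momenta, np.ndarray):
        arr = momenta
    else:
        arr = np.stack([m.vectors for m in momenta])
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("momenta must have shape (subjects, points, 3)")
    return np.asarray(arr, dtype=float)


def group_mean_shape(momenta, members, atlas: AtlasModel
                     ) -> tuple[SurfaceMesh, MomentaField]:
    """Mean momenta over a subject subset and the rendered mean shape."""
    arr = _as_array(momenta)
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if len(members) == 0:
        raise ValueError("empty subject subset")
    mean = MomentaField(arr[members].mean(axis=0))
    return atlas.deform_template(mean), mean


def _design(covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([np.ones((len(X), 1)), X])


def regress_momenta(momenta, covariates):
    """OLS of every momenta coordinate on a shared design matrix.

    Rows with missing covariate values are dropped (complete cases; no
    imputation).  Returns a dict with per-covariate coefficient fields,
    residuals, fitted values, the r^2 (%) over all coordinates, and the
    index of retained subjects.
    """
    arr = _as_array(momenta)
    cov = pd.DataFrame(covariates)
    mask = cov.notna().all(axis=1).to_numpy()
    arr, cov = arr[mask], cov[mask]
    n = len(arr)
    X = _design(cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear "
                         "covariate)")
    Y = arr.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    resid = Y - fitted
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    rss = float((resid ** 2).sum())
    r2 = 100.0 * (1.0 - rss / tss) if tss > 0 else 0.0
    coef_fields = {name: MomentaField(beta[j + 1].reshape(-1, 3))
                   for j, name in enumerate(cov.columns)}
    return {"coefficients": coef_fields, "intercept": beta[0].reshape(-1, 3),
            "residuals": resid.reshape(arr.shape), "r2": r2,
            "subjects": np.flatnonzero(mask), "design": X,
            "covariates": cov}


def render_effect(regression: dict, covariate, k: float,
                  atlas: AtlasModel) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Template renders at mean -/+ ``k`` covariate SDs along one effect."""
    if k <= 0:
        raise ValueError("k must be positive")
    coef = regression["coefficients"][covariate].vectors
    sd = float(np.std(regression["covariates"][covariate].to_numpy(
        dtype=float), ddof=1))
    # mean momenta = intercept + x_mean . coefficients
    names = list(regression["covariates"].columns)
    x_mean = regression["design"][:, 1:].mean(axis=0)
    mean = regression["intercept"].copy()
    for j, name in enumerate(names):
        mean = mean + x_mean[j] * regression["coefficients"][name].vectors
    lo = atlas.deform_template(MomentaField(mean - k * sd * coef))
    hi = atlas.deform_template(MomentaField(mean + k * sd * coef))
    return lo, hi


def _pooled_cov(groups: list[np.ndarray]) -> np.ndarray:
    """(K, 3, 3) pooled within-group covariance with a trace ridge."""
    K = groups[0].shape[1]
    dof = sum(len(g) for g in groups) - len(groups)
    S = np.zeros((K, 3, 3))
    for g in groups:
        d = g - g.mean(axis=0)
        S += np.einsum("nki,nkj->kij", d, d)
    S /= dof
    tr = np.trace(S, axis1=1, axis2=2) / 3.0
    S += (_RIDGE * np.maximum(tr, 1e-300))[:, None, None] * np.eye(3)
    return S


def hotelling_t2_map(momenta, labels) -> np.ndarray:
    """Two-sample Hotelling T^2 at every control point.

    ``labels`` is a binary vector; the 3x3 pooled covariance gets a
    small trace-proportional ridge so rank-deficient small groups stay
    invertible.
    """
    arr = _as_array(momenta)
    labels = np.asarray(labels)
    values = np.unique(labels)
    if len(values) != 2:
        raise ValueError("labels must be binary")
    g0, g1 = arr[labels == values[0]], arr[labels == values[1]]
    n0, n1 = len(g0), len(g1)
    if min(n0, n1) < 4:
        raise ValueError("each group needs >= 4 subjects for a 3x3 "
                         "covariance")
    S = _pooled_cov([g0, g1])
    d = g0.mean(axis=0) - g1.mean(axis=0)             # (K, 3)
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    return (n0 * n1 / (n0 + n1)) * np.einsum("ki,ki->k", d, sol)


def lr_stat_map(momenta, covariates) -> np.ndarray:
    """Wilks-type statistic ``n log(det S0 / det S1)`` per control point.

    Compares the intercept-only model to the full linear model for the
    3D momenta response; determinants are ridge-stabilised.
    """
    arr = _as_array(momenta)
    cov = pd.DataFrame(covariates)
    mask = cov.notna().all(axis=1).to_numpy()
    arr, cov = arr[mask], cov[mask]
    n = len(arr)
    X = _design(cov)
    if n <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")

    def resid_cov(design):
        Q, _ = np.linalg.qr(design)
        Y = arr.reshape(n, -1)
        R = (Y - Q @ (Q.T @ Y)).reshape(arr.shape)
        return np.einsum("nki,nkj->kij", R, R) / n

    S0 = resid_cov(np.ones((n, 1)))
    S1 = resid_cov(X)
    # one shared absolute ridge per point (from the null-model scale), so
    # degenerate coordinates cancel exactly in the determinant ratio
    tr = np.trace(S0, axis1=1, axis2=2) / 3.0
    ridge = (_RIDGE * np.maximum(tr, 1e-300))[:, None, None] * np.eye(3)
    S0 = S0 + ridge
    S1 = S1 + ridge
    sign0, logdet0 = np.linalg.slogdet(S0)
    sign1, logdet1 = np.linalg.slogdet(S1)
    return n * (logdet0 - logdet1)


def _encode_variable(variable):
    """Numeric matrix for a test variable; one-hot for categoricals."""
    if isinstance(variable, pd.DataFrame):
        return variable.to_numpy(dtype=float), False
    if isinstance(variable, np.ndarray) and variable.ndim == 2:
        return variable.astype(float), False
    s = pd.Series(variable)
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(s, drop_first=True)
        return dummies.to_numpy(dtype=float), True
    return s.to_numpy(dtype=float)[:, None], False


def max_stat_permutation_test(momenta, variable, statistic: str = "hotelling",
                              B: int = 1000, seed: int | None = None,
                              rng: np.random.Generator | None = None
                              ) -> ShapeTestResult:
    """Family-wise test of a shape-covariate association.

    The observed per-control-point map is summarised by its maximum;
    ``B`` permutations of the variable (momenta fixed) give the null of
    that maximum, and ``p = (1 + #{perm max >= observed}) / (B + 1)``.
    Categorical variables are one-hot coded and tested with the LR
    statistic.
    """
    if B < 100:
        raise ValueError("use at least 100 permutations")
    arr = _as_array(momenta)
    rng = rng or np.random.default_rng(seed)
    enc, categorical = _encode_variable(variable)
    mask = np.all(np.isfinite(enc), axis=1)
    arr, enc = arr[mask], enc[mask]
    if len(np.unique(enc, axis=0)) < 2:
        raise ValueError("variable is constant")

    if statistic == "hotelling":
        if categorical or len(np.unique(enc)) != 2:
            raise ValueError("hotelling requires a binary variable")
        labels = enc[:, 0]
        def stat(v): return hotelling_t2_map(arr, v)
        observed = stat(labels)
        perm_input = labels
    elif statistic == "lr":
        def stat(v): return lr_stat_map(arr, v)
        observed = stat(enc)
        perm_input = enc
    else:
        raise ValueError("statistic must be 'hotelling' or 'lr'")

    obs_max = float(observed.max())
    exceed = 0
    n = len(arr)
    for _ in range(B):
        perm = rng.permutation(n)
        if float(stat(perm_input[perm]).max()) >= obs_max:
            exceed += 1
    p = (1.0 + exceed) / (B + 1.0)

    try:
        reg = regress_momenta(arr, pd.DataFrame(enc))
        r2 = reg["r2"]
        first = next(iter(reg["coefficients"].values()))
        effect = first
    except ValueError:
        r2, effect = None, None
    return ShapeTestResult(stat_map=observed, max_stat=obs_max, p_value=p,
                           n_permutations=B, statistic=statistic, r2=r2,
                           effect=effect)


def adjusted_test(momenta, variable, co_regressors,
                  statistic: str = "hotelling", B: int = 1000,
                  seed: int | None = None) -> ShapeTestResult:
    """Covariate-adjusted max-statistic test.

    Momenta are residualised on the co-regressors by OLS; the test is
    then applied to the residuals while permuting the variable of
    interest (Freedman-Lane style).  With no co-regressors this reduces
    exactly to :func:`max_stat_permutation_test`.
    """
    co = pd.DataFrame(co_regressors) if co_regressors is not None else None
    if co is None or co.shape[1] == 0:
        return max_stat_permutation_test(momenta, variable, statistic, B,
                                         seed=seed)
    arr = _as_array(momenta)
    enc, _ = _encode_variable(variable)
    valid = (np.all(np.isfinite(enc), axis=1)
             & co.notna().all(axis=1).to_numpy())
    arr, enc, co = arr[valid], enc[valid], co[valid]

    Z = _design(co)
    x = enc.astype(float)
    aug = np.hstack([Z, x])
    cond = np.linalg.cond(aug)
    if cond > 1e8:
        warnings.warn(f"variable nearly collinear with co-regressors "
                      f"(condition number {cond:.3g})")
    Q, _ = np.linalg.qr(Z)
    Y = arr.reshape(len(arr), -1)
    resid = (Y - Q @ (Q.T @ Y)).reshape(arr.shape)

    if statistic == "hotelling":
        labels = enc[:, 0]
        med = np.median(labels)
        binary = labels if len(np.unique(labels)) == 2 else labels > med
        return max_stat_permutation_test(resid, binary, "hotelling", B,
                                         seed=seed)
    return max_stat_permutation_test(resid, pd.DataFrame(enc), "lr", B,
                                     seed=seed)


def momenta_stat_maps_export(result: ShapeTestResult, atlas: AtlasModel
                             ) -> np.ndarray:
    """Interpolate a control-point statistic map to template vertices.

    Normalised Gaussian-kernel interpolation with the deformation kernel
    width; returns the per-vertex field (write it with
    :func:`tavimorph.io.write_mesh` as a VTK scalar).
    """
    W = kernel_matrix(atlas.template.vertices, atlas.grid.points,
                      atlas.deformation_kernel)
    wsum = W.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("vertex outside the kernel support of the grid")
    return (W @ result.stat_map) / wsum
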