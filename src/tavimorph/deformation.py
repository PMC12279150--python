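"""Kernel-parametrized diffeomorphic deformations.

A deformation is generated by a time-dependent velocity field

.. math::

    v_t(x) = \\sum_k K(x, c_k(t))\\, a_k(t),

where the ``c_k`` are control points on a regular lattice, the ``a_k``
are the momenta (one 3D vector per control point) and
``K(x, y) = exp(-|x - y|^2 / lambda_V^2)`` is a Gaussian reproducing
kernel of width ``lambda_V``.  Geodesic paths in the induced metric
follow the Hamiltonian point-vortex equations

.. math::

    \\dot c_k = \\sum_l K(c_k, c_l)\\, a_l, \\qquad
    \\dot a_k = -\\sum_l (a_k \\cdot a_l)\\, \\nabla_1 K(c_k, c_l),

integrated here with a fixed-step RK4 scheme over ``t in [0, 1]``.  The
flow conserves the Hamiltonian ``H = 0.5 * sum_{kl} K(c_k,c_l) a_k.a_l``
and is invertible by reverse-time integration of the same field.

A linearised "small-deformation" map ``x -> x + sum_k K(x, c_k) a_k`` is
also provided; it shares the momenta parametrization and is used where a
single explicit (and linear-in-momenta) step is preferable, e.g. inside
gradient-based registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "DeformationKernel", "ControlPointGrid", "MomentaField",
    "FlowTrajectory", "build_control_grid", "kernel_matrix", "shoot",
    "flow_points", "deform_mesh", "small_deform", "rkhs_norm",
    "rigid_align", "hamiltonian",
]


@dataclass(frozen=True)
class DeformationKernel:
    """Gaussian RKHS kernel ``K(x, y) = exp(-|x-y|^2 / width^2)``.

    ``width`` is the deformation scale lambda_V in mm; it controls the
    stiffness of the deformations (points closer than ~width move
    together).
    """

    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("kernel width must be positive")

    def __call__(self, points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
        return kernel_matrix(points_a, points_b, self)


def kernel_matrix(points_a: np.ndarray, points_b: np.ndarray,
                  kernel: DeformationKernel) -> np.ndarray:
    """Gram matrix ``K[i, j] = exp(-|a_i - b_j|^2 / width^2)``."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty point set")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / kernel.width ** 2)


@dataclass
class ControlPointGrid:
    """Regular axis-aligned lattice of control points.

    ``points`` is the (K, 3) array of lattice nodes, ``spacing`` the
    lattice step and ``margin`` the inflation that was applied to the
    data bounding box when the grid was built.
    """

    points: np.ndarray
    spacing: float
    margin: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def n_points(self) -> int:
        return len(self.points)


def build_control_grid(meshes, spacing: float,
                       margin: float = 1.0) -> ControlPointGrid:
    """Regular control-point lattice covering a collection of meshes.

    The lattice spans the joint bounding box of all vertices, inflated by
    ``margin`` mm on every side; the last lattice node in each axis is at
    or beyond the inflated upper bound.
    """
    meshes = list(meshes)
    if not meshes:
        raise ValueError("at least one mesh required")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    lo = np.min([m.vertices.min(axis=0) for m in meshes], axis=0) - margin
    hi = np.max([m.vertices.max(axis=0) for m in meshes], axis=0) + margin
    axes = []
    for d in range(3):
        n = int(np.ceil((hi[d] - lo[d]) / spacing - 1e-9)) + 1
        axes.append(lo[d] + spacing * np.arange(n))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return ControlPointGrid(grid, spacing=spacing, margin=margin)


@dataclass
class MomentaField:
    """One 3D momentum vector per control point (mm units)."""

    vectors: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[1] != 3:
            raise ValueError("momenta must be a (K, 3) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite momenta")

    @classmethod
    def zeros(cls, grid: ControlPointGrid, reference: str = "") -> "MomentaField":
        return cls(np.zeros((grid.n_points, 3)), reference=reference)


@dataclass
class FlowTrajectory:
    """Discretised geodesic flow of control points and momenta.

    ``positions``/``momenta`` have shape (steps + 1, K, 3); row 0 is the
    initial condition, row ``steps`` the state at t = 1.
    """

    positions: np.ndarray
    momenta: np.ndarray
    kernel: DeformationKernel
    integrator: str = "rk4"

    @property
    def steps(self) -> int:
        return len(self.positions) - 1


def _hamiltonian_rhs(c: np.ndarray, a: np.ndarray,
                     kernel: DeformationKernel):
    """Right-hand side of the geodesic equations for state (c, a)."""
    diff = c[:, None, :] - c[None, :, :]
    K = np.exp(-np.sum(diff ** 2, axis=-1) / kernel.width ** 2)
    dc = K @ a
    # da_k = sum_l (a_k . a_l) * 2 (c_k - c_l) / width^2 * K_kl
    dots = a @ a.T
    da = 2.0 / kernel.width ** 2 * np.einsum("kl,klj->kj", K * dots, diff)
    return dc, da


def hamiltonian(c: np.ndarray, a: np.ndarray,
                kernel: DeformationKernel) -> float:
    """``0.5 * sum_{kl} K(c_k, c_l) a_k . a_l`` — conserved along shoot."""
    K = kernel(c, c)
    return float(0.5 * np.einsum("kl,kd,ld->", K, a, a))


def shoot(grid: ControlPointGrid, momenta: MomentaField,
          kernel: DeformationKernel, steps: int = 10) -> FlowTrajectory:
    """Integrate the geodesic equations from ``(grid, momenta)``.

    Returns the full trajectory over t in [0, 1] with RK4 at ``steps``
    uniform time steps.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    c = np.asarray(grid.points, dtype=float)
    a = np.asarray(momenta.vectors, dtype=float)
    if a.shape != c.shape:
        raise ValueError("momenta size does not match control grid")
    h = 1.0 / steps
    cs = np.empty((steps + 1,) + c.shape)
    as_ = np.empty_like(cs)
    cs[0], as_[0] = c, a
    for s in range(steps):
        c0, a0 = cs[s], as_[s]
        k1c, k1a = _hamiltonian_rhs(c0, a0, kernel)
        k2c, k2a = _hamiltonian_rhs(c0 + 0.5 * h * k1c, a0 + 0.5 * h * k1a, kernel)
        k3c, k3a = _hamiltonian_rhs(c0 + 0.5 * h * k2c, a0 + 0.5 * h * k2a, kernel)
        k4c, k4a = _hamiltonian_rhs(c0 + h * k3c, a0 + h * k3a, kernel)
        cs[s + 1] = c0 + h / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
        as_[s + 1] = a0 + h / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
    return FlowTrajectory(cs, as_, kernel)


def _flow_rhs(x, c, a, kernel):
    dc, da = _hamiltonian_rhs(c, a, kernel)
    dx = kernel(x, c) @ a
    return dx, dc, da


def flow_points(points: np.ndarray, trajectory: FlowTrajectory,
                kernel: DeformationKernel | None = None,
                direction: str = "forward") -> np.ndarray:
    """Transport points along (or against) the flow of a trajectory.

    ``forward`` integrates ``dx/dt = sum_k K(x, c_k(t)) a_k(t)`` from
    t=0 to t=1.  ``inverse`` integrates the same field in reverse time
    starting from the endpoint state, which is the exact inverse map of
    the forward flow (up to integrator error).

    The control-point state is co-integrated with the passive points so
    that RK4 sub-steps see a consistent field.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    kernel = kernel or trajectory.kernel
    x = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input points")
    steps = trajectory.steps
    h = 1.0 / steps
    if direction == "forward":
        c, a, sign = trajectory.positions[0], trajectory.momenta[0], 1.0
    else:
        c, a, sign = trajectory.positions[-1], trajectory.momenta[-1], -1.0
    c, a = c.copy(), a.copy()
    for _ in range(steps):
        k1 = _flow_rhs(x, c, a, kernel)
        k2 = _flow_rhs(x + sign * 0.5 * h * k1[0], c + sign * 0.5 * h * k1[1],
                       a + sign * 0.5 * h * k1[2], kernel)
        k3 = _flow_rhs(x + sign * 0.5 * h * k2[0], c + sign * 0.5 * h * k2[1],
                       a + sign * 0.5 * h * k2[2], kernel)
        k4 = _flow_rhs(x + sign * h * k3[0], c + sign * h * k3[1],
                       a + sign * h * k3[2], kernel)
        x = x + sign * h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        c = c + sign * h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        a = a + sign * h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return x


def deform_mesh(mesh: SurfaceMesh, trajectory: FlowTrajectory,
                kernel: DeformationKernel | None = None,
                direction: str = "forward") -> SurfaceMesh:
    """Transport mesh vertices by the flow; connectivity is untouched."""
    new_vertices = flow_points(mesh.vertices, trajectory, kernel, direction)
    out = mesh.with_vertices(new_vertices)
    areas = np.linalg.norm(out.face_normals(), axis=1)
    if np.any(areas < 1e-12) and not np.any(
            np.linalg.norm(mesh.face_normals(), axis=1) < 1e-12):
        warnings.warn("deformation produced degenerate faces")
    return out


def small_deform(points: np.ndarray, grid: ControlPointGrid,
                 momenta: MomentaField,
                 kernel: DeformationKernel) -> np.ndarray:
    """Single-step map ``x -> x + sum_k K(x, c_k) a_k`` (linear in momenta)."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    return x + kernel(x, grid.points) @ momenta.vectors


def rkhs_norm(momenta: MomentaField, grid: ControlPointGrid,
              kernel: DeformationKernel) -> float:
    """RKHS norm ``sqrt(sum_{kl} K(c_k, c_l) a_k . a_l)`` of a momenta field.

    This is the deformation-regularity penalty of the atlas objective
    (used squared there); it vanishes iff the momenta are all zero.
    """
    a = momenta.vectors
    if len(a) != grid.n_points:
        raise ValueError("momenta size does not match control grid")
    K = kernel(grid.points, grid.points)
    val = float(np.einsum("kl,kd,ld->", K, a, a))
    return float(np.sqrt(max(val, 0.0)))


def rigid_align(mesh: SurfaceMesh, reference,
                landmarks: np.ndarray | None = None,
                reference_landmarks: np.ndarray | None = None):
    """Least-squares rigid (rotation + translation, no scaling) alignment.

    Correspondence comes either from explicit landmark pairs or, when
    ``mesh`` and ``reference`` share their vertex count, from the
    vertices themselves.  Classic Kabsch solution via SVD with the
    determinant sign fix.

    Returns
    -------
    aligned : SurfaceMesh
    rotation : (3, 3) array
    translation : (3,) array
        such that ``aligned.vertices = mesh.vertices @ rotation.T + translation``.
    """
    if landmarks is None:
        src = mesh.vertices
        dst = reference.vertices if isinstance(reference, SurfaceMesh) \
            else np.asarray(reference, dtype=float)
        if len(src) != len(dst):
            raise ValueError("vertex counts differ; supply landmarks")
    else:
        src = np.atleast_2d(np.asarray(landmarks, dtype=float))
        dst = np.atleast_2d(np.asarray(reference_landmarks, dtype=float))
        if len(src) != len(dst):
            raise ValueError("landmark sets must pair up")
    if len(src) < 3:
        raise ValueError("at least 3 landmarks required")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("landmarks are collinear")
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    aligned = mesh.with_vertices(mesh.vertices @ R.T + t)
    return aligned, R, t
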