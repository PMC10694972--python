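"""Forward transfer operator and regularized inverse reconstruction.

The torso potentials relate linearly to the epicardial potentials,
phi_T = A phi_E. A is built either from a simple monopole kernel (vertex area
over 4*pi*distance, Wilson-terminal re-referenced) or from the
homogeneous-torso boundary-element double-layer formulation. The inverse is
zero-order Tikhonov,

    phi_E = argmin ||A phi - phi_T||^2 + lambda^2 ||phi||^2,

solved per time sample through one SVD of A, with lambda chosen once per beat
(at the time of maximal torso RMS) by the CRESO criterion, the L-curve corner,
or a fixed user value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InverseSolverError
from .geometry import ElectrodeSet, SurfaceMesh
from .sigproc import AveragedBeat

__all__ = [
    "TransferMatrix",
    "EpicardialSignalSet",
    "build_transfer_matrix",
    "solve_inverse",
    "creso_function",
]


@dataclass
class TransferMatrix:
    """Linear operator mapping heart-node potentials to electrode potentials."""

    A: np.ndarray  # electrodes x heart nodes, dimensionless gain
    row_index: np.ndarray  # electrode ids
    col_index: np.ndarray  # heart node ids
    kernel_kind: str = "custom"
    condition_estimate: float = float("nan")

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise InverseSolverError("A must be 2-D")
        if not np.all(np.isfinite(self.A)):
            raise InverseSolverError("A contains non-finite entries")
        self.row_index = np.asarray(self.row_index)
        self.col_index = np.asarray(self.col_index)
        if len(self.row_index) != self.A.shape[0]:
            raise InverseSolverError("row_index length mismatch")
        if len(self.col_index) != self.A.shape[1]:
            raise InverseSolverError("col_index length mismatch")

    @classmethod
    def identity(cls, n: int) -> "TransferMatrix":
        return cls(np.eye(n), np.arange(n), np.arange(n), "identity", 1.0)


@dataclass
class EpicardialSignalSet:
    """Unipolar electrograms, one waveform per heart node (mV)."""

    ueg: np.ndarray  # nodes x samples
    fs: float
    lambda_used: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ueg = np.asarray(self.ueg, dtype=float)
        if self.ueg.ndim != 2:
            raise InverseSolverError("ueg must be nodes x samples")
        if not np.all(np.isfinite(self.ueg)):
            raise InverseSolverError("ueg contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.ueg.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.ueg.shape[1]) * 1000.0 / self.fs


# -- forward operator ----------------------------------------------------------


def build_transfer_matrix(
    heart: SurfaceMesh,
    electrodes: ElectrodeSet,
    kernel: str = "monopole",
    torso: SurfaceMesh | None = None,
) -> TransferMatrix:
    """Build the electrodes x heart-nodes forward operator.

    ``monopole``: A[i, j] = vertex_area[j] / (4 pi |e_i - x_j|), every column
    then re-referenced to its mean across electrodes (the Wilson-terminal
    analogue, so a common-mode epicardial potential maps to zero).

    ``bem``: homogeneous-torso boundary-element double-layer formulation; the
    potential is solved on the torso surface (requires ``torso``) and
    interpolated at the electrodes.
    """
    if kernel == "monopole":
        d = np.linalg.norm(
            electrodes.positions[:, None, :] - heart.vertices[None, :, :], axis=2
        )
        if d.min() < 1e-9:
            raise InverseSolverError(
                "electrode coincides with a heart node: singular monopole kernel"
            )
        A = heart.vertex_area[None, :] / (4.0 * np.pi * d)
        A = A - A.mean(axis=0, keepdims=True)
    elif kernel == "bem":
        if torso is None:
            raise InverseSolverError("bem kernel requires the torso mesh")
        A = _bem_transfer(heart, torso, electrodes.positions)
    else:
        raise InverseSolverError(f"unknown kernel {kernel!r}")
    s = np.linalg.svd(A, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    return TransferMatrix(
        A=A,
        row_index=np.arange(electrodes.n_electrodes),
        col_index=np.arange(heart.n_vertices),
        kernel_kind=kernel,
        condition_estimate=cond,
    )


# -- boundary element machinery --------------------------------------------


def _solid_angles(obs: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Signed solid angle (sr) of every triangle seen from every observation
    point, van Oosterom & Strackee closed form. Positive when the triangle's
    outward normal faces away from the observer side consistent with the
    right-handed vertex order."""
    v = mesh.vertices
    t = mesh.triangles
    out = np.zeros((len(obs), len(t)))
    # loop observation points in blocks to bound memory
    block = max(1, int(3e6) // max(1, len(t)))
    for s in range(0, len(obs), block):
        o = obs[s : s + block]  # b x 3
        r1 = v[t[:, 0]][None] - o[:, None]  # b x m x 3
        r2 = v[t[:, 1]][None] - o[:, None]
        r3 = v[t[:, 2]][None] - o[:, None]
        n1 = np.linalg.norm(r1, axis=2)
        n2 = np.linalg.norm(r2, axis=2)
        n3 = np.linalg.norm(r3, axis=2)
        num = np.einsum("bmi,bmi->bm", r1, np.cross(r2, r3))
        den = (
            n1 * n2 * n3
            + np.einsum("bmi,bmi->bm", r1, r2) * n3
            + np.einsum("bmi,bmi->bm", r1, r3) * n2
            + np.einsum("bmi,bmi->bm", r2, r3) * n1
        )
        out[s : s + block] = 2.0 * np.arctan2(num, den)
    return out


def _single_layer(obs: np.ndarray, mesh: SurfaceMesh,
                  near_factor: float = 3.0) -> np.ndarray:
    """G[i, j] = (1/4pi) * integral over the surface of 1/r, lumped 1/3 per
    triangle vertex. Far triangles use the centroid rule; near ones are
    subdivided; triangles incident to an observation vertex use polar
    quadrature about the vertex (the 1/r vertex singularity is integrable)."""
    v = mesh.vertices
    t = mesh.triangles
    areas = mesh.triangle_areas
    cent = v[t].mean(axis=1)
    size = np.sqrt(areas)
    G = np.zeros((len(obs), mesh.n_vertices))
    d = np.linalg.norm(obs[:, None, :] - cent[None, :, :], axis=2)
    far = d > near_factor * size[None, :]
    # far-field centroid rule, vectorized
    with np.errstate(divide="ignore"):
        contrib = np.where(far, areas[None, :] / np.maximum(d, 1e-300), 0.0)
    for k in range(3):
        np.add.at(G.T, t[:, k], contrib.T / 3.0)
    # near-field: per (obs, triangle) accurate integral
    near_pairs = np.argwhere(~far)
    for i, j in near_pairs:
        val = _triangle_inv_r_integral(obs[i], v[t[j]])
        for k in range(3):
            G[i, t[j, k]] += val / 3.0
    return G / (4.0 * np.pi)


def _triangle_inv_r_integral(p: np.ndarray, tri: np.ndarray, depth: int = 3) -> float:
    """Integral of 1/|x - p| over a triangle.

    If p coincides with a vertex, integrate exactly in polar coordinates about
    that vertex (Gauss quadrature in angle); otherwise subdivide recursively
    until the centroid rule is accurate."""
    for k in range(3):
        if np.linalg.norm(tri[k] - p) < 1e-9:
            a = tri[(k + 1) % 3] - tri[k]
            b = tri[(k + 2) % 3] - tri[k]
            return _vertex_polar_integral(a, b)
    c = tri.mean(axis=0)
    r = np.linalg.norm(c - p)
    area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    size = np.sqrt(area)
    if depth == 0 or r > 3.0 * size:
        return area / max(r, 1e-300)
    m01 = 0.5 * (tri[0] + tri[1])
    m12 = 0.5 * (tri[1] + tri[2])
    m20 = 0.5 * (tri[2] + tri[0])
    return (
        _triangle_inv_r_integral(p, np.array([tri[0], m01, m20]), depth - 1)
        + _triangle_inv_r_integral(p, np.array([m01, tri[1], m12]), depth - 1)
        + _triangle_inv_r_integral(p, np.array([m20, m12, tri[2]]), depth - 1)
        + _triangle_inv_r_integral(p, np.array([m01, m12, m20]), depth - 1)
    )


_GAUSS_X, _GAUSS_W = np.polynomial.legendre.leggauss(32)


def _vertex_polar_integral(a: np.ndarray, b: np.ndarray) -> float:
    """Integral of 1/r over the triangle (0, a, b) with the observer at 0.

    In polar coordinates about the vertex the integrand cancels the Jacobian:
    the integral is the angular integral of the distance to the opposite edge.
    """
    la, lb = np.linalg.norm(a), np.linalg.norm(b)
    cosg = float(np.clip(a @ b / (la * lb), -1.0, 1.0))
    gamma = float(np.arccos(cosg))
    if gamma < 1e-12:
        return 0.0
    # R(theta): distance from vertex to the edge a->b along direction at angle
    # theta from a (in the triangle plane). Edge param: a + s(b - a).
    th = 0.5 * gamma * (_GAUSS_X + 1.0)
    w = 0.5 * gamma * _GAUSS_W
    # distance from origin to line through a, b along unit direction u(theta):
    # solve a + s(b-a) = R u; use 2-D coordinates in the triangle plane.
    ex = a / la
    ezn = np.cross(a, b)
    ey = np.cross(ezn / np.linalg.norm(ezn), ex)
    ax, ay = la, 0.0
    bx, by = float(b @ ex), float(b @ ey)
    ux, uy = np.cos(th), np.sin(th)
    # line through (ax,ay),(bx,by): n.(x,y)=c with n normal to the edge
    nx, ny = ay - by, bx - ax
    c = nx * ax + ny * ay
    denom = nx * ux + ny * uy
    R = c / denom
    return float(np.sum(w * R))


def _bem_transfer(
    heart: SurfaceMesh, torso: SurfaceMesh, electrode_positions: np.ndarray
) -> np.ndarray:
    """Transfer matrix for the homogeneous volume between epicardium and an
    insulated torso, by vertex collocation.

    With P the double-layer (solid angle, lumped 1/3 per triangle vertex and
    diagonal set by the row-sum identity so a constant potential transfers
    exactly) and G the single layer over the heart, eliminating the unknown
    epicardial normal current gives

        (I - P_BB + G_BH G_HH^{-1} P_HB) phi_B
            = (P_BH + G_BH G_HH^{-1} (I - P_HH)) phi_H.
    """
    nB, nH = torso.n_vertices, heart.n_vertices

    def lumped_P(obs: np.ndarray, src: SurfaceMesh) -> np.ndarray:
        omega = _solid_angles(obs, src) / (4.0 * np.pi)
        P = np.zeros((len(obs), src.n_vertices))
        for k in range(3):
            np.add.at(P.T, src.triangles[:, k], omega.T / 3.0)
        return P

    P_BB = lumped_P(torso.vertices, torso)
    P_BH = lumped_P(torso.vertices, heart)
    P_HB = lumped_P(heart.vertices, torso)
    P_HH = lumped_P(heart.vertices, heart)
    # sign convention: potentials inside the volume are written with the
    # double layer negated relative to outward normals of the enclosing
    # surface; calibrate signs so row sums can be made exactly 1 on the
    # diagonal (heart outward normal points out of the volume's cavity).
    P_BH = -P_BH
    P_HH = -P_HH
    np.fill_diagonal(P_BB, 0.0)
    np.fill_diagonal(P_BB, 1.0 - P_BB.sum(axis=1) - P_BH.sum(axis=1))
    np.fill_diagonal(P_HH, 0.0)
    np.fill_diagonal(P_HH, 1.0 - P_HH.sum(axis=1) - P_HB.sum(axis=1))

    G_BH = _single_layer(torso.vertices, heart)
    G_HH = _single_layer(heart.vertices, heart)
    X = G_BH @ np.linalg.solve(G_HH, np.eye(nH))
    lhs = np.eye(nB) - P_BB + X @ P_HB
    rhs = P_BH + X @ (np.eye(nH) - P_HH)
    Z = np.linalg.solve(lhs, rhs)  # torso vertices x heart vertices

    # interpolate at electrode positions with barycentric weights on the
    # closest torso triangle
    import trimesh

    from .geometry import closest_point_on_mesh

    closest, _, tid = closest_point_on_mesh(electrode_positions, torso)
    tri_pts = torso.vertices[torso.triangles[tid]]
    bary = trimesh.triangles.points_to_barycentric(tri_pts, closest)
    A = np.zeros((len(electrode_positions), nH))
    for e in range(len(electrode_positions)):
        for k in range(3):
            A[e] += bary[e, k] * Z[torso.triangles[tid[e], k]]
    return A


# -- Tikhonov inverse -----------------------------------------------------------


def creso_function(lam: np.ndarray, s: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """CRESO criterion C(lambda) = d/d(lambda^2)[lambda^2 ||x||^2 - ||Ax-b||^2].

    In the SVD basis with singular values s and projections beta = U^T b,
    C = sum beta_i^2 s_i^2 (s_i^2 - 3 lambda^2) / (s_i^2 + lambda^2)^3.
    The selected lambda is the first local maximiser on an ascending grid.
    """
    lam2 = np.asarray(lam)[:, None] ** 2
    s2 = s[None, :] ** 2
    return ((beta[None, :] ** 2) * s2 * (s2 - 3 * lam2) / (s2 + lam2) ** 3).sum(axis=1)


def _first_local_max(x: np.ndarray, y: np.ndarray) -> float | None:
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            return float(x[i])
    return None


def _lcurve_corner(lam: np.ndarray, s: np.ndarray, beta: np.ndarray,
                   b_perp2: float) -> float:
    s2 = s[None, :] ** 2
    lam2 = lam[:, None] ** 2
    eta2 = ((s2 * beta[None, :] ** 2) / (s2 + lam2) ** 2).sum(axis=1)
    rho2 = ((lam2**2 * beta[None, :] ** 2) / (s2 + lam2) ** 2).sum(axis=1) + b_perp2
    x = 0.5 * np.log(np.maximum(rho2, 1e-300))
    y = 0.5 * np.log(np.maximum(eta2, 1e-300))
    t = np.log(lam)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / np.maximum(denom, 1e-300)
    kappa[~np.isfinite(kappa)] = -np.inf
    return float(lam[int(np.argmax(kappa[1:-1])) + 1])


def solve_inverse(
    beat: AveragedBeat,
    A: TransferMatrix,
    lambda_rule: str = "creso",
    lam: float | None = None,
    n_grid: int = 200,
) -> EpicardialSignalSet:
    """Reconstruct epicardial electrograms from an averaged beat.

    Channels excluded by lead QC are dropped (the corresponding rows of A are
    removed, never interpolated). One SVD of A is reused across all time
    samples; lambda is selected once per beat at the time of maximal torso RMS.
    """
    included = beat.included
    if len(included) != A.A.shape[0]:
        raise InverseSolverError(
            f"beat has {len(included)} channels but A has {A.A.shape[0]} rows"
        )
    Ai = A.A[included]
    b = beat.waveforms[included]  # channels x samples

    U, s, Vt = np.linalg.svd(Ai, full_matrices=False)
    if lambda_rule == "fixed" and lam is not None and lam == 0.0:
        if s[-1] <= 1e-12 * s[0]:
            raise InverseSolverError("A is rank deficient and lambda = 0")

    # lambda selection at the sample of maximal torso RMS
    rms = np.sqrt((b**2).mean(axis=0))
    t_star = int(np.argmax(rms))
    beta = U.T @ b[:, t_star]
    b_perp2 = float(b[:, t_star] @ b[:, t_star] - beta @ beta)
    grid = np.logspace(np.log10(s[0]) - 8, np.log10(s[0]) + 1, n_grid)

    if lambda_rule == "fixed":
        if lam is None:
            raise InverseSolverError("lambda_rule='fixed' requires lam")
        lam_used = float(lam)
    elif lambda_rule == "creso":
        c = creso_function(grid, s, beta)
        lam_used = _first_local_max(grid, c)
        if lam_used is None:
            warnings.warn(
                "CRESO has no local maximum on the grid; falling back to L-curve",
                stacklevel=2,
            )
            lam_used = _lcurve_corner(grid, s, beta, b_perp2)
    elif lambda_rule == "lcurve":
        lam_used = _lcurve_corner(grid, s, beta, b_perp2)
    else:
        raise InverseSolverError(f"unknown lambda rule {lambda_rule!r}")

    filt = s / (s**2 + lam_used**2)  # SVD filter factors over sigma
    phi = Vt.T @ (filt[:, None] * (U.T @ b))
    return EpicardialSignalSet(
        ueg=phi,
        fs=beat.fs,
        lambda_used=lam_used,
        provenance={
            "lambda_rule": lambda_rule,
            "kernel_kind": A.kernel_kind,
            "n_channels_used": int(included.sum()),
            "t_star_sample": t_star,
        },
    )


def tikhonov_norms(
    A: np.ndarray, b: np.ndarray, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solution and residual norms over a lambda grid (diagnostic; the solution
    norm is non-increasing and the residual norm non-decreasing in lambda)."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    beta = U.T @ b
    b_perp2 = float(b @ b - beta @ beta)
    sol, res = [], []
    for lam in lambdas:
        f = s / (s**2 + lam**2)
        x = Vt.T @ (f * beta)
        sol.append(np.linalg.norm(x))
        res.append(np.sqrt(np.sum((lam**2 / (s**2 + lam**2) * beta) ** 2) + b_perp2))
    return np.asarray(sol), np.asarray(res)
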