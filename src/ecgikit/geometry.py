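"""Surface meshes, electrode sets, landmark reconstruction and site pairing.

All coordinates are millimetres in a right-handed LPS patient frame and all
vertex indexing is 0-based, including in file exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import trimesh

from .errors import GeometryError, InvalidParameterError

__all__ = [
    "SurfaceMesh",
    "ElectrodeSet",
    "PairedSites",
    "node_neighbours",
    "match_paired_sites",
    "exclude_valve_plane",
    "resample_and_smooth",
    "reconstruct_virtual_vest",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface (heart or torso).

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    triangles : (m, 3) int array of vertex index triples.
    labels : named vertex subsets, e.g. ``{"valve_plane": array of indices}``.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must be an (m, 3) array")
        n = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise GeometryError("triangle indices out of range")
        self.labels = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.labels.items()
        }
        for k, idx in self.labels.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise GeometryError(f"label {k!r} has out-of-range vertex indices")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def vertex_area(self) -> np.ndarray:
        """Per-vertex area weight: one third of each incident triangle, mm^2."""
        areas = self.triangle_areas / 3.0
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.triangles[:, k], areas)
        return va

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals)

    def euler_characteristic(self) -> int:
        n_e = len(self.edge_array())
        return self.n_vertices - n_e + len(self.triangles)

    def edge_array(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.labels.items()},
        )


@dataclass
class ElectrodeSet:
    """Vest electrodes on the torso surface.

    ``grid_id`` rows are (panel, row, col); exactly four electrodes per panel
    carry a corner flag (the panel's grid corners, used as CMR-bright markers).
    """

    positions: np.ndarray  # (n, 3) mm
    grid_id: list[tuple[str, int, int]]
    spacing: float  # mm, centre-to-centre
    corner_flags: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.corner_flags = np.asarray(self.corner_flags, dtype=bool)
        if len(self.grid_id) != len(self.positions):
            raise GeometryError("grid_id length must match positions")
        if len(set(self.grid_id)) != len(self.grid_id):
            raise GeometryError("grid_ids must be unique")
        panels = {p for p, _, _ in self.grid_id}
        for p in panels:
            n_c = sum(
                1
                for (pp, _, _), c in zip(self.grid_id, self.corner_flags)
                if pp == p and c
            )
            if n_c != 4:
                raise GeometryError(f"panel {p!r} must have exactly 4 corner flags")

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    @property
    def panels(self) -> list[str]:
        seen: list[str] = []
        for p, _, _ in self.grid_id:
            if p not in seen:
                seen.append(p)
        return seen

    def corner_positions(self, panel: str) -> np.ndarray:
        """The 4 corner-marker positions of a panel, ordered by (row, col)."""
        idx = [
            i
            for i, ((p, _, _), c) in enumerate(zip(self.grid_id, self.corner_flags))
            if p == panel and c
        ]
        idx.sort(key=lambda i: (self.grid_id[i][1], self.grid_id[i][2]))
        return self.positions[idx]


@dataclass
class PairedSites:
    """Closest-site correspondence between two cardiac meshes."""

    pairs: np.ndarray  # (k, 2) int: index in mesh A, index in mesh B
    pair_distance: np.ndarray  # (k,) mm

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.pair_distance = np.asarray(self.pair_distance, dtype=float)
        if np.any(self.pair_distance < 0):
            raise GeometryError("pair distances must be non-negative")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# -- operations --------------------------------------------------------------


def closest_point_on_mesh(
    points: np.ndarray, mesh: SurfaceMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest point on the triangulated surface for each query point.

    Vectorized point-to-triangle projection (region decomposition over the
    barycentric domain), brute force over triangles in memory-bounded chunks.
    Returns (closest points, distances, triangle ids).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    ab = b - a
    ac = c - a
    n_pts, n_tri = len(points), len(t)
    best_d2 = np.full(n_pts, np.inf)
    best_pt = np.zeros((n_pts, 3))
    best_id = np.zeros(n_pts, dtype=np.int64)
    chunk = max(1, int(4e6) // max(1, n_tri))
    for s in range(0, n_pts, chunk):
        p = points[s : s + chunk][:, None, :]  # q x 1 x 3
        ap = p - a[None]
        d1 = np.einsum("mi,qmi->qm", ab, ap)
        d2_ = np.einsum("mi,qmi->qm", ac, ap)
        bp = p - b[None]
        d3 = np.einsum("mi,qmi->qm", ab, bp)
        d4 = np.einsum("mi,qmi->qm", ac, bp)
        cp = p - c[None]
        d5 = np.einsum("mi,qmi->qm", ab, cp)
        d6 = np.einsum("mi,qmi->qm", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2_ - d1 * d6
        vc = d1 * d4 - d3 * d2_
        denom_ab = d1 - d3
        denom_ac = d2_ - d6
        # default: interior projection p' = a + v*ab + w*ac
        denom = va + vb + vc
        safe = np.where(np.abs(denom) > 1e-300, denom, 1.0)
        vcoef = np.where(np.abs(denom) > 1e-300, vb / safe, 0.0)
        wcoef = np.where(np.abs(denom) > 1e-300, vc / safe, 0.0)
        cand = a[None] + vcoef[..., None] * ab[None] + wcoef[..., None] * ac[None]
        # vertex regions
        reg_a = (d1 <= 0) & (d2_ <= 0)
        reg_b = (d3 >= 0) & (d4 <= d3)
        reg_c = (d6 >= 0) & (d5 <= d6)
        # edge AB region
        tt = np.clip(d1 / np.where(np.abs(denom_ab) > 1e-300, denom_ab, 1.0),
                     0.0, 1.0)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        pt_ab = a[None] + tt[..., None] * ab[None]
        # edge AC region
        ss = np.clip(d2_ / np.where(np.abs(denom_ac) > 1e-300, denom_ac, 1.0),
                     0.0, 1.0)
        on_ac = (vb <= 0) & (d2_ >= 0) & (d6 <= 0)
        pt_ac = a[None] + ss[..., None] * ac[None]
        # edge BC region
        den_bc = (d4 - d3) + (d5 - d6)
        uu = np.clip((d4 - d3) / np.where(np.abs(den_bc) > 1e-300, den_bc, 1.0),
                     0.0, 1.0)
        on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        pt_bc = b[None] + uu[..., None] * (c - b)[None]

        cand = np.where(on_bc[..., None], pt_bc, cand)
        cand = np.where(on_ac[..., None], pt_ac, cand)
        cand = np.where(on_ab[..., None], pt_ab, cand)
        cand = np.where(reg_c[..., None], c[None], cand)
        cand = np.where(reg_b[..., None], b[None], cand)
        cand = np.where(reg_a[..., None], a[None], cand)

        d2full = ((p - cand) ** 2).sum(axis=2)
        j = np.argmin(d2full, axis=1)
        rows = np.arange(len(j))
        best_d2[s : s + chunk] = d2full[rows, j]
        best_pt[s : s + chunk] = cand[rows, j]
        best_id[s : s + chunk] = j
    return best_pt, np.sqrt(best_d2), best_id


def node_neighbours(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Undirected vertex adjacency with edge lengths (mm) from triangle edges.

    Returns a symmetric sparse CSR matrix whose stored entries are Euclidean
    edge lengths. Zero-length edges are stored as tiny positives to keep the
    sparsity pattern explicit.
    """
    e = mesh.edge_array()
    if e.size == 0:
        return sp.csr_matrix((mesh.n_vertices, mesh.n_vertices))
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    d = np.maximum(d, 1e-300)
    n = mesh.n_vertices
    adj = sp.coo_matrix(
        (np.concatenate([d, d]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    return adj.tocsr()


def _non_valve_indices(mesh: SurfaceMesh) -> np.ndarray:
    mask = np.ones(mesh.n_vertices, dtype=bool)
    valve = mesh.labels.get("valve_plane")
    if valve is not None and valve.size:
        mask[valve] = False
    return np.flatnonzero(mask)


def match_paired_sites(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> PairedSites:
    """Nearest-neighbour site pairing from mesh A into mesh B.

    For every non-valve vertex of A the Euclidean-closest non-valve vertex of
    B is selected (ties broken to the lowest B index). Pairing is
    one-directional: the pair count equals the non-valve vertex count of A.
    """
    ia = _non_valve_indices(mesh_a)
    ib = _non_valve_indices(mesh_b)
    if ia.size == 0 or ib.size == 0:
        raise GeometryError("empty non-valve vertex set")
    pa = mesh_a.vertices[ia]
    pb = mesh_b.vertices[ib]
    pairs = np.empty((len(ia), 2), dtype=np.int64)
    dist = np.empty(len(ia))
    # chunked brute force: deterministic lowest-index tie-break via argmin
    chunk = max(1, int(2e7) // max(1, len(ib)))
    for s in range(0, len(ia), chunk):
        block = pa[s : s + chunk]
        d2 = ((block[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        j = np.argmin(d2, axis=1)
        pairs[s : s + chunk, 0] = ia[s : s + chunk]
        pairs[s : s + chunk, 1] = ib[j]
        dist[s : s + chunk] = np.sqrt(d2[np.arange(len(block)), j])
    return PairedSites(pairs=pairs, pair_distance=dist)


def exclude_valve_plane(markers, mesh: SurfaceMesh):
    """Flag marker entries at valve-plane vertices as excluded.

    The basal valve plane shows anomalous electrogram behaviour and is removed
    from every downstream mean, gradient, dispersion and reliability
    computation. Marker values at retained nodes are untouched.
    """
    if "valve_plane" not in mesh.labels:
        raise GeometryError("mesh has no 'valve_plane' label")
    out = markers.copy()
    valve = mesh.labels["valve_plane"]
    if valve.size == 0:
        return out
    if valve.max() >= len(out.excluded):
        raise GeometryError("valve label indices exceed marker length")
    newly = valve[~out.excluded[valve]]
    out.excluded[newly] = True
    for i in newly:
        out.reason[i] = "valve_plane"
    return out


def _fit_sphere_rms(vertices: np.ndarray) -> float:
    c = vertices.mean(axis=0)
    r = np.linalg.norm(vertices - c, axis=1)
    return float(np.std(r))


def _taubin_smooth(mesh: SurfaceMesh, iterations: int,
                   lamb: float = 0.5, nu: float = -0.53) -> SurfaceMesh:
    if iterations <= 0:
        return mesh.copy()
    tm = mesh.to_trimesh()
    trimesh.smoothing.filter_taubin(tm, lamb=lamb, nu=nu, iterations=iterations)
    return SurfaceMesh(np.asarray(tm.vertices), mesh.triangles.copy(),
                       {k: v.copy() for k, v in mesh.labels.items()})


def _star_triangulate(points: np.ndarray) -> np.ndarray:
    """Triangulate points of a star-shaped surface via the unit-direction hull.

    Valid when every ray from the centroid crosses the surface once (true for
    the ellipsoidal epicardial shells this package works with). Triangles are
    oriented with outward normals.
    """
    from scipy.spatial import ConvexHull

    c = points.mean(axis=0)
    d = points - c
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    hull = ConvexHull(u)
    tri = hull.simplices.copy()
    # orient outward: normal . (centroid->face centroid) > 0
    v = points
    fc = v[tri].mean(axis=1)
    nrm = np.cross(v[tri[:, 1]] - v[tri[:, 0]], v[tri[:, 2]] - v[tri[:, 0]])
    flip = (nrm * (fc - c)).sum(axis=1) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def _farthest_point_subset(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point subsample: k indices with even coverage."""
    n = len(points)
    sel = np.empty(k, dtype=np.int64)
    sel[0] = start
    d = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, k):
        j = int(np.argmax(d))
        sel[i] = j
        d = np.minimum(d, np.linalg.norm(points - points[j], axis=1))
    return sel


def resample_and_smooth(
    mesh: SurfaceMesh, target_nodes: int, smoothing_iters: int = 10
) -> SurfaceMesh:
    """Resample a watertight surface to ~target_nodes vertices and smooth.

    Vertex count lands within +-1% of the target. Smoothing is Taubin
    (volume-preserving: enclosed volume drifts < 2%). Re-triangulation assumes
    a star-shaped surface about the centroid.
    """
    if target_nodes < 50:
        raise InvalidParameterError("target_nodes must be >= 50")
    if not mesh.is_watertight():
        raise GeometryError("input mesh is not watertight")
    if target_nodes == mesh.n_vertices and smoothing_iters == 0:
        return mesh.copy()
    if target_nodes == mesh.n_vertices:
        out = mesh.copy()
    else:
        pts = mesh.vertices
        if target_nodes < mesh.n_vertices:
            sel = _farthest_point_subset(pts, target_nodes)
            new_pts = pts[sel]
        else:
            # upsample: add midpoints of the longest edges (deterministic)
            e = mesh.edge_array()
            lengths = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1)
            order = np.argsort(-lengths)
            extra = target_nodes - mesh.n_vertices
            if extra > len(e):
                raise InvalidParameterError(
                    "target exceeds vertex+edge count; refine input first"
                )
            mids = 0.5 * (pts[e[order[:extra], 0]] + pts[e[order[:extra], 1]])
            new_pts = np.vstack([pts, mids])
        tri = _star_triangulate(new_pts)
        out = SurfaceMesh(new_pts, tri)
    out = _taubin_smooth(out, smoothing_iters)
    if not out.is_watertight():
        raise GeometryError("resampled mesh failed watertightness")
    return out


def _project_to_surface(points: np.ndarray, torso: SurfaceMesh) -> np.ndarray:
    closest, _, _ = closest_point_on_mesh(points, torso)
    return closest


def reconstruct_virtual_vest(
    corner_markers: dict[str, np.ndarray],
    torso: SurfaceMesh,
    grid_shape: tuple[int, int],
    spacing: float,
    max_corner_distance: float = 20.0,
) -> ElectrodeSet:
    """Rebuild the full electrode grid from 4 corner markers per panel.

    The grid is bilinearly interpolated in the patch spanned by the corners
    (ordered row-major: (r0,c0), (r0,cN), (rN,c0), (rN,cN)) and every
    interpolated point is projected to the nearest point on the torso surface.
    Exact on planar panels.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise InvalidParameterError("grid must be at least 2x2")
    positions = []
    grid_id: list[tuple[str, int, int]] = []
    corner_flags = []
    for panel, corners in corner_markers.items():
        corners = np.asarray(corners, dtype=float)
        if corners.shape != (4, 3):
            raise GeometryError(f"panel {panel!r}: need 4 corner positions")
        # degenerate checks: duplicates / collinearity
        d2 = ((corners[:, None] - corners[None]) ** 2).sum(axis=2)
        if np.any(d2[np.triu_indices(4, 1)] < 1e-12):
            raise GeometryError(f"panel {panel!r}: duplicated corner marker")
        e1 = corners[1] - corners[0]
        e2 = corners[2] - corners[0]
        if np.linalg.norm(np.cross(e1, e2)) < 1e-9 * max(
            np.linalg.norm(e1), np.linalg.norm(e2)
        ) ** 2:
            raise GeometryError(f"panel {panel!r}: collinear corner markers")
        _, cd, _ = closest_point_on_mesh(corners, torso)
        if np.any(cd > max_corner_distance):
            raise GeometryError(
                f"panel {panel!r}: corner marker farther than "
                f"{max_corner_distance} mm from the torso surface"
            )
        u = np.linspace(0.0, 1.0, rows)[:, None, None]
        v = np.linspace(0.0, 1.0, cols)[None, :, None]
        patch = (
            (1 - u) * (1 - v) * corners[0]
            + (1 - u) * v * corners[1]
            + u * (1 - v) * corners[2]
            + u * v * corners[3]
        )  # rows x cols x 3
        pts = patch.reshape(-1, 3)
        proj = _project_to_surface(pts, torso)
        for k, p in enumerate(proj):
            r, c = divmod(k, cols)
            positions.append(p)
            grid_id.append((panel, r, c))
            corner_flags.append(r in (0, rows - 1) and c in (0, cols - 1))
    return ElectrodeSet(
        positions=np.asarray(positions),
        grid_id=grid_id,
        spacing=spacing,
        corner_flags=np.asarray(corner_flags, dtype=bool),
    )


def rigid_icp_align(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh,
                    iterations: int = 20) -> SurfaceMesh:
    """Optional rigid ICP pre-alignment of mesh A onto mesh B (off by default
    in pairing; scan-to-scan meshes are otherwise kept in their own scanner
    coordinates)."""
    src = mesh_a.vertices.copy()
    for _ in range(iterations):
        closest, _, _ = closest_point_on_mesh(src, mesh_b)
        mu_s, mu_t = src.mean(axis=0), closest.mean(axis=0)
        h = (src - mu_s).T @ (closest - mu_t)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        src = (src - mu_s) @ rot.T + mu_t
    return SurfaceMesh(src, mesh_a.triangles.copy(),
                       {k: w.copy() for k, w in mesh_a.labels.items()})
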