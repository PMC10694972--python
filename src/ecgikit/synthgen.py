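"""Synthetic vest-study generator: geometry, ground-truth sources, recordings.

Everything the pipeline consumes can be generated here with known ground
truth: a closed ellipsoidal epicardial shell (~2000 nodes), an elliptic-
cylinder torso carrying a 256-electrode two-panel vest, a propagating
activation sequence with per-node activation/repolarization times, unipolar
electrogram templates, and multi-beat noisy 2400 Hz torso recordings obtained
by forward projection. Every generator is a pure function of its seed and
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
from scipy.special import expit

from .errors import GeometryError, InvalidParameterError, SignalError
from .geometry import (
    ElectrodeSet,
    SurfaceMesh,
    _star_triangulate,
    closest_point_on_mesh,
    node_neighbours,
)
from .inverse import EpicardialSignalSet, TransferMatrix
from .sigproc import CLIP_MV, BeatRecording

__all__ = [
    "GroundTruthSource",
    "NoiseModel",
    "generate_heart_mesh",
    "generate_torso_and_vest",
    "simulate_activation",
    "synthesize_epicardial_potentials",
    "forward_project_beats",
    "synthetic_participant",
]


@dataclass
class GroundTruthSource:
    """True per-node activation/repolarization times driving the generator."""

    node_at: np.ndarray  # ms
    node_rt: np.ndarray  # ms
    breakthrough_node: int
    conduction_velocity: float  # mm/ms
    apd_base: float  # ms
    rng_seed: int

    def __post_init__(self) -> None:
        self.node_at = np.asarray(self.node_at, dtype=float)
        self.node_rt = np.asarray(self.node_rt, dtype=float)
        if not np.all(np.isfinite(self.node_at)) or not np.all(
            np.isfinite(self.node_rt)
        ):
            raise InvalidParameterError("AT/RT must be finite")
        if np.any(self.node_at < 0):
            raise InvalidParameterError("AT must be non-negative")
        if not np.all(self.node_rt > self.node_at):
            raise InvalidParameterError("RT must exceed AT at every node")
        if self.node_at[self.breakthrough_node] > self.node_at.min() + 1e-12:
            raise InvalidParameterError("breakthrough node must carry minimal AT")

    @property
    def n_nodes(self) -> int:
        return len(self.node_at)


@dataclass
class NoiseModel:
    """Additive recording artefacts: broadband, baseline wander, powerline."""

    broadband_sd: float = 0.03  # mV
    baseline_wander_amp: float = 0.10  # mV
    baseline_wander_freq: float = 0.3  # Hz
    powerline_amp: float = 0.01  # mV
    powerline_freq: float = 50.0  # Hz

    def __post_init__(self) -> None:
        for name in ("broadband_sd", "baseline_wander_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.3, 0.0, 50.0)

    @classmethod
    def broadband_for_snr(cls, beat_signals: np.ndarray, snr_db: float) -> "NoiseModel":
        """Broadband-only noise whose SD realises the requested SNR relative to
        the RMS of the projected beat waveforms."""
        rms = float(np.sqrt(np.mean(beat_signals**2)))
        sd = rms / 10 ** (snr_db / 20.0)
        return cls(sd, 0.0, 0.3, 0.0, 50.0)


# -- geometry -------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.c_[r * np.cos(theta), r * np.sin(theta), z]


DEFAULT_HEART_SHAPE = {
    "semi_axes": (35.0, 35.0, 50.0),  # mm; apex at -z, base at +z
    "bump_amp": 0.02,  # relative smooth radial perturbation
    "n_bumps": 6,
    "bump_width": 25.0,  # mm
    "valve_radius": 15.0,  # mm geodesic radius of the basal valve-plane label
    "center": (0.0, 0.0, 0.0),
}


def generate_heart_mesh(
    n_nodes: int, shape_params: dict | None = None, seed: int = 0
) -> SurfaceMesh:
    """Closed, watertight ellipsoid-like epicardial shell with ``n_nodes``
    vertices, outward normals and a labelled basal "valve_plane" subset."""
    if n_nodes < 50:
        raise InvalidParameterError("n_nodes must be >= 50")
    params = {**DEFAULT_HEART_SHAPE, **(shape_params or {})}
    rng = np.random.default_rng(seed)
    u = _fibonacci_directions(n_nodes)
    a, b, c = params["semi_axes"]
    pts = u * np.array([a, b, c])
    if params["bump_amp"] > 0 and params["n_bumps"] > 0:
        centres = _fibonacci_directions(max(4, int(params["n_bumps"]))) * np.array(
            [a, b, c]
        )
        coef = rng.normal(size=len(centres))
        w = np.zeros(n_nodes)
        for ck, cc in zip(coef, centres):
            d2 = ((pts - cc) ** 2).sum(axis=1)
            w += ck * np.exp(-d2 / (2.0 * params["bump_width"] ** 2))
        wmax = np.abs(w).max()
        if wmax > 0:
            pts = pts * (1.0 + params["bump_amp"] * (w / wmax))[:, None]
    pts = pts + np.asarray(params["center"], dtype=float)
    tri = _star_triangulate(pts)
    mesh = SurfaceMesh(pts, tri)
    # label the valve plane: geodesic disc about the basal pole
    basal = int(np.argmax(mesh.vertices[:, 2]))
    adj = node_neighbours(mesh)
    dist = csgraph.dijkstra(adj, indices=basal)
    mesh.labels["valve_plane"] = np.flatnonzero(dist <= params["valve_radius"])
    return mesh


DEFAULT_TORSO = {
    "semi_axis_x": 160.0,  # mm, lateral
    "semi_axis_y": 110.0,  # mm, antero-posterior
    "height": 520.0,  # mm
    "n_theta": 256,
    "n_z": 48,
    "panel_z_center": 0.0,
}


def _ellipse_point(theta: np.ndarray, ax: float, ay: float) -> np.ndarray:
    """Point on the torso ellipse; theta measured from the anterior (+y) axis."""
    return np.c_[ax * np.sin(theta), ay * np.cos(theta)]


def _ellipse_arclength_lookup(ax: float, ay: float, n: int = 20000):
    th = np.linspace(-np.pi, np.pi, n)
    p = _ellipse_point(th, ax, ay)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return th, s


def _elliptic_cylinder_mesh(params: dict) -> SurfaceMesh:
    ax, ay = params["semi_axis_x"], params["semi_axis_y"]
    h = params["height"]
    nt, nz = params["n_theta"], params["n_z"]
    theta = np.linspace(-np.pi, np.pi, nt, endpoint=False)
    z = np.linspace(-h / 2, h / 2, nz)
    ring = _ellipse_point(theta, ax, ay)
    verts = np.concatenate(
        [np.c_[np.tile(ring, (nz, 1)), np.repeat(z, nt)]]
    )
    tris = []
    for k in range(nz - 1):
        for i in range(nt):
            a0 = k * nt + i
            a1 = k * nt + (i + 1) % nt
            b0 = (k + 1) * nt + i
            b1 = (k + 1) * nt + (i + 1) % nt
            tris.append([a0, a1, b1])
            tris.append([a0, b1, b0])
    # cap the ends with pole fans so the surface is closed
    bottom = len(verts)
    verts = np.vstack([verts, [0.0, 0.0, -h / 2], [0.0, 0.0, h / 2]])
    top = bottom + 1
    for i in range(nt):
        j = (i + 1) % nt
        tris.append([bottom, j, i])
        tris.append([top, (nz - 1) * nt + i, (nz - 1) * nt + j])
    return SurfaceMesh(verts, np.asarray(tris))


def generate_torso_and_vest(
    torso_params: dict | None = None,
    n_electrodes: int = 256,
    grid_shape: tuple[int, int] = (8, 16),
    spacing: float = 25.0,
    heart: SurfaceMesh | None = None,
    anterior_drop: tuple[tuple[int, int], ...] = ((3, 7),),
    posterior_extra: int = 1,
) -> tuple[SurfaceMesh, ElectrodeSet]:
    """Elliptic-cylinder torso enclosing the heart, with a two-panel vest grid.

    Rows run along the circumference with arc-length ``spacing``; columns run
    vertically. The anterior panel drops the ``anterior_drop`` interior cells
    and the posterior panel appends ``posterior_extra`` electrodes below its
    grid, realising the study's 127 anterior / 129 posterior split while the
    total stays rows*cols*2. The 4 grid corners per panel are corner-marker
    flagged.
    """
    params = {**DEFAULT_TORSO, **(torso_params or {})}
    rows, cols = grid_shape
    if n_electrodes != 2 * rows * cols:
        raise InvalidParameterError(
            f"n_electrodes ({n_electrodes}) must equal rows*cols per panel "
            f"summed over two panels ({2 * rows * cols})"
        )
    if len(anterior_drop) != posterior_extra:
        raise InvalidParameterError(
            "anterior_drop count must equal posterior_extra to conserve the total"
        )
    torso = _elliptic_cylinder_mesh(params)
    if heart is not None:
        ax, ay, h = params["semi_axis_x"], params["semi_axis_y"], params["height"]
        v = heart.vertices
        inside = ((v[:, 0] / ax) ** 2 + (v[:, 1] / ay) ** 2 < 1.0) & (
            np.abs(v[:, 2]) < h / 2
        )
        if not inside.all():
            raise GeometryError("heart mesh is not strictly inside the torso")

    ax, ay = params["semi_axis_x"], params["semi_axis_y"]
    th_grid, s_grid = _ellipse_arclength_lookup(ax, ay)
    perimeter = s_grid[-1]

    def theta_at_arc(s: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(s, perimeter), s_grid, th_grid)

    z0 = params["panel_z_center"]
    panel_centre_arc = {
        "anterior": float(np.interp(0.0, th_grid, s_grid)),
        "posterior": float(np.interp(np.pi - 1e-9, th_grid, s_grid)),
    }

    positions: list[np.ndarray] = []
    grid_id: list[tuple[str, int, int]] = []
    corner_flags: list[bool] = []
    drops = {"anterior": set(anterior_drop), "posterior": set()}

    def add_point(panel: str, r: int, c: int) -> None:
        s = panel_centre_arc[panel] + (r - (rows - 1) / 2.0) * spacing
        th = theta_at_arc(np.array([s]))[0]
        xy = _ellipse_point(np.array([th]), ax, ay)[0]
        z = z0 + (c - (cols - 1) / 2.0) * spacing
        p = np.array([xy[0], xy[1], z])
        positions.append(p)
        grid_id.append((panel, r, c))
        corner_flags.append(
            r in (0, rows - 1) and c in (0, cols - 1) and r < rows
        )

    for panel in ("anterior", "posterior"):
        for r in range(rows):
            for c in range(cols):
                if (r, c) in drops[panel]:
                    continue
                add_point(panel, r, c)
        if panel == "posterior":
            for k in range(posterior_extra):
                add_point(panel, rows + k, cols // 2)

    pts = np.asarray(positions)
    closest, _, _ = closest_point_on_mesh(pts, torso)
    electrodes = ElectrodeSet(
        positions=closest,
        grid_id=grid_id,
        spacing=spacing,
        corner_flags=np.asarray(corner_flags, dtype=bool),
    )
    return torso, electrodes


# -- activation / repolarization ground truth ----------------------------------


def simulate_activation(
    heart: SurfaceMesh,
    breakthrough_node: int,
    conduction_velocity: float = 1.5,
    apd_base: float = 235.0,
    apd_gradient: float = 0.25,
    apd_noise_sd: float = 0.0,
    seed: int = 0,
) -> GroundTruthSource:
    """Geodesic wavefront spread from the breakthrough node.

    AT = geodesic edge-graph distance / conduction velocity; RT = AT + APD
    where APD varies linearly along the apex-base (z) axis at
    ``apd_gradient`` ms/mm (plus optional smooth seeded noise).
    """
    if conduction_velocity <= 0:
        raise InvalidParameterError("conduction_velocity must be > 0")
    if apd_base <= 0:
        raise InvalidParameterError("apd_base must be > 0")
    adj = node_neighbours(heart)
    dist = csgraph.dijkstra(adj, indices=breakthrough_node)
    if np.any(~np.isfinite(dist)):
        bad = np.flatnonzero(~np.isfinite(dist))
        raise GeometryError(
            f"mesh is disconnected: nodes unreachable from breakthrough: "
            f"{bad[:10].tolist()}{'...' if len(bad) > 10 else ''}"
        )
    node_at = dist / conduction_velocity
    z = heart.vertices[:, 2]
    s_axial = z - z.min()  # mm from the apex along the apex-base axis
    apd = apd_base + apd_gradient * s_axial
    if apd_noise_sd > 0:
        rng = np.random.default_rng(seed)
        centres = heart.vertices[
            rng.choice(heart.n_vertices, size=8, replace=False)
        ]
        coef = rng.normal(size=len(centres))
        w = np.zeros(heart.n_vertices)
        for ck, cc in zip(coef, centres):
            d2 = ((heart.vertices - cc) ** 2).sum(axis=1)
            w += ck * np.exp(-d2 / (2.0 * 20.0**2))
        sdw = w.std()
        if sdw > 0:
            apd = apd + apd_noise_sd * (w - w.mean()) / sdw
    apd = np.maximum(apd, 1.0)
    return GroundTruthSource(
        node_at=node_at,
        node_rt=node_at + apd,
        breakthrough_node=breakthrough_node,
        conduction_velocity=conduction_velocity,
        apd_base=apd_base,
        rng_seed=seed,
    )


# -- electrogram synthesis ------------------------------------------------------

TAU_UP_MS = 2.0  # logistic upstroke time constant
TAU_REP_MS = 15.0  # logistic repolarization time constant


def action_potential_template(
    t_ms: np.ndarray,
    at: float,
    rt: float,
    amplitude: float = 1.0,
    tau_up: float = TAU_UP_MS,
    tau_rep: float = TAU_REP_MS,
) -> np.ndarray:
    """Smooth action-potential surrogate: logistic upstroke times logistic
    repolarization, with derivative extrema at the assigned AT and RT."""
    return amplitude * expit((t_ms - at) / tau_up) * expit((rt - t_ms) / tau_rep)


def synthesize_epicardial_potentials(
    truth: GroundTruthSource,
    fs: float,
    duration_ms: float,
    vertex_area: np.ndarray | None = None,
    amplitude: float = 1.0,
    farfield: bool = True,
    farfield_weight: float = 0.4,
    margin_ms: float = 60.0,
) -> EpicardialSignalSet:
    """Per-node unipolar electrograms UEG = farfield_weight * farfield - local.

    ``local`` is the action-potential template of the node (upstroke midpoint
    exactly at node_at, repolarization midpoint exactly at node_rt) and
    ``farfield`` the area-weighted mean of all local templates, so the QRS of
    the UEG is a negative deflection whose steepest downslope marks AT and the
    T wave's steepest upslope marks RT. The remote contribution is weighted
    below the local one (a unipolar contact electrode sees the local solid
    angle dominate); an equal-weight farfield biases the T-wave upslope time
    away from the mean repolarization time and distorts the RT map scale.
    """
    if not 0.0 <= farfield_weight <= 1.0:
        raise InvalidParameterError("farfield_weight must be in [0, 1]")
    if fs < 500:
        raise InvalidParameterError("fs must be >= 500 Hz")
    if duration_ms < truth.node_rt.max() + margin_ms:
        raise SignalError(
            f"duration {duration_ms} ms too short: need >= "
            f"{truth.node_rt.max() + margin_ms:.0f} ms"
        )
    n = truth.n_nodes
    t = np.arange(int(round(duration_ms * fs / 1000.0))) * 1000.0 / fs
    local = amplitude * expit(
        (t[None, :] - truth.node_at[:, None]) / TAU_UP_MS
    ) * expit((truth.node_rt[:, None] - t[None, :]) / TAU_REP_MS)
    if farfield:
        w = np.ones(n) if vertex_area is None else np.asarray(vertex_area, float)
        far = (w[:, None] * local).sum(axis=0) / w.sum()
        ueg = farfield_weight * far[None, :] - local
    else:
        ueg = -local
    return EpicardialSignalSet(
        ueg=ueg,
        fs=fs,
        provenance={"farfield": farfield, "amplitude": amplitude,
                    "farfield_weight": farfield_weight, "seed": truth.rng_seed},
    )


# -- beat-train forward projection ----------------------------------------------


def forward_project_beats(
    phi_e: EpicardialSignalSet,
    A: TransferMatrix,
    n_beats: int,
    rr_mean: float = 950.0,
    rr_sd: float = 30.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    channel_table: pd.DataFrame | None = None,
    fs_out: float = 2400.0,
    start_ms: float = 500.0,
    pad_ms: float = 500.0,
    rr_floor: float = 400.0,
) -> BeatRecording:
    """Assemble a multi-beat noisy vest recording phi_T = A phi_E.

    Beats are placed at successive onsets drawn from a truncated normal RR
    distribution (floor 400 ms); NoiseModel terms are added per channel and
    the result is clipped to the amplifier's +-10 mV range. The true onsets
    are kept in ``meta['true_onsets_ms']``.
    """
    if n_beats < 1:
        raise InvalidParameterError("n_beats must be >= 1")
    if A.A.shape[1] != phi_e.n_nodes:
        raise InverseDimError(A.A.shape, phi_e.n_nodes)
    if abs(phi_e.fs - fs_out) > 1e-9:
        raise SignalError(
            f"epicardial set sampled at {phi_e.fs} Hz; resample to {fs_out} Hz first"
        )
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    beat = A.A @ phi_e.ueg  # channels x beat samples
    n_ch, beat_len = beat.shape

    rr = rng.normal(rr_mean, rr_sd, size=max(0, n_beats - 1))
    while np.any(rr < rr_floor):  # truncated normal: redraw below the floor
        bad = rr < rr_floor
        rr[bad] = rng.normal(rr_mean, rr_sd, size=bad.sum())
    onsets_ms = start_ms + np.concatenate([[0.0], np.cumsum(rr)])
    total_ms = onsets_ms[-1] + beat_len * 1000.0 / fs_out + pad_ms
    n_samples = int(round(total_ms * fs_out / 1000.0))

    signals = np.zeros((n_ch, n_samples))
    onset_samples = np.round(onsets_ms * fs_out / 1000.0).astype(int)
    for s0 in onset_samples:
        signals[:, s0 : s0 + beat_len] += beat

    t_s = np.arange(n_samples) / fs_out
    if noise.broadband_sd > 0:
        for ch in range(n_ch):  # per-channel to bound peak memory
            signals[ch] += rng.normal(0.0, noise.broadband_sd, size=n_samples)
    if noise.baseline_wander_amp > 0:
        for ch in range(n_ch):
            phase = rng.uniform(0, 2 * np.pi)
            signals[ch] += noise.baseline_wander_amp * np.sin(
                2 * np.pi * noise.baseline_wander_freq * t_s + phase
            )
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        pl = noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t_s + phase)
        signals += pl[None, :]
    np.clip(signals, -CLIP_MV, CLIP_MV, out=signals)

    if channel_table is None:
        channel_table = pd.DataFrame(
            {"panel": ["?"] * n_ch, "row": np.zeros(n_ch, int),
             "col": np.arange(n_ch)}
        )
    return BeatRecording(
        signals=signals,
        fs=fs_out,
        channel_table=channel_table,
        meta={
            "true_onsets_ms": onsets_ms,
            "seed": seed,
            "noise": noise,
            "beat_len_samples": beat_len,
        },
    )


class InverseDimError(SignalError):
    def __init__(self, shape, n_nodes):
        super().__init__(
            f"transfer matrix has {shape[1]} columns but the epicardial set "
            f"has {n_nodes} nodes"
        )


# -- one-call synthetic participant ---------------------------------------------


def synthetic_participant(
    seed: int = 0,
    n_heart_nodes: int = 2000,
    n_beats: int = 300,
    fs: float = 2400.0,
    snr_db: float | None = 20.0,
    kernel: str = "monopole",
    conduction_velocity: float = 1.5,
    apd_base: float = 235.0,
    apd_gradient: float = 0.25,
    rr_mean: float = 950.0,
    rr_sd: float = 30.0,
    beat_duration_ms: float | None = None,
    grid_shape: tuple[int, int] = (8, 16),
    spacing: float = 25.0,
) -> dict:
    """Generate one complete synthetic study participant.

    Returns a dict with the heart and torso meshes, electrode set, ground
    truth, epicardial signal set, transfer matrix and the noisy multi-beat
    recording. ``snr_db=None`` uses the default NoiseModel; otherwise the
    noise is broadband-only at the stated SNR.
    """
    from .inverse import build_transfer_matrix

    rng = np.random.default_rng(seed)
    heart = generate_heart_mesh(n_heart_nodes, seed=seed)
    torso, electrodes = generate_torso_and_vest(
        n_electrodes=2 * grid_shape[0] * grid_shape[1],
        grid_shape=grid_shape,
        spacing=spacing,
        heart=heart,
    )
    # breakthrough in the basal right-ventricular free wall: a high-z,
    # lateral node outside the valve plane
    v = heart.vertices
    candidates = np.setdiff1d(
        np.arange(heart.n_vertices), heart.labels["valve_plane"]
    )
    score = v[candidates, 2] + v[candidates, 0]
    breakthrough = int(candidates[np.argmax(score)])
    truth = simulate_activation(
        heart,
        breakthrough,
        conduction_velocity=conduction_velocity,
        apd_base=apd_base,
        apd_gradient=apd_gradient,
        seed=seed,
    )
    if beat_duration_ms is None:
        beat_duration_ms = float(truth.node_rt.max() + 120.0)
    phi_e = synthesize_epicardial_potentials(
        truth, fs=fs, duration_ms=beat_duration_ms, vertex_area=heart.vertex_area
    )
    A = build_transfer_matrix(heart, electrodes, kernel=kernel, torso=torso)
    beat = A.A @ phi_e.ueg
    if snr_db is None:
        noise = NoiseModel()
    else:
        noise = NoiseModel.broadband_for_snr(beat, snr_db)
    channel_table = pd.DataFrame(
        [(p, r, c) for p, r, c in electrodes.grid_id],
        columns=["panel", "row", "col"],
    )
    rec = forward_project_beats(
        phi_e,
        A,
        n_beats=n_beats,
        rr_mean=rr_mean,
        rr_sd=rr_sd,
        noise=noise,
        seed=int(rng.integers(2**31 - 1)),
        channel_table=channel_table,
        fs_out=fs,
    )
    return {
        "heart": heart,
        "torso": torso,
        "electrodes": electrodes,
        "truth": truth,
        "phi_e": phi_e,
        "transfer": A,
        "recording": rec,
    }
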