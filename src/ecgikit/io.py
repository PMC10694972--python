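"""Readers and writers: VTK (legacy ASCII) / PLY meshes, HDF5 signal stores,
CSV tables, JSON reports, YAML configs.

Round-trip contract: write(read(x)) preserves integers and strings exactly and
reals to 1e-12. All distances are mm, potentials mV, times ms.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import EcgiKitError
from .geometry import ElectrodeSet, PairedSites, SurfaceMesh
from .inverse import EpicardialSignalSet, TransferMatrix
from .markers import NodeMarkers
from .sigproc import AveragedBeat, BeatRecording, FiducialWindows
from .synthgen import GroundTruthSource

__all__ = [
    "write_vtk", "read_vtk", "write_ply", "read_ply",
    "write_electrodes_csv", "read_electrodes_csv",
    "write_recording_h5", "read_recording_h5",
    "write_averaged_beat_h5", "read_averaged_beat_h5",
    "write_transfer_h5", "read_transfer_h5",
    "write_ueg_h5", "read_ueg_h5",
    "write_markers_csv", "read_markers_csv",
    "write_ground_truth_csv", "read_ground_truth_csv",
    "write_pairs_csv", "read_pairs_csv",
    "write_json", "read_json", "read_yaml",
]


class ParseError(EcgiKitError):
    """Malformed input file; message names the offending location."""


# -- VTK legacy ASCII polydata ---------------------------------------------------


def write_vtk(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("ecgikit surface mesh (mm, LPS)\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        m = len(mesh.triangles)
        f.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if mesh.labels:
            f.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, idx in mesh.labels.items():
                flag = np.zeros(mesh.n_vertices, dtype=int)
                flag[idx] = 1
                f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(str(x) for x in flag) + "\n")


def read_vtk(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    i = 0

    def fail(msg: str) -> ParseError:
        return ParseError(f"{path}:{i + 1}: {msg}")

    try:
        if not lines[0].startswith("# vtk DataFile"):
            raise fail("missing VTK header")
        while i < len(lines) and not lines[i].startswith("POINTS"):
            i += 1
        if i == len(lines):
            raise fail("no POINTS section")
        n = int(lines[i].split()[1])
        vals: list[float] = []
        i += 1
        while len(vals) < 3 * n:
            vals.extend(float(x) for x in lines[i].split())
            i += 1
        vertices = np.array(vals).reshape(n, 3)
        while i < len(lines) and not lines[i].startswith("POLYGONS"):
            i += 1
        if i == len(lines):
            raise fail("no POLYGONS section")
        m = int(lines[i].split()[1])
        tris = np.empty((m, 3), dtype=np.int64)
        for k in range(m):
            i += 1
            parts = lines[i].split()
            if parts[0] != "3":
                raise fail("only triangles are supported")
            tris[k] = [int(parts[1]), int(parts[2]), int(parts[3])]
        labels: dict[str, np.ndarray] = {}
        while i < len(lines):
            if lines[i].startswith("SCALARS"):
                name = lines[i].split()[1]
                i += 2  # skip LOOKUP_TABLE line
                flags: list[int] = []
                while len(flags) < n:
                    flags.extend(int(x) for x in lines[i].split())
                    i += 1
                labels[name] = np.flatnonzero(np.array(flags))
                continue
            i += 1
        return SurfaceMesh(vertices, tris, labels)
    except (IndexError, ValueError) as e:
        raise ParseError(f"{path}:{i + 1}: malformed VTK ({e})") from e


# -- PLY (via trimesh; vertex labels are not stored in PLY) ----------------------


def write_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    data = mesh.to_trimesh().export(file_type="ply", encoding="ascii")
    Path(path).write_bytes(data if isinstance(data, bytes) else data.encode())


def read_ply(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="ply", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# -- electrodes -------------------------------------------------------------------


def write_electrodes_csv(es: ElectrodeSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "panel": [p for p, _, _ in es.grid_id],
            "row": [r for _, r, _ in es.grid_id],
            "col": [c for _, _, c in es.grid_id],
            "x": es.positions[:, 0],
            "y": es.positions[:, 1],
            "z": es.positions[:, 2],
            "corner": es.corner_flags.astype(int),
            "spacing": es.spacing,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_electrodes_csv(path: str | Path) -> ElectrodeSet:
    df = _read_csv(path)
    return ElectrodeSet(
        positions=df[["x", "y", "z"]].to_numpy(float),
        grid_id=[(str(p), int(r), int(c))
                 for p, r, c in zip(df.panel, df.row, df.col)],
        spacing=float(df.spacing.iloc[0]),
        corner_flags=df.corner.to_numpy(bool),
    )


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e


# -- HDF5 signal stores -----------------------------------------------------------


def write_recording_h5(rec: BeatRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals)
        f.create_dataset("fs", data=rec.fs)
        g = f.create_group("channel_table")
        g.create_dataset(
            "panel",
            data=np.array(rec.channel_table["panel"], dtype="S"),
        )
        g.create_dataset("row", data=rec.channel_table["row"].to_numpy(int))
        g.create_dataset("col", data=rec.channel_table["col"].to_numpy(int))
        if "true_onsets_ms" in rec.meta:
            f.create_dataset("true_onsets_ms", data=rec.meta["true_onsets_ms"])


def read_recording_h5(path: str | Path) -> BeatRecording:
    with h5py.File(path, "r") as f:
        signals = f["signals"][:]
        fs = float(f["fs"][()])
        ct = pd.DataFrame(
            {
                "panel": [s.decode() for s in f["channel_table/panel"][:]],
                "row": f["channel_table/row"][:],
                "col": f["channel_table/col"][:],
            }
        )
        meta = {}
        if "true_onsets_ms" in f:
            meta["true_onsets_ms"] = f["true_onsets_ms"][:]
    return BeatRecording(signals=signals, fs=fs, channel_table=ct, meta=meta)


def write_averaged_beat_h5(beat: AveragedBeat, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=beat.waveforms)
        f.create_dataset("fs", data=beat.fs)
        f.create_dataset("rr_mean", data=beat.rr_mean)
        f.create_dataset("n_beats_used", data=beat.n_beats_used)
        f.create_dataset(
            "windows",
            data=np.array([beat.windows.qrs_on, beat.windows.qrs_off,
                           beat.windows.t_on, beat.windows.t_off]),
        )
        f.create_dataset("lead_included",
                         data=beat.lead_status["included"].to_numpy(bool))
        f.create_dataset(
            "lead_reason",
            data=np.array(beat.lead_status["reason"], dtype="S"),
        )


def read_averaged_beat_h5(path: str | Path) -> AveragedBeat:
    with h5py.File(path, "r") as f:
        win = f["windows"][:]
        return AveragedBeat(
            waveforms=f["waveforms"][:],
            fs=float(f["fs"][()]),
            rr_mean=float(f["rr_mean"][()]),
            n_beats_used=int(f["n_beats_used"][()]),
            windows=FiducialWindows(*map(float, win)),
            lead_status=pd.DataFrame(
                {
                    "included": f["lead_included"][:].astype(bool),
                    "reason": [s.decode() for s in f["lead_reason"][:]],
                }
            ),
        )


def write_transfer_h5(tm: TransferMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=tm.A)
        f.create_dataset("row_index", data=np.asarray(tm.row_index, dtype=np.int64))
        f.create_dataset("col_index", data=np.asarray(tm.col_index, dtype=np.int64))
        f.attrs["kernel_kind"] = tm.kernel_kind
        f.attrs["condition_estimate"] = tm.condition_estimate


def read_transfer_h5(path: str | Path) -> TransferMatrix:
    with h5py.File(path, "r") as f:
        return TransferMatrix(
            A=f["A"][:],
            row_index=f["row_index"][:],
            col_index=f["col_index"][:],
            kernel_kind=str(f.attrs["kernel_kind"]),
            condition_estimate=float(f.attrs["condition_estimate"]),
        )


def write_ueg_h5(phi: EpicardialSignalSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ueg", data=phi.ueg)
        f.create_dataset("fs", data=phi.fs)
        if phi.lambda_used is not None:
            f.attrs["lambda_used"] = phi.lambda_used
        f.attrs["provenance"] = json.dumps(
            {k: v for k, v in phi.provenance.items()
             if isinstance(v, (str, int, float, bool))}
        )


def read_ueg_h5(path: str | Path) -> EpicardialSignalSet:
    with h5py.File(path, "r") as f:
        return EpicardialSignalSet(
            ueg=f["ueg"][:],
            fs=float(f["fs"][()]),
            lambda_used=float(f.attrs["lambda_used"])
            if "lambda_used" in f.attrs else None,
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


# -- marker / truth / pair tables -------------------------------------------------


def write_markers_csv(markers: NodeMarkers, path: str | Path) -> None:
    df = markers.to_frame()
    df.insert(1, "rr_ms", markers.rr)
    df.to_csv(path, index=False, float_format="%.17g")


def read_markers_csv(path: str | Path) -> NodeMarkers:
    df = _read_csv(path)
    return NodeMarkers.from_frame(df, rr=float(df["rr_ms"].iloc[0]))


def write_ground_truth_csv(truth: GroundTruthSource, path: str | Path) -> None:
    pd.DataFrame(
        {"node": np.arange(truth.n_nodes), "at_ms": truth.node_at,
         "rt_ms": truth.node_rt}
    ).to_csv(path, index=False, float_format="%.17g")


def read_ground_truth_csv(path: str | Path, breakthrough_node: int | None = None,
                          conduction_velocity: float = float("nan"),
                          apd_base: float = float("nan"),
                          seed: int = 0) -> GroundTruthSource:
    df = _read_csv(path)
    at = df["at_ms"].to_numpy(float)
    if breakthrough_node is None:
        breakthrough_node = int(np.argmin(at))
    return GroundTruthSource(
        node_at=at, node_rt=df["rt_ms"].to_numpy(float),
        breakthrough_node=breakthrough_node,
        conduction_velocity=conduction_velocity, apd_base=apd_base, rng_seed=seed,
    )


def write_pairs_csv(pairs: PairedSites, path: str | Path) -> None:
    pd.DataFrame(
        {"idx_a": pairs.pairs[:, 0], "idx_b": pairs.pairs[:, 1],
         "distance_mm": pairs.pair_distance}
    ).to_csv(path, index=False, float_format="%.17g")


def read_pairs_csv(path: str | Path) -> PairedSites:
    df = _read_csv(path)
    return PairedSites(
        pairs=df[["idx_a", "idx_b"]].to_numpy(np.int64),
        pair_distance=df["distance_mm"].to_numpy(float),
    )


# -- JSON / YAML ------------------------------------------------------------------


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}:{e.lineno}: {e.msg}") from e


def read_yaml(path: str | Path) -> dict:
    try:
        out = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ParseError(f"{path}: {e}") from e
    if not isinstance(out, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return out
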