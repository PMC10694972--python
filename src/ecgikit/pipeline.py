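"""Pipeline orchestration: average -> inverse -> markers -> valve exclusion ->
summarize, with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .errors import EcgiKitError, PipelineError
from .geometry import ElectrodeSet, SurfaceMesh, exclude_valve_plane
from .inverse import TransferMatrix, build_transfer_matrix, solve_inverse
from .markers import compute_markers, qc_markers
from .sigproc import BeatRecording, detect_beats, qc_leads, signal_average
from .epstats import summarize_participant

log = logging.getLogger(__name__)

STAGES = ("average", "inverse", "markers", "exclude_valve", "summarize")


def _hash_array(a) -> str:
    import numpy as np

    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    recording: BeatRecording,
    heart: SurfaceMesh,
    electrodes: ElectrodeSet,
    torso: SurfaceMesh | None = None,
    transfer: TransferMatrix | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Run all pipeline stages on one participant.

    Returns a dict with every stage output plus a provenance ``manifest``
    (config, input hashes, version, per-stage timings). Any stage error aborts
    with the stage name; partial outputs are kept alongside a FAILED marker.
    """
    out_dir = Path(output_dir if output_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "schema_version": config.schema_version,
        "config": json.loads(config.model_dump_json()),
        "inputs": {
            "recording_sha": _hash_array(recording.signals),
            "heart_sha": _hash_array(heart.vertices),
            "electrodes_sha": _hash_array(electrodes.positions),
        },
        "stages": [],
    }
    results: dict = {"manifest": manifest}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except EcgiKitError as e:
            manifest["stages"].append(
                {"name": name, "status": "FAILED", "error": str(e)}
            )
            _write_manifest(manifest, out_dir, failed=True)
            raise PipelineError(name, str(e)) from e
        manifest["stages"].append(
            {"name": name, "status": "ok",
             "seconds": round(time.perf_counter() - t0, 3)}
        )
        return out

    def _average():
        status = qc_leads(
            recording,
            flat_sd_mv=config.qc.flat_sd_mv,
            artifact_sd_mv=config.qc.artifact_sd_mv,
            clip_fraction=config.qc.clip_fraction,
        )
        onsets = detect_beats(recording, lead_status=status)
        mw = config.marker_windows
        return signal_average(
            recording, onsets, reject_fraction=config.reject_fraction,
            lead_status=status, qrs_threshold=mw.qrs_threshold,
            qrs_pad_ms=mw.qrs_pad_ms, t_gap_ms=mw.t_gap_ms, t_span_ms=mw.t_span_ms,
        )

    beat = stage("average", _average)
    results["beat"] = beat

    def _inverse():
        A = transfer
        if A is None:
            A = build_transfer_matrix(
                heart, electrodes, kernel=config.kernel_kind, torso=torso
            )
        return A, solve_inverse(
            beat, A, lambda_rule=config.lambda_rule, lam=config.lambda_fixed
        )

    A, phi_e = stage("inverse", _inverse)
    results["transfer"] = A
    results["phi_e"] = phi_e

    def _markers():
        m = compute_markers(phi_e, beat.windows, rr_ms=beat.rr_mean)
        return qc_markers(m, beat.windows,
                          amplitude_floor_mv=config.qc.amplitude_floor_mv)

    markers = stage("markers", _markers)
    results["markers_raw"] = markers

    markers_v = stage("exclude_valve", lambda: exclude_valve_plane(markers, heart))
    results["markers"] = markers_v

    summary = stage("summarize", lambda: summarize_participant(markers_v, heart))
    results["summary"] = summary

    _write_manifest(manifest, out_dir, failed=False)
    return results


def _write_manifest(manifest: dict, out_dir: Path, failed: bool) -> None:
    from .io import write_json

    write_json(manifest, out_dir / "manifest.json")
    marker = out_dir / "FAILED"
    if failed:
        marker.write_text(manifest["stages"][-1].get("error", "unknown error"))
    elif marker.exists():
        marker.unlink()
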