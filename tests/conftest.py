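"""Shared fixtures: one small synthetic participant processed end to end,
plus lightweight meshes. Session-scoped because generation dominates runtime."""

import numpy as np
import pandas as pd
import pytest

from ecgikit.geometry import SurfaceMesh, _star_triangulate
from ecgikit.inverse import solve_inverse
from ecgikit.markers import compute_markers, qc_markers
from ecgikit.sigproc import detect_beats, qc_leads, signal_average
from ecgikit.synthgen import (
    _fibonacci_directions,
    generate_heart_mesh,
    synthetic_participant,
)


@pytest.fixture(scope="session")
def participant():
    """Small synthetic participant: 300 heart nodes, 20 beats, 20 dB SNR."""
    return synthetic_participant(seed=3, n_heart_nodes=300, n_beats=20, snr_db=20.0)


@pytest.fixture(scope="session")
def processed(participant):
    """The participant run through averaging, inversion and marker extraction."""
    rec = participant["recording"]
    status = qc_leads(rec)
    onsets = detect_beats(rec, lead_status=status)
    beat = signal_average(rec, onsets, lead_status=status)
    phi = solve_inverse(beat, participant["transfer"], lambda_rule="creso")
    markers = qc_markers(
        compute_markers(phi, beat.windows, rr_ms=beat.rr_mean), beat.windows
    )
    return {
        "status": status,
        "onsets": onsets,
        "beat": beat,
        "phi": phi,
        "markers": markers,
    }


@pytest.fixture(scope="session")
def heart_small():
    return generate_heart_mesh(200, seed=1)


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit-ish sphere with 300 vertices (radius 40 mm)."""
    pts = 40.0 * _fibonacci_directions(300)
    return SurfaceMesh(pts, _star_triangulate(pts))


@pytest.fixture()
def tiny_recording():
    """4-channel recording: gaussian 'QRS' train plus known noise."""
    rng = np.random.default_rng(0)
    fs, rr, n_b, nch = 1000.0, 800.0, 20, 4
    t = np.arange(int(rr * (n_b + 2))) / fs * 1000.0
    wave = np.exp(-0.5 * (((t % rr) - 200.0) / 10.0) ** 2)
    sig = np.tile(wave, (nch, 1)) + rng.normal(scale=0.02, size=(nch, len(t)))
    table = pd.DataFrame(
        {"panel": ["anterior"] * nch, "row": range(nch), "col": [0] * nch}
    )
    from ecgikit.sigproc import BeatRecording

    return BeatRecording(signals=sig, fs=fs, channel_table=table, meta={"rr": rr})
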