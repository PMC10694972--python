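import numpy as np
import pytest

from ecgikit.errors import GeometryError, InvalidParameterError, SignalError
from ecgikit.inverse import TransferMatrix, build_transfer_matrix
from ecgikit.sigproc import CLIP_MV
from ecgikit.synthgen import (
    GroundTruthSource,
    NoiseModel,
    action_potential_template,
    forward_project_beats,
    generate_heart_mesh,
    generate_torso_and_vest,
    simulate_activation,
    synthesize_epicardial_potentials,
    synthetic_participant,
)


class TestGroundTruthSource:
    def test_rt_must_exceed_at(self):
        with pytest.raises(InvalidParameterError):
            GroundTruthSource(
                node_at=np.array([0.0, 10.0]),
                node_rt=np.array([250.0, 5.0]),
                breakthrough_node=0,
                conduction_velocity=1.5,
                apd_base=235.0,
                rng_seed=0,
            )

    def test_breakthrough_must_be_minimum(self):
        with pytest.raises(InvalidParameterError):
            GroundTruthSource(
                node_at=np.array([5.0, 0.0]),
                node_rt=np.array([250.0, 240.0]),
                breakthrough_node=0,
                conduction_velocity=1.5,
                apd_base=235.0,
                rng_seed=0,
            )


class TestHeartMesh:
    def test_vertex_count_exact(self):
        for n in (50, 137, 300):
            m = generate_heart_mesh(n, seed=0)
            assert m.n_vertices == n

    def test_closed_and_watertight(self, heart_small):
        assert heart_small.euler_characteristic() == 2
        assert heart_small.is_watertight()

    def test_valve_plane_near_base(self, heart_small):
        valve = heart_small.labels["valve_plane"]
        assert valve.size > 0
        zmax = heart_small.vertices[:, 2].max()
        assert np.all(heart_small.vertices[valve, 2] > 0.5 * zmax)

    def test_seed_reproducible(self):
        a = generate_heart_mesh(100, seed=9)
        b = generate_heart_mesh(100, seed=9)
        assert np.array_equal(a.vertices, b.vertices)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_heart_mesh(20)


class TestTorsoAndVest:
    def test_default_split_127_129(self, heart_small):
        _, el = generate_torso_and_vest(heart=heart_small)
        panels = np.array([p for p, _, _ in el.grid_id])
        assert el.n_electrodes == 256
        assert (panels == "anterior").sum() == 127
        assert (panels == "posterior").sum() == 129

    def test_electrodes_on_surface(self, heart_small):
        from ecgikit.geometry import closest_point_on_mesh

        torso, el = generate_torso_and_vest(heart=heart_small)
        _, d, _ = closest_point_on_mesh(el.positions, torso)
        assert d.max() < 1e-6

    def test_heart_must_fit_inside(self):
        big = generate_heart_mesh(
            100, shape_params={"semi_axes": (400.0, 400.0, 600.0)}
        )
        with pytest.raises(GeometryError):
            generate_torso_and_vest(heart=big)

    def test_grid_spacing_near_nominal(self, heart_small):
        _, el = generate_torso_and_vest(heart=heart_small)
        idx = {g: i for i, g in enumerate(el.grid_id)}
        gaps = []
        for (p, r, c), i in idx.items():
            j = idx.get((p, r, c + 1))
            if j is not None:
                gaps.append(np.linalg.norm(el.positions[i] - el.positions[j]))
        gaps = np.array(gaps)
        assert np.all(np.abs(gaps - 25.0) < 2.0)


class TestActivation:
    def test_breakthrough_has_zero_at(self, heart_small):
        truth = simulate_activation(heart_small, breakthrough_node=0)
        assert truth.node_at[0] == 0.0
        assert truth.node_at.min() == 0.0

    def test_at_bounded_by_geodesic_speed(self, heart_small):
        v = 2.0
        truth = simulate_activation(heart_small, 0, conduction_velocity=v)
        # straight-line distance / v is a lower bound on the geodesic AT
        d = np.linalg.norm(
            heart_small.vertices - heart_small.vertices[0], axis=1
        )
        assert np.all(truth.node_at >= d / v - 1e-9)

    def test_apd_gradient_along_z(self, heart_small):
        truth = simulate_activation(heart_small, 0, apd_gradient=0.5)
        apd = truth.node_rt - truth.node_at
        z = heart_small.vertices[:, 2]
        slope = np.polyfit(z - z.min(), apd, 1)[0]
        assert np.isclose(slope, 0.5, atol=1e-6)


class TestTemplateAndUeg:
    def test_template_midpoints_at_fiducials(self):
        t = np.arange(0, 500, 0.1)
        ap = action_potential_template(t, at=100.0, rt=330.0)
        d = np.gradient(ap, t)
        assert abs(t[np.argmax(d)] - 100.0) < 1.0
        assert abs(t[np.argmin(d)] - 330.0) < 1.0

    def test_ueg_farfield_off_is_negative_template(self, heart_small):
        truth = simulate_activation(heart_small, 0)
        phi = synthesize_epicardial_potentials(
            truth, fs=1000.0, duration_ms=truth.node_rt.max() + 80, farfield=False
        )
        assert np.all(phi.ueg <= 1e-12)

    def test_duration_too_short_rejected(self, heart_small):
        truth = simulate_activation(heart_small, 0)
        with pytest.raises(SignalError):
            synthesize_epicardial_potentials(truth, fs=1000.0, duration_ms=100.0)

    def test_farfield_weight_validated(self, heart_small):
        truth = simulate_activation(heart_small, 0)
        with pytest.raises(InvalidParameterError):
            synthesize_epicardial_potentials(
                truth, fs=1000.0, duration_ms=400.0, farfield_weight=1.5
            )


class TestNoiseAndProjection:
    def test_broadband_for_snr_hits_target(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(8, 4000))
        nm = NoiseModel.broadband_for_snr(sig, snr_db=20.0)
        rms = np.sqrt((sig**2).mean())
        assert np.isclose(nm.broadband_sd, rms / 10.0, rtol=1e-12)

    def test_forward_projection_clips_at_rails(self, heart_small):
        truth = simulate_activation(heart_small, 0)
        phi = synthesize_epicardial_potentials(
            truth, fs=500.0, duration_ms=truth.node_rt.max() + 80,
            amplitude=100.0, farfield=False
        )
        A = TransferMatrix.identity(heart_small.n_vertices)
        rec = forward_project_beats(phi, A, n_beats=6, seed=0,
                                    noise=NoiseModel.silent(), fs_out=500.0)
        assert rec.signals.min() >= -CLIP_MV - 1e-12
        assert rec.signals.max() <= CLIP_MV + 1e-12
        assert (np.abs(rec.signals) >= CLIP_MV - 1e-9).any()

    def test_true_onsets_recorded(self, participant):
        rec = participant["recording"]
        onsets = np.asarray(rec.meta["true_onsets_ms"])
        assert len(onsets) == 20
        rr = np.diff(onsets)
        assert np.all(rr >= 400.0)
        assert 850 < np.median(rr) < 1050


class TestSyntheticParticipant:
    def test_bundle_shapes_consistent(self, participant):
        n = participant["heart"].n_vertices
        assert participant["truth"].n_nodes == n
        assert participant["transfer"].A.shape == (256, n)
        assert participant["recording"].n_channels == 256
        assert participant["phi_e"].n_nodes == n

    def test_seed_reproducible_signals(self):
        a = synthetic_participant(seed=5, n_heart_nodes=80, n_beats=6, snr_db=20.0)
        b = synthetic_participant(seed=5, n_heart_nodes=80, n_beats=6, snr_db=20.0)
        assert np.array_equal(a["recording"].signals, b["recording"].signals)
        assert np.array_equal(a["transfer"].A, b["transfer"].A)

    def test_seeds_differ(self):
        a = synthetic_participant(seed=5, n_heart_nodes=80, n_beats=6, snr_db=20.0)
        b = synthetic_participant(seed=6, n_heart_nodes=80, n_beats=6, snr_db=20.0)
        assert not np.array_equal(a["recording"].signals, b["recording"].signals)
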