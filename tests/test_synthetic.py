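"""Generator tests: geometry, input function, tissue kinetics, rendering."""

import json

import numpy as np
import pytest

from qmpm.curves import TimeCurve
from qmpm.synthetic import (
    GroundTruth,
    InputFunctionParams,
    KineticParams,
    NetworkConfig,
    NoiseDriftParams,
    VesselGeometry,
    linear_drift,
    make_vessel_network,
    render_timelapse,
    simulate_input_function,
    simulate_tissue_curve,
)


# ---------------------------------------------------------------------------
# Vessel networks
# ---------------------------------------------------------------------------

class TestVesselNetwork:
    def test_single_straight_tube(self):
        geom = make_vessel_network(
            NetworkConfig(
                n_vessels=1, radius_range_um=(10.0, 10.0), waviness_um=0.0, seed=1
            )
        )
        assert len(geom.segments) == 1
        _, r = geom.segments[0]
        assert 2 * r == pytest.approx(20.0)
        assert geom.rasterize_segment(0).any()

    def test_determinism(self):
        cfg = NetworkConfig(n_vessels=5, radius_range_um=(5.0, 15.0), seed=11)
        a = make_vessel_network(cfg)
        b = make_vessel_network(cfg)
        for (pa, ra), (pb, rb) in zip(a.segments, b.segments):
            np.testing.assert_array_equal(pa, pb)
            assert ra == rb

    def test_raster_diameters_brute_force(self):
        # 20 vessels with radii in [5, 25] um need ~54 um lanes
        cfg = NetworkConfig(
            n_vessels=20,
            radius_range_um=(5.0, 25.0),
            fov_um=(1100.0, 1100.0),
            pixel_size_um=2.0,
            seed=7,
        )
        geom = make_vessel_network(cfg)
        rng = np.random.default_rng(0)
        for i, (poly, r) in enumerate(geom.segments):
            assert 10.0 <= 2 * r <= 50.0
            mask = geom.rasterize_segment(i)
            assert mask.any()
            # brute force: densely resampled centerline vs a pixel subsample
            steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            dense = []
            for a, b, s in zip(poly[:-1], poly[1:], steps):
                n = max(2, int(np.ceil(s / 0.05)))
                dense.append(a + np.linspace(0, 1, n)[:, None] * (b - a))
            dense = np.vstack(dense)
            rows, cols = np.nonzero(mask)
            pick = rng.choice(rows.size, size=min(rows.size, 150), replace=False)
            ps = geom.pixel_size_um
            for rr, cc in zip(rows[pick], cols[pick]):
                center = np.array([(cc + 0.5) * ps, (rr + 0.5) * ps])
                d = np.min(np.linalg.norm(dense - center, axis=1))
                assert d <= r + 0.06  # dense-sampling slack

    def test_infeasible_radius_raises(self):
        with pytest.raises(ValueError, match="geometry infeasible"):
            make_vessel_network(
                NetworkConfig(
                    n_vessels=1, radius_range_um=(200.0, 200.0), fov_um=(256.0, 256.0)
                )
            )

    def test_centerline_outside_fov_rejected(self):
        with pytest.raises(ValueError, match="inside the field of view"):
            VesselGeometry(
                segments=[(np.array([[0.0, -5.0], [256.0, 10.0]]), 5.0)],
                fov_um=(256.0, 256.0),
                pixel_size_um=1.0,
            )


# ---------------------------------------------------------------------------
# Input function
# ---------------------------------------------------------------------------

class TestInputFunction:
    def test_zero_before_arrival_window(self):
        # arrival drawn anywhere in the 6-12 s post-injection window
        times = np.linspace(0.0, 60.0, 601)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = InputFunctionParams(t_arrival_s=float(rng.uniform(6.0, 12.0)))
            curve = simulate_input_function(p, times)
            assert np.all(curve.values[times < 6.0] == 0.0)
            assert np.all(curve.values[times < p.t_arrival_s] == 0.0)

    def test_degenerate_plateau(self):
        p = InputFunctionParams(
            t_arrival_s=5.0, A1=0.8, A2=0.0, lambda1_per_s=0.0, lambda2_per_s=0.0
        )
        times = np.linspace(0.0, 100.0, 501)
        curve = simulate_input_function(p, times)
        post = times >= p.t_peak_s
        np.testing.assert_allclose(curve.values[post], 0.8)

    def test_continuity(self):
        p = InputFunctionParams(t_arrival_s=7.3)
        t = np.linspace(0.0, 60.0, 60001)
        v = p.evaluate(t)
        assert np.max(np.abs(np.diff(v))) < 1e-2  # no jumps at 1 ms resolution

    def test_unsorted_times_rejected(self):
        p = InputFunctionParams()
        with pytest.raises(ValueError, match="sorted"):
            simulate_input_function(p, np.array([0.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# Tissue curve
# ---------------------------------------------------------------------------

class TestTissueCurve:
    def test_zero_transfer(self, curve_pair):
        blood, _ = curve_pair
        out = simulate_tissue_curve(KineticParams(0.0, 0.3), blood)
        assert np.all(out.values == 0.0)

    def test_constant_input_closed_form(self):
        t = np.arange(0.0, 600.1, 0.1)
        C0, K, V = 2.0, 0.05, 0.3
        blood = TimeCurve(t, np.full(t.size, C0))
        out = simulate_tissue_curve(KineticParams(K, V), blood)
        k_ep = K / 60.0 / V
        exact = V * C0 * (1.0 - np.exp(-k_ep * t))
        err = np.abs(out.values[1:] - exact[1:]) / exact[1:]
        assert err.max() < 1e-9

    def test_quadrature_oracle(self):
        # fine-grid trapezoid quadrature of the convolution integral
        K, V = 0.05, 0.3
        k_ep = K / 60.0 / V

        def biexp(t):
            return 0.7 * np.exp(-0.05 * t) + 0.3 * np.exp(-0.005 * t)

        t = np.arange(0.0, 60.0005, 1e-3)
        out = simulate_tissue_curve(KineticParams(K, V), TimeCurve(t, biexp(t)))
        scale = np.max(np.abs(out.values))
        for i in np.linspace(10, t.size - 1, 25).astype(int):
            oracle = K / 60.0 * np.trapezoid(
                biexp(t[: i + 1]) * np.exp(-k_ep * (t[i] - t[: i + 1])), t[: i + 1]
            )
            assert abs(out.values[i] - oracle) / scale < 1e-6

    def test_ill_posed_rejected(self, curve_pair):
        blood, _ = curve_pair
        with pytest.raises(ValueError):
            KineticParams(0.05, 0.0)
        from qmpm.kinetics import tissue_response

        with pytest.raises(ValueError, match="ill-posed"):
            tissue_response(blood.times, blood.values, 0.05, 0.0)

    def test_monotone_in_k_trans_for_nondecaying_input(self):
        # pointwise monotonicity in K_trans holds when the input does not
        # decay (a decaying input washes out faster at larger K_trans, so
        # late-time uptake is not monotone there)
        t = 2.0 * np.arange(301)
        blood = TimeCurve(t, np.minimum(t / 30.0, 1.0))
        prev = None
        for k in np.linspace(0.0, 0.5, 11):
            out = simulate_tissue_curve(KineticParams(k, 0.3), blood)
            assert np.all(out.values >= -1e-12)
            if prev is not None:
                assert np.all(out.values >= prev - 1e-9)
            prev = out.values


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

class TestRendering:
    def test_conservation_with_true_masks(self, noiseless_stack):
        stack, truth = noiseless_stack
        lumen = truth.geometry.rasterize()
        img = stack.channel("tracer")
        blood_mean = img[:, lumen].mean(axis=1)
        tissue_mean = img[:, ~lumen].mean(axis=1)
        t = stack.frame_times
        blood = truth.input_function.evaluate(t)
        tissue = simulate_tissue_curve(
            truth.kinetics, TimeCurve(t, blood)
        ).values
        np.testing.assert_allclose(blood_mean, blood, rtol=0, atol=1e-12)
        np.testing.assert_allclose(tissue_mean, tissue, rtol=0, atol=1e-12)

    def test_bit_identical_for_same_seed(self):
        from qmpm.synthetic import SimulationConfig, simulate_stack

        cfg = SimulationConfig(duration_s=60.0)
        a, truth_a = simulate_stack(cfg, seed=5)
        b, truth_b = simulate_stack(cfg, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        assert truth_a.input_function == truth_b.input_function

    def test_programmed_drift_recovered_by_phase_correlation(self):
        from skimage.registration import phase_cross_correlation

        geom = make_vessel_network(NetworkConfig(seed=3))
        t = 2.0 * np.arange(6)
        const = TimeCurve(t, np.full(t.size, 1.0))
        zero = TimeCurve(t, np.zeros(t.size))
        drift = np.zeros((t.size, 2))
        drift[3] = (3.4, -2.1)
        stack, _ = render_timelapse(
            geom, const, zero, NoiseDriftParams(drift_px=drift, seed=8),
            include_blood_pool=True,
        )
        pool = stack.channel("blood_pool")
        shift, _, _ = phase_cross_correlation(
            pool[0], pool[3], upsample_factor=50, normalization="phase"
        )
        assert abs(-shift[1] - 3.4) < 0.25
        assert abs(-shift[0] - (-2.1)) < 0.25

    def test_cell_faster_than_field_rejected(self):
        geom = make_vessel_network(NetworkConfig(seed=3))
        t = 2.0 * np.arange(5)
        const = TimeCurve(t, np.full(t.size, 1.0))
        zero = TimeCurve(t, np.zeros(t.size))
        with pytest.raises(ValueError, match="beyond the field of view"):
            render_timelapse(geom, const, zero, NoiseDriftParams(), cells=[1000.0])

    def test_mismatched_time_bases_rejected(self):
        geom = make_vessel_network(NetworkConfig(seed=3))
        t = 2.0 * np.arange(5)
        const = TimeCurve(t, np.full(t.size, 1.0))
        other = TimeCurve(t + 1.0, np.zeros(t.size))
        with pytest.raises(ValueError, match="time base"):
            render_timelapse(geom, const, other, NoiseDriftParams())

    def test_ground_truth_roundtrip(self, tmp_path, noiseless_stack):
        _, truth = noiseless_stack
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.kinetics == truth.kinetics
        assert back.input_function == truth.input_function
        assert back.n_frames == truth.n_frames
        for (pa, ra), (pb, rb) in zip(
            back.geometry.segments, truth.geometry.segments
        ):
            np.testing.assert_allclose(pa, pb)
            assert ra == rb
        # sidecar is valid JSON with the drift trajectory intact
        d = json.loads(path.read_text())
        assert d["noise_drift"]["seed"] == truth.noise_drift.seed

    def test_drift_trajectory_length_checked(self):
        geom = make_vessel_network(NetworkConfig(seed=3))
        t = 2.0 * np.arange(5)
        const = TimeCurve(t, np.full(t.size, 1.0))
        zero = TimeCurve(t, np.zeros(t.size))
        nd = NoiseDriftParams(drift_px=linear_drift(3, 1.0, 1.0))
        with pytest.raises(ValueError, match="one entry per frame"):
            render_timelapse(geom, const, zero, nd)
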