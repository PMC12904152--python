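"""Phantom generator: mechanics, rendering, calibration synthesis."""

import numpy as np
import pytest

from optpal import PhantomSpec, compute_compression_state, generate_series, render_volume
from optpal.phantom import (
    FORCE_SENSOR_MAX_N,
    generate_calibration_data,
    solve_stress_bisection,
)


class TestCompressionState:
    def test_dead_zone_transmits_no_stress(self, small_spec):
        st = compute_compression_state(small_spec, 0)
        assert np.all(st.thickness == small_spec.L0)
        assert np.all(st.eps1 == 0) and np.all(st.sigma == 0)

    def test_symmetric_springs_split_displacement_evenly(self):
        spec = PhantomSpec(
            nx=4, ny=4, tissue_modulus_map=49.0, tissue_thickness_map=600.0,
            dead_zone_increments=0, n_increments=5,
        )
        st = compute_compression_state(spec, 2)  # d = 200 um
        assert np.allclose(spec.L0 - st.thickness, 100.0)

    def test_hand_solved_two_spring_equilibrium(self):
        # E2 = 2*E1, H = L0, d = 300 -> layer takes 200 um, eps1 = 1/3
        spec = PhantomSpec(
            nx=2, ny=2, E1=49.0, tissue_modulus_map=98.0,
            tissue_thickness_map=600.0, dead_zone_increments=0, n_increments=5,
        )
        st = compute_compression_state(spec, 3)
        assert np.allclose(spec.L0 - st.thickness, 200.0)
        assert np.allclose(st.eps1, 1.0 / 3.0)
        assert np.allclose(st.sigma, 49.0 / 3.0)

    def test_agrees_with_bisection_oracle_on_random_specs(self, rng):
        for _ in range(100):
            L0 = rng.uniform(300, 1200)
            E1 = rng.uniform(10, 200)
            H = rng.uniform(200, 2000)
            E2 = rng.uniform(5, 300)
            spec = PhantomSpec(
                nx=1, ny=1, L0=L0, E1=E1, tissue_modulus_map=E2,
                tissue_thickness_map=H, dead_zone_increments=0,
                n_increments=5, stage_step=rng.uniform(20, 60),
            )
            st = compute_compression_state(spec, 4)
            sigma_ref = solve_stress_bisection(st.displacement, L0, E1, H, E2)
            assert st.sigma[0, 0] == pytest.approx(sigma_ref, rel=1e-9)

    def test_index_out_of_range_raises(self, small_spec):
        with pytest.raises(ValueError):
            compute_compression_state(small_spec, small_spec.n_increments)

    def test_layer_crush_raises_with_diagnostic(self):
        spec = PhantomSpec(
            nx=2, ny=2, tissue_modulus_map=1e6, tissue_thickness_map=600.0,
            dead_zone_increments=0, n_increments=8, stage_step=100.0,
        )
        with pytest.raises(ValueError, match="negative-thickness"):
            compute_compression_state(spec, 7)  # d = 700 > L0


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L0": -1.0},
            {"E1": 0.0},
            {"tissue_modulus_map": -5.0},
            {"dead_zone_increments": 5, "n_increments": 8},
            {"L0": 30.0},  # fewer than 10 depth pixels
            {"n_increments": 17},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(nx=4, ny=4, **kwargs)


class TestRendering:
    def test_noiseless_ascan_has_exactly_two_maxima_at_interfaces(self, noiseless_spec):
        st = compute_compression_state(noiseless_spec, 4)
        vol = render_volume(noiseless_spec, st)
        prof = vol.intensity[3, 5]
        interior = prof[1:-1]
        maxima = np.nonzero((interior > prof[:-2]) & (interior > prof[2:]))[0] + 1
        top = round(noiseless_spec.glass_depth / noiseless_spec.dz)
        bottom = round((noiseless_spec.glass_depth + st.thickness[3, 5]) / noiseless_spec.dz)
        assert maxima.tolist() == [top, bottom]

    def test_same_seed_gives_bit_identical_volumes(self, small_spec):
        v1, _ = generate_series(small_spec)
        v2, _ = generate_series(small_spec)
        for a, b in zip(v1, v2):
            assert np.array_equal(a.intensity, b.intensity)

    def test_interface_peaks_exceed_tissue_99th_percentile(self, small_spec):
        st = compute_compression_state(small_spec, 4)
        vol = render_volume(small_spec, st)
        bottom = np.rint(
            (small_spec.glass_depth + st.thickness) / small_spec.dz
        ).astype(int)
        z = np.arange(small_spec.nz)
        tissue = vol.intensity[z[None, None, :] > bottom[:, :, None]]
        top = round(small_spec.glass_depth / small_spec.dz)
        peak = vol.intensity[:, :, top].min()
        assert peak > np.percentile(tissue, 99)

    def test_layer_bottom_beyond_volume_raises(self, small_spec):
        spec = small_spec.with_(nz=128)  # 448 um depth < glass + L0
        st = compute_compression_state(spec, 0)
        with pytest.raises(ValueError, match="imaging depth"):
            render_volume(spec, st)


class TestSeries:
    def test_stage_positions_and_monotone_truth(self, small_spec):
        spec = small_spec.with_(n_increments=5, dead_zone_increments=1)
        vols, truth = generate_series(spec)
        assert [v.stage_position for v in vols] == [0, 100, 200, 300, 400]
        per_inc = truth.thickness.mean(axis=(1, 2))
        assert np.all(np.diff(per_inc) <= 0)
        assert np.all(np.diff(truth.sigma.mean(axis=(1, 2))) >= 0)
        truth.self_check(spec.E1, spec.E2)

    def test_stiff_inclusion_raises_stress_inside_disk(self, small_spec):
        E2 = np.full((24, 24), 25.0)
        xx, yy = np.mgrid[:24, :24]
        disk = (xx - 12) ** 2 + (yy - 12) ** 2 <= 36
        E2[disk] = 100.0
        spec = small_spec.with_(tissue_modulus_map=E2, tissue_thickness_map=1400.0)
        _, truth = generate_series(spec)
        for i in range(spec.dead_zone_increments + 1, spec.n_increments):
            assert truth.sigma[i][disk].min() > truth.sigma[i][~disk].max()

    def test_uniform_noiseless_phantom_has_uniform_strain(self, noiseless_spec):
        _, truth = generate_series(noiseless_spec)
        assert np.all(truth.eps1 == truth.eps1[:, :1, :1])


class TestCalibrationData:
    def test_first_increment_has_zero_force(self, small_spec):
        tab = generate_calibration_data(small_spec)
        assert tab["force_N"].iloc[0] == 0.0
        assert tab["increment"].iloc[0] == 0

    def test_known_strain_force_arithmetic(self):
        # eps = 0.1, E1 = 49 kPa, 10 mm disk, fixed area -> F = 4.9 kPa * A
        spec = PhantomSpec(nx=2, ny=2, E1=49.0)
        tab = generate_calibration_data(
            spec, layer_diameter_mm=10.0, layer_thickness_um=1000.0,
            conserve_volume=False,
        )
        row = tab[tab["stage_um"] == 100.0].iloc[0]
        expected = 4900.0 * np.pi * 0.005**2
        assert row["force_N"] == pytest.approx(expected)  # ~0.385 N
        assert expected == pytest.approx(0.3848, abs=5e-4)

    def test_series_truncates_at_force_sensor_range(self, small_spec):
        tab = generate_calibration_data(small_spec)
        assert (tab["force_N"] <= FORCE_SENSOR_MAX_N).all()
        # the next increment would have exceeded the sensor range
        nxt = len(tab) * small_spec.stage_step / 1500.0
        assert nxt < 1.0  # sanity: truncation happened before full crush

    def test_thickness_decreases_by_stage_step(self, small_spec):
        tab = generate_calibration_data(small_spec)
        assert np.allclose(np.diff(tab["thickness_um"]), -small_spec.stage_step)

    def test_diameter_growth_conserves_volume(self, small_spec):
        tab = generate_calibration_data(small_spec, layer_diameter_mm=10.0)
        vol = tab["diameter_mm"] ** 2 * tab["thickness_um"]
        assert np.allclose(vol, vol.iloc[0])
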