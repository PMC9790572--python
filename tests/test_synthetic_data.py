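"""Simulator unit and property tests: AIF, residue, IRF, sampling, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfquant import (
    AIFParams,
    AcquisitionParams,
    SampledCurve,
    SimConfig,
    add_rician_noise,
    convolve_curves,
    fermi_residue,
    generate_aif,
    generate_dataset,
    make_irf,
    make_reference_pair,
    resample_at_hr,
)
from perfquant.curves import GroundTruth, TimeGrid


class TestGenerateAIF:
    def test_zero_amplitude_gives_zero_curve(self, dense_grid):
        aif = generate_aif(AIFParams(amplitude=0.0), dense_grid)
        assert np.all(aif.values == 0.0)

    def test_mass_conservation_of_cascade(self, default_aif):
        # total area = amplitude / (1 - recirculation_fraction)
        expected = 1.0 / (1.0 - AIFParams().recirculation_fraction)
        assert default_aif.integral() == pytest.approx(expected, rel=1e-3)

    def test_time_to_peak_within_physiological_range(self, default_aif):
        p = AIFParams()
        ttp = default_aif.times[np.argmax(default_aif.values)] - p.bolus_delay
        assert 5.0 <= ttp <= 30.0

    def test_non_negative_with_single_dominant_peak(self, default_aif):
        v = default_aif.values
        assert np.all(v >= 0)
        peak = np.argmax(v)
        # first-pass peak dominates the recirculation shoulder
        later = v[peak + int(10 * 30) :]
        assert later.max() < v[peak]

    def test_first_pass_width_realistic(self, default_aif):
        v = default_aif.values
        peak = np.argmax(v)
        above = np.nonzero(v >= v[peak] / 2)[0]
        fwhm = (above[-1] - above[0]) / 30.0
        assert 8.0 <= fwhm <= 15.0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            AIFParams(rates=-0.5)
        with pytest.raises(ValueError):
            AIFParams(rates=(0.5, 0.5), n_stages=3)
        with pytest.raises(ValueError):
            AIFParams(recirculation_fraction=1.0)


class TestFermiResidue:
    @pytest.mark.parametrize(
        "mbf,mtt", [(1, 18.0), (2, 9.0), (3, 6.0), (4, 4.5), (5, 3.6)]
    )
    def test_area_matches_mean_transit_time(self, dense_grid, mbf, mtt):
        r = fermi_residue(mtt, dense_grid)
        assert r.integral() == pytest.approx(mtt, rel=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mtt=st.floats(min_value=0.5, max_value=120.0))
    def test_residue_shape_properties(self, mtt):
        r = fermi_residue(mtt)
        assert r.values[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r.values) <= 1e-15)
        assert np.all((r.values >= 0) & (r.values <= 1.0))

    def test_unreachable_area_raises(self):
        grid = TimeGrid(dt=0.1, n=101)  # 10 s span
        with pytest.raises(ValueError, match="mtt"):
            fermi_residue(6.0, grid)


class TestMakeIRF:
    def test_initial_height_is_flow_per_second(self, dense_grid):
        h = make_irf(fermi_residue(6.0, dense_grid), mbf=3.0)
        assert h.values[0] == pytest.approx(0.05)

    @pytest.mark.parametrize("mbf", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_irf_area_equals_blood_volume(self, dense_grid, mbf):
        truth = GroundTruth(mbf=mbf, vb=0.3)
        h = make_irf(fermi_residue(truth.mtt, dense_grid), mbf)
        assert h.integral() == pytest.approx(0.3, rel=1e-3)

    def test_zero_flow_gives_zero_irf(self, dense_grid):
        h = make_irf(fermi_residue(6.0, dense_grid), 0.0)
        assert np.all(h.values == 0.0)


class TestConvolveCurves:
    def test_unit_impulse_is_identity(self):
        n, dt = 400, 0.5
        t = dt * np.arange(n)
        a = SampledCurve(t, np.exp(-(((t - 40) / 8) ** 2)), kind="aif")
        imp = np.zeros(n)
        imp[0] = 2.0 / dt  # unit area under trapezoidal quadrature
        out = convolve_curves(a, SampledCurve(t, imp, kind="irf"))
        np.testing.assert_allclose(out.values, a.values, atol=1e-6)

    def test_area_theorem(self, default_aif, dense_grid):
        h = make_irf(fermi_residue(3.6, dense_grid), 5.0)
        tissue = convolve_curves(default_aif, h)
        assert tissue.integral() == pytest.approx(
            default_aif.integral() * h.integral(), rel=5e-3
        )

    def test_zero_aif_gives_zero_tissue(self, dense_grid):
        z = SampledCurve(dense_grid.times, np.zeros(dense_grid.n), kind="aif")
        h = make_irf(fermi_residue(6.0, dense_grid), 3.0)
        assert np.all(convolve_curves(z, h).values == 0.0)

    def test_mismatched_grids_rejected(self, default_aif):
        short = SampledCurve(np.arange(10.0), np.ones(10), kind="irf")
        with pytest.raises(ValueError):
            convolve_curves(default_aif, short)


class TestReferencePair:
    @pytest.mark.parametrize("mbf", [1.0, 3.0, 5.0])
    def test_tissue_to_aif_area_ratio_is_blood_volume(self, default_aif, mbf):
        pair = make_reference_pair(mbf, aif=default_aif)
        ratio = pair.tissue.integral() / pair.aif.integral()
        assert ratio == pytest.approx(0.3, rel=1e-3)

    def test_ground_truth_consistency(self):
        truth = GroundTruth(mbf=4.0, vb=0.3)
        assert truth.mtt == pytest.approx(60.0 * 0.3 / 4.0)


class TestResampleAtHR:
    def test_hr60_without_jitter_matches_integer_seconds(self, default_aif, rng):
        acq = AcquisitionParams(input_hr=60.0, jitter_limit=0.0)
        out = resample_at_hr(default_aif, acq, rng)
        assert out.dt == pytest.approx(1.0)
        idx = (np.round(out.times * 30)).astype(int)
        np.testing.assert_array_equal(out.values, default_aif.values[idx])

    def test_sampling_interval_is_sixty_over_hr(self, default_aif, rng):
        out = resample_at_hr(
            default_aif, AcquisitionParams(input_hr=30.0, jitter_limit=0.0), rng
        )
        assert out.dt == pytest.approx(2.0)

    def test_jitter_shift_bounded(self, default_aif):
        rng = np.random.default_rng(5)
        acq = AcquisitionParams(input_hr=90.0, jitter_limit=0.5)
        shifts = [
            resample_at_hr(default_aif, acq, rng).meta["t_shift"]
            for _ in range(200)
        ]
        assert np.max(np.abs(shifts)) <= 0.5

    def test_nominal_time_stamps_hide_the_shift(self, default_aif, rng):
        acq = AcquisitionParams(input_hr=90.0, jitter_limit=0.5)
        out = resample_at_hr(default_aif, acq, rng)
        np.testing.assert_allclose(out.times, (60.0 / 90.0) * np.arange(len(out)))

    def test_every_other_dense_sample_at_900bpm(self, default_aif, rng):
        # 900 bpm on the 30 Hz grid picks exactly every 2nd dense sample
        acq = AcquisitionParams(input_hr=900.0, jitter_limit=0.0)
        out = resample_at_hr(default_aif, acq, rng)
        np.testing.assert_array_equal(out.values, default_aif.values[::2])

    def test_oversampling_rejected(self, default_aif, rng):
        with pytest.raises(ValueError):
            resample_at_hr(
                default_aif, AcquisitionParams(input_hr=1800.0), rng
            )


class TestRicianNoise:
    def test_zero_sigma_is_identity(self, default_aif, rng):
        out = add_rician_noise(default_aif, 0.0, rng)
        np.testing.assert_array_equal(out.values, default_aif.values)

    def test_zero_signal_mean_is_rayleigh(self):
        rng = np.random.default_rng(3)
        n = 100_000
        z = SampledCurve(np.arange(n, dtype=float), np.zeros(n), kind="aif")
        out = add_rician_noise(z, 2.0, rng)
        assert out.values.mean() == pytest.approx(2.0 * np.sqrt(np.pi / 2), rel=0.01)

    def test_high_snr_limit_is_unbiased(self):
        rng = np.random.default_rng(4)
        n = 100_000
        v = 100.0
        c = SampledCurve(np.arange(n, dtype=float), np.full(n, v), kind="aif")
        out = add_rician_noise(c, 1.0, rng)
        assert out.values.mean() == pytest.approx(v, rel=5e-3)


class TestGenerateDataset:
    def test_grid_size(self):
        cfg = SimConfig(n_realizations=2, master_seed=1)
        ds = generate_dataset(cfg)
        assert len(ds) == 5 * 5 * 2
        assert sum(1 for _ in ds) == 50

    def test_single_cell(self):
        cfg = SimConfig(mbf_list=(3.0,), hr_list=(60.0,), n_realizations=1,
                        master_seed=1)
        assert len(list(generate_dataset(cfg))) == 1

    def test_seed_determinism(self):
        cfg = SimConfig(mbf_list=(2.0,), hr_list=(60.0, 90.0),
                        n_realizations=3, master_seed=99)
        d1 = [rz for rz in generate_dataset(cfg)]
        d2 = [rz for rz in generate_dataset(cfg)]
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.aif.values, b.aif.values)
            np.testing.assert_array_equal(a.tissue.values, b.tissue.values)

    def test_truth_and_sampling_attached(self):
        cfg = SimConfig(mbf_list=(2.0,), hr_list=(120.0,), n_realizations=1,
                        master_seed=0)
        rz = next(iter(generate_dataset(cfg)))
        assert rz.truth.mbf == 2.0
        assert rz.aif.dt == pytest.approx(0.5)
        assert rz.acquisition.noise_sigma > 0

    def test_noise_scale_follows_target_snr(self):
        ds = generate_dataset(SimConfig(n_realizations=1, master_seed=0,
                                        target_peak_snr=20.0))
        for mbf, pair in ds.reference_pairs.items():
            assert ds.noise_sigma(mbf) == pytest.approx(
                pair.tissue.values.max() / 20.0
            )
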