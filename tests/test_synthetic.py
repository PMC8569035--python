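import numpy as np
import pytest
from scipy import integrate, stats

from pgrange import (
    BeamConfig,
    CameraGeometry,
    DetectorResponse,
    EmissionModel,
    EnergyWindow,
    apply_energy_window,
    generate_events,
    sample_emission_depth,
    sample_klein_nishina,
    select_compton_events,
    smear_energy,
    total_projectiles,
)
from pgrange.recon import cone_from_event
from pgrange.synthetic import energy_fwhm, klein_nishina_pdf

from conftest import make_noiseless_config


class TestEmissionDepth:
    def test_degenerate_mixture_collapses_to_the_peak(self, rng):
        model = EmissionModel(plateau_fraction=0.0, peak_sigma=0.0, peak_depth_offset=2.0)
        beam = BeamConfig()
        d = sample_emission_depth(model, beam, rng, 100)
        assert np.allclose(d, beam.bp_depth + 2.0)

    def test_pure_plateau_has_uniform_mean(self, rng):
        model = EmissionModel(plateau_fraction=1.0)
        d = sample_emission_depth(model, BeamConfig(), rng, 100_000)
        assert d.mean() == pytest.approx(98.4 / 2.0, abs=1.0)
        assert d.min() >= 0.0 and d.max() <= 98.4

    def test_default_mixture_mode_sits_at_the_bragg_peak(self, rng):
        d = sample_emission_depth(EmissionModel(), BeamConfig(), rng, 100_000)
        counts, edges = np.histogram(d, bins=np.arange(0.0, 130.0, 1.0))
        mode = edges[np.argmax(counts)] + 0.5
        assert mode == pytest.approx(98.4, abs=1.0)

    def test_phantom_shift_translates_the_distribution(self):
        model = EmissionModel()
        d0 = sample_emission_depth(model, BeamConfig(phantom_shift=0.0),
                                   np.random.default_rng(3), 20_000)
        d30 = sample_emission_depth(model, BeamConfig(phantom_shift=30.0),
                                    np.random.default_rng(3), 20_000)
        assert np.allclose(d30 - d0, 30.0)


class TestKleinNishina:
    def _pdf_on_grid(self, e0):
        c = np.linspace(-1.0, 1.0, 4001)
        f = klein_nishina_pdf(c, e0)
        return c, f / integrate.trapezoid(f, c)

    def test_forward_peaked_mean_cosine_at_718_keV(self, rng):
        c, pdf = self._pdf_on_grid(718.0)
        mean_quad = integrate.trapezoid(c * pdf, c)
        assert mean_quad > 0.25  # quadrature oracle: distinctly forward-peaked
        theta = sample_klein_nishina(718.0, rng, 100_000)
        assert np.cos(np.deg2rad(theta)).mean() == pytest.approx(mean_quad, abs=0.01)

    def test_samples_follow_the_quadrature_cdf(self, rng):
        c, pdf = self._pdf_on_grid(718.0)
        cdf = integrate.cumulative_trapezoid(pdf, c, initial=0.0)
        cdf /= cdf[-1]
        samples = np.cos(np.deg2rad(sample_klein_nishina(718.0, rng, 10_000)))
        res = stats.ks_1samp(samples, lambda x: np.interp(x, c, cdf))
        assert res.pvalue > 0.01

    def test_low_energy_limit_is_symmetric_thomson(self, rng):
        theta = sample_klein_nishina(1.0, rng, 100_000)
        assert np.cos(np.deg2rad(theta)).mean() == pytest.approx(0.0, abs=0.02)


class TestEnergySmearing:
    def test_zero_resolution_is_identity(self, rng):
        resp = DetectorResponse(fwhm_frac_at_662=0.0)
        assert smear_energy(662.0, resp, rng) == 662.0

    def test_recovers_printed_resolution_at_662(self, rng):
        smeared = smear_energy(np.full(100_000, 662.0), DetectorResponse(), rng)
        fwhm_frac = 2.3548 * smeared.std() / 662.0
        assert fwhm_frac == pytest.approx(0.022, abs=0.001)

    def test_noise_sigma_at_662(self):
        # FWHM = 0.022 * 662 = 14.564 keV -> sigma = 6.18 keV
        assert energy_fwhm(662.0, DetectorResponse()) / 2.3548 == pytest.approx(6.18, abs=0.01)

    def test_sqrt_scaling_shrinks_fractional_width_at_higher_energy(self):
        resp = DetectorResponse(resolution_scaling="SQRT_E")
        assert energy_fwhm(1324.0, resp) / 1324.0 < energy_fwhm(662.0, resp) / 662.0
        const = DetectorResponse(resolution_scaling="CONSTANT_FRACTION")
        assert energy_fwhm(1324.0, const) / 1324.0 == pytest.approx(0.022)


class TestExposure:
    def test_default_run_delivers_6e11_ions(self):
        assert total_projectiles(BeamConfig()) == pytest.approx(6e11)

    @pytest.mark.parametrize("duration, expected", [(3.0, 3e9), (4.5, 3e9)])
    def test_partial_pulses_are_excluded(self, duration, expected):
        beam = BeamConfig(duration=duration)
        assert total_projectiles(beam) == pytest.approx(expected)


class TestGenerator:
    def test_empty_request_yields_empty_list(self, rng):
        cfg = make_noiseless_config()
        out = generate_events(cfg.beam, cfg.geometry, cfg.emission, cfg.response, 0, rng)
        assert out == []

    def test_noiseless_events_conserve_line_energy_and_kinematics(self, noiseless_events):
        assert len(noiseless_events) > 50
        for ev in noiseless_events:
            assert ev.total_energy == pytest.approx(718.0, abs=1e-9)

    def test_noiseless_cone_passes_through_the_true_emission_point(self, noiseless_events):
        for ev in noiseless_events:
            apex, axis, theta = cone_from_event(ev)
            u = np.asarray(ev.truth.emission_point) - apex
            alpha = np.arccos(np.clip(u @ axis / np.linalg.norm(u), -1.0, 1.0))
            assert abs(alpha - theta) < 1e-6

    def test_truth_tags_conserved_and_never_increase_through_filters(self, default_config):
        cfg = default_config
        rng = np.random.default_rng(cfg.seed)
        groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                                 cfg.response, 200, rng)
        n_signal_raw = sum(1 for g in groups if not g.truth.is_background)
        selected = select_compton_events(groups)
        n_signal_sel = sum(1 for ev in selected if not ev.truth.is_background)
        windowed = apply_energy_window(selected, cfg.windows.main)
        n_signal_win = sum(1 for ev in windowed if not ev.truth.is_background)
        assert n_signal_raw >= n_signal_sel >= n_signal_win > 0

    def test_hits_lie_on_their_layer_planes_inside_the_aperture(self, noiseless_events):
        geom = CameraGeometry()
        for ev in noiseless_events:
            s, a = ev.scatter_hit, ev.absorb_hit
            assert s.position[2] == pytest.approx(geom.si_layer_z(s.layer))
            assert a.position[2] == pytest.approx(geom.cdte_layer_z(a.layer))
            assert abs(s.position[0] - geom.camera_center_x) <= geom.half_side
            assert abs(s.position[1]) <= geom.half_side

    def test_timestamps_fall_in_beam_on_intervals(self, noiseless_events):
        beam = BeamConfig()
        for ev in noiseless_events:
            assert 0.0 <= ev.t_s < beam.duration
            assert ev.t_s % beam.pulse_period <= beam.pulse_on

    def test_background_dominated_spectrum_buries_the_line(self):
        # beam-on measurement regime: random coincidences vastly outnumber
        # the line, so the photopeak window is not resolvable in the summed
        # spectrum (<= 3x the neighbouring-window mean)
        cfg = make_noiseless_config(seed=9)
        cfg.response.fwhm_frac_at_662 = 0.022
        cfg.response.background_fraction = 0.98
        rng = np.random.default_rng(9)
        groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                                 cfg.response, 300, rng)
        selected = select_compton_events(groups)
        n_main = len(apply_energy_window(selected, cfg.windows.main))
        neighbours = [EnergyWindow("n", lo, lo + 20.0)
                      for lo in (608.0, 638.0, 668.0, 748.0, 778.0, 808.0)]
        mean_neigh = np.mean([len(apply_energy_window(selected, w)) for w in neighbours])
        assert n_main <= 3.0 * mean_neigh

    def test_zero_aperture_raises(self, rng):
        cfg = make_noiseless_config()
        with pytest.raises(ValueError):
            CameraGeometry(layer_side=0.0)
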