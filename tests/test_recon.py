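import math

import numpy as np
import pytest

from pgrange import (
    BackprojectionParams,
    ComptonEvent,
    Detector,
    EnergyPair,
    Hit,
    ImageGrid,
    Kernel,
    backproject,
    compute_cos_theta,
    cone_from_event,
    generate_events,
    select_compton_events,
    split_energy,
)

from conftest import make_noiseless_config


def make_event(e1, e2, scatter_pos=(98.0, 0.0, 168.0), absorb_pos=(99.0, 1.0, 176.0)):
    return ComptonEvent(
        scatter_hit=Hit(Detector.SI, 7, scatter_pos, e1),
        absorb_hit=Hit(Detector.CDTE, 0, absorb_pos, e2),
        event_id=17,
    )


def naive_backprojection(event, grid, params):
    """Independent per-pixel loop: the oracle the fast path must match."""
    apex, axis, theta = cone_from_event(event)
    sigma = math.radians(params.arm_fwhm) / math.sqrt(8.0 * math.log(2.0))
    values = np.zeros((grid.ny, grid.nx))
    for iy, y in enumerate(grid.y_centers):
        for ix, x in enumerate(grid.x_centers):
            v = np.array([x, y, 0.0]) - apex
            alpha = math.acos(max(-1.0, min(1.0, v @ axis / np.linalg.norm(v))))
            resid = alpha - theta
            if params.kernel is Kernel.GAUSSIAN_ARM:
                values[iy, ix] = math.exp(-0.5 * (resid / sigma) ** 2)
            else:
                values[iy, ix] = 1.0 if abs(resid) <= math.radians(params.shell_halfwidth) else 0.0
    if params.per_event_normalization and values.sum() > 0:
        values /= values.sum()
    return values


class TestConeFromEvent:
    def test_zero_recoil_gives_degenerate_ray(self):
        _, _, half_angle = cone_from_event(make_event(0.0, 718.0))
        assert half_angle == 0.0

    def test_axis_points_from_absorber_through_scatterer(self):
        ev = make_event(100.0, 618.0, scatter_pos=(0.0, 0.0, 140.0),
                        absorb_pos=(0.0, 0.0, 148.0))
        apex, axis, _ = cone_from_event(ev)
        assert np.allclose(apex, [0.0, 0.0, 140.0])
        assert np.allclose(axis, [0.0, 0.0, -1.0])

    def test_half_angle_matches_the_energy_pair(self):
        pair = split_energy(718.0, 40.0)
        ev = make_event(pair.e_scatter, pair.e_absorb)
        _, _, half_angle = cone_from_event(ev)
        assert half_angle == pytest.approx(math.radians(40.0), abs=1e-9)

    def test_invalid_kinematics_error_names_the_event(self):
        with pytest.raises(ValueError, match="17"):
            cone_from_event(make_event(600.0, 118.0))


class TestBackprojection:
    grid = ImageGrid.centered(98.4)

    @pytest.mark.parametrize("kernel", [Kernel.GAUSSIAN_ARM, Kernel.HARD_SHELL])
    def test_single_event_matches_naive_per_pixel_loop(self, kernel):
        pair = split_energy(718.0, 35.0)
        ev = make_event(pair.e_scatter, pair.e_absorb,
                        scatter_pos=(95.0, 3.0, 168.0), absorb_pos=(100.0, -2.0, 180.0))
        params = BackprojectionParams(kernel=kernel, shell_halfwidth=3.0)
        img = backproject([ev], self.grid, params)
        oracle = naive_backprojection(ev, self.grid, params)
        scale = max(oracle.max(), 1e-300)
        assert np.max(np.abs(img.values - oracle)) / scale < 1e-10

    def test_zero_events_gives_zero_image(self):
        img = backproject([], self.grid, BackprojectionParams())
        assert img.n_events == 0
        assert not img.values.any()

    def test_additive_over_event_partition(self):
        cfg = make_noiseless_config()
        rng = np.random.default_rng(21)
        groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                                 cfg.response, 40, rng)
        events = select_compton_events(groups)
        params = BackprojectionParams()
        whole = backproject(events, self.grid, params)
        parts = (backproject(events[:13], self.grid, params).values
                 + backproject(events[13:], self.grid, params).values)
        assert np.allclose(whole.values, parts, rtol=0, atol=1e-12)

    def test_normalized_total_mass_equals_event_count(self):
        cfg = make_noiseless_config()
        rng = np.random.default_rng(22)
        groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                                 cfg.response, 30, rng)
        events = select_compton_events(groups)
        img = backproject(events, self.grid, BackprojectionParams())
        # cones whose kernel support leaks outside the FOV carry less mass
        assert img.values.sum() <= img.n_events + 1e-6
        assert img.values.sum() > 0.5 * img.n_events

    def test_translation_equivariance(self):
        pair = split_energy(718.0, 30.0)
        dx, dy = 7.0, -4.0
        ev = make_event(pair.e_scatter, pair.e_absorb,
                        scatter_pos=(95.0, 0.0, 168.0), absorb_pos=(98.0, 2.0, 178.0))
        ev2 = make_event(pair.e_scatter, pair.e_absorb,
                         scatter_pos=(95.0 + dx, 0.0 + dy, 168.0),
                         absorb_pos=(98.0 + dx, 2.0 + dy, 178.0))
        g1 = ImageGrid.centered(98.4)
        g2 = ImageGrid.centered(98.4 + dx, dy)
        params = BackprojectionParams()
        assert np.allclose(backproject([ev], g1, params).values,
                           backproject([ev2], g2, params).values, atol=1e-12)

    def test_point_source_argmax_recovery(self):
        cfg = make_noiseless_config(seed=7, point_source=True)
        rng = np.random.default_rng(7)
        groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                                 cfg.response, 200, rng)
        events = select_compton_events(groups)
        assert len(events) >= 150
        img = backproject(events, cfg.grid, cfg.backprojection)
        iy, ix = np.unravel_index(np.argmax(img.values), img.values.shape)
        assert abs(cfg.grid.x_centers[ix] - 98.4) <= 2.0
        assert abs(cfg.grid.y_centers[iy]) <= 2.0

    def test_invalid_events_skipped_with_count(self, caplog):
        bad = make_event(600.0, 118.0)
        good_pair = split_energy(718.0, 30.0)
        good = make_event(good_pair.e_scatter, good_pair.e_absorb)
        with caplog.at_level("WARNING", logger="pgrange.recon"):
            img = backproject([bad, good], self.grid, BackprojectionParams())
        assert img.n_events == 1
        assert "1" in caplog.text


class TestImageGrid:
    def test_default_fov_is_200_by_200_at_1mm(self):
        grid = ImageGrid.centered(98.4)
        assert (grid.nx, grid.ny) == (200, 200)
        assert grid.x_centers[0] == pytest.approx(98.4 - 99.5)

    def test_non_multiple_extent_rejected(self):
        with pytest.raises(ValueError):
            ImageGrid(0.0, 10.5, 0.0, 10.0, pixel=1.0)
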