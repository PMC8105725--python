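"""Generator correctness: rendering identities, kinetic laws, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from myddo.core import Movie
from myddo.simulate import (GroundTruthPunctum, SimulationConfig, add_gaussian_spot,
                            simulate_calibration_stack, simulate_fixedcell_field,
                            simulate_frap_trace, simulate_kinetics, simulate_puncta_movie,
                            simulate_two_channel_movie)


class TestConfigValidation:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            simulate_puncta_movie(SimulationConfig(image_shape=(0, 64)))

    def test_rejects_huge_psf(self):
        with pytest.raises(ValueError):
            simulate_puncta_movie(SimulationConfig(image_shape=(32, 32), psf_sigma_px=10.0))

    @pytest.mark.parametrize("kwargs", [
        dict(p_grow=-0.1), dict(p_shrink=1.5), dict(gfp_unit_cv=-0.2),
        dict(pixel_size_um=0.0), dict(frame_interval_s=-1.0),
    ])
    def test_rejects_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestRendering:
    def test_zero_nucleation_gives_pure_noise_and_empty_truth(self, noise_free_config):
        movie, gt = simulate_puncta_movie(noise_free_config)
        assert gt == []
        assert np.all(movie.frames == 0.0)

    def test_single_monomer_integrates_to_unit_intensity(self, noise_free_config):
        """Pixel-integrated PSF: summed rendered signal equals the punctum
        brightness within the Gaussian truncation (<0.5%)."""
        frame = np.zeros((64, 64))
        add_gaussian_spot(frame, 32 * 0.15, 32 * 0.15, 500.0, sigma_px=1.1, pixel_size_um=0.15)
        assert frame.sum() == pytest.approx(500.0, rel=5e-3)

    def test_intensity_linearity_in_copy_number(self):
        """With noise off, integrated intensity / unit mean = n exactly."""
        cfg = SimulationConfig(image_shape=(64, 64), gfp_unit_cv=0.0, shot_noise=False,
                               read_noise_sd=0.0, camera_offset=0.0)
        for n in (1, 3, 7):
            frame = np.zeros((64, 64))
            add_gaussian_spot(frame, 4.8, 4.8, n * cfg.gfp_unit_mean, cfg.psf_sigma_px, cfg.pixel_size_um)
            assert frame.sum() / cfg.gfp_unit_mean == pytest.approx(n, rel=5e-3)

    def test_camera_offset_added_to_every_pixel(self):
        cfg = SimulationConfig(image_shape=(32, 32), n_frames=2, nucleation_rate=0.0,
                               shot_noise=False, read_noise_sd=0.0, camera_offset=100.0)
        movie, _ = simulate_puncta_movie(cfg)
        assert np.all(movie.frames == 100.0)


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_movie_and_truth(self):
        cfg = SimulationConfig(image_shape=(64, 64), n_frames=30, nucleation_rate=0.5, seed=7)
        m1, g1 = simulate_puncta_movie(cfg)
        m2, g2 = simulate_puncta_movie(cfg)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert len(g1) == len(g2)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.n, b.n)
            np.testing.assert_array_equal(a.x_um, b.x_um)

    def test_different_seed_differs(self):
        cfg1 = SimulationConfig(image_shape=(64, 64), n_frames=30, nucleation_rate=0.5, seed=7)
        cfg2 = SimulationConfig(image_shape=(64, 64), n_frames=30, nucleation_rate=0.5, seed=8)
        m1, _ = simulate_puncta_movie(cfg1)
        m2, _ = simulate_puncta_movie(cfg2)
        assert not np.array_equal(m1.frames, m2.frames)


class TestKinetics:
    def test_nucleation_count_matches_poisson_moments(self):
        """Total puncta over T frames ~ Poisson(rate*T): within 3 SD of the mean."""
        cfg = SimulationConfig(image_shape=(256, 256), n_frames=600, nucleation_rate=0.5,
                               p_grow=0.0, p_shrink=1.0, seed=0)
        gt = simulate_kinetics(cfg)
        lam = 0.5 * 600
        assert abs(len(gt) - lam) <= 3 * math.sqrt(lam)

    def test_ground_truth_invariants(self):
        cfg = SimulationConfig(image_shape=(128, 128), n_frames=120, nucleation_rate=1.0,
                               partner_size_threshold=5, seed=3)
        gt = simulate_kinetics(cfg)
        assert len(gt) > 0
        for g in gt:
            assert g.birth_frame <= g.death_frame
            assert np.all(g.n >= 1)
            assert g.lifetime_frames == g.n.size == g.x_um.size
            if g.partner_recruit_frame is not None:
                assert g.partner_recruit_frame >= g.birth_frame
                assert g.partner_recruit_frame <= g.death_frame

    def test_monomer_lifetimes_are_geometric(self):
        """With p_grow=0 and p_shrink=q, 1-mer lifetimes follow geometric(q):
        chi-square goodness of fit at alpha=0.01 over >=10^4 puncta."""
        q = 0.35
        cfg = SimulationConfig(image_shape=(512, 512), n_frames=700, nucleation_rate=20.0,
                               initial_size_range=(1, 1), p_grow=0.0, p_shrink=q, seed=99)
        gt = simulate_kinetics(cfg)
        lifetimes = np.array([g.lifetime_frames for g in gt if not g.censored])
        assert lifetimes.size >= 10_000
        kmax = 12
        observed = np.array([(lifetimes == k).sum() for k in range(1, kmax)]
                            + [(lifetimes >= kmax).sum()])
        probs = np.array([q * (1 - q) ** (k - 1) for k in range(1, kmax)])
        probs = np.append(probs, 1.0 - probs.sum())
        _, p = stats.chisquare(observed, probs * lifetimes.size)
        assert p > 0.01

    def test_stable_puncta_marked_and_growing(self):
        cfg = SimulationConfig(image_shape=(256, 256), n_frames=400, nucleation_rate=2.0,
                               stable_p_grow=0.2, stable_p_death=0.0, seed=5)
        gt = simulate_kinetics(cfg)
        stable = [g for g in gt if g.is_stable]
        transient = [g for g in gt if not g.is_stable]
        assert stable and transient
        assert all(g.max_n >= cfg.stable_size_threshold for g in stable)
        assert all(g.max_n < cfg.stable_size_threshold for g in transient)
        # stable puncta live longer on average: the two-population structure
        assert np.mean([g.lifetime_frames for g in stable]) > \
            3 * np.mean([g.lifetime_frames for g in transient])

    def test_max_size_cap_respected(self):
        cfg = SimulationConfig(image_shape=(128, 128), n_frames=300, nucleation_rate=2.0,
                               stable_p_grow=0.5, stable_p_death=0.0, max_size=8, seed=6)
        gt = simulate_kinetics(cfg)
        assert max(g.max_n for g in gt) <= 8


class TestCalibrationStack:
    def test_noise_free_emitters_have_unit_brightness(self, noise_free_config):
        movie, truth = simulate_calibration_stack(noise_free_config, n_emitters=50,
                                                  return_truth=True)
        assert np.all(truth["brightness"] == noise_free_config.gfp_unit_mean)
        # per-frame total signal = 50 emitters x unit intensity
        assert movie.frames[0].sum() == pytest.approx(50 * 500.0, rel=5e-3)

    def test_zero_bleach_rate_all_emitters_persist(self, noise_free_config):
        movie = simulate_calibration_stack(noise_free_config, n_emitters=40, bleach_rate=0.0)
        np.testing.assert_allclose(movie.frames[-1], movie.frames[0])

    def test_bleaching_follows_exponential_survival(self):
        """Surviving fraction at frame t ~ (1-k)^t ~ e^(-kt), within binomial error."""
        cfg = SimulationConfig(image_shape=(640, 640), n_frames=30, seed=8)
        k = 0.1
        _, truth = simulate_calibration_stack(cfg, n_emitters=400, bleach_rate=k,
                                              return_truth=True)
        n = len(truth)
        for t in (5, 10, 20):
            surv = (truth["bleach_frame"] > t).mean()
            expected = (1 - k) ** t
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(surv - expected) < 4 * se

    def test_refuses_overcrowded_field(self):
        cfg = SimulationConfig(image_shape=(32, 32), n_frames=1)
        with pytest.raises(ValueError, match="density"):
            simulate_calibration_stack(cfg, n_emitters=500)


class TestFrapTrace:
    def test_no_recovery_stays_at_floor(self):
        tr = simulate_frap_trace(prebleach_level=1000, bleach_depth=0.8,
                                 recovery_fraction=0.0, tau_s=30, n_frames=60, noise_sd=0.0)
        post = tr.intensity[tr.bleach_index:]
        np.testing.assert_allclose(post, 200.0)

    def test_full_recovery_returns_to_prebleach(self):
        tr = simulate_frap_trace(prebleach_level=1000, bleach_depth=0.8,
                                 recovery_fraction=1.0, tau_s=5, n_frames=400, noise_sd=0.0)
        assert tr.intensity[-1] == pytest.approx(1000.0, rel=1e-3)

    def test_recovery_matches_closed_form(self):
        """recovery_fraction 0.57, tau 30 s: normalized value at t=120 s is
        0.57*(1-exp(-4))."""
        tr = simulate_frap_trace(prebleach_level=1000, bleach_depth=1.0,
                                 recovery_fraction=0.57, tau_s=30.0, n_frames=130, noise_sd=0.0)
        t120 = tr.bleach_index + 120
        expected = 0.57 * (1 - math.exp(-4.0)) * 1000
        assert tr.intensity[t120] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("bad", [dict(bleach_depth=1.5), dict(recovery_fraction=-0.1),
                                     dict(tau_s=0.0)])
    def test_rejects_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            simulate_frap_trace(**bad)


class TestFixedCellField:
    def test_unit_ratio_field(self):
        channels, truth = simulate_fixedcell_field(n_cells=3, nuclear_ratio=1.0, seed=2)
        stain = channels["stain"]
        inside = stain[channels["marker"] > 0]
        assert np.all(inside == inside[0])

    def test_constructed_ratio_measured_on_truth_masks(self):
        channels, truth = simulate_fixedcell_field(n_cells=3, nuclear_ratio=3.0, seed=2)
        nuc = channels["dapi"] > 0.5
        cyto = (channels["marker"] > 0.5) & ~nuc
        ratio = channels["stain"][nuc].mean() / channels["stain"][cyto].mean()
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_rejects_impossible_packing(self):
        with pytest.raises(RuntimeError):
            simulate_fixedcell_field(n_cells=60, image_shape=(256, 256), seed=0)


class TestTwoChannel:
    def test_partner_channel_dark_before_recruitment(self):
        cfg = SimulationConfig(image_shape=(96, 96), n_frames=80, nucleation_rate=0.3,
                               partner_size_threshold=4, gfp_unit_cv=0.0, shot_noise=False,
                               read_noise_sd=0.0, camera_offset=0.0,
                               stable_p_death=0.0, seed=4)
        movie_a, movie_b, gt = simulate_two_channel_movie(cfg)
        recruited = [g for g in gt if g.partner_recruit_frame is not None]
        assert recruited, "config should produce at least one recruitment"
        first = min(g.partner_recruit_frame for g in recruited)
        assert np.all(movie_b.frames[:first] == 0.0)
        assert movie_b.frames[first:].sum() > 0
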