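"""Forward model: lamina sigmoid, LIF dynamics, medulla and lobula responses."""

import numpy as np
import pytest

from lobulanet.optic_lobe import (
    GainConfig,
    LifParams,
    N_LAMINA,
    SigmoidParams,
    VisualLobeWeights,
    init_visual_lobe,
    lamina_response,
    lif_rate,
    lif_rate_closed,
    lobula_response,
    medulla_response,
    sigmoid_activation,
)
from lobulanet.stimuli import PATCH_SIZE, make_moving_bar


class TestSigmoid:
    def test_midpoint_and_limits(self):
        assert sigmoid_activation(0.5) == pytest.approx(0.5)
        assert sigmoid_activation(1e3) == pytest.approx(1.0)
        assert sigmoid_activation(-1e3) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_activation(0.0) == pytest.approx(1 / (1 + np.exp(0.5)))

    def test_monotone_increasing(self):
        r = np.linspace(-5, 5, 101)
        out = sigmoid_activation(r)
        assert np.all(np.diff(out) > 0)


class TestLamina:
    def test_uniform_patches(self):
        dark = lamina_response(np.zeros((75, 75)))
        bright = lamina_response(np.ones((75, 75)))
        assert np.allclose(dark, 0.37754, atol=1e-5)
        assert np.allclose(bright, 1 / (1 + np.exp(-9 + 0.5)), atol=1e-9)

    def test_single_block_elevates_one_unit(self):
        patch = np.zeros((75, 75))
        patch[9:12, 30:33] = 1.0  # exactly one non-overlapping 3x3 block
        out = lamina_response(patch)
        baseline = sigmoid_activation(0.0)
        elevated = np.flatnonzero(out > baseline + 1e-9)
        assert len(elevated) == 1
        assert elevated[0] == (9 // 3) * 25 + 30 // 3

    def test_block_permutation_invariance(self, rng):
        patch = rng.random((75, 75))
        out1 = lamina_response(patch)
        shuffled = patch.copy()
        block = shuffled[3:6, 6:9].ravel()
        rng.shuffle(block)
        shuffled[3:6, 6:9] = block.reshape(3, 3)
        assert np.allclose(lamina_response(shuffled), out1)

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError, match="75x75"):
            lamina_response(np.zeros((74, 75)))


class TestLif:
    def test_subthreshold_silent(self):
        rate, spikes = lif_rate(-1.0)
        assert rate == 0 and len(spikes) == 0
        assert lif_rate_closed(-1.0) == 0
        assert lif_rate_closed(0.0) == 0

    @pytest.mark.parametrize("I", [0.5, 2.0, 16.0, 50.0])
    def test_isi_matches_closed_form(self, I):
        p = LifParams(duration=200.0)
        rate, spikes = lif_rate(I, p)
        isi_sim = np.diff(spikes).mean()
        drive = p.R * I
        isi_exact = p.tau_m * np.log((drive - p.v0) / (drive - p.VT))
        assert abs(isi_sim - isi_exact) < p.dt

    def test_reference_current(self):
        # I = 16: ISI = 10 ln(240/160) ~ 4.055 ms, rate ~ 246.6 spikes/s
        assert lif_rate_closed(16.0) == pytest.approx(246.63, abs=0.01)
        rate, spikes = lif_rate(16.0)
        assert np.diff(spikes)[0] == pytest.approx(4.055, abs=0.1)

    def test_halving_duration_halves_count(self):
        p1 = LifParams(duration=200.0)
        p2 = LifParams(duration=100.0)
        _, s1 = lif_rate(5.0, p1)
        _, s2 = lif_rate(5.0, p2)
        assert abs(len(s1) - 2 * len(s2)) <= 1

    def test_nonfinite_current_raises(self):
        with pytest.raises(ValueError):
            lif_rate(np.nan)


class TestMedulla:
    def test_zero_weights_silent(self):
        out = medulla_response(np.random.default_rng(0).random(N_LAMINA),
                               np.zeros(N_LAMINA))
        assert np.all(out.rates == 0)

    def test_noise_free_matches_closed_form(self, rng):
        lam = rng.random(N_LAMINA)
        w = rng.standard_normal(N_LAMINA) * 0.05
        gains = GainConfig(noise_scale=0.0)
        out = medulla_response(lam, w, gains=gains, noise_seed=3)
        expect = lif_rate_closed(gains.medulla_gain * w @ lam)
        assert out.rates[0] == pytest.approx(expect)

    def test_poisson_noise_preserves_mean(self, rng):
        lam = np.full(N_LAMINA, 0.8)
        w = np.full(N_LAMINA, 0.01)
        gains = GainConfig(noise_scale=1.0)
        base = medulla_response(lam, w, gains=GainConfig(noise_scale=0)).rates[0]
        draws = np.array([
            medulla_response(lam, w, gains=gains, noise_seed=s).rates[0]
            for s in range(1000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - base) < 3 * se + 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            medulla_response(np.zeros(N_LAMINA), np.zeros(10))


def _template_weights(n=4):
    """Weights whose unit 0 encodes a vertical bar stepping left to right."""
    rng = np.random.default_rng(0)
    W = rng.standard_normal((n, 5, N_LAMINA)) * 0.02
    side = 25
    for k in range(5):
        slice_img = np.full((side, side), -0.1)
        col = 5 + 3 * k  # bar advances 3 lamina px (= 9 photoreceptor px)
        slice_img[:, col:col + 2] = 1.0
        W[0, k] = slice_img.ravel()
    Q = np.zeros((n, n))
    return VisualLobeWeights(W=np.clip(W, -1, 1), Q=Q)


class TestLobula:
    def test_no_inhibition_is_lif_of_bank_sum(self):
        weights = _template_weights()
        scan = make_moving_bar(90.0, shift_px=9)
        gains = GainConfig(noise_scale=0)
        out = lobula_response(scan, weights, gains=gains)
        drive = out.extras["medulla_rates"].sum(axis=1)
        expect = lif_rate_closed(gains.lobula_gain * drive)
        assert np.allclose(out.rates, expect, atol=1e-3)

    def test_template_prefers_matching_motion(self):
        weights = _template_weights()
        gains = GainConfig(noise_scale=0)
        matched = lobula_response(make_moving_bar(90.0, shift_px=9),
                                  weights, gains=gains).rates[0]
        ortho = lobula_response(make_moving_bar(0.0, shift_px=9),
                                weights, gains=gains).rates[0]
        assert matched > ortho

    def test_stronger_inhibition_never_increases_rates(self, rng):
        gains = GainConfig(noise_scale=0)
        scan = make_moving_bar(45.0, shift_px=15)
        for _ in range(20):
            lobe = init_visual_lobe(8, seed=int(rng.integers(1 << 31)))
            r1 = lobula_response(scan, lobe, gains=gains).rates
            doubled = VisualLobeWeights(W=lobe.W, Q=np.clip(2 * lobe.Q, 0, 1))
            r2 = lobula_response(scan, doubled, gains=gains).rates
            # slack covers the 1e-3 fixed-point stopping tolerance
            assert np.all(r2 <= r1 + 5e-3)

    def test_seeded_forward_pass_reproducible(self):
        lobe = init_visual_lobe(8, seed=0)
        scan = make_moving_bar(90.0, shift_px=15)
        r1 = lobula_response(scan, lobe, rng=7).rates
        r2 = lobula_response(scan, lobe, rng=7).rates
        assert np.array_equal(r1, r2)

    def test_fixed_point_converges(self):
        lobe = init_visual_lobe(16, seed=2)
        scan = make_moving_bar(0.0, shift_px=15)
        out = lobula_response(scan, lobe, gains=GainConfig(noise_scale=0))
        assert out.extras["converged"]
        assert np.all(out.rates >= 0)


class TestWeightContainers:
    def test_bounds_validation(self):
        with pytest.raises(ValueError, match="W entries"):
            VisualLobeWeights(W=np.full((2, 5, N_LAMINA), 2.0), Q=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="diagonal"):
            VisualLobeWeights(W=np.zeros((2, 5, N_LAMINA)), Q=np.eye(2))

    def test_save_load_roundtrip(self, tmp_path):
        lobe = init_visual_lobe(4, seed=9)
        path = tmp_path / "w.npz"
        lobe.save(path)
        back = VisualLobeWeights.load(path)
        assert np.array_equal(back.W, lobe.W)
        assert np.array_equal(back.Q, lobe.Q)

    def test_init_distributions(self):
        lobe = init_visual_lobe(50, seed=3)
        assert lobe.W.min() >= -1 and lobe.W.max() <= 1
        assert lobe.Q.min() >= 0 and lobe.Q.max() <= 1
        assert np.all(np.diag(lobe.Q) == 0)
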