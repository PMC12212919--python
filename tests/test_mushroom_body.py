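"""Mushroom body: KC sparse coding, MBON readout, STDP kernels, conditioning."""

import numpy as np
import pytest

import lobulanet as ln
from lobulanet.mushroom_body import (
    KC_ACTIVE_FRACTION,
    StdpParams,
    choice_test,
    conditioning_trial,
    init_mushroom_body,
    kc_response,
    mbon_response,
    stdp_kernel,
)
from lobulanet.optic_lobe import GainConfig, LifParams
from lobulanet.experiments import pattern_scans


@pytest.fixture(scope="module")
def scan_pair():
    return pattern_scans(region="lower_half", shift_px=15)


class TestKenyonCells:
    def test_zero_input_zero_output(self):
        mb = init_mushroom_body(10, n_kc=100, seed=0)
        out = kc_response(np.zeros(10), mb)
        assert np.all(out.rates == 0)

    def test_active_fraction_bounded(self, rng):
        mb = init_mushroom_body(50, n_kc=2000, seed=1)
        for _ in range(20):
            r = rng.random(50) * 30
            out = kc_response(r, mb)
            assert out.extras["active"].mean() <= KC_ACTIVE_FRACTION + 1e-12

    def test_orthogonal_inputs_low_kc_overlap(self):
        # two lobula patterns with disjoint support activate KC sets with
        # low Jaccard overlap under random expansion
        overlaps = []
        for seed in range(30):
            mb = init_mushroom_body(50, n_kc=2000, seed=seed)
            r1 = np.zeros(50); r1[:25] = 20.0
            r2 = np.zeros(50); r2[25:] = 20.0
            a = set(np.flatnonzero(kc_response(r1, mb).extras["active"]))
            b = set(np.flatnonzero(kc_response(r2, mb).extras["active"]))
            overlaps.append(len(a & b) / max(len(a | b), 1))
        assert np.mean(overlaps) < 0.5

    def test_spike_trains_only_for_active(self, rng):
        mb = init_mushroom_body(10, n_kc=50, seed=2)
        out = kc_response(rng.random(10) * 20, mb, rng=rng)
        for k, spikes in enumerate(out.spikes):
            if out.rates[k] == 0:
                assert spikes is None


class TestMbon:
    def test_zero_weights_silent(self):
        mb = init_mushroom_body(10, n_kc=50, seed=0)
        kc = kc_response(np.random.default_rng(0).random(10) * 20, mb)
        out = mbon_response(kc, np.zeros(mb.n_kc))
        assert out.rates[0] == 0

    def test_scaling_weights_never_decreases_rate(self, rng):
        mb = init_mushroom_body(10, n_kc=200, seed=3)
        kc = kc_response(rng.random(10) * 25, mb)
        rates = [mbon_response(kc, c * mb.D).rates[0] for c in (0.5, 1.0, 2.0)]
        assert rates[0] <= rates[1] <= rates[2]

    def test_spiking_mode_tracks_rate_mode(self):
        # the Euler-integrated MBON driven by KC spike trains should agree on
        # average with the closed-form rate for the equivalent constant input
        mb = init_mushroom_body(20, n_kc=500, seed=4)
        lob = np.random.default_rng(7).random(20) * 25
        closed = mbon_response(kc_response(lob, mb), mb.D).rates[0]
        spiking = np.mean([
            mbon_response(kc_response(lob, mb, rng=np.random.default_rng(s)),
                          mb.D).rates[0]
            for s in range(30)
        ])
        assert abs(spiking - closed) < 0.35 * max(closed, 1.0)


class TestStdpKernel:
    def test_dopamine_closed_form(self):
        p = StdpParams()
        assert stdp_kernel(20.0, "dopamine", p) == pytest.approx(0.01 * np.exp(-1))
        assert stdp_kernel(-20.0, "dopamine", p) == pytest.approx(-0.01 * np.exp(-1))
        assert stdp_kernel(1e-9, "dopamine", p) == pytest.approx(0.01, rel=1e-6)

    def test_dopamine_odd_octopamine_even(self):
        dts = np.array([-40.0, -5.0, 5.0, 40.0])
        dop = stdp_kernel(dts, "dopamine")
        oct_ = stdp_kernel(dts, "octopamine")
        assert np.allclose(dop, -dop[::-1])
        assert np.all(oct_ < 0)
        assert np.allclose(oct_, oct_[::-1])

    def test_zero_lag_contributes_nothing(self):
        assert stdp_kernel(0.0, "dopamine") == 0
        assert stdp_kernel(0.0, "octopamine") == 0

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            stdp_kernel(1.0, "serotonin")


class TestConditioning:
    def test_silent_kc_never_updated(self, trained_lobe_small, scan_pair):
        rng = np.random.default_rng(0)
        mb = init_mushroom_body(16, n_kc=300, seed=0)
        d0 = mb.D.copy()
        conditioning_trial(scan_pair[0], "reward", trained_lobe_small, mb, rng)
        # untouched entries must be bitwise identical
        changed = mb.D != d0
        assert changed.sum() < mb.n_kc  # plenty of silent KCs remain
        assert np.array_equal(mb.D[~changed], d0[~changed])

    def test_reward_decreases_punishment_increases_mbon(
            self, trained_lobe_small, scan_pair):
        # noise-free visual input isolates the synaptic dynamics; KC and
        # MBON spiking stay stochastic
        rng = np.random.default_rng(5)
        quiet = GainConfig(noise_scale=0)
        mb_r = init_mushroom_body(16, n_kc=1000, seed=1)
        rates_r = [conditioning_trial(scan_pair[0], "reward",
                                      trained_lobe_small, mb_r, rng, gains=quiet)
                   for _ in range(40)]
        mb_p = init_mushroom_body(16, n_kc=1000, seed=1)
        rates_p = [conditioning_trial(scan_pair[1], "punishment",
                                      trained_lobe_small, mb_p, rng, gains=quiet)
                   for _ in range(40)]
        assert np.mean(rates_r[-10:]) < np.mean(rates_r[:10])
        assert np.mean(rates_p[-10:]) > np.mean(rates_p[:10])

    def test_octopamine_never_increases_d(self, trained_lobe_small, scan_pair):
        rng = np.random.default_rng(2)
        mb = init_mushroom_body(16, n_kc=500, seed=3)
        d0 = mb.D.copy()
        for _ in range(5):
            conditioning_trial(scan_pair[0], "reward", trained_lobe_small, mb, rng)
        assert np.all(mb.D <= d0 + 1e-12)

    def test_d_stays_in_bounds(self, trained_lobe_small, scan_pair):
        rng = np.random.default_rng(4)
        mb = init_mushroom_body(16, n_kc=300, seed=5)
        for _ in range(20):
            conditioning_trial(scan_pair[1], "punishment",
                               trained_lobe_small, mb, rng)
        assert mb.D.min() >= 0 and mb.D.max() <= 1

    def test_invalid_valence_raises(self, trained_lobe_small, scan_pair):
        mb = init_mushroom_body(16, n_kc=50, seed=0)
        with pytest.raises(ValueError):
            conditioning_trial(scan_pair[0], "neutral", trained_lobe_small,
                               mb, np.random.default_rng(0))


class TestChoice:
    def test_choice_is_plasticity_free(self, trained_lobe_small, scan_pair):
        rng = np.random.default_rng(0)
        mb = init_mushroom_body(16, n_kc=300, seed=7)
        S0, D0 = mb.S.copy(), mb.D.copy()
        for _ in range(5):
            choice_test(trained_lobe_small, mb, *scan_pair, rng=rng)
        assert np.array_equal(mb.S, S0)
        assert np.array_equal(mb.D, D0)

    def test_handbuilt_preference_wins(self, trained_lobe_small, scan_pair):
        # lower D on the KCs driven by pattern A -> lower MBON rate -> choose A
        rng = np.random.default_rng(1)
        mb = init_mushroom_body(16, n_kc=1000, seed=8)
        lob = ln.lobula_response(scan_pair[0], trained_lobe_small,
                                 gains=GainConfig(noise_scale=0))
        active_a = kc_response(lob.rates, mb).extras["active"]
        mb.D[active_a] = 0.0
        quiet = GainConfig(noise_scale=0)
        wins = sum(choice_test(trained_lobe_small, mb, *scan_pair, rng=rng,
                               gains=quiet).choice == 0
                   for _ in range(20))
        assert wins >= 15

    def test_untrained_bee_at_chance(self, trained_lobe_small, scan_pair):
        rng = np.random.default_rng(3)
        mb = init_mushroom_body(16, n_kc=1000, seed=9)
        wins = sum(choice_test(trained_lobe_small, mb, *scan_pair, rng=rng).choice == 0
                   for _ in range(200))
        # binomial 95% interval around 0.5 for n = 200
        assert 79 <= wins <= 121


class TestProtocol:
    def test_zero_exposures_is_chance(self, trained_lobe_small, scan_pair):
        proto = ln.ConditioningProtocol(n_exposures=0, n_bees=4, n_tests=40,
                                        n_kc=500, seed=0)
        table, curves = ln.run_protocol(proto, trained_lobe_small, *scan_pair)
        assert len(table) == 4
        assert 0.25 <= table.accuracy.mean() <= 0.75
        assert curves.empty

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ln.ConditioningProtocol(n_bees=0)
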