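"""Synthetic-data generator: trial mixes, noise spectrum, evoked linearity,
behavioural marginals, dataset determinism."""

import numpy as np
import pytest
from scipy import signal, stats

from dpxdyn.data import TimeAxis, WindowError
from dpxdyn.simulate import (
    BehaviourSpec,
    BlockSpec,
    EffectComponent,
    NoiseSpec,
    default_channel_set,
    default_cue_components,
    grid_channel_set,
    make_dataset,
    make_trial_sequence,
    simulate_behaviour,
    simulate_evoked,
    simulate_noise,
)


class TestTrialSequence:
    def test_standard_block_counts(self):
        t = make_trial_sequence(BlockSpec(), seed=0)
        assert len(t) == 258
        assert (t["pair"] == "AX").sum() == 180
        # exact per-block mix
        for b in (0, 1):
            blk = t[t["block"] == b]
            counts = blk["pair"].value_counts()
            assert counts["AX"] == 90 and counts["AY"] == 13
            assert counts["BX"] == 13 and counts["BY"] == 13

    def test_ax_share_per_block(self):
        t = make_trial_sequence(BlockSpec(n_blocks=1), seed=3)
        share = (t["pair"] == "AX").sum() / len(t)
        assert share == pytest.approx(90 / 129, abs=1e-12)

    def test_seeded_determinism(self):
        a = make_trial_sequence(BlockSpec(), seed=42)
        b = make_trial_sequence(BlockSpec(), seed=42)
        assert (a["pair"] == b["pair"]).all()

    def test_pair_consistent_with_cue_probe(self):
        t = make_trial_sequence(BlockSpec(), seed=1)
        assert (t["pair"] == t["cue"] + t["probe"]).all()

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty design"):
            make_trial_sequence(
                BlockSpec(n_AX=0, n_AY=0, n_BX=0, n_BY=0), seed=0
            )


class TestNoise:
    def test_zero_sds_give_zero_array(self, small_channels, small_axis):
        x = simulate_noise(
            3, small_channels, small_axis,
            NoiseSpec(background_sd=0.0, sensor_white_sd=0.0), seed=0,
        )
        assert not x.any()

    def test_determinism(self, small_channels, small_axis):
        a = simulate_noise(4, small_channels, small_axis, NoiseSpec(), seed=9)
        b = simulate_noise(4, small_channels, small_axis, NoiseSpec(), seed=9)
        assert np.array_equal(a, b)

    def test_spectral_slope_matches_exponent(self):
        # exponent 1.0, no lowpass so the slope is clean over the fit band
        ch = grid_channel_set(4)
        ax = TimeAxis.from_span(-0.5, 1.5, 128.0)
        spec = NoiseSpec(spectral_exponent=1.0, sensor_white_sd=0.0, lowpass=None)
        x = simulate_noise(200, ch, ax, spec, seed=5)
        f, p = signal.periodogram(x, fs=128.0, axis=-1)
        pm = p.mean(axis=(0, 1))
        sel = (f > 1) & (f < 40)
        slope = np.polyfit(np.log(f[sel]), np.log(pm[sel]), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_marginal_sd_calibrated(self, small_axis):
        ch = grid_channel_set(8)
        x = simulate_noise(300, ch, small_axis, NoiseSpec(), seed=2)
        expected = np.sqrt(NoiseSpec().background_sd ** 2 + NoiseSpec().sensor_white_sd ** 2)
        assert x.std() == pytest.approx(expected, rel=0.05)


class TestEvoked:
    def _setup(self):
        channels = default_channel_set()
        ax = TimeAxis.from_span(-0.5, 2.0, 64.0)
        trials = make_trial_sequence(BlockSpec(n_blocks=1), seed=0)
        return channels, ax, trials

    def test_zero_amplitudes_give_zero(self):
        channels, ax, trials = self._setup()
        comps = [
            EffectComponent(
                "null", np.ones(len(channels)), (0.1, 0.3), "bump",
                {p: 0.0 for p in ("AX", "AY", "BX", "BY")},
            )
        ]
        data, gt = simulate_evoked(trials, comps, channels, ax, seed=0)
        assert not data.any()
        assert not gt.masks["cue_B_minus_A"].any()

    def test_linearity_in_amplitudes(self):
        channels, ax, trials = self._setup()
        comps = default_cue_components(channels)
        doubled = [
            EffectComponent(
                c.name, c.topography, c.window, c.kernel,
                {p: 2 * a for p, a in c.amplitude_by_pair.items()}, 0.0,
            )
            for c in comps
        ]
        d1, _ = simulate_evoked(trials, comps, channels, ax, seed=0)
        d2, _ = simulate_evoked(trials, doubled, channels, ax, seed=0)
        assert np.allclose(d2, 2.0 * d1)

    def test_parietal_positivity_support_inside_window(self):
        channels, ax, trials = self._setup()
        comps = default_cue_components(channels)
        _, gt = simulate_evoked(trials, comps, channels, ax, seed=0)
        sup = gt.component_masks["cue_parietal_positivity"]
        t_on = ax.times[sup.any(axis=0)]
        assert t_on.min() >= 0.40 - 1e-9
        assert t_on.max() <= 0.75 + 1e-9
        # and it contributes to the B-minus-A contrast mask
        assert (gt.masks["cue_B_minus_A"] & sup).any()

    def test_window_outside_axis_raises(self):
        channels, ax, trials = self._setup()
        comp = EffectComponent(
            "late", np.ones(len(channels)), (3.0, 3.5), "bump", {"AX": 1.0}
        )
        with pytest.raises(WindowError):
            simulate_evoked(trials, [comp], channels, ax, seed=0)


class TestBehaviour:
    def test_zero_error_prob_all_correct(self):
        trials = make_trial_sequence(BlockSpec(), seed=0)
        spec = BehaviourSpec(error_prob_by_pair={p: 0.0 for p in ("AX", "AY", "BX", "BY")})
        out = simulate_behaviour(trials, spec, seed=1)
        assert out["correct"].all()
        assert (out.loc[out["pair"] == "AX", "response"] == "target").all()

    def test_determinism(self):
        trials = make_trial_sequence(BlockSpec(), seed=0)
        a = simulate_behaviour(trials, BehaviourSpec(), seed=5)
        b = simulate_behaviour(trials, BehaviourSpec(), seed=5)
        assert np.array_equal(a["rt"].to_numpy(), b["rt"].to_numpy())

    def test_rts_positive_and_lognormal_scale(self):
        trials = make_trial_sequence(BlockSpec(), seed=0)
        out = simulate_behaviour(trials, BehaviourSpec(), seed=2)
        assert (out["rt"] > 0).all()
        ax = out[(out["pair"] == "AX") & out["correct"].astype(bool)]
        assert 0.25 < ax["rt"].median() < 0.45


class TestMakeDataset:
    def test_smoke_and_invariants(self):
        subs, gt = make_dataset(2, channels=grid_channel_set(8), components=[],
                                seed=3, sfreq=64.0, epoch_span=(-0.25, 0.5))
        assert len(subs) == 2
        assert subs[0].data.shape[1] == 8
        assert gt.subject_scales.shape == (2,)

    def test_master_seed_determinism(self):
        a, _ = make_dataset(2, seed=11, sfreq=64.0, channels=grid_channel_set(8),
                            components=[], epoch_span=(-0.25, 0.5))
        b, _ = make_dataset(2, seed=11, sfreq=64.0, channels=grid_channel_set(8),
                            components=[], epoch_span=(-0.25, 0.5))
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_null_components_grand_average_near_zero(self):
        subs, _ = make_dataset(
            6, components=[], channels=grid_channel_set(8), seed=7,
            sfreq=64.0, epoch_span=(-0.25, 0.5),
        )
        grand = np.mean([s.data.mean(axis=0) for s in subs], axis=0)
        channel_means = grand.mean(axis=1)
        n_eff = sum(s.n_trials for s in subs)
        point_sd = np.sqrt(NoiseSpec().background_sd ** 2 + NoiseSpec().sensor_white_sd ** 2)
        # time-averaging positively correlated noise cannot exceed the
        # single-point variance, so this per-channel se bound is conservative
        se = point_sd / np.sqrt(n_eff)
        assert np.abs(channel_means).max() < 3.0 * se

    def test_rejects_no_subjects(self):
        with pytest.raises(ValueError):
            make_dataset(0, seed=0)
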