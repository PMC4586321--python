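import dataclasses

import numpy as np
import pandas as pd
import pytest

from predatt import behavior, erp, paradigm, synthetic
from predatt.epochs import EpochSet, sample_indices
from predatt.montage import standard_64_montage

from conftest import make_events, make_presses


def _epochs_from_events(events, presses, config, group="18-24", seed=0):
    epochs, _ = synthetic.simulate_subject(config, group, events, seed=seed)
    epochs = synthetic.annotate_press_adjacency(epochs, events, presses)
    outcomes = behavior.score_responses(events, presses)
    return epochs, outcomes


def brute_force_exclusions(events, outcomes):
    """Independent rule scanner: re-derives rules 1/3/4/5 from the raw
    category sequence by explicit look-back/look-ahead (no shared code with
    erp.select_trials)."""
    cats = events["category"].astype(str).tolist()
    blocks = events["block"].tolist()
    n = len(cats)
    targets = set(paradigm.TARGET_CATEGORIES)
    flags = {"after_target": [False] * n, "potential_predS2": [False] * n,
             "missed_target": [False] * n,
             "insufficient_standards": [False] * n}
    for i in range(n):
        same = lambda j: 0 <= j < n and blocks[j] == blocks[i]
        if cats[i] not in targets and same(i - 1) and cats[i - 1] in targets:
            flags["after_target"][i] = True
        if (cats[i] == "randS2" and same(i - 1) and cats[i - 1] == "randS1"
                and not (same(i + 1) and cats[i + 1] == "randS3")):
            flags["potential_predS2"][i] = True
        if cats[i] in targets:
            if outcomes.loc[i, "outcome"] != "hit":
                flags["missed_target"][i] = True
            prev = [j for j in (i - 1, i - 2, i - 3) if same(j)]
            if len(prev) < 3 or any(cats[j] in targets for j in prev):
                flags["insufficient_standards"][i] = True
    return flags


class TestSelectTrials:
    def test_standard_after_target_excluded(self, noise_free_config):
        events = make_events(["randS1", "randT", "randS1", "randS2", "randS3"])
        epochs, outcomes = _epochs_from_events(
            events, make_presses([]), noise_free_config)
        sel = erp.select_trials(epochs, outcomes)
        assert sel.exclusions.loc[2, "after_target"]
        assert not sel.exclusions.loc[3, "after_target"]

    def test_potential_predS2_excluded(self, noise_free_config):
        events = make_events(["randS1", "randS2", "randT", "randS1",
                              "randS2", "randS3"])
        epochs, outcomes = _epochs_from_events(
            events, make_presses([events.loc[2, "onset_ms"] + 400.0]),
            noise_free_config)
        sel = erp.select_trials(epochs, outcomes)
        assert sel.exclusions.loc[1, "potential_predS2"]   # no randS3 follows
        assert not sel.exclusions.loc[4, "potential_predS2"]

    def test_press_adjacent_standards_excluded(self, noise_free_config):
        events = make_events(["randS1", "randS2", "randS3", "randS1"])
        # false alarm 400 ms after the second standard
        epochs, outcomes = _epochs_from_events(
            events, make_presses([events.loc[1, "onset_ms"] + 400.0]),
            noise_free_config)
        sel = erp.select_trials(epochs, outcomes)
        assert sel.exclusions.loc[1, "press_adjacent"]     # right before press
        assert sel.exclusions.loc[2, "press_adjacent"]     # right after press
        assert not sel.exclusions.loc[3, "press_adjacent"]

    def test_missed_target_and_insufficient_standards(self, noise_free_config):
        events = make_events(["randS1", "randT", "randS1", "randS2", "randS3",
                              "randT"])
        # only the second target is hit
        epochs, outcomes = _epochs_from_events(
            events, make_presses([events.loc[5, "onset_ms"] + 300.0]),
            noise_free_config)
        sel = erp.select_trials(epochs, outcomes)
        assert sel.exclusions.loc[1, "missed_target"]
        assert sel.exclusions.loc[1, "insufficient_standards"]  # position 1
        assert not sel.exclusions.loc[5, "missed_target"]
        assert not sel.exclusions.loc[5, "insufficient_standards"]

    def test_artifact_threshold(self, noise_free_config):
        events = make_events(["randS1", "randS2", "randS3"])
        epochs, outcomes = _epochs_from_events(
            events, make_presses([]), noise_free_config)
        epochs.data[1, 0, 100] = 150.0          # inject a large transient
        sel = erp.select_trials(epochs, outcomes)
        assert sel.exclusions["artifact"].tolist() == [False, True, False]

    def test_rules_match_brute_force_scanner(self, noise_free_config,
                                             two_block_session):
        """Full-session cross-check of rules 1/3/4/5 against an independent
        scanner (no presses near standards in this noise-free stream)."""
        cfg = noise_free_config
        epochs, presses = synthetic.simulate_subject(
            cfg, "18-24", two_block_session, seed=4)
        outcomes = behavior.score_responses(two_block_session, presses)
        sel = erp.select_trials(epochs, outcomes)
        oracle = brute_force_exclusions(two_block_session, outcomes)
        for rule, expected in oracle.items():
            assert sel.exclusions[rule].tolist() == expected, rule

    def test_exclusions_idempotent(self, noise_free_config, two_block_session):
        cfg = noise_free_config
        epochs, presses = synthetic.simulate_subject(
            cfg, "14-17", two_block_session, seed=5)
        outcomes = behavior.score_responses(two_block_session, presses)
        a = erp.select_trials(epochs, outcomes).exclusions
        b = erp.select_trials(erp.select_trials(epochs, outcomes),
                              outcomes).exclusions
        pd.testing.assert_frame_equal(a, b)

    def test_missing_metadata_rejected(self, noise_free_config):
        events = make_events(["randS1", "randS2"])
        epochs, outcomes = _epochs_from_events(
            events, make_presses([]), noise_free_config)
        broken = dataclasses.replace(
            epochs, trial_meta=epochs.trial_meta.drop(
                columns=["preceding_category"]))
        with pytest.raises(ValueError, match="neighbor"):
            erp.select_trials(broken, outcomes)


class TestEqualize:
    def _selected(self, config, session, seed=6):
        epochs, presses = synthetic.simulate_subject(
            config, "12-14", session, seed=seed)
        outcomes = behavior.score_responses(session, presses)
        return erp.select_trials(epochs, outcomes)

    def test_larger_condition_subsampled_to_smaller(self, noise_free_config,
                                                    two_block_session):
        sel = self._selected(noise_free_config, two_block_session)
        eq = erp.equalize_pairs(sel, ("randS1", "predS1"), seed=0)
        cats = eq.trial_meta["category"].astype(str)
        assert (cats == "randS1").sum() == (cats == "predS1").sum()
        assert eq.clean_mask().all()

    def test_equal_counts_identity(self, noise_free_config, two_block_session):
        sel = self._selected(noise_free_config, two_block_session)
        clean_cats = sel.trial_meta["category"].astype(str)[sel.clean_mask()]
        eq = erp.equalize_pairs(sel, ("randT", "predT"), seed=1)
        n_pred = (clean_cats == "predT").sum()
        n_rand = (clean_cats == "randT").sum()
        cats = eq.trial_meta["category"].astype(str)
        assert (cats == "randT").sum() == (cats == "predT").sum() == \
            min(n_pred, n_rand)

    def test_determinism_under_seed(self, noise_free_config, two_block_session):
        sel = self._selected(noise_free_config, two_block_session)
        a = erp.equalize_pairs(sel, ("randS2", "predS2"), seed=3)
        b = erp.equalize_pairs(sel, ("randS2", "predS2"), seed=3)
        pd.testing.assert_frame_equal(a.trial_meta, b.trial_meta)

    def test_empty_condition_named_in_error(self, noise_free_config):
        events = make_events(["randS1", "randS2", "randS3"])
        epochs, outcomes = _epochs_from_events(
            events, make_presses([]), noise_free_config)
        sel = erp.select_trials(epochs, outcomes)
        with pytest.raises(ValueError, match="predS1"):
            erp.equalize_pairs(sel, ("randS1", "predS1"), seed=0)


def _flat_epochs(values_per_trial, categories, sfreq=512.0,
                 window=(-700.0, 800.0), n_ch=2):
    """Epochs with constant per-trial values on every channel/sample."""
    n_samples = len(sample_indices(window, sfreq))
    data = np.zeros((len(values_per_trial), n_ch, n_samples))
    for i, v in enumerate(values_per_trial):
        data[i] = v
    meta = pd.DataFrame({
        "category": categories, "block": 0,
        "position": np.arange(len(categories)),
        "onset_ms": np.arange(len(categories)) * paradigm.SOA_MS,
        "preceding_category": None, "following_category": None,
        "followed_by_press": False, "preceded_by_press": False,
    })
    return EpochSet(data=data, trial_meta=meta,
                    channel_labels=tuple(f"ch{i}" for i in range(n_ch)),
                    sfreq=sfreq, window_ms=window)


class TestAverage:
    def test_pointwise_mean(self):
        eps = _flat_epochs([1.0, 3.0], ["randS1", "randS1"])
        e = erp.average_erp(eps, "randS1")
        assert np.allclose(e.waveform, 2.0)
        assert e.n_trials == 2

    def test_baseline_correction_removes_constant(self):
        eps = _flat_epochs([2.0], ["randS1"])
        e = erp.average_erp(eps, "randS1", baseline=(-100.0, 0.0))
        assert np.allclose(e.waveform, 0.0)
        assert e.baseline == (-100.0, 0.0)

    def test_pooled_standards_weights_categories_equally(self):
        # 2 trials of randS1 at +3, 1 trial each of randS2/randS3 at 0:
        # trial-weighted mean would be 1.5; category-weighted mean is 1.0
        eps = _flat_epochs([3.0, 3.0, 0.0, 0.0],
                           ["randS1", "randS1", "randS2", "randS3"])
        e = erp.average_erp(eps, "standards")
        assert np.allclose(e.waveform, 1.0)
        assert e.n_trials == 4

    def test_zero_trials_error(self):
        eps = _flat_epochs([1.0], ["randS1"])
        with pytest.raises(ValueError):
            erp.average_erp(eps, "predT")

    def test_average_commutes_with_baseline(self, noise_free_subject):
        epochs, _ = noise_free_subject
        e1 = erp.apply_baseline(erp.average_erp(epochs, "randT"))
        # trial-wise baseline then average
        t = epochs.times_ms
        mask = (t >= -100.0) & (t < 0.0)
        shifted = epochs.data - epochs.data[:, :, mask].mean(
            axis=2, keepdims=True)
        e2 = dataclasses.replace(epochs, data=shifted)
        e2 = erp.average_erp(e2, "randT")
        assert np.allclose(e1.waveform, e2.waveform, atol=1e-4)


class TestFilter:
    def _tone(self, freq_hz, sfreq=512.0, window=(-10_000.0, 10_000.0)):
        # long window so the 0.5 Hz high-pass edge transient dies out
        idx = sample_indices(window, sfreq)
        t = idx / sfreq
        wave = np.sin(2 * np.pi * freq_hz * t)[None, :]
        return erp.Erp("randS1", wave, 1, ("ch0",), sfreq, window)

    def test_passband_preserves_10hz(self):
        e = erp.bandpass_filter(self._tone(10.0))
        n = e.waveform.shape[1]
        central = e.waveform[0, n // 4: 3 * n // 4]
        assert np.abs(central).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuates_60hz(self):
        e = erp.bandpass_filter(self._tone(60.0))
        n = e.waveform.shape[1]
        central = e.waveform[0, n // 4: 3 * n // 4]
        # documented stopband floor: ~-50 dB at 60 Hz after forward-backward
        assert np.abs(central).max() < 5e-3

    def test_dc_removed(self):
        window = (-10_000.0, 10_000.0)
        idx = sample_indices(window, 512.0)
        wave = np.full((1, len(idx)), 5.0)
        e = erp.Erp("randS1", wave, 1, ("ch0",), 512.0, window)
        out = erp.bandpass_filter(e)
        n = out.waveform.shape[1]
        assert np.abs(out.waveform[0, n // 4: 3 * n // 4]).max() < 0.05

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            erp.bandpass_filter(self._tone(10.0), low=30.0, high=0.5)


class TestMeasurement:
    def _erp_from_time_course(self, tc_fn, sfreq=512.0, window=(-700.0, 800.0)):
        idx = sample_indices(window, sfreq)
        t_ms = idx / sfreq * 1000.0
        wave = tc_fn(t_ms)[None, :]
        return erp.Erp("randT", wave, 1, ("CPz",), sfreq, window)

    def test_cnv_mean_of_linear_ramp(self):
        # ramp 0 µV at -300 ms to -6 µV at 0 ms: mean over [-150, 0) = -4.5
        ramp = lambda t: np.where((t >= -300) & (t <= 0), -6 * (t + 300) / 300, 0.0)
        e = self._erp_from_time_course(ramp)
        got = erp.measure_mean(e, "CPz", (-150.0, 0.0))
        assert got == pytest.approx(-4.5, abs=0.05)

    def test_p3_peak_of_gaussian(self):
        bump = lambda t: 8.0 * np.exp(-0.5 * ((t - 400.0) / 60.0) ** 2)
        e = self._erp_from_time_course(bump)
        amp, lat = erp.measure_peak(e, "CPz")
        assert lat == pytest.approx(400.0, abs=1000.0 / 512.0)
        assert amp == pytest.approx(8.0, rel=1e-3)

    def test_flat_waveform_measures_zero(self):
        e = self._erp_from_time_course(lambda t: np.zeros_like(t))
        assert erp.measure_mean(e, "CPz", (-150.0, 0.0)) == 0.0
        assert erp.measure_mean(e, "CPz", (350.0, 600.0)) == 0.0
        amp, _ = erp.measure_peak(e, "CPz")
        assert amp == 0.0

    def test_peak_tie_breaks_to_earliest(self):
        plateau = lambda t: np.where((t >= 300) & (t <= 500), 5.0, 0.0)
        e = self._erp_from_time_course(plateau)
        _, lat = erp.measure_peak(e, "CPz")
        assert lat == pytest.approx(300.0, abs=1000.0 / 512.0)

    def test_missing_electrode_error(self):
        e = self._erp_from_time_course(lambda t: np.zeros_like(t))
        with pytest.raises(KeyError):
            erp.measure_mean(e, "Oz", (-150.0, 0.0))

    def test_noise_free_recovery_of_generator_truth(self, noise_free_config,
                                                    noise_free_subject):
        """On noise-free epochs the measured CNV/P3 amplitudes and P3 peak
        latency equal the analytic values implied by the generator config."""
        cfg = noise_free_config
        epochs, presses = noise_free_subject
        outcomes = behavior.score_responses(
            epochs.trial_meta[["onset_ms", "category", "block", "position"]],
            presses)
        sel = erp.select_trials(epochs, outcomes)
        dt_ms = 1000.0 / cfg.sfreq
        for cond in ("randT", "predT", "randS3", "predS3"):
            e = erp.average_erp(sel, cond)
            eb = erp.apply_baseline(e)
            for el in ("Fz", "Cz", "Pz", "CPz"):
                cnv = erp.measure_mean(e, el, erp.CNV_WINDOW_MS)
                exp_cnv = synthetic.expected_cnv_amp(cfg, "18-24", cond, el)
                slope = abs(cfg.cnv_params["18-24"][cond].slope_uv_per_s)
                assert cnv == pytest.approx(exp_cnv,
                                            abs=slope * dt_ms / 1000.0 + 1e-6)
                p3 = erp.measure_mean(eb, el, erp.P3_WINDOW_MS)
                exp_p3 = synthetic.expected_p3_amp(cfg, "18-24", cond, el)
                assert p3 == pytest.approx(exp_p3, abs=0.05)
            if cond.endswith("T"):
                _, lat = erp.measure_peak(eb, "CPz")
                assert lat == pytest.approx(
                    synthetic.expected_p3_peak_latency(cfg, "18-24", cond),
                    abs=dt_ms + 1e-9)


class TestNormalization:
    def test_three_four_five(self):
        assert np.allclose(erp.normalize_topography([3.0, 4.0]), [0.6, 0.8])

    def test_sign_preserved(self):
        assert np.allclose(erp.normalize_topography([-3.0, -4.0]), [-0.6, -0.8])

    def test_scale_invariance_and_unit_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 10))
            if np.linalg.norm(v) == 0:
                continue
            n1 = erp.normalize_topography(v)
            n2 = erp.normalize_topography(17.3 * v)
            assert np.allclose(n1, n2)
            assert np.linalg.norm(n1) == pytest.approx(1.0)
            assert (np.argsort(np.abs(n1)) == np.argsort(np.abs(v))).all()

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            erp.normalize_topography([0.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def montage64():
    return standard_64_montage()


class TestSphericalSpline:
    def _erp_with_field(self, montage, field):
        window, sfreq = (-700.0, 800.0), 512.0
        n = len(sample_indices(window, sfreq))
        wave = np.tile(field[:, None], (1, n))
        return erp.Erp("randS1", wave, 1, tuple(montage.labels), sfreq, window)

    def test_constant_field_reproduced(self, montage64):
        e = self._erp_with_field(montage64, np.full(64, 3.7))
        out = erp.interpolate_channels(e, ["Cz"], montage64)
        i = out.channel_index("Cz")
        assert np.allclose(out.waveform[i], 3.7, atol=1e-3)

    def test_low_order_harmonic_field(self, montage64):
        """A smooth dipolar field (first-order spherical harmonic) is
        recovered at a held-out electrode within a small tolerance."""
        z = montage64.positions[:, 2]
        field = 5.0 * z                       # Y_1^0 up to scale
        e = self._erp_with_field(montage64, field)
        for bad in ("Fz", "Pz"):
            out = erp.interpolate_channels(e, [bad], montage64)
            i = out.channel_index(bad)
            assert out.waveform[i, 0] == pytest.approx(field[i], abs=0.15)

    def test_good_channels_untouched(self, montage64):
        rng = np.random.default_rng(1)
        e = self._erp_with_field(montage64, rng.normal(size=64))
        out = erp.interpolate_channels(e, ["POz"], montage64)
        for lb in montage64.labels:
            if lb == "POz":
                continue
            i = out.channel_index(lb)
            assert np.array_equal(out.waveform[i], e.waveform[i])

    def test_too_many_bad_channels_rejected(self, montage64):
        e = self._erp_with_field(montage64, np.ones(64))
        with pytest.raises(ValueError):
            erp.interpolate_channels(e, ["Fz", "Cz", "Pz"], montage64)
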