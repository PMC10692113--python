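"""Synthetic generator: sequences, confound, forward model, cohort, IO."""

import numpy as np
import pytest
from scipy import signal as sps

from babytrf.features import phonetic_feature_matrix
from babytrf.io import (
    load_dataset,
    load_stimulus,
    load_truth,
    load_weights,
    save_dataset,
    save_stimulus,
    save_truth,
    save_weights,
)
from babytrf.simulate import (
    SimConfig,
    default_spectral_templates,
    generate_phoneme_sequence,
    generate_stimulus_features,
    make_channel_labels,
    make_kernels,
    pink_noise,
    simulate_eeg_from_kernels,
    simulate_longitudinal_cohort,
)
from babytrf.trf import LagWindow, TRFModel, lag_design_matrix


class TestPhonemeSequence:
    def test_deterministic_for_fixed_rng(self, inventory):
        a = generate_phoneme_sequence(inventory, 8.0, 10.0,
                                      np.random.default_rng(3))
        b = generate_phoneme_sequence(inventory, 8.0, 10.0,
                                      np.random.default_rng(3))
        assert a == b

    def test_sorted_nonoverlapping_tiling(self, inventory, rng):
        al = generate_phoneme_sequence(inventory, 8.0, 20.0, rng)
        for prev, cur in zip(al, al[1:]):
            assert cur.onset == pytest.approx(prev.offset)
        assert al[0].onset == 0.0
        assert al[-1].offset <= 20.0 + 1e-9

    def test_mean_rate_matches_request(self, inventory, rng):
        al = generate_phoneme_sequence(inventory, 8.0, 200.0, rng)
        durs = np.array([a.offset - a.onset for a in al])
        # log-normal with mean 1/rate; SE of the mean over ~1600 draws
        se = durs.std() / np.sqrt(len(durs))
        assert abs(durs.mean() - 1.0 / 8.0) < 3 * se + 1e-3

    def test_label_frequencies_near_uniform(self, rng):
        labels = ["B", "P", "S", "IY"]
        al = generate_phoneme_sequence(labels, 50.0, 200.0, rng)
        counts = np.array([sum(a.label == l for a in al) for l in labels])
        n = counts.sum()
        se = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 3 * se)

    def test_custom_label_probs(self, rng):
        al = generate_phoneme_sequence(["B", "S"], 20.0, 100.0, rng,
                                       label_probs={"B": 1.0, "S": 0.0})
        assert all(a.label == "B" for a in al)

    def test_bad_rate_raises(self, inventory, rng):
        with pytest.raises(ValueError):
            generate_phoneme_sequence(inventory, -1.0, 10.0, rng)


def _r2(y, X):
    """OLS R^2 of y on [X, 1] — oracle, not package code."""
    Xa = np.column_stack([X, np.ones(len(y))])
    resid = y - Xa @ np.linalg.lstsq(Xa, y, rcond=None)[0]
    return 1.0 - resid.var() / y.var()


class TestStimulusFeatures:
    def _trial(self, inventory, confound, seed, duration=60.0, fs=50.0):
        r = np.random.default_rng(seed)
        templates = default_spectral_templates(inventory, r)
        al = generate_phoneme_sequence(inventory, 8.0, duration,
                                       np.random.default_rng(seed + 1))
        return generate_stimulus_features(
            al, templates, confound, fs, duration, np.random.default_rng(seed + 2),
            inventory=inventory), al

    def test_shapes_and_nonnegativity(self, inventory):
        stim, _ = self._trial(inventory, 0.5, 10, duration=10.0)
        assert stim.S.shape == (500, 8)
        assert stim.F.shape == (500, 14)
        assert stim.D.shape == (500,) and stim.V.shape == (500,)
        assert (stim.S >= 0).all() and (stim.D >= 0).all() and (stim.V >= 0).all()

    def test_f_matches_features_module_exactly(self, inventory):
        stim, al = self._trial(inventory, 0.5, 11, duration=10.0)
        ref = phonetic_feature_matrix(al, inventory, 50.0, 10.0)
        assert np.array_equal(stim.F, ref)

    def test_zero_templates_give_zero_s_and_d(self, inventory, rng):
        al = generate_phoneme_sequence(inventory, 8.0, 5.0, rng)
        templates = {ph: np.zeros(8) for ph in inventory.phonemes}
        stim = generate_stimulus_features(al, templates, 0.5, 50.0, 5.0, rng,
                                          inventory=inventory)
        assert np.allclose(stim.S, 0.0) and np.allclose(stim.D, 0.0)
        assert stim.F.any()

    def test_confound_strength_monotone_in_s_f_coupling(self, inventory):
        # the multiplicative prosody envelope hides the coupling in raw S;
        # the spectral SHAPE (rows normalised to sum 1) is prosody-invariant
        # and its predictability from F must grow with the confound strength
        r2s = []
        for confound in (0.0, 0.5, 1.0):
            stim, _ = self._trial(inventory, confound, seed=99)
            tot = stim.S.sum(axis=1)
            mask = tot > 1e-6 * tot.max()
            shape = stim.S[mask] / tot[mask][:, None]
            Xa = np.column_stack([stim.F[mask],
                                  np.ones(mask.sum())])
            resid = shape - Xa @ np.linalg.lstsq(Xa, shape, rcond=None)[0]
            r2s.append(1.0 - resid.var() / shape.var())
        assert r2s[0] < r2s[1] < r2s[2]

    def test_missing_template_raises(self, inventory, rng):
        from babytrf.config import DataError
        from babytrf.features import PhonemeAlignment

        with pytest.raises(DataError):
            generate_stimulus_features(
                [PhonemeAlignment("B", 0.0, 0.2)], {}, 0.5, 50.0, 1.0, rng,
                inventory=inventory)


class TestForwardModel:
    def _kernels(self, rng, n_scalp=4, fs=50.0, tmax=0.4):
        n_lags = int(round(tmax * fs)) + 1
        ak = make_kernels(8, n_lags, n_scalp, fs, rng)
        pk = make_kernels(14, n_lags, n_scalp, fs, rng)
        return ak, pk, n_lags

    def test_noiseless_eeg_is_exact_convolution(self, inventory, rng):
        ak, pk, n_lags = self._kernels(rng)
        templates = default_spectral_templates(inventory, rng)
        al = generate_phoneme_sequence(inventory, 8.0, 8.0, rng)
        stim = generate_stimulus_features(al, templates, 0.5, 50.0, 8.0, rng,
                                          inventory=inventory)
        eeg = simulate_eeg_from_kernels(stim, ak, pk, gain=0.7, noise_sd=0.0,
                                        rng=rng)
        w = LagWindow(0.0, (n_lags - 1) / 50.0, 50.0)
        expected = (lag_design_matrix(stim.S, w) @ ak.reshape(-1, 4)
                    + 0.7 * lag_design_matrix(stim.F, w) @ pk.reshape(-1, 4)).T
        assert np.allclose(eeg.data[:4], expected)

    def test_channel_layout_scalp_mastoid_facial(self, inventory, rng):
        ak, pk, _ = self._kernels(rng)
        templates = default_spectral_templates(inventory, rng)
        al = generate_phoneme_sequence(inventory, 8.0, 4.0, rng)
        stim = generate_stimulus_features(al, templates, 0.5, 50.0, 4.0, rng,
                                          inventory=inventory)
        eeg = simulate_eeg_from_kernels(stim, ak, pk, gain=1.0, noise_sd=1.0,
                                        rng=rng, n_facial=4, n_mastoids=2)
        assert eeg.n_channels == 10
        assert eeg.channel_labels[:4] == ["E01", "E02", "E03", "E04"]
        assert eeg.mastoid_labels == ("M1", "M2")
        assert eeg.channel_labels[-4:] == ["FA1", "FA2", "FA3", "FA4"]

    def test_nan_kernel_rejected(self, inventory, rng):
        ak, pk, _ = self._kernels(rng)
        ak[0, 0, 0] = np.nan
        templates = default_spectral_templates(inventory, rng)
        al = generate_phoneme_sequence(inventory, 8.0, 2.0, rng)
        stim = generate_stimulus_features(al, templates, 0.5, 50.0, 2.0, rng,
                                          inventory=inventory)
        with pytest.raises(ValueError):
            simulate_eeg_from_kernels(stim, ak, pk, 1.0, 1.0, rng)

    def test_noise_sd_scales_with_signal(self, inventory, rng):
        ak, pk, _ = self._kernels(rng)
        templates = default_spectral_templates(inventory, rng)
        al = generate_phoneme_sequence(inventory, 8.0, 40.0, rng)
        stim = generate_stimulus_features(al, templates, 0.5, 50.0, 40.0, rng,
                                          inventory=inventory)
        clean = simulate_eeg_from_kernels(stim, ak, pk, 1.0, 0.0,
                                          np.random.default_rng(0))
        noisy = simulate_eeg_from_kernels(stim, ak, pk, 1.0, 2.0,
                                          np.random.default_rng(0))
        resid = noisy.data[:4] - clean.data[:4]
        target = 2.0 * clean.data[:4].std(axis=1).mean()
        assert abs(resid.std() - target) / target < 0.15


class TestPinkNoise:
    def test_unit_sd_per_row(self, rng):
        x = pink_noise((5, 4096), rng)
        assert np.allclose(x.std(axis=1), 1.0)

    def test_spectral_slope_near_minus_one(self, rng):
        x = pink_noise((8, 2 ** 14), rng, slope=1.0)
        f, P = sps.welch(x, fs=1.0, nperseg=2048, axis=-1)
        band = (f > 0.01) & (f < 0.3)
        slope = np.polyfit(np.log(f[band]), np.log(P.mean(axis=0)[band]), 1)[0]
        assert abs(slope + 1.0) < 0.2


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = SimConfig(seed=777, n_participants=2, n_trials=2,
                    trial_duration=4.0, fs=25.0, n_channels=10,
                    session_gains={"4mo": 0.0, "11mo": 1.0})
    return cfg, simulate_longitudinal_cohort(cfg)


class TestCohort:
    def test_structure_and_shapes(self, tiny_cohort):
        cfg, (cohort, truth) = tiny_cohort
        assert cohort.participants == ["P01", "P02"]
        assert cohort.sessions == ["4mo", "11mo"]
        assert cohort.trial_ids == ["trial00", "trial01"]
        rec = cohort.eeg["P01"]["4mo"]["trial00"][0]
        assert rec.data.shape == (10, 100)
        assert len(cohort.montage) == 10
        assert truth.acoustic_kernels.shape == (8, 11, 4)
        assert truth.phonetic_kernels.shape == (14, 11, 4)

    def test_repetition_dropout_bounds(self, tiny_cohort):
        cfg, (cohort, _) = tiny_cohort
        for pid in cohort.participants:
            for sess in cohort.sessions:
                for reps in cohort.eeg[pid][sess].values():
                    assert 2 <= len(reps) <= cfg.n_repetitions

    def test_same_seed_byte_identical(self, tiny_cohort):
        cfg, (cohort, truth) = tiny_cohort
        cohort2, truth2 = simulate_longitudinal_cohort(cfg)
        a = cohort.eeg["P02"]["11mo"]["trial01"][0].data
        b = cohort2.eeg["P02"]["11mo"]["trial01"][0].data
        assert a.tobytes() == b.tobytes()
        assert truth.phonetic_kernels.tobytes() == \
            truth2.phonetic_kernels.tobytes()

    def test_different_seed_differs(self, tiny_cohort):
        cfg, (cohort, _) = tiny_cohort
        cfg2 = SimConfig(**{**cfg.__dict__, "seed": 778})
        cohort2, _ = simulate_longitudinal_cohort(cfg2)
        assert not np.array_equal(cohort.eeg["P01"]["4mo"]["trial00"][0].data,
                                  cohort2.eeg["P01"]["4mo"]["trial00"][0].data)

    def test_stimuli_shared_across_participants(self, tiny_cohort):
        # one stimulus dict keyed by trial, independent of participant/session
        cfg, (cohort, _) = tiny_cohort
        assert set(cohort.eeg["P01"]["4mo"]) == set(cohort.stimuli)
        assert set(cohort.eeg["P02"]["11mo"]) == set(cohort.stimuli)

    def test_missing_seed_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            SimConfig(seed=None)


class TestIO:
    def test_dataset_round_trip(self, tiny_cohort, tmp_path):
        cfg, (cohort, _) = tiny_cohort
        p = tmp_path / "cohort.h5"
        save_dataset(p, cohort)
        back = load_dataset(p)
        assert back.participants == cohort.participants
        assert back.sessions == cohort.sessions
        a = cohort.eeg["P01"]["4mo"]["trial00"][0]
        b = back.eeg["P01"]["4mo"]["trial00"][0]
        assert np.array_equal(a.data, b.data)
        assert a.channel_labels == b.channel_labels
        assert np.array_equal(back.stimuli["trial01"].S,
                              cohort.stimuli["trial01"].S)
        assert np.allclose(back.montage.to_numpy(), cohort.montage.to_numpy())

    def test_truth_never_in_dataset_payload(self, tiny_cohort, tmp_path):
        import h5py

        cfg, (cohort, _) = tiny_cohort
        p = tmp_path / "cohort.h5"
        save_dataset(p, cohort)
        names = []
        with h5py.File(p, "r") as f:
            f.visit(names.append)
        assert not any("kernel" in n.lower() or "truth" in n.lower()
                       or "gain" in n.lower() for n in names)

    def test_truth_round_trip(self, tiny_cohort, tmp_path):
        cfg, (_, truth) = tiny_cohort
        p = tmp_path / "truth.h5"
        save_truth(p, truth)
        back = load_truth(p)
        assert np.array_equal(back.phonetic_kernels, truth.phonetic_kernels)
        assert back.session_gains == truth.session_gains
        assert np.array_equal(back.participant_kernels["P01"][0],
                              truth.participant_kernels["P01"][0])

    def test_stimulus_round_trip(self, tiny_cohort, tmp_path):
        import h5py

        cfg, (cohort, _) = tiny_cohort
        stim = cohort.stimuli["trial00"]
        with h5py.File(tmp_path / "s.h5", "w") as f:
            save_stimulus(f.create_group("s"), stim)
        with h5py.File(tmp_path / "s.h5", "r") as f:
            back = load_stimulus(f["s"])
        for name in ("S", "D", "F", "V"):
            assert np.array_equal(getattr(back, name), getattr(stim, name))
        assert back.fs == stim.fs and back.trial_id == stim.trial_id

    def test_weights_round_trip(self, rng, tmp_path):
        w = LagWindow(-0.1, 0.5, 50.0)
        m = TRFModel(weights=rng.standard_normal((3, w.n_lags, 4)),
                     bias=rng.standard_normal(4), lam=10.0, window=w,
                     feature_names=["a", "b", "c"], penalty="identity")
        p = tmp_path / "w.h5"
        save_weights(p, {"full": m})
        back = load_weights(p)["full"]
        assert np.array_equal(back.weights, m.weights)
        assert back.lam == 10.0 and back.penalty == "identity"
        assert back.window.n_lags == w.n_lags
        assert back.feature_names == ["a", "b", "c"]
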