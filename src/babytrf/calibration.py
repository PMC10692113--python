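"""Scaled simulation experiments for calibrating the FS-S gain statistic.

These helpers run the core method — cross-validated full vs reduced TRF
models against a cohort ground-truth EEG — on compact synthetic cohorts, so
that repeated-cohort experiments (null calibration of the gain statistic,
age-effect recovery) finish at desk scale.  The stimuli are shared across
participants (as in the study), which also lets the lagged design matrices
be computed once per cohort.

The default experiment sizes here are deliberately smaller than the
generator's study-scale defaults (fewer/shorter trials, a reduced montage,
a 25 Hz analysis rate); they keep the statistic's sampling behaviour while
making hundreds of cohort replicates tractable.
"""

from __future__ import annotations

import numpy as np

from .config import LAMBDA_GRID, MODELS_GAIN
from .preprocess import zero_phase_bandpass
from .simulate import SimConfig, simulate_longitudinal_cohort
from .trf import LagWindow, _TrialCache, cross_validated_fit_predict, prediction_gain

__all__ = ["CalibrationSettings", "cohort_gains", "null_rejection_rate",
           "age_effect_replicates"]


class CalibrationSettings:
    """Compact cohort conditions for repeated-simulation experiments."""

    def __init__(self, n_participants: int = 15, n_trials: int = 3,
                 trial_duration: float = 20.0, fs: float = 25.0,
                 n_scalp: int = 8, noise_sd: float = 1.0,
                 confound_strength: float = 0.5,
                 band: tuple[float, float] = (1.0, 4.0),
                 lag_window: tuple[float, float] = (-0.1, 0.5),
                 grid: tuple[float, ...] = LAMBDA_GRID):
        self.n_participants = n_participants
        self.n_trials = n_trials
        self.trial_duration = trial_duration
        self.fs = fs
        self.n_scalp = n_scalp
        self.noise_sd = noise_sd
        self.confound_strength = confound_strength
        self.band = band
        self.lag_window = lag_window
        self.grid = grid

    def sim_config(self, seed: int, session_gains: dict[str, float]) -> SimConfig:
        return SimConfig(
            seed=seed, n_participants=self.n_participants,
            session_gains=dict(session_gains), n_trials=self.n_trials,
            trial_duration=self.trial_duration, fs=self.fs,
            n_channels=self.n_scalp, n_facial=0, n_mastoids=0,
            noise_sd=self.noise_sd, confound_strength=self.confound_strength,
            n_repetitions=1, dropout=0.0)


def cohort_gains(settings: CalibrationSettings, session_gains: dict[str, float],
                 seed: int) -> dict[str, np.ndarray]:
    """Per-participant FS-S gains for each session of one simulated cohort.

    Follows the study's scoring path: band-filter the EEG, build the cohort
    ground-truth trace per trial (grand mean over channels and
    participants), then leave-one-trial-out cross-validation of the full
    (S, D, V, F) and reduced (S, D, V) models with nested lambda tuning.
    """
    cfg = settings.sim_config(seed, session_gains)
    cohort, _ = simulate_longitudinal_cohort(cfg)
    window = LagWindow(settings.lag_window[0], settings.lag_window[1], cfg.fs)
    L = window.n_lags
    full_cols = np.arange((8 + 1 + 1 + 14) * L)
    reduced_cols = np.arange((8 + 1 + 1) * L)

    # lagged design matrices are shared across participants and sessions
    from .trf import lag_design_matrix
    lagged = {}
    for tid, stim in cohort.stimuli.items():
        feats, _ = stim.stack(("S", "D", "V", "F"))
        X = lag_design_matrix(feats, window)
        lagged[tid] = (X, X.T @ X, X.sum(axis=0))

    lo, hi = settings.band
    banded = {
        pid: {sess: {tid: zero_phase_bandpass(reps[0].data, lo, hi, fs=cfg.fs)
                     for tid, reps in trials.items()}
              for sess, trials in sessions.items()}
        for pid, sessions in cohort.eeg.items()}

    out: dict[str, np.ndarray] = {}
    for session in cohort.sessions:
        truth = {}
        for tid in cohort.trial_ids:
            grand = np.mean([banded[p][session][tid].mean(axis=0)
                             for p in cohort.participants], axis=0)
            truth[tid] = grand
        gains = []
        for pid in cohort.participants:
            caches = [
                _TrialCache(lagged[tid][0], banded[pid][session][tid].T, tid,
                            G=lagged[tid][1], sx=lagged[tid][2])
                for tid in cohort.trial_ids]
            scores = {}
            for name, cols in (("full", full_cols), ("reduced", reduced_cols)):
                sub = [c.subset(cols) for c in caches]
                scores[name] = cross_validated_fit_predict(
                    sub, truth, window, grid=settings.grid, model=name,
                    band="delta", participant=pid, session=session)
            gains.append(prediction_gain(scores["full"], scores["reduced"]).gain)
        out[session] = np.asarray(gains)
    return out


def null_rejection_rate(settings: CalibrationSettings, n_cohorts: int,
                        seed: int, alpha: float = 0.05) -> tuple[float, list[float]]:
    """Type-I behaviour of the gain statistic under a zero phonetic gain.

    Simulates ``n_cohorts`` independent cohorts with the phonetic kernels
    switched off (but the acoustic S<->F confound on), runs the one-sample
    Wilcoxon on each cohort's gains, and returns the rejection rate at
    ``alpha`` plus all p-values.
    """
    from .stats import wilcoxon_signed_rank

    ss = np.random.SeedSequence(seed)
    pvals = []
    for child in ss.spawn(n_cohorts):
        cohort_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        gains = cohort_gains(settings, {"s1": 0.0}, cohort_seed)["s1"]
        pvals.append(wilcoxon_signed_rank(gains).p)
    rate = float(np.mean([p <= alpha for p in pvals]))
    return rate, pvals


def age_effect_replicates(settings: CalibrationSettings,
                          session_gains: dict[str, float],
                          n_replicates: int, seed: int,
                          alpha: float = 0.05) -> dict[str, float]:
    """Recovery of an increasing phonetic gain across sessions.

    For each replicate cohort: the repeated-measures ANOVA on per-session
    FS-S gains, and whether the session-mean gains are strictly increasing.
    Returns the fraction of replicates with a significant age effect and
    the fraction with strictly increasing means.
    """
    from .stats import rm_anova_oneway

    ss = np.random.SeedSequence(seed)
    sig, increasing = [], []
    for child in ss.spawn(n_replicates):
        cohort_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        gains = cohort_gains(settings, session_gains, cohort_seed)
        table = np.column_stack([gains[s] for s in session_gains])
        res = rm_anova_oneway(table)
        sig.append(res.p <= alpha)
        means = table.mean(axis=0)
        increasing.append(bool(np.all(np.diff(means) > 0)))
    return {"significant_fraction": float(np.mean(sig)),
            "increasing_fraction": float(np.mean(increasing)),
            "n_replicates": n_replicates}
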