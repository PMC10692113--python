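"""Synthetic stimuli and longitudinal EEG cohorts with known ground truth.

Emulates the study conditions end-to-end without any real data: nursery-
rhyme-like phoneme sequences, correlated S/F stimulus streams (the acoustic
confound the FS-S statistic must be invariant to), multi-channel EEG built
as lagged linear convolution of S and F with smooth channel-specific
kernels plus 1/f noise, and a three-session longitudinal structure in which
the phonetic kernel gain increases with "age".

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning; the hidden kernels and gains (``SimTruth``) are returned as a
separate artifact and never enter the dataset payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import ANALYSIS_FS, PHONETIC_FEATURE_NAMES, DataError
from .features import (
    FeatureInventory,
    PhonemeAlignment,
    StimulusFeatures,
    envelope_and_derivative,
    phonetic_feature_matrix,
)
from .preprocess import EEGRecording
from .trf import LagWindow, lag_design_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "CohortData",
    "generate_phoneme_sequence",
    "default_spectral_templates",
    "generate_stimulus_features",
    "make_kernels",
    "simulate_eeg_from_kernels",
    "simulate_participant",
    "simulate_longitudinal_cohort",
    "make_montage",
    "make_channel_labels",
    "pink_noise",
]


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Synthetic-cohort parameters.

    Defaults mirror the study conditions: a 47-infant longitudinal cohort
    recorded at three ages, 18 nursery-rhyme trials per session at the 50 Hz
    analysis rate, 64 channels (58 scalp + 2 mastoids + 4 facial), noise at
    signal level, and a phonetic kernel gain that grows across sessions
    (absent at the first age, present and stronger thereafter).
    """

    seed: int
    n_participants: int = 47
    session_gains: dict[str, float] = field(
        default_factory=lambda: {"4mo": 0.0, "7mo": 0.5, "11mo": 1.0})
    n_trials: int = 18
    trial_duration: float = 20.0
    fs: float = ANALYSIS_FS
    n_channels: int = 64
    n_facial: int = 4
    n_mastoids: int = 2
    noise_sd: float = 1.0            # relative to mean scalp signal SD
    confound_strength: float = 0.5   # 1 = S fully determined by phoneme identity
    kernel_smoothness: float = 0.04  # bump width (s)
    kernel_tmax: float = 0.4         # kernel support (s), within the lag window
    phoneme_rate: float = 8.0        # phonemes per second
    lead_in: float = 0.5             # silent seconds before the first word
    n_repetitions: int = 3
    dropout: float = 0.2             # chance of losing a repetition beyond 2
    participant_kernel_jitter: float = 0.3
    pink_fraction: float = 0.8       # share of noise power with a 1/f spectrum
    pink_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if any(g < 0 for g in self.session_gains.values()):
            raise ValueError("session gains must be >= 0")
        if self.trial_duration <= 0 or self.fs <= 0:
            raise ValueError("durations and rates must be positive")

    @property
    def n_scalp(self) -> int:
        return self.n_channels - self.n_facial - self.n_mastoids

    @property
    def sessions(self) -> list[str]:
        return list(self.session_gains)


@dataclass
class SimTruth:
    """Hidden generator parameters, retained only for recovery tests."""

    acoustic_kernels: np.ndarray        # 8 x L x scalp channels (cohort level)
    phonetic_kernels: np.ndarray        # 14 x L x scalp channels
    participant_kernels: dict[str, tuple[np.ndarray, np.ndarray]]
    session_gains: dict[str, float]
    kernel_lags: np.ndarray
    fs: float
    noise_sd: float


@dataclass
class CohortData:
    """Synthetic dataset payload: stimuli, EEG, montage — no hidden truth."""

    stimuli: dict[str, StimulusFeatures]                       # trial_id ->
    eeg: dict[str, dict[str, dict[str, list[EEGRecording]]]]   # pid/session/trial
    montage: pd.DataFrame
    fs: float
    facial_labels: list[str]
    mastoid_labels: tuple[str, str]
    sessions: list[str]

    @property
    def participants(self) -> list[str]:
        return list(self.eeg)

    @property
    def trial_ids(self) -> list[str]:
        return list(self.stimuli)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def make_channel_labels(n_channels: int, n_facial: int = 4,
                        n_mastoids: int = 2) -> tuple[list[str], list[str], tuple[str, str]]:
    """Channel labels: scalp E01.., mastoids M1/M2, facial FA1.. ."""
    n_scalp = n_channels - n_facial - n_mastoids
    if n_scalp < 1:
        raise ValueError("n_channels too small for the requested montage")
    scalp = [f"E{i + 1:02d}" for i in range(n_scalp)]
    mastoids = tuple(f"M{i + 1}" for i in range(n_mastoids))
    facial = [f"FA{i + 1}" for i in range(n_facial)]
    return scalp + list(mastoids) + facial, facial, mastoids  # type: ignore[return-value]


def make_montage(labels: Sequence[str]) -> pd.DataFrame:
    """Deterministic quasi-uniform positions on the upper unit sphere."""
    n = len(labels)
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 0.05 + 0.95 * (i + 0.5) / n          # upper hemisphere-ish shell
    r = np.sqrt(np.maximum(1 - z ** 2, 0))
    theta = golden * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pd.DataFrame(pos, columns=["x", "y", "z"], index=list(labels))


# ---------------------------------------------------------------------------
# phoneme sequences and stimulus streams
# ---------------------------------------------------------------------------

def generate_phoneme_sequence(
    inventory: FeatureInventory | Sequence[str],
    rate: float,
    duration: float,
    rng: np.random.Generator,
    label_probs: Mapping[str, float] | None = None,
    duration_sigma: float = 0.4,
) -> list[PhonemeAlignment]:
    """Non-overlapping phoneme alignments tiling [0, duration].

    Phoneme durations are log-normal with mean 1/rate; labels are drawn from
    ``label_probs`` (uniform over the inventory by default).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    labels = (inventory.phonemes if isinstance(inventory, FeatureInventory)
              else list(inventory))
    if duration * rate < 1:
        raise ValueError("duration too short for a single phoneme at this rate")
    if label_probs is not None:
        labels = list(label_probs)
        probs = np.array([label_probs[l] for l in labels], dtype=float)
        probs = probs / probs.sum()
    else:
        probs = np.full(len(labels), 1.0 / len(labels))
    mu = np.log(1.0 / rate) - duration_sigma ** 2 / 2.0
    out: list[PhonemeAlignment] = []
    t = 0.0
    min_dur = 0.2 / rate
    while t < duration - min_dur:
        d = float(rng.lognormal(mu, duration_sigma))
        d = min(d, duration - t)
        if d < min_dur:
            break
        label = labels[int(rng.choice(len(labels), p=probs))]
        out.append(PhonemeAlignment(label, t, t + d))
        t += d
    return out


def default_spectral_templates(
    inventory: FeatureInventory,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-phoneme 8-band spectral templates, driven by the feature vectors.

    Templates are positive, distinct across phonemes, and structured so that
    phonemes sharing articulatory features have similar spectra (the source
    of the acoustic-phonetic confound).
    """
    W = rng.normal(0.0, 1.0, size=(8, len(PHONETIC_FEATURE_NAMES)))
    templates = {}
    for ph in inventory.phonemes:
        v = inventory.vector(ph)
        base = np.abs(W @ v) + 0.3 * np.abs(rng.normal(0.0, 1.0, 8))
        templates[ph] = base / max(base.mean(), 1e-12)
    return templates


def generate_stimulus_features(
    alignments: Sequence[PhonemeAlignment],
    templates: Mapping[str, np.ndarray],
    confound_strength: float,
    fs: float,
    duration: float,
    rng: np.random.Generator,
    inventory: FeatureInventory | None = None,
    trial_id: str = "",
) -> StimulusFeatures:
    """Build S, D, F, V for one synthetic trial.

    F comes from :func:`babytrf.features.phonetic_feature_matrix` (exact
    reuse).  S places each phoneme's spectral template over its samples with
    per-instance log-normal spectral jitter of width ``1 - confound_strength``
    (so the S<->F coupling grows with the confound strength), scaled by a
    slow random prosodic envelope and smoothed.  D is the rectified envelope
    derivative; V is smoothed noise, independent of the audio.
    """
    inv = inventory or FeatureInventory.default()
    n = int(round(duration * fs))
    F = phonetic_feature_matrix(alignments, inv, fs, duration)

    S0 = np.zeros((n, 8))
    jitter_sd = max(0.0, 1.0 - confound_strength)
    for a in alignments:
        if a.label not in templates:
            raise DataError(f"no spectral template for phoneme {a.label!r}")
        i0 = int(round(a.onset * fs))
        i1 = max(int(round(a.offset * fs)), i0 + 1)
        tpl = np.asarray(templates[a.label], dtype=float)
        inst = tpl * np.exp(rng.normal(0.0, jitter_sd, 8)) if jitter_sd > 0 else tpl
        S0[i0:min(i1, n)] = inst
    prosody = np.exp(gaussian_filter1d(rng.normal(0.0, 0.5, n), sigma=0.2 * fs))
    S = gaussian_filter1d(S0 * prosody[:, None], sigma=0.03 * fs, axis=0)
    S = np.clip(S, 0.0, None)
    _, D = envelope_and_derivative(S)
    V = np.clip(gaussian_filter1d(np.abs(rng.normal(0.0, 1.0, n)),
                                  sigma=0.1 * fs), 0.0, None)
    return StimulusFeatures(S=S, D=D, F=F, V=V, fs=fs, trial_id=trial_id)


# ---------------------------------------------------------------------------
# kernels, noise, EEG
# ---------------------------------------------------------------------------

def make_kernels(
    n_features: int,
    n_lags: int,
    n_channels: int,
    fs: float,
    rng: np.random.Generator,
    smoothness: float = 0.04,
    n_bumps: int = 3,
) -> np.ndarray:
    """Smooth random TRF kernels: Gaussian-bump mixtures times a topography.

    Each feature gets a temporal profile (mixture of 2-3 Gaussian bumps over
    the kernel support) and a smooth random channel map; the kernel is their
    outer product.  Shape: (n_features, n_lags, n_channels).
    """
    lags_s = np.arange(n_lags) / fs
    kernels = np.empty((n_features, n_lags, n_channels))
    for f in range(n_features):
        profile = np.zeros(n_lags)
        for _ in range(int(rng.integers(2, n_bumps + 1))):
            center = rng.uniform(0.03, lags_s[-1] * 0.95)
            width = smoothness * rng.uniform(0.6, 1.6)
            amp = rng.normal(0.0, 1.0)
            profile += amp * np.exp(-0.5 * ((lags_s - center) / width) ** 2)
        topo = gaussian_filter1d(rng.normal(0.0, 1.0, n_channels),
                                 sigma=max(n_channels / 12.0, 1.0), mode="wrap")
        topo /= max(np.abs(topo).max(), 1e-12)
        kernels[f] = np.outer(profile, topo)
    return kernels


def pink_noise(shape: tuple[int, ...], rng: np.random.Generator,
               slope: float = 1.0) -> np.ndarray:
    """Unit-SD noise with a 1/f**slope power spectrum along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-slope / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def simulate_eeg_from_kernels(
    features: StimulusFeatures,
    acoustic_kernels: np.ndarray,
    phonetic_kernels: np.ndarray,
    gain: float,
    noise_sd: float,
    rng: np.random.Generator,
    n_facial: int = 4,
    n_mastoids: int = 2,
    pink_fraction: float = 0.8,
    pink_slope: float = 1.0,
    participant_id: str = "",
    session: str = "",
    repetition: int = 0,
) -> EEGRecording:
    """Forward-generate one trial's EEG from the hidden kernels.

    Scalp channels are the lagged convolution of S with the acoustic kernels
    plus ``gain`` times the convolution of F with the phonetic kernels, plus
    mixed pink/white noise whose SD is ``noise_sd`` times the mean scalp
    signal SD.  Mastoid channels carry a small reference-consistent share of
    the common signal; facial channels carry noise only.
    """
    for k in (acoustic_kernels, phonetic_kernels):
        if not np.isfinite(k).all():
            raise ValueError("kernels must be finite (no NaN)")
    if acoustic_kernels.shape[1] != phonetic_kernels.shape[1]:
        raise ValueError("kernel lag spans must match")
    n_lags = acoustic_kernels.shape[1]
    n_scalp = acoustic_kernels.shape[2]
    fs = features.fs
    window = LagWindow(0.0, (n_lags - 1) / fs, fs)

    Xs = lag_design_matrix(features.S, window)
    Xf = lag_design_matrix(features.F, window)
    signal = (Xs @ acoustic_kernels.reshape(-1, n_scalp)
              + gain * (Xf @ phonetic_kernels.reshape(-1, n_scalp)))
    signal = signal.T                                  # channels x time
    sig_sd = signal.std(axis=1).mean()
    base_sd = noise_sd * (sig_sd if sig_sd > 0 else 1.0)

    labels, facial, mastoids = make_channel_labels(
        n_scalp + n_facial + n_mastoids, n_facial, n_mastoids)
    n_all = len(labels)
    T = features.n_samples
    pink = pink_noise((n_all, T), rng, slope=pink_slope)
    white = rng.standard_normal((n_all, T))
    noise = base_sd * (np.sqrt(pink_fraction) * pink
                       + np.sqrt(1.0 - pink_fraction) * white)

    data = np.empty((n_all, T))
    data[:n_scalp] = signal + noise[:n_scalp]
    common = signal.mean(axis=0)
    for m in range(n_mastoids):
        data[n_scalp + m] = 0.05 * common + noise[n_scalp + m]
    data[n_scalp + n_mastoids:] = noise[n_scalp + n_mastoids:]
    return EEGRecording(
        data=data, fs=fs, channel_labels=labels, mastoid_labels=mastoids,
        participant_id=participant_id, session=session,
        trial_id=features.trial_id, repetition=repetition,
    )


# ---------------------------------------------------------------------------
# participants and cohorts
# ---------------------------------------------------------------------------

def _jitter_kernels(kernels: np.ndarray, jitter: float, fs: float,
                    rng: np.random.Generator,
                    smoothness: float) -> np.ndarray:
    if jitter <= 0:
        return kernels.copy()
    scale = jitter * np.abs(kernels).std()
    noise = gaussian_filter1d(rng.normal(0.0, 1.0, kernels.shape),
                              sigma=max(smoothness * fs, 1.0), axis=1)
    noise /= max(noise.std(), 1e-12)
    return kernels + scale * noise


def _cohort_stimuli(config: SimConfig, inventory: FeatureInventory,
                    templates: Mapping[str, np.ndarray],
                    rng: np.random.Generator) -> dict[str, StimulusFeatures]:
    stimuli = {}
    lead = min(config.lead_in, config.trial_duration / 4.0)
    for t in range(config.n_trials):
        tid = f"trial{t:02d}"
        alignments = generate_phoneme_sequence(
            inventory, config.phoneme_rate, config.trial_duration - lead, rng)
        if lead > 0:  # silent lead-in, as in the stimulus videos
            alignments = [PhonemeAlignment(a.label, a.onset + lead,
                                           a.offset + lead) for a in alignments]
        stimuli[tid] = generate_stimulus_features(
            alignments, templates, config.confound_strength, config.fs,
            config.trial_duration, rng, inventory=inventory, trial_id=tid)
    return stimuli


def simulate_participant(
    config: SimConfig,
    stimuli: Mapping[str, StimulusFeatures] | None = None,
    gain: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[dict[str, list[EEGRecording]], SimTruth, dict[str, StimulusFeatures]]:
    """Simulate one participant (single session) with their own kernels.

    Returns (trial_id -> repetitions, the participant's SimTruth, stimuli).
    Used directly for parameter-recovery checks.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(config.seed if seed is None else seed))
    ss_stim, ss_kern, ss_eeg = ss.spawn(3)
    inventory = FeatureInventory.default()
    rng_stim = np.random.default_rng(ss_stim)
    if stimuli is None:
        templates = default_spectral_templates(inventory, rng_stim)
        stimuli = _cohort_stimuli(config, inventory, templates, rng_stim)
    rng_k = np.random.default_rng(ss_kern)
    n_lags = int(round(config.kernel_tmax * config.fs)) + 1
    ak = make_kernels(8, n_lags, config.n_scalp, config.fs, rng_k,
                      config.kernel_smoothness)
    pk = make_kernels(14, n_lags, config.n_scalp, config.fs, rng_k,
                      config.kernel_smoothness)
    rng_eeg = np.random.default_rng(ss_eeg)
    trials: dict[str, list[EEGRecording]] = {}
    for tid, stim in stimuli.items():
        trials[tid] = [simulate_eeg_from_kernels(
            stim, ak, pk, gain, config.noise_sd, rng_eeg,
            n_facial=config.n_facial, n_mastoids=config.n_mastoids,
            pink_fraction=config.pink_fraction, pink_slope=config.pink_slope,
            participant_id="P01", repetition=0)]
    truth = SimTruth(
        acoustic_kernels=ak, phonetic_kernels=pk,
        participant_kernels={"P01": (ak, pk)},
        session_gains={"": gain}, kernel_lags=np.arange(n_lags),
        fs=config.fs, noise_sd=config.noise_sd)
    return trials, truth, dict(stimuli)


def simulate_longitudinal_cohort(config: SimConfig) -> tuple[CohortData, SimTruth]:
    """Generate the full synthetic longitudinal cohort plus its hidden truth.

    Stimuli (the "nursery rhymes") are shared across participants and
    sessions, as in the study.  Each participant gets kernels jittered
    around the cohort-level kernels; the phonetic kernels are scaled by the
    session gain.  All sub-seeds derive deterministically from the master
    seed.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_stim, ss_kern, ss_part = ss.spawn(3)
    inventory = FeatureInventory.default()
    rng_stim = np.random.default_rng(ss_stim)
    templates = default_spectral_templates(inventory, rng_stim)
    stimuli = _cohort_stimuli(config, inventory, templates, rng_stim)

    rng_k = np.random.default_rng(ss_kern)
    n_lags = int(round(config.kernel_tmax * config.fs)) + 1
    ak = make_kernels(8, n_lags, config.n_scalp, config.fs, rng_k,
                      config.kernel_smoothness)
    pk = make_kernels(14, n_lags, config.n_scalp, config.fs, rng_k,
                      config.kernel_smoothness)

    labels, facial, mastoids = make_channel_labels(
        config.n_channels, config.n_facial, config.n_mastoids)
    montage = make_montage(labels)

    pids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    if len(set(pids)) != len(pids):
        raise DataError("duplicate participant ids")
    eeg: dict[str, dict[str, dict[str, list[EEGRecording]]]] = {}
    participant_kernels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid, ss_p in zip(pids, ss_part.spawn(len(pids))):
        ss_jit, ss_sess = ss_p.spawn(2)
        rng_j = np.random.default_rng(ss_jit)
        pak = _jitter_kernels(ak, config.participant_kernel_jitter, config.fs,
                              rng_j, config.kernel_smoothness)
        ppk = _jitter_kernels(pk, config.participant_kernel_jitter, config.fs,
                              rng_j, config.kernel_smoothness)
        participant_kernels[pid] = (pak, ppk)
        eeg[pid] = {}
        for session, ss_s in zip(config.sessions,
                                 ss_sess.spawn(len(config.sessions))):
            rng_s = np.random.default_rng(ss_s)
            g = config.session_gains[session]
            eeg[pid][session] = {}
            for tid, stim in stimuli.items():
                n_reps = config.n_repetitions
                reps = []
                for rep in range(n_reps):
                    if rep >= 2 and rng_s.random() < config.dropout:
                        continue
                    reps.append(simulate_eeg_from_kernels(
                        stim, pak, ppk, g, config.noise_sd, rng_s,
                        n_facial=config.n_facial,
                        n_mastoids=config.n_mastoids,
                        pink_fraction=config.pink_fraction,
                        pink_slope=config.pink_slope,
                        participant_id=pid, session=session, repetition=rep))
                eeg[pid][session][tid] = reps

    cohort = CohortData(
        stimuli=stimuli, eeg=eeg, montage=montage, fs=config.fs,
        facial_labels=facial, mastoid_labels=mastoids,
        sessions=config.sessions)
    truth = SimTruth(
        acoustic_kernels=ak, phonetic_kernels=pk,
        participant_kernels=participant_kernels,
        session_gains=dict(config.session_gains),
        kernel_lags=np.arange(n_lags), fs=config.fs,
        noise_sd=config.noise_sd)
    return cohort, truth
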