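"""Stimulus feature extraction for continuous (sung) speech.

Turns audio, phoneme alignments and per-frame luminance into the four
time-aligned regressor streams used by the forward encoding models:

* ``S`` — 8-band acoustic spectrogram (band-envelope matrix, Greenwood-spaced
  bands between 250 Hz and 8 kHz),
* ``D`` — half-wave-rectified derivative of the broadband envelope
  (the row-sum of ``S``),
* ``F`` — 14-dimensional binary phonetic-feature matrix (unit rectangular
  pulses spanning each phoneme),
* ``V`` — mean absolute frame-to-frame luminance change (visual motion).

All streams are resampled to one analysis rate and share a common length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .config import (
    GREENWOOD_A,
    GREENWOOD_a,
    GREENWOOD_k,
    PHONETIC_FEATURE_NAMES,
    DataError,
)

__all__ = [
    "PhonemeAlignment",
    "StimulusFeatures",
    "FeatureInventory",
    "greenwood_band_edges",
    "acoustic_spectrogram",
    "envelope_and_derivative",
    "parse_textgrid",
    "phoneme_to_features",
    "phonetic_feature_matrix",
    "visual_motion_regressor",
    "read_wav",
    "load_luminance_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhonemeAlignment:
    """A single phoneme interval: symbol plus onset/offset in seconds."""

    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (self.offset > self.onset >= 0.0):
            raise ValueError(
                f"invalid alignment {self.label!r}: need offset > onset >= 0, "
                f"got [{self.onset}, {self.offset}]"
            )


@dataclass
class StimulusFeatures:
    """Time-aligned regressor streams for one trial at the analysis rate."""

    S: np.ndarray          # time x n_bands, nonnegative
    D: np.ndarray          # time, nonnegative
    F: np.ndarray          # time x 14, binary
    V: np.ndarray          # time, nonnegative
    fs: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        n = self.S.shape[0]
        if not (self.D.shape[0] == self.F.shape[0] == self.V.shape[0] == n):
            raise ValueError("S, D, F, V must share one length")
        if self.F.shape[1] != len(PHONETIC_FEATURE_NAMES):
            raise ValueError(f"F must have {len(PHONETIC_FEATURE_NAMES)} columns")
        if not np.isin(self.F, (0.0, 1.0)).all():
            raise ValueError("F entries must be binary")
        if (self.S < 0).any() or (self.D < 0).any() or (self.V < 0).any():
            raise ValueError("S, D and V must be nonnegative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.S.shape[0]

    def stack(self, components: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        """Horizontally stack the requested streams into one regressor matrix.

        Returns the (time, n_features) matrix and per-column names.
        """
        blocks, names = [], []
        for comp in components:
            if comp == "S":
                blocks.append(self.S)
                names += [f"S{b}" for b in range(self.S.shape[1])]
            elif comp == "D":
                blocks.append(self.D[:, None])
                names.append("D")
            elif comp == "F":
                blocks.append(self.F)
                names += list(PHONETIC_FEATURE_NAMES)
            elif comp == "V":
                blocks.append(self.V[:, None])
                names.append("V")
            else:
                raise ValueError(f"unknown stimulus component {comp!r}")
        return np.hstack(blocks), names


class FeatureInventory:
    """Phoneme -> binary 14-vector lookup table.

    The default table (ARPAbet-like symbols, standard British-English
    inventory) is reconstructed from the conventional articulatory feature
    system for voicing, manner and place; it ships as an editable TSV.
    """

    feature_names = PHONETIC_FEATURE_NAMES

    def __init__(self, table: Mapping[str, np.ndarray]):
        self._table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        self._validate()

    def _validate(self) -> None:
        iv = self.feature_names.index("voiced consonant")
        iu = self.feature_names.index("unvoiced consonant")
        for label, vec in self._table.items():
            if vec.shape != (len(self.feature_names),):
                raise ValueError(f"{label!r}: feature vector must have length 14")
            if not np.isin(vec, (0.0, 1.0)).all():
                raise ValueError(f"{label!r}: feature vector must be binary")
            if vec.sum() < 1:
                raise ValueError(f"{label!r}: phoneme must carry >= 1 feature")
            if vec[iv] and vec[iu]:
                raise ValueError(
                    f"{label!r}: cannot be both voiced and unvoiced consonant"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureInventory":
        table: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header: list[str] | None = None
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cells = line.split("\t")
                if header is None:
                    header = cells
                    if tuple(header[1:]) != PHONETIC_FEATURE_NAMES:
                        raise DataError(
                            f"{path}: feature columns must be exactly the 14 "
                            "canonical names in order"
                        )
                    continue
                table[cells[0]] = np.array([float(c) for c in cells[1:]])
        if not table:
            raise DataError(f"{path}: no phoneme rows found")
        return cls(table)

    @classmethod
    def default(cls) -> "FeatureInventory":
        with resources.as_file(
            resources.files("babytrf.data") / "phoneme_features.tsv"
        ) as p:
            return cls.from_tsv(p)

    @property
    def phonemes(self) -> list[str]:
        return list(self._table)

    def __contains__(self, label: str) -> bool:
        return label in self._table

    def vector(self, label: str) -> np.ndarray:
        if label not in self._table:
            raise KeyError(
                f"unknown phoneme symbol {label!r}; known: {sorted(self._table)}"
            )
        return self._table[label].copy()


# ---------------------------------------------------------------------------
# acoustic streams
# ---------------------------------------------------------------------------

def greenwood_position(freq: np.ndarray | float) -> np.ndarray | float:
    """Normalised cochlear position x in [0, 1] for frequency in Hz."""
    return np.log10(np.asarray(freq) / GREENWOOD_A + GREENWOOD_k) / GREENWOOD_a


def greenwood_frequency(x: np.ndarray | float) -> np.ndarray | float:
    """Characteristic frequency (Hz) at normalised cochlear position x."""
    return GREENWOOD_A * (10.0 ** (GREENWOOD_a * np.asarray(x)) - GREENWOOD_k)


def greenwood_band_edges(fmin: float, fmax: float, n_bands: int) -> np.ndarray:
    """Band edges equally spaced in Greenwood cochlear position.

    Returns ``n_bands + 1`` strictly increasing edge frequencies whose first
    and last entries equal ``fmin`` and ``fmax`` exactly.
    """
    if not (0 < fmin < fmax):
        raise ValueError(f"need 0 < fmin < fmax, got ({fmin}, {fmax})")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    x = np.linspace(greenwood_position(fmin), greenwood_position(fmax), n_bands + 1)
    edges = np.asarray(greenwood_frequency(x), dtype=float)
    edges[0], edges[-1] = fmin, fmax
    return edges


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along axis 0, trimmed/padded to round(n*fs_out/fs_in)."""
    n_out = int(round(x.shape[0] * fs_out / fs_in))
    if fs_out == fs_in:
        return x[:n_out]
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=0)
    if y.shape[0] >= n_out:
        return y[:n_out]
    pad = np.repeat(y[-1:], n_out - y.shape[0], axis=0)
    return np.concatenate([y, pad], axis=0)


def acoustic_spectrogram(
    audio: np.ndarray,
    fs_audio: float,
    edges: np.ndarray,
    fs_out: float,
    compression: float | None = None,
) -> np.ndarray:
    """Band-envelope spectrogram: time x n_bands at ``fs_out``.

    Each column is the amplitude envelope (magnitude of the analytic signal)
    of the waveform band-passed to the corresponding edge interval with a
    4th-order zero-phase Butterworth filter, anti-alias low-passed and
    resampled.  ``compression`` optionally applies power-law amplitude
    compression (e.g. 0.3); default is linear amplitude.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a 1-D waveform")
    edges = np.asarray(edges, dtype=float)
    if fs_audio <= 2 * edges[-1]:
        raise ValueError(
            f"audio rate {fs_audio} Hz violates Nyquist for top edge {edges[-1]} Hz"
        )
    if fs_out > fs_audio:
        raise ValueError("fs_out must not exceed fs_audio")
    n_out = int(round(audio.shape[0] / fs_audio * fs_out))
    if n_out < 1:
        raise ValueError("audio shorter than one output sample")

    n_bands = len(edges) - 1
    envs = np.empty((audio.shape[0], n_bands))
    for b in range(n_bands):
        sos = sps.butter(4, [edges[b], edges[b + 1]], btype="bandpass",
                         fs=fs_audio, output="sos")
        banded = sps.sosfiltfilt(sos, audio)
        envs[:, b] = np.abs(sps.hilbert(banded))
    # anti-alias before the rate change
    if fs_out < fs_audio:
        sos_lp = sps.butter(4, 0.45 * fs_out, btype="lowpass", fs=fs_audio,
                            output="sos")
        envs = sps.sosfiltfilt(sos_lp, envs, axis=0)
    S = np.clip(_resample_to(envs, fs_audio, fs_out), 0.0, None)
    if compression is not None:
        S = S ** compression
    return S


def envelope_and_derivative(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Broadband envelope (row-sum of S) and its half-wave-rectified derivative.

    The derivative stream has the same length as the envelope; its first
    sample is defined as zero.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty spectrogram")
    if (S < 0).any():
        raise ValueError("S must be nonnegative")
    env = S.sum(axis=1)
    D = np.maximum(np.diff(env, prepend=env[:1]), 0.0)
    D[0] = 0.0
    return env, D


# ---------------------------------------------------------------------------
# phoneme alignments and the phonetic-feature matrix
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"=\s*([-+0-9.eE]+)\s*$")
_TEXT_RE = re.compile(r'=\s*"(.*)"\s*$')


def parse_textgrid(path: str | Path, tier: str | None = None) -> list[PhonemeAlignment]:
    """Read phoneme alignments from a Praat TextGrid (long text format).

    Selects the named interval tier, or — if ``tier`` is None — the first
    interval tier whose name contains "phon" (falling back to the only
    interval tier present).  Empty-labelled intervals (silences) are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"TextGrid not found: {path}")
    lines = path.read_text().splitlines()

    def _num(i: int) -> float:
        m = _NUM_RE.search(lines[i])
        if not m:
            raise DataError(f"{path}:{i + 1}: expected a numeric field: {lines[i]!r}")
        return float(m.group(1))

    def _text(i: int) -> str:
        m = _TEXT_RE.search(lines[i])
        if m is None:
            raise DataError(f"{path}:{i + 1}: expected a quoted text field: {lines[i]!r}")
        return m.group(1)

    tiers: list[tuple[str, list[PhonemeAlignment]]] = []
    i = 0
    try:
        while i < len(lines):
            line = lines[i].strip()
            if line.startswith("class") and "IntervalTier" in line:
                name = _text(i + 1)
                n_int = int(_num(i + 4))
                j = i + 5
                intervals: list[PhonemeAlignment] = []
                for _ in range(n_int):
                    while "intervals [" not in lines[j]:
                        j += 1
                    xmin, xmax, text = _num(j + 1), _num(j + 2), _text(j + 3)
                    if text.strip():
                        intervals.append(PhonemeAlignment(text.strip(), xmin, xmax))
                    j += 4
                tiers.append((name, intervals))
                i = j
            else:
                i += 1
    except (IndexError, ValueError) as exc:
        raise DataError(f"{path}: truncated or malformed TextGrid near line {i + 1}: {exc}")

    if tier is not None:
        for name, intervals in tiers:
            if name == tier:
                return sorted(intervals, key=lambda a: a.onset)
        raise DataError(f"{path}: no interval tier named {tier!r}")
    for name, intervals in tiers:
        if "phon" in name.lower():
            return sorted(intervals, key=lambda a: a.onset)
    if len(tiers) == 1:
        return sorted(tiers[0][1], key=lambda a: a.onset)
    raise DataError(f"{path}: no phoneme tier found (tiers: {[t[0] for t in tiers]})")


def phoneme_to_features(label: str, inventory: FeatureInventory) -> np.ndarray:
    """Binary 14-vector of articulatory features for one phoneme symbol."""
    return inventory.vector(label)


def phonetic_feature_matrix(
    alignments: Sequence[PhonemeAlignment],
    inventory: FeatureInventory,
    fs_out: float,
    duration: float,
) -> np.ndarray:
    """Unit-rectangular-pulse phonetic feature matrix: time x 14, binary.

    Each phoneme marks its feature columns with ones over the half-open
    sample range ``[round(onset*fs), round(offset*fs))`` (at least one sample
    after rounding); overlaps combine by logical OR.
    """
    n = int(round(duration * fs_out))
    F = np.zeros((n, len(PHONETIC_FEATURE_NAMES)))
    for a in alignments:
        if a.offset > duration + 1e-9:
            raise ValueError(
                f"alignment {a.label!r} [{a.onset}, {a.offset}] extends beyond "
                f"trial duration {duration}"
            )
        i0 = int(round(a.onset * fs_out))
        i1 = int(round(a.offset * fs_out))
        if i1 <= i0:          # zero duration after rounding: force one sample
            i1 = i0 + 1
        i0, i1 = min(i0, n - 1), min(i1, n)
        vec = inventory.vector(a.label)
        F[i0:i1] = np.logical_or(F[i0:i1], vec)
    return F


# ---------------------------------------------------------------------------
# visual motion
# ---------------------------------------------------------------------------

def visual_motion_regressor(
    luminance: np.ndarray,
    frame_rate: float,
    fs_out: float,
    duration: float,
) -> np.ndarray:
    """Visual motion stream from per-frame mean luminance values.

    The per-frame motion signal is the absolute luminance difference between
    consecutive frames (first value zero), resampled to ``fs_out`` and
    length-matched to ``round(duration * fs_out)`` samples.
    """
    luminance = np.asarray(luminance, dtype=float)
    if luminance.ndim != 1 or luminance.shape[0] < 2:
        raise ValueError("need at least 2 luminance frames")
    motion = np.abs(np.diff(luminance, prepend=luminance[:1]))
    motion[0] = 0.0
    n_out = int(round(duration * fs_out))
    if fs_out == frame_rate:
        v = motion
    else:
        frac = Fraction(fs_out / frame_rate).limit_denominator(10000)
        v = sps.resample_poly(motion, frac.numerator, frac.denominator)
    if v.shape[0] >= n_out:
        v = v[:n_out]
    else:
        v = np.concatenate([v, np.repeat(v[-1:], n_out - v.shape[0])])
    return np.clip(v, 0.0, None)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Mono waveform (first channel of multi-channel files) in float, plus rate."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.abs(np.iinfo(data.dtype).min)
    return data.astype(float), float(fs)


def load_luminance_table(path: str | Path) -> np.ndarray:
    """Per-frame mean luminance from a plain one-column delimited table."""
    arr = np.loadtxt(path, ndmin=2)
    return arr[:, -1]
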