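"""Shared constants, defaults and exception types for the babytrf pipeline.

Every tunable that the analysis depends on is named here once, so a run can
be described completely by a config file plus a seed.
"""

from __future__ import annotations

# --- Greenwood cochlear map (human constants, position x normalised to [0,1]) ---
GREENWOOD_A = 165.4
GREENWOOD_a = 2.1
GREENWOOD_k = 0.88

#: spectrogram band range (Hz) and count
SPECTROGRAM_FMIN = 250.0
SPECTROGRAM_FMAX = 8000.0
SPECTROGRAM_N_BANDS = 8

#: the 14 binary articulatory features, in canonical column order
PHONETIC_FEATURE_NAMES = (
    "voiced consonant",
    "unvoiced consonant",
    "plosive",
    "fricative",
    "nasal",
    "strident",
    "labial",
    "coronal",
    "dorsal",
    "anterior",
    "front",
    "back",
    "high",
    "low",
)

#: analysis sampling rate (Hz) after downsampling
ANALYSIS_FS = 50.0

#: EEG frequency bands of interest (Hz): low-delta, delta, theta
BANDS = {
    "lowdelta": (0.1, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
}

#: broadband conditioning limits (Hz) applied before band-specific filtering
BROADBAND = (0.1, 8.0)

#: Butterworth order used throughout the conditioning chain
FILTER_ORDER = 2

#: TRF lag window (s); negative lags absorb regression edge artefacts
LAG_TMIN = -0.1
LAG_TMAX = 0.5

#: regularisation grid: powers of ten from 1e-2 to 1e6
LAMBDA_GRID = tuple(10.0 ** e for e in range(-2, 7))

#: model compositions.  Single-feature models quantify raw tracking of the
#: spectrogram (S) and the phonetic features (F); the full/reduced pair
#: isolates acoustically invariant phonetic encoding (the FS-S gain).
MODELS_SINGLE = {"S": ("S",), "F": ("F",)}
MODELS_GAIN = {"full": ("S", "D", "V", "F"), "reduced": ("S", "D", "V")}

#: bootstrap defaults for the topography-similarity analysis
TOPO_GROUP_SIZE = 17
TOPO_ITERATIONS = 100

#: ERP SNR control windows (s) around the first-word onset
SNR_PRE_WINDOW = 0.5
SNR_POST_WINDOW = 0.5

ALPHA = 0.05


class BabyTRFError(Exception):
    """Base class for all package errors."""


class ConfigError(BabyTRFError):
    """Invalid or incomplete run configuration (detected before any compute)."""


class DataError(BabyTRFError):
    """Missing, malformed or internally inconsistent input data."""
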