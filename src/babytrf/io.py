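"""HDF5-style containers for stimuli, EEG cohorts, truth and TRF weights.

The synthetic generator writes the same fixture containers the real-data
path reads, so downstream stages cannot distinguish synthetic from real
inputs.  The hidden generator truth is stored in a separate file and is
never part of the dataset payload.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .config import DataError
from .features import StimulusFeatures
from .preprocess import EEGRecording
from .simulate import CohortData, SimTruth
from .trf import LagWindow, TRFModel

__all__ = [
    "save_stimulus", "load_stimulus",
    "save_dataset", "load_dataset",
    "save_truth", "load_truth",
    "save_weights", "load_weights",
]


def _write_strs(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.array(list(values), dtype="S"))


def _read_strs(group: h5py.Group, name: str) -> list[str]:
    return [s.decode() for s in group[name][()]]


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def save_stimulus(group: h5py.Group, stim: StimulusFeatures) -> None:
    for name in ("S", "D", "F", "V"):
        group.create_dataset(name, data=getattr(stim, name))
    group.attrs["fs"] = stim.fs
    group.attrs["trial_id"] = stim.trial_id


def load_stimulus(group: h5py.Group) -> StimulusFeatures:
    return StimulusFeatures(
        S=group["S"][()], D=group["D"][()], F=group["F"][()], V=group["V"][()],
        fs=float(group.attrs["fs"]), trial_id=str(group.attrs["trial_id"]))


# ---------------------------------------------------------------------------
# cohort datasets
# ---------------------------------------------------------------------------

def save_dataset(path: str | Path, cohort: CohortData) -> None:
    """Write the dataset payload (stimuli, EEG, montage) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["fs"] = cohort.fs
        _write_strs(meta, "sessions", cohort.sessions)
        _write_strs(meta, "facial_labels", cohort.facial_labels)
        _write_strs(meta, "mastoid_labels", cohort.mastoid_labels)
        mg = f.create_group("montage")
        _write_strs(mg, "labels", cohort.montage.index)
        mg.create_dataset("pos", data=cohort.montage[["x", "y", "z"]].to_numpy())
        gs = f.create_group("stimuli")
        for tid, stim in cohort.stimuli.items():
            save_stimulus(gs.create_group(tid), stim)
        ge = f.create_group("eeg")
        for pid, sessions in cohort.eeg.items():
            gp = ge.create_group(pid)
            for session, trials in sessions.items():
                gsn = gp.create_group(session)
                for tid, reps in trials.items():
                    gt = gsn.create_group(tid)
                    for rec in reps:
                        gr = gt.create_group(f"rep{rec.repetition}")
                        gr.create_dataset("data", data=rec.data)
                        gr.attrs["fs"] = rec.fs
                        _write_strs(gr, "channel_labels", rec.channel_labels)


def load_dataset(path: str | Path) -> CohortData:
    path = Path(path)
    if not path.exists():
        raise DataError(f"dataset not found: {path}")
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        fs = float(meta.attrs["fs"])
        sessions = _read_strs(meta, "sessions")
        facial = _read_strs(meta, "facial_labels")
        mastoids = tuple(_read_strs(meta, "mastoid_labels"))
        labels = _read_strs(f["montage"], "labels")
        montage = pd.DataFrame(f["montage"]["pos"][()],
                               columns=["x", "y", "z"], index=labels)
        stimuli = {tid: load_stimulus(f["stimuli"][tid])
                   for tid in sorted(f["stimuli"])}
        eeg: dict = {}
        for pid in sorted(f["eeg"]):
            eeg[pid] = {}
            for session in f["eeg"][pid]:
                eeg[pid][session] = {}
                for tid in sorted(f["eeg"][pid][session]):
                    reps = []
                    gt = f["eeg"][pid][session][tid]
                    for rep_name in sorted(gt):
                        gr = gt[rep_name]
                        reps.append(EEGRecording(
                            data=gr["data"][()], fs=float(gr.attrs["fs"]),
                            channel_labels=_read_strs(gr, "channel_labels"),
                            mastoid_labels=mastoids,  # type: ignore[arg-type]
                            participant_id=pid, session=session, trial_id=tid,
                            repetition=int(rep_name[3:])))
                    eeg[pid][session][tid] = reps
        ordered = [s for s in sessions if any(s in eeg[p] for p in eeg)]
    return CohortData(stimuli=stimuli, eeg=eeg, montage=montage, fs=fs,
                      facial_labels=facial, mastoid_labels=mastoids,  # type: ignore[arg-type]
                      sessions=ordered or sessions)


# ---------------------------------------------------------------------------
# generator truth (separate artifact)
# ---------------------------------------------------------------------------

def save_truth(path: str | Path, truth: SimTruth) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("acoustic_kernels", data=truth.acoustic_kernels)
        f.create_dataset("phonetic_kernels", data=truth.phonetic_kernels)
        f.create_dataset("kernel_lags", data=truth.kernel_lags)
        f.attrs["fs"] = truth.fs
        f.attrs["noise_sd"] = truth.noise_sd
        g = f.create_group("session_gains")
        for k, v in truth.session_gains.items():
            g.attrs[k] = v
        gp = f.create_group("participant_kernels")
        for pid, (ak, pk) in truth.participant_kernels.items():
            gg = gp.create_group(pid)
            gg.create_dataset("acoustic", data=ak)
            gg.create_dataset("phonetic", data=pk)


def load_truth(path: str | Path) -> SimTruth:
    with h5py.File(path, "r") as f:
        return SimTruth(
            acoustic_kernels=f["acoustic_kernels"][()],
            phonetic_kernels=f["phonetic_kernels"][()],
            participant_kernels={
                pid: (f["participant_kernels"][pid]["acoustic"][()],
                      f["participant_kernels"][pid]["phonetic"][()])
                for pid in f["participant_kernels"]},
            session_gains=dict(f["session_gains"].attrs),
            kernel_lags=f["kernel_lags"][()],
            fs=float(f.attrs["fs"]), noise_sd=float(f.attrs["noise_sd"]))


# ---------------------------------------------------------------------------
# TRF weight tensors
# ---------------------------------------------------------------------------

def save_weights(path: str | Path, models: Mapping[str, TRFModel]) -> None:
    with h5py.File(path, "w") as f:
        for name, m in models.items():
            g = f.create_group(name)
            g.create_dataset("weights", data=m.weights)
            g.create_dataset("bias", data=m.bias)
            g.attrs["lambda"] = m.lam
            g.attrs["penalty"] = m.penalty
            g.attrs["tmin"] = m.window.tmin
            g.attrs["tmax"] = m.window.tmax
            g.attrs["fs"] = m.window.fs
            _write_strs(g, "feature_names", m.feature_names)


def load_weights(path: str | Path) -> dict[str, TRFModel]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            out[name] = TRFModel(
                weights=g["weights"][()], bias=g["bias"][()],
                lam=float(g.attrs["lambda"]),
                window=LagWindow(float(g.attrs["tmin"]), float(g.attrs["tmax"]),
                                 float(g.attrs["fs"])),
                feature_names=_read_strs(g, "feature_names"),
                penalty=str(g.attrs["penalty"]))
    return out
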