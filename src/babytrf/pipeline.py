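"""Config-driven orchestration of the full analysis.

Stages run in a fixed acyclic order — data (simulate or load), preprocess,
fit, gains, stats, report — and a run is fully reproducible from
(config, seed): the provenance log records the config hash, seed and
package versions.

The statistical flow mirrors the study design: single-feature TRF models
(S alone, F alone) quantify raw tracking per band and per session; the
FS-S prediction gain is computed from full vs reduced multi-feature models,
but only in the bands where the phonetic model shows a significant age
effect on the run's own data (overridable in config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import config as defaults
from .config import ConfigError, DataError
from .preprocess import (
    average_trials,
    ground_truth_average,
    preprocess_recording,
    snr_first_word,
    zero_phase_bandpass,
)
from .simulate import CohortData, SimConfig, simulate_longitudinal_cohort
from .stats import (
    StatResult,
    assumption_screen,
    bootstrap_topography_similarity,
    fdr_bh,
    friedman_kendall,
    rm_anova_oneway,
    wilcoxon_signed_rank,
)
from .trf import LagWindow, precompute_trial, prediction_gain

logger = logging.getLogger("babytrf")

__all__ = [
    "RunConfig", "ResultsBundle", "run_full_analysis", "export_report",
    "load_config", "default_config_dict", "validate_stats_summary",
]

_COMPONENT_SIZES = {"S": 8, "D": 1, "V": 1, "F": 14}
_FULL_ORDER = ("S", "D", "V", "F")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config_dict() -> dict:
    """A complete, valid configuration dictionary (simulation mode)."""
    return {
        "seed": 1,
        "lag_window": [defaults.LAG_TMIN, defaults.LAG_TMAX],
        "lambda_grid": list(defaults.LAMBDA_GRID),
        "bands": {k: list(v) for k, v in defaults.BANDS.items()},
        "models": {
            "single": {k: list(v) for k, v in defaults.MODELS_SINGLE.items()},
            "gain": {k: list(v) for k, v in defaults.MODELS_GAIN.items()},
        },
        "penalty": "identity",
        "simulate": {},
        "preprocess": {
            "lowpass": defaults.BROADBAND[1],
            "highpass": defaults.BROADBAND[0],
            "fs_out": defaults.ANALYSIS_FS,
            "z_threshold": 3.0,
        },
        "analysis": {
            "alpha": defaults.ALPHA,
            "gain_bands": "auto",
            "topo_group_size": defaults.TOPO_GROUP_SIZE,
            "topo_iterations": defaults.TOPO_ITERATIONS,
            "snr_pre": defaults.SNR_PRE_WINDOW,
            "snr_post": defaults.SNR_POST_WINDOW,
        },
    }


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    lag_window: tuple[float, float]
    lambda_grid: tuple[float, ...]
    bands: dict[str, tuple[float, float]]
    models_single: dict[str, tuple[str, ...]]
    models_gain: dict[str, tuple[str, ...]]
    penalty: str = "identity"
    simulate: dict = field(default_factory=dict)
    dataset: str | None = None
    preprocess: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        required = ("seed", "lag_window", "lambda_grid", "bands", "models")
        missing = [k for k in required if k not in d]
        if missing:
            raise ConfigError(f"config missing required keys: {missing}")
        if ("simulate" in d) == ("data" in d):
            raise ConfigError("config must contain exactly one of "
                              "'simulate' or 'data'")
        lw = tuple(float(x) for x in d["lag_window"])
        if len(lw) != 2 or not lw[0] < lw[1]:
            raise ConfigError(f"lag_window must be [tmin, tmax], got {d['lag_window']}")
        grid = tuple(float(x) for x in d["lambda_grid"])
        if len(grid) == 0 or any(g < 0 for g in grid):
            raise ConfigError("lambda_grid must be a nonempty list of >= 0 values")
        bands = {str(k): (float(v[0]), float(v[1]))
                 for k, v in dict(d["bands"]).items()}
        ordered = sorted(bands.values())
        for (lo1, hi1), (lo2, _) in zip(ordered, ordered[1:]):
            if not (lo1 < hi1 <= lo2):
                raise ConfigError("bands must be non-overlapping and ordered")
        models = d["models"]
        if "single" not in models or "gain" not in models:
            raise ConfigError("models must define 'single' and 'gain' sets")
        for group in ("single", "gain"):
            for name, comps in dict(models[group]).items():
                bad = [c for c in comps if c not in _COMPONENT_SIZES]
                if bad:
                    raise ConfigError(
                        f"model {name!r} names unavailable features: {bad}")
        gain_models = {k: tuple(v) for k, v in dict(models["gain"]).items()}
        if set(gain_models) != {"full", "reduced"}:
            raise ConfigError("models.gain must define 'full' and 'reduced'")
        penalty = str(d.get("penalty", "identity"))
        if penalty not in ("identity", "derivative"):
            raise ConfigError(f"unknown penalty {penalty!r}")
        return cls(
            seed=int(d["seed"]), lag_window=lw, lambda_grid=grid, bands=bands,
            models_single={k: tuple(v) for k, v in dict(models["single"]).items()},
            models_gain=gain_models, penalty=penalty,
            simulate=dict(d.get("simulate", {})) if "simulate" in d else {},
            dataset=(dict(d["data"]).get("dataset") if "data" in d else None),
            preprocess=dict(d.get("preprocess", {})),
            analysis=dict(d.get("analysis", {})), raw=dict(d),
        )

    @property
    def alpha(self) -> float:
        return float(self.analysis.get("alpha", defaults.ALPHA))


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON config file (schema checked up front)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(d)


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    """All tables a run produces, plus provenance."""

    scores: pd.DataFrame          # participant, session, band, model, channel, r
    gains: pd.DataFrame           # participant, session, band, gain
    stats: pd.DataFrame           # analysis, test, statistic, df, p, ...
    stats_summary: dict
    topography: dict[str, pd.DataFrame]   # band -> (participant x channel r, per session)
    snr: pd.DataFrame             # participant, session, snr
    provenance: dict

    def is_empty(self) -> bool:
        return self.scores.empty and self.gains.empty


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_data(cfg: RunConfig) -> CohortData:
    if cfg.dataset is not None:
        from .io import load_dataset
        return load_dataset(cfg.dataset)
    try:
        sim = SimConfig(seed=int(cfg.simulate.get("seed", cfg.seed)),
                        **{k: v for k, v in cfg.simulate.items() if k != "seed"})
    except TypeError as exc:
        raise ConfigError(f"invalid simulate block: {exc}")
    cohort, _truth = simulate_longitudinal_cohort(sim)
    return cohort


def stage_preprocess(cohort: CohortData, cfg: RunConfig):
    """Average repetitions and run the conditioning chain on every trial.

    Returns (preprocessed[pid][session][tid] -> EEGRecording, snr table,
    provenance list).
    """
    pp = cfg.preprocess
    snr_pre = float(cfg.analysis.get("snr_pre", defaults.SNR_PRE_WINDOW))
    snr_post = float(cfg.analysis.get("snr_post", defaults.SNR_POST_WINDOW))
    out: dict = {}
    prov: list[dict] = []
    snr_rows = []
    onsets = {tid: _first_onset(stim) for tid, stim in cohort.stimuli.items()}
    for pid, sessions in cohort.eeg.items():
        out[pid] = {}
        for session, trials in sessions.items():
            out[pid][session] = {}
            snr_vals = []
            for tid, reps in trials.items():
                avg = average_trials(reps)
                clean, p = preprocess_recording(
                    avg, montage=cohort.montage,
                    facial_labels=cohort.facial_labels,
                    lowpass=float(pp.get("lowpass", defaults.BROADBAND[1])),
                    highpass=float(pp.get("highpass", defaults.BROADBAND[0])),
                    fs_out=float(pp.get("fs_out", defaults.ANALYSIS_FS)),
                    z_threshold=float(pp.get("z_threshold", 3.0)),
                )
                out[pid][session][tid] = clean
                p.update(participant=pid, session=session, trial=tid)
                prov.append(p)
                onset = onsets[tid]
                if onset - snr_pre >= 0:
                    try:
                        snr_vals.append(snr_first_word(clean, onset,
                                                       snr_pre, snr_post))
                    except ValueError:
                        pass
            if snr_vals:
                snr_rows.append({"participant": pid, "session": session,
                                 "snr": float(np.mean(snr_vals))})
    return out, pd.DataFrame(snr_rows), prov


def _first_onset(stim) -> float:
    nz = np.flatnonzero(stim.F.any(axis=1))
    return float(nz[0] / stim.fs) if nz.size else 0.0


def _model_columns(components, n_lags: int) -> np.ndarray:
    """Column indices of the requested components inside the full lagged design."""
    offsets = {}
    pos = 0
    for comp in _FULL_ORDER:
        offsets[comp] = pos
        pos += _COMPONENT_SIZES[comp] * n_lags
    idx = []
    for comp in components:
        start = offsets[comp]
        idx.extend(range(start, start + _COMPONENT_SIZES[comp] * n_lags))
    return np.asarray(idx)


def stage_fit(cohort: CohortData, preprocessed: dict, cfg: RunConfig):
    """Fit all models per (participant, session, band) with leave-one-out CV.

    Returns (scores table with per-channel rows, gains table).
    """
    from .trf import _TrialCache, cross_validated_fit_predict

    fs = next(iter(preprocessed.values()))
    fs = next(iter(fs.values()))
    fs = next(iter(fs.values())).fs
    window = LagWindow(cfg.lag_window[0], cfg.lag_window[1], fs)
    n_lags = window.n_lags
    all_models = dict(cfg.models_single)
    all_models.update(cfg.models_gain)
    model_cols = {name: _model_columns(comps, n_lags)
                  for name, comps in all_models.items()}

    # band-filtered EEG and ground-truth traces
    banded: dict = {}
    for pid, sessions in preprocessed.items():
        banded[pid] = {}
        for session, trials in sessions.items():
            banded[pid][session] = {}
            for band, (lo, hi) in cfg.bands.items():
                banded[pid][session][band] = {
                    tid: zero_phase_bandpass(rec.data, lo, hi, fs=rec.fs)
                    for tid, rec in trials.items()}
    truths: dict = {}
    sessions_all = cohort.sessions
    for session in sessions_all:
        truths[session] = {}
        pids = [p for p in preprocessed if session in preprocessed[p]]
        for band, (lo, hi) in cfg.bands.items():
            traces = {}
            for tid in cohort.trial_ids:
                cohort_trials = [preprocessed[p][session][tid] for p in pids]
                traces[tid] = ground_truth_average(cohort_trials, (lo, hi),
                                                   band_name=band, group=session)
            truths[session][band] = traces

    score_rows, gain_rows = [], []
    for pid, sessions in preprocessed.items():
        for session, trials in sessions.items():
            # one lagged design matrix per trial, shared across bands/models
            lagged = {}
            for tid in trials:
                stim = cohort.stimuli[tid]
                feats, _ = stim.stack(_FULL_ORDER)
                cache = precompute_trial(feats, np.zeros((feats.shape[0], 1)),
                                         window, tid)
                lagged[tid] = (cache.X, cache.G, cache.sx)
            for band in cfg.bands:
                caches = []
                for tid in trials:
                    X, G, sx = lagged[tid]
                    Y = banded[pid][session][band][tid].T
                    caches.append(_TrialCache(X, Y, tid, G=G, sx=sx))
                chan_labels = next(iter(trials.values())).channel_labels
                scores = {}
                for name in all_models:
                    idx = model_cols[name]
                    sub = [c.subset(idx) for c in caches]
                    score = cross_validated_fit_predict(
                        sub, truths[session][band], window,
                        grid=cfg.lambda_grid, penalty=cfg.penalty,
                        model=name, band=band, participant=pid,
                        session=session)
                    scores[name] = score
                    for ch, r in zip(chan_labels, score.r_per_channel):
                        score_rows.append({
                            "participant": pid, "session": session,
                            "band": band, "model": name, "channel": ch,
                            "r": r})
                g = prediction_gain(scores["full"], scores["reduced"])
                gain_rows.append({"participant": pid, "session": session,
                                  "band": band, "gain": g.gain})
            logger.debug("fit done: %s %s", pid, session)
    return pd.DataFrame(score_rows), pd.DataFrame(gain_rows)


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------

def _screened_test(table: np.ndarray, alpha: float) -> StatResult:
    """Run the assumption-appropriate age-effect test on an n x k table."""
    try:
        rec = assumption_screen(table, alpha)
    except ValueError:
        rec = "Friedman"
    if rec == "Friedman":
        if table.shape[1] == 2:
            # Friedman needs k >= 3 conditions; the two-condition
            # nonparametric analogue is the paired Wilcoxon test
            return wilcoxon_signed_rank(table[:, 0], y=table[:, 1])
        return friedman_kendall(table)
    return rm_anova_oneway(table)


def _pivot(df: pd.DataFrame, value: str, sessions: list[str]) -> np.ndarray:
    wide = df.pivot_table(index="participant", columns="session",
                          values=value).reindex(columns=sessions).dropna()
    return wide.to_numpy()


def stage_stats(scores: pd.DataFrame, gains: pd.DataFrame, snr: pd.DataFrame,
                cfg: RunConfig, sessions: list[str]):
    """The full statistical battery over scores, gains, topographies and SNR."""
    alpha = cfg.alpha
    rows: list[dict] = []
    summary: dict = {"alpha": alpha, "sessions": sessions}

    mean_scores = (scores.groupby(
        ["participant", "session", "band", "model"], as_index=False)["r"]
        .mean())

    # --- per-band age effects for the single-feature models (Fig.1-style) ---
    age_results: dict[tuple[str, str], StatResult] = {}
    for model in cfg.models_single:
        for band in cfg.bands:
            sub = mean_scores[(mean_scores["model"] == model)
                              & (mean_scores["band"] == band)]
            table = _pivot(sub, "r", sessions)
            if table.shape[0] < 3 or table.shape[1] < 2:
                continue
            res = _screened_test(table, alpha)
            age_results[(model, band)] = res
            rows.append(_result_row(f"age_effect_TRF_{model}_{band}", res))

    # --- bands admitted to the gain analysis (Fig.2-style conditional flow) ---
    gain_bands_cfg = cfg.analysis.get("gain_bands", "auto")
    if gain_bands_cfg == "auto":
        f_model = "F" if "F" in cfg.models_single else next(iter(cfg.models_single))
        gain_bands = [b for b in cfg.bands
                      if (f_model, b) in age_results
                      and age_results[(f_model, b)].p <= alpha]
    else:
        gain_bands = [b for b in gain_bands_cfg if b in cfg.bands]
    summary["gain_bands"] = gain_bands

    # --- FS-S gain: age effect + post hoc Wilcoxon tests, FDR as one family ---
    posthoc: list[tuple[str, StatResult]] = []
    for band in gain_bands:
        sub = gains[gains["band"] == band]
        table = _pivot(sub, "gain", sessions)
        if table.shape[0] >= 3:
            res = _screened_test(table, alpha)
            rows.append(_result_row(f"age_effect_gain_{band}", res))
        for session in sessions:
            vals = sub[sub["session"] == session]["gain"].to_numpy()
            if len(vals) >= 3 and (vals != 0).sum() >= 3:
                posthoc.append((f"gain_vs_zero_{band}_{session}",
                                wilcoxon_signed_rank(vals)))
        wide = sub.pivot_table(index="participant", columns="session",
                               values="gain").reindex(columns=sessions).dropna()
        for i, s1 in enumerate(sessions):
            for s2 in sessions[i + 1:]:
                d = wide[s1].to_numpy() - wide[s2].to_numpy()
                if (d != 0).sum() >= 3:
                    posthoc.append((f"gain_paired_{band}_{s1}_vs_{s2}",
                                    wilcoxon_signed_rank(d)))
    if posthoc:
        adj = fdr_bh(np.array([r.p for _, r in posthoc]))
        for (name, res), pf in zip(posthoc, adj):
            res.p_fdr = float(pf)
            rows.append(_result_row(name, res))

    # --- topography similarity bootstrap ---
    topo_tables: dict[str, pd.DataFrame] = {}
    topo_summary: dict = {}
    group_size = int(cfg.analysis.get("topo_group_size", defaults.TOPO_GROUP_SIZE))
    iterations = int(cfg.analysis.get("topo_iterations", defaults.TOPO_ITERATIONS))
    f_model = "F" if "F" in cfg.models_single else next(iter(cfg.models_single))
    for band in (gain_bands or list(cfg.bands)[:1]):
        sub = scores[(scores["model"] == f_model) & (scores["band"] == band)]
        topo = sub.pivot_table(index=["session", "participant"],
                               columns="channel", values="r")
        topo_tables[band] = topo
        if sessions[-1] not in topo.index.get_level_values(0):
            continue
        reference = topo.loc[sessions[-1]].mean(axis=0).to_numpy()
        topo_summary[band] = {}
        for si, session in enumerate(sessions[:-1]):
            if session not in topo.index.get_level_values(0):
                continue
            mats = topo.loc[session].to_numpy()
            mean_r, _ = bootstrap_topography_similarity(
                mats, reference, group_size=min(group_size, mats.shape[0]),
                iterations=iterations, seed=cfg.seed + si)
            topo_summary[band][session] = mean_r
    summary["topography_mean_r"] = topo_summary

    # --- ERP SNR control (rules out group SNR differences) ---
    if not snr.empty:
        table = _pivot(snr, "snr", sessions)
        if table.shape[0] >= 3 and table.shape[1] >= 2:
            res = _screened_test(table, alpha)
            rows.append(_result_row("snr_age_effect", res))

    stats_df = pd.DataFrame(rows)
    summary["tests"] = {r["analysis"]: {k: r[k] for k in
                                        ("test", "statistic", "df1", "df2",
                                         "p", "p_fdr", "effect_size")}
                        for r in rows}
    return stats_df, summary, topo_tables


def _result_row(name: str, res: StatResult) -> dict:
    df1 = res.df[0] if len(res.df) > 0 else np.nan
    df2 = res.df[1] if len(res.df) > 1 else np.nan
    return {"analysis": name, "test": res.test,
            "statistic": float(res.statistic),
            "df1": float(df1), "df2": float(df2), "p": float(res.p),
            "p_fdr": (float(res.p_fdr) if res.p_fdr is not None else np.nan),
            "effect_size": (float(res.effect_size)
                            if res.effect_size is not None else np.nan),
            "effect_name": res.effect_name, "correction": res.correction,
            "epsilon": (float(res.epsilon) if res.epsilon is not None
                        else np.nan), "n": res.n}


# ---------------------------------------------------------------------------
# run-all and reporting
# ---------------------------------------------------------------------------

def run_full_analysis(config: RunConfig | Mapping) -> ResultsBundle:
    """Execute every stage in order and return the complete results bundle."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    timings = {}
    t0 = time.perf_counter()
    cohort = stage_data(cfg)
    timings["data"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    preprocessed, snr_df, prep_prov = stage_preprocess(cohort, cfg)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores, gains = stage_fit(cohort, preprocessed, cfg)
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_df, summary, topo = stage_stats(scores, gains, snr_df, cfg,
                                          cohort.sessions)
    timings["stats"] = time.perf_counter() - t0
    for stage, secs in timings.items():
        logger.info("stage %-10s %.2f s", stage, secs)

    cfg_json = json.dumps(cfg.raw, sort_keys=True, default=str)
    provenance = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": _versions(),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "flagged_channels": sorted({c for p in prep_prov
                                    for c in p.get("flagged_channels", [])}),
        "n_participants": len(cohort.participants),
        "n_trials": len(cohort.trial_ids),
    }
    return ResultsBundle(scores=scores, gains=gains, stats=stats_df,
                         stats_summary=summary, topography=topo,
                         snr=snr_df, provenance=provenance)


def _versions() -> dict:
    import scipy
    return {"babytrf": "0.1.0", "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


_STATS_SCHEMA = {
    "required": {"alpha": float, "sessions": list, "gain_bands": list,
                 "topography_mean_r": dict, "tests": dict},
    "test_fields": {"test": str, "statistic": (int, float), "p": (int, float)},
}


def validate_stats_summary(summary: Mapping) -> None:
    """Check the stats JSON summary against the shipped schema; raise on failure."""
    for key, typ in _STATS_SCHEMA["required"].items():
        if key not in summary:
            raise DataError(f"stats summary missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise DataError(f"stats summary key {key!r} has wrong type")
    for name, rec in summary["tests"].items():
        for fkey, ftyp in _STATS_SCHEMA["test_fields"].items():
            if fkey not in rec or not isinstance(rec[fkey], ftyp):
                raise DataError(f"stats summary test {name!r}: bad field {fkey!r}")
        if not (0.0 <= rec["p"] <= 1.0):
            raise DataError(f"stats summary test {name!r}: p outside [0, 1]")


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def export_report(bundle: ResultsBundle, out_dir: str | Path,
                  plots: bool = False) -> list[Path]:
    """Write the bundle as delimited tables plus a JSON summary.

    Deterministic: re-exporting the same bundle produces byte-identical
    files.  Returns the list of files written.
    """
    if bundle.is_empty():
        raise DataError("refusing to export an empty results bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, df in (("scores", bundle.scores), ("gains", bundle.gains),
                     ("stats", bundle.stats), ("snr", bundle.snr)):
        p = out / f"{name}.csv"
        _df_to_csv(df, p)
        written.append(p)
    for band, topo in sorted(bundle.topography.items()):
        p = out / f"topography_{band}.csv"
        topo.sort_index().to_csv(p, float_format="%.12g", lineterminator="\n")
        written.append(p)

    validate_stats_summary(bundle.stats_summary)
    for name, payload in (("stats", bundle.stats_summary),
                          ("provenance", bundle.provenance)):
        p = out / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                default=float) + "\n")
        written.append(p)

    if plots:
        written += _export_plots(bundle, out)
    return written


def _export_plots(bundle: ResultsBundle, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    mean_scores = (bundle.scores.groupby(
        ["participant", "session", "band", "model"], as_index=False)["r"].mean())
    for frame, value, fname in ((mean_scores, "r", "scores_violin.png"),
                                (bundle.gains, "gain", "gains_violin.png")):
        if frame.empty:
            continue
        bands = sorted(frame["band"].unique())
        fig, axes = plt.subplots(1, len(bands), figsize=(4 * len(bands), 3),
                                 squeeze=False)
        for ax, band in zip(axes[0], bands):
            sub = frame[frame["band"] == band]
            sessions = sorted(sub["session"].unique())
            data = [sub[sub["session"] == s][value].to_numpy() for s in sessions]
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(sessions) + 1), sessions)
            ax.set_title(band)
            ax.set_ylabel(value)
        fig.tight_layout()
        p = out / fname
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
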