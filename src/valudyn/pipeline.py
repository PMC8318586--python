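"""Pipeline orchestration: synth -> fit -> predict -> features -> regress ->
compare -> groupstats -> report.

Each stage is a function over in-memory objects; :func:`run_pipeline` wires
them with file artifacts under an output directory, stamps every artifact
with the config hash and master seed, and surfaces warnings (dropped
trials, edge-contaminated bins) in the report.  Two presets: ``paper``
(50 subjects, 64 channels, 512 Hz, 1000 ensemble datasets) and ``test``
(8 subjects, 16 channels, 256 Hz, 100 datasets).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ddm, io as vio
from .comparison import MatchResult, joint_criterion, match_timecourse, resample_to_bins
from .ddm import CONDITIONS, DDMParameters, code_attributes, fit_cohort
from .eeg import DEFAULT_BANDS, band_bin_features, band_bin_power, bin_erp, morlet_power, preprocess_epochs
from .groupstats import paired_contrasts, repeated_measures_anova
from .regression import BinGrid, RegressionDesign, group_bin_tests, mass_ols, COEF_NAMES
from .signals import SignalConfig, ensemble_average_signals, model1_timecourses, peak_latency
from .synth import MONTAGE_16, MONTAGE_64, CohortConfig, EffectConfig, generate_cohort, generate_synthetic_eeg

logger = logging.getLogger(__name__)

STAGES = ("synth", "fit", "predict", "features", "regress", "compare", "groupstats", "report")

#: model template -> Model-1/Model-2 coefficient used for matching
TEMPLATE_COEFS = {
    "taste_ac": ("taste_ac", "b_tastiness"),
    "health_ac": ("health_ac", "b_healthiness"),
    "ea_taste": ("ea", "b_tastiness"),
    "ea_health": ("ea", "b_healthiness"),
}


@dataclass
class RunConfig:
    out_dir: str = "valudyn_out"
    behaviour_path: str | None = None
    eeg_path: str | None = None
    stages: tuple = STAGES
    seed: int = 0
    n_subjects: int = 8
    n_trials_per_condition: int = 180
    fs: float = 256.0
    montage: str = "16"
    n_datasets: int = 100
    n_starts: int = 4
    signal_grid_dt: float = 0.002
    freqs_max: float = 80.0
    freq_step: float = 1.0
    r_threshold: float = 0.85
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        if name == "paper":
            base = dict(n_subjects=50, fs=512.0, montage="64", n_datasets=1000, n_starts=8, signal_grid_dt=0.001)
        elif name == "test":
            base = dict(n_subjects=8, fs=256.0, montage="16", n_datasets=100, n_starts=4, signal_grid_dt=0.002)
        else:
            raise ValueError("preset must be 'paper' or 'test'")
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return hashlib.sha1(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    @property
    def montage_obj(self):
        return MONTAGE_64 if str(self.montage) == "64" else MONTAGE_16


# ---------------------------------------------------------------------------
# stages (in-memory)
# ---------------------------------------------------------------------------

def stage_synth(config: RunConfig):
    cohort_cfg = CohortConfig(n_subjects=config.n_subjects, n_trials_per_condition=config.n_trials_per_condition)
    params, trials = generate_cohort(cohort_cfg, seed=config.seed)
    epochs, truth = generate_synthetic_eeg(
        trials, params, effects=EffectConfig(), montage=config.montage_obj, fs=config.fs, seed=config.seed + 1
    )
    return params, trials, epochs, truth


def stage_fit(trials: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    return fit_cohort(trials, n_starts=config.n_starts, seed=config.seed, min_trials=40)


def stage_predict(fits: pd.DataFrame, trials: pd.DataFrame, config: RunConfig):
    """Ensemble-averaged signals and Model-1 coefficient time courses per cell."""
    sig_cfg = SignalConfig(grid_dt=config.signal_grid_dt, n_datasets=config.n_datasets)
    model1 = {}
    for _, row in fits.iterrows():
        g = trials[(trials.subject == row.subject) & (trials.condition == row.condition)]
        g = g[g.choice != "none"]
        params = DDMParameters(*(row[k] for k in ddm.PARAM_NAMES))
        t_c, h_c = code_attributes(g.tastiness.to_numpy(float), g.healthiness.to_numpy(float))
        cell_seed = int(hashlib.sha1(f"{row.subject}|{row.condition}|{config.seed}".encode()).hexdigest()[:7], 16)
        ens = ensemble_average_signals(params, t_c, h_c, SignalConfig(
            grid_dt=sig_cfg.grid_dt, n_datasets=sig_cfg.n_datasets, rng_seed=cell_seed))
        model1[(row.subject, row.condition)] = model1_timecourses(ens, t_c, h_c)
    return model1


def stage_features(epochs: dict, config: RunConfig, freqs=None, bands=None):
    """ERP bins and band-power bins per subject x condition cell."""
    grid = BinGrid.from_sampling(config.fs) if abs(config.fs - 512.0) < 1 else BinGrid()
    bands = bands or DEFAULT_BANDS
    if freqs is None:
        freqs = np.arange(1.0, config.freqs_max + 0.5, config.freq_step)
    feats = {}
    for key, ep in epochs.items():
        pe = preprocess_epochs(ep) if config.fs >= 2 * 100.0 else preprocess_epochs(ep, h_freq=config.fs / 2 - 5)
        erp = bin_erp(pe, grid)
        bp = band_bin_features(ep, grid, freqs=freqs, bands=bands)
        # components axis: ERP then the bands
        feats[key] = np.concatenate([erp[:, :, None, :], bp], axis=2)
    comp_names = ["erp"] + list(bands)
    return feats, grid, comp_names


def stage_regress(feats: dict, trials: pd.DataFrame, grid: BinGrid, epochs: dict):
    """Model-2 mass-univariate regression: betas per cell x channel x
    component x bin for every coefficient."""
    betas = {}
    for key, y in feats.items():
        ep = epochs[key]
        g = trials.loc[ep.trial_index]
        t_c, h_c = code_attributes(g.tastiness.to_numpy(float), g.healthiness.to_numpy(float))
        design = RegressionDesign(t_c, h_c, g.rt.to_numpy(float))
        n, n_ch, n_comp, n_bins = y.shape
        beta, se, _, _ = mass_ols(y.reshape(n, -1), design.matrix)
        betas[key] = {
            c: beta[i].reshape(n_ch, n_comp, n_bins) for i, c in enumerate(COEF_NAMES)
        }
    return betas


def stage_compare(model1: dict, betas: dict, grid: BinGrid, channels, comp_names, config: RunConfig) -> pd.DataFrame:
    """Model-EEG matching plus the joint criterion per condition."""
    subjects = sorted({s for s, _ in betas})
    n_comparisons = len(channels) * len(comp_names)
    entries = []
    for cond in CONDITIONS:
        cells = [s for s in subjects if (s, cond) in betas and (s, cond) in model1]
        if len(cells) < 3:
            continue
        for template, (signal, coef) in TEMPLATE_COEFS.items():
            m1 = [model1[(s, cond)][signal] for s in cells]
            model_mean = np.mean([b[coef] for b in m1], axis=0)
            mt = m1[0].times
            model_bins = resample_to_bins(mt, model_mean, grid)
            in_peak = (mt >= 0) & (mt <= 1.0)
            peak = float(mt[in_peak][np.argmax(np.abs(model_mean[in_peak]))])
            for ch_i, ch in enumerate(channels):
                for co_i, comp in enumerate(comp_names):
                    subj_mat = np.stack([betas[(s, cond)][coef][ch_i, co_i] for s in cells])
                    gt_res = group_bin_tests(subj_mat, coef)
                    match = match_timecourse(subj_mat.mean(axis=0), model_bins, grid.bin_centres)
                    entries.append({
                        "condition": cond, "template": template, "channel": ch, "component": comp,
                        "coefficient": coef, "model_peak_s": peak,
                        "match": match, "group_p": gt_res["p"], "group_mean": gt_res["mean"],
                        "bin_centres": grid.bin_centres, "model_peak_latency": peak,
                    })
    return joint_criterion(entries, r_threshold=config.r_threshold, alpha=config.alpha, n_comparisons=n_comparisons)


def stage_groupstats(fits: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Condition effects on behaviour and fitted parameters."""
    rows = []
    beh = trials[trials.choice != "none"].copy()
    beh["accept"] = (beh.choice == "accept").astype(float)
    for var in ("rt", "accept"):
        wide = beh.pivot_table(index="subject", columns="condition", values=var)[list(CONDITIONS)]
        res = repeated_measures_anova(wide.to_numpy(), condition_names=list(CONDITIONS))
        rows.append({"measure": var, "test": "rm_anova", "statistic": res.statistic, "df1": res.df[0], "df2": res.df[1], "p": res.p})
        for t in paired_contrasts(wide.to_numpy(), [(1, 0), (2, 0), (2, 1)], condition_names=list(CONDITIONS)):
            rows.append({"measure": var, "test": t.name, "statistic": t.statistic, "df1": t.df[0], "df2": np.nan, "p": t.p})
    for par in ddm.PARAM_NAMES:
        wide = fits.pivot(index="subject", columns="condition", values=par)[list(CONDITIONS)]
        if wide.isna().any().any():
            continue
        res = repeated_measures_anova(wide.to_numpy(), condition_names=list(CONDITIONS))
        rows.append({"measure": par, "test": "rm_anova", "statistic": res.statistic, "df1": res.df[0], "df2": res.df[1], "p": res.p})
        for t in paired_contrasts(wide.to_numpy(), [(1, 0), (2, 0), (2, 1)], condition_names=list(CONDITIONS)):
            rows.append({"measure": par, "test": t.name, "statistic": t.statistic, "df1": t.df[0], "df2": np.nan, "p": t.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-level orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns artifact paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts = {}
    timings = {}
    enabled = set(config.stages)

    deps = {
        "fit": {"synth"}, "predict": {"fit"}, "features": {"synth"},
        "regress": {"features"}, "compare": {"predict", "regress"},
        "groupstats": {"fit"}, "report": set(),
    }
    for st in enabled:
        need = deps.get(st, set()) & (set(STAGES) - enabled)
        for miss in need:
            if st == "compare" and miss in ("features", "regress", "predict"):
                raise RuntimeError("compare requires features+regress and predict stages")
            if not ((miss == "synth") and (config.behaviour_path or config.eeg_path)):
                raise RuntimeError(f"stage '{st}' requires stage '{miss}'")

    t0 = time.time()
    trials = epochs = params = truth = None
    if "synth" in enabled:
        params, trials, epochs, truth = stage_synth(config)
        vio.write_behaviour(trials, out / "behaviour.csv")
        vio.write_epochs_h5(epochs, out / "eeg.h5")
        (out / "ground_truth.json").write_text(json.dumps({
            **stamp,
            "alpha_gain_by_subject": truth["alpha_gain_by_subject"],
            "delta_w_tastiness": truth["delta_w_tastiness"],
        }, indent=1))
        params.to_csv(out / "true_params.csv", index=False)
        artifacts["behaviour"] = str(out / "behaviour.csv")
        artifacts["eeg"] = str(out / "eeg.h5")
        timings["synth"] = time.time() - t0
    else:
        if config.behaviour_path:
            trials = vio.read_behaviour(config.behaviour_path)
        if config.eeg_path:
            epochs = vio.read_epochs_h5(config.eeg_path)

    fits = model1 = None
    if "fit" in enabled:
        t0 = time.time()
        fits = stage_fit(trials, config)
        vio.write_params(fits, out / "fitted_params.csv")
        artifacts["fitted_params"] = str(out / "fitted_params.csv")
        timings["fit"] = time.time() - t0

    if "predict" in enabled:
        t0 = time.time()
        model1 = stage_predict(fits, trials, config)
        frames = []
        for (s, c), tcs in model1.items():
            for name, tc in tcs.items():
                df = tc.to_frame()
                df["subject"], df["condition"], df["signal"] = s, c, name
                frames.append(df)
        pd.concat(frames).to_csv(out / "model1_timecourses.csv", index=False)
        artifacts["model1"] = str(out / "model1_timecourses.csv")
        timings["predict"] = time.time() - t0

    feats = grid = comp_names = betas = None
    if "features" in enabled:
        t0 = time.time()
        feats, grid, comp_names = stage_features(epochs, config)
        timings["features"] = time.time() - t0
    if "regress" in enabled:
        t0 = time.time()
        betas = stage_regress(feats, trials, grid, epochs)
        timings["regress"] = time.time() - t0

    criteria = None
    if "compare" in enabled:
        t0 = time.time()
        channels = list(next(iter(epochs.values())).channels)
        criteria = stage_compare(model1, betas, grid, channels, comp_names, config)
        criteria.to_csv(out / "criterion_mask.csv", index=False)
        artifacts["criterion_mask"] = str(out / "criterion_mask.csv")
        timings["compare"] = time.time() - t0

    gstats = None
    if "groupstats" in enabled:
        t0 = time.time()
        gstats = stage_groupstats(fits, trials)
        gstats.to_csv(out / "group_stats.csv", index=False)
        artifacts["group_stats"] = str(out / "group_stats.csv")
        timings["groupstats"] = time.time() - t0

    if "report" in enabled:
        lines = [f"# valudyn run report", "", f"config hash: {stamp['config_hash']}  seed: {stamp['seed']}", ""]
        lines += [f"- {k}: {v:.1f} s" for k, v in timings.items()]
        if fits is not None:
            lines += ["", "## Fitted parameters (condition means)", "",
                      fits.groupby("condition")[list(ddm.PARAM_NAMES)].mean().round(3).to_markdown()]
        if criteria is not None and len(criteria):
            flagged = criteria[criteria.flag]
            lines += ["", f"## Joint-criterion detections ({len(flagged)})", "",
                      (flagged[["condition", "template", "channel", "component", "r_eeg_model"]]
                       .round(3).to_markdown(index=False) if len(flagged) else "none")]
        if gstats is not None:
            lines += ["", "## Group statistics", "", gstats.round(4).to_markdown(index=False)]
        (out / "report.md").write_text("\n".join(lines))
        artifacts["report"] = str(out / "report.md")

    (out / "run_meta.json").write_text(json.dumps({**stamp, "timings": timings, "artifacts": artifacts}, indent=1))
    return {"artifacts": artifacts, "timings": timings, "fits": fits, "criteria": criteria, "group_stats": gstats}
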