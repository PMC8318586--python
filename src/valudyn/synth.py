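"""Synthetic study generator: cohort behaviour and EEG with injected effects.

Emulates the structure of the dietary self-regulation task: each subject
completes 180 trials per condition (NATURAL, HEALTH, DECREASE) with integer
1-6 tastiness/healthiness ratings, choices and RTs generated by the
drift-diffusion model under condition-specific parameters (attribute
weights shrink under regulation), and a 4 s response deadline.

Synthetic EEG epochs (food-locked, -1.0 to 1.5 s) contain 1/f background,
white noise and ongoing alpha (10 Hz) / theta (6 Hz) oscillations.  Effects
are injected as the minimal structure the analysis assumes: an additive
broadband transient shaped by the trial's taste-AC boxcar on fronto-central
channels, a multiplicative EA-shaped alpha envelope modulation (negative
taste coupling, NATURAL only by default), and an early-window theta
envelope modulation (positive taste coupling, regulation conditions only).
Per-subject alpha-gain changes are coupled to the change in the fitted
tastiness weight across conditions so individual-difference analyses have
a known ground truth.  Everything is deterministic under the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import CONDITIONS, DDMParameters, code_attributes, simulate_trials
from .eeg import EpochArray

__all__ = [
    "Montage",
    "MONTAGE_64",
    "MONTAGE_16",
    "CohortConfig",
    "EffectConfig",
    "generate_cohort",
    "generate_synthetic_eeg",
]


@dataclass(frozen=True)
class Montage:
    """Channel labels plus the named subsets that receive injected effects."""

    channels: tuple
    sets: dict

    def __post_init__(self):
        for name, chans in self.sets.items():
            missing = set(chans) - set(self.channels)
            if missing:
                raise ValueError(f"set {name} references unknown channels {missing}")

    def mask(self, set_name: str) -> np.ndarray:
        chans = self.sets[set_name]
        return np.array([c in chans for c in self.channels])


_CH64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P9", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
)

MONTAGE_64 = Montage(
    channels=_CH64,
    sets={
        "fronto_central": ("FC1", "FCz", "FC2", "C1", "Cz", "C2"),
        "frontal": ("F3", "F1", "Fz", "F2", "F4", "AF3", "AFz", "AF4"),
        "parieto_occipital": ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "P3", "P1", "Pz", "P2", "P4"),
        "occipital": ("O1", "Oz", "O2"),
    },
)

MONTAGE_16 = Montage(
    channels=("Fz", "F3", "F4", "FC1", "FCz", "FC2", "Cz", "C3", "C4", "Pz", "P3", "P4", "PO3", "PO4", "Oz", "O1"),
    sets={
        "fronto_central": ("FC1", "FCz", "FC2", "Cz"),
        "frontal": ("Fz", "F3", "F4"),
        "parieto_occipital": ("Pz", "P3", "P4", "PO3", "PO4", "Oz", "O1"),
        "occipital": ("Oz", "O1"),
    },
)

#: per-condition parameter means; NATURAL is centred on the worked-example
#: parameter set, regulation shifts follow the observed directions (the
#: tastiness weight drops under both strategies, the healthiness weight
#: rises when attending health, the value constant drops and the threshold
#: rises when down-regulating desire)
DEFAULT_PARAM_MEANS = {
    "NATURAL": {"w_tastiness": 0.7, "w_healthiness": 0.1, "val_const": 0.5, "threshold": 0.9, "sp_bias": 0.45, "ndt": 0.462},
    "HEALTH": {"w_tastiness": 0.35, "w_healthiness": 0.45, "val_const": 0.35, "threshold": 1.0, "sp_bias": 0.45, "ndt": 0.462},
    "DECREASE": {"w_tastiness": 0.35, "w_healthiness": 0.1, "val_const": 0.05, "threshold": 1.05, "sp_bias": 0.45, "ndt": 0.462},
}

DEFAULT_PARAM_SDS = {
    "w_tastiness": 0.15, "w_healthiness": 0.12, "val_const": 0.15,
    "threshold": 0.12, "sp_bias": 0.05, "ndt": 0.06,
}

_PARAM_BOUNDS = {
    "w_tastiness": (-5, 5), "w_healthiness": (-5, 5), "val_const": (-5, 5),
    "threshold": (0.3, 6.0), "sp_bias": (0.15, 0.85), "ndt": (0.15, 1.2),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale knobs for the behavioural generator."""

    n_subjects: int = 20
    n_trials_per_condition: int = 180
    rating_corr: float = -0.2
    param_means: dict = field(default_factory=lambda: {c: dict(DEFAULT_PARAM_MEANS[c]) for c in CONDITIONS})
    param_sds: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SDS))
    deadline: float = 4.0
    centred_coding: bool = True

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("invalid cohort size")
        for cond, means in self.param_means.items():
            for k, v in means.items():
                lo, hi = _PARAM_BOUNDS[k]
                if not lo <= v <= hi:
                    raise ValueError(f"{cond}.{k}={v} outside generator bounds {(lo, hi)}")


def _draw_ratings(rng, n, corr):
    """Correlated integer 1-6 tastiness/healthiness ratings."""
    cov = np.array([[1.0, corr], [corr, 1.0]])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2)) @ L.T
    ratings = np.clip(np.round(3.5 + 1.3 * z), 1, 6).astype(int)
    return ratings[:, 0], ratings[:, 1]


def generate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Draw ground-truth parameters and simulate the behavioural study.

    Returns ``(params_df, trials_df)``: one ground-truth parameter row per
    subject x condition, and the full trial table with choices and RTs
    (``choice='none'`` and missing RT past the 4 s deadline).
    """
    config = config or CohortConfig()
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    p_rows, t_rows = [], []
    for si in range(config.n_subjects):
        rng = np.random.default_rng(sub_seeds[si])
        subj = f"S{si + 1:03d}"
        for cond in CONDITIONS:
            means = config.param_means[cond]
            draw = {}
            for k, mu in means.items():
                lo, hi = _PARAM_BOUNDS[k]
                v = rng.normal(mu, config.param_sds[k])
                draw[k] = float(np.clip(v, lo, hi))
            params = DDMParameters(**draw)
            taste, health = _draw_ratings(rng, config.n_trials_per_condition, config.rating_corr)
            t_c, h_c = code_attributes(taste, health, config.centred_coding)
            choice, rt = simulate_trials(params, t_c, h_c, dt=0.001, horizon=config.deadline - params.ndt, rng=rng)
            over = np.isfinite(rt) & (rt > config.deadline)
            choice[over], rt[over] = 0, np.nan
            p_rows.append({"subject": subj, "condition": cond, **draw})
            for i in range(config.n_trials_per_condition):
                t_rows.append({
                    "subject": subj, "condition": cond, "food": f"food{i % 60:03d}",
                    "tastiness": int(taste[i]), "healthiness": int(health[i]),
                    "choice": {1: "accept", -1: "reject", 0: "none"}[int(choice[i])],
                    "rt": float(rt[i]) if np.isfinite(rt[i]) else np.nan,
                })
    return pd.DataFrame(p_rows), pd.DataFrame(t_rows)


@dataclass(frozen=True)
class EffectConfig:
    """Injected EEG effect structure and background noise model.

    Gains are in relative envelope units per coded-rating unit (alpha /
    theta) or microvolts per coded-rating unit (ERP).  The alpha effect is
    EA-shaped with negative taste coupling and lives in NATURAL only; the
    theta effect occupies a 0.2-0.5 s window with positive taste coupling
    in the regulation conditions; the ERP transient follows the taste-AC
    boxcar in all conditions.  ``coupling_rho`` is the target correlation
    between the per-subject alpha-gain change (DECREASE - NATURAL) and the
    change in the true tastiness weight.
    """

    erp_gain: float = 1.2
    alpha_gain: float = -0.22
    alpha_gain_sd: float = 0.05
    theta_gain: float = 0.18
    theta_window: tuple = (0.2, 0.5)
    coupling_rho: float = -0.5
    coupling_delta_sd: float = 0.08
    pink_exponent: float = 1.0
    pink_amp: float = 1.0
    white_sd: float = 0.5
    alpha_amp: float = 3.0
    theta_amp: float = 2.0
    erp_channel_set: str = "fronto_central"
    alpha_channel_sets: tuple = ("frontal", "parieto_occipital")
    theta_channel_sets: tuple = ("frontal", "occipital")

    def __post_init__(self):
        for g in (self.erp_gain, self.alpha_gain, self.theta_gain):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")


def _pink_noise(rng, shape, n_samp, fs, exponent, amp):
    """1/f^exponent background via spectral shaping."""
    n_f = n_samp // 2 + 1
    f = np.fft.rfftfreq(n_samp, 1.0 / fs)
    scale = np.zeros(n_f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((*shape, n_f)) + 1j * rng.standard_normal((*shape, n_f))) * scale
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    x = x / max(np.std(x), 1e-12) * amp
    return x


def _alpha_gains(rng, n_subjects, delta_w, effects: EffectConfig):
    """Per-subject alpha envelope gains with the configured cross-subject
    coupling between the DECREASE-NATURAL gain change and delta w_tastiness."""
    g_nat = effects.alpha_gain + rng.standard_normal(n_subjects) * effects.alpha_gain_sd
    dw = np.asarray(delta_w, float)
    z = (dw - dw.mean()) / max(dw.std(), 1e-12)
    eps = rng.standard_normal(n_subjects)
    # orthogonalise the noise component against z so the sample correlation
    # of the gain change with delta-w equals the target exactly
    eps = eps - z * (eps @ z) / max(z @ z, 1e-12)
    eps = (eps - eps.mean()) / max(eps.std(), 1e-12)
    rho = effects.coupling_rho
    q = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
    delta_g = -g_nat.mean() + effects.coupling_delta_sd * q
    g_dec = g_nat + delta_g
    return {"NATURAL": g_nat, "HEALTH": np.zeros(n_subjects), "DECREASE": g_dec}


def generate_synthetic_eeg(
    trials: pd.DataFrame,
    ground_truth: pd.DataFrame,
    effects: EffectConfig | None = None,
    montage: Montage = MONTAGE_16,
    fs: float = 512.0,
    seed: int = 0,
    epoch_window: tuple = (-1.0, 1.5),
    conditions=CONDITIONS,
):
    """Generate food-locked epochs for every subject x condition.

    ``trials`` and ``ground_truth`` come from :func:`generate_cohort`.
    No-response trials are skipped.  Returns ``(epochs, truth)`` where
    ``epochs`` maps (subject, condition) to an :class:`EpochArray` whose
    ``trial_index`` points into ``trials``, and ``truth`` records every
    injected gain and template parameter for recovery tests.
    """
    effects = effects or EffectConfig()
    master = np.random.default_rng(seed)
    subjects = sorted(trials.subject.unique())
    gt = ground_truth.set_index(["subject", "condition"])
    # per-subject alpha gains coupled to the true tastiness-weight change
    dw = np.array([
        gt.loc[(s, "DECREASE"), "w_tastiness"] - gt.loc[(s, "NATURAL"), "w_tastiness"] for s in subjects
    ])
    gains_alpha = _alpha_gains(master, len(subjects), dw, effects)

    n_samp = int(round((epoch_window[1] - epoch_window[0]) * fs))
    times = epoch_window[0] + np.arange(n_samp) / fs
    erp_mask = montage.mask(effects.erp_channel_set)
    alpha_mask = np.zeros(len(montage.channels), bool)
    for s in effects.alpha_channel_sets:
        alpha_mask |= montage.mask(s)
    theta_mask = np.zeros(len(montage.channels), bool)
    for s in effects.theta_channel_sets:
        theta_mask |= montage.mask(s)
    n_ch = len(montage.channels)

    sub_seeds = master.integers(0, 2**31 - 1, size=(len(subjects), len(conditions)))
    epochs, truth_rows = {}, []
    for si, subj in enumerate(subjects):
        for ci, cond in enumerate(conditions):
            rng = np.random.default_rng(sub_seeds[si, ci])
            g = trials[(trials.subject == subj) & (trials.condition == cond)]
            usable = g[g.choice != "none"]
            idx = usable.index.to_numpy()
            n_tr = len(usable)
            if n_tr == 0:
                continue
            pars = gt.loc[(subj, cond)]
            ndt = float(pars["ndt"])
            onset = max(0.0, ndt - 0.080)
            taste_c, _ = code_attributes(usable.tastiness.to_numpy(float), usable.healthiness.to_numpy(float))
            rt = usable.rt.to_numpy(float)

            # trial-wise templates on the epoch grid
            tt = times[None, :]
            rt_col = rt[:, None]
            boxcar = ((tt >= onset) & (tt <= rt_col)).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                ramp = np.clip((tt - onset) / np.maximum(rt_col - onset, 1e-6), 0.0, 1.0) * boxcar
            th_win = ((tt >= effects.theta_window[0]) & (tt <= effects.theta_window[1])).astype(float)

            x = _pink_noise(rng, (n_tr, n_ch), n_samp, fs, effects.pink_exponent, effects.pink_amp)
            x += rng.standard_normal((n_tr, n_ch, n_samp)) * effects.white_sd

            ga = gains_alpha[cond][si] if cond in gains_alpha else 0.0
            phase = rng.uniform(0, 2 * np.pi, (n_tr, n_ch, 1))
            osc_a = np.sin(2 * np.pi * 10.0 * tt[None, :, :] + phase)
            env_a = np.ones((n_tr, 1, n_samp))
            env_a = env_a + (ga * taste_c[:, None, None]) * ramp[:, None, :]
            env_mask = np.where(alpha_mask[None, :, None], np.clip(env_a, 0.05, None), 1.0)
            x += effects.alpha_amp * env_mask * osc_a

            gt_theta = effects.theta_gain if cond in ("HEALTH", "DECREASE") else 0.0
            phase = rng.uniform(0, 2 * np.pi, (n_tr, n_ch, 1))
            osc_t = np.sin(2 * np.pi * 6.0 * tt[None, :, :] + phase)
            env_t = 1.0 + (gt_theta * taste_c[:, None, None]) * th_win[:, None, :]
            env_mask_t = np.where(theta_mask[None, :, None], np.clip(env_t, 0.05, None), 1.0)
            x += effects.theta_amp * env_mask_t * osc_t

            erp = effects.erp_gain * taste_c[:, None] * boxcar
            x[:, erp_mask, :] += erp[:, None, :]

            epochs[(subj, cond)] = EpochArray(x, fs, epoch_window[0], list(montage.channels), trial_index=idx)
            truth_rows.append({
                "subject": subj, "condition": cond,
                "alpha_gain": float(ga), "theta_gain": float(gt_theta), "erp_gain": effects.erp_gain,
                "onset": onset, "n_trials": n_tr,
            })
    truth = {
        "per_cell": pd.DataFrame(truth_rows),
        "alpha_gain_by_subject": {c: gains_alpha[c].tolist() for c in gains_alpha},
        "delta_w_tastiness": dw.tolist(),
        "subjects": subjects,
        "effects": effects,
    }
    return epochs, truth
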