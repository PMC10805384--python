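"""End-to-end orchestration of the empirical and in-silico analyses.

``run_empirical`` takes per-subject paired cortical/thalamic recordings
through trial segmentation, cleaning, band-pair directed-transfer testing
in both directions (low 1-13 Hz send -> high 52-104 Hz receive), chaoticity
estimation, per-subject aggregation (cross-trial medians, harmonic-mean p,
baseline normalization), and group statistics (one-tailed Wilcoxon across
subjects, binomial test of per-subject significance) plus control analyses
(non-spectral TE, phase-amplitude modulation index, permutation ANCOVA with
band-power covariates).

``run_insilico`` sweeps simulated anesthetic and seizure dose, collecting
per-dose median Lyapunov exponents, 0-1 test K, and bidirectional
band-pair transfer strengths -- the strength-versus-criticality curve.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import chaos as _chaos
from . import spectral as _spectral
from . import stats as _stats
from .meanfield import ModelConfig, dose_sweep
from .preprocess import Recording, clean, resample, segment_trials, welch_psd

log = logging.getLogger("thalcort.pipeline")

__all__ = ["EmpiricalConfig", "run_empirical", "run_insilico"]

LOW_LEVELS = (5, 6, 7, 8)    # ~0.81-13 Hz at 416 Hz
HIGH_LEVELS = (2,)           # 52-104 Hz at 416 Hz
WORKING_FS_TE = 416.0
WORKING_FS_CHAOS = 500.0


@dataclass
class EmpiricalConfig:
    n_surr: int = 100
    seed: int = 0
    trial_length: float = 10.0
    controls: bool = True
    knn: int = 4
    u_candidates: tuple = tuple(range(1, 21))
    dims: tuple = (1, 2, 3, 4, 5)


def _pair_channels(trial):
    ctx = [i for i, r in enumerate(trial.channel_regions) if r == "cortex"]
    thal = [i for i, r in enumerate(trial.channel_regions) if r == "thalamus"]
    return [(c, t) for c in ctx for t in thal]


def _to_rate(trial, fs):
    if trial.fs == fs:
        return trial
    if trial.fs < fs:
        if trial.fs < 200:
            raise ValueError(f"sample rate {trial.fs} too low to analyze")
        return trial  # already below the working rate: use native rate
    return resample(trial, fs)


def _trial_measures(trial, cfg: EmpiricalConfig, seed: int):
    """Per-trial bidirectional band-pair TE, chaoticity, and controls."""
    if trial.fs < WORKING_FS_TE:
        raise ValueError(
            f"trial at {trial.fs} Hz cannot reach the {WORKING_FS_TE} Hz "
            "working rate")
    te416 = _to_rate(trial, WORKING_FS_TE)
    ch500 = _to_rate(trial, WORKING_FS_CHAOS)
    bp = _spectral.BandPair(send_levels=LOW_LEVELS, recv_levels=HIGH_LEVELS)
    pairs = _pair_channels(trial)
    if not pairs:
        raise ValueError("trial lacks a cortex/thalamus channel pair")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, (ci, ti) in enumerate(pairs):
            x = te416.data[ci]
            y = te416.data[ti]
            r_ct = _spectral.soso_test(x, y, bp, n_surr=cfg.n_surr,
                                       seed=seed + 17 * j, knn=cfg.knn,
                                       u_candidates=cfg.u_candidates,
                                       dims=cfg.dims)
            r_tc = _spectral.soso_test(y, x, bp, n_surr=cfg.n_surr,
                                       seed=seed + 17 * j + 1, knn=cfg.knn,
                                       u_candidates=cfg.u_candidates,
                                       dims=cfg.dims)
            row = {
                "strength_ct": r_ct.strength, "p_ct": r_ct.p,
                "strength_tc": r_tc.strength, "p_tc": r_tc.p,
            }
            if cfg.controls:
                row["te_ct"] = r_ct.te_original
                row["te_tc"] = r_tc.te_original
                row["mi_ct"] = _stats.modulation_index(x, y, WORKING_FS_TE)
                row["mi_tc"] = _stats.modulation_index(y, x, WORKING_FS_TE)
                f, p = welch_psd(te416.data, fs=WORKING_FS_TE)
                lo = (f >= 1) & (f <= 13)
                hi = (f >= 52) & (f <= 104)
                row["power_low"] = float(p[:, lo].mean())
                row["power_high"] = float(p[:, hi].mean())
            rows.append(row)
    med = {k: float(np.median([r[k] for r in rows])) for k in rows[0]}
    try:
        med["K"] = _chaos.median_chaoticity(list(ch500.data), WORKING_FS_CHAOS,
                                            seed=seed).K
    except ValueError:
        med["K"] = np.nan
    # harmonic-mean combination needs the raw per-pair p-values, not medians
    med["p_ct"] = _spectral.harmonic_mean_p([r["p_ct"] for r in rows])
    med["p_tc"] = _spectral.harmonic_mean_p([r["p_tc"] for r in rows])
    return med


def run_empirical(recordings: dict, cfg: EmpiricalConfig | None = None):
    """Run the full empirical analysis on per-subject recording sets.

    ``recordings`` maps subject -> {state: Recording}; every subject must
    include a "waking" entry (subjects without one are skipped with a log
    entry).  Returns ``{"trials": ..., "subjects": ..., "group": ...}``
    DataFrames; every row carries seed and config provenance.
    """
    cfg = cfg or EmpiricalConfig()
    if not recordings:
        raise ValueError("empty recording set")
    cfg_hash = hashlib.sha1(
        json.dumps(asdict(cfg), default=str, sort_keys=True).encode()
    ).hexdigest()[:10]
    trial_rows = []
    for si, (subject, states) in enumerate(sorted(recordings.items())):
        if "waking" not in states:
            log.warning("subject %s lacks a waking baseline: skipped", subject)
            continue
        for state, rec in sorted(states.items()):
            t_start = time.perf_counter()
            trials = [clean(t) for t in segment_trials(rec, cfg.trial_length)]
            trials = [t for t in trials if not t.artifact_flag]
            for trial in trials:
                seed = cfg.seed + 1000 * si + 10 * trial.index
                med = _trial_measures(trial, cfg, seed)
                med.update(subject=subject, state=state, trial=trial.index,
                           seed=seed, config=cfg_hash, n_surr=cfg.n_surr)
                trial_rows.append(med)
            log.info("subject %s state %s: %d trials in %.1f s", subject,
                     state, len(trials), time.perf_counter() - t_start)
    trials_df = pd.DataFrame(trial_rows)
    if trials_df.empty:
        raise ValueError("no analyzable trials (missing baselines or data)")

    subj_rows = []
    for (subject, state), g in trials_df.groupby(["subject", "state"]):
        row = {"subject": subject, "state": state, "n_trials": len(g),
               "config": cfg_hash}
        for d in ("ct", "tc"):
            row[f"strength_{d}"] = float(g[f"strength_{d}"].median())
            row[f"hmp_{d}"] = _spectral.harmonic_mean_p(g[f"p_{d}"].to_numpy())
        row["K"] = float(g["K"].median())
        subj_rows.append(row)
    subjects_df = pd.DataFrame(subj_rows)

    # normalize to each subject's waking baseline
    base = subjects_df[subjects_df.state == "waking"].set_index("subject")
    for d in ("ct", "tc"):
        norm = []
        for _, r in subjects_df.iterrows():
            b = base.loc[r.subject, f"strength_{d}"]
            norm.append(np.nan if b == 0
                        else float(_stats.normalize_to_baseline(
                            r[f"strength_{d}"], b)))
        subjects_df[f"strength_{d}_norm"] = norm

    group_rows = []
    states = [s for s in subjects_df.state.unique() if s != "waking"]
    for state in states:
        merged = base.join(
            subjects_df[subjects_df.state == state].set_index("subject"),
            lsuffix="_wake", rsuffix="_alt", how="inner")
        for d in ("ct", "tc"):
            sample = _stats.PairedSample(
                subjects=list(merged.index),
                baseline=merged[f"strength_{d}_wake"].to_numpy(),
                condition=merged[f"strength_{d}_alt"].to_numpy())
            direction = "greater" if state == "psychedelic" else "less"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = _stats.wilcoxon_one_tailed(sample, direction)
            except ValueError as exc:
                log.warning("wilcoxon skipped for %s/%s: %s", state, d, exc)
                p = np.nan
            group_rows.append({"state": state, "direction": d,
                               "test": "wilcoxon", "p": p,
                               "n": len(merged), "config": cfg_hash})
    for d in ("ct", "tc"):
        wake = subjects_df[subjects_df.state == "waking"]
        succ = int((wake[f"hmp_{d}"] < 0.05).sum())
        group_rows.append({"state": "waking", "direction": d,
                           "test": "binomial",
                           "p": _stats.binomial_subjects(succ, len(wake)),
                           "n": len(wake), "config": cfg_hash})
    if cfg.controls and {"power_low", "power_high"} <= set(trials_df.columns):
        for d in ("ct", "tc"):
            p = _stats.perm_ancova(
                trials_df[f"strength_{d}"].to_numpy(),
                trials_df["state"].to_numpy(),
                trials_df[["power_low", "power_high"]].to_numpy(),
                n_perm=2000, seed=cfg.seed)
            group_rows.append({"state": "all", "direction": d,
                               "test": "perm_ancova", "p": p,
                               "n": len(trials_df), "config": cfg_hash})
    return {"trials": trials_df, "subjects": subjects_df,
            "group": pd.DataFrame(group_rows)}


def run_insilico(waking_cfg: ModelConfig, anesthesia_cfg: ModelConfig,
                 seizure_cfg: ModelConfig, doses=None, n_runs: int = 10,
                 seeds=None, **sweep_kwargs) -> pd.DataFrame:
    """Dose sweeps along both arms: anesthetic (chaotic) and seizure (periodic).

    Returns the combined per-dose table with signed dose (negative = seizure
    arm, positive = anesthetic arm), median LLE, median K of the 1-13 Hz
    filtered LFPs, and median bidirectional band-pair TE strengths.
    """
    if doses is None:
        doses = np.linspace(0, 1, 50)
    doses = np.asarray(doses, dtype=float)
    t0 = time.perf_counter()
    anes = dose_sweep(waking_cfg, anesthesia_cfg, doses, n_runs=n_runs,
                      seeds=seeds, **sweep_kwargs)
    anes["arm"] = "anesthetic"
    log.info("anesthetic arm done in %.1f s", time.perf_counter() - t0)
    seiz = dose_sweep(waking_cfg, seizure_cfg,
                      [d for d in doses if d > 0], n_runs=n_runs,
                      seeds=seeds, **sweep_kwargs)
    seiz["arm"] = "seizure"
    seiz["dose"] = -seiz["dose"]
    log.info("both arms done in %.1f s", time.perf_counter() - t0)
    out = pd.concat([seiz.iloc[::-1], anes], ignore_index=True)
    return out.sort_values("dose").reset_index(drop=True)
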