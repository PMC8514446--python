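"""End-to-end orchestration: simulate -> metrics -> fit -> BMS -> group stats.

The pipeline consumes a trialwise keystroke CSV (one row per keystroke; see
``rewardtap.simulate.CSV_COLUMNS``) or simulates one, then reproduces the
analysis chain: behavioural metrics per block, per-session joint HGF +
response-model fits over the candidate model table, random-effects model
selection over subjects, and the non-parametric group statistics, writing
tidy TSV/JSON artifacts plus a Markdown report into the output directory.
Every stochastic stage derives its seed from the run seed, and the resolved
configuration (with a content hash) is serialised alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bms import random_effects_bms
from .hgf import HGFParams
from .metrics import (
    Block,
    InsufficientDataError,
    ScoreSeries,
    Trial,
    block_variability,
    exploration_after_outcome,
    exploration_series,
    iki_difference_norm,
    reward_score,
    within_trial_cv,
    DEFAULT_LOG_EPS,
)
from .response import FitConfig, FitFailureError, enumerate_response_models, fit_subject
from .simulate import CSV_COLUMNS, AgentConfig, simulate_cohort
from .stats import (
    adaptive_fdr,
    bootstrap_ci_delta,
    paired_perm_test,
    perm_factorial_rm,
    perm_oneway_rm,
)

__all__ = ["RunConfig", "run_pipeline", "load_sessions", "STAGES"]

STAGES = ("simulate", "metrics", "fit", "bms", "stats", "report")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    ``condition_overrides`` maps condition names to ``AgentConfig`` field
    overrides for the simulator (identical conditions by default — the null
    cohort).  ``models`` is either ``"all"`` (the full candidate table) or a
    list of model ids.
    """

    out_dir: str = "rewardtap_out"
    input_csv: str | None = None
    n_subjects: int = 19
    condition_overrides: dict = field(
        default_factory=lambda: {"lM1": {}, "rFPC": {}, "sham": {}})
    seed: int = 0
    n_perm: int = 5000
    q: float = 0.05
    n_boot: int = 5000
    n_bms_samples: int = 1_000_000
    models: object = "all"
    n_restarts: int = 8
    target_norm: float = 1.9596
    hgf: dict = field(default_factory=dict)
    log_eps: float = DEFAULT_LOG_EPS
    #: z-score each response series within session before fitting, so log
    #: evidences are comparable across response variables in the BMS
    standardize_responses: bool = True

    def hgf_params(self) -> HGFParams:
        return HGFParams(**self.hgf)

    def model_table(self):
        table = enumerate_response_models()
        if self.models == "all":
            return table
        wanted = set(self.models)
        table = [m for m in table if m.model_id in wanted]
        missing = wanted - {m.model_id for m in table}
        if missing:
            raise ValueError(f"unknown model ids: {sorted(missing)}")
        return table

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data loading

def _trial_from_rows(rows: pd.DataFrame) -> Trial:
    rows = rows.sort_values("position")
    return Trial(
        iki=rows["iki_s"].to_numpy(dtype=float)[1:],
        velocity=rows["velocity"].to_numpy(dtype=float),
        pitches=rows["pitch"].to_numpy(),
        is_error=bool(rows["is_error"].max()),
    )


def load_sessions(data: pd.DataFrame, target_norm: float) -> dict:
    """Group a trialwise keystroke table into per-session block structures.

    Returns ``{(subject_id, condition): {"baseline": Block, "learning":
    [Block, ...], "scores": ScoreSeries}}``.  Scores are recomputed from the
    performed IKI patterns through the reward mapping (the feedback the task
    machine produced is a deterministic function of the performance); error
    trials are scored as played.
    """
    missing = set(CSV_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"input table lacks columns {sorted(missing)}")
    sessions: dict = {}
    for (subj, cond), g in data.groupby(["subject_id", "condition"], sort=True):
        baseline_trials = [
            _trial_from_rows(tg)
            for _, tg in g[g.phase == "baseline"].groupby("trial", sort=True)
        ]
        learning = g[g.phase == "learning"]
        blocks = []
        all_scores = []
        for block_idx, bg in learning.groupby("block", sort=True):
            trials = [
                _trial_from_rows(tg) for _, tg in bg.groupby("trial", sort=True)
            ]
            scores = np.array([
                reward_score(iki_difference_norm(t.iki), target_norm)
                for t in trials
            ])
            blocks.append(Block(
                phase="learning", trials=trials,
                block_index=int(block_idx), scores=scores,
            ))
            all_scores.append(scores)
        sessions[(subj, cond)] = {
            "baseline": Block(phase="baseline", trials=baseline_trials),
            "learning": blocks,
            "scores": ScoreSeries(np.concatenate(all_scores))
            if all_scores else None,
        }
    return sessions


# ---------------------------------------------------------------------------
# response-variable extraction

def _response_series(session: dict, variable: str, eps: float) -> np.ndarray:
    """Trialwise response series for one model's response variable.

    Each series is a log unsigned change from the previous trial; the last
    baseline trial provides the predecessor of learning trial 1, so the
    series has one value per learning trial.
    """
    baseline_last = session["baseline"].trials[-1]
    trials = [baseline_last] + [
        t for b in session["learning"] for t in b.trials
    ]
    if variable == "timing_exploration":
        series = [within_trial_cv(t) for t in trials]
    elif variable == "velocity_exploration":
        series = [float(np.std(t.velocity) / np.mean(t.velocity)) for t in trials]
    elif variable == "tempo_change":
        series = [float(np.mean(t.iki)) for t in trials]
    elif variable == "velocity_change":
        series = [float(np.mean(t.velocity)) for t in trials]
    else:
        raise ValueError(f"unknown response variable {variable!r}")
    return exploration_series(np.asarray(series), eps=eps)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out: Path) -> pd.DataFrame:
    conditions = {
        name: AgentConfig(**{**overrides, **({"hgf_params": cfg.hgf_params()}
                                             if cfg.hgf else {})})
        for name, overrides in cfg.condition_overrides.items()
    }
    data, latents, gen = simulate_cohort(
        n_subjects=cfg.n_subjects,
        condition_configs=conditions,
        seed=cfg.seed,
    )
    data.to_csv(out / "cohort.csv", index=False)
    latents.to_csv(out / "latents.tsv", sep="\t", index=False)
    gen.to_csv(out / "gen_params.tsv", sep="\t", index=False)
    return data


def stage_metrics(cfg: RunConfig, out: Path, sessions: dict) -> pd.DataFrame:
    rows = []
    outcome_rows = []
    for (subj, cond), sess in sorted(sessions.items()):
        blocks = [("baseline", 0, sess["baseline"])] + [
            ("learning", b.block_index, b) for b in sess["learning"]
        ]
        for phase, idx, block in blocks:
            row = {"subject_id": subj, "condition": cond, "phase": phase,
                   "block": idx, "n_trials": block.n_trials,
                   "error_rate": block.error_rate()}
            try:
                row["cv_timing"] = block_variability(block, "timing")
                row["cv_velocity"] = block_variability(block, "velocity")
            except InsufficientDataError:
                row["cv_timing"] = row["cv_velocity"] = math.nan
            usable = [t for t in block.trials if not t.is_error]
            row["mean_iki"] = float(np.mean([np.mean(t.iki) for t in usable]))
            row["mean_velocity"] = float(
                np.mean([np.mean(t.velocity) for t in usable]))
            row["score_mean"] = (
                float(np.mean(block.scores)) if block.scores is not None
                else math.nan)
            rows.append(row)
        if sess["scores"] is not None:
            y = _response_series(sess, "timing_exploration", cfg.log_eps)
            try:
                after_drop, after_rise = exploration_after_outcome(
                    sess["scores"].u, y[1:])
                outcome_rows.append({
                    "subject_id": subj, "condition": cond,
                    "explore_after_drop": after_drop,
                    "explore_after_rise": after_rise,
                })
            except InsufficientDataError:
                pass
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame(outcome_rows).to_csv(
        out / "exploration_outcome.tsv", sep="\t", index=False)
    return metrics


def stage_fit(cfg: RunConfig, out: Path, sessions: dict) -> pd.DataFrame:
    table = cfg.model_table()
    fit_cfg = FitConfig(
        base_params=cfg.hgf_params(),
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
    )
    rows = []
    for (subj, cond), sess in sorted(sessions.items()):
        if sess["scores"] is None:
            continue
        u = sess["scores"]
        series_cache = {}
        for spec in table:
            rv = spec.response_variable
            if rv not in series_cache:
                y = _response_series(sess, rv, cfg.log_eps)
                if cfg.standardize_responses:
                    sd = y.std()
                    y = (y - y.mean()) / (sd if sd > 0 else 1.0)
                series_cache[rv] = y
            try:
                fit = fit_subject(u, series_cache[rv], spec, fit_cfg)
            except FitFailureError as err:
                rows.append({"subject_id": subj, "condition": cond,
                             "model_id": spec.model_id, "family": spec.family,
                             "response_variable": rv, "converged": False,
                             "error": str(err)})
                continue
            rows.append({
                "subject_id": subj, "condition": cond,
                "model_id": spec.model_id, "family": spec.family,
                "response_variable": rv,
                "beta0": fit.beta0, "beta1": fit.beta1, "beta2": fit.beta2,
                "zeta": fit.zeta, "omega": fit.params.omega,
                "lme": fit.lme, "converged": fit.converged,
            })
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    return fits


def stage_bms(cfg: RunConfig, out: Path, fits: pd.DataFrame) -> dict:
    """Random-effects BMS over subjects, pooling sessions within subject.

    Sessions of one subject are assumed to share the subject's model, so
    their log evidences add (fixed-effects pooling within subject, random
    effects across subjects).
    """
    ok = fits[fits.converged.notna()]
    lme = ok.pivot_table(index="subject_id", columns="model_id", values="lme",
                         aggfunc="sum")
    if lme.isna().any().any():
        raise ValueError("missing LME cells; cannot run BMS")
    result = random_effects_bms(
        lme.to_numpy(), n_samples=cfg.n_bms_samples, seed=cfg.seed + 7)
    payload = result.to_dict()
    payload["model_ids"] = list(lme.columns)
    best = int(np.argmax(result.xp))
    payload["winning_model"] = payload["model_ids"][best]
    payload["winning_xp"] = float(result.xp[best])
    payload["winning_frequency"] = float(result.r[best])
    (out / "bms.json").write_text(json.dumps(payload, indent=2))
    return payload


def _pairwise_posthoc(values: pd.DataFrame, conditions: list[str],
                      cfg: RunConfig, seed: int) -> list[dict]:
    """Paired permutation tests with effect sizes for all condition pairs."""
    out = []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            x = values[a].to_numpy()
            y = values[b].to_numpy()
            res = paired_perm_test(x, y, n_perm=cfg.n_perm, seed=seed)
            eff = bootstrap_ci_delta(x, y, n_boot=cfg.n_boot,
                                     seed=seed + 1)
            out.append({
                "pair": f"{a}-{b}", "mean_diff": res.observed_stat,
                "p": res.p, "n_perm": res.n_perm,
                "delta_dep": eff.delta_dep,
                "ci": [eff.ci_low, eff.ci_high],
            })
    return out


def stage_stats(cfg: RunConfig, out: Path, metrics: pd.DataFrame,
                fits: pd.DataFrame, bms_payload: dict) -> dict:
    learning = metrics[metrics.phase == "learning"]
    conditions = sorted(learning.condition.unique())
    blocks = sorted(learning.block.unique())
    seed = cfg.seed + 101
    results: dict = {"factorial": {}, "oneway_change": {}, "betas": {}}

    def cube(var: str) -> np.ndarray:
        wide = learning.pivot_table(index="subject_id", columns=["block", "condition"],
                                    values=var)
        n = wide.shape[0]
        return wide.to_numpy().reshape(n, len(blocks), len(conditions))

    if len(conditions) >= 2 and len(blocks) >= 2:
        for var in ("score_mean", "cv_timing", "cv_velocity"):
            fac = perm_factorial_rm(cube(var), n_perm=cfg.n_perm, seed=seed)
            results["factorial"][var] = {
                "block": {"stat": fac.factor_a.observed_stat, "p": fac.factor_a.p},
                "stimulation": {"stat": fac.factor_b.observed_stat,
                                "p": fac.factor_b.p},
                "interaction": {"stat": fac.interaction.observed_stat,
                                "p": fac.interaction.p},
                "n_perm": cfg.n_perm,
            }

    # offline (last block) minus online (first block) changes, per condition
    if len(conditions) >= 2:
        b_first, b_last = blocks[0], blocks[-1]
        for var in ("score_mean", "cv_timing"):
            wide_first = learning[learning.block == b_first].pivot(
                index="subject_id", columns="condition", values=var)
            wide_last = learning[learning.block == b_last].pivot(
                index="subject_id", columns="condition", values=var)
            change = wide_last - wide_first
            res = perm_oneway_rm(change[conditions].to_numpy(),
                                 n_perm=cfg.n_perm, seed=seed + 3)
            posthoc = _pairwise_posthoc(change, conditions, cfg, seed + 5)
            fdr = adaptive_fdr([p["p"] for p in posthoc], q=cfg.q)
            results["oneway_change"][var] = {
                "stat": res.observed_stat, "p": res.p,
                "exhaustive": res.exhaustive,
                "change_means": {c: float(change[c].mean()) for c in conditions},
                "change_sems": {
                    c: float(change[c].std(ddof=1) / math.sqrt(len(change)))
                    for c in conditions},
                "posthoc": posthoc, "p_fdr": fdr.p_fdr,
                "rejected": fdr.rejected.tolist(),
            }

    # winning-model coefficients across stimulation conditions
    win = bms_payload.get("winning_model")
    wfits = fits[(fits.model_id == win) & fits.converged.notna()]
    if win is not None and len(conditions) >= 2 and not wfits.empty:
        for coef in ("beta1", "beta2", "zeta"):
            wide = wfits.pivot(index="subject_id", columns="condition",
                               values=coef)
            if wide.isna().any().any():
                continue
            res = perm_oneway_rm(wide[conditions].to_numpy(),
                                 n_perm=cfg.n_perm, seed=seed + 11)
            posthoc = _pairwise_posthoc(wide, conditions, cfg, seed + 13)
            fdr = adaptive_fdr([p["p"] for p in posthoc], q=cfg.q)
            results["betas"][coef] = {
                "stat": res.observed_stat, "p": res.p,
                "means": {c: float(wide[c].mean()) for c in conditions},
                "sems": {c: float(wide[c].std(ddof=1) / math.sqrt(len(wide)))
                         for c in conditions},
                "posthoc": posthoc, "p_fdr": fdr.p_fdr,
                "rejected": fdr.rejected.tolist(),
            }

    results["q"] = cfg.q
    results["n_perm"] = cfg.n_perm
    results["seed"] = seed
    (out / "stats.json").write_text(json.dumps(results, indent=2))
    return results


def stage_report(cfg: RunConfig, out: Path, metrics: pd.DataFrame,
                 bms_payload: dict, stats_payload: dict) -> str:
    lines = [
        "# Reward-based motor sequence learning: analysis report", "",
        f"- package version: {__version__}",
        f"- config hash: {cfg.content_hash()}",
        f"- run seed: {cfg.seed}", "",
        "## Scores and variability per block (mean over subjects)", "",
    ]
    learning = metrics[metrics.phase == "learning"]
    summary = learning.groupby(["condition", "block"])[
        ["score_mean", "cv_timing", "cv_velocity"]].mean().round(4)
    lines.append(summary.to_markdown())
    lines += ["", "## Model selection", ""]
    if bms_payload:
        lines += [
            f"- winning model: `{bms_payload['winning_model']}`",
            f"- exceedance probability: {bms_payload['winning_xp']:.4f}",
            f"- expected frequency: {bms_payload['winning_frequency']:.2%}",
            "",
        ]
    lines += ["## Group statistics", "",
              "```json", json.dumps(stats_payload, indent=2), "```", ""]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the artifact payloads."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(
        {"config": cfg.to_dict(), "hash": cfg.content_hash(),
         "version": __version__}))

    if cfg.input_csv is not None:
        data = pd.read_csv(cfg.input_csv)
    else:
        data = stage_simulate(cfg, out)
    sessions = load_sessions(data, cfg.target_norm)
    metrics = stage_metrics(cfg, out, sessions)
    fits = stage_fit(cfg, out, sessions)
    bms_payload = stage_bms(cfg, out, fits)
    stats_payload = stage_stats(cfg, out, metrics, fits, bms_payload)
    report = stage_report(cfg, out, metrics, bms_payload, stats_payload)
    return {
        "data": data, "metrics": metrics, "fits": fits,
        "bms": bms_payload, "stats": stats_payload, "report": report,
    }
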