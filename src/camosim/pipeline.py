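"""End-to-end pipeline: stimuli, simulated study, threshold fits, group stats.

Stages are plain functions over DataFrames so each can also be run in
isolation from the CLI: ``simulate_study`` produces the trial table,
``fit_thresholds`` the participant x condition threshold table, and
``analyze_thresholds`` the Bayes-factor comparisons plus bootstrap group
summary. ``run_study`` chains them and writes all artefacts (CSV/JSON) with a
structured run log recording the derived stage seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import bootstrap_group_ci, jzs_bf_one_sample, jzs_bf_paired
from .config import PipelineConfig, config_summary, default_config
from .leaves import apply_leaf_shadows, generate_leaf_background, save_background
from .observers import generate_cohort
from .psychometric import FitError, fit_condition
from .snakes import compose_scene
from .staircase import TRIAL_COLUMNS, run_session
from .textures import (
    apply_edge_enhancement,
    make_uniform_texture,
    pick_patch_palette,
    save_texture,
    synthesize_two_tone,
)

__all__ = [
    "generate_stimuli",
    "simulate_study",
    "fit_thresholds",
    "analyze_thresholds",
    "run_study",
]


def _stage_seeds(master_seed: int) -> dict:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(4)
    return {
        "stimuli": children[0],
        "cohort": children[1],
        "sessions": children[2],
        "bootstrap": children[3],
    }


def generate_stimuli(cfg: PipelineConfig | None = None, out_dir: str | Path | None = None):
    """Generate the full stimulus set: backgrounds, textures, example scenes.

    Returns ``(backgrounds, textures_by_colouration, palette)``; when
    ``out_dir`` is given, also writes PNGs, JSON sidecars, and a manifest CSV.
    """
    cfg = cfg or default_config()
    seeds = _stage_seeds(cfg.seed)["stimuli"].spawn(3)
    bg_rng = np.random.default_rng(seeds[0])
    backgrounds = []
    for _ in range(cfg.n_backgrounds):
        bg = generate_leaf_background(
            cfg.leaf_spec, cfg.calibration, bg_rng, size=cfg.scene_size
        )
        backgrounds.append(apply_leaf_shadows(bg, cfg.leaf_spec, cfg.calibration))

    palette_rng = np.random.default_rng(seeds[1])
    palette = pick_patch_palette(backgrounds[0].colour_population, palette_rng)

    tex_rng = np.random.default_rng(seeds[2])
    textures = {"uniform": [], "flat_disruptive": [], "edge_enhanced_disruptive": []}
    for _ in range(cfg.n_textures_per_type):
        flat = synthesize_two_tone(cfg.filter_spec, palette, tex_rng)
        textures["flat_disruptive"].append(flat)
        textures["edge_enhanced_disruptive"].append(
            apply_edge_enhancement(flat, cfg.ee_spec, cfg.calibration)
        )
    textures["uniform"].append(make_uniform_texture(palette, cfg.filter_spec.size))

    if out_dir is not None:
        out = Path(out_dir)
        rows = []
        for i, bg in enumerate(backgrounds):
            save_background(bg, out / "backgrounds" / f"leaf_bg_{i:02d}.png")
            rows.append({"kind": "background", "id": i, "colouration": ""})
        for colouration, texs in textures.items():
            for i, tex in enumerate(texs):
                save_texture(tex, out / "textures" / f"{colouration}_{i:02d}.png")
                rows.append({"kind": "texture", "id": i, "colouration": colouration})
        scene_rng = np.random.default_rng(cfg.seed)
        for colouration in textures:
            for background in ("grey", "leaf"):
                scene = compose_scene(
                    1.3, 1.0, colouration, background, cfg.calibration, scene_rng,
                    textures[colouration], backgrounds, cfg.snake_spec,
                    size=cfg.scene_size, grey=cfg.grey,
                )
                from PIL import Image

                name = f"scene_{colouration}_{background}.png"
                (out / "scenes").mkdir(parents=True, exist_ok=True)
                Image.fromarray(scene.image).save(out / "scenes" / name)
                rows.append(
                    {"kind": "scene", "id": 0, "colouration": f"{colouration}:{background}"}
                )
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return backgrounds, textures, palette


def simulate_study(cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Simulate the whole cohort's sessions; returns the trial table."""
    cfg = cfg or default_config()
    seeds = _stage_seeds(cfg.seed)
    cohort = generate_cohort(cfg.cohort, np.random.default_rng(seeds["cohort"]))
    session_seeds = seeds["sessions"].spawn(len(cohort))
    frames = []
    for i, (obs, s) in enumerate(zip(cohort, session_seeds)):
        records = run_session(obs, cfg.design, s, participant=f"P{i + 1:02d}")
        frames.append(pd.DataFrame([asdict(r) for r in records]))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def fit_thresholds(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit each participant x condition cell; returns the threshold table.

    Index: participant; columns: condition labels; values: 75%-correct wiggle
    thresholds (amplitude multipliers). Flagged fits yield NaN.
    """
    from .staircase import TrialRecord

    out: dict[str, dict[str, float]] = {}
    for (participant, condition), grp in trials.groupby(
        ["participant", "condition"], sort=True
    ):
        recs = [TrialRecord(**row) for row in grp.to_dict("records")]
        try:
            fit = fit_condition(recs)
            value = np.nan if fit.flagged else fit.threshold
        except FitError:
            value = np.nan
        out.setdefault(participant, {})[condition] = value
    return pd.DataFrame(out).T.sort_index()


_PAIRED_COMPARISONS = [
    ("edge_enhanced_disruptive", "flat_disruptive"),
    ("edge_enhanced_disruptive", "uniform"),
    ("flat_disruptive", "uniform"),
]


def analyze_thresholds(
    thresholds: pd.DataFrame, cfg: PipelineConfig | None = None
) -> dict:
    """Group-level Bayes-factor comparisons and bootstrap summary.

    Within each background: paired tests between colourations; for every
    condition: a one-sample test against the baseline amplitude 1.0.
    """
    cfg = cfg or default_config()
    seeds = _stage_seeds(cfg.seed)
    complete = thresholds.dropna()
    comparisons = []
    for background in ("leaf", "grey"):
        for col_a, col_b in _PAIRED_COMPARISONS:
            a, b = f"{col_a}:{background}", f"{col_b}:{background}"
            if a not in complete or b not in complete:
                continue
            res = jzs_bf_paired(complete[a], complete[b], cfg.prior_scale)
            comparisons.append(
                {
                    "background": background,
                    "a": a,
                    "b": b,
                    "t": res.t_stat,
                    "n": res.n,
                    "bf10": res.bf10,
                    "mean_diff": res.mean_diff,
                    "evidence": res.evidence_label,
                }
            )
    baseline_tests = []
    for cond in complete.columns:
        res = jzs_bf_one_sample(
            complete[cond], 1.0, cfg.prior_scale, one_sided=cfg.one_sided_baseline
        )
        baseline_tests.append(
            {
                "condition": cond,
                "t": res.t_stat,
                "n": res.n,
                "bf10": res.bf10,
                "evidence": res.evidence_label,
                "direction": res.direction,
            }
        )
    summary = bootstrap_group_ci(
        complete,
        n_resamples=cfg.bootstrap_resamples,
        seed=np.random.default_rng(seeds["bootstrap"]),
    )
    return {
        "comparisons": comparisons,
        "baseline_tests": baseline_tests,
        "group_summary": {
            cond: {
                "mean": float(row["mean"]),
                "ci_lo": float(row["ci_lo"]),
                "ci_hi": float(row["ci_hi"]),
            }
            for cond, row in summary.table.iterrows()
        },
        "n_participants": summary.n_participants,
    }


def run_study(
    cfg: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Simulate, fit, analyse; optionally write all artefacts plus a run log."""
    cfg = cfg or default_config()
    log: dict = {"seed": cfg.seed, "stages": {}}
    t0 = time.time()
    trials = simulate_study(cfg)
    log["stages"]["simulate"] = {"seconds": round(time.time() - t0, 3), "rows": len(trials)}
    t0 = time.time()
    thresholds = fit_thresholds(trials)
    log["stages"]["fit"] = {
        "seconds": round(time.time() - t0, 3),
        "participants": thresholds.shape[0],
        "conditions": thresholds.shape[1],
        "flagged": int(thresholds.isna().to_numpy().sum()),
    }
    t0 = time.time()
    analysis = analyze_thresholds(thresholds, cfg)
    log["stages"]["analyze"] = {"seconds": round(time.time() - t0, 3)}
    analysis["config"] = config_summary(cfg)
    result = {
        "trials": trials,
        "thresholds": thresholds,
        "analysis": analysis,
        "log": log,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        reread = pd.read_csv(out / "trials.csv")
        if len(reread) != len(trials):
            raise IOError("trial CSV failed round-trip validation")
        thresholds.to_csv(out / "thresholds.csv", index_label="participant")
        group = pd.DataFrame(analysis["group_summary"]).T
        group.to_csv(out / "group_summary.csv", index_label="condition")
        (out / "analysis.json").write_text(
            json.dumps(
                {k: v for k, v in analysis.items() if k != "config"}
                | {"config": analysis["config"]},
                indent=2,
            )
        )
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
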