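"""End-to-end analysis pipeline: ingest -> aggregate -> score -> fit ->
compare -> report.

The report mirrors the study's results structure: inter-rater reliability,
knowledge contrasts, evaluator accuracy by number of descriptions with the
split-half ceiling, and the two fitted choice models with per-term
Savage-Dickey Bayes factors and prior-robustness curves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import aggregate_table, read_annotations, reliability_report
from .bayes import (
    InvalidInputError,
    PriorSpec,
    SamplerConfig,
    bf_robustness,
)
from .choice_models import (
    build_features,
    compare_models,
    fit_model,
    predict_curves,
    read_trials,
)
from .default_bf import jzs_ttest_bf10, ttest_summary_from_data
from .knowledge import (
    profiles_by_key,
    read_answers,
    score_knowledge,
    selection_contrast,
    split_half_ceiling,
)
from .synthetic import SimulationConfig, generate_study

logger = logging.getLogger("knowjudge")

DEFAULT_PRIOR_SCALE = 1.0
ROBUSTNESS_SCALES = (0.5, 1.0, 2.0)

REPORT_SCHEMA = {
    "type": "object",
    "required": ["reliability", "knowledge", "evaluator", "models", "provenance"],
    "properties": {
        "reliability": {"type": "array"},
        "knowledge": {"type": "object"},
        "evaluator": {"type": "object"},
        "models": {"type": "object"},
        "provenance": {"type": "object"},
    },
}


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def setup_logging(log_file: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("knowjudge")
    root.setLevel(level)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def accuracy_by_condition(trials: pd.DataFrame, profiles: dict) -> dict:
    """Evaluator accuracy per number-of-descriptions level.

    Accuracy is against the ground truth (higher multiple-choice accuracy).
    Returns per-level means plus a paired default-prior t-test Bayes factor
    comparing each evaluator's accuracy at the fewest vs. the most
    descriptions; evaluators missing a level are excluded from the paired
    test with a logged warning.
    """
    recs = []
    for row in trials.itertuples(index=False):
        pa = profiles.get((str(row.informant_A), str(row.category_id)))
        pb = profiles.get((str(row.informant_B), str(row.category_id)))
        if pa is None or pb is None:
            raise InvalidInputError(
                f"trial {row.trial_id}: informant profile missing")
        truth = "A" if pa.theta > pb.theta else "B"
        recs.append((str(row.evaluator_id), int(row.n_descriptions),
                     int(str(row.choice) == truth)))
    df = pd.DataFrame(recs, columns=["evaluator_id", "n_descriptions", "correct"])
    level_means = df.groupby("n_descriptions")["correct"].mean()
    per_eval = df.groupby(["evaluator_id", "n_descriptions"])["correct"].mean().unstack()
    lo_level, hi_level = int(level_means.index.min()), int(level_means.index.max())
    paired = per_eval[[lo_level, hi_level]].dropna()
    dropped = len(per_eval) - len(paired)
    if dropped:
        logger.warning("%d evaluators missing a descriptions level; excluded "
                       "from the paired test", dropped)
    x, y = paired[hi_level].to_numpy(), paired[lo_level].to_numpy()
    if np.allclose(x - y, (x - y).mean()):
        bf10, bf_display = None, "undefined"
    else:
        bf = jzs_ttest_bf10(ttest_summary_from_data(x, y, "paired"))
        bf10, bf_display = bf.bf10, bf.display
    return {
        "accuracy_by_level": {int(k): float(v) for k, v in level_means.items()},
        "paired_levels": [lo_level, hi_level],
        "paired_bf10": bf10,
        "paired_bf_display": bf_display,
        "n_evaluators_paired": int(len(paired)),
        "per_trial": df,
    }


def _fit_section(model: str, features, seed: int, sampler: SamplerConfig,
                 skip_robustness: bool = False) -> dict:
    prior = PriorSpec("normal", DEFAULT_PRIOR_SCALE)
    samples, summary = fit_model(model, features, prior, sampler)
    bfs = compare_models(model, features, prior, samples=samples)
    section = {
        "posterior_mean": summary.mean,
        "ci95": {k: list(v) for k, v in summary.ci95.items()},
        "rhat": summary.rhat,
        "bf": {k: {"bf10": v.bf10, "display": v.display,
                   "evidence": v.evidence} for k, v in bfs.items()},
    }
    if not skip_robustness:
        def refit(scale: float):
            p = PriorSpec("normal", scale)
            cfg = SamplerConfig(seed=sampler.seed + 101, n_chains=sampler.n_chains,
                                burn_in=sampler.burn_in, thin=sampler.thin,
                                draws_per_chain=sampler.draws_per_chain)
            s, _ = fit_model(model, features, p, cfg)
            return compare_models(model, features, p, samples=s)["w2"]

        section["robustness_w2"] = [
            [s, b] for s, b in bf_robustness(refit, ROBUSTNESS_SCALES)]
    curves = predict_curves(model, samples)
    section["_curves"] = curves
    return section


def run_pipeline(config: SimulationConfig | str | Path,
                 out_dir: str | Path,
                 simulate_first: bool = True,
                 in_dir: str | Path | None = None,
                 models: tuple[str, ...] = ("informant", "evaluator"),
                 skip_robustness: bool = False,
                 ceiling_splits: int = 10_000,
                 sampler: SamplerConfig | None = None) -> dict:
    """Run the full analysis and write report.json / report.md plus tables.

    With ``simulate_first`` a synthetic study is generated into ``out_dir``
    and analysed; otherwise the three input tables are read from ``in_dir``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_file(config)
    seed = config.seed
    sampler = sampler or SamplerConfig(seed=seed + 7)

    # --- ingest ---------------------------------------------------------
    stage = "ingest"
    try:
        if simulate_first:
            study = generate_study(config, out / "study")
            answers, annotations, trials = study.answers, study.annotations, study.trials
        else:
            src = Path(in_dir if in_dir is not None else out)
            for name in ("answers.csv", "annotations.csv", "trials.csv"):
                if not (src / name).exists():
                    raise InvalidInputError(f"input table not found: {src / name}")
            answers = read_answers(src / "answers.csv")
            annotations = read_annotations(src / "annotations.csv")
            trials = read_trials(src / "trials.csv")
        logger.info("[%s] %d answers, %d annotations, %d trials (%.1fs)",
                    stage, len(answers), len(annotations), len(trials),
                    time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- aggregate ------------------------------------------------------
    stage = "aggregate"
    try:
        aggregated = aggregate_table(annotations)
        reliability = reliability_report(annotations)
        aggregated.to_csv(out / "aggregated_annotations.csv", index=False)
        reliability.to_csv(out / "reliability.csv", index=False)
        logger.info("[%s] %d descriptions aggregated (%.1fs)", stage,
                    len(aggregated), time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- score ----------------------------------------------------------
    stage = "score"
    try:
        prof_list = score_knowledge(answers, config.questions_per_category)
        profiles = profiles_by_key(prof_list)
        contrast = selection_contrast(prof_list)
        acc = accuracy_by_condition(trials, profiles)
        pairs = sorted({(str(r.informant_A), str(r.informant_B), str(r.category_id))
                        for r in trials.itertuples(index=False)})
        pair_vectors = []
        for a, b, cat in pairs:
            va = np.array(profiles[(a, cat)].answers)
            vb = np.array(profiles[(b, cat)].answers)
            if va.sum() != vb.sum():
                pair_vectors.append((va, vb))
        ceiling = split_half_ceiling(pair_vectors, n_splits=ceiling_splits,
                                     seed=seed + 13)
        logger.info("[%s] %d profiles, ceiling %.3f over %d pairs (%.1fs)",
                    stage, len(prof_list), ceiling.probability,
                    ceiling.n_pairs, time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- fit / compare --------------------------------------------------
    stage = "fit"
    model_sections = {}
    try:
        for i, model in enumerate(models):
            features = build_features(trials, aggregated, profiles, model)
            cfg = SamplerConfig(seed=sampler.seed + i, n_chains=sampler.n_chains,
                                burn_in=sampler.burn_in, thin=sampler.thin,
                                draws_per_chain=sampler.draws_per_chain)
            section = _fit_section(model, features, seed, cfg, skip_robustness)
            curves = section.pop("_curves")
            curves.to_csv(out / f"curves_{model}.csv", index=False)
            model_sections[model] = section
            logger.info("[%s] %s model fitted (%.1fs)", stage, model,
                        time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- report ---------------------------------------------------------
    stage = "report"
    try:
        acc_out = {k: v for k, v in acc.items() if k != "per_trial"}
        cfg_yaml = yaml.safe_dump(asdict(config), sort_keys=True)
        report = {
            "reliability": reliability.to_dict(orient="records"),
            "knowledge": {
                "selection_contrast": contrast,
                "accuracy_spread": _accuracy_spread(prof_list),
            },
            "evaluator": {
                "accuracy": acc_out,
                "split_half_ceiling": {
                    "probability": ceiling.probability,
                    "n_splits": ceiling.n_splits,
                    "n_pairs": ceiling.n_pairs,
                    "seed": ceiling.seed,
                },
            },
            "models": model_sections,
            "provenance": {
                "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
                "seed": seed,
                "sampler": asdict(sampler),
                "version": __version__,
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        (out / "report.md").write_text(render_report_md(report))
        logger.info("[%s] report written to %s (%.1fs)", stage, out,
                    time.time() - t0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return report


def _accuracy_spread(profiles) -> dict:
    """Worst-to-best accuracy difference per category, averaged."""
    by_cat: dict[str, list[float]] = {}
    for p in profiles:
        by_cat.setdefault(p.category_id, []).append(p.theta)
    spreads = [max(v) - min(v) for v in by_cat.values() if len(v) >= 2]
    return {"mean_worst_best_difference": float(np.mean(spreads)),
            "n_categories": len(spreads)}


def render_report_md(report: dict) -> str:
    """Human-readable summary of the report JSON."""
    lines = ["# Analysis report", ""]
    lines.append("## Inter-rater reliability")
    for row in report["reliability"]:
        lines.append(f"- group {row['rater_group']}, {row['statement_type']} "
                     f"statements: ICC = {row['icc']:.3f}")
    kn = report["knowledge"]["selection_contrast"]
    lines += ["", "## Knowledge",
              f"- self-selected vs assigned accuracy: "
              f"{kn['mean_self_selected']:.3f} vs {kn['mean_assigned']:.3f} "
              f"(BF = {kn['bf_display']})",
              f"- mean worst-best spread per category: "
              f"{report['knowledge']['accuracy_spread']['mean_worst_best_difference']:.3f}"]
    ev = report["evaluator"]
    lines += ["", "## Evaluator accuracy"]
    for lvl, v in sorted(ev["accuracy"]["accuracy_by_level"].items(),
                         key=lambda kv: int(kv[0])):
        lines.append(f"- {lvl} descriptions: {v:.3f}")
    lines.append(f"- paired BF ({ev['accuracy']['paired_levels'][0]} vs "
                 f"{ev['accuracy']['paired_levels'][1]} descriptions): "
                 f"{ev['accuracy']['paired_bf_display']}")
    lines.append(f"- split-half ceiling: "
                 f"{ev['split_half_ceiling']['probability']:.3f}")
    for model, sec in report["models"].items():
        lines += ["", f"## {model.capitalize()} model"]
        for nm, m in sec["posterior_mean"].items():
            lo, hi = sec["ci95"][nm]
            lines.append(f"- {nm}: M = {m:.3f}, 95% CI = [{lo:.3f}, {hi:.3f}]")
        for nm, bf in sec["bf"].items():
            lines.append(f"- BF for dropping {nm}: {bf['display']} ({bf['evidence']})")
    lines.append("")
    return "\n".join(lines)


def validate_report(report: dict) -> bool:
    """Check the report against the shipped schema (required keys + types)."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise InvalidInputError(f"report missing section {key!r}")
    if not isinstance(report["reliability"], list):
        raise InvalidInputError("reliability section must be a list")
    for key in ("knowledge", "evaluator", "models", "provenance"):
        if not isinstance(report[key], dict):
            raise InvalidInputError(f"{key} section must be an object")
    return True
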