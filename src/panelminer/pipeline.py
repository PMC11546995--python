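"""End-to-end pipeline orchestration.

Stage order: simulate/load → preprocess → [propensity-score match] →
select (NB, SVC, PCA) → combine into the set catalogue → evaluate the
catalogue → random panel search → consolidate → prune → report exports.

Four experimental arms are supported: matched vs original (unmatched)
cohort, each with or without the age variable.  Age exclusion drops the
column before selection *and* evaluation, so no evaluated set can contain
it.  A single global seed propagates to every stage, and a rerun with the
same config reproduces every artifact byte for byte (no timestamps are
written).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from ._cohort import Cohort, read_cohort_csv, write_cohort_csv
from .evaluate import EvalConfig, repeated_cv_eval
from .feature_select import (
    FeatureSet,
    SelectorConfig,
    nb_univariate_select,
    pca_loading_select,
    svc_l2_select,
)
from .panel_search import PanelSearchConfig, consolidate, prune_by_feature_loocv, sample_panels
from .preprocess import PreprocessConfig, run_preprocess
from .psm import MatchConfig, balance_check, fit_propensity, match_controls
from .set_algebra import build_catalog
from .stats_report import pca_projection, wilcoxon_table, zscore_matrix
from .synthetic_cohort import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

RUN_MODES = ("matched", "original")


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None            # simulate when set …
    input_csv: str | None = None            # … or load a cohort CSV
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    search: PanelSearchConfig = field(default_factory=PanelSearchConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    run_mode: str = "matched"
    include_age: bool = True
    outdir: str = "panelminer_run"
    seed: int = 0
    run_search: bool = True

    def __post_init__(self) -> None:
        if self.run_mode not in RUN_MODES:
            raise ValueError(f"run_mode must be one of {RUN_MODES}")
        if self.sim is None and self.input_csv is None:
            self.sim = SimConfig(seed=self.seed)
        # one global seed drives every stage
        self.sim = replace(self.sim, seed=self.seed) if self.sim else None
        self.match = replace(self.match, seed=self.seed + 1)
        self.selector = replace(self.selector, seed=self.seed + 2)
        self.search = replace(
            self.search,
            seed=self.seed + 3,
            eval_config=replace(self.search.eval_config, seed=self.seed + 4),
        )
        self.eval = replace(self.eval, seed=self.seed + 5)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = {}
        converters = {
            "sim": SimConfig,
            "preprocess": PreprocessConfig,
            "match": MatchConfig,
            "selector": SelectorConfig,
            "eval": EvalConfig,
        }
        for key, value in payload.items():
            if key == "search":
                inner = dict(value)
                if "eval_config" in inner:
                    inner["eval_config"] = EvalConfig(**inner["eval_config"])
                kwargs[key] = PanelSearchConfig(**inner)
            elif key in converters and isinstance(value, dict):
                kwargs[key] = converters[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _drop_age(cohort: Cohort) -> Cohort:
    if "age" not in cohort.data.columns:
        return cohort
    return cohort.with_data(cohort.data.drop(columns=["age"]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    # -- input ----------------------------------------------------------- #
    if config.sim is not None:
        cohort = generate_cohort(config.sim)
        write_cohort_csv(cohort, out / "cohort.csv")
        say(f"simulated cohort: {cohort.n_cases} cases / {cohort.n_controls} controls")
    else:
        cohort = read_cohort_csv(config.input_csv)
        say(f"loaded cohort from {config.input_csv}")

    # -- preprocess ------------------------------------------------------ #
    clean, prep_report = run_preprocess(cohort, config.preprocess)
    write_cohort_csv(clean, out / "clean.csv")
    (out / "preprocess_report.json").write_text(json.dumps(prep_report, indent=2))
    say(f"preprocess: {prep_report['n_features']} features, "
        f"{len(prep_report['dropped_sparse_features'])} sparse dropped")

    # -- match ----------------------------------------------------------- #
    if config.run_mode == "matched":
        scores = fit_propensity(clean, config.match)
        result = match_controls(scores, clean, config.match)
        working = result.augmented
        balance = balance_check(clean, working)
        balance.to_csv(out / "balance.csv")
        (out / "match_report.json").write_text(json.dumps(result.report(), indent=2))
        say(f"matched: +{result.n_additional_controls} duplicated controls "
            f"({working.n_controls} total vs {working.n_cases} cases)")
    else:
        working = clean
        say("run_mode=original: matching skipped")

    if not config.include_age:
        working = _drop_age(working)
        say("age excluded before selection and evaluation")
    write_cohort_csv(working, out / "analysis_table.csv")

    # -- select ---------------------------------------------------------- #
    nb = nb_univariate_select(working, config.selector)
    svc = svc_l2_select(working, config.selector)
    pca = pca_loading_select(working, config.selector)
    sets_dir = out / "sets"
    sets_dir.mkdir(exist_ok=True)
    for fs, fname in ((nb, "nb.json"), (svc, "svc.json"), (pca, "pca.json")):
        fs.to_json(sets_dir / fname)
    say(f"selectors: |SVC|={len(svc)} |PCA|={len(pca)} |NB|={len(nb)}")

    # -- combine / search / prune ---------------------------------------- #
    all_features = FeatureSet("All", working.numeric_features())
    panels: list[FeatureSet] = []
    search_payload = {}
    if config.run_search:
        pool_catalog = build_catalog(svc, pca, nb, all_features)
        pool = pool_catalog["SVC ∪ PCA ∪ NB"]
        search_cfg = config.search
        if len(pool) < search_cfg.panel_size_max:
            say("pool smaller than panel_size_max; search skipped")
        else:
            result = sample_panels(pool, working, search_cfg)
            result.to_json(out / "search.json")
            core = consolidate(result, search_cfg)
            say(f"search: {len(result.high_performers)}/{len(result.panels)} panels "
                f"above AUC {result.auc_threshold:.3f}; "
                f"{len(result.unique_biomarkers)} unique biomarkers; core={len(core)}")
            search_payload = {
                "n_high_performers": len(result.high_performers),
                "n_unique_biomarkers": len(result.unique_biomarkers),
                "core_panel": list(core.members),
            }
            if len(core) >= 3:
                panels.append(FeatureSet(f"core-{len(core)}", core.members))
                prune = prune_by_feature_loocv(core, working, search_cfg)
                for fs, score in prune.subsets:
                    panels.append(FeatureSet(f"core-{len(fs)}", fs.members))
                (out / "prune_trace.json").write_text(
                    json.dumps(
                        [
                            {
                                "removed": s.removed,
                                "score": s.score,
                                "candidates": s.candidates,
                            }
                            for s in prune.trace
                        ],
                        indent=2,
                        ensure_ascii=False,
                    )
                )
                search_payload["pruned_panels"] = {
                    fs.name: list(fs.members) for fs in panels[1:]
                }

    catalog = build_catalog(svc, pca, nb, all_features, panels=panels)
    catalog.to_json(out / "catalog.json")

    # -- evaluate catalogue ---------------------------------------------- #
    rows = []
    for fs in catalog:
        if len(fs) == 0:
            say(f"catalogue entry {fs.name!r} is empty; not evaluated")
            continue
        summary = repeated_cv_eval(working, fs, config.eval)
        rows.append(summary.as_dict())
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    say(f"evaluated {len(metrics)} catalogue entries")

    # -- report exports --------------------------------------------------- #
    report_set = panels[-1] if panels else (nb if len(nb) else all_features)
    figures = out / "figures_data"
    figures.mkdir(exist_ok=True)
    wilcoxon_table(working, report_set).to_csv(figures / "wilcoxon.csv", index=False)
    zmat, groups = zscore_matrix(working, report_set)
    zmat.to_csv(figures / "heatmap_z.csv")
    groups.to_csv(figures / "heatmap_groups.csv")
    pca_projection(working, report_set).to_csv(figures / "pca_scores.csv")
    long = working.data[list(report_set.members)].copy()
    long["group"] = working.data["group"]
    long.melt(id_vars="group", var_name="feature", value_name="value").to_csv(
        figures / "violin_long.csv", index=False
    )

    report = {
        "run_mode": config.run_mode,
        "include_age": config.include_age,
        "seed": config.seed,
        "preprocess": prep_report,
        "catalog_sizes": catalog.cardinalities(),
        "search": search_payload,
        "metrics": rows,
        "log": log,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, ensure_ascii=False))
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return report
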