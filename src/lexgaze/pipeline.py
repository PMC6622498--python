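"""End-to-end orchestration: vocab -> networks -> gaze -> inference.

``run_pipeline`` executes the stages in order on either a simulated cohort
or delimited-text input files, writing metric tables, the design table,
model reports, the binned timecourse, the exclusion ledger and a run
manifest (written first and updated as stages complete, so an aborted run
still records its progress).
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
from .gaze import (
    DEFAULT_BIN_MS,
    DEFAULT_MIN_ONSCREEN,
    DEFAULT_MIN_RATING,
    DEFAULT_SMOOTHING,
    DEFAULT_WINDOW,
    GazeState,
    GazeTrial,
    accuracy_table,
    filter_trials,
    grand_timecourse,
    trial_log_gaze,
)
from .model import (
    build_design,
    fit_condition_model,
    fit_group_model,
    model_report,
)
from .network import FeatureNorms, NormsAdjacency, degree_table, metrics_table
from .simulate import EXPERIMENTAL_ITEMS, Cohort, SimConfig, simulate_cohort
from .vocab import (
    ChecklistDefinition,
    assign_density,
    category_proportions,
    density_table,
    group_table,
    read_vocabulary_reports,
    split_vocab_groups,
)

logger = logging.getLogger(__name__)


DEFAULT_THRESHOLDS = {
    "edge_threshold": 2,
    "window": list(DEFAULT_WINDOW),
    "bin_ms": DEFAULT_BIN_MS,
    "min_rating": DEFAULT_MIN_RATING,
    "min_onscreen": DEFAULT_MIN_ONSCREEN,
    "smoothing_c": DEFAULT_SMOOTHING,
    "proportion_mode": "per-category-size",
}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class RunManifest:
    """Config snapshot, input digests, stage counts, version and seed."""

    def __init__(self, outdir: Path, config: dict) -> None:
        self.path = Path(outdir) / "manifest.json"
        self.data = {
            "version": __version__,
            "config": config,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {},
            "stages": {},
            "status": "running",
        }
        self.write()

    def record_input(self, name: str, path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _digest(Path(path))}
        self.write()

    def record_stage(self, name: str, counts: dict) -> None:
        self.data["stages"][name] = counts
        self.write()

    def finish(self, status: str = "complete") -> None:
        self.data["status"] = status
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.write()

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def load_trials_from_files(samples_path, metadata_path, sep: str = ",") -> list[GazeTrial]:
    """Read labeled sample streams plus trial metadata from delimited text.

    Samples need columns ``trial_id, t_ms, state`` (state names as in
    :class:`GazeState`); metadata ``trial_id, child_id, condition, target,
    distractor, rating`` and optionally ``target_side``.
    """
    samples = pd.read_csv(samples_path, sep=sep)
    meta = pd.read_csv(metadata_path, sep=sep).set_index("trial_id")
    code = {s.name: int(s) for s in GazeState}
    trials = []
    for trial_id, grp in samples.groupby("trial_id", sort=True):
        if trial_id not in meta.index:
            raise ValueError(f"samples reference unknown trial {trial_id!r}")
        row = meta.loc[trial_id]
        grp = grp.sort_values("t_ms")
        trials.append(
            GazeTrial(
                trial_id=str(trial_id),
                child_id=str(row["child_id"]),
                condition=str(row["condition"]),
                target=str(row["target"]),
                distractor=str(row["distractor"]),
                comprehension_rating=int(row["rating"]),
                times=grp["t_ms"].to_numpy(),
                states=np.array([code[s] for s in grp["state"]], dtype=np.int8),
                target_side=str(row.get("target_side", "left")),
            )
        )
    return trials


def write_sample_files(cohort: Cohort, outdir: Path, sep: str = ",") -> None:
    """Dump simulated gaze streams in the pipeline's own input format."""
    rows = []
    for t in cohort.trials:
        names = [GazeState(int(s)).name for s in t.states]
        rows.append(pd.DataFrame(
            {"trial_id": t.trial_id, "t_ms": t.times, "state": names}
        ))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "samples.csv", index=False, sep=sep)
    meta = pd.DataFrame(
        [
            {
                "trial_id": t.trial_id, "child_id": t.child_id,
                "condition": t.condition, "target": t.target,
                "distractor": t.distractor, "rating": t.comprehension_rating,
                "target_side": t.target_side,
            }
            for t in cohort.trials
        ]
    )
    meta.to_csv(outdir / "trial_metadata.csv", index=False, sep=sep)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full analysis; returns the manifest data.

    ``config`` keys: ``simulate`` (bool), ``sim`` (SimConfig fields),
    ``thresholds`` (see ``DEFAULT_THRESHOLDS``), ``inputs`` (file paths when
    not simulating), ``write_samples``, ``figures``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    manifest = RunManifest(outdir, {**config, "thresholds": thresholds})
    try:
        result = _run_stages(config, thresholds, outdir, manifest)
    except Exception:
        manifest.finish("failed")
        raise
    manifest.finish("complete")
    return result


def _run_stages(config, thresholds, outdir: Path, manifest: RunManifest) -> dict:
    targets = sorted(EXPERIMENTAL_ITEMS)

    # --- stage: inputs / simulation -------------------------------------
    if config.get("simulate", True):
        sim_cfg = SimConfig(**config.get("sim", {}))
        logger.info("simulate: cohort of %d children, seed %d",
                    sim_cfg.n_children, sim_cfg.seed)
        cohort = simulate_cohort(
            sim_cfg, proportion_mode=thresholds["proportion_mode"]
        )
        checklist, children = cohort.checklist, cohort.children
        density, groups, metrics = cohort.density, cohort.groups, cohort.metrics
        trials = cohort.trials
        cohort.truth.to_json(outdir / "sim_truth.json")
        sim_cfg.to_yaml(outdir / "sim_config.yaml")
        if config.get("write_samples", False):
            write_sample_files(cohort, outdir)
        manifest.record_stage("simulate", {
            "n_children": len(children), "n_trials": len(trials),
        })
    else:
        paths = config["inputs"]
        checklist = ChecklistDefinition.read_csv(paths["checklist"])
        manifest.record_input("checklist", paths["checklist"])
        children = read_vocabulary_reports(paths["vocab_reports"], checklist)
        manifest.record_input("vocab_reports", paths["vocab_reports"])
        norms = FeatureNorms.read_csv(paths["norms"])
        manifest.record_input("norms", paths["norms"])
        trials = load_trials_from_files(paths["samples"], paths["trial_metadata"])
        manifest.record_input("samples", paths["samples"])
        manifest.record_input("trial_metadata", paths["trial_metadata"])
        density = {
            c.child_id: assign_density(
                c.child_id,
                category_proportions(c, checklist, thresholds["proportion_mode"]),
            )
            for c in children
        }
        groups = split_vocab_groups(children)
        adjacency = NormsAdjacency(norms, threshold=thresholds["edge_threshold"])
        metrics = {
            c.child_id: adjacency.child_metrics(c.child_id, set(c.produced), targets)
            for c in children
        }

    # --- stage: vocab + networks ----------------------------------------
    density_table(list(density.values())).to_csv(
        outdir / "density_assignments.csv", index=False
    )
    group_table(groups, children).to_csv(outdir / "vocab_groups.csv", index=False)
    mlist = [metrics[c.child_id] for c in children]
    metrics_table(mlist).to_csv(outdir / "network_metrics.csv", index=False)
    degree_table(mlist).to_csv(outdir / "target_degrees.csv", index=False)
    manifest.record_stage("structure", {
        "n_children": len(children),
        "median_split": groups.split_value,
    })

    # --- stage: gaze ------------------------------------------------------
    window = tuple(thresholds["window"])
    accuracies = [
        trial_log_gaze(t, window=window, smoothing_c=thresholds["smoothing_c"])
        for t in trials
    ]
    retained, ledger = filter_trials(
        trials, accuracies,
        min_rating=thresholds["min_rating"],
        min_onscreen=thresholds["min_onscreen"],
    )
    accuracy_table(accuracies).to_csv(outdir / "trial_accuracy.csv", index=False)
    ledger.to_csv(outdir / "exclusion_ledger.csv", index=False)
    stages = ledger.attrs["stages"]
    manifest.record_stage("gaze_filters", stages)
    logger.info(
        "gaze: %d trials in, %d removed (comprehension), %d removed "
        "(track loss), %d retained",
        stages["input"], stages["removed_comprehension"],
        stages["removed_track_loss"], stages["retained"],
    )
    groups_map = {
        t.trial_id: f"{t.condition}" for t, _ in retained
    }
    timecourse = grand_timecourse(
        [t for t, _ in retained], groups_map, bin_ms=thresholds["bin_ms"]
    )
    timecourse.to_csv(outdir / "timecourse.csv", index=False)

    # --- stage: inference -------------------------------------------------
    design = build_design(retained, metrics, density, groups, EXPERIMENTAL_ITEMS)
    design.to_csv(outdir / "design_table.csv", index=False)
    results = []
    for cond in ("unrelated", "related"):
        results.append(fit_condition_model(design, cond))
        for grp in ("High", "Low"):
            results.append(fit_group_model(design, cond, grp))
    report_df, report_text = model_report(results)
    report_df.to_csv(outdir / "model_report.csv", index=False)
    (outdir / "model_report.txt").write_text(report_text + "\n")
    manifest.record_stage("inference", {
        "n_models": len(results),
        "n_design_rows": len(design),
        "all_converged": all(r.converged for r in results),
    })

    if config.get("figures", False):
        make_figures(timecourse, design, outdir)

    return {
        "design": design,
        "results": results,
        "ledger": ledger,
        "timecourse": timecourse,
        "manifest": manifest.data,
    }


def make_figures(timecourse: pd.DataFrame, design: pd.DataFrame, outdir) -> list[Path]:
    """Timecourse panels per condition and accuracy summaries per metric."""
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []
    if timecourse.empty or design.empty:
        warnings.warn("empty tables; no figures written", stacklevel=2)
        return written

    groups = sorted(timecourse["group"].unique())
    fig, axes = plt.subplots(
        1, len(groups), figsize=(5 * len(groups), 4), squeeze=False
    )
    for ax, grp in zip(axes[0], groups):
        sub = timecourse[timecourse["group"] == grp]
        ax.plot(sub["bin_start_ms"], sub["p_target"], label="Target")
        ax.plot(sub["bin_start_ms"], sub["p_distractor"], label="Distractor")
        ax.set_title(grp)
        ax.set_xlabel("time from label onset (ms)")
        ax.set_ylabel("fixation proportion")
        ax.legend()
    fig.tight_layout()
    p = outdir / "timecourse.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for ax, metric in zip(axes, ("density_level", "degree", "gcc")):
        if metric == "density_level":
            means = design.groupby(["condition", "density_level"])["log_gaze"].mean()
            means.unstack("density_level").plot.bar(ax=ax)
            ax.set_title("category density")
        else:
            for cond, sub in design.groupby("condition"):
                ax.scatter(sub[metric], sub["log_gaze"], s=4, alpha=0.3, label=cond)
            ax.set_title(metric)
            ax.legend()
        ax.set_ylabel("log-gaze ratio")
    fig.tight_layout()
    p = outdir / "accuracy_by_structure.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
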