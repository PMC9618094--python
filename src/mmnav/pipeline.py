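"""End-to-end study analyses: from a cohort of trajectory logs to metric
tables, ANOVAs, correlation matrices and a reproducible report.

``run_study1`` mirrors a between-subject environment-validation design:
training x environment mixed ANOVAs on training time and chests found, and
one-way ANOVAs across environments on immediate-test time and placement
accuracy. ``run_study2`` mirrors a within-subject sleep/wake retention
design: per-measure condition x test rmANOVAs, the condition x radius x test
dwell rmANOVA, item-level analyses after the 2.5-SD item filter, and
Pearson/Bonferroni correlation families at the global and item level.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .metrics import (
    MetricConfig,
    NoApproachError,
    DegenerateTrialError,
    aggregate,
    approach_angle,
    training_summary_table,
)
from .model import CohortDataset, TRAINING_PHASES
from .stats import (
    AnovaResult,
    DegenerateVarianceError,
    IncompleteDesignError,
    CorrelationMatrixResult,
    mixed_anova,
    one_way_anova,
    pearson_bonferroni,
    rm_anova,
    rm_anova_2x2,
    sd_outlier_filter,
)

__all__ = ["StudyConfig", "StudyReport", "run_study1", "run_study2",
           "make_report"]

GLOBAL_CORR_MEASURES = (
    "placement_error", "path_length", "header_direction", "initial_orientation",
)

PARTICIPANT_MEASURES = (
    "placement_error", "path_length", "header_direction", "cumulative_error",
    "initial_orientation", "test_time_s",
)


@dataclass(frozen=True)
class StudyConfig:
    """One structured configuration object; the defaults reproduce the full
    analysis battery (all measures, 2.5-SD filters, radii 10/20/30)."""

    metric_config: MetricConfig = field(default_factory=MetricConfig)
    item_filter_sd: float = 2.5
    participant_filter_sd: float = 2.5
    alpha: float = 0.05
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metric_config"]["dwell_radii"] = list(
            self.metric_config.dwell_radii
        )
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    study_label: str
    tables: dict[str, pd.DataFrame]
    anovas: dict[str, AnovaResult]
    correlations: dict[str, CorrelationMatrixResult]
    manifest: dict


def _try_anova(anovas: dict, manifest: dict, name: str, fn, *args, **kw):
    try:
        anovas[name] = fn(*args, **kw)
    except (DegenerateVarianceError, IncompleteDesignError) as e:
        manifest.setdefault("degenerate_analyses", {})[name] = str(e)


def _base_manifest(ds: CohortDataset, config: StudyConfig) -> dict:
    return {
        "study_label": ds.study_label,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "mmnav": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_sessions_input": len(ds.sessions),
    }


# ---------------------------------------------------------------------------
# study 1: environment validation


def run_study1(ds: CohortDataset, config: StudyConfig = StudyConfig()
               ) -> StudyReport:
    """Between-subject environment assessment on a test1-only cohort."""
    if ds.study_label != "study1":
        raise ValueError("run_study1 expects a study1 dataset")
    for sess in ds.sessions:
        if sess.environment is None:
            raise ValueError("session without environment assignment")
    manifest = _base_manifest(ds, config)
    mc = config.metric_config
    training = training_summary_table(ds, mc)
    env_of = {
        s.participant_id: s.environment.env_id for s in ds.sessions
    }
    training["env_id"] = training["participant_id"].map(env_of)
    part, item = aggregate(ds, mc, config.item_filter_sd)
    part = part[part["phase"] == "test1"].copy()
    part["env_id"] = part["participant_id"].map(env_of)

    anovas: dict[str, AnovaResult] = {}
    for name, dv in (("training_time", "time_in_phase_s"),
                     ("chests_opened", "chests_opened_distinct"),
                     ("training_steps", "total_steps")):
        _try_anova(anovas, manifest, name, mixed_anova,
                   training, dv, "phase", "env_id", "participant_id")
    by_env = [g["test_time_s"].to_numpy() for _, g in part.groupby("env_id")]
    _try_anova(anovas, manifest, "test_time", one_way_anova, by_env)
    by_env_acc = [
        g["placement_error"].to_numpy() for _, g in part.groupby("env_id")
    ]
    _try_anova(anovas, manifest, "placement_accuracy", one_way_anova, by_env_acc)

    manifest["n_participants_analyzed"] = int(part["participant_id"].nunique())
    manifest["n_participants_excluded"] = (
        manifest["n_sessions_input"] - manifest["n_participants_analyzed"]
    )
    return StudyReport(
        study_label="study1",
        tables={"training": training, "participant": part, "item": item},
        anovas=anovas,
        correlations={},
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# study 2: sleep vs wake retention


def run_study2(ds: CohortDataset, config: StudyConfig = StudyConfig()
               ) -> StudyReport:
    """Within-subject sleep/wake analysis battery."""
    if ds.study_label != "study2":
        raise ValueError("run_study2 expects a study2 dataset")
    manifest = _base_manifest(ds, config)
    mc = config.metric_config

    # pairing: participants must have one sleep and one wake session
    by_pid: dict[str, set] = {}
    for s in ds.sessions:
        by_pid.setdefault(s.participant_id, set()).add(s.condition)
    unpaired = sorted(p for p, c in by_pid.items() if c != {"sleep", "wake"})
    if unpaired:
        warnings.warn(f"excluding unpaired participants: {unpaired}")
        ds = CohortDataset(
            sessions=[s for s in ds.sessions
                      if s.participant_id not in unpaired],
            study_label="study2", ground_truth=ds.ground_truth,
        )
    manifest["unpaired_excluded"] = unpaired

    part_all, item = aggregate(ds, mc, config.item_filter_sd)

    # participant-level exclusion: poor learning/memory performance,
    # one-sided (high placement error only)
    perf = part_all.groupby("participant_id")["placement_error"].mean()
    excluded_participants: list[str] = []
    if config.participant_filter_sd is not None and len(perf) >= 3:
        filt = sd_outlier_filter(
            perf.to_numpy(), config.participant_filter_sd, "above_only"
        )
        excluded_participants = sorted(perf.index[filt.removed])
    manifest["outlier_participants_excluded"] = excluded_participants
    part = part_all[~part_all["participant_id"].isin(excluded_participants)]
    item = item[~item["participant_id"].isin(excluded_participants)].copy()
    manifest["n_participants_analyzed"] = int(part["participant_id"].nunique())
    manifest["n_participants_excluded"] = (
        len(by_pid) - manifest["n_participants_analyzed"]
    )

    anovas: dict[str, AnovaResult] = {}
    for dv in PARTICIPANT_MEASURES:
        _try_anova(anovas, manifest, dv, rm_anova_2x2,
                   part, dv, ["condition", "phase"], "participant_id")

    training = training_summary_table(ds, mc)
    training = training[
        ~training["participant_id"].isin(excluded_participants)
    ]
    for name, dv in (("training_time", "time_in_phase_s"),
                     ("training_chests_opened", "chests_opened_distinct"),
                     ("training_steps", "total_steps")):
        _try_anova(anovas, manifest, name, rm_anova_2x2,
                   training, dv, ["condition", "phase"], "participant_id")

    # dwell: condition x radius x test
    dwell_cols = [c for c in part.columns if c.startswith("dwell_")]
    if dwell_cols:
        dwell_long = part.melt(
            id_vars=["participant_id", "condition", "phase"],
            value_vars=dwell_cols, var_name="radius", value_name="dwell",
        )
        dwell_long["radius"] = (
            dwell_long["radius"].str.replace("dwell_", "").astype(float)
        )
        _try_anova(anovas, manifest, "proximity_dwell", rm_anova,
                   dwell_long, "dwell", ["condition", "radius", "phase"],
                   "participant_id")

    # item-level ANOVAs: each surviving (participant, object) pair is a unit
    # crossed with condition and test
    item_ok = item[~item["excluded_item"]].copy()
    item_ok["unit"] = item_ok["participant_id"] + ":" + item_ok["object_id"]
    complete = item_ok.groupby("unit")["phase"].transform("size") == 4
    item_cc = item_ok[complete]
    for dv in ("placement_error", "path_length", "header_direction"):
        sub = item_cc.dropna(subset=[dv])
        units = sub.groupby("unit")[dv].transform("size") == 4
        _try_anova(anovas, manifest, f"item_{dv}", rm_anova_2x2,
                   sub[units], dv, ["condition", "phase"], "unit")

    # correlation families
    correlations: dict[str, CorrelationMatrixResult] = {}
    for cond in ("sleep", "wake"):
        for phase in ("test1", "test2"):
            sub = part[(part["condition"] == cond) & (part["phase"] == phase)]
            tab = sub.set_index("participant_id")[list(GLOBAL_CORR_MEASURES)]
            if len(tab) >= 3:
                correlations[f"global_{cond}_{phase}"] = pearson_bonferroni(
                    tab, alpha=config.alpha
                )
            isub = item_cc[(item_cc["condition"] == cond)
                           & (item_cc["phase"] == phase)]
            itab = isub.set_index("unit")[list(GLOBAL_CORR_MEASURES)]
            if len(itab) >= 3:
                correlations[f"item_{cond}_{phase}"] = pearson_bonferroni(
                    itab, alpha=config.alpha
                )

    approach = _approach_angle_table(ds, mc, excluded_participants)
    for cond in ("sleep", "wake"):
        sub = approach[approach["condition"] == cond]
        tab = sub.set_index("unit")[
            ["training1", "training2", "test1", "test2"]
        ]
        if len(tab) >= 3:
            correlations[f"approach_{cond}"] = pearson_bonferroni(
                tab, alpha=config.alpha
            )

    # difference scores (test2 - test1) per participant; placement error is
    # negated so positive always means maintained/improved performance
    wide = part.pivot_table(
        index=["participant_id", "condition"], columns="phase",
        values=list(PARTICIPANT_MEASURES),
    )
    diffs = {}
    for dv in PARTICIPANT_MEASURES:
        if (dv, "test1") in wide.columns and (dv, "test2") in wide.columns:
            d = wide[(dv, "test2")] - wide[(dv, "test1")]
            diffs[dv if dv != "placement_error"
                  else "placement_error_improvement"] = (
                -d if dv == "placement_error" else d
            )
    diff_tab = pd.DataFrame(diffs).reset_index()

    manifest["n_items_excluded"] = int(item["excluded_item"].sum())
    return StudyReport(
        study_label="study2",
        tables={
            "participant": part,
            "item": item,
            "training": training,
            "approach_angles": approach,
            "difference_scores": diff_tab,
        },
        anovas=anovas,
        correlations=correlations,
        manifest=manifest,
    )


def _approach_angle_table(ds: CohortDataset, mc: MetricConfig,
                          excluded: list[str]) -> pd.DataFrame:
    """Per (participant, condition, object): approach angle toward the true
    chest location in each of the four phases (missing where the trajectory
    never approached)."""
    rows = []
    for sess in ds.sessions:
        if sess.participant_id in excluded:
            continue
        env = sess.environment
        phase_trials = {
            ph: sess.trials_in_phase(ph)
            for ph in TRAINING_PHASES + ("test1", "test2")
        }
        for oid, true in env.chest_locations.items():
            rec = {
                "participant_id": sess.participant_id,
                "condition": sess.condition,
                "object_id": oid,
                "unit": f"{sess.participant_id}:{oid}",
            }
            for ph, trials in phase_trials.items():
                if ph.startswith("training"):
                    cands = trials
                else:
                    cands = [t for t in trials if t.object_id == oid]
                ang = np.nan
                for t in cands:
                    try:
                        ang = approach_angle(
                            t, true, k=mc.approach_k,
                            radius=mc.approach_radius, config=mc,
                        )
                        break
                    except (NoApproachError, DegenerateTrialError):
                        continue
                rec[ph] = ang
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering


def make_report(report: StudyReport, outdir) -> list[Path]:
    """Write tables (CSV), the ANOVA set (tidy CSV plus an inline-style text
    report), correlation families, the manifest, and summary figures.

    Text outputs are deterministic given the report; re-rendering a report
    produces byte-identical tables and manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, tab in report.tables.items():
        p = outdir / f"table_{name}.csv"
        tab.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    if report.anovas:
        tidy = pd.concat(
            [r.to_frame().assign(analysis=name)
             for name, r in report.anovas.items()],
            ignore_index=True,
        )[["analysis", "effect", "F", "df1", "df2", "p", "partial_eta2"]]
        p = outdir / "anovas.csv"
        tidy.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        lines = []
        for name, r in report.anovas.items():
            lines.append(f"== {name} ==")
            lines.extend(e.format() for e in r.effects.values())
            lines.append("")
        p = outdir / "anovas.txt"
        p.write_text("\n".join(lines), encoding="utf-8")
        written.append(p)
    for name, corr in report.correlations.items():
        p = outdir / f"correlations_{name}.csv"
        corr.to_frame().to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    p = outdir / "manifest.json"
    p.write_text(json.dumps(report.manifest, indent=2, sort_keys=True) + "\n",
                 encoding="utf-8")
    written.append(p)
    written.extend(_figures(report, outdir))
    return written


def _figures(report: StudyReport, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    part = report.tables.get("participant")
    if part is None or part.empty:
        return written
    group_cols = [c for c in ("condition", "phase") if c in part.columns]
    for dv in ("placement_error", "path_length", "header_direction"):
        if dv not in part.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        means = part.groupby(group_cols)[dv].mean()
        sems = part.groupby(group_cols)[dv].sem()
        means.plot.bar(ax=ax, yerr=sems, capsize=3, color="#4477aa")
        ax.set_ylabel(dv.replace("_", " "))
        ax.set_title(f"{dv.replace('_', ' ')} by {' x '.join(group_cols)}")
        fig.tight_layout()
        p = outdir / f"fig_{dv}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    dwell_cols = [c for c in part.columns if c.startswith("dwell_")]
    if dwell_cols and "phase" in part.columns:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        m = part.groupby(group_cols)[dwell_cols].mean()
        m.T.plot.bar(ax=ax)
        ax.set_ylabel("dwell fraction")
        ax.set_title("proximity dwell by radius")
        fig.tight_layout()
        p = outdir / "fig_dwell.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    diff = report.tables.get("difference_scores")
    if diff is not None and "placement_error_improvement" in getattr(
            diff, "columns", ()):
        fig, ax = plt.subplots(figsize=(4, 3.2))
        m = diff.groupby("condition")["placement_error_improvement"].mean()
        s = diff.groupby("condition")["placement_error_improvement"].sem()
        m.plot.bar(ax=ax, yerr=s, capsize=3, color=["#4477aa", "#ee6677"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("accuracy change (blocks,\npositive = maintained)")
        fig.tight_layout()
        p = outdir / "fig_difference_scores.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
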