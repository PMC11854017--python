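"""End-to-end study orchestration: QC -> models -> PAS -> comparisons.

:func:`run_study` reproduces the full analysis shape on any input, real or
synthetic: sample-level QC and filtering, pathway-model calibration (or
loading of serialized models), per-sample pathway activity scoring, the
design-appropriate group statistics, and on-disk tables (PAS long table,
comparison table, a baseline-summary table of per-group PAS mean/SD, QC
report, JSON manifest with content hashes).

Because absolute pathway activity scores are only interpretable against a
defined reference range for the same pathway and cell type, the summary
header carries an explicit disclaimer: without such a range, only
differences in log2-odds PAS between samples of one pathway are
meaningful.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    ExpressionMatrix,
    FeatureAnnotation,
    SampleMetadata,
    align_metadata,
    read_annotation,
    read_matrix,
    read_metadata,
)
from .model import (
    CalibratedPathwayModel,
    PathwayDefinition,
    calibrate,
    pas_table,
    read_definitions,
)
from .qc import QCReport, QCThresholds, apply_qc_filter, compute_qc
from .simulate import (
    SyntheticCohort,
    design_from_template,
    generate_calibration_set,
    generate_cohort,
)
from .stats import (
    ComparisonResult,
    annotate,
    bonferroni,
    compare_groups,
    lmm_timecourse,
    paired_t_two_sided,
)

PAS_RANGE_DISCLAIMER = (
    "PAS values are log2 odds; each pathway has its own score range. "
    "Without a defined activity range for this cell type, only differences "
    "in log2 odds between samples of the same pathway are interpretable; "
    "a negative PAS does not by itself mean the pathway is inactive."
)

ContrastKind = Literal["unpaired", "paired", "timecourse"]


@dataclass
class ContrastPlan:
    """Which groups to compare and with which test family."""

    kind: ContrastKind
    #: for ``unpaired``: list of (group A, group B); for ``paired``: a single
    #: (before, after) pair; ignored for ``timecourse``
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    baseline_time: float | None = None
    bonferroni_family: str = "per_pathway"

    def __post_init__(self) -> None:
        if self.kind not in ("unpaired", "paired", "timecourse"):
            raise ValueError(f"unknown contrast kind: {self.kind!r}")
        if self.kind == "paired" and len(self.contrasts) != 1:
            raise ValueError("paired plan needs exactly one (before, after) pair")
        if self.kind == "unpaired" and not self.contrasts:
            raise ValueError("unpaired plan needs at least one contrast")


def default_contrast_plan(template: str) -> ContrastPlan:
    """Ready-made contrast plans for the four simulation templates."""
    if template == "two_group_pbmc":
        return ContrastPlan(
            kind="unpaired",
            contrasts=[
                ("healthy", "gram_positive"),
                ("healthy", "gram_negative"),
                ("healthy", "mixed"),
                ("healthy", "unidentified"),
            ],
        )
    if template == "primed_pbmc":
        return ContrastPlan(
            kind="unpaired",
            contrasts=[
                ("medium", "LPS_unprimed"),
                ("medium", "LPS_primed"),
                ("LPS_unprimed", "LPS_primed"),
            ],
        )
    if template == "paired_whole_blood":
        return ContrastPlan(kind="paired", contrasts=[("vehicle", "LPS")])
    if template == "timecourse_endotoxemia":
        return ContrastPlan(kind="timecourse", baseline_time=0.0)
    raise ValueError(f"no default contrast plan for template {template!r}")


@dataclass
class StudyConfig:
    """Configuration for one pipeline run.

    Exactly one input mode:

    * ``template`` set -> a synthetic cohort is generated (seeded) and
      models are calibrated on synthetic calibration sets;
    * ``matrix_path`` set -> files are read; then exactly one of
      ``models_path`` (serialized models) or ``definitions_path`` plus
      calibration inputs must be given.
    """

    template: str | None = None
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    definitions_path: str | None = None
    models_path: str | None = None
    calibration_matrix_path: str | None = None
    calibration_labels_path: str | None = None
    qc_thresholds: dict = field(default_factory=dict)
    contrast_plan: ContrastPlan | None = None
    output_dir: str = "stp_run"
    seed: int = 0
    skip_failures: bool = False

    def __post_init__(self) -> None:
        if (self.template is None) == (self.matrix_path is None):
            raise ValueError("set exactly one of template / matrix_path")
        if self.matrix_path is not None:
            has_models = self.models_path is not None
            has_defs = self.definitions_path is not None
            if has_models == has_defs:
                raise ValueError(
                    "file mode needs exactly one of models_path / definitions_path"
                )
            if has_defs and (
                self.calibration_matrix_path is None or self.calibration_labels_path is None
            ):
                raise ValueError(
                    "definitions_path requires calibration_matrix_path and "
                    "calibration_labels_path"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        plan = doc.pop("contrast_plan", None)
        if plan is not None:
            plan = ContrastPlan(
                kind=plan["kind"],
                contrasts=[tuple(c) for c in plan.get("contrasts", [])],
                baseline_time=plan.get("baseline_time"),
                bonferroni_family=plan.get("bonferroni_family", "per_pathway"),
            )
        return cls(contrast_plan=plan, **doc)

    def content_hash(self) -> str:
        blob = json.dumps(
            {k: (v if not isinstance(v, ContrastPlan) else vars(v)) for k, v in vars(self).items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudySummary:
    """Everything a run produces, in memory."""

    pas_long: pd.DataFrame
    comparisons: pd.DataFrame
    baseline_summary: pd.DataFrame
    qc_report: QCReport
    manifest: dict
    output_dir: Path


def summarize_controls(
    pas_long: pd.DataFrame,
    baseline_group_labels: Sequence[str],
    group_col: str = "group_label",
) -> pd.DataFrame:
    """Per-(pathway, baseline group) PAS mean and SD (n-1 denominator).

    A single-sample group gets an NA marker for SD; an empty group is a
    hard error.
    """
    rows = []
    for group in baseline_group_labels:
        sub = pas_long.loc[pas_long[group_col] == group]
        if sub.empty:
            raise ValueError(f"baseline group {group!r} has no samples")
        for pathway, psub in sub.groupby("pathway", sort=True):
            vals = psub["pas"].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            rows.append(
                dict(group=group, pathway=pathway, n=int(vals.size), mean=mean, sd=sd)
            )
    return pd.DataFrame(rows)


def _comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                pathway=r.pathway_name,
                contrast=r.contrast_label,
                statistic_name=r.statistic_name,
                statistic=r.statistic,
                p_raw=r.p_raw,
                p_adjusted=r.p_adjusted,
                m=r.m,
                annotation=r.annotation,
            )
            for r in results
        ],
        columns=["pathway", "contrast", "statistic_name", "statistic", "p_raw",
                 "p_adjusted", "m", "annotation"],
    )


def _paired_comparisons(joined: pd.DataFrame, before: str, after: str) -> pd.DataFrame:
    rows = []
    for pathway, sub in joined.groupby("pathway", sort=True):
        b = sub.loc[sub["group_label"] == before].set_index("pairing_key")["pas"]
        a = sub.loc[sub["group_label"] == after].set_index("pairing_key")["pas"]
        shared = sorted(set(b.index) & set(a.index))
        label = f"{before} vs {after}"
        if len(shared) < 2:
            rows.append(
                dict(pathway=pathway, contrast=label, statistic_name="paired_t",
                     statistic=np.nan, p_raw=np.nan, p_adjusted=np.nan, m=1,
                     annotation="not evaluable")
            )
            continue
        t, df, p = paired_t_two_sided(b.loc[shared].to_numpy(), a.loc[shared].to_numpy())
        rows.append(
            dict(pathway=pathway, contrast=label, statistic_name="paired_t",
                 statistic=t, p_raw=p, p_adjusted=p, m=1, annotation=annotate(p))
        )
    return pd.DataFrame(rows)


def _timecourse_comparisons(joined: pd.DataFrame, baseline: float | None) -> pd.DataFrame:
    frames = []
    for pathway in sorted(joined["pathway"].unique()):
        sub = joined.loc[joined["pathway"] == pathway]
        ok = sub.groupby("time_point")["sample_id"].count()
        if (ok < 2).any() or sub["subject_id"].nunique() < 2:
            frames.append(
                pd.DataFrame(
                    [dict(pathway=pathway, contrast="timecourse", statistic_name="wald_t",
                          statistic=np.nan, p_raw=np.nan, p_adjusted=np.nan, m=1,
                          annotation="not evaluable")]
                )
            )
            continue
        results = lmm_timecourse(sub, pathway=pathway, baseline=baseline)
        frames.append(_comparison_frame(results))
    return pd.concat(frames, ignore_index=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> StudySummary:
    """Execute a full study: QC, scoring, statistics, tables on disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []

    # ------------------------------------------------------------------ inputs
    if config.template is not None:
        design = design_from_template(config.template, seed=config.seed)
        cohort = generate_cohort(design)
        matrix, metadata, annotation = cohort.matrix, cohort.metadata, cohort.annotation
        definitions = cohort.definitions
        models = _calibrate_synthetic(definitions, config.seed)
        plan = config.contrast_plan or default_contrast_plan(config.template)
    else:
        matrix = read_matrix(config.matrix_path)
        metadata = read_metadata(config.metadata_path)
        annotation = (
            read_annotation(config.annotation_path) if config.annotation_path else None
        )
        matrix, metadata, drop_report = align_metadata(matrix, metadata)
        if drop_report["dropped_from_matrix"] or drop_report["dropped_from_metadata"]:
            run_warnings.append(f"sample alignment dropped ids: {drop_report}")
        if config.models_path is not None:
            models = [
                CalibratedPathwayModel.load(p)
                for p in sorted(Path(config.models_path).glob("*.json"))
            ]
            if not models:
                raise ValueError(f"no model JSON files under {config.models_path}")
        else:
            definitions = read_definitions(config.definitions_path)
            cal_matrix = read_matrix(config.calibration_matrix_path)
            labels_table = pd.read_csv(config.calibration_labels_path, sep="\t")
            labels = dict(
                zip(labels_table["sample_id"], labels_table["active"].astype(bool))
            )
            models = [calibrate(d, cal_matrix, labels) for d in definitions]
        plan = config.contrast_plan
        if plan is None:
            raise ValueError("file mode requires an explicit contrast_plan")

    # validate the plan against known groups before any computation
    known_groups = set(metadata.table["group_label"].dropna().unique())
    if plan.kind in ("unpaired", "paired"):
        for a, b in plan.contrasts:
            for g in (a, b):
                if g not in known_groups:
                    raise ValueError(f"contrast references unknown group {g!r}")

    # ------------------------------------------------------------------ QC
    thresholds = QCThresholds.from_dict(config.qc_thresholds) if config.qc_thresholds else QCThresholds()
    qc_report = compute_qc(matrix, annotation, thresholds)
    filtered, removed = apply_qc_filter(matrix, qc_report)
    if removed:
        run_warnings.append(f"QC removed samples: {removed}")
    metadata_f = metadata.subset(filtered.samples)

    # ------------------------------------------------------------------ PAS
    pas = pas_table(models, filtered, skip_failures=config.skip_failures)
    joined = pas.merge(
        metadata_f.table.reset_index(drop=True), on="sample_id", how="left"
    )

    # ------------------------------------------------------------------ stats
    if plan.kind == "unpaired":
        comparisons = compare_groups(
            joined, plan.contrasts, family=plan.bonferroni_family
        )
    elif plan.kind == "paired":
        before, after = plan.contrasts[0]
        comparisons = _paired_comparisons(joined, before, after)
    else:
        comparisons = _timecourse_comparisons(joined, plan.baseline_time)

    # ------------------------------------------------------------------ summary
    baseline_groups = _baseline_groups(plan, joined)
    baseline_summary = summarize_controls(joined, baseline_groups)

    # ------------------------------------------------------------------ outputs
    paths = {}
    pas_path = out / "pas_long.tsv"
    joined.to_csv(pas_path, sep="\t", index=False)
    paths["pas_long"] = pas_path
    cmp_path = out / "comparisons.tsv"
    comparisons.to_csv(cmp_path, sep="\t", index=False)
    paths["comparisons"] = cmp_path
    summary_path = out / "baseline_summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("# " + PAS_RANGE_DISCLAIMER + "\n")
        baseline_summary.to_csv(fh, sep="\t", index=False)
    paths["baseline_summary"] = summary_path
    qc_tsv = qc_report.write_tsv(out / "qc_report.tsv")
    qc_json = qc_report.write_json(out / "qc_report.json")
    paths["qc_report_tsv"] = qc_tsv
    paths["qc_report_json"] = qc_json
    boxplot_path = out / "boxplot_long.tsv"
    joined[["pathway", "group_label", "sample_id", "pas"]].to_csv(
        boxplot_path, sep="\t", index=False
    )
    paths["boxplot_long"] = boxplot_path

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "disclaimer": PAS_RANGE_DISCLAIMER,
        "warnings": run_warnings,
        "n_samples_scored": int(len(filtered.samples)),
        "n_samples_removed_by_qc": len(removed),
        "files": {name: {"path": str(p), "sha256": _hash_file(p)} for name, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    return StudySummary(
        pas_long=joined,
        comparisons=comparisons,
        baseline_summary=baseline_summary,
        qc_report=qc_report,
        manifest=manifest,
        output_dir=out,
    )


def _baseline_groups(plan: ContrastPlan, joined: pd.DataFrame) -> list[str]:
    if plan.kind == "unpaired":
        # first group of the first contrast is the reference by convention
        return [plan.contrasts[0][0]]
    if plan.kind == "paired":
        return [plan.contrasts[0][0]]
    times = joined["time_point"].dropna()
    base = plan.baseline_time if plan.baseline_time is not None else float(times.min())
    labels = joined.loc[joined["time_point"] == base, "group_label"].unique()
    return sorted(labels)


def _calibrate_synthetic(
    definitions: Sequence[PathwayDefinition], seed: int
) -> list[CalibratedPathwayModel]:
    """One calibration set per pathway, seeded reproducibly from ``seed``."""
    models = []
    for i, definition in enumerate(definitions):
        cal = generate_calibration_set(definition, seed=(seed * 1009 + i) % (2**31 - 1))
        labels = dict(
            zip(cal.metadata.table["sample_id"], cal.truth.set_index("sample_id")["activity"] > 0.5)
        )
        models.append(calibrate(definition, cal.matrix, labels))
    return models
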