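"""Matrix-level microarray quality control.

Implements sample-level analogs of the standard Affymetrix QC battery on a
summarized log2 expression matrix: mean probe intensity, presence of
negative or saturated (>16-bit) values, 3'/5' degradation ratios for
housekeeping control probe pairs (GAPDH, ACTB), spike-in presence
(poly-A sample-preparation and cRNA hybridization spikes), center of
intensity, border-control summaries, and a degradation-slope proxy.

Probe-level computations (RNA degradation curves from individual probe
positions, as affyQCReport/AffyRNAdeg compute from CEL files) are out of
scope; the analogs here operate on the summarized matrix plus a feature
annotation that flags control features.

No community-agreed numeric pass thresholds exist at matrix level; the
defaults in :class:`QCThresholds` (mean intensity in [4, 12] log2, 3'/5'
ratio <= 3.0) are this package's documented defaults and are fully
config-overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FeatureAnnotation

#: log2 of the 16-bit scanner ceiling; values at or above are "saturated".
SATURATION_LOG2 = 16.0

PASS = "pass"
FAIL = "fail"
NOT_EVALUABLE = "not evaluable"


@dataclass
class QCThresholds:
    """Numeric QC acceptance thresholds (log2 units unless noted)."""

    min_mean_intensity: float = 4.0
    max_mean_intensity: float = 12.0
    #: maximum acceptable 3'/5' ratio, linear scale
    max_three_five_ratio: float = 3.0
    require_spike_polyA: bool = False
    require_spike_hyb: bool = False
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if not self.min_mean_intensity < self.max_mean_intensity:
            raise ValueError("min_mean_intensity must be < max_mean_intensity")
        if self.max_three_five_ratio <= 0:
            raise ValueError("max_three_five_ratio must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        return cls(**d)


@dataclass
class SampleQC:
    """QC measurements and verdict for one sample."""

    sample_id: str
    mean_intensity: float
    center_of_intensity: float
    n_negative: int
    n_saturated: int
    three_five_ratios: dict[str, float]
    spike_in_present: dict[str, bool]
    border_control_summary: dict[str, float]
    degradation_proxy: float | None
    checks: dict[str, str]
    failed_checks: list[str]

    @property
    def passed(self) -> bool:
        return not self.failed_checks


@dataclass
class QCReport:
    """Per-sample QC results for a matrix."""

    samples: list[SampleQC]
    thresholds: QCThresholds

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.passed != (not s.failed_checks):
                raise ValueError("inconsistent pass flag")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def passing_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.passed]

    @property
    def failing_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.passed]

    def __getitem__(self, sample_id: str) -> SampleQC:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "mean_intensity": s.mean_intensity,
                "center_of_intensity": s.center_of_intensity,
                "n_negative": s.n_negative,
                "n_saturated": s.n_saturated,
                "degradation_proxy": s.degradation_proxy,
                "pass": s.passed,
                "failed_checks": ";".join(s.failed_checks),
            }
            for label, ratio in s.three_five_ratios.items():
                row[f"ratio_3p5p_{label}"] = ratio
            for cls, present in s.spike_in_present.items():
                row[f"spike_{cls}"] = present
            for cls, mean in s.border_control_summary.items():
                row[f"border_{cls}_mean"] = mean
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, sep="\t", index=False)
        return Path(path)

    def write_json(self, path: str | Path) -> Path:
        doc = {
            "thresholds": asdict(self.thresholds),
            "samples": [asdict(s) | {"pass": s.passed} for s in self.samples],
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=float))
        return Path(path)


def three_five_ratio(log2_three: float, log2_five: float) -> float:
    """Linear-scale 3'/5' ratio from log2 intensities: 2^(3' - 5')."""
    return float(2.0 ** (log2_three - log2_five))


def compute_qc(
    matrix: ExpressionMatrix,
    annotation: FeatureAnnotation | None = None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Compute the QC battery for every sample of ``matrix``.

    Checks that need control features absent from the annotation are
    reported as "not evaluable", never as a pass.  Deterministic and
    order-independent over samples.
    """
    if matrix.data.empty:
        raise ValueError("cannot run QC on an empty matrix")
    thresholds = thresholds or QCThresholds()

    ann = annotation.table if annotation is not None else None
    pair_labels: list[str] = annotation.pair_labels() if annotation is not None else []
    in_matrix = set(matrix.features)

    def feats(cls: str) -> list:
        if ann is None:
            return []
        sel = ann.loc[ann["control_class"] == cls, "feature_id"]
        return [f for f in sel if f in in_matrix]

    spike_classes = {"spike_polyA": feats("spike_polyA"), "spike_hyb": feats("spike_hyb")}
    border = {
        "border_positive": feats("border_positive"),
        "border_negative": feats("border_negative"),
    }
    pairs: dict[str, tuple[list, list]] = {}
    for label in pair_labels:
        sub = ann.loc[ann["control_group_label"] == label]
        three = [f for f in sub.loc[sub["control_class"] == "three_prime", "feature_id"] if f in in_matrix]
        five = [f for f in sub.loc[sub["control_class"] == "five_prime", "feature_id"] if f in in_matrix]
        pairs[label] = (three, five)

    degradation_order = None
    if ann is not None and "five_to_three_index" in ann.columns:
        idx = pd.to_numeric(ann["five_to_three_index"], errors="coerce").dropna()
        idx = idx[idx.index.isin(in_matrix)]
        if len(idx) >= 3:
            degradation_order = idx.sort_values().index.tolist()

    results = []
    for sample_id in matrix.samples:
        vec = matrix.data[sample_id]
        obs = vec.dropna()
        checks: dict[str, str] = {}

        mean_intensity = float(obs.mean())
        center = float(obs.median())
        n_negative = int((obs < 0).sum())
        n_saturated = int((obs >= SATURATION_LOG2).sum())

        checks["mean_intensity_range"] = (
            PASS
            if thresholds.min_mean_intensity <= mean_intensity <= thresholds.max_mean_intensity
            else FAIL
        )
        if thresholds.allow_negative:
            checks["negative_intensities"] = PASS
        else:
            checks["negative_intensities"] = FAIL if n_negative > 0 else PASS
        checks["saturated_intensities"] = FAIL if n_saturated > 0 else PASS

        ratios: dict[str, float] = {}
        if not pairs:
            checks["three_five_ratio"] = NOT_EVALUABLE
        else:
            worst_ok = True
            evaluable = False
            for label, (three, five) in pairs.items():
                if not three or not five:
                    continue
                evaluable = True
                r = three_five_ratio(float(vec[three].mean()), float(vec[five].mean()))
                ratios[label] = r
                if r > thresholds.max_three_five_ratio:
                    worst_ok = False
            if not evaluable:
                checks["three_five_ratio"] = NOT_EVALUABLE
            else:
                checks["three_five_ratio"] = PASS if worst_ok else FAIL

        spike_present: dict[str, bool] = {}
        for cls, flist in spike_classes.items():
            required = getattr(thresholds, f"require_{cls}")
            if not flist:
                spike_present[cls] = False
                checks[f"{cls}_present"] = NOT_EVALUABLE if required else PASS
            else:
                # spike considered present when detectably above background
                present = bool((vec[flist] > center).any())
                spike_present[cls] = present
                if required:
                    checks[f"{cls}_present"] = PASS if present else FAIL
                else:
                    checks[f"{cls}_present"] = PASS

        border_summary: dict[str, float] = {}
        for cls, flist in border.items():
            if flist:
                border_summary[cls] = float(vec[flist].mean())

        if degradation_order is not None:
            y = vec[degradation_order].to_numpy(dtype=float)
            x = np.arange(len(y), dtype=float)
            ok = np.isfinite(y)
            degradation = float(np.polyfit(x[ok], y[ok], 1)[0]) if ok.sum() >= 3 else None
        else:
            degradation = None

        failed = sorted(name for name, status in checks.items() if status == FAIL)
        results.append(
            SampleQC(
                sample_id=sample_id,
                mean_intensity=mean_intensity,
                center_of_intensity=center,
                n_negative=n_negative,
                n_saturated=n_saturated,
                three_five_ratios=ratios,
                spike_in_present=spike_present,
                border_control_summary=border_summary,
                degradation_proxy=degradation,
                checks=checks,
                failed_checks=failed,
            )
        )
    return QCReport(samples=results, thresholds=thresholds)


def apply_qc_filter(matrix: ExpressionMatrix, report: QCReport) -> tuple[ExpressionMatrix, list[str]]:
    """Drop failing samples; returns (filtered matrix, removed sample ids).

    The report must cover exactly the samples of ``matrix``; zero surviving
    samples is a hard error (review thresholds rather than proceed).
    """
    if set(report.sample_ids) != set(matrix.samples):
        raise ValueError("QC report samples do not match matrix samples")
    passing = [s for s in matrix.samples if s in set(report.passing_ids)]
    removed = [s for s in matrix.samples if s not in set(passing)]
    if not passing:
        raise ValueError(
            "all samples failed QC; review thresholds before filtering"
        )
    return matrix.subset_samples(passing), removed
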