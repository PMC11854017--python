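"""Synthetic expression-cohort generation with known pathway activity.

Cohorts are generated under an additive log2 model per feature f and
sample s:

    value(f, s) = mu_f + d_f * delta * a(p(f), s) + u_subject(s) + eps

where ``mu_f ~ Uniform(5, 10)`` is the feature's baseline log2 intensity,
``d_f`` the regulation direction of the target gene the probe measures,
``delta`` the pathway effect size in log2 units, ``a(p, s)`` the programmed
activity of pathway p in sample s's condition (0..1), ``u ~ Normal(0,
tau^2)`` a subject random intercept and ``eps ~ Normal(0, sigma^2)``
measurement noise.  Nuisance features carry no activity term; AFFX-style
control features sit at fixed documented intensities so QC checks have
material to work on.  Corruptions (negative values, saturation, extreme
3' bias) are applied last and mimic exactly the failure modes the QC
module must catch.

Four design templates mirror common sepsis / LPS endotoxemia study shapes:

* ``two_group_pbmc`` — healthy controls (n=16) vs septic patients (n=54)
  with pathogen subgroups; by default only AR activity is raised, and only
  in the Gram-positive subgroup.
* ``primed_pbmc`` — PBMCs from 6 donors in three arms (medium, LPS
  unprimed, LPS primed); by default no pathway responds in any arm,
  emulating the absence of a PBMC LPS response.
* ``paired_whole_blood`` — 4 subjects, paired vehicle/LPS stimulation;
  NFKB, JAK-STAT1/2 and JAK-STAT3 respond to LPS.
* ``timecourse_endotoxemia`` — in vivo endotoxemia time course at 0/2/6 h;
  NFKB, AR, TGFB and JAK-STAT3 switch on from 2 h, JAK-STAT1/2 only at
  6 h, and a synthetic always-inactive CONTROL pathway is carried along.

Defaults (delta=1.5, sigma=0.5, tau=0.3, 500 nuisance genes) are this
package's choices, documented in the methods note; they produce clearly
separable but noisy cohorts of the published sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FeatureAnnotation, SampleMetadata
from .model import PathwayDefinition, TargetGene, bundled_definitions

TEMPLATES = (
    "two_group_pbmc",
    "primed_pbmc",
    "paired_whole_blood",
    "timecourse_endotoxemia",
    "calibration_set",
)

CORRUPTION_TYPES = ("negative_values", "saturated_values", "extreme_3prime_bias")

#: fixed log2 intensities of synthetic control features
CONTROL_INTENSITIES = {
    "three_prime": 10.0,
    "five_prime": 10.0,
    "spike_polyA": 11.0,
    "spike_hyb": 12.0,
    "border_positive": 13.0,
    "border_negative": 2.0,
}

DEFAULT_DELTA = 1.5
DEFAULT_SIGMA = 0.5
DEFAULT_TAU = 0.3
DEFAULT_N_NUISANCE = 500


@dataclass
class SimulationDesign:
    """Everything needed to generate one synthetic cohort."""

    template: str
    group_sizes: dict[str, int] | None = None
    n_subjects: int | None = None
    time_points: tuple[float, ...] | None = None
    activity_map: dict[tuple[str, str], float] = field(default_factory=dict)
    delta: float = DEFAULT_DELTA
    sigma: float = DEFAULT_SIGMA
    tau: float = DEFAULT_TAU
    n_nuisance_genes: int = DEFAULT_N_NUISANCE
    corrupt_samples: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template: {self.template!r}")
        for value in (self.delta, self.sigma, self.tau):
            if value < 0:
                raise ValueError("delta, sigma, tau must be >= 0")
        if self.group_sizes is not None and any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for (pathway, condition), a in self.activity_map.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"activity for ({pathway}, {condition}) outside [0,1]")
        for _, kind in self.corrupt_samples:
            if kind not in CORRUPTION_TYPES:
                raise ValueError(f"unknown corruption type: {kind!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    matrix: ExpressionMatrix
    metadata: SampleMetadata
    annotation: FeatureAnnotation
    truth: pd.DataFrame  # columns pathway, sample_id, activity
    definitions: list[PathwayDefinition]
    design: SimulationDesign

    def activity_of(self, pathway: str, sample_id: str) -> float:
        sel = self.truth.loc[
            (self.truth["pathway"] == pathway) & (self.truth["sample_id"] == sample_id),
            "activity",
        ]
        return float(sel.iloc[0])


def make_control_definition(
    n_targets: int = 20, name: str = "CONTROL", seed: int = 7
) -> PathwayDefinition:
    """Synthetic always-usable control pathway (for null checks)."""
    rng = np.random.default_rng(seed)
    targets = tuple(
        TargetGene(
            gene=f"{name}_T{i:02d}",
            direction=1 if rng.random() < 0.8 else -1,
            probes=(f"{name}_T{i:02d}_at",),
        )
        for i in range(1, n_targets + 1)
    )
    return PathwayDefinition(pathway_name=name, transcription_factor_label=name, targets=targets)


def default_definitions(template: str) -> list[PathwayDefinition]:
    """Bundled placeholder pathways, plus a CONTROL pathway for time courses."""
    defs = bundled_definitions()
    if template == "timecourse_endotoxemia":
        defs = defs + [make_control_definition()]
    return defs


# ---------------------------------------------------------------------------
# design templates
# ---------------------------------------------------------------------------

def design_from_template(template: str, seed: int = 0, **overrides) -> SimulationDesign:
    """Build the default design for a named study template."""
    if template == "two_group_pbmc":
        base = SimulationDesign(
            template=template,
            group_sizes={
                "healthy": 16,
                "gram_positive": 16,
                "gram_negative": 18,
                "mixed": 6,
                "unidentified": 14,
            },
            activity_map={("AR", "gram_positive"): 1.0},
            seed=seed,
        )
    elif template == "primed_pbmc":
        base = SimulationDesign(
            template=template,
            n_subjects=6,
            group_sizes={"medium": 6, "LPS_unprimed": 6, "LPS_primed": 6},
            activity_map={},  # LPS does not move pathway activity in PBMCs
            seed=seed,
        )
    elif template == "paired_whole_blood":
        base = SimulationDesign(
            template=template,
            n_subjects=4,
            group_sizes={"vehicle": 4, "LPS": 4},
            activity_map={
                ("NFKB", "LPS"): 1.0,
                ("JAK-STAT1/2", "LPS"): 1.0,
                ("JAK-STAT3", "LPS"): 1.0,
            },
            seed=seed,
        )
    elif template == "timecourse_endotoxemia":
        base = SimulationDesign(
            template=template,
            n_subjects=8,
            time_points=(0.0, 2.0, 6.0),
            activity_map={
                ("NFKB", "2h"): 1.0,
                ("NFKB", "6h"): 1.0,
                ("AR", "2h"): 1.0,
                ("AR", "6h"): 1.0,
                ("TGFB", "2h"): 1.0,
                ("TGFB", "6h"): 1.0,
                ("JAK-STAT3", "2h"): 1.0,
                ("JAK-STAT3", "6h"): 1.0,
                ("JAK-STAT1/2", "6h"): 1.0,
            },
            seed=seed,
        )
    else:
        raise ValueError(f"unknown template: {template!r}")
    for key, value in overrides.items():
        if not hasattr(base, key):
            raise TypeError(f"unknown design field: {key!r}")
        setattr(base, key, value)
    base.__post_init__()
    return base


def _sample_plan(design: SimulationDesign) -> pd.DataFrame:
    """Expand a design into one row per sample (id, group, subject, time)."""
    rows = []
    t = design.template
    if t == "two_group_pbmc":
        i = 0
        for group, n in design.group_sizes.items():
            for _ in range(n):
                i += 1
                rows.append(
                    dict(sample_id=f"S{i:03d}", group_label=group, subject_id=f"subj{i:03d}",
                         time_point=None, pairing_key=None)
                )
    elif t == "primed_pbmc":
        n = design.n_subjects or 6
        i = 0
        for arm in ("medium", "LPS_unprimed", "LPS_primed"):
            for d in range(1, n + 1):
                i += 1
                rows.append(
                    dict(sample_id=f"S{i:03d}", group_label=arm, subject_id=f"donor{d:02d}",
                         time_point=None, pairing_key=f"donor{d:02d}")
                )
    elif t == "paired_whole_blood":
        n = design.n_subjects or 4
        i = 0
        for arm in ("vehicle", "LPS"):
            for d in range(1, n + 1):
                i += 1
                rows.append(
                    dict(sample_id=f"S{i:03d}", group_label=arm, subject_id=f"subj{d:02d}",
                         time_point=None, pairing_key=f"subj{d:02d}")
                )
    elif t == "timecourse_endotoxemia":
        n = design.n_subjects or 8
        times = design.time_points or (0.0, 2.0, 6.0)
        i = 0
        for tp in times:
            for d in range(1, n + 1):
                i += 1
                rows.append(
                    dict(sample_id=f"S{i:03d}", group_label=f"{tp:g}h", subject_id=f"subj{d:02d}",
                         time_point=tp, pairing_key=f"subj{d:02d}")
                )
    else:
        raise ValueError(f"template {t!r} has no sample plan; use generate_calibration_set")
    return pd.DataFrame(rows)


def _control_annotation_rows() -> list[dict]:
    rows = []
    for hk in ("GAPDH", "ACTB"):
        rows.append(dict(feature_id=f"AFFX-{hk}-3_at", gene_symbol=hk,
                         control_class="three_prime", control_group_label=hk))
        rows.append(dict(feature_id=f"AFFX-{hk}-5_at", gene_symbol=hk,
                         control_class="five_prime", control_group_label=hk))
    for k in range(1, 4):
        rows.append(dict(feature_id=f"AFFX-polyA-{k}_at", gene_symbol="",
                         control_class="spike_polyA", control_group_label=""))
        rows.append(dict(feature_id=f"AFFX-hyb-{k}_at", gene_symbol="",
                         control_class="spike_hyb", control_group_label=""))
    for k in range(1, 3):
        rows.append(dict(feature_id=f"AFFX-border-pos-{k}", gene_symbol="",
                         control_class="border_positive", control_group_label=""))
        rows.append(dict(feature_id=f"AFFX-border-neg-{k}", gene_symbol="",
                         control_class="border_negative", control_group_label=""))
    return rows


def _apply_corruptions(
    values: np.ndarray,
    features: list[str],
    annotation: FeatureAnnotation,
    corrupt: list[tuple[int, str]],
    rng: np.random.Generator,
) -> None:
    """Corrupt selected sample columns in place."""
    three_prime = set(annotation.features_of_class("three_prime"))
    fid_index = {f: i for i, f in enumerate(features)}
    n_features = len(features)
    for col, kind in corrupt:
        if not 0 <= col < values.shape[1]:
            raise IndexError(f"corrupt sample index {col} out of range")
        if kind == "negative_values":
            hit = rng.choice(n_features, size=max(1, n_features // 20), replace=False)
            values[hit, col] = -np.abs(values[hit, col]) - 0.5
        elif kind == "saturated_values":
            hit = rng.choice(n_features, size=max(1, n_features // 20), replace=False)
            values[hit, col] = 16.0 + rng.uniform(0.0, 0.5, size=hit.size)
        elif kind == "extreme_3prime_bias":
            for f in three_prime:
                values[fid_index[f], col] += 4.0  # ratio 2^4 = 16 against intact 5'
        else:  # pragma: no cover - validated in SimulationDesign
            raise ValueError(f"unknown corruption type: {kind!r}")


def generate_cohort(
    design: SimulationDesign,
    definitions: Sequence[PathwayDefinition] | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort for a template design.

    Fully reproducible from ``design.seed``; identical design + seed gives
    a bit-identical cohort.
    """
    if definitions is None:
        definitions = default_definitions(design.template)
    definitions = list(definitions)
    if not definitions:
        raise ValueError("no pathway definitions supplied")

    plan = _sample_plan(design)
    rng = np.random.default_rng(design.seed)

    probe_rows = []
    for d in definitions:
        for t in d.targets:
            for p in t.probes:
                probe_rows.append((p, d.pathway_name, t.direction))
    probe_ids = [r[0] for r in probe_rows]
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("duplicate probe ids across pathway definitions")
    nuisance_ids = [f"NUIS_{i:04d}" for i in range(1, design.n_nuisance_genes + 1)]
    control_rows = _control_annotation_rows()
    control_ids = [r["feature_id"] for r in control_rows]
    features = probe_ids + nuisance_ids + control_ids

    ann_rows = (
        [dict(feature_id=p, gene_symbol=p.rsplit("_at", 1)[0], control_class="none",
              control_group_label="") for p in probe_ids]
        + [dict(feature_id=f, gene_symbol="", control_class="none", control_group_label="")
           for f in nuisance_ids]
        + control_rows
    )
    annotation = FeatureAnnotation(pd.DataFrame(ann_rows))

    n_bio = len(probe_ids) + len(nuisance_ids)
    n_samples = len(plan)
    mu = rng.uniform(5.0, 10.0, size=n_bio)
    subjects = plan["subject_id"].tolist()
    unique_subjects = list(dict.fromkeys(subjects))
    u = dict(zip(unique_subjects, rng.normal(0.0, design.tau, size=len(unique_subjects))))
    eps = rng.normal(0.0, design.sigma, size=(n_bio, n_samples))

    values = np.empty((len(features), n_samples))
    values[:n_bio, :] = mu[:, None] + eps
    for i, fid in enumerate(control_ids):
        values[n_bio + i, :] = CONTROL_INTENSITIES[control_rows[i]["control_class"]]

    groups = plan["group_label"].tolist()
    activity = np.zeros((len(definitions), n_samples))
    for pi, d in enumerate(definitions):
        for si, g in enumerate(groups):
            activity[pi, si] = design.activity_map.get((d.pathway_name, g), 0.0)
    pathway_index = {d.pathway_name: i for i, d in enumerate(definitions)}
    for fi, (probe, pathway, direction) in enumerate(probe_rows):
        a_row = activity[pathway_index[pathway]]
        values[fi, :] += direction * design.delta * a_row
    subj_eff = np.array([u[s] for s in subjects])
    values[:n_bio, :] += subj_eff[None, :]

    _apply_corruptions(values, features, annotation, design.corrupt_samples, rng)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=plan["sample_id"].tolist()), "log2"
    )
    metadata = SampleMetadata(plan)
    truth = pd.DataFrame(
        [
            dict(pathway=d.pathway_name, sample_id=s, activity=activity[pathway_index[d.pathway_name], si])
            for d in definitions
            for si, s in enumerate(plan["sample_id"])
        ]
    )
    return SyntheticCohort(
        matrix=matrix,
        metadata=metadata,
        annotation=annotation,
        truth=truth,
        definitions=definitions,
        design=design,
    )


def generate_calibration_set(
    definition: PathwayDefinition,
    n_active: int = 20,
    n_inactive: int = 20,
    delta: float = DEFAULT_DELTA,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    n_nuisance_genes: int = 0,
) -> SyntheticCohort:
    """Binary-labeled training cohort for one pathway (no subject effects).

    The generative model is the same as :func:`generate_cohort` with
    tau = 0; truth activity is exactly 0 or 1.
    """
    if n_active < 2 or n_inactive < 2:
        raise ValueError("need >=2 samples per label")
    design = SimulationDesign(
        template="calibration_set",
        group_sizes={"active": n_active, "inactive": n_inactive},
        delta=delta,
        sigma=sigma,
        tau=0.0,
        n_nuisance_genes=n_nuisance_genes,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    probe_rows = [(p, t.direction) for t in definition.targets for p in t.probes]
    probe_ids = [p for p, _ in probe_rows]
    nuisance_ids = [f"NUIS_{i:04d}" for i in range(1, n_nuisance_genes + 1)]
    features = probe_ids + nuisance_ids
    sample_ids = [f"A{i:03d}" for i in range(1, n_active + 1)] + [
        f"I{i:03d}" for i in range(1, n_inactive + 1)
    ]
    labels = np.array([1.0] * n_active + [0.0] * n_inactive)

    mu = rng.uniform(5.0, 10.0, size=len(features))
    eps = rng.normal(0.0, sigma, size=(len(features), len(sample_ids)))
    values = mu[:, None] + eps
    for fi, (_, direction) in enumerate(probe_rows):
        values[fi, :] += direction * delta * labels

    matrix = ExpressionMatrix(pd.DataFrame(values, index=features, columns=sample_ids), "log2")
    metadata = SampleMetadata(
        pd.DataFrame(
            dict(
                sample_id=sample_ids,
                group_label=["active"] * n_active + ["inactive"] * n_inactive,
            )
        )
    )
    annotation = FeatureAnnotation(
        pd.DataFrame(
            [dict(feature_id=f, gene_symbol="", control_class="none", control_group_label="")
             for f in features]
        )
    )
    truth = pd.DataFrame(
        dict(pathway=definition.pathway_name, sample_id=sample_ids, activity=labels)
    )
    return SyntheticCohort(
        matrix=matrix,
        metadata=metadata,
        annotation=annotation,
        truth=truth,
        definitions=[definition],
        design=design,
    )
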