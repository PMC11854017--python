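"""Bayesian target-gene model for pathway activity scoring.

Each signal transduction pathway (STP) ends in a transcription complex that
drives a characteristic program of target genes.  The model is a
three-layer Bayesian network per pathway:

* root — binary transcription-complex activity ``T`` (active / inactive)
  with prior ``P(active) = pi``;
* middle — one binary node per target gene ``g`` (transcriptionally up /
  down), with ``alpha_g = P(up | active)`` and ``beta_g = P(up | inactive)``.
  A down-regulated target (direction -1) has ``alpha_g < beta_g``;
* leaves — one binary node per probe ``j`` measuring gene ``g``: the
  observed log2 intensity is discretized against a calibrated threshold
  ``t_j``, with ``P(high | up) = p_hi_up_j`` and ``P(high | down) =
  p_hi_dn_j``.  A value exactly at the threshold counts as high.

Probes are conditionally independent given their gene's state and genes are
conditionally independent given ``T``, so inference factorizes:

    PAS = log2 P(active | evidence) - log2 P(inactive | evidence)
        = log2 pi - log2 (1 - pi) + sum_g [log2 L_g(active) - log2 L_g(inactive)]

with ``L_g(T) = sum_{G in {up, down}} P(G | T) * prod_j P(e_j | G)``.

The pathway activity score (PAS) is this log2 posterior odds.  Score
semantics matter: every pathway model has its own log2-odds range, so PAS
values are comparable between samples within one pathway, never across
pathways, and a negative PAS does not by itself mean the pathway is
inactive — without a reference range only differences between samples are
interpretable.  The library therefore exposes no cross-pathway
normalization.

Calibration (:func:`calibrate`) estimates the probe layer from labeled
reference samples: the threshold is the midpoint between label-conditional
means and exceedance probabilities are Laplace-smoothed counts.  The
gene-layer probabilities default to a strong but non-deterministic link
(0.95 / 0.05).  :func:`brute_force_pas` enumerates the full joint and
serves as an independent inference oracle for small models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

#: PAS is clamped to this magnitude to keep downstream statistics finite
#: even with degenerate conditional probability tables.
PAS_CLAMP = 64.0

#: defaults for the pathway -> gene-state layer (direction +1; mirrored for -1)
DEFAULT_ALPHA = 0.95
DEFAULT_BETA = 0.05
DEFAULT_PRIOR = 0.5
DEFAULT_PSEUDOCOUNT = 1.0

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TargetGene:
    """A transcription-factor target gene with regulation direction."""

    gene: str
    direction: int  # +1 up-regulated when pathway active, -1 down-regulated
    probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not self.probes:
            raise ValueError(f"target gene {self.gene!r} has no probe features")


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway's transcription factor and its directed target-gene list."""

    pathway_name: str
    transcription_factor_label: str
    targets: tuple[TargetGene, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"pathway {self.pathway_name!r} has no targets")
        genes = [t.gene for t in self.targets]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate target genes in {self.pathway_name!r}")

    @property
    def genes(self) -> list[str]:
        return [t.gene for t in self.targets]

    @property
    def all_probes(self) -> list[str]:
        return [p for t in self.targets for p in t.probes]


@dataclass
class ProbeCPT:
    """Discretization threshold and exceedance probabilities for one probe."""

    probe: str
    threshold: float
    p_hi_up: float
    p_hi_dn: float

    def __post_init__(self) -> None:
        for name in ("p_hi_up", "p_hi_dn"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must lie strictly in (0,1)")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class GeneCPT:
    """Gene-layer parameters: P(gene up | pathway active/inactive)."""

    gene: str
    direction: int
    alpha: float  # P(up | active)
    beta: float  # P(up | inactive)
    probes: list[ProbeCPT]

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must lie strictly in (0,1)")


@dataclass
class CalibratedPathwayModel:
    """A pathway definition plus all conditional probability tables."""

    definition: PathwayDefinition
    prior_active: float
    genes: list[GeneCPT]

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_active < 1.0:
            raise ValueError("prior_active must lie strictly in (0,1)")

    @property
    def pathway_name(self) -> str:
        return self.definition.pathway_name

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "pathway_name": self.definition.pathway_name,
            "transcription_factor_label": self.definition.transcription_factor_label,
            "prior_active": self.prior_active,
            "genes": [
                {
                    "gene": g.gene,
                    "direction": g.direction,
                    "alpha": g.alpha,
                    "beta": g.beta,
                    "probes": [
                        {
                            "probe": p.probe,
                            "threshold": p.threshold,
                            "p_hi_up": p.p_hi_up,
                            "p_hi_dn": p.p_hi_dn,
                        }
                        for p in g.probes
                    ],
                }
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedPathwayModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version: {d.get('schema_version')!r}"
            )
        genes = [
            GeneCPT(
                gene=g["gene"],
                direction=int(g["direction"]),
                alpha=float(g["alpha"]),
                beta=float(g["beta"]),
                probes=[
                    ProbeCPT(
                        probe=p["probe"],
                        threshold=float(p["threshold"]),
                        p_hi_up=float(p["p_hi_up"]),
                        p_hi_dn=float(p["p_hi_dn"]),
                    )
                    for p in g["probes"]
                ],
            )
            for g in d["genes"]
        ]
        definition = PathwayDefinition(
            pathway_name=d["pathway_name"],
            transcription_factor_label=d["transcription_factor_label"],
            targets=tuple(
                TargetGene(
                    gene=g.gene,
                    direction=g.direction,
                    probes=tuple(p.probe for p in g.probes),
                )
                for g in genes
            ),
        )
        return cls(definition=definition, prior_active=float(d["prior_active"]), genes=genes)

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "CalibratedPathwayModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PathwayActivityScore:
    """Per-sample log2-odds pathway activity score."""

    sample_id: str
    pathway_name: str
    pas: float
    n_genes_used: int
    n_genes_dropped: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.pas):
            raise ValueError("PAS must be finite")


# ---------------------------------------------------------------------------
# definition I/O
# ---------------------------------------------------------------------------

def read_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read pathway definitions from TSV.

    Columns: ``pathway``, ``gene``, ``direction`` (+1/-1), ``probe_id``
    (one row per probe); optional ``transcription_factor``.
    """
    table = pd.read_csv(path, sep="\t", dtype={"pathway": str, "gene": str, "probe_id": str})
    required = {"pathway", "gene", "direction", "probe_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"definition file missing columns: {sorted(missing)}")
    defs = []
    for pathway, sub in table.groupby("pathway", sort=False):
        tf = (
            str(sub["transcription_factor"].iloc[0])
            if "transcription_factor" in sub.columns
            else pathway
        )
        targets = []
        for gene, gsub in sub.groupby("gene", sort=False):
            directions = set(int(d) for d in gsub["direction"])
            if len(directions) != 1:
                raise ValueError(f"conflicting directions for gene {gene!r} in {pathway!r}")
            targets.append(
                TargetGene(gene=str(gene), direction=directions.pop(), probes=tuple(gsub["probe_id"]))
            )
        defs.append(
            PathwayDefinition(pathway_name=str(pathway), transcription_factor_label=tf, targets=tuple(targets))
        )
    return defs


def write_definitions(definitions: Sequence[PathwayDefinition], path: str | Path) -> Path:
    rows = []
    for d in definitions:
        for t in d.targets:
            for p in t.probes:
                rows.append(
                    {
                        "pathway": d.pathway_name,
                        "transcription_factor": d.transcription_factor_label,
                        "gene": t.gene,
                        "direction": t.direction,
                        "probe_id": p,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def bundled_definitions() -> list[PathwayDefinition]:
    """Placeholder target-gene lists for the five immune-relevant pathways.

    These are synthetic gene/probe identifiers sized like real models
    (20-30 targets each); they exercise the machinery but carry no
    biological content.  To score real data, supply curated target-gene
    lists from the pathway-model literature via :func:`read_definitions`.
    """
    path = Path(__file__).parent / "resources" / "placeholder_definitions.tsv"
    return read_definitions(path)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    definition: PathwayDefinition,
    training_matrix: ExpressionMatrix,
    labels: Mapping[str, bool],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_active: float = DEFAULT_PRIOR,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> CalibratedPathwayModel:
    """Fit probe thresholds and CPTs from labeled reference samples.

    Parameters
    ----------
    definition
        The pathway's target-gene list.
    training_matrix
        Log2 expression of the training samples; must contain every probe
        of the definition.
    labels
        sample_id -> True (pathway active) / False (inactive); at least two
        samples per label.
    pseudocount
        Laplace pseudocount kappa for the exceedance probabilities:
        ``p = (count + kappa) / (n + 2 kappa)``, which keeps every CPT entry
        strictly inside (0, 1).
    alpha, beta
        Gene-layer defaults for up-regulated targets, mirrored (1-alpha,
        1-beta swapped roles) for down-regulated targets.

    Notes
    -----
    The threshold ``t_j`` is the midpoint between the label-conditional
    means of probe j.  For an up-regulated gene the "up" state aligns with
    the active samples; for a down-regulated gene with the inactive
    samples, so the label roles swap when counting exceedances.  A probe
    that is constant across all training samples carries no information and
    is dropped with a warning.
    """
    active_ids = [s for s, lab in labels.items() if lab]
    inactive_ids = [s for s, lab in labels.items() if not lab]
    if len(active_ids) < 2 or len(inactive_ids) < 2:
        raise ValueError(
            f"need >=2 samples per label, got {len(active_ids)} active / "
            f"{len(inactive_ids)} inactive"
        )
    missing = [s for s in (*active_ids, *inactive_ids) if s not in set(training_matrix.samples)]
    if missing:
        raise ValueError(f"labeled samples absent from training matrix: {missing}")
    missing_probes = [p for p in definition.all_probes if p not in set(training_matrix.features)]
    if missing_probes:
        raise ValueError(f"probes absent from training matrix: {missing_probes}")

    data = training_matrix.data
    act = data[active_ids]
    inact = data[inactive_ids]
    kappa = float(pseudocount)
    n_act, n_inact = len(active_ids), len(inactive_ids)

    genes: list[GeneCPT] = []
    for target in definition.targets:
        if target.direction == 1:
            g_alpha, g_beta = alpha, beta
        else:
            g_alpha, g_beta = 1.0 - alpha, 1.0 - beta
        probes: list[ProbeCPT] = []
        for probe in target.probes:
            row = data.loc[probe, [*active_ids, *inactive_ids]]
            if float(row.max() - row.min()) == 0.0:
                warnings.warn(
                    f"probe {probe!r} constant across training samples; dropped"
                )
                continue
            mu_act = float(act.loc[probe].mean())
            mu_inact = float(inact.loc[probe].mean())
            t_j = 0.5 * (mu_act + mu_inact)
            hi_act = int((act.loc[probe] >= t_j).sum())
            hi_inact = int((inact.loc[probe] >= t_j).sum())
            if target.direction == 1:
                # gene "up" state aligns with pathway-active samples
                p_hi_up = (hi_act + kappa) / (n_act + 2 * kappa)
                p_hi_dn = (hi_inact + kappa) / (n_inact + 2 * kappa)
            else:
                p_hi_up = (hi_inact + kappa) / (n_inact + 2 * kappa)
                p_hi_dn = (hi_act + kappa) / (n_act + 2 * kappa)
            probes.append(ProbeCPT(probe=probe, threshold=t_j, p_hi_up=p_hi_up, p_hi_dn=p_hi_dn))
        if probes:
            genes.append(
                GeneCPT(gene=target.gene, direction=target.direction, alpha=g_alpha, beta=g_beta, probes=probes)
            )
    if not genes:
        raise ValueError(f"no informative probes for pathway {definition.pathway_name!r}")
    return CalibratedPathwayModel(definition=definition, prior_active=float(prior_active), genes=genes)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _probe_loglik(evidence: list[tuple[ProbeCPT, bool]], up: bool) -> float:
    ll = 0.0
    for probe, high in evidence:
        p = probe.p_hi_up if up else probe.p_hi_dn
        ll += np.log(p if high else 1.0 - p)
    return ll


def infer_pas(model: CalibratedPathwayModel, sample_vector, sample_id: str = "") -> PathwayActivityScore:
    """Compute the log2-odds pathway activity score for one sample.

    ``sample_vector`` maps probe feature ids to log2 values (a pandas
    Series or dict).  Missing probes are marginalized out, which for this
    network equals dropping them; a gene with no observed probe is dropped
    and counted in ``n_genes_dropped``.  The result is clamped to +/-64.
    """
    getter = sample_vector.get if hasattr(sample_vector, "get") else None
    if getter is None:
        raise TypeError("sample_vector must be a mapping of probe id -> value")

    log_odds = np.log2(model.prior_active) - np.log2(1.0 - model.prior_active)
    n_used = 0
    n_dropped = 0
    for gene in model.genes:
        evidence = []
        for probe in gene.probes:
            value = getter(probe.probe)
            if value is None or not np.isfinite(value):
                continue
            evidence.append((probe, bool(value >= probe.threshold)))
        if not evidence:
            n_dropped += 1
            continue
        n_used += 1
        ll_up = _probe_loglik(evidence, up=True)
        ll_dn = _probe_loglik(evidence, up=False)
        # log-sum-exp over the two hidden gene states, per pathway state
        ref = max(ll_up, ll_dn)
        lik_up = np.exp(ll_up - ref)
        lik_dn = np.exp(ll_dn - ref)
        l_active = gene.alpha * lik_up + (1.0 - gene.alpha) * lik_dn
        l_inactive = gene.beta * lik_up + (1.0 - gene.beta) * lik_dn
        log_odds += np.log2(l_active) - np.log2(l_inactive)
    if n_used == 0:
        raise ValueError(
            f"sample {sample_id!r}: no target gene of pathway "
            f"{model.pathway_name!r} has an observed probe"
        )
    pas = float(np.clip(log_odds, -PAS_CLAMP, PAS_CLAMP))
    return PathwayActivityScore(
        sample_id=sample_id,
        pathway_name=model.pathway_name,
        pas=pas,
        n_genes_used=n_used,
        n_genes_dropped=n_dropped,
    )


def brute_force_pas(model: CalibratedPathwayModel, sample_vector, sample_id: str = "") -> PathwayActivityScore:
    """Inference oracle: full joint enumeration over all hidden states.

    Enumerates pathway state x every combination of gene states and sums
    the joint probability of the observed evidence.  Limited to 12 genes;
    identical contract to :func:`infer_pas`.
    """
    getter = sample_vector.get if hasattr(sample_vector, "get") else None
    if getter is None:
        raise TypeError("sample_vector must be a mapping of probe id -> value")

    observed: list[tuple[GeneCPT, list[tuple[ProbeCPT, bool]]]] = []
    n_dropped = 0
    for gene in model.genes:
        evidence = []
        for probe in gene.probes:
            value = getter(probe.probe)
            if value is None or not np.isfinite(value):
                continue
            evidence.append((probe, bool(value >= probe.threshold)))
        if evidence:
            observed.append((gene, evidence))
        else:
            n_dropped += 1
    if not observed:
        raise ValueError(
            f"sample {sample_id!r}: no target gene of pathway "
            f"{model.pathway_name!r} has an observed probe"
        )
    n_genes = len(observed)
    if n_genes > 12:
        raise ValueError(f"brute force limited to 12 genes, got {n_genes}")

    joint = {True: 0.0, False: 0.0}
    for active in (True, False):
        p_t = model.prior_active if active else 1.0 - model.prior_active
        total = 0.0
        for states in range(2**n_genes):
            p = 1.0
            for i, (gene, evidence) in enumerate(observed):
                up = bool((states >> i) & 1)
                p_state_given_t = (gene.alpha if active else gene.beta)
                p_g = p_state_given_t if up else 1.0 - p_state_given_t
                p *= p_g * float(np.exp(_probe_loglik(evidence, up=up)))
            total += p
        joint[active] = p_t * total
    pas = float(np.clip(np.log2(joint[True]) - np.log2(joint[False]), -PAS_CLAMP, PAS_CLAMP))
    return PathwayActivityScore(
        sample_id=sample_id,
        pathway_name=model.pathway_name,
        pas=pas,
        n_genes_used=n_genes,
        n_genes_dropped=n_dropped,
    )


def pas_table(
    models: Sequence[CalibratedPathwayModel],
    matrix: ExpressionMatrix,
    skip_failures: bool = False,
) -> pd.DataFrame:
    """Score every sample with every model; long-format result table.

    Columns: sample_id, pathway, pas, n_genes_used, n_genes_dropped.
    With ``skip_failures`` a failing (pathway, sample) cell is dropped with
    a warning instead of aborting the whole table.
    """
    if not models:
        raise ValueError("no models supplied")
    rows = []
    for model in models:
        for sample_id in matrix.samples:
            vec = matrix.data[sample_id]
            try:
                score = infer_pas(model, vec, sample_id=sample_id)
            except ValueError as exc:
                if skip_failures:
                    warnings.warn(
                        f"skipping pathway {model.pathway_name!r} / sample "
                        f"{sample_id!r}: {exc}"
                    )
                    continue
                raise ValueError(
                    f"scoring failed for pathway {model.pathway_name!r}, "
                    f"sample {sample_id!r}: {exc}"
                ) from exc
            rows.append(
                {
                    "sample_id": score.sample_id,
                    "pathway": score.pathway_name,
                    "pas": score.pas,
                    "n_genes_used": score.n_genes_used,
                    "n_genes_dropped": score.n_genes_dropped,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "pathway", "pas", "n_genes_used", "n_genes_dropped"])
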