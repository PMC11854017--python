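import numpy as np
import pandas as pd
import pytest

from stpscore.model import (
    CalibratedPathwayModel,
    GeneCPT,
    PathwayDefinition,
    ProbeCPT,
    TargetGene,
)


@pytest.fixture
def single_gene_model() -> CalibratedPathwayModel:
    """One up-regulated gene, one near-perfect probe (epsilon-guarded)."""
    eps = 1e-9
    definition = PathwayDefinition(
        pathway_name="demo",
        transcription_factor_label="TF",
        targets=(TargetGene(gene="g1", direction=1, probes=("p1",)),),
    )
    return CalibratedPathwayModel(
        definition=definition,
        prior_active=0.5,
        genes=[
            GeneCPT(
                gene="g1",
                direction=1,
                alpha=0.95,
                beta=0.05,
                probes=[ProbeCPT(probe="p1", threshold=5.0, p_hi_up=1 - eps, p_hi_dn=eps)],
            )
        ],
    )


@pytest.fixture
def two_probe_model() -> CalibratedPathwayModel:
    """One gene, two moderately informative probes."""
    definition = PathwayDefinition(
        pathway_name="demo",
        transcription_factor_label="TF",
        targets=(TargetGene(gene="g1", direction=1, probes=("p1", "p2")),),
    )
    return CalibratedPathwayModel(
        definition=definition,
        prior_active=0.5,
        genes=[
            GeneCPT(
                gene="g1",
                direction=1,
                alpha=0.95,
                beta=0.05,
                probes=[
                    ProbeCPT(probe="p1", threshold=5.0, p_hi_up=0.9, p_hi_dn=0.2),
                    ProbeCPT(probe="p2", threshold=5.0, p_hi_up=0.9, p_hi_dn=0.2),
                ],
            )
        ],
    )


def random_small_model(rng: np.random.Generator, max_genes: int = 4, max_probes: int = 3):
    """A random model with <= max_genes genes and a random evidence vector."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    targets = []
    evidence = {}
    for gi in range(n_genes):
        n_probes = int(rng.integers(1, max_probes + 1))
        direction = 1 if rng.random() < 0.5 else -1
        probe_names = tuple(f"g{gi}p{j}" for j in range(n_probes))
        targets.append(TargetGene(gene=f"g{gi}", direction=direction, probes=probe_names))
        probes = []
        for name in probe_names:
            probes.append(
                ProbeCPT(
                    probe=name,
                    threshold=float(rng.uniform(4, 10)),
                    p_hi_up=float(rng.uniform(0.01, 0.99)),
                    p_hi_dn=float(rng.uniform(0.01, 0.99)),
                )
            )
            evidence[name] = float(rng.uniform(2, 12))
        genes.append(
            GeneCPT(
                gene=f"g{gi}",
                direction=direction,
                alpha=float(rng.uniform(0.01, 0.99)),
                beta=float(rng.uniform(0.01, 0.99)),
                probes=probes,
            )
        )
    definition = PathwayDefinition(
        pathway_name="rand", transcription_factor_label="TF", targets=tuple(targets)
    )
    model = CalibratedPathwayModel(definition=definition, prior_active=float(rng.uniform(0.1, 0.9)), genes=genes)
    return model, evidence


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
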