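import numpy as np
import pandas as pd
import pytest

from stpscore.io import ExpressionMatrix
from stpscore.model import (
    CalibratedPathwayModel,
    GeneCPT,
    PathwayDefinition,
    ProbeCPT,
    TargetGene,
    brute_force_pas,
    bundled_definitions,
    calibrate,
    infer_pas,
    pas_table,
    read_definitions,
    write_definitions,
)
from stpscore.simulate import generate_calibration_set

from conftest import random_small_model


class TestWorkedExamples:
    def test_single_perfect_probe_gives_log2_19(self, single_gene_model):
        """One d=+1 gene (alpha=.95), perfectly informative probe, probe high."""
        score = infer_pas(single_gene_model, {"p1": 6.0}, sample_id="s")
        assert score.pas == pytest.approx(np.log2(19), abs=1e-7)

    def test_two_probe_enumeration_value(self, two_probe_model):
        # L(active) = .95*.81 + .05*.04 = .7715 ; L(inactive) = .05*.81 + .95*.04 = .0785
        score = infer_pas(two_probe_model, {"p1": 6.0, "p2": 6.0}, sample_id="s")
        assert score.pas == pytest.approx(np.log2(0.7715 / 0.0785), abs=1e-9)
        oracle = brute_force_pas(two_probe_model, {"p1": 6.0, "p2": 6.0}, sample_id="s")
        assert oracle.pas == pytest.approx(score.pas, abs=1e-9)

    def test_symmetric_model_scores_zero(self):
        definition = PathwayDefinition(
            "sym", "TF", (TargetGene("g", 1, ("p",)),)
        )
        model = CalibratedPathwayModel(
            definition,
            0.5,
            [GeneCPT("g", 1, 0.5, 0.5, [ProbeCPT("p", 5.0, 0.8, 0.3)])],
        )
        assert infer_pas(model, {"p": 9.0}).pas == 0.0
        assert brute_force_pas(model, {"p": 9.0}).pas == 0.0


class TestOracleEquivalence:
    def test_factorized_matches_joint_enumeration(self, rng):
        """Tree-shaped network: factorized inference is exact for any CPTs."""
        worst = 0.0
        for _ in range(300):
            model, evidence = random_small_model(rng)
            a = infer_pas(model, evidence).pas
            b = brute_force_pas(model, evidence).pas
            worst = max(worst, abs(a - b))
        assert worst < 1e-9

    def test_brute_force_rejects_large_models(self, rng):
        targets = tuple(TargetGene(f"g{i}", 1, (f"p{i}",)) for i in range(13))
        definition = PathwayDefinition("big", "TF", targets)
        model = CalibratedPathwayModel(
            definition,
            0.5,
            [GeneCPT(f"g{i}", 1, 0.9, 0.1, [ProbeCPT(f"p{i}", 5.0, 0.9, 0.1)]) for i in range(13)],
        )
        evidence = {f"p{i}": 6.0 for i in range(13)}
        with pytest.raises(ValueError, match="12 genes"):
            brute_force_pas(model, evidence)


class TestMonotonicityAndSemantics:
    def test_flipping_up_probe_high_never_decreases_pas(self, rng):
        for _ in range(100):
            model, evidence = random_small_model(rng)
            base = infer_pas(model, evidence).pas
            for gene in model.genes:
                # the invariant holds for direction-consistent CPTs, which
                # calibration guarantees for separable training data
                if gene.direction != 1 or gene.alpha <= gene.beta:
                    continue
                for probe in gene.probes:
                    if evidence[probe.probe] >= probe.threshold:
                        continue
                    if probe.p_hi_up <= probe.p_hi_dn:
                        continue  # informative direction must match the flip
                    flipped = dict(evidence)
                    flipped[probe.probe] = probe.threshold + 1.0
                    assert infer_pas(model, flipped).pas >= base - 1e-12

    def test_uniform_prior_no_evidence_gives_zero(self):
        """With pi=.5 and alpha=beta everywhere the score is exactly 0."""
        definition = PathwayDefinition(
            "null", "TF", tuple(TargetGene(f"g{i}", 1, (f"p{i}",)) for i in range(3))
        )
        model = CalibratedPathwayModel(
            definition,
            0.5,
            [GeneCPT(f"g{i}", 1, 0.6, 0.6, [ProbeCPT(f"p{i}", 5.0, 0.9, 0.2)]) for i in range(3)],
        )
        evidence = {f"p{i}": float(v) for i, v in enumerate([9.0, 1.0, 5.0])}
        assert infer_pas(model, evidence).pas == 0.0

    def test_threshold_tie_counts_as_high(self):
        definition = PathwayDefinition("t", "TF", (TargetGene("g", 1, ("p",)),))
        model = CalibratedPathwayModel(
            definition, 0.5, [GeneCPT("g", 1, 0.95, 0.05, [ProbeCPT("p", 5.0, 0.9, 0.1)])]
        )
        at = infer_pas(model, {"p": 5.0}).pas
        above = infer_pas(model, {"p": 5.1}).pas
        assert at == above
        assert at > 0

    def test_pas_clamped_for_degenerate_cpts(self):
        eps = 1e-12
        definition = PathwayDefinition(
            "c", "TF", tuple(TargetGene(f"g{i}", 1, (f"p{i}",)) for i in range(10))
        )
        model = CalibratedPathwayModel(
            definition,
            0.5,
            [
                GeneCPT(f"g{i}", 1, 1 - eps, eps,
                        [ProbeCPT(f"p{i}", 5.0, 1 - eps, eps)])
                for i in range(10)
            ],
        )
        score = infer_pas(model, {f"p{i}": 6.0 for i in range(10)})
        assert score.pas == 64.0


class TestMissingData:
    def make_model(self):
        definition = PathwayDefinition(
            "m", "TF",
            (TargetGene("g1", 1, ("a1", "a2")), TargetGene("g2", 1, ("b1",))),
        )
        return CalibratedPathwayModel(
            definition,
            0.5,
            [
                GeneCPT("g1", 1, 0.95, 0.05,
                        [ProbeCPT("a1", 5.0, 0.9, 0.2), ProbeCPT("a2", 5.0, 0.9, 0.2)]),
                GeneCPT("g2", 1, 0.95, 0.05, [ProbeCPT("b1", 5.0, 0.9, 0.2)]),
            ],
        )

    def test_gene_with_no_probes_dropped_and_counted(self):
        model = self.make_model()
        score = infer_pas(model, {"a1": 6.0, "a2": 6.0})
        assert score.n_genes_used == 1
        assert score.n_genes_dropped == 1

    def test_missing_probe_equals_marginalization(self):
        """Dropping an unobserved probe equals scoring without that probe."""
        model = self.make_model()
        with_missing = infer_pas(model, {"a1": 6.0, "b1": 6.0, "a2": np.nan})
        reduced = self.make_model()
        reduced.genes[0].probes = reduced.genes[0].probes[:1]
        explicit = infer_pas(reduced, {"a1": 6.0, "b1": 6.0})
        assert with_missing.pas == pytest.approx(explicit.pas, abs=1e-12)

    def test_zero_usable_genes_names_sample(self):
        model = self.make_model()
        with pytest.raises(ValueError, match="S77"):
            infer_pas(model, {}, sample_id="S77")


class TestCalibration:
    def test_laplace_counting_example(self):
        """Probe high in 9/10 active, 2/10 inactive; kappa=1 -> 10/12 and 3/12."""
        n = 10
        samples = [f"A{i}" for i in range(n)] + [f"I{i}" for i in range(n)]
        active_vals = [8.0] * 9 + [2.0]
        inactive_vals = [8.0] * 2 + [2.0] * 8
        data = pd.DataFrame([active_vals + inactive_vals], index=["p1"], columns=samples)
        matrix = ExpressionMatrix(data)
        definition = PathwayDefinition("cal", "TF", (TargetGene("g", 1, ("p1",)),))
        labels = {s: s.startswith("A") for s in samples}
        model = calibrate(definition, matrix, labels, pseudocount=1.0)
        probe = model.genes[0].probes[0]
        # label-conditional means: active 7.4, inactive 3.2 -> threshold 5.3
        assert probe.threshold == pytest.approx(5.3)
        assert probe.p_hi_up == pytest.approx(10 / 12)
        assert probe.p_hi_dn == pytest.approx(3 / 12)

    def test_identical_groups_give_uninformative_probe(self):
        samples = [f"A{i}" for i in range(3)] + [f"I{i}" for i in range(3)]
        data = pd.DataFrame([[4.0, 8.0, 6.0, 4.0, 8.0, 6.0]], index=["p1"], columns=samples)
        definition = PathwayDefinition("cal", "TF", (TargetGene("g", 1, ("p1",)),))
        labels = {s: s.startswith("A") for s in samples}
        model = calibrate(definition, ExpressionMatrix(data), labels)
        probe = model.genes[0].probes[0]
        assert probe.p_hi_up == pytest.approx(probe.p_hi_dn)

    def test_single_active_sample_rejected(self):
        samples = ["A0", "I0", "I1"]
        data = pd.DataFrame([[8.0, 2.0, 3.0]], index=["p1"], columns=samples)
        definition = PathwayDefinition("cal", "TF", (TargetGene("g", 1, ("p1",)),))
        with pytest.raises(ValueError, match=">=2 samples per label"):
            calibrate(definition, ExpressionMatrix(data), {"A0": True, "I0": False, "I1": False})

    def test_constant_probe_dropped_with_warning(self):
        samples = ["A0", "A1", "I0", "I1"]
        data = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0], [8.0, 8.0, 2.0, 2.0]],
            index=["flat", "ok"], columns=samples,
        )
        definition = PathwayDefinition("cal", "TF", (TargetGene("g", 1, ("flat", "ok")),))
        labels = {s: s.startswith("A") for s in samples}
        with pytest.warns(UserWarning, match="flat"):
            model = calibrate(definition, ExpressionMatrix(data), labels)
        assert [p.probe for p in model.genes[0].probes] == ["ok"]

    def test_down_regulated_gene_gets_mirrored_gene_layer(self):
        samples = ["A0", "A1", "I0", "I1"]
        data = pd.DataFrame([[2.0, 3.0, 8.0, 9.0]], index=["p1"], columns=samples)
        definition = PathwayDefinition("cal", "TF", (TargetGene("g", -1, ("p1",)),))
        labels = {s: s.startswith("A") for s in samples}
        model = calibrate(definition, ExpressionMatrix(data), labels)
        gene = model.genes[0]
        assert gene.alpha < gene.beta  # "up" state is rare when pathway active
        probe = gene.probes[0]
        assert probe.p_hi_up > probe.p_hi_dn  # gene-up aligns with inactive/high

    def test_recovery_of_empirical_exceedance_and_separation(self):
        """Calibration on synthetic data recovers count-based exceedance
        probabilities within the Laplace-smoothing band and ranks held-out
        active above inactive samples (AUC >= 0.95)."""
        definition = bundled_definitions()[2]
        cal = generate_calibration_set(definition, 20, 20, delta=1.5, sigma=0.5, seed=11)
        labels = {r.sample_id: r.activity > 0.5 for r in cal.truth.itertuples()}
        model = calibrate(definition, cal.matrix, labels)
        active = [s for s, lab in labels.items() if lab]
        inactive = [s for s, lab in labels.items() if not lab]
        gene_dir = {g.gene: g.direction for g in model.genes}
        for gene in model.genes:
            for probe in gene.probes:
                row = cal.matrix.data.loc[probe.probe]
                frac_act = float((row[active] >= probe.threshold).mean())
                frac_inact = float((row[inactive] >= probe.threshold).mean())
                if gene.direction == 1:
                    emp_up, emp_dn = frac_act, frac_inact
                else:
                    emp_up, emp_dn = frac_inact, frac_act
                assert abs(probe.p_hi_up - emp_up) <= 0.05
                assert abs(probe.p_hi_dn - emp_dn) <= 0.05
        test = generate_calibration_set(definition, 25, 25, delta=1.5, sigma=0.5, seed=99)
        scores = pas_table([model], test.matrix)
        truth = test.truth.set_index("sample_id")["activity"]
        y = truth[scores["sample_id"]].to_numpy() > 0.5
        pas = scores["pas"].to_numpy()
        # ranking AUC by direct pair counting
        pos, neg = pas[y], pas[~y]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        auc = wins / (len(pos) * len(neg))
        assert auc >= 0.95


class TestTablesAndSerialization:
    def test_pas_table_cardinality_and_determinism(self):
        definitions = bundled_definitions()[:2]
        models = []
        matrices = []
        for i, d in enumerate(definitions):
            cal = generate_calibration_set(d, 5, 5, seed=i)
            labels = {r.sample_id: r.activity > 0.5 for r in cal.truth.itertuples()}
            models.append(calibrate(d, cal.matrix, labels))
            matrices.append(cal.matrix.data)
        merged = ExpressionMatrix(pd.concat(matrices))
        t1 = pas_table(models, merged)
        t2 = pas_table(models, merged)
        assert len(t1) == len(models) * len(merged.samples)
        pd.testing.assert_frame_equal(t1, t2)

    def test_skip_failures_keeps_other_rows(self, two_probe_model):
        data = pd.DataFrame(
            {"ok": [6.0, 6.0], "broken": [np.nan, np.nan]}, index=["p1", "p2"]
        )
        matrix = ExpressionMatrix(data)
        with pytest.raises(ValueError, match="broken"):
            pas_table([two_probe_model], matrix)
        with pytest.warns(UserWarning, match="broken"):
            table = pas_table([two_probe_model], matrix, skip_failures=True)
        assert list(table["sample_id"]) == ["ok"]

    def test_model_json_round_trip(self, tmp_path, two_probe_model):
        path = tmp_path / "model.json"
        two_probe_model.save(path)
        loaded = CalibratedPathwayModel.load(path)
        assert loaded.to_dict() == two_probe_model.to_dict()
        before = infer_pas(two_probe_model, {"p1": 6.0, "p2": 2.0}).pas
        after = infer_pas(loaded, {"p1": 6.0, "p2": 2.0}).pas
        assert after == before

    def test_definition_tsv_round_trip(self, tmp_path):
        defs = bundled_definitions()
        path = tmp_path / "defs.tsv"
        write_definitions(defs, path)
        back = read_definitions(path)
        assert [d.pathway_name for d in back] == [d.pathway_name for d in defs]
        assert back[0].targets == defs[0].targets

    def test_bundled_definitions_are_well_formed(self):
        defs = bundled_definitions()
        assert {d.pathway_name for d in defs} == {"AR", "TGFB", "NFKB", "JAK-STAT1/2", "JAK-STAT3"}
        for d in defs:
            assert 20 <= len(d.targets) <= 30
            assert all(t.direction in (1, -1) for t in d.targets)
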