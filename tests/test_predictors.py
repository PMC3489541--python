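"""Training-data preparation, RT/PT models, fragment rules, overrides."""

import warnings

import numpy as np
import pytest

import srmdesign as sd
from srmdesign.digest import Peptide, ValidationError
from srmdesign.predictors import RESIDUES, _rt_design_matrix


def rec(seq, charge=2, rt=10.0, q=0.005, tic=100.0):
    return sd.IdentifiedPeptideRecord(seq, charge, rt, q, tic)


class TestPreparation:
    def test_dedupe_keeps_max_tic(self):
        records = [rec("PEPK", tic=10.0), rec("PEPK", tic=20.0)]
        kept = sd.dedupe_by_tic(records)
        assert len(kept) == 1 and kept[0].tic == 20.0

    def test_dedupe_key_includes_charge_and_is_order_invariant(self):
        records = [rec("PEPK", charge=2), rec("PEPK", charge=3),
                   rec("AAAK", tic=5.0), rec("AAAK", tic=5.0, rt=11.0)]
        kept = sd.dedupe_by_tic(records)
        assert len(kept) == 3
        # TIC tie broken by first occurrence
        assert next(k for k in kept if k.sequence == "AAAK").retention_time == 10.0
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = [records[i] for i in rng.permutation(len(records))]
            assert {(k.sequence, k.charge, k.tic) for k in sd.dedupe_by_tic(shuffled)} \
                == {(k.sequence, k.charge, k.tic) for k in kept}

    def test_positive_selection_filters_ranks_truncates(self):
        qs = [0.001, 0.02, 0.005, 0.5, 0.009]
        records = [rec(f"PEP{aa}K", q=q) for aa, q in zip("ACDEF", qs)]
        got = sd.select_training_positives(records, 0.01, 1000)
        assert [r.q_value for r in got] == [0.001, 0.005, 0.009]
        assert [r.q_value for r in sd.select_training_positives(records, 0.01, 2)] \
            == [0.001, 0.005]
        assert sd.select_training_positives(records, 0.0001, 1000) == []

    def test_negatives_require_coverage_and_exclude_identified(self):
        # 20-residue protein, identified peptide covers 8 residues = 40%
        prot = sd.ProteinRecord("A", "WWWFFFWKLLLLVVVVFFFK")
        identified = [rec("WWWFFFWK")]
        negs = sd.select_training_negatives(
            identified, [prot], coverage_min=0.15, mz_range=(400.0, 1500.0)
        )
        seqs = {n.sequence for n in negs}
        assert "LLLLVVVVFFFK" in seqs
        assert "WWWFFFWK" not in seqs  # identified peptides are never negatives

    def test_low_coverage_protein_contributes_nothing(self):
        prot = sd.ProteinRecord("A", "WWWFFFWK" + "L" * 72)  # coverage 10%
        with pytest.raises(ValidationError, match="0.100"):
            sd.select_training_negatives([rec("WWWFFFWK")], [prot],
                                         coverage_min=0.15)


class TestRTModel:
    def test_noiseless_data_is_interpolated(self):
        rng = np.random.default_rng(3)
        coefs = {aa: rng.normal(0, 1) for aa in RESIDUES}
        seqs = ["".join(rng.choice(RESIDUES, size=rng.integers(6, 20)))
                for _ in range(120)]
        examples = [
            (s, 7.0 + sum(coefs[aa] * s.count(aa) for aa in RESIDUES))
            for s in seqs
        ]
        model = sd.train_rt(examples, ridge_lambda=0.0)
        for s, rt in examples:
            assert sd.predict_rt(model, s) == pytest.approx(rt, abs=1e-6)

    def test_minimum_example_count(self):
        examples = [("AAAAAK", 10.0)] * 39
        with pytest.raises(ValidationError, match="40"):
            sd.train_rt(examples)

    def test_prediction_depends_only_on_composition(self):
        model = sd.train_rt([("ACDEFGHIKL", float(i)) for i in range(40)])
        assert model.predict("ACDEFGHIKL") == pytest.approx(
            model.predict("LKIHGFEDCA"), abs=1e-9
        )

    def test_zero_coefficient_model_predicts_intercept(self):
        model = sd.RTModel(
            intercept=17.5,
            residue_coefficients={aa: 0.0 for aa in RESIDUES},
            length_coefficient=0.0,
            training_rmse=0.0,
        )
        assert model.predict("AW") == 17.5 and model.predict("KKKKKK") == 17.5

    def test_coefficient_convergence_with_n(self):
        # fitted effective per-residue coefficients approach truth as n grows
        rng = np.random.default_rng(5)
        coefs = {aa: rng.normal(0, 1.5) for aa in RESIDUES}
        def fit_err(n):
            seqs = ["".join(rng.choice(RESIDUES, size=rng.integers(6, 25)))
                    for _ in range(n)]
            examples = [
                (s, 5.0 + sum(coefs[aa] * s.count(aa) for aa in RESIDUES)
                 + rng.normal(0, 0.5))
                for s in seqs
            ]
            m = sd.train_rt(examples)
            eff = {aa: m.residue_coefficients[aa] + m.length_coefficient
                   for aa in RESIDUES}
            return np.sqrt(np.mean([(eff[aa] - coefs[aa]) ** 2 for aa in RESIDUES]))
        assert fit_err(1000) < fit_err(100) < 0.5


class TestPTModel:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(4)
        hydro = "AILMFVW"
        charged = "DEKRH"
        pos = [Peptide(sequence="".join(rng.choice(list(hydro), size=10)))
               for _ in range(60)]
        neg = [Peptide(sequence="".join(rng.choice(list(charged), size=10)))
               for _ in range(60)]
        with pytest.warns(UserWarning, match="recommended"):
            model = sd.train_pt(pos, neg)
        preds = [sd.predict_pt(model, p.sequence) >= 0.5 for p in pos] + \
                [sd.predict_pt(model, p.sequence) < 0.5 for p in neg]
        assert np.mean(preds) >= 0.95
        assert all(0.0 <= sd.predict_pt(model, p.sequence) <= 1.0
                   for p in pos + neg)

    def test_uninformative_data_predicts_half(self):
        peps = [Peptide(sequence=s) for s in ("AAAK", "CCCK", "DDDK", "EEEK")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sd.train_pt(peps, list(peps))
        for p in peps:
            assert sd.predict_pt(model, p.sequence) == pytest.approx(0.5, abs=0.01)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            sd.train_pt([], [Peptide(sequence="AAAK")])

    def test_training_order_invariance(self):
        rng = np.random.default_rng(9)
        peps = [Peptide(sequence="".join(rng.choice(RESIDUES, size=10)))
                for _ in range(40)]
        pos, neg = peps[:20], peps[20:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = sd.train_pt(pos, neg)
            m2 = sd.train_pt(pos[::-1], neg[::-1])
        for p in peps:
            assert m1.predict(p.sequence) == pytest.approx(
                m2.predict(p.sequence), abs=1e-8
            )


class TestFragments:
    def test_gg_y1_mz(self):
        ions = sd.predict_fragments("GG", 1)
        y1 = next(i for i in ions if i.series == "y" and i.position == 1)
        assert y1.mz == pytest.approx(76.03930, abs=1e-4)

    def test_y_dominates_b_at_same_position(self):
        ions = sd.predict_fragments("LGEYGFQNALIVR", 2)
        by_key = {(i.series, i.position): i.relative_intensity for i in ions}
        for pos in range(2, 13):  # b1 suppressed entirely
            assert by_key[("y", pos)] >= by_key[("b", pos)]

    def test_b1_suppressed(self):
        ions = sd.predict_fragments("LGEYGFQNALIVR", 2)
        assert ("b", 1) not in {(i.series, i.position) for i in ions}

    def test_proline_enhancement(self):
        plain = {(i.series, i.position): i.relative_intensity
                 for i in sd.predict_fragments("AAAAAAAR", 2)}
        prol = {(i.series, i.position): i.relative_intensity
                for i in sd.predict_fragments("AAAPAAAR", 2)}
        # cleavage N-terminal to the proline at position 4 boosts y5/b3
        assert prol[("y", 5)] > plain[("y", 5)]

    def test_exactly_one_base_peak_and_range(self):
        for seq in ("GG", "AAAAAAAR", "PEPTIDEK", "LGEYGFQNALIVR", "KKKKHHHK"):
            ions = sd.predict_fragments(seq, 2)
            assert all(0.0 < i.relative_intensity <= 1.0 for i in ions)
            assert sum(1 for i in ions if i.relative_intensity == 1.0) == 1

    def test_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            sd.predict_fragments("G", 2)


class TestOverrides:
    def test_rt_override_beats_model(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text("sequence\trt\nPEPTIDEK\t23.4\n")
        ov = sd.import_predictions(path)
        ps = sd.PredictorSet(
            rt_model=sd.RTModel(0.0, {aa: 0.0 for aa in RESIDUES}, 1.0, 0.0),
            overrides=ov,
        )
        assert ps.rt("PEPTIDEK") == 23.4
        assert ps.rt("AAAAK") == 5.0  # falls back to the model

    def test_empty_table_no_overrides(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text("sequence\trt\n")
        ov = sd.import_predictions(path)
        assert not ov.rt and not ov.pt and not ov.fragments

    def test_bad_pt_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text("sequence\tpt\nAAAK\t0.5\nCCCK\t1.5\n")
        with pytest.raises(ValidationError, match="line 3"):
            sd.import_predictions(path)

    def test_fragment_overrides_normalised(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text(
            "sequence\tseries\tposition\tintensity\n"
            "PEPTIDEK\ty\t3\t50\nPEPTIDEK\ty\t5\t100\n"
        )
        ov = sd.import_predictions(path)
        ions = ov.fragments["PEPTIDEK"]
        assert [i.relative_intensity for i in ions] == [1.0, 0.5]
        assert ions[0].position == 5


def test_rt_design_matrix_shape():
    X = _rt_design_matrix(["AAK", "CCK"])
    assert X.shape == (2, 21)
    assert X[0, RESIDUES.index("A")] == 2 and X[0, -1] == 3
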