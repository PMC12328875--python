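"""Binding predictor contract, neoantigen rule and DAI."""

import numpy as np
import pandas as pd
import pytest

from neoquant.binding import (
    BindingPrediction,
    MockBindingPredictor,
    PredictorContractError,
    TableBindingPredictor,
    build_neoantigen_records,
    classify_neoantigens,
    compute_dai,
)
from neoquant.io import SomaticVariant, parse_hla_allele
from neoquant.peptides import enumerate_peptide_pairs

from conftest import random_peptide

A0201 = parse_hla_allele("HLA-A*02:01")
B0702 = parse_hla_allele("HLA-B*07:02")


def pred(pep, ic50, el, allele=A0201):
    return BindingPrediction(pep, allele, ic50, el)


class TestMockPredictor:
    def test_deterministic_within_and_across_instances(self):
        rng = np.random.default_rng(0)
        a = MockBindingPredictor(seed=42)
        b = MockBindingPredictor(seed=42)
        for _ in range(20):
            p = random_peptide(rng, int(rng.integers(8, 15)))
            assert a.predict(p, A0201) == a.predict(p, A0201)
            assert a.predict(p, A0201) == b.predict(p, A0201)

    def test_different_seed_changes_landscape(self):
        rng = np.random.default_rng(1)
        a = MockBindingPredictor(seed=1)
        b = MockBindingPredictor(seed=2)
        peps = [random_peptide(rng, 9) for _ in range(30)]
        assert any(a.predict(p, A0201) != b.predict(p, A0201) for p in peps)

    def test_outputs_within_contract_ranges(self):
        rng = np.random.default_rng(2)
        mock = MockBindingPredictor(seed=3)
        for _ in range(200):
            p = random_peptide(rng, int(rng.integers(8, 15)))
            ic50, el = mock.predict(p, B0702)
            assert 1.0 <= ic50 <= 50000.0
            assert 0 < el <= 100.0

    def test_strong_binder_fraction_zero_yields_no_neoantigens(self):
        rng = np.random.default_rng(3)
        mock = MockBindingPredictor(seed=4, strong_binder_frac=0.0)
        preds = [
            BindingPrediction(p, A0201, *mock.predict(p, A0201))
            for p in (random_peptide(rng, 9) for _ in range(300))
        ]
        assert classify_neoantigens(preds) == []

    def test_el_rank_marginal_tracks_strong_binder_fraction(self):
        # marginal over random peptides, averaged across alleles and
        # lengths (each single hashed PWM has its own finite-sample tilt)
        rng = np.random.default_rng(4)
        mock = MockBindingPredictor(seed=5, strong_binder_frac=0.1)
        alleles = [A0201, B0702, parse_hla_allele("HLA-C*07:01"),
                   parse_hla_allele("HLA-A*01:01")]
        n = hits = 0
        for _ in range(2000):
            pep = random_peptide(rng, int(rng.integers(8, 15)))
            al = alleles[n % len(alleles)]
            hits += mock.predict(pep, al)[1] <= 2.0
            n += 1
        assert 0.06 < hits / n < 0.14


class TestNeoantigenRule:
    def test_el_arm_alone_qualifies(self):
        recs = classify_neoantigens([pred("A" * 9, ic50=600.0, el=1.5)])
        assert len(recs) == 1 and recs[0].passes_el and not recs[0].passes_ic50

    def test_ic50_arm_alone_qualifies(self):
        recs = classify_neoantigens([pred("A" * 9, ic50=400.0, el=3.0)])
        assert len(recs) == 1 and recs[0].passes_ic50 and not recs[0].passes_el

    def test_neither_arm_fails(self):
        assert classify_neoantigens([pred("A" * 9, ic50=600.0, el=2.5)]) == []

    def test_boundaries_are_inclusive(self):
        assert len(classify_neoantigens([pred("A" * 9, 500.0, 50.0)])) == 1
        assert len(classify_neoantigens([pred("C" * 9, 5000.0, 2.0)])) == 1

    def test_unique_by_peptide_across_alleles(self):
        recs = classify_neoantigens(
            [pred("A" * 9, 100.0, 1.0, A0201), pred("A" * 9, 200.0, 1.5, B0702)]
        )
        assert len(recs) == 1
        assert len(recs[0].binding_alleles) == 2
        assert recs[0].best_ic50 == 100.0
        assert recs[0].best_el_rank == 1.0

    def test_tightening_thresholds_never_adds_neoantigens(self):
        rng = np.random.default_rng(6)
        preds = [
            pred(random_peptide(rng, 9), float(rng.uniform(10, 5000)),
                 float(rng.uniform(0.1, 20)))
            for _ in range(300)
        ]
        base = {r.peptide for r in classify_neoantigens(preds, 500, 2)}
        for ic_cut, el_cut in [(250, 2), (500, 1), (100, 0.5)]:
            tightened = {r.peptide
                         for r in classify_neoantigens(preds, ic_cut, el_cut)}
            assert tightened <= base

    def test_contract_violation_rejected(self):
        with pytest.raises(PredictorContractError):
            pred("A" * 9, -5.0, 1.0)
        with pytest.raises(PredictorContractError):
            pred("A" * 9, 100.0, 0.0)


class FixedPredictor:
    """Predictor defined by an explicit (peptide, allele-name) -> values map."""

    def __init__(self, table, default=(25000.0, 60.0)):
        self.table = table
        self.default = default

    def predict(self, peptide, allele):
        return self.table.get((peptide, allele.name), self.default)


class TestDAI:
    def setup_method(self):
        self.seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        self.variant = SomaticVariant(
            patient_id="P1", gene="G", protein_position=20,
            ref_aa=self.seq[19], alt_aa="A",
        )
        self.pairs = enumerate_peptide_pairs(self.variant, {"G": self.seq},
                                             lengths=[9])
        self.pair = self.pairs[0]

    def _dai_for(self, wt_ic50, mut_ic50):
        table = {
            (self.pair.mutant_seq, A0201.name): (mut_ic50, 1.0),
            (self.pair.wildtype_seq, A0201.name): (wt_ic50, 50.0),
        }
        return compute_dai(self.pair, FixedPredictor(table), [A0201])

    def test_tenfold_improvement_hits_threshold(self):
        assert self._dai_for(5000.0, 500.0) == pytest.approx(10.0)

    def test_identical_binding_gives_unity(self):
        assert self._dai_for(400.0, 400.0) == pytest.approx(1.0)

    def test_mutant_binding_worse_gives_fractional_dai(self):
        assert self._dai_for(400.0, 4000.0) == pytest.approx(0.1)

    def test_records_carry_max_dai_over_binding_alleles(self):
        table = {
            (self.pair.mutant_seq, A0201.name): (100.0, 1.0),
            (self.pair.wildtype_seq, A0201.name): (1000.0, 50.0),
            (self.pair.mutant_seq, B0702.name): (400.0, 1.5),
            (self.pair.wildtype_seq, B0702.name): (40000.0, 60.0),
        }
        recs = build_neoantigen_records(
            [self.pair], [A0201, B0702], FixedPredictor(table)
        )
        assert len(recs) == 1
        assert recs[0].dai == pytest.approx(100.0)  # B arm: 40000/400


def test_same_peptide_from_two_variants_collapses_to_one_record():
    seq = "A" * 30
    v1 = SomaticVariant(patient_id="P1", gene="G1", protein_position=10,
                        ref_aa="A", alt_aa="K")
    v2 = SomaticVariant(patient_id="P1", gene="G2", protein_position=10,
                        ref_aa="A", alt_aa="K")
    proteome = {"G1": seq, "G2": seq}
    pairs = enumerate_peptide_pairs(v1, proteome, lengths=[9]) + \
        enumerate_peptide_pairs(v2, proteome, lengths=[9])
    mut_peps = {p.mutant_seq for p in pairs}
    table = {(p, A0201.name): (50.0, 0.5) for p in mut_peps}
    recs = build_neoantigen_records(pairs, [A0201], FixedPredictor(table))
    by_pep = {r.peptide: r for r in recs}
    assert len(recs) == len(mut_peps)
    for r in recs:
        assert len(r.source_variants) == 2  # same window from both genes


def test_predict_binding_covers_mutant_and_wildtype_peptides():
    from neoquant.binding import predict_binding

    seq = "ACDEFGHIKLMNPQRSTVWY" * 2
    v = SomaticVariant(patient_id="P1", gene="G", protein_position=20,
                       ref_aa=seq[19], alt_aa="A")
    pairs = enumerate_peptide_pairs(v, {"G": seq}, lengths=[9])
    mock = MockBindingPredictor(seed=0)
    preds = predict_binding(pairs, [A0201, B0702], mock)
    expected_peps = {p.mutant_seq for p in pairs} | {p.wildtype_seq for p in pairs}
    assert {p.peptide for p in preds} == expected_peps
    assert len(preds) == 2 * len(expected_peps)  # one per allele
    mutant_only = predict_binding(pairs, [A0201], mock, include_wildtype=False)
    assert {p.peptide for p in mutant_only} == {p.mutant_seq for p in pairs}


def test_table_predictor_roundtrip_and_missing_pair():
    df = pd.DataFrame(
        {"peptide": ["AAAAKAAAA"], "allele": ["HLA-A*02:01"],
         "ic50_nm": [123.0], "el_rank_pct": [0.7]}
    )
    tp = TableBindingPredictor(df)
    assert tp.predict("AAAAKAAAA", A0201) == (123.0, 0.7)
    with pytest.raises(KeyError):
        tp.predict("AAAAKAAAA", B0702)
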