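"""TP/FP/uncertain classification, summaries, F-max, and profile comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from ogmap.benchmark import (
    FP,
    TP,
    UNCERTAIN,
    FunctionalProfile,
    GoldStandard,
    build_gold_standard,
    classify_terms,
    compare_profiles,
    fmax,
    functional_profile,
    summarize,
)
from ogmap.ontology import NEVER_IN, GoDag, TaxonConstraint, propagate


@pytest.fixture()
def dag():
    return GoDag({
        "GO:0000001": set(),
        "GO:0000002": {"GO:0000001"},
        "GO:0000003": {"GO:0000001"},
        "GO:0000004": {"GO:0000002"},
    })


@pytest.fixture()
def gold(dag, chain_taxonomy):
    # proteins of species 4 (inside "plant" clade 2) and species 3
    tp = {
        "4.p1": propagate(dag, {"GO:0000004"}),
        "3.p2": propagate(dag, {"GO:0000002"}),
    }
    constraints = [TaxonConstraint("GO:0000003", NEVER_IN, 2)]
    return GoldStandard(tp_terms=tp, constraints=constraints)


class TestClassify:
    def test_exact_gold_prediction_all_tp(self, dag, gold, chain_taxonomy):
        cls = classify_terms({"4.p1": gold.tp_terms["4.p1"]}, gold, dag, chain_taxonomy)
        assert set(cls["4.p1"].values()) == {TP}

    def test_never_in_clade_term_is_fp_for_plant_protein(self, dag, gold, chain_taxonomy):
        cls = classify_terms({"4.p1": {"GO:0000003"}}, gold, dag, chain_taxonomy)
        assert cls["4.p1"]["GO:0000003"] == FP
        # same term on a protein outside the clade is merely uncertain
        cls2 = classify_terms({"3.p2": {"GO:0000003"}}, gold, dag, chain_taxonomy)
        assert cls2["3.p2"]["GO:0000003"] == UNCERTAIN

    def test_protein_absent_from_gold_still_classified(self, dag, gold, chain_taxonomy):
        cls = classify_terms({"5.px": {"GO:0000001", "GO:0000003"}}, gold, dag, chain_taxonomy)
        assert cls["5.px"]["GO:0000003"] == FP  # species 5 under clade 2
        assert cls["5.px"]["GO:0000001"] == UNCERTAIN

    def test_partition_matches_membership_oracle(self, dag, chain_taxonomy, rng):
        terms = sorted(dag.terms)
        for _ in range(30):
            tp_set = {t for t in terms if rng.random() < 0.4}
            pred = {t for t in terms if rng.random() < 0.6}
            cons = ([TaxonConstraint(terms[int(rng.integers(len(terms)))], NEVER_IN, 2)]
                    if rng.random() < 0.7 else [])
            gold = GoldStandard(tp_terms={"4.p": tp_set}, constraints=cons)
            cls = classify_terms({"4.p": pred}, gold, dag, chain_taxonomy)["4.p"]
            assert set(cls) == pred  # labels partition the predicted set
            for t in pred:
                if t in tp_set:
                    assert cls[t] == TP
                else:
                    affected = cons and cons[0].term in ({t} | set(dag.ancestors(t)))
                    assert cls[t] == (FP if affected else UNCERTAIN)


class TestSummarize:
    def test_all_tp(self):
        cls = {f"p{i}": {"GO:0000001": TP, "GO:0000002": TP} for i in range(4)}
        s = summarize(cls, proteome_size=8)
        assert s.tp_ratio == 1.0
        assert s.coverage == 0.5
        assert s.tp_only_fraction == s.coverage
        assert s.mixed_fraction == s.no_tp_fraction == 0.0

    def test_no_predictions(self):
        s = summarize({}, proteome_size=10)
        assert s.coverage == 0.0
        assert s.tp_ratio is None and s.tp_fp_proportion is None

    def test_hand_computed_fixture(self):
        cls = {
            "p1": {"a": TP, "b": TP},            # tp_only
            "p2": {"a": TP, "b": FP, "c": UNCERTAIN},  # mixed
            "p3": {"a": FP},                     # no_tp
            "p4": {"a": UNCERTAIN, "b": UNCERTAIN},    # no_tp
            "p5": {},                            # unannotated
        }
        s = summarize(cls, proteome_size=5)
        assert s.n_annotated == 4
        assert s.mean_tp == pytest.approx(3 / 4)
        assert s.mean_fp == pytest.approx(2 / 4)
        assert s.mean_uncertain == pytest.approx(3 / 4)
        assert s.tp_ratio == pytest.approx(3 / 8)
        assert s.tp_fp_proportion == pytest.approx(3 / 5)
        assert s.coverage == pytest.approx(4 / 5)
        assert s.tp_only_fraction == pytest.approx(1 / 5)
        assert s.mixed_fraction == pytest.approx(1 / 5)
        assert s.no_tp_fraction == pytest.approx(2 / 5)
        # partition & denominator-dominance invariants
        assert s.tp_only_fraction + s.mixed_fraction + s.no_tp_fraction == pytest.approx(s.coverage)
        assert s.tp_ratio <= s.tp_fp_proportion


class TestFmax:
    def test_perfect_predictor(self):
        gold = {"p1": {"a", "b"}, "p2": {"c"}}
        preds = {p: {t: 1.0 for t in ts} for p, ts in gold.items()}
        assert fmax(preds, gold).fmax == 1.0

    def test_single_protein_worked_example(self):
        res = fmax({"p1": {"a": 1.0}}, {"p1": {"a", "b"}})
        assert res.fmax == pytest.approx(2 / 3)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            fmax({"p1": {"a": 1.0}}, {"p1": set()})

    def test_matches_finer_grid_oracle_on_grid_scores(self, rng):
        terms = [f"t{i}" for i in range(12)]
        for trial in range(10):
            gold = {f"p{i}": {t for t in terms if rng.random() < 0.4} for i in range(6)}
            if not any(gold.values()):
                gold["p0"] = {terms[0]}
            preds = {
                f"p{i}": {t: float(rng.integers(1, 101)) / 100 for t in terms
                          if rng.random() < 0.5}
                for i in range(6)
            }
            coarse = fmax(preds, gold)
            fine = fmax(preds, gold, thresholds=np.round(np.arange(0.001, 1.0005, 0.001), 3))
            assert coarse.fmax == pytest.approx(fine.fmax, abs=1e-12)

    def test_invariant_under_order_preserving_regrading(self):
        gold = {"p1": {"a", "b"}, "p2": {"a"}}
        preds = {"p1": {"a": 0.2, "b": 0.5, "c": 0.9}, "p2": {"a": 0.5}}
        remap = {0.2: 0.1, 0.5: 0.65, 0.9: 0.97}
        regraded = {p: {t: remap[s] for t, s in d.items()} for p, d in preds.items()}
        f1 = fmax(preds, gold, thresholds=np.array(sorted({s for d in preds.values() for s in d.values()})))
        f2 = fmax(regraded, gold, thresholds=np.array(sorted({s for d in regraded.values() for s in d.values()})))
        assert f1.fmax == pytest.approx(f2.fmax)

    def test_partial_mode_ignores_nonpredicting_proteins_in_precision(self):
        # p2 predicts nothing: precision averages over p1 only; recall over both
        gold = {"p1": {"a"}, "p2": {"b"}}
        res = fmax({"p1": {"a": 1.0}}, gold)
        assert res.fmax == pytest.approx(2 * 1.0 * 0.5 / 1.5)


class TestProfiles:
    def test_single_gene_counts_ancestors(self, diamond_dag):
        prof = functional_profile({"g1": 5.0}, {"g1": {"GO:0000004"}}, diamond_dag)
        assert prof.abundances == {
            "GO:0000001": 5.0, "GO:0000002": 5.0, "GO:0000003": 5.0, "GO:0000004": 5.0,
        }

    def test_additivity(self):
        prof = functional_profile({"g1": 2.0, "g2": 3.0},
                                  {"g1": {"t"}, "g2": {"t"}})
        assert prof.abundances == {"t": 5.0}

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            functional_profile({"g1": -1.0}, {"g1": {"t"}})

    def test_read_count_construction_equivalence(self, rng):
        # counting reads per term equals summing per-gene read counts per term
        genes = {f"g{i}": {f"t{j}" for j in rng.choice(5, size=2, replace=False)}
                 for i in range(10)}
        reads = {g: float(rng.integers(0, 30)) for g in genes}
        by_term = {}
        for g, terms in genes.items():
            for t in terms:
                by_term[t] = by_term.get(t, 0.0) + reads[g]
        prof = functional_profile(reads, genes)
        assert prof.abundances == by_term

    def test_identical_profiles_rho_one(self):
        a = FunctionalProfile({"a": 1.0, "b": 2.0, "c": 5.0, "d": 3.0})
        assert compare_profiles(a, a).rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = FunctionalProfile({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        b = FunctionalProfile({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        assert compare_profiles(a, b).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(100):
            keys = [f"t{i}" for i in range(50)]
            a = FunctionalProfile({k: float(rng.integers(0, 20)) for k in keys})
            b = FunctionalProfile({k: float(rng.integers(0, 20)) for k in keys})
            got = compare_profiles(a, b, exact=False)
            va = [a.abundances[k] for k in sorted(keys)]
            vb = [b.abundances[k] for k in sorted(keys)]
            if len(set(va)) == 1 or len(set(vb)) == 1:
                assert math.isnan(got.rho)
                continue
            expected = stats.pearsonr(stats.rankdata(va), stats.rankdata(vb)).statistic
            assert got.rho == pytest.approx(expected, abs=1e-12)

    def test_union_of_keys_with_disjoint_supports(self):
        a = FunctionalProfile({"a": 1.0, "b": 2.0})
        b = FunctionalProfile({"c": 3.0, "d": 4.0})
        res = compare_profiles(a, b, exact=False)
        assert res.n_terms == 4  # union, zeros filled in

    def test_constant_vector_undefined(self):
        a = FunctionalProfile({"a": 1.0, "b": 1.0, "c": 1.0})
        b = FunctionalProfile({"a": 1.0, "b": 2.0, "c": 3.0})
        assert math.isnan(compare_profiles(a, b).rho)

    def test_symmetry(self, rng):
        a = FunctionalProfile({f"t{i}": float(rng.integers(0, 9)) for i in range(20)})
        b = FunctionalProfile({f"t{i}": float(rng.integers(0, 9)) for i in range(20)})
        ra, rb = compare_profiles(a, b, exact=False), compare_profiles(b, a, exact=False)
        if not math.isnan(ra.rho):
            assert ra.rho == pytest.approx(rb.rho)

    def test_too_few_terms_rejected(self):
        a = FunctionalProfile({"a": 1.0})
        with pytest.raises(ValueError):
            compare_profiles(a, a)


class TestGoldBuilding:
    def test_experimental_codes_only(self, dag):
        rows = [("4.p1", "GO:0000004", "IDA"), ("4.p1", "GO:0000003", "IEA")]
        gold = build_gold_standard(rows, dag)
        assert gold.tp_terms == {"4.p1": {"GO:0000004", "GO:0000002", "GO:0000001"}}

    def test_closure_optional(self, dag):
        rows = [("4.p1", "GO:0000004", "EXP")]
        gold = build_gold_standard(rows, dag, closed=False)
        assert gold.tp_terms == {"4.p1": {"GO:0000004"}}
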