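import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molevoscreen import (
    Alignment,
    PhyloTree,
    build_amino_model,
    classify_branch_pair,
    expected_counts,
    genome_regression_null,
    marginal_reconstruct,
    tail_probability,
    zhang_kumar_test,
)
from molevoscreen import simulate
from molevoscreen.alignments import AA_INDEX
from molevoscreen.convergence import SITE_CLASSES, classify_site, PairCounts


from conftest import recon_with_states as _recon_with_states


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")


class TestClassification:
    def test_textbook_cases(self, quartet):
        # columns: 1) T->S twice (parallel)  2) A->S vs V->S (convergent)
        # 3) T->S vs T->A (divergent)  4) substitution on one branch only
        # 5) no change  6) gap exclusion
        rec = _recon_with_states(
            quartet,
            {"a": "SSSATA", "b": "TATTT-", "c": "SSATTT", "d": "TVTTTT"},
            {"root": "TATTTT", "a+b": "TATTTT", "c+d": "TVTTTT"},
        )
        prof = classify_branch_pair(rec, ("a", "c"))
        assert prof.per_site_class() == [
            "parallel", "convergent", "divergent", "single", "none", "single",
        ]
        prof_gap = classify_branch_pair(rec, ("a", "b"))
        assert prof_gap.per_site_class()[5] == "excluded"

    def test_every_site_in_exactly_one_class(self, quartet, jtt_model):
        aln, _ = simulate.simulate_protein_gene(quartet, jtt_model, 200, [21, 0])
        rec = marginal_reconstruct(quartet, jtt_model, aln)
        prof = classify_branch_pair(rec, ("a", "c"))
        counts = {c: prof.per_site_class().count(c) for c in SITE_CLASSES}
        assert sum(counts.values()) == 200

    def test_symmetric_in_pair_order(self, quartet, jtt_model):
        aln, _ = simulate.simulate_protein_gene(quartet, jtt_model, 300, [22, 0])
        rec = marginal_reconstruct(quartet, jtt_model, aln)
        p1 = classify_branch_pair(rec, ("a", "c"))
        p2 = classify_branch_pair(rec, ("c", "a"))
        assert (p1.n_conv, p1.n_par, p1.n_div) == (p2.n_conv, p2.n_par, p2.n_div)

    def test_nested_pair_rejected(self, quartet, jtt_model):
        aln, _ = simulate.simulate_protein_gene(quartet, jtt_model, 10, [23, 0])
        rec = marginal_reconstruct(quartet, jtt_model, aln)
        with pytest.raises(ValueError):
            classify_branch_pair(rec, ("a", "a+b"))

    def test_scalar_classifier_matches_definitions(self):
        # spot checks of the scalar helper used for cross-validation
        A, S, T, V = (AA_INDEX[c] for c in "ASTV")
        assert SITE_CLASSES[classify_site(T, S, T, S)] == "parallel"
        assert SITE_CLASSES[classify_site(A, S, V, S)] == "convergent"
        assert SITE_CLASSES[classify_site(T, S, T, A)] == "divergent"
        assert SITE_CLASSES[classify_site(T, S, T, T)] == "single"
        assert SITE_CLASSES[classify_site(T, T, T, T)] == "none"
        assert SITE_CLASSES[classify_site(-1, S, T, S)] == "excluded"


class TestExpectedCounts:
    def test_zero_branch_lengths_zero_expectation(self, jtt_model):
        tree = PhyloTree.from_newick("((a:0.0,b:0.1):0.1,(c:0.0,d:0.1):0.1);")
        aln = Alignment([("a", "A"), ("b", "C"), ("c", "D"), ("d", "E")])
        rec = marginal_reconstruct(tree, jtt_model, aln)
        test = expected_counts(jtt_model, rec, ("a", "c"))
        assert test.expected_conv == pytest.approx(0.0, abs=1e-12)
        assert test.expected_par == pytest.approx(0.0, abs=1e-12)

    def test_parallel_probability_direct_sum(self, quartet, jtt_model):
        # ancestors fixed at A on both sides, t = 0.1 each:
        # p_par = sum_{d != A} P_{A->d}(0.1)^2
        rec = _recon_with_states(
            quartet,
            {"a": "A", "b": "A", "c": "A", "d": "A"},
            {"root": "A", "a+b": "A", "c+d": "A"},
        )
        test = expected_counts(jtt_model, rec, ("a", "c"))
        p = jtt_model.transition(0.1)
        a = AA_INDEX["A"]
        direct = sum(p[a, d] ** 2 for d in range(20) if d != a)
        assert test.per_site_par[0] == pytest.approx(direct, abs=1e-12)
        # with identical fixed ancestors no convergent event is possible
        assert test.per_site_conv[0] == pytest.approx(0.0, abs=1e-15)

    def test_expectation_equals_sum_of_site_probs(self, quartet, jtt_model):
        aln, _ = simulate.simulate_protein_gene(quartet, jtt_model, 100, [24, 0])
        rec = marginal_reconstruct(quartet, jtt_model, aln)
        test = expected_counts(jtt_model, rec, ("a", "c"))
        assert test.expected_par == pytest.approx(test.per_site_par.sum(), abs=1e-10)
        assert ((test.per_site_par >= 0) & (test.per_site_par <= 1)).all()
        assert ((test.per_site_conv >= 0) & (test.per_site_conv <= 1)).all()


class TestTailProbability:
    def test_zero_observed_gives_one(self):
        assert tail_probability([0.3, 0.4], 0) == 1.0
        assert tail_probability([], 0, method="poisson") == 1.0

    def test_poisson_tail_value(self):
        # P(X >= 3) with E = 0.5
        expected = 1 - np.exp(-0.5) * (1 + 0.5 + 0.125)
        assert tail_probability([0.5], 3, method="poisson") == pytest.approx(
            expected, abs=1e-12
        )

    def test_poisson_binomial_exact_enumeration(self):
        assert tail_probability([0.1, 0.2], 2) == pytest.approx(0.02, abs=1e-15)
        # full enumeration for three sites
        probs = [0.1, 0.25, 0.5]
        for k in (1, 2, 3):
            exact = 0.0
            for bits in range(8):
                draw = [(bits >> i) & 1 for i in range(3)]
                if sum(draw) >= k:
                    pr = 1.0
                    for p, b in zip(probs, draw):
                        pr *= p if b else 1 - p
                    exact += pr
            assert tail_probability(probs, k) == pytest.approx(exact, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        observed=st.integers(1, 12),
    )
    def test_tail_properties(self, probs, observed):
        p = tail_probability(probs, observed)
        assert 0.0 <= p <= 1.0
        # monotone decreasing in the observed count
        assert p <= tail_probability(probs, observed - 1) + 1e-12
        # exact tail bounded by the Markov/union bound sum of probabilities
        assert p <= min(1.0, sum(probs) / observed + 1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tail_probability([1.2], 1)
        with pytest.raises(ValueError):
            tail_probability([0.1], -1)


class TestRegressionNull:
    def test_exact_line_r_squared_one(self):
        profiles = [
            PairCounts(f"a{i}", f"b{i}", n_conv=i, n_par=0, n_div=10 * i)
            for i in range(1, 8)
        ]
        null = genome_regression_null(profiles)
        assert null.r_squared == pytest.approx(1.0, abs=1e-10)
        assert np.abs(null.points["residual"]).max() < 1e-8
        assert len(null.flagged) == 0
        assert null.slope == pytest.approx(0.1, abs=1e-10)

    def test_degenerate_x_rejected(self):
        profiles = [PairCounts("a", "b", 1, 1, 5) for _ in range(4)]
        with pytest.raises(ValueError):
            genome_regression_null(profiles)

    def test_excess_pair_flagged(self):
        rng = np.random.default_rng(5)
        profiles = [
            PairCounts(f"a{i}", f"b{i}", int(rng.poisson(0.1 * x)), 0, x)
            for i, x in enumerate(range(20, 220, 10))
        ]
        profiles.append(PairCounts("hot", "pair", 40, 0, 100))
        null = genome_regression_null(profiles)
        flagged = null.flagged
        assert ("hot" in set(flagged["pair_a"]))
        assert null.points["student_resid"].idxmax() == len(profiles) - 1


class TestZhangKumar:
    def test_injected_parallel_sites_drive_p_down(self, study_tree, jtt_model):
        pair = ("shedao_pitviper", "alligator")
        pvals = []
        for k in (0, 2, 5, 10):
            aln, _ = simulate.simulate_protein_gene(study_tree, jtt_model, 300, [30, 0])
            if k:
                aln, _ = simulate.inject_convergence(
                    aln, study_tree, pair, k, "parallel", [30, 0, k]
                )
            model = build_amino_model(aln, "JTT-Fgene")
            rec = marginal_reconstruct(study_tree, model, aln)
            test = zhang_kumar_test(model, rec, pair)
            pvals.append(test.p_par)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))
        assert pvals[-1] < 1e-6
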