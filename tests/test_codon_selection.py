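import numpy as np
import pytest
import scipy.optimize

from molevoscreen import (
    Alignment,
    PhyloTree,
    branch_site_fit,
    extract_4d_sites,
    fdr_adjust,
    free_ratio_fit,
)
from molevoscreen import simulate
from molevoscreen.alignments import FrameError
from molevoscreen.codon_selection import pairwise_dnds_counting
from molevoscreen.substmodels import CodonEig, CodonModel, codon_frequencies


class TestFourfoldSites:
    def test_glycine_family_extracted(self):
        aln = Alignment([("a", "GGA"), ("b", "GGT"), ("c", "GGC")], kind="codon")
        out = extract_4d_sites(aln)
        assert len(out) == 1
        assert out["a"], out["b"] == ("A", "T")

    def test_twofold_family_excluded(self):
        aln = Alignment([("a", "AAA"), ("b", "AAG"), ("c", "AAA")], kind="codon")
        assert len(extract_4d_sites(aln)) == 0

    def test_hand_built_fixture_has_seven_sites(self, fourfold_fixture):
        aln, truth_cols = fourfold_fixture
        out = extract_4d_sites(aln)
        assert len(out) == 7
        assert out.source_columns == truth_cols

    def test_positional_audit_and_alphabet(self, fourfold_fixture):
        aln, truth_cols = fourfold_fixture
        out = extract_4d_sites(aln)
        for t in aln.taxa:
            assert set(out[t]) <= set("ACGT")
            expected = "".join(aln[t][3 * c + 2] for c in truth_cols)
            assert out[t] == expected

    def test_internal_stop_reported(self):
        aln = Alignment([("a", "TAAGGA"), ("b", "GGAGGT")], kind="codon")
        with pytest.raises(FrameError, match="a"):
            extract_4d_sites(aln)

    def test_frame_violation_rejected(self):
        with pytest.raises(FrameError):
            Alignment([("a", "GGAA"), ("b", "GGTT")], kind="codon")


class TestFdr:
    def test_bh_worked_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_uniform_grid_against_step_up_enumeration(self):
        p = np.arange(0.1, 1.01, 0.1)
        q = fdr_adjust(p)
        # manual step-up: q_i = min_{j >= i} (m * p_j / j), sorted order
        m = len(p)
        manual = np.minimum.accumulate((m * p / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(q, np.minimum(manual, 1.0), atol=1e-12)
        assert (np.diff(q) >= -1e-15).all()


class TestCountingDnDs:
    def test_single_synonymous_difference(self):
        dn, ds = pairwise_dnds_counting("ATGGGA", "ATGGGT")
        assert dn == 0.0
        assert ds > 0.0

    def test_single_nonsynonymous_difference(self):
        dn, ds = pairwise_dnds_counting("ATGGGA", "ATGAGA")  # G->R
        assert ds == 0.0
        assert dn > 0.0


class TestFreeRatio:
    def test_identical_sequences_give_zero_rates(self, six_taxon_tree):
        seq = "ATGGGATTTAAACATGAACCC" * 3
        aln = Alignment([(t, seq) for t in six_taxon_tree.leaves], kind="codon")
        fit = free_ratio_fit(aln, six_taxon_tree, rounds=1)
        for dn, ds, _, _ in fit.rates.values():
            assert dn < 1e-4 and ds < 1e-4

    def test_omega_equals_dn_over_ds(self, six_taxon_tree):
        model = CodonModel(2.0, 0.3, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(six_taxon_tree, model, 200, [40, 0])
        fit = free_ratio_fit(aln, six_taxon_tree, rounds=1)
        for dn, ds, omega, _ in fit.rates.values():
            if ds > 1e-6:
                assert dn / ds == pytest.approx(omega, rel=1e-6)

    def test_two_branch_problem_matches_direct_ml_oracle(self):
        tree = PhyloTree.from_newick("(x:0.2,y:0.2);")
        model = CodonModel(2.5, 0.4, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(tree, model, 300, [41, 0])
        fit = free_ratio_fit(aln, tree, rounds=3)
        pi = codon_frequencies(aln, "F3x4")
        states = aln.codon_states()

        def neg_ll(x):
            kappa, w1, w2, t1, t2 = np.exp(x)
            p1 = CodonEig(kappa, w1, pi).transition(t1)
            p2 = CodonEig(kappa, w2, pi).transition(t2)
            # direct sum over the root state, no pruning machinery
            l1 = pi[None, :] * p1[:, states[:, 0]].T * p2[:, states[:, 1]].T
            return -np.log(l1.sum(axis=1)).sum()

        best = np.inf
        for s in range(3):
            rng = np.random.default_rng(s)
            x0 = np.log([2.0, 0.5, 0.5, 0.2, 0.2]) + rng.normal(0, 0.3, 5)
            res = scipy.optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                          options={"xatol": 1e-6, "fatol": 1e-9,
                                                   "maxiter": 4000, "maxfev": 4000})
            best = min(best, res.fun)
        assert fit.log_likelihood == pytest.approx(-best, abs=0.01)

    def test_parameter_recovery_under_purifying_selection(self, six_taxon_tree):
        model = CodonModel(2.0, 0.2, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(six_taxon_tree, model, 500, [42, 0])
        fit = free_ratio_fit(aln, six_taxon_tree, rounds=2)
        omegas = [w for _, _, w, _ in fit.rates.values()]
        assert 0.1 <= np.median(omegas) <= 0.35


class TestBranchSite:
    def test_alternative_never_below_null(self, six_taxon_tree):
        model = CodonModel(2.0, 0.2, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(six_taxon_tree, model, 120, [43, 0])
        fit = branch_site_fit(aln, six_taxon_tree, "shedao_pitviper", restarts=1, maxiter=80)
        assert fit.lnl_alt >= fit.lnl_null - 1e-6
        assert fit.lrt_stat >= -1e-6
        assert 0.0 <= fit.p_value <= 1.0
        pa = fit.params_alt
        assert pa["p0"] + pa["p1"] + pa["p2a"] + pa["p2b"] == pytest.approx(1.0, abs=1e-9)
        assert pa["omega2"] >= 1.0
        assert 0.0 < pa["omega0"] < 1.0
        assert fit.site_posteriors.shape == (120,)
        assert ((fit.site_posteriors >= 0) & (fit.site_posteriors <= 1)).all()

    def test_engineered_selection_detected(self, six_taxon_tree):
        tree = six_taxon_tree.with_lengths({"shedao_pitviper": 0.5})
        model = CodonModel(2.0, 0.2, np.full(61, 1 / 61))
        aln, truth = simulate.simulate_codon_gene(
            tree, model, 400, [200, 5], foreground="shedao_pitviper",
            class_probs=(0.425, 0.425, 0.075, 0.075), omega2=4.0,
        )
        fit = branch_site_fit(aln, tree, "shedao_pitviper", restarts=1)
        assert fit.p_value < 0.05
        assert fit.params_alt["omega2"] > 1.5
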