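import io

import numpy as np
import pytest
import scipy.stats

from molevoscreen import Alignment, PhyloTree, build_amino_model
from molevoscreen import simulate
from molevoscreen.alignments import AMINO_ACIDS, NT_INDEX
from molevoscreen.substmodels import CodonModel
from molevoscreen.simulate import SimulationTruth


class TestProteinSimulation:
    def test_zero_lengths_identical_leaves(self, jtt_model):
        tree = PhyloTree.from_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln, _ = simulate.simulate_protein_gene(tree, jtt_model, 50, [60, 0])
        seqs = {aln[t] for t in aln.taxa}
        assert len(seqs) == 1

    def test_same_seed_byte_identical(self, four_taxon_tree, jtt_model, tmp_path):
        out = []
        for run in range(2):
            aln, _ = simulate.simulate_protein_gene(four_taxon_tree, jtt_model, 80, [61, 3])
            path = tmp_path / f"run{run}.fasta"
            aln.write_fasta(path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_long_branch_reaches_stationarity(self, jtt_model):
        tree = PhyloTree.from_newick("(a:5.0,b:5.0);")
        aln, _ = simulate.simulate_protein_gene(tree, jtt_model, 50000, [62, 0])
        counts = np.array([aln["a"].count(c) for c in AMINO_ACIDS])
        stat = scipy.stats.chisquare(counts, jtt_model.pi() * counts.sum())
        assert stat.pvalue > 0.001

    def test_branch_substitution_counts_match_model(self, jtt_model):
        # exact two-leaf check: P(leaves differ) = 1 - sum_i pi_i P_ii(2t)
        t = 0.05
        tree = PhyloTree.from_newick(f"(a:{t},b:{t});")
        length = 20000
        aln, _ = simulate.simulate_protein_gene(tree, jtt_model, length, [63, 0])
        p = jtt_model.transition(2 * t)
        p_diff = 1 - float(jtt_model.pi() @ np.diag(p))
        observed = sum(x != y for x, y in zip(aln["a"], aln["b"]))
        sd = np.sqrt(length * p_diff * (1 - p_diff))
        assert abs(observed - length * p_diff) < 4 * sd

    def test_missing_branch_lengths_rejected(self, jtt_model):
        tree = PhyloTree.from_newick("(a,b,c);")
        with pytest.raises(ValueError):
            simulate.simulate_protein_gene(tree, jtt_model, 10, [64, 0])


class TestCodonSimulation:
    def test_omega_zero_no_amino_acid_differences(self, six_taxon_tree):
        model = CodonModel(2.0, 1e-9, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(six_taxon_tree, model, 150, [65, 0])
        prots = {aln.translate()[t] for t in aln.taxa}
        assert len(prots) == 1

    def test_no_stop_codons_generated(self, six_taxon_tree):
        model = CodonModel(2.0, 0.5, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(six_taxon_tree, model, 200, [66, 0])
        states = aln.codon_states()
        assert (states >= 0).all()

    def test_large_kappa_suppresses_transversions(self):
        tree = PhyloTree.from_newick("(a:0.4,b:0.4);")
        model = CodonModel(50.0, 1.0, np.full(61, 1 / 61))
        aln, _ = simulate.simulate_codon_gene(tree, model, 4000, [67, 0])
        ts = tv = 0
        ts_pairs = {frozenset("AG"), frozenset("CT")}
        for x, y in zip(aln["a"][2::3], aln["b"][2::3]):  # third positions
            if x != y:
                if frozenset((x, y)) in ts_pairs:
                    ts += 1
                else:
                    tv += 1
        assert ts > 0 and tv < 0.2 * ts

    def test_truth_records_positive_class_sites(self, six_taxon_tree):
        model = CodonModel(2.0, 0.2, np.full(61, 1 / 61))
        _, truth = simulate.simulate_codon_gene(
            six_taxon_tree, model, 200, [68, 0],
            foreground="shedao_pitviper", class_probs=(0.4, 0.4, 0.1, 0.1), omega2=5.0,
        )
        assert len(truth.site_classes) == 200
        assert truth.positive_class_sites() == [
            i for i, c in enumerate(truth.site_classes) if c in (2, 3)
        ]


class TestInjection:
    def test_zero_sites_unchanged(self, study_tree, jtt_model):
        aln, _ = simulate.simulate_protein_gene(study_tree, jtt_model, 100, [70, 0])
        out, truth = simulate.inject_convergence(
            aln, study_tree, ("shedao_pitviper", "alligator"), 0, "parallel", [70, 1]
        )
        assert all(out[t] == aln[t] for t in aln.taxa)
        assert truth.injections[0]["sites"] == []

    def test_chained_injections_disjoint(self, study_tree, jtt_model):
        aln, _ = simulate.simulate_protein_gene(study_tree, jtt_model, 300, [71, 0])
        pair = ("shedao_pitviper", "alligator")
        a1, t1 = simulate.inject_convergence(aln, study_tree, pair, 8, "parallel", [71, 1])
        sites1 = set(t1.injections[0]["sites"])
        a2, t2 = simulate.inject_convergence(
            a1, study_tree, pair, 8, "parallel", [71, 2], exclude=sites1
        )
        sites2 = set(t2.injections[0]["sites"])
        assert not (sites1 & sites2)

    def test_convergent_mode_changes_both_clades(self, study_tree, jtt_model):
        aln, _ = simulate.simulate_protein_gene(study_tree, jtt_model, 400, [72, 0])
        pair = ("shedao_pitviper", "turtle")
        out, truth = simulate.inject_convergence(
            aln, study_tree, pair, 3, "convergent", [72, 1]
        )
        for s in truth.injections[0]["sites"]:
            assert out["shedao_pitviper"][s] == out["turtle"][s]

    def test_nested_pair_rejected(self, study_tree, jtt_model):
        aln, _ = simulate.simulate_protein_gene(study_tree, jtt_model, 50, [73, 0])
        with pytest.raises(ValueError):
            simulate.inject_convergence(
                aln, study_tree,
                ("shedao_pitviper", "black_eyebrow_pitviper+shedao_pitviper"),
                1, "parallel", [73, 1],
            )


class TestTruthRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        truth = SimulationTruth(
            gene="g1",
            seed=7,
            kind="codon",
            params={"kappa": 2.0, "omega2": 4.0},
            branch_omegas={"shedao_pitviper": 1.5},
            site_classes=[0, 1, 2, 3, 0],
            injections=[{"mode": "parallel", "branch_a": "a", "branch_b": "b", "sites": [3, 9]}],
            focal_specific=[{"site": 4, "ref": "A", "variant": "T"}],
        )
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        assert SimulationTruth.from_tsv(path) == truth


class TestFixtureSet:
    def test_gene_set_reproducible_and_labeled(self, tmp_path, study_tree):
        kwargs = dict(
            n_genes=3, length=60, master_seed=9,
            psg_genes={1: 4.0},
            parallel_inject={2: (("shedao_pitviper", "alligator"), 3)},
            specific_inject={0: 2},
        )
        set1 = simulate.make_gene_set(**kwargs)
        set2 = simulate.make_gene_set(**kwargs)
        for (n1, a1, t1), (n2, a2, t2) in zip(set1, set2):
            assert n1 == n2 and t1 == t2
            assert all(a1[t] == a2[t] for t in a1.taxa)
        assert set1[1][2].site_classes  # PSG gene has class assignments
        assert set1[2][2].injections
        assert set1[0][2].focal_specific
        simulate.write_fixture_set(tmp_path, set1)
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "gene0001.truth.tsv").exists()
        reread = Alignment.read_fasta(tmp_path / "gene0000.fasta", kind="codon")
        assert reread.taxa == set1[0][1].taxa
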