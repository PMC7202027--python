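import itertools

import numpy as np
import pytest

from molevoscreen import Alignment, PhyloTree, build_amino_model
from molevoscreen import simulate


@pytest.fixture(scope="session")
def study_tree() -> PhyloTree:
    return simulate.default_tree()


@pytest.fixture(scope="session")
def six_taxon_tree(study_tree) -> PhyloTree:
    return study_tree.pruned_to(
        ["frog", "turtle", "alligator", "python", "black_eyebrow_pitviper", "shedao_pitviper"]
    )


@pytest.fixture(scope="session")
def jtt_model():
    return build_amino_model(None, "JTT")


@pytest.fixture(scope="session")
def four_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("((a:0.2,b:0.35):0.1,(c:0.15,d:0.4):0.25);")


@pytest.fixture(scope="session")
def five_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("((a:0.2,b:0.35):0.1,((c:0.15,d:0.4):0.2,e:0.3):0.25);")


def recon_with_states(tree, leaf_cols, internal_cols):
    """AncestralReconstruction with hand-set (point-mass) states.

    ``leaf_cols``: taxon -> residue string; ``internal_cols``: branch id
    (or "root") -> residue string.
    """
    from molevoscreen.alignments import AA_INDEX
    from molevoscreen.ancestral import AncestralReconstruction

    taxa = list(leaf_cols)
    n_sites = len(next(iter(leaf_cols.values())))
    leaf_states = np.full((n_sites, len(taxa)), -1, dtype=np.int8)
    for j, t in enumerate(taxa):
        leaf_states[:, j] = [AA_INDEX.get(c, -1) for c in leaf_cols[t]]
    map_states, posts = {}, {}
    for v in range(tree.n_nodes):
        if tree.is_leaf(v):
            continue
        key = "root" if v == tree.root else tree.branch_id(v)
        states = np.array([AA_INDEX[c] for c in internal_cols[key]], dtype=np.int8)
        map_states[v] = states
        post = np.zeros((n_sites, 20))
        post[np.arange(n_sites), states] = 1.0
        posts[v] = post
    return AncestralReconstruction(
        tree=tree,
        node_posteriors=posts,
        map_states=map_states,
        site_log_likelihoods=np.zeros(n_sites),
        leaf_states=leaf_states,
        taxon_col={t: j for j, t in enumerate(taxa)},
    )


# --------------------------------------------------------------------------
# Independent brute-force oracles (enumeration over internal states)
# --------------------------------------------------------------------------


def brute_force_site_likelihood(tree: PhyloTree, model, column: dict) -> float:
    """Site likelihood by exhaustive summation over all internal-node (and
    gap-leaf) state assignments; independent of the pruning code path."""
    from molevoscreen.alignments import AA_INDEX

    free_nodes = []
    fixed = {}
    for v in range(tree.n_nodes):
        if tree.is_leaf(v):
            res = column[tree.leaf_name[v]]
            if res in AA_INDEX:
                fixed[v] = AA_INDEX[res]
            else:
                free_nodes.append(v)  # gap: marginalize
        else:
            free_nodes.append(v)
    pi = np.atleast_2d(model.pi())[0]
    ps = {}
    for v in tree.branches():
        m = model.transition(float(tree.lengths[v]))
        ps[v] = m[0] if m.ndim == 3 else m
    total = 0.0
    for combo in itertools.product(range(20), repeat=len(free_nodes)):
        state = dict(fixed)
        state.update(dict(zip(free_nodes, combo)))
        prob = pi[state[tree.root]]
        for v in tree.branches():
            prob *= ps[v][state[tree.parent[v]], state[v]]
        total += prob
    return total


def brute_force_node_posterior(tree: PhyloTree, model, column: dict, node: int) -> np.ndarray:
    """P(state at one internal node | column) by enumeration."""
    from molevoscreen.alignments import AA_INDEX

    free_nodes = []
    fixed = {}
    for v in range(tree.n_nodes):
        if tree.is_leaf(v):
            res = column[tree.leaf_name[v]]
            if res in AA_INDEX:
                fixed[v] = AA_INDEX[res]
            else:
                free_nodes.append(v)
        else:
            free_nodes.append(v)
    pi = np.atleast_2d(model.pi())[0]
    ps = {}
    for v in tree.branches():
        m = model.transition(float(tree.lengths[v]))
        ps[v] = m[0] if m.ndim == 3 else m
    joint = np.zeros(20)
    for combo in itertools.product(range(20), repeat=len(free_nodes)):
        state = dict(fixed)
        state.update(dict(zip(free_nodes, combo)))
        prob = pi[state[tree.root]]
        for v in tree.branches():
            prob *= ps[v][state[tree.parent[v]], state[v]]
        joint[state[node]] += prob
    return joint / joint.sum()


@pytest.fixture(scope="session")
def fourfold_fixture():
    """Hand-built 100-codon alignment with exactly 7 fourfold-degenerate
    columns (known positions), plus distractor columns."""
    rng = np.random.default_rng(42)
    taxa = ["a", "b", "c", "d"]
    n_codons = 100
    fourfold_cols = [3, 17, 30, 44, 58, 71, 99]
    fourfold_prefixes = ["GG", "GC", "CC", "AC", "GT", "CT", "TC"]
    twofold_cols = {10: "AA", 25: "GA", 60: "TT"}  # AAx/GAx/TTx: not fourfold
    mixed_col = 80  # fourfold families but different prefixes across taxa
    gap_col = 90  # fourfold prefix but one taxon gapped
    third = "ACGT"
    seqs = {t: [] for t in taxa}
    for i in range(n_codons):
        if i in fourfold_cols:
            prefix = fourfold_prefixes[fourfold_cols.index(i)]
            for t in taxa:
                seqs[t].append(prefix + third[rng.integers(4)])
        elif i in twofold_cols:
            prefix = twofold_cols[i]
            for t in taxa:
                seqs[t].append(prefix + ("A" if rng.random() < 0.5 else "G"))
        elif i == mixed_col:
            for t, pref in zip(taxa, ["GG", "GC", "GG", "CC"]):
                seqs[t].append(pref + third[rng.integers(4)])
        elif i == gap_col:
            for t in taxa:
                seqs[t].append("---" if t == "d" else "GG" + third[rng.integers(4)])
        else:
            codon = ["ATG", "TGG", "AAA", "CAT", "GAA"][rng.integers(5)]
            for t in taxa:
                seqs[t].append(codon)
    aln = Alignment([(t, "".join(seqs[t])) for t in taxa], kind="codon")
    return aln, fourfold_cols
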