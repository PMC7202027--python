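"""Felsenstein pruning and marginal ancestral sequence reconstruction.

The down-pass computes per-node conditional ("below") partial likelihoods
with per-site rescaling; the up-pass propagates "above" partials from the
root, giving each internal node's marginal posterior over residues
(empirical Bayes, integrating over all other nodes).  The most probable
(MAP) state per node and site is recorded, with ties resolved to the
alphabetically earlier residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignments import AMINO_ACIDS, AA_INDEX, Alignment
from .substmodels import AminoAcidModel
from .trees import PhyloTree

_TINY = 1e-300


def _branch_transitions(tree: PhyloTree, model: AminoAcidModel, n_sites: int):
    """Per-branch P(t): (20, 20) or (L, 20, 20) arrays keyed by node."""
    ps = {}
    for v in tree.branches():
        t = tree.lengths[v]
        if np.isnan(t):
            raise ValueError(f"branch {tree.branch_id(v)} has no length")
        ps[v] = model.transition(t)
    return ps


def _message(p: np.ndarray, below: np.ndarray) -> np.ndarray:
    """Sum_j P[i, j] * below[s, j] for flat or site-specific P."""
    if p.ndim == 2:
        return below @ p.T
    return np.einsum("sij,sj->si", p, below)


def _down_pass(tree: PhyloTree, ps, leaf_states: np.ndarray, taxon_col: Mapping[str, int]):
    """Below partials and per-site log scaling factors for every node."""
    n_sites = leaf_states.shape[0]
    below = {}
    log_scale = {}
    messages = {}
    for v in tree.postorder:
        if tree.is_leaf(v):
            obs = leaf_states[:, taxon_col[tree.leaf_name[v]]]
            part = np.ones((n_sites, 20))
            scored = obs >= 0
            part[scored] = 0.0
            part[np.flatnonzero(scored), obs[scored].astype(int)] = 1.0
            below[v] = part
            log_scale[v] = np.zeros(n_sites)
        else:
            part = np.ones((n_sites, 20))
            ls = np.zeros(n_sites)
            for c in tree.children[v]:
                m = _message(ps[c], below[c])
                messages[c] = m
                part = part * m
                ls = ls + log_scale[c]
            mx = part.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            below[v] = part / mx[:, None]
            log_scale[v] = ls + np.log(np.maximum(mx, _TINY))
    # messages for leaves hanging off the root path may still be needed
    for v in tree.branches():
        if v not in messages:
            messages[v] = _message(ps[v], below[v])
    return below, log_scale, messages


def _root_pi(model: AminoAcidModel, n_sites: int) -> np.ndarray:
    pi = model.pi()
    if pi.ndim == 1:
        return np.broadcast_to(pi, (n_sites, 20))
    return pi


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and MAP states at every internal node."""

    tree: PhyloTree
    node_posteriors: dict[int, np.ndarray]  # node -> (L, 20)
    map_states: dict[int, np.ndarray]  # node -> (L,) int
    site_log_likelihoods: np.ndarray  # (L,)
    leaf_states: np.ndarray  # (L, n_taxa)
    taxon_col: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.site_log_likelihoods.shape[0]

    def total_log_likelihood(self) -> float:
        return float(self.site_log_likelihoods.sum())

    def states_at(self, node: int) -> np.ndarray:
        """(L,) state indices: observed at leaves, MAP at internal nodes.

        Gap/ambiguous leaf positions are -1.
        """
        if self.tree.is_leaf(node):
            return self.leaf_states[:, self.taxon_col[self.tree.leaf_name[node]]]
        return self.map_states[node]

    def node_label(self, node: int) -> str:
        if node == self.tree.root:
            return "root"
        return self.tree.branch_id(node)

    def to_tsv(self, path: str | Path) -> None:
        """Dump node, site (1-based), MAP residue, max posterior."""
        with open(path, "w") as fh:
            fh.write("node\tsite\tmap_residue\tmax_posterior\n")
            for v in sorted(self.node_posteriors):
                post = self.node_posteriors[v]
                states = self.map_states[v]
                label = self.node_label(v)
                for s in range(post.shape[0]):
                    fh.write(
                        f"{label}\t{s + 1}\t{AMINO_ACIDS[states[s]]}\t"
                        f"{post[s, states[s]]:.6f}\n"
                    )


def _check_taxa(tree: PhyloTree, taxa) -> None:
    if set(tree.leaves) != set(taxa):
        missing = set(tree.leaves) ^ set(taxa)
        raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")


def marginal_reconstruct(
    tree: PhyloTree,
    model: AminoAcidModel,
    alignment: Alignment,
) -> AncestralReconstruction:
    """Marginal (empirical Bayes) reconstruction of all internal nodes."""
    _check_taxa(tree, alignment.taxa)
    leaf_states = alignment.protein_states()
    n_sites = leaf_states.shape[0]
    if model.site_specific and model.n_sites != n_sites:
        raise ValueError("site-specific model length does not match alignment")
    taxon_col = {t: j for j, t in enumerate(alignment.taxa)}
    ps = _branch_transitions(tree, model, n_sites)
    below, log_scale, messages = _down_pass(tree, ps, leaf_states, taxon_col)

    pi = _root_pi(model, n_sites)
    root_like = (pi * below[tree.root]).sum(axis=1)
    site_ll = np.log(np.maximum(root_like, _TINY)) + log_scale[tree.root]
    site_ll[root_like <= 0] = -np.inf

    # up-pass
    above = {tree.root: pi.copy()}
    posteriors: dict[int, np.ndarray] = {}
    map_states: dict[int, np.ndarray] = {}

    def norm_post(v: int) -> None:
        post = below[v] * above[v]
        tot = post.sum(axis=1, keepdims=True)
        tot = np.where(tot > 0, tot, 1.0)
        post = post / tot
        posteriors[v] = post
        map_states[v] = post.argmax(axis=1).astype(np.int8)

    norm_post(tree.root)
    for v in reversed(tree.postorder):  # preorder
        for c in tree.children[v]:
            pre = above[v].copy()
            for w in tree.children[v]:
                if w is not c:
                    pre = pre * messages[w]
            mx = pre.max(axis=1, keepdims=True)
            pre = pre / np.where(mx > 0, mx, 1.0)
            p = ps[c]
            if p.ndim == 2:
                above[c] = pre @ p
            else:
                above[c] = np.einsum("sji,sj->si", p, pre)
            if not tree.is_leaf(c):
                norm_post(c)
    return AncestralReconstruction(
        tree=tree,
        node_posteriors=posteriors,
        map_states=map_states,
        site_log_likelihoods=site_ll,
        leaf_states=leaf_states,
        taxon_col=taxon_col,
    )


def site_log_likelihood(
    tree: PhyloTree,
    model: AminoAcidModel,
    column: Mapping[str, str],
) -> float:
    """Log-likelihood of a single alignment column under the model.

    ``column`` maps every leaf to a one-letter residue (or ``-`` for a
    gap, contributing an all-ones partial).
    """
    _check_taxa(tree, column.keys())
    taxa = list(column)
    states = np.array([[AA_INDEX.get(column[t], -1) for t in taxa]], dtype=np.int8)
    taxon_col = {t: j for j, t in enumerate(taxa)}
    ps = _branch_transitions(tree, model, 1)
    below, log_scale, _ = _down_pass(tree, ps, states, taxon_col)
    pi = _root_pi(model, 1)
    like = float((pi[0] * below[tree.root][0]).sum())
    if like <= 0:
        return -np.inf
    return float(np.log(like) + log_scale[tree.root][0])


def alignment_log_likelihood(
    tree: PhyloTree, model: AminoAcidModel, alignment: Alignment
) -> float:
    """Whole-alignment log-likelihood (sum of independent site terms)."""
    return marginal_reconstruct(tree, model, alignment).total_log_likelihood()
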