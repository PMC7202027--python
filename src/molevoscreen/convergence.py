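"""Convergent/parallel substitution detection and model-based null tests.

A substitution on branch pair (A, B) at one site is classified from the
(parent, child) states of each branch: both branches substituting to the
same residue is *convergent* when the two ancestral residues differ and
*parallel* when they coincide; both substituting to different residues is
*divergent*.  Expected numbers of convergent/parallel events under the
substitution model (the chance null) are sums over sites of per-site event
probabilities, integrating ancestral-state uncertainty; observed counts are
tested against the Poisson-binomial (or Poisson) tail of that null —
the per-gene chance-convergence test of Zhang & Kumar.  Across many branch
pairs, an ordinary least-squares regression of convergent+parallel counts
on divergent counts provides the genome-wide empirical null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .ancestral import AncestralReconstruction
from .substmodels import AminoAcidModel
from .trees import PhyloTree

#: Site classification codes.
SITE_CLASSES = ("none", "single", "convergent", "parallel", "divergent", "excluded")
_NONE, _SINGLE, _CONV, _PAR, _DIV, _EXCL = range(6)


@dataclass
class BranchPairProfile:
    """Observed per-site substitution classification for one branch pair."""

    branch_a: str
    branch_b: str
    site_class: np.ndarray  # (L,) int8 codes into SITE_CLASSES

    @property
    def n_conv(self) -> int:
        return int((self.site_class == _CONV).sum())

    @property
    def n_par(self) -> int:
        return int((self.site_class == _PAR).sum())

    @property
    def n_div(self) -> int:
        return int((self.site_class == _DIV).sum())

    @property
    def n_both_substituted(self) -> int:
        """Sites where both branches carry a substitution (conv+par+div)."""
        return self.n_conv + self.n_par + self.n_div

    @property
    def scorable(self) -> np.ndarray:
        return self.site_class != _EXCL

    def sites_of(self, cls: str) -> np.ndarray:
        """0-based site indices of one class."""
        return np.flatnonzero(self.site_class == SITE_CLASSES.index(cls))

    def per_site_class(self) -> list[str]:
        return [SITE_CLASSES[c] for c in self.site_class]


@dataclass
class PairCounts:
    """Aggregated substitution counts for one branch pair (e.g. summed
    across the genes of a genome-wide screen); duck-typed like
    :class:`BranchPairProfile` for the regression null."""

    branch_a: str
    branch_b: str
    n_conv: int
    n_par: int
    n_div: int

    @property
    def n_both_substituted(self) -> int:
        return self.n_conv + self.n_par + self.n_div


def _pair_nodes(tree: PhyloTree, pair: tuple[str, str]) -> tuple[int, int]:
    va, vb = tree.branch(pair[0]), tree.branch(pair[1])
    if tree.is_nested(pair[0], pair[1]):
        raise ValueError(
            f"nested branch pair ({pair[0]!r}, {pair[1]!r}): "
            "independent derivation is undefined along one lineage"
        )
    return va, vb


def classify_site(a1: int, d1: int, a2: int, d2: int) -> int:
    """Classify one site from the two branches' (ancestor, descendant) states."""
    if min(a1, d1, a2, d2) < 0:
        return _EXCL
    s1, s2 = a1 != d1, a2 != d2
    if s1 and s2:
        if d1 == d2:
            return _PAR if a1 == a2 else _CONV
        return _DIV
    if s1 or s2:
        return _SINGLE
    return _NONE


def classify_branch_pair(
    recon: AncestralReconstruction, pair: tuple[str, str]
) -> BranchPairProfile:
    """Classify every site of a reconstruction on a non-nested branch pair.

    Parent states are MAP ancestral states; child states are observed
    residues at leaves and MAP states at internal nodes.  Sites with a gap
    or ambiguity in any of the four states are ``excluded``.
    """
    tree = recon.tree
    va, vb = _pair_nodes(tree, pair)
    a1 = np.asarray(recon.states_at(tree.parent[va]), dtype=int)
    d1 = np.asarray(recon.states_at(va), dtype=int)
    a2 = np.asarray(recon.states_at(tree.parent[vb]), dtype=int)
    d2 = np.asarray(recon.states_at(vb), dtype=int)
    sub1, sub2 = a1 != d1, a2 != d2
    both, same_dest = sub1 & sub2, d1 == d2
    codes = np.full(recon.n_sites, _NONE, dtype=np.int8)
    codes[sub1 ^ sub2] = _SINGLE
    codes[both & ~same_dest] = _DIV
    codes[both & same_dest & (a1 != a2)] = _CONV
    codes[both & same_dest & (a1 == a2)] = _PAR
    codes[(a1 < 0) | (d1 < 0) | (a2 < 0) | (d2 < 0)] = _EXCL
    return BranchPairProfile(tree.branch_id(va), tree.branch_id(vb), codes)


# --------------------------------------------------------------------------
# Expected counts under the substitution model
# --------------------------------------------------------------------------


@dataclass
class ConvergenceTest:
    """Model-based null expectations and tail probabilities for one pair."""

    branch_a: str
    branch_b: str
    per_site_conv: np.ndarray
    per_site_par: np.ndarray
    method: str = "poisson_binomial"
    observed_conv: int | None = None
    observed_par: int | None = None
    p_conv: float | None = None
    p_par: float | None = None
    p_joint: float | None = None

    @property
    def expected_conv(self) -> float:
        return float(self.per_site_conv.sum())

    @property
    def expected_par(self) -> float:
        return float(self.per_site_par.sum())


def _site_transitions(model: AminoAcidModel, t: float, n_sites: int) -> np.ndarray:
    p = model.transition(t)
    if p.ndim == 2:
        return np.broadcast_to(p, (n_sites, 20, 20))
    return p


def expected_counts(
    model: AminoAcidModel,
    recon: AncestralReconstruction,
    pair: tuple[str, str],
    site_mask: np.ndarray | None = None,
    use_map_ancestors: bool = False,
) -> ConvergenceTest:
    """Per-site chance probabilities of convergent and parallel events.

    For each site the probability of each ancestral-state pair (a1, a2) is
    taken from the marginal posteriors of the two parent nodes (their
    product when the parents differ; the shared marginal when the branches
    are sisters), and multiplied by the probability that both branches end
    in the same residue d under the classification's constraints.  Summing
    over sites gives the expected counts ("the null").
    """
    tree = recon.tree
    va, vb = _pair_nodes(tree, pair)
    ta, tb = tree.lengths[va], tree.lengths[vb]
    if np.isnan(ta) or np.isnan(tb):
        raise ValueError("branch lengths missing for tested pair")
    n_sites = recon.n_sites
    pa_node, pb_node = int(tree.parent[va]), int(tree.parent[vb])
    post_a = recon.node_posteriors[pa_node]
    post_b = recon.node_posteriors[pb_node]
    if use_map_ancestors:
        post_a = _one_hot(recon.map_states[pa_node])
        post_b = _one_hot(recon.map_states[pb_node])

    pa = _site_transitions(model, float(ta), n_sites)
    pb = _site_transitions(model, float(tb), n_sites)
    s1 = np.einsum("sad,sbd->sab", pa, pb)  # sum_d PA[a1,d] PB[a2,d]
    diag_a = np.einsum("saa->sa", pa)
    diag_b = np.einsum("saa->sa", pb)
    # subtract d = a1 and d = a2 terms (distinct when a1 != a2)
    same_dest = s1 - np.einsum("sa,sba->sab", diag_a, pb) - pa * diag_b[:, None, :]

    if pa_node == pb_node:
        w_diag = post_a
        w_off = np.zeros((n_sites, 20, 20))
    else:
        w_off = post_a[:, :, None] * post_b[:, None, :]
        w_diag = np.einsum("saa->sa", w_off).copy()
        idx = np.arange(20)
        w_off = w_off.copy()
        w_off[:, idx, idx] = 0.0

    per_site_conv = np.einsum("sab,sab->s", w_off, np.clip(same_dest, 0.0, None))
    idx = np.arange(20)
    par_kernel = np.clip(s1[:, idx, idx] - diag_a * diag_b, 0.0, None)
    per_site_par = (w_diag * par_kernel).sum(axis=1)

    if site_mask is not None:
        per_site_conv = np.where(site_mask, per_site_conv, 0.0)
        per_site_par = np.where(site_mask, per_site_par, 0.0)
    return ConvergenceTest(
        tree.branch_id(va), tree.branch_id(vb), per_site_conv, per_site_par
    )


def _one_hot(states: np.ndarray) -> np.ndarray:
    out = np.zeros((states.shape[0], 20))
    out[np.arange(states.shape[0]), states.astype(int)] = 1.0
    return out


def tail_probability(
    per_site_probs: Sequence[float], observed: int, method: str = "poisson_binomial"
) -> float:
    """P(X >= observed) for the sum X of independent per-site Bernoullis.

    ``poisson_binomial`` computes the exact tail by dynamic-programming
    convolution; ``poisson`` uses the Poisson approximation with mean equal
    to the summed probabilities.
    """
    probs = np.asarray(per_site_probs, dtype=float)
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("per-site probabilities must lie in [0, 1]")
    if observed == 0:
        return 1.0
    if method == "poisson":
        return float(scipy.stats.poisson.sf(observed - 1, probs.sum()))
    if method != "poisson_binomial":
        raise ValueError(f"unknown method {method!r}")
    # P(X <= observed-1) by truncated convolution over counts 0..observed-1
    k = observed
    dist = np.zeros(k)  # P(X = 0..k-1); mass escaping past k-1 is the tail
    dist[0] = 1.0
    for p in probs:
        shifted = np.empty_like(dist)
        shifted[0] = 0.0
        shifted[1:] = dist[:-1] * p
        dist = dist * (1.0 - p) + shifted
    return float(min(max(1.0 - dist.sum(), 0.0), 1.0))


def zhang_kumar_test(
    model: AminoAcidModel,
    recon: AncestralReconstruction,
    pair: tuple[str, str],
    profile: BranchPairProfile | None = None,
    method: str = "poisson_binomial",
    use_map_ancestors: bool = False,
) -> ConvergenceTest:
    """Per-gene test of observed convergent/parallel counts against chance.

    Expectations are restricted to the sites scorable in the observed
    classification, so observed and expected counts cover the same sites.
    """
    if profile is None:
        profile = classify_branch_pair(recon, pair)
    test = expected_counts(
        model, recon, pair, site_mask=profile.scorable, use_map_ancestors=use_map_ancestors
    )
    test.method = method
    test.observed_conv = profile.n_conv
    test.observed_par = profile.n_par
    test.p_conv = tail_probability(test.per_site_conv, profile.n_conv, method)
    test.p_par = tail_probability(test.per_site_par, profile.n_par, method)
    test.p_joint = tail_probability(
        test.per_site_conv + test.per_site_par, profile.n_conv + profile.n_par, method
    )
    return test


# --------------------------------------------------------------------------
# Genome-wide regression null
# --------------------------------------------------------------------------


@dataclass
class RegressionNull:
    """OLS of convergent+parallel counts on divergence across branch pairs."""

    points: pd.DataFrame  # pair_a, pair_b, n_div, n_convpar, residual, student_resid, p_excess
    slope: float
    intercept: float
    r_squared: float
    alpha: float = 0.05

    @property
    def flagged(self) -> pd.DataFrame:
        """Pairs with one-sided significant excess of convergent+parallel."""
        return self.points[self.points["p_excess"] < self.alpha]


def genome_regression_null(
    profiles: Sequence[BranchPairProfile],
    divergence: str = "divergent",
    alpha: float = 0.05,
) -> RegressionNull:
    """Fit the empirical chance-convergence line across branch pairs.

    ``divergence`` selects the x-axis: the strict ``divergent`` class or
    ``both`` (all sites where both branches substituted).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 branch pairs for the regression null")
    x = np.array(
        [p.n_div if divergence == "divergent" else p.n_both_substituted for p in profiles],
        dtype=float,
    )
    y = np.array([p.n_conv + p.n_par for p in profiles], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regression: all divergence counts identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if model.ssr < 1e-10:  # numerically perfect fit: no outliers by definition
        student = np.zeros(len(x))
    else:
        influence = model.get_influence()
        student = influence.resid_studentized_external
    df_resid = int(model.df_resid) - 1  # external studentization drops one obs
    p_excess = scipy.stats.t.sf(student, df=max(df_resid, 1))
    points = pd.DataFrame(
        {
            "pair_a": [p.branch_a for p in profiles],
            "pair_b": [p.branch_b for p in profiles],
            "n_div": x.astype(int),
            "n_convpar": y.astype(int),
            "residual": model.resid,
            "student_resid": student,
            "p_excess": p_excess,
        }
    )
    return RegressionNull(
        points=points,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        alpha=alpha,
    )
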