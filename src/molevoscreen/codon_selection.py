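"""Codon-level selection inference.

Implements fourfold-degenerate site extraction, maximum-likelihood fits of
the GY94 codon model with one omega per branch (free-ratio), the
branch-site "model A" positive-selection test with its likelihood-ratio
test and per-site empirical-Bayes class posteriors, and Benjamini-Hochberg
FDR adjustment.

The likelihood engine prunes over the 61 sense codons with site-pattern
compression and per-site rescaling.  Branch-local parameter updates use the
standard factorization L_site = f' P(t) g, where f collects the partial
likelihood from the rest of the tree at the branch's parent and g the
partial below its child: re-optimizing one branch's (t, omega) then costs
one 61x61 eigendecomposition per trial value instead of a full pruning
pass.  The same factorization evaluates the branch-site foreground classes
(2a, 2b) from the two background prunings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import scipy.optimize
import scipy.stats
from scipy.special import expit, logsumexp
from statsmodels.stats.multitest import multipletests

from .alignments import (
    CODON_AA,
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    Alignment,
    FrameError,
)
from .substmodels import CodonEig, codon_frequencies, nonsyn_flux_fraction, total_flux
from .trees import PhyloTree

logger = logging.getLogger(__name__)

N_CODONS = len(SENSE_CODONS)
_TINY = 1e-300

OMEGA_MAX = 999.0
DS_FLOOR = 1e-8

#: First-two-nucleotide families whose third position is fourfold degenerate.
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
)


# --------------------------------------------------------------------------
# Fourfold-degenerate sites
# --------------------------------------------------------------------------


def extract_4d_sites(codon_alignment: Alignment) -> Alignment:
    """Third positions of codon columns that are fourfold degenerate in
    every taxon.

    A column qualifies when all taxa carry unambiguous codons sharing the
    same first two nucleotides and that dinucleotide starts a fourfold
    codon family (so any third-position mutation is synonymous in every
    lineage).  The returned nucleotide alignment carries the qualifying
    0-based codon column indices as ``source_columns``.
    """
    if codon_alignment.kind != "codon":
        raise FrameError("extract_4d_sites requires an in-frame codon alignment")
    codon_alignment.codon_states()  # frame + internal-stop validation
    n = codon_alignment.n_sites
    cols: list[int] = []
    pieces = {t: [] for t in codon_alignment.taxa}
    valid = set("ACGT")
    for i in range(n):
        col = codon_alignment.column(i)
        prefixes = set()
        ok = True
        for codon in col.values():
            if any(c not in valid for c in codon):
                ok = False
                break
            prefixes.add(codon[:2])
        if not ok or len(prefixes) != 1:
            continue
        if next(iter(prefixes)) not in FOURFOLD_PREFIXES:
            continue
        cols.append(i)
        for t, codon in col.items():
            pieces[t].append(codon[2])
    out = Alignment(
        [(t, "".join(pieces[t])) for t in codon_alignment.taxa], kind="nucleotide"
    )
    out.source_columns = cols
    return out


# --------------------------------------------------------------------------
# Likelihood engine
# --------------------------------------------------------------------------


class CodonEngine:
    """Pattern-compressed pruning over sense codons on a fixed tree."""

    def __init__(self, tree: PhyloTree, alignment: Alignment, pi: np.ndarray):
        if set(tree.leaves) != set(alignment.taxa):
            raise ValueError("tree/alignment taxon mismatch")
        self.tree = tree
        self.pi = pi
        states = alignment.codon_states()
        patterns, inverse, counts = np.unique(
            states, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_patterns, n_taxa)
        self.pattern_of_site = inverse
        self.weights = counts.astype(float)
        self.n_sites = states.shape[0]
        self.taxon_col = {t: j for j, t in enumerate(alignment.taxa)}
        self._leaf_partials = {}
        for v in tree.branches():
            if tree.is_leaf(v):
                obs = self.patterns[:, self.taxon_col[tree.leaf_name[v]]]
                part = np.ones((patterns.shape[0], N_CODONS))
                scored = obs >= 0
                part[scored] = 0.0
                part[np.flatnonzero(scored), obs[scored].astype(int)] = 1.0
                self._leaf_partials[v] = part

    def _below_pass(self, branch_p: dict[int, np.ndarray]):
        """Below partials, per-child messages, and log scalers."""
        tree = self.tree
        npat = self.patterns.shape[0]
        below, bscale, msg = {}, {}, {}
        for v in tree.postorder:
            if tree.is_leaf(v):
                below[v] = self._leaf_partials[v]
                bscale[v] = np.zeros(npat)
            else:
                part = np.ones((npat, N_CODONS))
                ls = np.zeros(npat)
                for c in tree.children[v]:
                    m = below[c] @ branch_p[c].T
                    msg[c] = m
                    part = part * m
                    ls = ls + bscale[c]
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                below[v] = part / mx[:, None]
                bscale[v] = ls + np.log(np.maximum(mx, _TINY))
        return below, bscale, msg

    def pattern_logliks(
        self, branch_p: dict[int, np.ndarray], passes=None
    ) -> np.ndarray:
        """Per-pattern site log-likelihoods."""
        below, bscale, _ = passes or self._below_pass(branch_p)
        root = self.tree.root
        like = (self.pi * below[root]).sum(axis=1)
        return np.log(np.maximum(like, _TINY)) + bscale[root]

    def loglik(self, branch_p: dict[int, np.ndarray]) -> float:
        return float(self.weights @ self.pattern_logliks(branch_p))

    def branch_context(self, branch_p: dict[int, np.ndarray], v: int, passes=None):
        """(f, g, log_scale) with pattern likelihood = sum_ij f_i P_ij g_j.

        ``f`` is the partial likelihood of everything outside branch v seen
        from its parent (above partials propagated along the root->v path
        only); ``g`` the below partial of its child node.
        """
        tree = self.tree
        below, bscale, msg = passes or self._below_pass(branch_p)
        # path root -> v
        path = [v]
        while path[-1] != tree.root:
            path.append(int(tree.parent[path[-1]]))
        path.reverse()  # root ... v
        pre = np.broadcast_to(self.pi, below[tree.root].shape)
        ls = np.zeros(self.patterns.shape[0])
        for u, nxt in zip(path[:-1], path[1:]):
            for w in tree.children[u]:
                if w != nxt:
                    pre = pre * msg[w]
                    ls = ls + bscale[w]
            if nxt != v:
                mx = pre.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                pre = (pre / mx[:, None]) @ branch_p[nxt]
                ls = ls + np.log(np.maximum(mx, _TINY))
        return pre, below[v], ls + bscale[v]

    def context_loglik(self, f, g, scale, p: np.ndarray) -> np.ndarray:
        like = ((f @ p) * g).sum(axis=1)
        return np.log(np.maximum(like, _TINY)) + scale

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map per-pattern values back to per-site values."""
        return per_pattern[self.pattern_of_site]


def _branch_transitions(
    tree: PhyloTree, eigs: dict[int, CodonEig], lengths: np.ndarray
) -> dict[int, np.ndarray]:
    return {v: eigs[v].transition(float(lengths[v])) for v in tree.branches()}


# --------------------------------------------------------------------------
# Free-ratio model
# --------------------------------------------------------------------------


@dataclass
class BranchRates:
    """Per-branch (dN, dS, omega, t) and the fit's log-likelihood."""

    rates: dict[str, tuple[float, float, float, float]]
    log_likelihood: float
    kappa: float
    converged: bool = True

    def omega(self, branch: str) -> float:
        return self.rates[branch][2]

    def dn(self, branch: str) -> float:
        return self.rates[branch][0]

    def ds(self, branch: str) -> float:
        return self.rates[branch][1]


def _dn_ds(t: float, kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Decompose a branch's expected substitutions into dN and dS.

    With Q normalized to one substitution per codon per unit t, the
    nonsynonymous flux fraction splits t; site counts use the neutral
    (omega=1) flux fraction, as in the usual codon-model N/S bookkeeping.
    """
    a = nonsyn_flux_fraction(kappa, omega, pi)
    rho1 = nonsyn_flux_fraction(kappa, 1.0, pi)
    dn = t * a / (3.0 * rho1)
    ds = t * (1.0 - a) / (3.0 * (1.0 - rho1))
    return dn, ds


def free_ratio_fit(
    codon_alignment: Alignment,
    tree: PhyloTree,
    freq_mode: str = "F3x4",
    kappa_init: float = 2.0,
    omega_init: float = 0.4,
    rounds: int = 2,
    tol: float = 1e-6,
) -> BranchRates:
    """ML fit of GY94 with an independent omega on every branch.

    Shared kappa and empirical codon frequencies; branch lengths and
    per-branch omegas optimized by coordinate ascent (global M0-style
    stage, then per-branch (t, omega) updates via the branch
    factorization, then a kappa refresh), which converges quickly because
    branch parameters are nearly separable given kappa.
    """
    if len(tree.leaves) < 2:
        raise ValueError("free-ratio fit needs at least 2 taxa")
    pi = codon_frequencies(codon_alignment, freq_mode)
    engine = CodonEngine(tree, codon_alignment, pi)
    branches = tree.branches()
    nb = len(branches)
    t0 = np.array(
        [tree.lengths[v] if np.isfinite(tree.lengths[v]) else 0.1 for v in branches]
    )
    t0 = np.clip(t0, 1e-4, 50.0)

    eig_cache: dict[tuple[float, float], CodonEig] = {}

    def eig(kappa: float, omega: float) -> CodonEig:
        key = (round(kappa, 10), round(omega, 10))
        if key not in eig_cache:
            eig_cache[key] = CodonEig(kappa, omega, pi)
        return eig_cache[key]

    def loglik(kappa: float, omegas: np.ndarray, ts: np.ndarray) -> float:
        bp = {
            v: eig(kappa, float(omegas[i])).transition(float(ts[i]))
            for i, v in enumerate(branches)
        }
        return engine.loglik(bp)

    # ---- stage 1: shared-omega (M0) fit of kappa, omega, branch scale
    def m0_obj(x):
        kappa, omega, scale = np.exp(x)
        return -loglik(kappa, np.full(nb, omega), t0 * scale)

    res = scipy.optimize.minimize(
        m0_obj,
        np.log([kappa_init, omega_init, 1.0]),
        method="L-BFGS-B",
        bounds=[(-4, 5), (-12, 5), (-5, 4)],
        options={"maxiter": 200},
    )
    kappa, omega0, scale = np.exp(res.x)
    omegas = np.full(nb, omega0)
    ts = t0 * scale
    lnl = prev = -res.fun

    # ---- stage 2: per-branch (t, omega) coordinate updates
    for _ in range(rounds):
        prev = lnl
        for i, v in enumerate(branches):
            bp = {
                w: eig(kappa, float(omegas[j])).transition(float(ts[j]))
                for j, w in enumerate(branches)
            }
            f, g, sc = engine.branch_context(bp, v)

            def branch_obj(x):
                t_b, w_b = np.exp(x)
                p = eig(kappa, min(w_b, OMEGA_MAX)).transition(t_b)
                ll = engine.context_loglik(f, g, sc, p)
                return -float(engine.weights @ ll)

            r = scipy.optimize.minimize(
                branch_obj,
                np.log([max(ts[i], 1e-4), max(omegas[i], 1e-6)]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200},
            )
            ts[i], omegas[i] = np.exp(r.x)
            omegas[i] = min(omegas[i], OMEGA_MAX)

        def kappa_obj(lk):
            return -loglik(float(np.exp(lk)), omegas, ts)

        r = scipy.optimize.minimize_scalar(
            kappa_obj, bounds=(-4, 5), method="bounded", options={"xatol": 1e-4}
        )
        kappa = float(np.exp(r.x))
        lnl = -r.fun
        if abs(lnl - prev) < tol:
            break

    # joint refinement for small trees: with few branches the (t, omega)
    # parameters are strongly coupled (near-ridges), where coordinate
    # ascent converges slowly; a joint quasi-Newton polish is cheap there
    if nb <= 6:
        def joint_obj(x):
            kap = float(np.exp(x[0]))
            om = np.exp(x[1 : 1 + nb])
            tt = np.exp(x[1 + nb :])
            return -loglik(kap, np.minimum(om, OMEGA_MAX), tt)

        x0 = np.concatenate([[np.log(kappa)], np.log(np.maximum(omegas, 1e-8)),
                             np.log(np.maximum(ts, 1e-8))])
        bounds = [(-4, 5)] + [(-14, np.log(OMEGA_MAX))] * nb + [(-16, 4)] * nb
        res = scipy.optimize.minimize(
            joint_obj, np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B", bounds=bounds, options={"maxiter": 500, "ftol": 1e-12},
        )
        if -res.fun > lnl:
            lnl = -res.fun
            kappa = float(np.exp(res.x[0]))
            omegas = np.minimum(np.exp(res.x[1 : 1 + nb]), OMEGA_MAX)
            ts = np.exp(res.x[1 + nb :])

    converged = True
    if lnl < prev - 1e-6:
        converged = False
        warnings.warn(f"free-ratio fit not converged (delta lnL {lnl - prev:.3g})")

    rates = {}
    for i, v in enumerate(branches):
        dn, ds = _dn_ds(float(ts[i]), kappa, float(omegas[i]), pi)
        rates[tree.branch_id(v)] = (dn, ds, float(omegas[i]), float(ts[i]))
    return BranchRates(rates=rates, log_likelihood=float(lnl), kappa=kappa, converged=converged)


# --------------------------------------------------------------------------
# Branch-site model A
# --------------------------------------------------------------------------


@dataclass
class BranchSiteFit:
    """Branch-site model A fit: alternative vs omega2=1 null, LRT, NEB sites."""

    lnl_alt: float
    lnl_null: float
    params_alt: dict[str, float]
    params_null: dict[str, float]
    lrt_stat: float = field(init=False)
    p_value: float = field(init=False)
    site_posteriors: np.ndarray | None = None  # P(class 2a|2b) per site, foreground
    fdr_q: float | None = None
    mixture_reference: bool = False

    def __post_init__(self) -> None:
        self.lrt_stat = 2.0 * (self.lnl_alt - self.lnl_null)
        stat = max(self.lrt_stat, 0.0)
        p = float(scipy.stats.chi2.sf(stat, df=1))
        if self.mixture_reference:
            p = 0.5 * p if stat > 0 else 1.0
        self.p_value = p

    def selected_sites(self, threshold: float = 0.95) -> list[tuple[int, float]]:
        """1-based sites with foreground positive-selection posterior above
        ``threshold``."""
        if self.site_posteriors is None:
            return []
        return [
            (i + 1, float(p))
            for i, p in enumerate(self.site_posteriors)
            if p >= threshold
        ]


def _model_a_unpack(x: np.ndarray, fix_omega2: bool):
    kappa = float(np.exp(x[0]))
    scale = float(np.exp(x[1]))
    q = float(expit(x[2]))  # p0 + p1
    r = float(expit(x[3]))  # p0 / (p0 + p1)
    omega0 = float(expit(x[4]))
    fg_t = float(np.exp(x[5]))  # foreground branch length (free, as in codeml)
    omega2 = 1.0 if fix_omega2 else 1.0 + float(np.exp(x[6]))
    probs = np.array([q * r, q * (1 - r), (1 - q) * r, (1 - q) * (1 - r)])
    return kappa, scale, probs, omega0, fg_t, min(omega2, OMEGA_MAX)


def _model_a_class_logliks(
    engine: CodonEngine,
    tree: PhyloTree,
    fg: int,
    lengths: np.ndarray,
    kappa: float,
    omega0: float,
    omega2: float,
    pi: np.ndarray,
):
    """Per-pattern log-likelihood for classes (0, 1, 2a, 2b).

    All class generators share the neutral (omega=1) normalization so the
    positive-selection class genuinely evolves faster; the overall rate
    unit is absorbed by the tree-scale parameter.
    """
    ref = total_flux(kappa, 1.0, pi)
    e0, e1, e2 = (CodonEig(kappa, w, pi, scale=ref) for w in (omega0, 1.0, omega2))
    p2 = e2.transition(float(lengths[fg]))
    out = np.empty((4, engine.patterns.shape[0]))
    for k, ebg in ((0, e0), (1, e1)):
        bp = {v: ebg.transition(float(lengths[v])) for v in tree.branches()}
        passes = engine._below_pass(bp)
        out[k] = engine.pattern_logliks(bp, passes=passes)
        f, g, sc = engine.branch_context(bp, fg, passes=passes)
        out[k + 2] = engine.context_loglik(f, g, sc, p2)
    return out  # rows: class0, class1, class2a, class2b


def _fit_model_a(
    engine: CodonEngine,
    tree: PhyloTree,
    fg: int,
    pi: np.ndarray,
    fix_omega2: bool,
    restarts: int,
    x0_extra: list[np.ndarray] | None = None,
    maxiter: int = 200,
):
    base_lengths = np.array(
        [tree.lengths[v] if np.isfinite(tree.lengths[v]) else 0.1 for v in range(tree.n_nodes)]
    )
    fg_t0 = float(base_lengths[fg]) if base_lengths[fg] > 0 else 0.1
    nparam = 6 if fix_omega2 else 7
    # the expensive class log-likelihoods depend only on the non-mixture
    # parameters; caching them makes finite-difference steps on the class
    # proportions nearly free
    ll_cache: dict[tuple, np.ndarray] = {}

    def objective(x):
        kappa, scale, probs, omega0, fg_t, omega2 = _model_a_unpack(x, fix_omega2)
        key = (
            round(kappa, 12), round(scale, 12), round(omega0, 12),
            round(fg_t, 12), round(omega2, 12),
        )
        class_ll = ll_cache.get(key)
        if class_ll is None:
            lengths = np.clip(base_lengths * scale, 1e-7, 60.0)
            lengths[fg] = fg_t
            class_ll = _model_a_class_logliks(
                engine, tree, fg, lengths, kappa, omega0, omega2, pi
            )
            if len(ll_cache) > 256:
                ll_cache.clear()
            ll_cache[key] = class_ll
        site_ll = logsumexp(class_ll, axis=0, b=probs[:, None])
        return -float(engine.weights @ site_ll)

    base_start = [np.log(2.0), 0.0, 1.5, 1.5, -2.0, np.log(fg_t0), -1.0]
    starts = [] if x0_extra else [np.array(base_start[:nparam])]
    rng = np.random.default_rng(12345)
    for s in range(max(restarts - 1, 0)):
        starts.append(np.array(base_start[:nparam]) + rng.normal(0, 0.8, size=nparam))
    if x0_extra:
        starts.extend(x0_extra)
    bounds = [
        (-3, 4), (-4, 4), (-9, 9), (-9, 9), (-9, 9), (-16, 4),
        (-9, np.log(OMEGA_MAX - 1)),
    ][:nparam]
    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            objective,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def branch_site_fit(
    codon_alignment: Alignment,
    tree: PhyloTree,
    foreground: str,
    freq_mode: str = "F3x4",
    restarts: int = 3,
    mixture_reference: bool = False,
    maxiter: int = 200,
) -> BranchSiteFit:
    """Branch-site positive-selection test on a designated foreground branch.

    Fits model A (site classes 0, 1, 2a, 2b; foreground omega2 free) and
    the null with omega2 fixed to 1; returns the LRT against chi-square
    with 1 df (or the 50:50 point-mass/chi-square mixture when
    ``mixture_reference``) and per-site NEB posteriors of the
    positive-selection classes on the foreground branch.
    """
    fg = tree.branch(foreground)
    pi = codon_frequencies(codon_alignment, freq_mode)
    engine = CodonEngine(tree, codon_alignment, pi)

    null = _fit_model_a(engine, tree, fg, pi, fix_omega2=True, restarts=restarts, maxiter=maxiter)
    # start the alternative from the null optimum, once with omega2 just
    # above 1 and once pushed into the selection regime (omega2 = 4 with a
    # non-vanishing 2a/2b proportion), which escapes the omega2 saddle when
    # the null absorbed selected sites into the neutral class
    null_seed = np.concatenate([null.x, [-4.0]])
    pushed = null.x.copy()
    pushed[2] = min(pushed[2], 1.4)  # p0+p1 <= ~0.80
    pushed_seed = np.concatenate([pushed, [np.log(3.0)]])
    alt = _fit_model_a(
        engine,
        tree,
        fg,
        pi,
        fix_omega2=False,
        restarts=restarts,
        x0_extra=[null_seed, pushed_seed],
        maxiter=maxiter,
    )
    lnl_alt, lnl_null = -float(alt.fun), -float(null.fun)
    if lnl_alt < lnl_null - 1e-6:
        # the null is nested in the alternative, so any deficit is optimizer
        # round-off; clamp (warn only when it exceeds rounding scale)
        log = logger.warning if lnl_alt < lnl_null - 0.01 else logger.debug
        log(
            "branch-site alternative below null (delta %.3g); clamping to null",
            lnl_alt - lnl_null,
        )
        lnl_alt = lnl_null

    kappa, scale, probs, omega0, fg_t, omega2 = _model_a_unpack(alt.x, fix_omega2=False)
    base_lengths = np.array(
        [tree.lengths[v] if np.isfinite(tree.lengths[v]) else 0.1 for v in range(tree.n_nodes)]
    )
    lengths = np.clip(base_lengths * scale, 1e-7, 60.0)
    lengths[fg] = fg_t
    class_ll = _model_a_class_logliks(engine, tree, fg, lengths, kappa, omega0, omega2, pi)
    log_weighted = np.log(np.maximum(probs[:, None], _TINY)) + class_ll
    log_tot = logsumexp(log_weighted, axis=0)
    post_sel = np.exp(logsumexp(log_weighted[2:], axis=0) - log_tot)

    kn, scn, pn, o0n, _, _ = _model_a_unpack(null.x, fix_omega2=True)
    fit = BranchSiteFit(
        lnl_alt=lnl_alt,
        lnl_null=lnl_null,
        params_alt={
            "kappa": kappa,
            "scale": scale,
            "fg_t": fg_t,
            "p0": float(probs[0]),
            "p1": float(probs[1]),
            "p2a": float(probs[2]),
            "p2b": float(probs[3]),
            "omega0": omega0,
            "omega2": omega2,
        },
        params_null={
            "kappa": kn,
            "scale": scn,
            "p0": float(pn[0]),
            "p1": float(pn[1]),
            "omega0": o0n,
            "omega2": 1.0,
        },
        site_posteriors=engine.expand(post_sel),
        mixture_reference=mixture_reference,
    )
    return fit


# --------------------------------------------------------------------------
# FDR and counting cross-check
# --------------------------------------------------------------------------


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _codon_syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible changes at one position that are synonymous."""
    aa = CODON_AA[CODON_INDEX[codon]]
    syn = tot = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        mut = codon[:pos] + nt + codon[pos + 1 :]
        if mut not in CODON_INDEX:
            continue  # change to stop: not counted as a site
        tot += 1
        if CODON_AA[CODON_INDEX[mut]] == aa:
            syn += 1
    return syn / 3.0


def pairwise_dnds_counting(seq1: str, seq2: str) -> tuple[float, float]:
    """Nei-Gojobori counting dN/dS for two in-frame sequences.

    Pathway-averaged difference counts, site counts averaged over both
    sequences, Jukes-Cantor correction.  Used as an independent
    cross-check of the likelihood fits on pairwise data.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise FrameError("sequences must be equal-length and in frame")
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue
        for c in (c1, c2):
            s = sum(_codon_syn_fraction(c, p) for p in range(3))
            s_sites += s / 2.0
            n_sites += (3.0 - s) / 2.0
        if c1 == c2:
            continue
        diff_pos = [p for p in range(3) if c1[p] != c2[p]]
        paths = list(permutations(diff_pos))
        path_nd = path_sd = 0.0
        n_valid = 0
        for order in paths:
            cur = c1
            pnd = psd = 0.0
            ok = True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt not in CODON_INDEX:
                    ok = False
                    break
                if CODON_AA[CODON_INDEX[cur]] == CODON_AA[CODON_INDEX[nxt]]:
                    psd += 1
                else:
                    pnd += 1
                cur = nxt
            if ok:
                n_valid += 1
                path_nd += pnd
                path_sd += psd
        if n_valid:
            nd += path_nd / n_valid
            sd += path_sd / n_valid
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0

    def jc(p):
        x = 1.0 - 4.0 * p / 3.0
        return -0.75 * np.log(x) if x > 0 else np.inf

    return float(jc(pn)), float(jc(ps))
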