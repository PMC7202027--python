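"""Amino-acid (JTT family) and codon (GY94) substitution models.

All rate matrices are time-reversible, built as ``Q[i, j] = S[i, j] * pi[j]``
from symmetric exchangeabilities ``S`` and equilibrium frequencies ``pi``,
and normalized to one expected substitution per site per unit branch length
(``-sum_i pi_i Q_ii = 1``).  Transition probabilities ``P(t) = exp(Qt)`` are
computed through the symmetric eigendecomposition of the
``diag(pi)^(1/2)``-similarity transform, which is numerically stable for
reversible generators.

The amino-acid model supports the JTT frequency family used for convergence
nulls: published JTT frequencies, gene-wide observed frequencies
(``JTT-Fgene``), or one frequency vector per alignment column
(``JTT-Fsite``).  The codon model is Goldman-Yang style: transition /
transversion ratio ``kappa``, selection ratio ``omega`` (globally, per
branch, or per site class), and F1x4/F3x4/F61 codon frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np

from .alignments import (
    AMINO_ACIDS,
    CODON_AA,
    NT_INDEX,
    SENSE_CODONS,
    Alignment,
    residue_counts,
)
from . import jtt_data

logger = logging.getLogger(__name__)

AA_MODES = ("JTT", "JTT-F", "JTT-Fgene", "JTT-Fsite")

# Reorder published JTT data (PAML residue order) into the package's
# alphabetical residue order.
_PERM = [jtt_data.PAML_ORDER.index(a) for a in AMINO_ACIDS]
JTT_EXCHANGEABILITIES = jtt_data.jtt_exchangeabilities_paml_order()[np.ix_(_PERM, _PERM)]
JTT_FREQUENCIES = jtt_data.jtt_frequencies_paml_order()[_PERM]
JTT_FREQUENCIES = JTT_FREQUENCIES / JTT_FREQUENCIES.sum()


def _assemble_q(s: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalized reversible generator(s) from exchangeabilities and pi.

    ``pi`` may be (k,) or batched (L, k); returns matching (k, k) or
    (L, k, k).
    """
    q = s * pi[..., None, :]
    rows = q.sum(axis=-1)
    idx = np.arange(s.shape[-1])
    q[..., idx, idx] -= rows
    mu = -(pi * q[..., idx, idx]).sum(axis=-1)
    return q / mu[..., None, None]


def _reversible_eig(s: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of the symmetrized generator.

    Returns (u, lam, sqrt_pi) with
    ``P(t) = diag(1/sqrt_pi) @ u @ diag(exp(lam t)) @ u.T @ diag(sqrt_pi)``.
    Supports batched ``pi`` of shape (L, k).
    """
    sqrt_pi = np.sqrt(pi)
    q = _assemble_q(s, pi)
    # symmetrize the *normalized* q: B = D^1/2 Q D^-1/2
    b = q * (sqrt_pi[..., :, None] / sqrt_pi[..., None, :])
    b = 0.5 * (b + np.swapaxes(b, -1, -2))  # clean round-off asymmetry
    lam, u = np.linalg.eigh(b)
    return u, lam, sqrt_pi


def _transition_from_eig(u, lam, sqrt_pi, t: float) -> np.ndarray:
    if t == 0:  # exact identity (round-off here breaks impossible-data cases)
        k = u.shape[-1]
        eye = np.eye(k)
        if u.ndim == 3:
            return np.broadcast_to(eye, u.shape).copy()
        return eye
    e = np.exp(lam * t)
    core = (u * e[..., None, :]) @ np.swapaxes(u, -1, -2)
    p = core * (sqrt_pi[..., None, :] / sqrt_pi[..., :, None])
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# Amino-acid models
# --------------------------------------------------------------------------


@dataclass
class AminoAcidModel:
    """JTT-family amino-acid model.

    ``frequencies`` is a 20-vector, or an (L, 20) array in site-specific
    mode (one vector per alignment column).
    """

    frequencies: np.ndarray
    mode: str = "JTT"
    exchangeabilities: np.ndarray = field(default_factory=lambda: JTT_EXCHANGEABILITIES.copy())

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.mode not in AA_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def site_specific(self) -> bool:
        return self.frequencies.ndim == 2

    @property
    def n_sites(self) -> int | None:
        return self.frequencies.shape[0] if self.site_specific else None

    @cached_property
    def _eig(self):
        return _reversible_eig(self.exchangeabilities, self.frequencies)

    def rate_matrix(self, site: int | None = None) -> np.ndarray:
        pi = self.pi(site)
        return _assemble_q(self.exchangeabilities, pi)

    def pi(self, site: int | None = None) -> np.ndarray:
        if self.site_specific:
            if site is None:
                return self.frequencies
            return self.frequencies[site]
        return self.frequencies

    def transition(self, t: float, site: int | None = None) -> np.ndarray:
        """P(t); (20, 20), or (L, 20, 20) when site-specific and site=None."""
        if t < 0:
            raise ValueError("negative branch length")
        u, lam, sqrt_pi = self._eig
        if self.site_specific and site is not None:
            u, lam, sqrt_pi = u[site], lam[site], sqrt_pi[site]
        return _transition_from_eig(u, lam, sqrt_pi, t)


def _smoothed_frequencies(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Pseudocount-smoothed frequency vector(s) from residue counts."""
    k = counts.shape[-1]
    tot = counts.sum(axis=-1, keepdims=True)
    return (counts + pseudocount) / (tot + k * pseudocount)


def build_amino_model(
    alignment: Alignment | None,
    mode: str = "JTT",
    pseudocount: float = 0.1,
) -> AminoAcidModel:
    """Build a JTT-family model, optionally with data-driven frequencies.

    * ``JTT`` — published equilibrium frequencies (alignment ignored).
    * ``JTT-F`` / ``JTT-Fgene`` — gene-wide observed residue frequencies,
      pseudocount-smoothed.
    * ``JTT-Fsite`` — one smoothed frequency vector per column; columns with
      no scorable residue fall back to the gene-wide vector.
    """
    if mode not in AA_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {AA_MODES}")
    if mode == "JTT":
        return AminoAcidModel(JTT_FREQUENCIES.copy(), mode=mode)
    if alignment is None:
        raise ValueError(f"mode {mode} requires an alignment")
    states = alignment.protein_states()
    counts = residue_counts(states)
    gene_pi = _smoothed_frequencies(counts.sum(axis=0), pseudocount)
    if mode in ("JTT-F", "JTT-Fgene"):
        return AminoAcidModel(gene_pi, mode=mode)
    # JTT-Fsite
    site_pi = _smoothed_frequencies(counts, pseudocount)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "JTT-Fsite: %d column(s) without scorable residues; using gene-wide frequencies",
            int(empty.sum()),
        )
        site_pi[empty] = gene_pi
    return AminoAcidModel(site_pi, mode=mode)


# --------------------------------------------------------------------------
# Codon model (GY94)
# --------------------------------------------------------------------------

N_CODONS = len(SENSE_CODONS)

def _codon_pair_structure():
    """Index arrays for single-nucleotide codon neighbors."""
    i_idx, j_idx, is_ts, is_nonsyn = [], [], [], []
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            i_idx.append(i)
            j_idx.append(j)
            is_ts.append(diffs[0] in ts_pairs)
            is_nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.asarray(i_idx),
        np.asarray(j_idx),
        np.asarray(is_ts),
        np.asarray(is_nonsyn),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_NONSYN = _codon_pair_structure()


def codon_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    normalize: bool = True,
    scale: float | None = None,
) -> np.ndarray:
    """GY94 generator.

    By default normalized to one substitution per codon per unit t (the
    branch-length unit of single-omega and free-ratio fits).  When
    ``scale`` is given the generator is divided by that externally chosen
    rate instead — used by mixture (branch-site) models, where all site
    classes must share one normalization so that high-omega classes really
    evolve faster.
    """
    q = np.zeros((N_CODONS, N_CODONS))
    rate = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    q[_PAIR_I, _PAIR_J] = rate
    idx = np.arange(N_CODONS)
    q[idx, idx] = -q.sum(axis=1)
    if scale is not None:
        if scale > 0:
            q /= scale
    elif normalize:
        mu = -(pi * q[idx, idx]).sum()
        if mu > 0:
            q /= mu
    return q


def total_flux(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit t of the unnormalized Q."""
    rate = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    return float((pi[_PAIR_I] * rate).sum())


def nonsyn_flux_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of the substitution flux that is nonsynonymous."""
    rate = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    flux = pi[_PAIR_I] * rate
    tot = flux.sum()
    return float(flux[_PAIR_NONSYN].sum() / tot) if tot > 0 else 0.0


class CodonEig:
    """Cached eigendecomposition of one GY94 generator."""

    def __init__(
        self, kappa: float, omega: float, pi: np.ndarray, scale: float | None = None
    ):
        self.kappa, self.omega, self.pi = kappa, omega, pi
        q = codon_rate_matrix(kappa, omega, pi, scale=scale)
        sqrt_pi = np.sqrt(pi)
        b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        b = 0.5 * (b + b.T)
        self.lam, self.u = np.linalg.eigh(b)
        self.sqrt_pi = sqrt_pi

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        return _transition_from_eig(self.u, self.lam, self.sqrt_pi, t)


@dataclass
class CodonModel:
    """GY94 codon model with a single or per-branch omega."""

    kappa: float
    omega_map: Mapping[str, float] | float
    codon_frequencies: np.ndarray
    freq_mode: str = "F3x4"

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        self.codon_frequencies = np.asarray(self.codon_frequencies, dtype=float)
        self._eig_cache: dict[float, CodonEig] = {}

    def omega(self, branch: str | None = None) -> float:
        if isinstance(self.omega_map, Mapping):
            if branch is None:
                raise KeyError("per-branch omega map requires a branch id")
            return float(self.omega_map[branch])
        return float(self.omega_map)

    def eig(self, omega: float) -> CodonEig:
        key = round(float(omega), 12)
        if key not in self._eig_cache:
            self._eig_cache[key] = CodonEig(self.kappa, omega, self.codon_frequencies)
        return self._eig_cache[key]

    def transition(self, t: float, branch: str | None = None) -> np.ndarray:
        return self.eig(self.omega(branch)).transition(t)

    def rate_matrix(self, branch: str | None = None) -> np.ndarray:
        return codon_rate_matrix(self.kappa, self.omega(branch), self.codon_frequencies)


def codon_frequencies(alignment: Alignment, mode: str = "F3x4") -> np.ndarray:
    """Empirical sense-codon frequencies (F1x4, F3x4 or F61), smoothed.

    Stop codons are excluded and the 61-vector renormalized.
    """
    states = alignment.codon_states(check_stops=False)
    if mode == "F61":
        counts = np.bincount(states[states >= 0].ravel(), minlength=N_CODONS).astype(float)
        pi = (counts + 0.1) / (counts.sum() + 0.1 * N_CODONS)
        return pi / pi.sum()
    # nucleotide counts, overall (F1x4) or per codon position (F3x4)
    pos_counts = np.zeros((3, 4))
    for t in alignment.taxa:
        s = alignment[t]
        for i in range(0, len(s), 3):
            for p in range(3):
                k = NT_INDEX.get(s[i + p])
                if k is not None:
                    pos_counts[p, k] += 1
    pos_counts += 0.1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    if mode == "F1x4":
        f = pos_counts.sum(axis=0)
        pos_freq = np.tile(f / f.sum(), (3, 1))
    elif mode != "F3x4":
        raise ValueError(f"unknown codon frequency mode {mode!r}")
    pi = np.array(
        [
            pos_freq[0, NT_INDEX[c[0]]] * pos_freq[1, NT_INDEX[c[1]]] * pos_freq[2, NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def transition_matrix(model, t: float, site: int | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for an amino-acid or codon model."""
    if t < 0:
        raise ValueError("negative branch length")
    if isinstance(model, AminoAcidModel):
        return model.transition(t, site=site)
    return model.transition(t)
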