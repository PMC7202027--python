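"""Synthetic ortholog-set generator.

Evolves gap-free protein (JTT family) or in-frame codon (GY94) alignments
site-independently down a fixed rooted tree, with controllable per-branch
omega, foreground site classes for branch-site power studies, injected
convergent/parallel sites on chosen branch pairs, and injected
focal-lineage-specific substitutions.  Every gene carries a
:class:`SimulationTruth` record that round-trips through TSV.

The default topology is an 11-taxon vertebrate tree shaped like the
island-pitviper study system (two sister pitvipers, a five-pacer viper
clade, other reptiles/birds, frog outgroup) with invented branch lengths
in [0.01, 0.5] — synthetic stand-ins, not estimates.

Seed policy: a gene set uses one master seed; gene ``k`` draws from
``numpy.random.default_rng([master_seed, k])`` so truth tables are
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignments import AMINO_ACIDS, CODON_AA, SENSE_CODONS, Alignment
from .substmodels import AminoAcidModel, CodonEig, CodonModel, total_flux
from .trees import PhyloTree

#: Synthetic 11-taxon study tree (frog-rooted); lengths are invented.
DEFAULT_TREE_NEWICK = (
    "(frog:0.45,((turtle:0.22,(alligator:0.16,chicken:0.26):0.06):0.07,"
    "((gecko:0.30,anole:0.28):0.05,(python:0.21,(king_cobra:0.16,"
    "(five_pacer_viper:0.11,(black_eyebrow_pitviper:0.05,shedao_pitviper:0.04)"
    ":0.05):0.05):0.06):0.07):0.06):0.12);"
)

FOCAL_TAXON = "shedao_pitviper"
COMPARATOR_TAXA = ("alligator", "turtle")


def default_tree() -> PhyloTree:
    return PhyloTree.from_newick(DEFAULT_TREE_NEWICK)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated gene."""

    gene: str
    seed: int
    kind: str = "protein"  # protein | codon
    params: dict[str, float] = field(default_factory=dict)
    branch_omegas: dict[str, float] = field(default_factory=dict)
    site_classes: list[int] = field(default_factory=list)  # codon sites: 0,1,2,3=2a,2b
    injections: list[dict] = field(default_factory=list)  # mode, branch_a, branch_b, sites
    focal_specific: list[dict] = field(default_factory=list)  # site, ref, variant

    def injected_sites(self) -> set[int]:
        out: set[int] = set()
        for inj in self.injections:
            out.update(inj["sites"])
        out.update(d["site"] for d in self.focal_specific)
        return out

    def positive_class_sites(self) -> list[int]:
        """0-based codon sites drawn into classes 2a/2b."""
        return [i for i, c in enumerate(self.site_classes) if c in (2, 3)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("field\tvalue\n")
            for key, value in asdict(self).items():
                fh.write(f"{key}\t{json.dumps(value)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimulationTruth":
        data = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                key, value = line.rstrip("\n").split("\t", 1)
                data[key] = json.loads(value)
        return cls(**data)


def _sample_markov(
    rng: np.random.Generator, parent_states: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Sample child states given parent states and transition matrix/matrices."""
    n = parent_states.shape[0]
    u = rng.random(n)
    if p.ndim == 2:
        rows = p[parent_states]
    else:  # site-specific: (L, k, k)
        rows = p[np.arange(n), parent_states]
    return (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)


def simulate_protein_gene(
    tree: PhyloTree,
    model: AminoAcidModel,
    length: int,
    seed: int | Sequence[int],
    gene: str = "gene",
) -> tuple[Alignment, SimulationTruth]:
    """Evolve a gap-free protein alignment under the amino-acid model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not tree.has_lengths():
        raise ValueError("tree branch lengths missing")
    if model.site_specific and model.n_sites != length:
        raise ValueError("site-specific model length mismatch")
    rng = np.random.default_rng(seed)
    pi = model.pi()
    if pi.ndim == 1:
        root = rng.choice(20, size=length, p=pi)
    else:
        u = rng.random(length)
        root = (pi.cumsum(axis=1) < u[:, None]).sum(axis=1)
    states = {tree.root: root}
    for v in reversed(tree.postorder):  # preorder
        for c in tree.children[v]:
            p = model.transition(float(tree.lengths[c]))
            states[c] = _sample_markov(rng, states[v], p)
    seqs = [
        (name, "".join(AMINO_ACIDS[k] for k in states[tree.leaf_index[name]]))
        for name in tree.leaves
    ]
    truth = SimulationTruth(
        gene=gene,
        seed=int(np.ravel(seed)[-1]),
        kind="protein",
        params={"mode_" + model.mode: 1.0},
    )
    return Alignment(seqs, kind="protein"), truth


def simulate_codon_gene(
    tree: PhyloTree,
    model: CodonModel,
    length: int,
    seed: int | Sequence[int],
    gene: str = "gene",
    foreground: str | None = None,
    class_probs: Sequence[float] | None = None,
    omega2: float = 1.0,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve an in-frame codon alignment under GY94.

    ``model.omega_map`` may be a scalar or per-branch map.  When
    ``foreground`` is given, sites are assigned to branch-site classes
    (0, 1, 2a, 2b) with ``class_probs`` (p0, p1, p2a, p2b): background
    branches use omega0/1, the foreground branch uses omega2 on class
    2a/2b sites.  The drawn class of every site is recorded in the truth.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not tree.has_lengths():
        raise ValueError("tree branch lengths missing")
    rng = np.random.default_rng(seed)
    pi = model.codon_frequencies

    branch_ids = {v: tree.branch_id(v) for v in tree.branches()}
    if foreground is not None:
        if class_probs is None:
            class_probs = (0.45, 0.45, 0.05, 0.05)
        site_class = rng.choice(4, size=length, p=np.asarray(class_probs))
        omega0 = model.omega() if not isinstance(model.omega_map, Mapping) else 0.2
        fg = tree.branch(foreground)

        def branch_site_omegas(v: int) -> np.ndarray:
            w = np.where(np.isin(site_class, [0, 2]), omega0, 1.0)
            if v == fg:
                w = np.where(site_class >= 2, omega2, w)
            return w

        omega_of = branch_site_omegas
        truth_classes = [int(c) for c in site_class]
        branch_omegas = {}
    else:
        site_class = None
        truth_classes = []

        def omega_of(v: int) -> np.ndarray:
            return np.full(length, model.omega(branch_ids[v]))

        branch_omegas = {branch_ids[v]: float(model.omega(branch_ids[v])) for v in tree.branches()}

    # branch-site simulation shares the neutral normalization across site
    # classes (high-omega classes must evolve faster); the single-omega /
    # free-ratio simulation keeps the per-branch unit normalization
    eig_cache: dict[float, CodonEig] = {}

    def eig_for(wval: float) -> CodonEig:
        if foreground is None:
            return model.eig(wval)
        if wval not in eig_cache:
            ref = total_flux(model.kappa, 1.0, pi)
            eig_cache[wval] = CodonEig(model.kappa, wval, pi, scale=ref)
        return eig_cache[wval]

    root = rng.choice(len(SENSE_CODONS), size=length, p=pi)
    states = {tree.root: root}
    for v in reversed(tree.postorder):
        for c in tree.children[v]:
            t = float(tree.lengths[c])
            w = omega_of(c)
            child = np.empty(length, dtype=np.int64)
            for wval in np.unique(w):
                mask = w == wval
                p = eig_for(float(wval)).transition(t)
                child[mask] = _sample_markov(rng, states[v][mask], p)
            states[c] = child
    seqs = [
        (name, "".join(SENSE_CODONS[k] for k in states[tree.leaf_index[name]]))
        for name in tree.leaves
    ]
    truth = SimulationTruth(
        gene=gene,
        seed=int(np.ravel(seed)[-1]),
        kind="codon",
        params={"kappa": float(model.kappa), "omega2": float(omega2)},
        branch_omegas=branch_omegas,
        site_classes=truth_classes,
    )
    return Alignment(seqs, kind="codon"), truth


# --------------------------------------------------------------------------
# Injections
# --------------------------------------------------------------------------


def _constant_residue_columns(
    alignment: Alignment, taxa: Sequence[str]
) -> dict[int, str]:
    """Columns where all given taxa share one standard residue."""
    out = {}
    for s in range(alignment.n_sites):
        col = alignment.column(s)
        residues = {col[t] for t in taxa}
        if len(residues) == 1:
            (r,) = residues
            if r in AMINO_ACIDS:
                out[s] = r
    return out


def inject_convergence(
    alignment: Alignment,
    tree: PhyloTree,
    pair: tuple[str, str],
    n_sites: int,
    mode: str = "parallel",
    seed: int | Sequence[int] = 0,
    exclude: set[int] | None = None,
) -> tuple[Alignment, SimulationTruth]:
    """Rewrite leaf residues so a branch pair carries convergent or
    parallel substitutions at sampled sites.

    Parallel sites are drawn from columns where every taxon outside the
    two subtended clades is constant (so both stem ancestors reconstruct
    to that residue) and both clades are rewritten to one different
    derived residue.  Convergent sites additionally require the two
    branches' local contexts (the leaves under each parent, outside the
    clade) to be constant for two *different* residues.  Only leaf
    sequences are edited; reconstruction may therefore miss a small
    fraction of injected sites.
    """
    if alignment.kind != "protein":
        raise ValueError("convergence injection operates on protein alignments")
    if mode not in ("parallel", "convergent"):
        raise ValueError(f"unknown mode {mode!r}")
    if tree.is_nested(*pair):
        raise ValueError("nested branch pair")
    rng = np.random.default_rng(seed)
    va, vb = tree.branch(pair[0]), tree.branch(pair[1])
    clade_a = sorted(tree.leafset(va))
    clade_b = sorted(tree.leafset(vb))
    outside = [t for t in alignment.taxa if t not in clade_a and t not in clade_b]
    exclude = set() if exclude is None else set(exclude)

    if mode == "parallel":
        const = _constant_residue_columns(alignment, outside)
        eligible = {s: (r, r) for s, r in const.items() if s not in exclude}
    else:
        ctx_a = [t for t in tree.leafset(tree.parent[va]) if t not in clade_a]
        ctx_b = [t for t in tree.leafset(tree.parent[vb]) if t not in clade_b]
        ca = _constant_residue_columns(alignment, ctx_a)
        cb = _constant_residue_columns(alignment, ctx_b)
        eligible = {
            s: (ca[s], cb[s])
            for s in set(ca) & set(cb)
            if ca[s] != cb[s] and s not in exclude
        }
    if len(eligible) < n_sites:
        raise ValueError(
            f"only {len(eligible)} eligible sites for {mode} injection, need {n_sites}"
        )
    sites = sorted(
        rng.choice(sorted(eligible), size=n_sites, replace=False).tolist()
    )
    seqs = {t: list(alignment[t]) for t in alignment.taxa}
    for s in sites:
        a1, a2 = eligible[s]
        choices = [r for r in AMINO_ACIDS if r not in (a1, a2)]
        d = choices[rng.integers(len(choices))]
        for t in clade_a + clade_b:
            seqs[t][s] = d
    new = Alignment([(t, "".join(seqs[t])) for t in alignment.taxa], kind="protein")
    truth = SimulationTruth(
        gene="",
        seed=int(np.ravel(seed)[-1]),
        kind="protein",
        injections=[
            {
                "mode": mode,
                "branch_a": tree.branch_id(va),
                "branch_b": tree.branch_id(vb),
                "sites": [int(s) for s in sites],
            }
        ],
    )
    return new, truth


def inject_specific_substitutions(
    alignment: Alignment,
    focal: str,
    n_sites: int,
    seed: int | Sequence[int] = 0,
    exclude: set[int] | None = None,
) -> tuple[Alignment, SimulationTruth]:
    """Plant focal-lineage-specific substitutions at fully conserved columns."""
    if focal not in alignment:
        raise KeyError(f"focal taxon {focal!r} not in alignment")
    rng = np.random.default_rng(seed)
    exclude = set() if exclude is None else set(exclude)
    const = _constant_residue_columns(alignment, list(alignment.taxa))
    eligible = {s: r for s, r in const.items() if s not in exclude}
    if len(eligible) < n_sites:
        raise ValueError(f"only {len(eligible)} fully conserved columns, need {n_sites}")
    sites = sorted(rng.choice(sorted(eligible), size=n_sites, replace=False).tolist())
    seqs = {t: list(alignment[t]) for t in alignment.taxa}
    records = []
    for s in sites:
        ref = eligible[s]
        choices = [r for r in AMINO_ACIDS if r != ref]
        var = choices[rng.integers(len(choices))]
        seqs[focal][s] = var
        records.append({"site": int(s), "ref": ref, "variant": var})
    new = Alignment([(t, "".join(seqs[t])) for t in alignment.taxa], kind=alignment.kind)
    truth = SimulationTruth(
        gene="", seed=int(np.ravel(seed)[-1]), kind="protein", focal_specific=records
    )
    return new, truth


# --------------------------------------------------------------------------
# Fixture sets
# --------------------------------------------------------------------------


def make_gene_set(
    n_genes: int,
    length: int,
    master_seed: int,
    tree: PhyloTree | None = None,
    kind: str = "codon",
    kappa: float = 2.0,
    omega: float = 0.2,
    psg_genes: Mapping[int, float] | None = None,
    psg_class_probs: Sequence[float] = (0.425, 0.425, 0.075, 0.075),
    foreground: str = FOCAL_TAXON,
    parallel_inject: Mapping[int, tuple[tuple[str, str], int]] | None = None,
    specific_inject: Mapping[int, int] | None = None,
) -> list[tuple[str, Alignment, SimulationTruth]]:
    """Generate a reproducible per-gene fixture set with optional truths.

    ``psg_genes`` maps gene index -> foreground omega2 (those genes are
    simulated with branch-site classes); ``parallel_inject`` maps gene
    index -> ((branch_a, branch_b), n_sites); ``specific_inject`` maps
    gene index -> number of focal-specific substitutions.
    """
    tree = tree or default_tree()
    psg_genes = dict(psg_genes or {})
    parallel_inject = dict(parallel_inject or {})
    specific_inject = dict(specific_inject or {})
    out = []
    for k in range(n_genes):
        name = f"gene{k:04d}"
        seed = [master_seed, k]
        if kind == "codon":
            if k in psg_genes:
                model = CodonModel(kappa, omega, _f_uniformish(), freq_mode="F1x4")
                aln, truth = simulate_codon_gene(
                    tree,
                    model,
                    length,
                    seed,
                    gene=name,
                    foreground=foreground,
                    class_probs=psg_class_probs,
                    omega2=psg_genes[k],
                )
            else:
                model = CodonModel(kappa, omega, _f_uniformish(), freq_mode="F1x4")
                aln, truth = simulate_codon_gene(tree, model, length, seed, gene=name)
        else:
            from .substmodels import build_amino_model

            model = build_amino_model(None, mode="JTT")
            aln, truth = simulate_protein_gene(tree, model, length, seed, gene=name)
        if k in parallel_inject:
            pair, n_sites = parallel_inject[k]
            target = aln.translate() if aln.kind == "codon" else aln
            target, inj_truth = inject_convergence(
                target, tree, pair, n_sites, mode="parallel", seed=[master_seed, k, 1]
            )
            if aln.kind == "codon":
                aln = _backtranslate_edits(aln, target)
            else:
                aln = target
            truth.injections.extend(inj_truth.injections)
        if k in specific_inject:
            target = aln.translate() if aln.kind == "codon" else aln
            target, sp_truth = inject_specific_substitutions(
                target,
                foreground,
                specific_inject[k],
                seed=[master_seed, k, 2],
                exclude=truth.injected_sites(),
            )
            if aln.kind == "codon":
                aln = _backtranslate_edits(aln, target)
            else:
                aln = target
            truth.focal_specific.extend(sp_truth.focal_specific)
        truth.gene = name
        out.append((name, aln, truth))
    return out


_PREFERRED_CODON: dict[str, str] = {}
for _c, _a in zip(SENSE_CODONS, CODON_AA):
    _PREFERRED_CODON.setdefault(_a, _c)


def _backtranslate_edits(codon_aln: Alignment, protein_aln: Alignment) -> Alignment:
    """Push amino-acid edits back onto a codon alignment (one codon per AA)."""
    original = codon_aln.translate()
    seqs = {t: list(codon_aln[t]) for t in codon_aln.taxa}
    for t in codon_aln.taxa:
        before, after = original[t], protein_aln[t]
        for i, (b, a) in enumerate(zip(before, after)):
            if b != a:
                seqs[t][3 * i : 3 * i + 3] = _PREFERRED_CODON[a]
    return Alignment([(t, "".join(seqs[t])) for t in codon_aln.taxa], kind="codon")


def _f_uniformish() -> np.ndarray:
    """Uniform sense-codon frequencies (keeps simulation neutral in base use)."""
    n = len(SENSE_CODONS)
    return np.full(n, 1.0 / n)


def write_fixture_set(
    out_dir: str | Path,
    genes: Sequence[tuple[str, Alignment, SimulationTruth]],
    tree: PhyloTree | None = None,
) -> None:
    """Write per-gene FASTA (+ protein translation), the tree and truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = tree or default_tree()
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    manifest = []
    for name, aln, truth in genes:
        aln.write_fasta(out / f"{name}.fasta")
        if aln.kind == "codon":
            aln.translate().write_fasta(out / f"{name}.protein.fasta")
        truth.to_tsv(out / f"{name}.truth.tsv")
        manifest.append(f"{name}\t{name}.fasta\t{aln.kind}")
    (out / "manifest.tsv").write_text(
        "gene\tfile\tkind\n" + "\n".join(manifest) + "\n"
    )
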