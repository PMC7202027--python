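# Methods

`molevoscreen` implements a comparative molecular-evolution screen of the
kind used to study island-endemic, metabolically suppressed vertebrates
(the running example throughout the package is an island pitviper, its
mainland sister, and two other dormancy-prone vertebrates — an alligator
and a turtle): chance-corrected detection of convergent/parallel
amino-acid substitutions, branch-site and free-ratio codon selection
analyses, fourfold-degenerate site extraction, and a focal-lineage
specific-substitution screen. All analyses are exercised end to end on a
built-in sequence-evolution simulator rather than on transcriptome data;
this note records the models, the numerical choices, and what the
synthetic experiments do and do not establish.

## Substitution models

**Amino acids.** The JTT empirical exchangeability matrix with three
frequency variants: the published JTT equilibrium frequencies, gene-wide
observed frequencies (`JTT-Fgene`), and one frequency vector per alignment
column (`JTT-Fsite`). Observed frequencies are smoothed with a pseudocount
of α = 0.1 per residue (configurable); a column with no scorable residue
falls back to the gene-wide vector. Rate matrices are built as
Q_ij = S_ij π_j, normalized to one expected substitution per site per unit
branch length, so branch lengths are in substitutions/site. Transition
probabilities use the symmetric eigendecomposition of the
diag(π)^{1/2}-similarity transform, which is stable for reversible
generators; P(0) is returned as an exact identity so that impossible
configurations at zero branch length yield likelihood 0 rather than
round-off noise. Gaps and ambiguity codes are excluded from all frequency
counts. Among-site rate variation (gamma) is not modeled; the frequency
variants are the only site heterogeneity, which matches the screen's
convergence nulls and keeps the likelihood kernel simple. A gamma model
would be the natural extension point if calibration on real data proved
too liberal.

**Codons.** Goldman–Yang 94: rate π_j · κ^[transition] · ω^[nonsynonymous]
between single-nucleotide codon neighbors over the 61 sense codons of the
standard code; codon frequencies from the alignment as F3x4 (default),
F1x4 or F61. Single-ω and free-ratio generators are normalized per branch
(lengths in substitutions/codon). In the branch-site mixture, all site
classes share the neutral (ω = 1) normalization instead: site classes must
differ in rate, not only in composition — per-class normalization would
silently remove the very signal the branch-site test measures (this is
also how the simulator generates branch-site data, so branch lengths in
that mode are in neutral-expected substitutions/codon; the overall unit is
absorbed by the fitted tree scale).

## Ancestral reconstruction

Felsenstein pruning with per-node, per-site rescaling; marginal (empirical
Bayes) posteriors at every internal node from one down-pass and one
up-pass. The tree must be rooted (the fixture tree is rooted at the frog
outgroup; unrooted input can be rooted at a named outgroup) because the
convergence classification needs a parent→child direction on every branch.
MAP ties break to the alphabetically earlier residue. Gap leaves contribute
all-ones partials; an all-gap column returns the prior π.

## Convergence screen

For a non-nested branch pair, each site is classified from the
(ancestor, descendant) MAP states of the two branches: both branches
substituting to the same residue is *convergent* when the two ancestral
residues differ and *parallel* when they coincide; different derived
residues is *divergent*; one substitution is *single*. Sites with a gap
or ambiguity in any of the four states are excluded, and the model-based
expectation is restricted to the same scorable sites.

The chance null follows the expected-count construction: per site, the
probability that both branches end in the same (appropriately constrained)
residue, summed over ancestral-state pairs weighted by the marginal
posteriors of the two parent nodes. When the parents are distinct nodes the
joint is approximated by the product of marginals (exact when they
coincide, i.e. sister branches); a strict-MAP mode is available. The
deviation of the product approximation is second-order and is covered by
the Monte-Carlo oracle tolerance in the acceptance suite. Observed counts
are tested against the exact Poisson-binomial tail of the per-site
probabilities (dynamic-programming convolution); the Poisson approximation
is retained as an option for comparability with older implementations.
Per-gene tests use `JTT-Fgene`; the genome-wide null uses `JTT-Fsite`,
which raises the expectation and is therefore the conservative choice.
Significance is α = 0.05 per gene with no FDR on convergence tests (FDR is
applied only to the branch-site screen).

Across branch pairs, counts are pooled over genes and ordinary least
squares of (convergent+parallel) on divergent counts provides the
empirical genome-wide null; per-pair excess is judged by the externally
studentized residual's one-sided t tail. The divergence axis uses the
strict divergent class; the both-substituted count is also recorded. With
~130 pairs, ~5% of null pairs are expected to exceed the α = 0.05 flag by
chance; the screen reports the count rather than interpreting single
flags.

## Codon selection analyses

**Free-ratio.** One ω per branch, shared κ, F3x4 frequencies. Estimation
is staged: a single-ω fit of (κ, ω, tree scale), then coordinate updates
of each branch's (t, ω) through the branch factorization
L_site = fᵀ P(t) g (one eigendecomposition per trial value instead of a
full pruning pass), then a κ refresh; for trees with ≤ 6 branches a joint
quasi-Newton polish follows, because small trees leave (t, ω) strongly
coupled along near-ridges where coordinate ascent is slow. Per-branch
dN and dS split the branch's expected substitutions by the nonsynonymous
flux fraction, with site counts from the neutral (ω = 1) flux fraction, so
dN/dS equals the fitted ω exactly. Guards: ω capped at 999, dS floored at
1e-8 when ratios are reported.

**Branch-site.** Model A (classes 0, 1, 2a, 2b; foreground ω₂ free vs
fixed at 1), LRT against χ²₁ (the 50:50 mixture reference is available
behind a flag but is not the default). Free parameters: κ, a global scale
on the input branch lengths, the foreground branch length (free, as in
full branch-length optimization), class proportions via two logits, ω₀,
and ω₂. The expensive class likelihoods are cached against the non-mixture
parameters, so finite-difference steps on the class proportions are free;
the foreground classes 2a/2b are evaluated from the two background
prunings via the same branch factorization. The alternative is started
from the null optimum twice — once with ω₂ just above 1 and once pushed
into the selection regime (ω₂ = 4 with a non-vanishing 2a/2b share) — to
escape the ω₂ = 1 saddle; additional random restarts follow a fixed seed
schedule. Site identification reports empirical-Bayes posteriors of
classes 2a∪2b at the MLEs (NEB); this is a documented stand-in for the
prior-averaged BEB computation of CODEML and is expected to be slightly
anti-conservative per site at low information.

**4D sites.** A codon column qualifies when every taxon carries an
unambiguous codon with the same first two nucleotides and that
dinucleotide starts a fourfold family — the conservative reading that
guarantees any third-position change is synonymous in every lineage.

**FDR.** Benjamini–Hochberg step-up, applied once across all genes of a
screen.

## Lineage-specific substitutions

A column is focal-specific when all scorable background taxa share one
standard residue and the focal taxon differs. Ambiguity codes in the
background disqualify the column; gaps only reduce the number of scorable
backgrounds, which must stay at or above `min_background` (default 8 of
the 10 non-focal taxa; strict mode requires all). The impact score is the
mean BLOSUM62 delta, mean_b [S(variant, b) − S(reference, b)] over the
background residues, with the deleterious/neutral call at ≤ −2.5. This
keeps the decision structure of PROVEAN-style screens but is an
alignment-column statistic: it does not and cannot reproduce
database-backed PROVEAN scores, which depend on homolog sets retrieved
from NR.

## Synthetic data

The simulator evolves gap-free alignments site-independently down a fixed
rooted tree (protein under the JTT variants, codon under GY94 with
per-branch ω and optional branch-site classes), drawing the root from π.
The default topology is an invented 11-taxon vertebrate tree shaped like
the island-pitviper study system — two sister pitvipers (the focal island
lineage and its mainland sister), a five-pacer-viper/cobra/python clade,
lizards, archosaurs and a turtle, frog outgroup — with synthetic branch
lengths in [0.01, 0.5]. One master seed per gene set; gene k draws from
`default_rng([master_seed, k])`, so truth tables reproduce across
platforms.

Convergence injection edits leaf sequences only: parallel sites are drawn
from columns where everything outside the two clades is constant (both
stems then reconstruct to that residue) and both clades are rewritten to a
shared different residue; convergent sites additionally require the two
local contexts to be constant for different residues. Because histories
are implied rather than written, reconstruction may miss a small fraction
of injected sites; the acceptance tolerance (≥ 8 of 10 recovered) encodes
this. Focal-specific injection rewrites the focal taxon at fully conserved
columns.

What the simulator does *not* emulate: indels and alignment error,
orthology mistakes, assembly artifacts, gene-tree discordance, selection
heterogeneity along background branches, and codon usage structure beyond
the frequency model. Passing tests therefore establish the correctness and
calibration of the statistics under their own model class, not robustness
to real-data violations of it.

## Experiment sizes and design choices

All simulation experiments run on one CPU; sizes were chosen as the
smallest that make the statistical claims sharp.

- Convergence null calibration: 200 genes × 150 aa on the 11-taxon tree;
  the per-gene test's p-values are checked as not anti-conservative
  (one-sided KS at α = 0.01) and genome-wide observed conv+par must not
  exceed the expectation's Poisson 95% band.
- Injection recovery: 10 genes × 200 aa. The fixture is deliberately
  small: the injected excess (10 parallel sites on one pair) must exceed
  the √-noise of the most divergent pairs' counts (~30 events, SD ≈ 5.5 at
  this scale) for a raw-residual ranking to be meaningful under OLS, whose
  constant-variance assumption ignores the count heteroscedasticity.
- Branch-site calibration and power: a six-taxon subtree of the fixture
  tree with the foreground branch set to 0.5 neutral substitutions/codon —
  the top of the fixture's branch-length range, chosen so the designed
  power experiment has adequate sensitivity at the stated effect size
  (ω₂ = 4 on 15% of 400 codons gives ≈ 30 expected events on the
  foreground); with the fixture's natural 0.04 island-pitviper terminal
  the likelihood is nearly flat in ω₂ and no method has power. Type-I
  error is measured on 100 null genes of 200 codons; χ²₁ is conservative
  here because the null truth lies on the boundary.
- The demonstration ortholog set (analysis scripts, acceptance script):
  40 genes × 200 codons with two engineered positively selected genes
  (ω₂ = 8 on ~20% of sites), one parallel-injected gene and one
  focal-specific gene; effect sizes again chosen so single-gene detection
  is expected rather than marginal. The elongated focal branch also
  produces genuine (non-injected) focal-specific substitutions at
  conserved columns; the screen reports them all, and truth recovery is
  asserted as a superset.
- End-to-end determinism: a 40-gene screen run twice must write
  byte-identical reports (fixed float formatting, no timestamps in
  metadata, config hash recorded).

## Known limitations

- The joint ancestral posterior over two distinct parent nodes is
  approximated by the product of marginals.
- NEB rather than BEB site identification.
- Branch lengths in the branch-site fit are the input tree scaled by one
  factor plus a free foreground length, not fully re-optimized per branch.
- The free-ratio optimizer is coordinate ascent with a small-tree polish;
  on large trees with many near-zero branches, per-branch ω estimates are
  noisy (as they are in any free-ratio fit).
- PROVEAN scores are not reproduced, only the decision structure.
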