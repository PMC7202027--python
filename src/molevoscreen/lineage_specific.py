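"""Focal-lineage-specific amino-acid substitutions and their predicted
functional impact.

A site is focal-specific when every scorable background taxon carries one
and the same residue while the focal taxon carries a different one.  The
predicted impact is a conservation delta score: the mean BLOSUM62 score
change of the column's background residues when the reference residue is
replaced by the focal variant.  Calls use the same decision threshold
(default -2.5) and deleterious/neutral vocabulary as PROVEAN-style
screens; the score itself is an alignment-column statistic and does not
reproduce database-backed PROVEAN values.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

from .alignments import AMINO_ACIDS, Alignment

BLOSUM62 = substitution_matrices.load("BLOSUM62")

DEFAULT_THRESHOLD = -2.5


@dataclass
class SpecificSubstitution:
    """One focal-lineage-specific substitution with its impact call."""

    gene: str
    site: int  # 1-based alignment column
    reference_residue: str
    focal_residue: str
    score: float
    call: str  # "deleterious" | "neutral"

    @property
    def label(self) -> str:
        """Compact reference/site/variant label, e.g. ``A318T``."""
        return f"{self.reference_residue}{self.site}{self.focal_residue}"


def conservation_delta_score(
    alignment: Alignment,
    site: int,
    reference: str,
    variant: str,
    focal: str | None = None,
) -> float:
    """Mean BLOSUM62 score change of replacing ``reference`` by ``variant``.

    Averages ``S(variant, b) - S(reference, b)`` over the column's non-gap
    background residues ``b`` (the focal taxon, if named, is excluded).
    ``site`` is a 0-based column index.
    """
    if variant == reference:
        raise ValueError("variant equals reference residue")
    column = alignment.column(site)
    background = [
        r for t, r in column.items() if t != focal and r in AMINO_ACIDS
    ]
    if len(background) < 2:
        raise ValueError("need >= 2 scorable background residues")
    deltas = [BLOSUM62[variant, b] - BLOSUM62[reference, b] for b in background]
    return float(sum(deltas) / len(deltas))


def detect_specific_substitutions(
    alignment: Alignment,
    focal: str,
    min_background: int = 8,
    gene: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SpecificSubstitution]:
    """All columns constant across background taxa but different in the
    focal taxon.

    Background residues must be one identical standard amino acid
    (ambiguity codes disqualify the column; gaps count as missing data and
    only reduce the number of scorable backgrounds, which must stay at or
    above ``min_background``).  Each detection is scored with
    :func:`conservation_delta_score` and called deleterious when the score
    is at or below ``threshold``.
    """
    if focal not in alignment:
        raise KeyError(f"focal taxon {focal!r} not in alignment")
    if alignment.kind == "codon":
        alignment = alignment.translate()
    n_background = alignment.n_taxa - 1
    if n_background < min_background:
        raise ValueError(
            f"only {n_background} background taxa; min_background={min_background}"
        )
    out: list[SpecificSubstitution] = []
    for s in range(alignment.n_sites):
        column = alignment.column(s)
        focal_res = column[focal]
        residues = set()
        n_present = 0
        ok = True
        for t, r in column.items():
            if t == focal:
                continue
            if r == "-":
                continue
            if r not in AMINO_ACIDS:
                ok = False  # ambiguity code disqualifies the column
                break
            residues.add(r)
            n_present += 1
        if not ok or len(residues) != 1 or n_present < min_background:
            continue
        (ref,) = residues
        if focal_res not in AMINO_ACIDS or focal_res == ref:
            continue
        score = conservation_delta_score(alignment, s, ref, focal_res, focal=focal)
        out.append(
            SpecificSubstitution(
                gene=gene,
                site=s + 1,
                reference_residue=ref,
                focal_residue=focal_res,
                score=score,
                call="deleterious" if score <= threshold else "neutral",
            )
        )
    return out
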