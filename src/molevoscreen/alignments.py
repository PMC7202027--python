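"""Alignment container for amino-acid and in-frame codon alignments.

Sequences are stored as upper-case strings keyed by taxon, in input order.
Integer state matrices (sites x taxa, ``-1`` for gap/ambiguity) are derived
on demand; FASTA IO goes through biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue order used throughout the package (alphabetical;
#: MAP ties in ancestral reconstruction resolve to the earlier residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: The 61 sense codons of the standard genetic code, alphabetical.
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS)


class FrameError(ValueError):
    """Codon alignment is out of frame or contains an internal stop."""


@dataclass
class Alignment:
    """Ordered, taxon-labeled multiple sequence alignment.

    Parameters
    ----------
    sequences:
        Mapping or iterable of ``(taxon, sequence)``; all sequences must
        share one length.
    kind:
        ``"protein"``, ``"codon"`` or ``"nucleotide"``.
    """

    sequences: Mapping[str, str] | Iterable[tuple[str, str]]
    kind: str = "protein"
    taxa: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        items = (
            list(self.sequences.items())
            if isinstance(self.sequences, Mapping)
            else list(self.sequences)
        )
        if not items:
            raise ValueError("empty alignment")
        self._seqs = {t: s.upper() for t, s in items}
        self.taxa = tuple(t for t, _ in items)
        lengths = {len(s) for s in self._seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        (self._length,) = lengths
        if self.kind == "codon" and self._length % 3 != 0:
            raise FrameError(f"codon alignment length {self._length} not divisible by 3")

    def __len__(self) -> int:
        return self._length

    def __getitem__(self, taxon: str) -> str:
        return self._seqs[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._seqs

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """Number of columns (codon columns for codon alignments)."""
        return self._length // 3 if self.kind == "codon" else self._length

    # ------------------------------------------------------------------ IO
    @classmethod
    def read_fasta(cls, path: str | Path | io.TextIOBase, kind: str = "protein") -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        return cls([(r.id, str(r.seq)) for r in records], kind=kind)

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(self._seqs[t]), id=t, description="") for t in self.taxa]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")

    # ------------------------------------------------------- state matrices
    def protein_states(self) -> np.ndarray:
        """(n_sites, n_taxa) int8 residue indices; -1 for gap/ambiguity."""
        if self.kind == "codon":
            return self.translate().protein_states()
        out = np.full((self._length, self.n_taxa), -1, dtype=np.int8)
        for j, t in enumerate(self.taxa):
            out[:, j] = [AA_INDEX.get(c, -1) for c in self._seqs[t]]
        return out

    def codon_states(self, check_stops: bool = True) -> np.ndarray:
        """(n_codons, n_taxa) int16 sense-codon indices; -1 for gap/ambiguity."""
        if self.kind != "codon":
            raise ValueError("codon_states requires a codon alignment")
        n_codons = self._length // 3
        out = np.full((n_codons, self.n_taxa), -1, dtype=np.int16)
        for j, t in enumerate(self.taxa):
            s = self._seqs[t]
            for i in range(n_codons):
                codon = s[3 * i : 3 * i + 3]
                if codon in CODON_INDEX:
                    out[i, j] = CODON_INDEX[codon]
                elif check_stops and codon in STOP_CODONS and i < n_codons - 1:
                    raise FrameError(f"internal stop codon {codon} in {t} at codon {i + 1}")
        return out

    def translate(self) -> "Alignment":
        """Translate an in-frame codon alignment to protein (gaps -> '-')."""
        if self.kind != "codon":
            raise ValueError("translate requires a codon alignment")
        fwd = _STANDARD_TABLE.forward_table
        out = []
        for t in self.taxa:
            s = self._seqs[t]
            aa = []
            for i in range(0, self._length, 3):
                codon = s[i : i + 3]
                aa.append(fwd.get(codon, "*" if codon in STOP_CODONS else "-"))
            out.append((t, "".join(aa)))
        return Alignment(out, kind="protein")

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        return Alignment([(t, self._seqs[t]) for t in taxa], kind=self.kind)

    def column(self, site: int) -> dict[str, str]:
        """Residues of one 0-based column (codon string for codon kind)."""
        if self.kind == "codon":
            return {t: self._seqs[t][3 * site : 3 * site + 3] for t in self.taxa}
        return {t: self._seqs[t][site] for t in self.taxa}


def residue_counts(states: np.ndarray, n_states: int = 20) -> np.ndarray:
    """Per-column counts of non-gap states; (n_sites, n_states)."""
    n_sites = states.shape[0]
    counts = np.zeros((n_sites, n_states))
    for k in range(n_states):
        counts[:, k] = (states == k).sum(axis=1)
    return counts
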