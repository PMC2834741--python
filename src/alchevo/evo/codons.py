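"""Codon alignments: back-translation threading, identity, frequencies.

Codon alignments are built by threading unaligned coding nucleotide sequences
through an existing protein alignment (each amino-acid column maps to one
codon triplet; protein gaps become codon gaps).  Likelihood computations use
the 61 sense codons of the standard genetic code; columns containing gaps or
ambiguous codons are removed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "CodonAlignment",
    "align_codons_from_protein",
    "pairwise_identity",
    "f3x4_frequencies",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"

#: The 61 sense codons of the standard genetic code, in lexicographic (ACGT)
#: order; stop codons are excluded.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in standard_dna_table.stop_codons
)

#: Codon string -> index into `SENSE_CODONS`.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Codon index -> encoded amino acid (one-letter).
CODON_AMINO_ACIDS: tuple[str, ...] = tuple(
    standard_dna_table.forward_table[c] for c in SENSE_CODONS
)

GAP_CODE = -1  # gap or ambiguous codon in the index matrix


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of coding sequences, one codon per column.

    Attributes
    ----------
    taxa : tuple of str
        Ordered sequence labels.
    codons : ndarray, shape (n_taxa, n_sites), dtype int
        Index into `SENSE_CODONS` per cell; `GAP_CODE` marks a gap or an
        ambiguous/unrecognized codon.
    source_columns : tuple of int
        For each column, its 0-based codon position in the source alignment
        (identity mapping unless columns have been dropped).
    """

    taxa: tuple[str, ...]
    codons: np.ndarray
    source_columns: tuple[int, ...]

    def __init__(self, taxa, codons, source_columns=None):
        taxa = tuple(str(t) for t in taxa)
        codons = np.asarray(codons, dtype=int)
        if codons.ndim != 2 or codons.shape[0] != len(taxa):
            raise ValueError("codons must be a (n_taxa, n_sites) matrix")
        if codons.size and (codons.max() >= len(SENSE_CODONS) or codons.min() < GAP_CODE):
            raise ValueError("codon indices out of range")
        if source_columns is None:
            source_columns = tuple(range(codons.shape[1]))
        source_columns = tuple(int(c) for c in source_columns)
        if len(source_columns) != codons.shape[1]:
            raise ValueError("source_columns length mismatch")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "codons", codons)
        object.__setattr__(self, "source_columns", source_columns)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def drop_incomplete_columns(self) -> "CodonAlignment":
        """Remove columns containing any gap/ambiguous codon (cleandata)."""
        keep = ~(self.codons == GAP_CODE).any(axis=0)
        return CodonAlignment(
            self.taxa,
            self.codons[:, keep],
            tuple(np.asarray(self.source_columns)[keep]),
        )

    def sequence(self, taxon: str) -> str:
        """Nucleotide sequence of one row, gaps as ``---``."""
        i = self.taxa.index(taxon)
        return "".join(
            SENSE_CODONS[c] if c != GAP_CODE else "---" for c in self.codons[i]
        )

    def reordered(self, taxa: Sequence[str]) -> "CodonAlignment":
        """Same alignment with rows in the given taxon order."""
        if sorted(taxa) != sorted(self.taxa):
            raise ValueError("taxon sets differ")
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(tuple(taxa), self.codons[idx], self.source_columns)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.sequence(t)}\n")

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], seqs: Sequence[str]) -> "CodonAlignment":
        """Build from equal-length aligned nucleotide strings (length % 3 == 0)."""
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"aligned length {length} is not divisible by 3")
        mat = np.empty((len(taxa), length // 3), dtype=int)
        for i, s in enumerate(seqs):
            s = s.upper()
            for j in range(0, length, 3):
                mat[i, j // 3] = CODON_INDEX.get(s[j:j + 3], GAP_CODE)
        return cls(taxa, mat)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {label: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def align_codons_from_protein(
    nucleotide_seqs: Mapping[str, str],
    protein_alignment: Mapping[str, str],
) -> CodonAlignment:
    """Thread coding sequences through their aligned protein sequences.

    Each nucleotide sequence must translate (standard code; a trailing stop
    codon is tolerated and dropped) to exactly the ungapped protein sequence
    of the same taxon; each amino-acid column then maps to the corresponding
    codon triplet, with protein gaps becoming codon gaps.
    """
    taxa = list(protein_alignment)
    missing = sorted(set(taxa) - set(nucleotide_seqs))
    if missing:
        raise ValueError(f"missing nucleotide sequences for: {missing}")
    aln_lengths = {len(p) for p in protein_alignment.values()}
    if len(aln_lengths) != 1:
        raise ValueError("protein alignment rows have unequal lengths")
    (n_cols,) = aln_lengths

    mat = np.full((len(taxa), n_cols), GAP_CODE, dtype=int)
    for i, taxon in enumerate(taxa):
        nuc = nucleotide_seqs[taxon].upper().replace("-", "")
        if len(nuc) % 3:
            raise ValueError(
                f"{taxon}: coding sequence length {len(nuc)} is not divisible by 3"
            )
        codons = [nuc[j:j + 3] for j in range(0, len(nuc), 3)]
        translated = str(Seq(nuc).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
            codons = codons[:-1]
        protein = protein_alignment[taxon].upper()
        ungapped = protein.replace("-", "")
        if len(translated) != len(ungapped):
            raise ValueError(
                f"{taxon}: translation has {len(translated)} residues but the "
                f"aligned protein has {len(ungapped)}"
            )
        for pos, (got, want) in enumerate(zip(translated, ungapped), start=1):
            if got != want and want != "X":
                raise ValueError(
                    f"{taxon}: translation mismatch at protein position {pos}: "
                    f"codon encodes {got!r}, alignment has {want!r}"
                )
        k = 0
        for col, aa in enumerate(protein):
            if aa == "-":
                continue
            mat[i, col] = CODON_INDEX.get(codons[k], GAP_CODE)
            k += 1
    return CodonAlignment(taxa, mat)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two aligned sequences, to 0.1.

    Positions where either sequence has a gap are excluded from the
    denominator; identity = matches / comparable positions * 100.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    comparable = matches = 0
    for x, y in zip(a, b):
        if x in "-." or y in "-.":
            continue
        comparable += 1
        matches += x == y
    if comparable == 0:
        raise ValueError("no comparable (gap-free) positions")
    return round(100.0 * matches / comparable, 1)


def f3x4_frequencies(alignment: CodonAlignment, pseudocount: float = 0.0) -> np.ndarray:
    """Empirical F3x4 codon frequencies over the 61 sense codons.

    Nucleotide frequencies are tabulated separately at the three codon
    positions; each sense codon's frequency is the product of its positional
    nucleotide frequencies, renormalized over sense codons.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for row in alignment.codons:
        for c in row:
            if c == GAP_CODE:
                continue
            codon = SENSE_CODONS[c]
            for pos in range(3):
                counts[pos, base_idx[codon[pos]]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous codons")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_idx[c[0]]]
            * pos_freq[1, base_idx[c[1]]]
            * pos_freq[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()
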