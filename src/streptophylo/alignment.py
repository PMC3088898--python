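"""Aligned character matrices (protein or recoded alphabets).

The canonical amino-acid state order follows the PAML dat-file convention
(ARNDCQEGHILKMFPSTWYV) so that bundled exchangeability files can be read
without reordering.  Ambiguity codes B, Z, X and the symbols '?', '-', '*'
and '.' are all treated as fully missing states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
MISSING_SYMBOLS = frozenset("-?XBZ*.")


@dataclass(frozen=True)
class Alphabet:
    """An ordered state alphabet with a set of missing-data symbols."""

    states: str
    name: str = "amino20"

    @property
    def size(self) -> int:
        return len(self.states)

    def encode(self, seq: str) -> np.ndarray:
        """Encode a sequence into int codes; missing/ambiguous -> -1."""
        lut = np.full(128, -2, dtype=np.int16)
        for s in MISSING_SYMBOLS:
            if s not in self.states:   # a state symbol always wins (e.g. 'B'
                lut[ord(s)] = -1       # is a real state of a toy alphabet)
        for i, s in enumerate(self.states):
            lut[ord(s)] = i
            lut[ord(s.lower())] = i
        codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (codes == -2).any():
            bad = seq[int(np.argmax(codes == -2))]
            raise ValueError(f"symbol {bad!r} is not in alphabet {self.name!r}")
        return codes


AMINO20 = Alphabet(AMINO_ACIDS, "amino20")
DAYHOFF6 = Alphabet("123456", "dayhoff6")


class Alignment:
    """An aligned matrix of sequences over named taxa.

    Sequences are stored as strings; numeric encodings are produced on
    demand.  All sequences must have equal length.
    """

    def __init__(self, sequences: Mapping[str, str], alphabet: Alphabet = AMINO20):
        self.sequences: dict[str, str] = dict(sequences)
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            detail = {t: len(s) for t, s in self.sequences.items()}
            raise ValueError(f"ragged alignment; per-taxon lengths: {detail}")
        self.length = lengths.pop()
        self.alphabet = alphabet

    # -- basic access ------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]

    def codes(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """(n_taxa, length) int matrix; -1 marks missing cells."""
        taxa = list(taxa) if taxa is not None else self.taxa
        return np.stack([self.alphabet.encode(self.sequences[t]) for t in taxa])

    def missing_fraction(self) -> float:
        codes = self.codes()
        return float((codes < 0).mean())

    # -- derived alignments ------------------------------------------------

    def subset_taxa(self, taxa: Iterable[str]) -> "Alignment":
        taxa = list(taxa)
        unknown = [t for t in taxa if t not in self.sequences]
        if unknown:
            raise KeyError(f"taxa not in alignment: {unknown}")
        return Alignment({t: self.sequences[t] for t in taxa}, self.alphabet)

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = np.asarray(cols, dtype=int)
        return Alignment(
            {t: "".join(s[c] for c in cols) for t, s in self.sequences.items()},
            self.alphabet)

    def bootstrap_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        return self.subset_columns(cols)

    def present_taxa(self) -> list[str]:
        """Taxa with at least one non-missing cell."""
        codes = self.codes()
        keep = (codes >= 0).any(axis=1)
        return [t for t, k in zip(self.taxa, keep) if k]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_biopython(cls, msa: MultipleSeqAlignment,
                       alphabet: Alphabet = AMINO20) -> "Alignment":
        seqs: dict[str, str] = {}
        for rec in msa:
            name = rec.id.strip().replace(" ", "_")
            if name in seqs:
                raise ValueError(f"duplicate taxon {name!r} in alignment")
            seqs[name] = str(rec.seq)
        return cls(seqs, alphabet)

    @classmethod
    def read(cls, path: str | Path, fmt: str = "fasta",
             alphabet: Alphabet = AMINO20) -> "Alignment":
        """Read one alignment; ``fmt`` is 'fasta', 'phylip' (interleaved,
        relaxed names) or 'phylip-sequential'."""
        biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed",
                  "phylip-sequential": "phylip-sequential"}[fmt]
        path = Path(path)
        if path.stat().st_size == 0:
            raise ValueError(f"empty alignment file: {path}")
        msa = AlignIO.read(str(path), biofmt)
        return cls.from_biopython(msa, alphabet)

    def to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=t, description="") for t, s in self.sequences.items()])

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed",
                  "phylip-sequential": "phylip-sequential"}[fmt]
        AlignIO.write(self.to_biopython(), str(path), biofmt)

    def to_phylip(self) -> str:
        buf = io.StringIO()
        AlignIO.write(self.to_biopython(), buf, "phylip-sequential")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa x {self.length} cols, {self.alphabet.name})"


class GeneAlignment(Alignment):
    """A per-gene alignment carrying its gene identifier."""

    def __init__(self, gene_id: str, sequences: Mapping[str, str],
                 alphabet: Alphabet = AMINO20):
        super().__init__(sequences, alphabet)
        self.gene_id = gene_id

    def subset_taxa(self, taxa: Iterable[str]) -> "GeneAlignment":
        base = super().subset_taxa(taxa)
        return GeneAlignment(self.gene_id, base.sequences, self.alphabet)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GeneAlignment({self.gene_id!r}, {self.n_taxa} taxa x "
                f"{self.length} cols)")
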