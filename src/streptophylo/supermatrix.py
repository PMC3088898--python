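"""Supermatrix assembly: gene-alignment ingestion, chimeric-OTU merging,
occupancy filtering, concatenation and missing-data accounting.

Conventions: coordinates are 0-based half-open internally; 1-based closed
only in the human-readable partition file.  '?' is the canonical missing
symbol on output; '-', 'X' and the ambiguity codes count as missing on
input.  Genes are concatenated in lexicographic gene-id order for
reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import Alignment, GeneAlignment, MISSING_SYMBOLS, AMINO20

logger = logging.getLogger(__name__)

MISSING_ON_COUNT = frozenset("?-X")


def _is_missing_seq(seq: str) -> bool:
    return all(ch in MISSING_SYMBOLS for ch in seq)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ChimeraRule:
    """Merge closely related taxa into one composite OTU.

    Per gene the composite takes the whole sequence of the highest-priority
    source taxon that has data (whole-gene donation, never intra-gene
    splicing); the source taxa disappear from the output.
    """

    target: str
    sources: list
    level: str = "genus"

    def __post_init__(self):
        if len(self.sources) < 2:
            raise ValueError("a chimera needs at least 2 source taxa")
        if self.target in self.sources:
            raise ValueError("chimera target name must differ from its sources")


@dataclass
class Supermatrix:
    """Concatenated gene blocks over a shared taxon set.

    ``partitions`` maps gene id -> (start, end) column interval, 0-based
    half-open, disjoint, contiguous, covering all columns in order.
    """

    sequences: dict                    # taxon -> concatenated sequence
    partitions: dict                   # gene_id -> (start, end)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("ragged supermatrix rows")
        self.n_columns = lengths.pop()
        pos = 0
        for gid, (a, b) in self.partitions.items():
            if a != pos or b <= a:
                raise ValueError(f"partition {gid!r} is not contiguous")
            pos = b
        if pos != self.n_columns:
            raise ValueError("partitions do not cover all columns")

    @property
    def taxa(self) -> list:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def to_alignment(self) -> Alignment:
        return Alignment(self.sequences)

    def gene_block(self, gene_id: str) -> GeneAlignment:
        a, b = self.partitions[gene_id]
        return GeneAlignment(gene_id,
                             {t: s[a:b] for t, s in self.sequences.items()})

    def missing_mask(self) -> np.ndarray:
        """(n_taxa, n_columns) boolean mask of missing cells."""
        rows = []
        for t in self.taxa:
            arr = np.frombuffer(self.sequences[t].encode(), dtype=np.uint8)
            mask = np.zeros(len(arr), dtype=bool)
            for ch in MISSING_ON_COUNT:
                mask |= arr == ord(ch)
            rows.append(mask)
        return np.stack(rows)

    # -- text outputs ------------------------------------------------------

    def write_phylip(self, path: str | Path) -> None:
        self.to_alignment().write(path, "phylip-sequential")

    def write_partitions(self, path: str | Path) -> None:
        """RAxML-style partition file, 1-based closed intervals."""
        lines = [f"{gid} = {a + 1}-{b}" for gid, (a, b) in self.partitions.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class OccupancyReport:
    """Missing-data bookkeeping for a gene set over a taxon panel."""

    gene_missing_taxa: dict            # gene_id -> count of missing taxa
    taxon_missing_fraction: dict       # taxon -> fraction of missing cells
    global_missing_fraction: float
    kept_genes: list = field(default_factory=list)
    discarded_genes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "missing_taxa": m,
                 "kept": g in set(self.kept_genes)}
                for g, m in sorted(self.gene_missing_taxa.items())]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_gene_alignments(paths: Sequence, fmt: str = "fasta") -> list:
    """Read one alignment per file; the gene id is the file stem.  Taxon
    names are whitespace-normalized to underscores (logged when changed)."""
    genes = []
    for p in paths:
        p = Path(p)
        aln = Alignment.read(p, fmt)
        for t in aln.taxa:
            if " " in t:
                logger.info("taxon %r normalized to %r", t, t.replace(" ", "_"))
        genes.append(GeneAlignment(p.stem, aln.sequences, aln.alphabet))
    return genes


def read_chimera_rules(path) -> list:
    """YAML chimera rules: a list of {target, sources, level} mappings."""
    data = yaml.safe_load(Path(path).read_text())
    return [ChimeraRule(d["target"], list(d["sources"]), d.get("level", "genus"))
            for d in data]


def apply_chimeras(genes: Sequence, rules: Sequence) -> tuple[list, dict]:
    """Merge source taxa into composite OTUs, gene by gene.

    Returns the rewritten genes and a log: rule target -> gene id -> donor
    taxon (or None when no source had data).
    """
    known = set()
    for g in genes:
        known |= set(g.taxa)
    for r in rules:
        unknown = [s for s in r.sources if s not in known]
        if unknown:
            logger.warning("chimera %r references unseen taxa %s", r.target, unknown)
    donors: dict = {r.target: {} for r in rules}
    out = []
    for g in genes:
        seqs = dict(g.sequences)
        for r in rules:
            donor = None
            for s in r.sources:
                seq = seqs.get(s)
                if seq is not None and not _is_missing_seq(seq):
                    donor = s
                    break
            for s in r.sources:
                seqs.pop(s, None)
            if donor is not None:
                seqs[r.target] = g.sequences[donor]
            donors[r.target][g.gene_id] = donor
        out.append(GeneAlignment(g.gene_id, seqs, g.alphabet))
    return out, donors


def gene_missing_taxa(gene: GeneAlignment, taxa: Sequence) -> int:
    """Number of panel taxa without usable data for this gene."""
    present = {t for t in gene.taxa if not _is_missing_seq(gene[t])}
    return len([t for t in taxa if t not in present])


def filter_gene_occupancy(genes: Sequence, taxa: Sequence,
                          max_missing: int = 16) -> tuple[list, OccupancyReport]:
    """Keep genes with at most ``max_missing`` missing taxa (a taxon is
    missing when it has no non-missing residue for the gene)."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    taxa = list(taxa)
    counts = {g.gene_id: gene_missing_taxa(g, taxa) for g in genes}
    kept = [g for g in genes if counts[g.gene_id] <= max_missing]
    discarded = [g.gene_id for g in genes if counts[g.gene_id] > max_missing]
    if kept:
        sm = concatenate(kept, taxa)
        mask = sm.missing_mask()
        taxon_frac = {t: float(mask[i].mean()) for i, t in enumerate(sm.taxa)}
        global_frac = float(mask.mean())
    else:
        taxon_frac = {t: 1.0 for t in taxa}
        global_frac = 1.0
    report = OccupancyReport(
        gene_missing_taxa=counts, taxon_missing_fraction=taxon_frac,
        global_missing_fraction=global_frac,
        kept_genes=[g.gene_id for g in kept], discarded_genes=discarded)
    return kept, report


def concatenate(genes: Sequence, taxa: Sequence | None = None,
                sort_genes: bool = True) -> Supermatrix:
    """Concatenate gene blocks into a supermatrix; absent taxon x gene
    blocks are filled with '?'."""
    if not genes:
        raise ValueError("no genes to concatenate")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    ordered = sorted(genes, key=lambda g: g.gene_id) if sort_genes else list(genes)
    if taxa is None:
        taxa = sorted(set().union(*(set(g.taxa) for g in ordered)))
    taxa = list(taxa)
    parts = {}
    chunks = {t: [] for t in taxa}
    pos = 0
    for g in ordered:
        parts[g.gene_id] = (pos, pos + g.length)
        pos += g.length
        for t in taxa:
            seq = g.sequences.get(t)
            if seq is None:
                seq = "?" * g.length
            else:
                seq = "".join("?" if ch in MISSING_SYMBOLS else ch for ch in seq)
            chunks[t].append(seq)
    return Supermatrix({t: "".join(chunks[t]) for t in taxa}, parts)


def missing_fraction(s: Supermatrix) -> float:
    """Fraction of cells that are '?', '-' or 'X' over taxa x columns."""
    return float(s.missing_mask().mean())


def subsample_taxa(s: Supermatrix, drop: Iterable,
                   prune_empty_columns: bool = False) -> Supermatrix:
    """Remove taxa; optionally prune columns that become entirely missing
    (the partition map is re-indexed; emptied genes are dropped)."""
    drop = set(drop)
    unknown = drop - set(s.taxa)
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    seqs = {t: q for t, q in s.sequences.items() if t not in drop}
    if not seqs:
        raise ValueError("cannot drop every taxon")
    if not prune_empty_columns:
        return Supermatrix(seqs, dict(s.partitions))
    sub = Supermatrix(seqs, dict(s.partitions))
    mask = sub.missing_mask()
    keep_cols = ~mask.all(axis=0)
    new_parts = {}
    pos = 0
    new_seqs = {t: [] for t in sub.taxa}
    for gid, (a, b) in s.partitions.items():
        width = int(keep_cols[a:b].sum())
        if width == 0:
            continue
        new_parts[gid] = (pos, pos + width)
        pos += width
        idx = np.nonzero(keep_cols[a:b])[0] + a
        for t in sub.taxa:
            row = sub.sequences[t]
            new_seqs[t].append("".join(row[i] for i in idx))
    return Supermatrix({t: "".join(v) for t, v in new_seqs.items()}, new_parts)
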