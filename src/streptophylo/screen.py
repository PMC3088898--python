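"""Ortholog-congruence screening of gene alignments against a reference
topology.

Each gene gets its own ML tree with bootstrap supports; gene-tree
bipartitions supported at or above a threshold (default 70%) are tested for
compatibility against the reference tree pruned to the gene's taxa.  A
supported incompatibility that a single NNI of the gene tree cannot resolve
is taken as evidence of paralogy/xenology and discards the whole gene;
NNI-resolvable conflicts are attributed to reconstruction error and the
gene is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import GeneAlignment
from .inference import BootstrapResult, bootstrap
from .substmodels import SubstitutionMixtureModel, make_model
from .trees import (Bipartition, Tree, TreeError, bipartitions, is_compatible,
                    nni_neighbors, restrict)

logger = logging.getLogger(__name__)


@dataclass
class ConflictRecord:
    """A supported gene-tree bipartition incompatible with the (restricted)
    reference tree."""

    gene_id: str
    bipartition: Bipartition
    support: float
    nni_resolvable: bool | None = None


@dataclass
class ScreenReport:
    kept: list = field(default_factory=list)
    discarded: dict = field(default_factory=dict)   # gene_id -> [ConflictRecord]
    shared_taxa: dict = field(default_factory=dict)  # gene_id -> count
    skipped: list = field(default_factory=list)      # <4 usable taxa, auto-kept
    gene_trees: dict = field(default_factory=dict)   # gene_id -> Tree

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.kept:
            rows.append({"gene": g, "status": "kept",
                         "shared_taxa": self.shared_taxa.get(g),
                         "n_conflicts": 0})
        for g, recs in self.discarded.items():
            rows.append({"gene": g, "status": "discarded",
                         "shared_taxa": self.shared_taxa.get(g),
                         "n_conflicts": len(recs)})
        return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        payload = {
            "kept": sorted(self.kept),
            "skipped_kept": sorted(self.skipped),
            "discarded": {
                g: [{"bipartition": str(r.bipartition), "support": r.support,
                     "nni_resolvable": r.nni_resolvable} for r in recs]
                for g, recs in self.discarded.items()},
            "shared_taxa": self.shared_taxa,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def infer_gene_tree(gene: GeneAlignment, model: SubstitutionMixtureModel,
                    replicates: int = 100, seed: int = 0) -> BootstrapResult:
    """ML tree with bootstrap supports on the gene's data-bearing taxa."""
    present = gene.present_taxa()
    if len(present) < 4:
        raise TreeError("gene has fewer than 4 usable taxa")
    sub = gene.subset_taxa(present)
    return bootstrap(sub, model, replicates=replicates, seed=seed)


def detect_conflicts(gene_tree: Tree, reference: Tree,
                     bp_threshold: float = 70.0,
                     gene_id: str = "") -> list:
    """Supported gene-tree bipartitions incompatible with the reference
    pruned to the gene's taxon set (support >= threshold, as printed)."""
    shared = gene_tree.taxa & reference.taxa
    if not shared:
        raise TreeError("gene tree and reference share no taxa")
    if gene_tree.taxa - reference.taxa:
        raise TreeError("gene tree contains taxa absent from the reference")
    ref = restrict(reference, gene_tree.taxa) \
        if reference.taxa != gene_tree.taxa else reference
    out = []
    for node in gene_tree.internal_edges():
        support = node.support
        if support is None or support < bp_threshold:
            continue
        leafset = frozenset(l.name for l in _leaves_below(node))
        if not (1 < len(leafset) < len(gene_tree.taxa) - 1):
            continue
        b = Bipartition.make(leafset, gene_tree.taxa)
        if not is_compatible(b, ref):
            out.append(ConflictRecord(gene_id=gene_id, bipartition=b,
                                      support=float(support)))
    return out


def _leaves_below(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def classify_nni_resolvable(gene_tree: Tree, conflicts: list,
                            reference: Tree) -> list:
    """Mark each conflict with whether a *single* NNI of the gene tree
    removes every supported conflict.

    Supports travel with persisting bipartitions; the one new split an NNI
    creates has unknown support and therefore cannot itself conflict.
    """
    if not conflicts:
        return conflicts
    ref = restrict(reference, gene_tree.taxa) \
        if reference.taxa != gene_tree.taxa else reference
    resolvable = False
    for neighbor in nni_neighbors(gene_tree):
        if not detect_conflicts(neighbor, ref):
            resolvable = True
            break
    for rec in conflicts:
        rec.nni_resolvable = resolvable
    return conflicts


def screen_genes(genes: Sequence, reference: Tree,
                 model: SubstitutionMixtureModel | str = "lg",
                 bp_threshold: float = 70.0, replicates: int = 100,
                 seed: int = 0) -> ScreenReport:
    """Screen every gene; discard genes with at least one supported conflict
    that no single NNI resolves.  Deterministic given ``seed`` (each gene's
    bootstrap seed derives from the gene id, so results are invariant to
    gene input order)."""
    if isinstance(model, str):
        model = make_model(model, alpha=0.8)
    report = ScreenReport()
    for gene in sorted(genes, key=lambda g: g.gene_id):
        present = [t for t in gene.present_taxa() if t in reference.taxa]
        report.shared_taxa[gene.gene_id] = len(present)
        if len(present) < 4:
            logger.warning("gene %s has %d usable taxa; kept without screening",
                           gene.gene_id, len(present))
            report.skipped.append(gene.gene_id)
            report.kept.append(gene.gene_id)
            continue
        gene_seed = (seed * 1_000_003 + _stable_hash(gene.gene_id)) % (2 ** 31)
        boot = infer_gene_tree(gene.subset_taxa(present), model,
                               replicates=replicates, seed=int(gene_seed))
        report.gene_trees[gene.gene_id] = boot.ml_tree
        conflicts = detect_conflicts(boot.ml_tree, reference, bp_threshold,
                                     gene_id=gene.gene_id)
        conflicts = classify_nni_resolvable(boot.ml_tree, conflicts, reference)
        if any(not c.nni_resolvable for c in conflicts):
            report.discarded[gene.gene_id] = conflicts
        else:
            report.kept.append(gene.gene_id)
    return report


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return h
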