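"""Compositional-heterogeneity diagnostics: per-taxon amino-acid frequency
matrix, principal component analysis of those frequencies, per-taxon
deviation scores, and Dayhoff 6-group recoding."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .alignment import (AMINO20, DAYHOFF6, Alignment, Alphabet,
                        GeneAlignment, MISSING_SYMBOLS)

# The standard six Dayhoff groups (small/polar AGPST; acid+amide DENQ;
# basic HKR; hydrophobic ILMV; aromatic FWY; cysteine alone), encoded as
# the six digit states used by the K=6 likelihood engine.
DAYHOFF_GROUPS: dict = {
    "1": "AGPST",
    "2": "DENQ",
    "3": "HKR",
    "4": "ILMV",
    "5": "FWY",
    "6": "C",
}
DAYHOFF_MAP = {aa: g for g, members in DAYHOFF_GROUPS.items() for aa in members}


@dataclass
class CompositionMatrix:
    """taxa x K matrix of state frequencies over non-missing cells."""

    taxa: list
    frequencies: np.ndarray          # rows sum to 1
    alphabet: Alphabet = AMINO20

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=self.taxa,
                            columns=list(self.alphabet.states))


@dataclass
class PCAResult:
    """Per-taxon coordinates on principal axes + explained-variance
    fractions (non-negative, non-increasing, summing to 1 unless the matrix
    has zero variance)."""

    taxa: list
    coordinates: np.ndarray          # (n_taxa, n_axes)
    explained_variance: np.ndarray   # fractions

    def to_frame(self, axes: int = 2) -> pd.DataFrame:
        axes = min(axes, self.coordinates.shape[1])
        df = pd.DataFrame(self.coordinates[:, :axes], index=self.taxa,
                          columns=[f"PC{i + 1}" for i in range(axes)])
        return df


def composition_matrix(alignment_like) -> CompositionMatrix:
    """Per-taxon state frequencies; missing cells are excluded from both
    numerator and denominator.  Accepts an Alignment or a Supermatrix."""
    aln = alignment_like.to_alignment() if hasattr(alignment_like, "to_alignment") \
        else alignment_like
    codes = aln.codes()
    K = aln.alphabet.size
    rows = []
    for i, taxon in enumerate(aln.taxa):
        obs = codes[i][codes[i] >= 0]
        if len(obs) == 0:
            raise ValueError(f"taxon {taxon!r} has no non-missing cells")
        counts = np.bincount(obs, minlength=K).astype(float)
        rows.append(counts / counts.sum())
    return CompositionMatrix(aln.taxa, np.stack(rows), aln.alphabet)


def pca_composition(c: CompositionMatrix, scale: bool = False) -> PCAResult:
    """Covariance PCA of the composition matrix (column-centered, unscaled
    by default; ``scale=True`` for correlation PCA).  Axis signs are fixed
    by making each axis's largest-magnitude loading positive."""
    X = c.frequencies
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 taxa")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 1e-30:
        n_axes = Vt.shape[0]
        return PCAResult(c.taxa, np.zeros((X.shape[0], n_axes)),
                         np.zeros(n_axes))
    # deterministic sign: largest |loading| positive per axis
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * s
    return PCAResult(c.taxa, coords, var / total)


def heterogeneity_score(c: CompositionMatrix) -> pd.Series:
    """Per-taxon Euclidean distance from the mean composition row, sorted
    descending (largest deviation first)."""
    if len(c.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    mean = c.frequencies.mean(axis=0)
    d = np.linalg.norm(c.frequencies - mean, axis=1)
    return pd.Series(d, index=c.taxa).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------

def read_recoding_scheme(path) -> dict:
    """Two-column text file (residue, group symbol) -> mapping."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, grp = line.split()
        mapping[aa.upper()] = grp
    return mapping


def dayhoff_recode(aln: Alignment, mapping: Mapping | None = None) -> Alignment:
    """Recode a protein alignment onto the six Dayhoff groups (or a custom
    residue -> group mapping).  Missing symbols stay missing ('?'); an
    unknown residue raises with its (taxon, column) location."""
    mapping = dict(mapping or DAYHOFF_MAP)
    groups = sorted(set(mapping.values()))
    alphabet = DAYHOFF6 if groups == sorted(DAYHOFF6.states) \
        else Alphabet("".join(groups), f"recoded{len(groups)}")
    out = {}
    for taxon, seq in aln.sequences.items():
        chars = []
        for col, ch in enumerate(seq):
            cu = ch.upper()
            if cu in MISSING_SYMBOLS:
                chars.append("?")
            elif cu in mapping:
                chars.append(mapping[cu])
            else:
                raise ValueError(f"unknown residue {ch!r} at taxon {taxon!r}, "
                                 f"column {col}")
        out[taxon] = "".join(chars)
    if isinstance(aln, GeneAlignment):
        return GeneAlignment(aln.gene_id, out, alphabet)
    return Alignment(out, alphabet)
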