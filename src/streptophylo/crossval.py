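"""Cross-validation comparison of substitution models.

The alignment's columns are split into training (9/10) and test (1/10)
sets; each model's free parameters (branch lengths, gamma shape, empirical
frequencies, exchangeabilities and/or mixture profiles, as the family
calls for) are fitted on the training columns with the topology held fixed
at the reference tree, then frozen and used to score the held-out columns.
A positive mean difference A - B over replicates means model A fits
better.  The standard deviation is the sample SD (n-1 denominator) over
replicate differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .likelihood import TreeLikelihood, log_likelihood
from .substmodels import SubstitutionMixtureModel, ModelError
from .trees import Tree

KNOWN_FAMILIES = ("poisson", "lg", "gtr", "cat", "catgtr")


@dataclass(frozen=True)
class CVSplit:
    """One train/test partition of the column indices."""

    replicate: int
    train: tuple
    test: tuple
    seed: int

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test columns overlap")


@dataclass
class CVResult:
    """Per-replicate test log-likelihood differences for one model pair."""

    model_a: str
    model_b: str
    differences: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.differences))

    @property
    def sd(self) -> float:
        return float(np.std(self.differences, ddof=1)) \
            if len(self.differences) > 1 else 0.0

    def __str__(self) -> str:
        return (f"{self.model_a} vs {self.model_b}\t"
                f"{self.mean:.2f} ± {self.sd:.2f}")


def make_cv_splits(n_columns: int, replicates: int = 10,
                   seed: int = 0) -> list:
    """Uniformly random test sets of round(n/10) columns, one per
    replicate, deterministic given ``seed``."""
    if n_columns < 10:
        raise ValueError("cross validation needs at least 10 columns")
    out = []
    test_size = int(round(n_columns / 10))
    for r in range(replicates):
        rng = np.random.default_rng((seed, r))
        test = np.sort(rng.choice(n_columns, size=test_size, replace=False))
        train = np.setdiff1d(np.arange(n_columns), test)
        out.append(CVSplit(replicate=r, train=tuple(train.tolist()),
                           test=tuple(test.tolist()), seed=seed))
    return out


def fit_on_training(model_kind: str, split: CVSplit, alignment: Alignment,
                    tree: Tree, n_classes: int = 10, gamma_categories: int = 4,
                    seed: int = 0, **fit_kwargs):
    """Fit one model family on the training columns (fixed topology).
    Returns (fitted submodel, tree with trained branch lengths)."""
    if model_kind not in KNOWN_FAMILIES:
        raise ModelError(f"unknown model family {model_kind!r}; "
                         f"expected one of {KNOWN_FAMILIES}")
    train_aln = alignment.subset_columns(list(split.train))
    tl = TreeLikelihood(train_aln, tree, model_kind, n_classes=n_classes,
                        gamma_categories=gamma_categories, seed=seed)
    res = tl.fit(**fit_kwargs)
    return res.submodel, res.tree


def cv_score(model_kind: str, split: CVSplit, alignment: Alignment,
             tree: Tree, **kwargs) -> float:
    """Test-column log-likelihood under parameters trained on the training
    columns only."""
    submodel, fitted_tree = fit_on_training(model_kind, split, alignment,
                                            tree, **kwargs)
    test_aln = alignment.subset_columns(list(split.test))
    return log_likelihood(test_aln, fitted_tree, submodel).loglik


def cv_compare(model_a: str, model_b: str, splits: Sequence, alignment: Alignment,
               tree: Tree, score_cache: dict | None = None, **kwargs) -> CVResult:
    """Per-replicate difference of test scores (A - B) on identical splits."""
    cache = score_cache if score_cache is not None else {}
    diffs = []
    for split in splits:
        key_a = (model_a, split.replicate)
        key_b = (model_b, split.replicate)
        if key_a not in cache:
            cache[key_a] = cv_score(model_a, split, alignment, tree, **kwargs)
        if key_b not in cache:
            cache[key_b] = cv_score(model_b, split, alignment, tree, **kwargs)
        diffs.append(cache[key_a] - cache[key_b])
    return CVResult(model_a, model_b, np.array(diffs))


def cv_table(models: Sequence, baseline: str, splits, alignment, tree,
             **kwargs) -> pd.DataFrame:
    """Model-comparison table against a common baseline (one row per model,
    'likelihood difference +/- SD' convention: positive favours the model)."""
    cache: dict = {}
    rows = []
    for m in models:
        if m == baseline:
            continue
        r = cv_compare(m, baseline, splits, alignment, tree,
                       score_cache=cache, **kwargs)
        rows.append({"model": f"{m} vs {baseline}", "mean": r.mean, "sd": r.sd})
    return pd.DataFrame(rows)
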