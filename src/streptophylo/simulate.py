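"""Seed-controlled forward simulation of protein alignments and study-like
multi-gene datasets.

The generator produces data with the statistical structure the analysis
pipeline assumes (and some deliberate violations of it): site-class
mixtures, discrete-gamma rate variation, lineage-specific rate multipliers
(a fast-evolving clade at roughly twice the background rate), per-taxon
compositional shifts applied on terminal branches (a stationarity
violation, mimicking compositionally deviant taxa), per-gene taxon dropout
calibrated to a target global missing fraction, and paralog injection
(re-simulating one taxon's sequence on a discordant topology).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .alignment import Alignment, GeneAlignment, AMINO20, MISSING_SYMBOLS
from .substmodels import (FrequencyProfile, SubstitutionMixtureModel,
                          discrete_gamma, make_model)
from .trees import Node, Tree, TreeError, bipartitions
from .inference import random_binary_tree


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Everything one forward simulation needs.

    ``lineage_multipliers`` maps a clade (a frozenset/tuple of taxon names
    spanning a subtree, or a single taxon name for a terminal branch) to a
    positive rate factor applied to every branch inside that clade.
    ``composition_shift`` maps a taxon name to ``(profile, weight)``: on the
    terminal branch the emitted state is redrawn from ``profile`` with
    probability ``weight`` (blend weight in [0, 1])."""

    tree: Tree
    model: SubstitutionMixtureModel
    sites: int
    lineage_multipliers: Mapping = field(default_factory=dict)
    composition_shift: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sites < 1:
            raise SimulationError("need at least one site")
        taxa = self.tree.taxa
        for clade, factor in self.lineage_multipliers.items():
            if factor <= 0:
                raise SimulationError("rate multipliers must be positive")
            names = {clade} if isinstance(clade, str) else set(clade)
            unknown = names - taxa
            if unknown:
                raise SimulationError(f"unknown taxa in rate-multiplier clade: "
                                      f"{sorted(unknown)}")
        for taxon, (profile, w) in self.composition_shift.items():
            if taxon not in taxa:
                raise SimulationError(f"composition-shift taxon {taxon!r} not in tree")
            if not (0.0 <= w <= 1.0):
                raise SimulationError("blend weight must be in [0, 1]")


def _edge_multiplier(node: Node, below: frozenset,
                     multipliers: Mapping) -> float:
    factor = 1.0
    for clade, f in multipliers.items():
        names = frozenset([clade]) if isinstance(clade, str) else frozenset(clade)
        if below <= names:
            factor *= f
    return factor


def _sample_rows(P: np.ndarray, states: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw: one child state per site from the row of
    P selected by the parent state."""
    cum = np.cumsum(P, axis=1)
    u = rng.uniform(size=len(states))
    return (u[:, None] > cum[states]).sum(axis=1).astype(np.int64)


def simulate_alignment(cfg: SimulationConfig) -> tuple[Alignment, dict]:
    """Evolve an alignment along ``cfg.tree`` under ``cfg.model``.

    Per site, a mixture class and a gamma category are drawn; the root state
    comes from the class stationary profile; each branch applies the class
    transition matrix at (branch length x lineage multiplier x gamma rate).
    Returns the alignment and per-site truth (class and rate-category
    indices).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.model
    S = cfg.sites
    K = model.K
    classes = rng.choice(model.n_classes, size=S, p=model.weights)
    G = model.gamma.n_categories
    gammas = rng.integers(0, G, size=S)
    rates = model.gamma.rates[gammas]

    # subtree leaf sets for multiplier lookup
    below: dict[int, frozenset] = {}
    for node in cfg.tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

    states: dict[int, np.ndarray] = {}
    root_states = np.empty(S, dtype=np.int64)
    for c in range(model.n_classes):
        idx = classes == c
        root_states[idx] = rng.choice(K, size=int(idx.sum()),
                                      p=model.profiles[c])
    states[id(cfg.tree.root)] = root_states

    order = [n for n in cfg.tree.preorder() if n.parent is not None]
    for node in order:
        parent_states = states[id(node.parent)]
        mult = _edge_multiplier(node, below[id(node)], cfg.lineage_multipliers)
        t = (node.length if node.length is not None else 0.0) * mult
        child = np.empty(S, dtype=np.int64)
        for c in range(model.n_classes):
            for g in range(G):
                idx = (classes == c) & (gammas == g)
                if not idx.any():
                    continue
                P = model.transition(c, t * model.gamma.rates[g])
                child[idx] = _sample_rows(P, parent_states[idx], rng)
        if node.is_leaf and node.name in cfg.composition_shift:
            profile, w = cfg.composition_shift[node.name]
            redraw = rng.uniform(size=S) < w
            if redraw.any():
                child[redraw] = rng.choice(K, size=int(redraw.sum()),
                                           p=profile.values)
        states[id(node)] = child

    alpha = model.alphabet.states
    seqs = {n.name: "".join(alpha[s] for s in states[id(n)])
            for n in cfg.tree.leaves()}
    truth = {"site_class": classes, "site_gamma_category": gammas,
             "site_rate": rates}
    return Alignment(seqs, model.alphabet), truth


def inject_paralog(gene: GeneAlignment, taxon: str, alt_topology: Tree,
                   cfg: SimulationConfig, seed: int = 0) -> GeneAlignment:
    """Replace one taxon's sequence with a paralogous copy that evolved on
    a discordant topology.  Exactly one row of the alignment changes; the
    result carries ``paralog_injected=True``.

    The new row is sampled *conditionally on the untouched rows* under the
    alternative topology: per site, the posterior state distribution at the
    taxon's attachment node (given every other sequence, mixing over
    classes and rate categories) is computed by pruning on
    ``alt_topology``, a state is drawn there and evolved down the pendant
    branch.  An unconditional redraw would be statistically independent of
    the other rows and would carry no placement signal at all - the taxon
    would behave like random noise instead of like a misplaced homolog.
    """
    if taxon not in gene.sequences:
        raise SimulationError(f"taxon {taxon!r} absent from gene {gene.gene_id!r}")
    if alt_topology.taxa != cfg.tree.taxa:
        raise SimulationError("alternative topology must cover the same taxa")
    from .likelihood import PatternData, _Engine

    rng = np.random.default_rng(seed)
    model = cfg.model
    masked = dict(gene.sequences)
    masked[taxon] = "?" * gene.length
    aln = Alignment(masked, gene.alphabet)
    alt = alt_topology.copy()
    if not alt.is_binary():
        from .trees import resolve_polytomies
        alt = resolve_polytomies(alt, seed=seed)
    pat = PatternData(aln)
    eng = _Engine(pat, alt, model)
    eng.ensure_messages()
    leaf_idx = next(i for i, n in enumerate(eng.nodes)
                    if n.is_leaf and n.name == taxon)
    R = eng._store["R"][leaf_idx]            # (M, S, K), conditional at parent
    q = eng.combo_posteriors()               # (M, S)
    pendant = eng.lengths[leaf_idx]
    P_pend = eng.tp(pendant)                 # (M, K, K)
    K = model.K
    sym = model.alphabet.states

    old = gene.sequences[taxon]
    chars = []
    for col, ch in enumerate(old):
        if ch in MISSING_SYMBOLS:
            chars.append(ch)                 # keep the original missing cells
            continue
        s = pat.site_to_pattern[col]
        m = int(rng.choice(len(q), p=q[:, s] / q[:, s].sum()))
        parent_p = eng.pis[m] * R[m, s]
        parent_p = parent_p / parent_p.sum()
        i = int(rng.choice(K, p=parent_p))
        j = int(rng.choice(K, p=P_pend[m, i] / P_pend[m, i].sum()))
        chars.append(sym[j])
    seqs = dict(gene.sequences)
    seqs[taxon] = "".join(chars)
    out = GeneAlignment(gene.gene_id, seqs, gene.alphabet)
    out.paralog_injected = True
    return out


def lba_mixture(alpha: float = 0.8,
                gamma_categories: int = 4) -> SubstitutionMixtureModel:
    """A two-class compositional mixture built to probe long-branch
    attraction and its remedies.

    Both classes put the *same* total mass on each of the six Dayhoff
    groups but prefer disjoint residues inside every group (class 1 e.g.
    A,G within AGPST; class 2 P,S,T).  Saturated branches therefore
    converge within the class's preferred residues, creating an
    artifactual signal for site-homogeneous models, while the recoded
    (group-level) data are compositionally homogeneous and a
    site-heterogeneous mixture can learn the per-site restriction.
    Exchangeabilities are uniform.
    """
    from .alignment import AMINO_ACIDS
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    group_weights = [0.25, 0.20, 0.15, 0.20, 0.12, 0.08]
    class_sets = [
        ["AG", "DE", "HK", "IL", "FW", "C"],
        ["PST", "NQ", "R", "MV", "Y", "C"],
    ]
    classes = []
    for sets in class_sets:
        v = np.zeros(20)
        for wg, members in zip(group_weights, sets):
            for aa in members:
                v[idx[aa]] = wg / len(members)
        classes.append((FrequencyProfile(v), 0.5))
    from .substmodels import ExchangeabilityMatrix
    return SubstitutionMixtureModel(
        ExchangeabilityMatrix.uniform(20), classes,
        discrete_gamma(alpha, gamma_categories), kind="cat")


def felsenstein_zone_tree(short: float, long: float) -> Tree:
    """The classic four-taxon long-branch-attraction topology: two long
    terminal branches (A and C) separated by a short internal edge,
    ((A:long, B:short), (C:long, D:short))."""
    if not (long > short > 0):
        raise SimulationError("requires long > short > 0")
    from .trees import parse_newick
    return parse_newick(
        f"((A:{long},B:{short}):{short},C:{long},D:{short});")


# ---------------------------------------------------------------------------
# Study-like multi-gene datasets
# ---------------------------------------------------------------------------

@dataclass
class StudyLikeDataset:
    """A simulated multi-gene dataset with recorded ground truth."""

    genes: list                  # list[GeneAlignment] (with '?' masking)
    tree: Tree                   # generating topology with branch lengths
    labels: dict                 # gene_id -> 'orthologous' | 'paralog-injected'
    fast_clade: frozenset
    shifted_taxa: frozenset
    target_missing: float

    @property
    def missing_fraction(self) -> float:
        total = 0
        miss = 0
        taxa = self.tree.taxa
        for g in self.genes:
            total += len(taxa) * g.length
            for t in taxa:
                seq = g.sequences.get(t)
                if seq is None:
                    miss += g.length
                else:
                    miss += sum(ch == "?" for ch in seq)
        return miss / total


def _truncated_binomial_p(n: int, cap: int, target_mean: float) -> float:
    """Success probability p such that a Binomial(n, p) truncated to <= cap
    has the requested mean."""

    def mean(p):
        k = np.arange(cap + 1)
        pk = binom.pmf(k, n, p)
        return float((k * pk).sum() / pk.sum())

    if target_mean <= 0:
        return 0.0
    hi = 0.999
    if mean(hi) < target_mean:
        raise SimulationError(
            f"target missing fraction {target_mean / n:.2f} is unreachable with "
            f"at most {cap} missing taxa per gene (max ~{mean(hi) / n:.2f})")
    return brentq(lambda p: mean(p) - target_mean, 1e-9, hi)


def regraft_taxon(tree: Tree, taxon: str, rng: np.random.Generator,
                  min_distance: int = 3) -> Tree:
    """Prune one leaf and reattach it on a distant edge (a deliberate deep
    misplacement, as an undetected paralog would produce).

    The reattachment point is chosen so that the resulting topology differs
    from the input by at least 2*(min_distance - 1) bipartitions, i.e. the
    conflict cannot be undone by fewer than ``min_distance - 1`` NNI moves.
    The leaf keeps its pendant length; the target edge is split at its
    midpoint.  The backbone (tree without the leaf) is unchanged.
    """
    from .trees import rf_distance

    original = tree.copy()
    tree = tree.copy()
    leaf = next(n for n in tree.leaves() if n.name == taxon)
    pendant = leaf.length if leaf.length is not None else 0.1
    parent = leaf.parent
    if parent is None:
        raise SimulationError("cannot regraft the root")
    parent.children.remove(leaf)
    if parent.parent is not None and len(parent.children) == 1:
        only = parent.children[0]
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    elif parent.parent is None and len(parent.children) == 2:
        tree = Tree(parent, rooted=False).deroot()
    pruned = Tree(tree.root, rooted=False)

    def node_path(t: Tree, target: Node):
        path = []
        node = target
        while node.parent is not None:
            path.append(node.parent.children.index(node))
            node = node.parent
        return tuple(reversed(path))

    def attach(path) -> Tree:
        out = pruned.copy()
        target = out.root
        for k in path:
            target = target.children[k]
        t_len = target.length if target.length is not None else 0.1
        mid = Node(length=t_len / 2)
        p = target.parent
        p.children[p.children.index(target)] = mid
        mid.parent = p
        target.length = t_len / 2
        mid.add(target)
        mid.add(Node(name=taxon, length=pendant))
        return Tree(out.root, rooted=False)

    edges = [n for n in pruned.preorder() if n.parent is not None]
    paths = [node_path(pruned, n) for n in edges]
    order = rng.permutation(len(paths))
    want = 2 * max(min_distance - 1, 1)
    best, best_d = None, -1
    for k in order:
        cand = attach(paths[int(k)])
        d = rf_distance(cand, original)
        if d >= want:
            return cand
        if d > best_d:
            best, best_d = cand, d
    return best


def _nni_chain(tree: Tree, steps: int, rng: np.random.Generator) -> Tree:
    """A topology ``steps`` NNI moves away from ``tree`` (each move chosen
    uniformly, never undoing to a previously visited split set)."""
    from .trees import nni_neighbors
    seen = {frozenset(bipartitions(tree))}
    cur = tree
    for _ in range(steps):
        neighbors = nni_neighbors(cur)
        rng.shuffle(neighbors)
        nxt = next((n for n in neighbors
                    if frozenset(bipartitions(n)) not in seen), neighbors[0])
        seen.add(frozenset(bipartitions(nxt)))
        cur = nxt
    return cur


def make_study_like_dataset(
        n_taxa: int = 46, n_genes: int = 129, target_missing: float = 0.30,
        fast_clade_size: int = 4, fast_factor: float = 2.0,
        n_shifted_taxa: int = 3, shift_weight: float = 0.15,
        paralog_fraction: float = 0.0, paralog_nni_steps: int = 3,
        gene_length_median: float = 235.0, gene_length_sigma: float = 0.35,
        max_missing_per_gene: int | None = None,
        model: SubstitutionMixtureModel | None = None,
        mean_branch_length: float = 0.12, min_branch_length: float = 0.0,
        seed: int = 0) -> StudyLikeDataset:
    """Generate a dataset shaped like an EST-derived phylogenomic matrix:
    many genes over a shared taxon set, lognormal gene lengths (median ~235
    columns so ~129 genes total ~30k positions), per-gene taxon dropout
    truncated at ``max_missing_per_gene`` (default: scaled from 16-of-46)
    and calibrated so the realized global missing fraction hits
    ``target_missing``, a fast-evolving clade (default twice the background
    rate), compositionally shifted taxa, and a fraction of genes carrying an
    injected paralog whose taxon evolved on a topology several NNI moves
    away from the truth.  All ground truth is recorded.
    """
    if not (0.0 <= target_missing < 1.0):
        raise SimulationError("target_missing must be in [0, 1)")
    if not (0.0 <= paralog_fraction <= 1.0):
        raise SimulationError("paralog_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"t{str(i + 1).zfill(2)}" for i in range(n_taxa)]
    tree = random_binary_tree(taxa, rng, mean_length=mean_branch_length,
                              min_length=min_branch_length)
    if model is None:
        model = make_model("lg", alpha=0.8, gamma_categories=4)

    # fast clade: smallest subtree with >= fast_clade_size leaves
    below = {}
    for node in tree.postorder():
        below[id(node)] = (frozenset([node.name]) if node.is_leaf else
                           frozenset().union(*(below[id(c)] for c in node.children)))
    candidates = [below[id(n)] for n in tree.preorder()
                  if n.parent is not None and not n.is_leaf
                  and fast_clade_size <= len(below[id(n)]) <= max(fast_clade_size,
                                                                  n_taxa // 3)]
    fast_clade = (min(candidates, key=len) if candidates and fast_clade_size > 0
                  else frozenset())
    multipliers = {tuple(sorted(fast_clade)): fast_factor} if fast_clade else {}

    shifted = frozenset(rng.choice(
        [t for t in taxa if t not in fast_clade],
        size=min(n_shifted_taxa, n_taxa), replace=False)) \
        if n_shifted_taxa > 0 else frozenset()
    K = model.K
    shift_map = {}
    for t in sorted(shifted):
        biased = FrequencyProfile(rng.dirichlet(np.full(K, 0.3)))
        shift_map[t] = (biased, shift_weight)

    if max_missing_per_gene is None:
        max_missing_per_gene = max(0, int(round(16 / 46 * n_taxa)))
    p_drop = _truncated_binomial_p(n_taxa, max_missing_per_gene,
                                   target_missing * n_taxa) \
        if target_missing > 0 else 0.0

    lengths = np.maximum(20, np.round(rng.lognormal(
        math.log(gene_length_median), gene_length_sigma, size=n_genes))).astype(int)

    n_paralog = int(round(paralog_fraction * n_genes))
    paralog_genes = set(rng.choice(n_genes, size=n_paralog, replace=False)) \
        if n_paralog else set()

    genes = []
    labels = {}
    victims = {}
    for gi in range(n_genes):
        gene_id = f"g{str(gi + 1).zfill(3)}"
        cfg = SimulationConfig(tree=tree, model=model, sites=int(lengths[gi]),
                               lineage_multipliers=multipliers,
                               composition_shift=shift_map,
                               seed=int(rng.integers(2 ** 31)))
        aln, _ = simulate_alignment(cfg)
        gene = GeneAlignment(gene_id, aln.sequences, aln.alphabet)
        label = "orthologous"
        victim = None
        if gi in paralog_genes:
            victim = str(rng.choice(sorted(tree.taxa)))
            alt = regraft_taxon(tree, victim, rng,
                                min_distance=paralog_nni_steps)
            gene = inject_paralog(gene, victim, alt, cfg,
                                  seed=int(rng.integers(2 ** 31)))
            label = "paralog-injected"
        # taxon dropout (whole-gene), truncated at the occupancy cap.
        # Paralog-injected genes are left at full occupancy: masking rows
        # could shorten the injected displacement (the conflict's depth is
        # defined on the full taxon set) and a missing victim row cannot
        # carry a paralogous sequence at all.
        while True:
            m = rng.binomial(n_taxa, p_drop) if p_drop > 0 else 0
            if m <= max_missing_per_gene:
                break
        if victim is not None:
            m = 0
        if m > 0:
            droppable = [t for t in taxa if t != victim]
            drop = rng.choice(droppable, size=min(m, len(droppable)),
                              replace=False)
            seqs = dict(gene.sequences)
            for t in drop:
                seqs[t] = "?" * gene.length
            g2 = GeneAlignment(gene_id, seqs, gene.alphabet)
            g2.paralog_injected = getattr(gene, "paralog_injected", False)
            gene = g2
        genes.append(gene)
        labels[gene_id] = label
        if victim is not None:
            victims[gene_id] = victim

    ds = StudyLikeDataset(genes=genes, tree=tree, labels=labels,
                          fast_clade=fast_clade, shifted_taxa=shifted,
                          target_missing=target_missing)
    ds.paralog_victims = victims
    return ds
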