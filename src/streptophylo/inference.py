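"""Tree inference: distance starting trees, greedy NNI hill-climbing under
the likelihood, nonparametric bootstrap, and a lightweight topology+length
MCMC with the two-chain bipartition-frequency convergence diagnostic.

The MCMC deliberately samples only topology and branch lengths at fixed
model parameters (an empirical-Bayes shortcut: substitution parameters are
plugged in at their ML/EM estimates).  Reports flag this, and flag any
between-chain maximum bipartition-frequency difference >= 0.1 as
non-converged.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .likelihood import (
    BRANCH_MAX, BRANCH_MIN, DEFAULT_BRANCH, LikelihoodError, PatternData,
    TreeLikelihood, _Engine, _optimize_lengths_inplace,
)
from .substmodels import SubstitutionMixtureModel
from .trees import (
    Bipartition, Node, Tree, TreeError, TreeSample, bipartitions,
    majority_consensus, bipartition_maxdiff, write_newick,
)


# ---------------------------------------------------------------------------
# ML pairwise distances and neighbor joining
# ---------------------------------------------------------------------------

def _pair_counts(pat: PatternData, i: int, j: int) -> np.ndarray:
    a = pat.patterns[i]
    b = pat.patterns[j]
    ok = (a >= 0) & (b >= 0)
    K = pat.alphabet.size
    F = np.zeros((K, K))
    np.add.at(F, (a[ok], b[ok]), pat.weights[ok])
    return F


def ml_pairwise_distance(F: np.ndarray, model: SubstitutionMixtureModel,
                         fallback: float = 3.0) -> float:
    """Maximum-likelihood distance for one taxon pair from its joint
    residue-pair count matrix, under the model's mixture (Brent search)."""
    if F.sum() <= 0:
        return fallback
    w = model.weights
    G = model.gamma
    mask = F > 0

    def nll(t: float) -> float:
        like = np.zeros_like(F)
        for c in range(model.n_classes):
            pi = model.profiles[c]
            for g in range(G.n_categories):
                P = model.transition(c, t * G.rates[g])
                like += (w[c] / G.n_categories) * pi[:, None] * P
        return -float((F[mask] * np.log(np.maximum(like[mask], 1e-320))).sum())

    res = minimize_scalar(nll, bounds=(1e-6, BRANCH_MAX), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def distance_matrix(alignment: Alignment, model: SubstitutionMixtureModel,
                    pat: PatternData | None = None) -> tuple[np.ndarray, list]:
    pat = pat or PatternData(alignment)
    taxa = pat.taxa
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(_pair_counts(pat, i, j), model)
    return D, taxa


def neighbor_joining(D: np.ndarray, taxa: Sequence[str]) -> Tree:
    """Classic neighbor joining; negative estimated edge lengths are clamped
    to a small positive value so downstream parsing and likelihood accept
    the tree.  Returns an unrooted tree (trifurcating root)."""
    n = len(taxa)
    if n < 2:
        raise TreeError("need at least 2 taxa")
    nodes = [Node(name=t) for t in taxa]
    D = D.copy().astype(float)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        ai, aj = np.unravel_index(np.argmin(Qm), Qm.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            child.length = float(np.clip(ln, BRANCH_MIN, BRANCH_MAX))
            parent.add(child)
        # distances to the new node
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]
    root = Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            nodes[idx].length = float(np.clip(ln, BRANCH_MIN, BRANCH_MAX))
            root.add(nodes[idx])
    else:  # exactly two
        i, j = active
        for idx, ln in ((i, D[i, j] / 2), (j, D[i, j] / 2)):
            nodes[idx].length = float(np.clip(ln, BRANCH_MIN, BRANCH_MAX))
            root.add(nodes[idx])
    return Tree(root, rooted=False)


def nj_start_tree(alignment: Alignment, model: SubstitutionMixtureModel,
                  pat: PatternData | None = None) -> Tree:
    D, taxa = distance_matrix(alignment, model, pat)
    return neighbor_joining(D, taxa)


# ---------------------------------------------------------------------------
# Greedy NNI hill-climbing
# ---------------------------------------------------------------------------

def _combine(msgs, scales):
    prod = msgs[0]
    sc = scales[0]
    for m, s in zip(msgs[1:], scales[1:]):
        prod = prod * m
        sc = sc + s
    return prod, sc


def _edge_candidates(eng: _Engine):
    """Yield (edge_idx, swap_which, objective) for every NNI rearrangement,
    where objective(t) is the total log-likelihood of the rearranged tree as
    a function of the central edge length (peripheral lengths fixed)."""
    if eng._stale:
        eng.refresh()
    st = eng._store
    M, S, K = eng.M, eng.pat.n_patterns, eng.K
    w = eng.pat.weights

    def bcast(a, s):
        return (np.broadcast_to(a, (M, S, K)), np.broadcast_to(s, (M, S)))

    for i, node in enumerate(eng.nodes):
        if i == eng.root or node.is_leaf:
            continue
        p_idx = eng.parent[i]
        x1, x2 = eng.children[i]
        sibs = [c for c in eng.children[p_idx] if c != i]
        s_idx = sibs[0]
        rest_msgs, rest_scales = [], []
        for other in sibs[1:]:
            rest_msgs.append(np.broadcast_to(st["U"][other], (M, S, K)))
            rest_scales.append(np.broadcast_to(st["sU"][other], (M, S)))
        if p_idx != eng.root:
            rest_msgs.append(np.broadcast_to(st["V"][p_idx], (M, S, K)))
            rest_scales.append(np.broadcast_to(st["sV"][p_idx], (M, S)))
        if not rest_msgs:
            rest_msgs = [np.ones((M, S, K))]
            rest_scales = [np.zeros((M, S))]
        rest, s_rest = _combine(rest_msgs, rest_scales)
        Ux1, sx1 = bcast(st["U"][x1], st["sU"][x1])
        Ux2, sx2 = bcast(st["U"][x2], st["sU"][x2])
        Us, ss = bcast(st["U"][s_idx], st["sU"][s_idx])

        def make_obj(A, sA, B, sB):
            Bpi = B * eng.pis[:, None, :]
            scale = sA + sB + eng.log_wm[:, None]

            def f(t: float) -> float:
                P = eng.tp(t)
                X = np.matmul(Bpi, P)
                val = np.maximum((X * A).sum(-1), 1e-320)
                return float(logsumexp(np.log(val) + scale, axis=0) @ w)

            return f

        # swap x1 <-> s : v holds {s, x2}, p side holds {x1, rest}
        yield i, 0, make_obj(Us * Ux2, ss + sx2, Ux1 * rest, sx1 + s_rest)
        # swap x2 <-> s : v holds {x1, s}, p side holds {x2, rest}
        yield i, 1, make_obj(Ux1 * Us, sx1 + ss, Ux2 * rest, sx2 + s_rest)


def _apply_nni(tree: Tree, eng: _Engine, edge_idx: int, which: int,
               new_central: float) -> None:
    v = eng.nodes[edge_idx]
    p = v.parent
    s = next(c for c in p.children if c is not v)
    x = v.children[which]
    v.children[v.children.index(x)] = s
    p.children[p.children.index(s)] = x
    x.parent, s.parent = p, v
    v.support = None
    v.length = float(np.clip(new_central, BRANCH_MIN, BRANCH_MAX))


def nni_search(alignment: Alignment, start: Tree,
               model: SubstitutionMixtureModel,
               tol: float = 1e-3, max_iter: int = 100,
               branch_rounds: int = 2,
               pat: PatternData | None = None) -> tuple[Tree, float]:
    """Greedy NNI hill-climbing with branch-length re-optimization.

    At each step every NNI rearrangement is scored by re-optimizing the
    central edge against cached messages; the best strictly improving move is
    applied (ties broken by lexicographic bipartition order for
    determinism), followed by a quick branch-length pass.  Stops at a local
    optimum.  Returns the tree and its final log-likelihood.
    """
    tree = start.copy()
    if not tree.is_binary():
        from .trees import resolve_polytomies
        tree = resolve_polytomies(tree, seed=0)
    pat = pat or PatternData(alignment)
    eng = _Engine(pat, tree, model)
    cur = _optimize_lengths_inplace(eng, tol=max(tol, 1e-4),
                                    max_rounds=branch_rounds)
    for _ in range(max_iter):
        best = None
        for i, which, obj in _edge_candidates(eng):
            res = minimize_scalar(lambda t: -obj(t),
                                  bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": 1e-6})
            ll = -res.fun
            if ll > cur + tol:
                key = (ll, -i, -which)
                if best is None or key > best[0]:
                    best = (key, i, which, float(res.x))
        if best is None:
            break
        _, i, which, t_new = best
        _apply_nni(tree, eng, i, which, t_new)
        eng = _Engine(pat, tree, eng.model)
        cur = _optimize_lengths_inplace(eng, tol=max(tol, 1e-4),
                                        max_rounds=branch_rounds)
    return tree, cur


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    ml_tree: Tree            # support-annotated ML tree
    sample: TreeSample       # replicate trees
    supports: dict           # Bipartition -> percentage


def _resampled_pattern_data(pat: PatternData, rng: np.random.Generator) -> PatternData:
    """Bootstrap columns by drawing multinomial weights over the existing
    site patterns (equivalent to resampling columns with replacement)."""
    new = copy.copy(pat)
    p = pat.weights / pat.weights.sum()
    w = rng.multinomial(int(pat.weights.sum()), p).astype(float)
    keep = w > 0                      # drop unsampled patterns
    new.patterns = pat.patterns[:, keep]
    new.weights = w[keep]
    new.site_to_pattern = None        # per-site expansion undefined for replicates
    return new


def bootstrap(alignment: Alignment, model: SubstitutionMixtureModel,
              replicates: int = 100, seed: int = 0,
              ml_tree: Tree | None = None,
              search: bool = True) -> BootstrapResult:
    """Nonparametric bootstrap: resample columns, re-search the topology per
    replicate (NJ start + NNI hill-climbing), and annotate the ML tree's
    bipartitions with the percentage of replicates containing them.

    Model parameters are held fixed at the supplied estimates across
    replicates; branch lengths and topology are re-inferred per replicate.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    pat = PatternData(alignment)
    if ml_tree is None:
        start = nj_start_tree(alignment, model, pat)
        ml_tree, _ = nni_search(alignment, start, model, pat=pat)
    ml_tree = ml_tree.copy()
    reps = []
    for _ in range(replicates):
        rpat = _resampled_pattern_data(pat, rng)
        D = np.zeros((len(rpat.taxa), len(rpat.taxa)))
        for i in range(len(rpat.taxa)):
            for j in range(i + 1, len(rpat.taxa)):
                D[i, j] = D[j, i] = ml_pairwise_distance(
                    _pair_counts(rpat, i, j), model)
        start = neighbor_joining(D, rpat.taxa)
        if search:
            t, _ = nni_search(alignment, start, model, pat=rpat,
                              branch_rounds=1)
        else:
            eng = _Engine(rpat, start, model)
            _optimize_lengths_inplace(eng, tol=1e-3, max_rounds=2)
            t = start
        reps.append(t)
    sample = TreeSample(reps)
    freqs = sample.split_frequencies()
    supports = {}
    for b in bipartitions(ml_tree):
        supports[b] = 100.0 * freqs.get(b, 0.0)
    _annotate_supports(ml_tree, supports)
    ml_tree.support_kind = "bp"
    return BootstrapResult(ml_tree=ml_tree, sample=sample, supports=supports)


def _annotate_supports(tree: Tree, supports: dict) -> None:
    taxa = tree.taxa
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is not tree.root and 1 < len(below[id(node)]) < len(taxa) - 1:
                b = Bipartition.make(below[id(node)], taxa)
                if b in supports:
                    node.support = supports[b]


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class McmcResult:
    chains: list                  # list[TreeSample]
    consensus: Tree               # PP-annotated consensus (supports 0-100)
    maxdiff: float
    converged: bool
    acceptance: dict              # move type -> acceptance fraction
    posterior_probs: dict         # Bipartition -> PP on 0-1 scale


def random_binary_tree(taxa: Sequence[str], rng: np.random.Generator,
                       mean_length: float = 0.1,
                       min_length: float = 0.0) -> Tree:
    """A uniformly assembled random binary unrooted tree with Exp(mean)
    branch lengths, optionally floored at ``min_length`` (used for MCMC
    chain starts and simulations; floor the lengths when every split must
    stay resolvable at finite alignment length)."""
    taxa = list(taxa)

    def draw() -> float:
        return float(max(rng.exponential(mean_length), min_length))

    nodes = [Node(name=t, length=draw()) for t in taxa]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(length=draw())
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    if len(taxa) == 2:
        root.children[0].length = root.children[0].length or DEFAULT_BRANCH
    return Tree(root, rooted=False)


def _log_prior(tree: Tree, mean: float = 0.1) -> float:
    s = 0.0
    for n in tree.preorder():
        if n.parent is not None:
            s += -math.log(mean) - (n.length or 0.0) / mean
    return s


def mcmc_sample(alignment: Alignment, model: SubstitutionMixtureModel,
                cycles: int = 10000, thin: int = 10, burnin: int = 1000,
                seed: int = 0, chains: int = 2,
                prior_mean_length: float = 0.1) -> McmcResult:
    """Metropolis-Hastings over topology (random NNI) and branch lengths
    (multiplier proposals) at fixed substitution-model parameters.

    One cycle = one topology proposal plus one multiplier proposal per
    branch.  Every ``thin``-th cycle after ``burnin`` is sampled.  The
    convergence report is the maximum bipartition-frequency difference
    between chains; >= 0.1 is flagged (the run still completes).
    """
    pat = PatternData(alignment)
    samples = []
    acc: dict[str, list] = {"nni": [0, 0], "length": [0, 0]}
    for chain in range(chains):
        rng = np.random.default_rng((seed, chain))
        tree = random_binary_tree(alignment.taxa, rng, prior_mean_length)
        eng = _Engine(pat, tree, model)
        cur_ll = eng.loglik()
        cur_prior = _log_prior(tree, prior_mean_length)
        kept = []
        for cycle in range(1, cycles + 1):
            # one NNI proposal (uniform over 2(n-3) rearrangements, symmetric)
            internal = tree.internal_edges()
            if internal:
                cand = tree.copy()
                cand_internal = cand.internal_edges()
                v = cand_internal[int(rng.integers(len(cand_internal)))]
                which = int(rng.integers(2))
                p = v.parent
                s = next(c for c in p.children if c is not v)
                x = v.children[which]
                v.children[v.children.index(x)] = s
                p.children[p.children.index(s)] = x
                x.parent, s.parent = p, v
                ceng = _Engine(pat, cand, model)
                new_ll = ceng.loglik()
                new_prior = _log_prior(cand, prior_mean_length)
                acc["nni"][1] += 1
                if math.log(rng.uniform()) < (new_ll + new_prior
                                              - cur_ll - cur_prior):
                    tree, eng = cand, ceng
                    cur_ll, cur_prior = new_ll, new_prior
                    acc["nni"][0] += 1
            # multiplier proposals on each branch
            lam = 1.0
            for i in range(len(eng.nodes)):
                if i == eng.root:
                    continue
                t_old = eng.lengths[i]
                factor = math.exp(lam * (rng.uniform() - 0.5))
                t_new = float(np.clip(t_old * factor, BRANCH_MIN, BRANCH_MAX))
                f = eng.edge_loglik_fn(i)
                ll_old = f(t_old)
                ll_new = f(t_new)
                dprior = (t_old - t_new) / prior_mean_length
                log_hastings = math.log(t_new / t_old)
                acc["length"][1] += 1
                if math.log(rng.uniform()) < ll_new - ll_old + dprior + log_hastings:
                    eng.set_length(i, t_new)
                    eng.refresh()
                    cur_ll = eng.loglik()
                    cur_prior = _log_prior(tree, prior_mean_length)
                    acc["length"][0] += 1
            if cycle > burnin and cycle % thin == 0:
                kept.append(tree.copy())
        samples.append(TreeSample(kept))
    maxdiff = bipartition_maxdiff(samples[0], samples[1]) if chains >= 2 else 0.0
    pooled = TreeSample([t for s in samples for t in s])
    consensus = majority_consensus(pooled)
    consensus.support_kind = "pp"
    pp = {b: f for b, f in pooled.split_frequencies().items()}
    rates = {k: (v[0] / v[1] if v[1] else 0.0) for k, v in acc.items()}
    return McmcResult(chains=samples, consensus=consensus, maxdiff=maxdiff,
                      converged=maxdiff < 0.1, acceptance=rates,
                      posterior_probs=pp)
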