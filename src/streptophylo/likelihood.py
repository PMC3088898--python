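"""Felsenstein pruning likelihood for mixture models on unrooted trees, and
maximum-likelihood fitting of branch lengths, gamma shape, exchangeabilities
and mixture profiles.

The central objects follow the statsmodels convention: build a
:class:`TreeLikelihood` model from data (alignment + tree + substitution
model), call :meth:`TreeLikelihood.fit` and work with the returned
:class:`TreeLikelihoodResults`.

Implementation notes
--------------------
Sites are compressed to unique columns ("patterns") with multiplicities.
For every mixture class c and gamma category g the engine keeps directional
messages on every edge:

* ``D[v]`` - conditional likelihood of the subtree below node v, given the
  state at v;
* ``U[v]`` - the same subtree seen from v's parent (``D[v]`` pushed through
  the edge's transition matrix);
* ``R[v]`` - conditional likelihood of everything *outside* v's subtree,
  given the state at v's parent.

Because all models here are time-reversible, the site likelihood can be
evaluated on any single edge as ``sum_ij pi_i R_i P(t)_ij D_j``; this makes
one-dimensional branch-length optimization and NNI rearrangement scoring
cheap (the messages away from the edge are reused unchanged).  Per-node
rescaling keeps partial likelihoods in floating range for long alignments;
all log-likelihoods are natural logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment, Alphabet, AMINO20
from .substmodels import (
    ExchangeabilityMatrix, FrequencyProfile, GammaRates, SubstitutionMixtureModel,
    _SpectralDecomposition, build_rate_matrix, discrete_gamma, make_model,
)
from .trees import Tree, TreeError

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0
DEFAULT_BRANCH = 0.1


class LikelihoodError(ValueError):
    pass


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods (nats), with optional per-site
    mixture-class posterior probabilities."""

    loglik: float
    site_logliks: np.ndarray
    class_posteriors: np.ndarray | None = None  # (n_classes, n_sites)


# ---------------------------------------------------------------------------
# Pattern compression
# ---------------------------------------------------------------------------

class PatternData:
    """Unique alignment columns with multiplicities, in a fixed taxon order."""

    def __init__(self, alignment: Alignment, taxa: Sequence[str] | None = None):
        self.taxa = list(taxa) if taxa is not None else alignment.taxa
        codes = alignment.codes(self.taxa)          # (n_taxa, n_cols)
        self.n_sites = codes.shape[1]
        cols, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = cols.T                       # (n_taxa, n_patterns)
        self.weights = counts.astype(float)
        self.site_to_pattern = inverse
        self.alphabet = alignment.alphabet

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector (last axis) back to per-site order."""
        return per_pattern[..., self.site_to_pattern]

    def state_counts(self) -> np.ndarray:
        """(n_patterns, K) residue counts over non-missing rows, used by the
        mixture-profile M-step."""
        K = self.alphabet.size
        S = self.n_patterns
        out = np.zeros((S, K))
        for row in self.patterns:
            ok = row >= 0
            np.add.at(out, (np.nonzero(ok)[0], row[ok]), 1.0)
        return out


# ---------------------------------------------------------------------------
# The message-passing engine
# ---------------------------------------------------------------------------

class _Engine:
    """Pruning engine bound to one (patterns, tree topology, model) triple.

    The tree's Node objects are referenced directly; ``lengths`` mirrors the
    node branch lengths (clamped to [BRANCH_MIN, BRANCH_MAX], missing values
    replaced by DEFAULT_BRANCH).  Call :meth:`refresh` after editing lengths
    on the tree, or use :meth:`set_length` to keep both in sync.
    """

    def __init__(self, pat: PatternData, tree: Tree, model: SubstitutionMixtureModel):
        if not tree.is_binary():
            raise LikelihoodError("likelihood requires a binary tree")
        missing = set(pat.taxa) - set(tree.taxa)
        if missing:
            raise LikelihoodError(
                f"taxon {sorted(missing)[0]!r} is in the alignment but not the tree")
        if model.alphabet.size != pat.alphabet.size:
            raise LikelihoodError("model alphabet does not match the alignment")
        self.pat = pat
        self.tree = tree
        self.model = model

        # postorder arrays; root is last
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1
             for n in self.nodes])
        self.children = [[self.index[id(c)] for c in n.children] for n in self.nodes]
        self.root = len(self.nodes) - 1
        self.lengths = np.array(
            [np.clip(n.length if n.length is not None else DEFAULT_BRANCH,
                     BRANCH_MIN, BRANCH_MAX)
             if n.parent is not None else 0.0 for n in self.nodes])
        taxon_row = {t: i for i, t in enumerate(pat.taxa)}
        self.leaf_row = [taxon_row.get(n.name, -1) if n.is_leaf else -1
                         for n in self.nodes]

        # (class, gamma) combos
        g = model.gamma
        self.combos = [(c, gi) for c in range(model.n_classes)
                       for gi in range(g.n_categories)]
        self.rates = np.array([g.rates[gi] for _, gi in self.combos])
        self.log_wm = np.log(np.array(
            [model.weights[c] / g.n_categories for c, _ in self.combos]))
        self.pis = np.stack([model.profiles[c] for c, _ in self.combos])  # (M,K)
        self.M = len(self.combos)
        self.K = model.K
        self._leaf_D_cache: dict[int, np.ndarray] = {}
        self._stale = True
        self._outward_stale = True
        self._store: dict = {}

    # -- transition matrices ----------------------------------------------

    def tp(self, t: float) -> np.ndarray:
        """(M, K, K) transition matrices for one branch length."""
        decs = self.model.decompositions()
        out = np.empty((self.M, self.K, self.K))
        for m, (c, _) in enumerate(self.combos):
            out[m] = decs[c].transition(t * self.rates[m])
        return out

    # -- leaf partials -----------------------------------------------------

    def _leaf_D(self, node_idx: int) -> np.ndarray:
        D = self._leaf_D_cache.get(node_idx)
        if D is None:
            codes = self.pat.patterns[self.leaf_row[node_idx]]
            D = np.zeros((1, self.pat.n_patterns, self.K))
            ok = codes >= 0
            D[0, ok, codes[ok]] = 1.0
            D[0, ~ok, :] = 1.0
            self._leaf_D_cache[node_idx] = D
        return D

    # -- message passes ----------------------------------------------------

    @staticmethod
    def _rescale(arr: np.ndarray, logs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mx = arr.max(axis=-1)
        mx = np.where(mx > 0, mx, 1.0)
        return arr / mx[..., None], logs + np.log(mx)

    def refresh(self) -> None:
        """Recompute all directional messages (full two-pass sweep)."""
        self._refresh_inward()
        self._refresh_outward()

    def _refresh_inward(self) -> None:
        """Postorder pass: subtree partials D and up messages U."""
        S, M = self.pat.n_patterns, self.M
        D: list = [None] * len(self.nodes)
        sD: list = [None] * len(self.nodes)
        U: list = [None] * len(self.nodes)
        sU: list = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if node.is_leaf and self.leaf_row[i] >= 0:
                D[i], sD[i] = self._leaf_D(i), np.zeros((1, S))
            else:
                prod = None
                scale = 0.0
                for c in self.children[i]:
                    prod = U[c] if prod is None else prod * U[c]
                    scale = scale + sU[c]
                D[i], sD[i] = self._rescale(prod, scale)
            if i != self.root:
                P = self.tp(self.lengths[i])
                U[i] = np.matmul(D[i] if D[i].shape[0] == M else
                                 np.broadcast_to(D[i], (M, S, self.K)), P.transpose(0, 2, 1))
                sU[i] = np.broadcast_to(sD[i], (M, S)).copy()
                U[i], sU[i] = self._rescale(U[i], sU[i])
        self._store.update(D=D, sD=sD, U=U, sU=sU)
        self._stale = False
        self._outward_stale = True

    def _refresh_outward(self) -> None:
        """Preorder pass: outside partials R and down messages V (requires
        current inward messages)."""
        if self._stale:
            self._refresh_inward()
        S, M = self.pat.n_patterns, self.M
        U, sU = self._store["U"], self._store["sU"]
        R: list = [None] * len(self.nodes)
        sR: list = [None] * len(self.nodes)
        V: list = [None] * len(self.nodes)
        sV: list = [None] * len(self.nodes)
        V[self.root] = np.ones((1, S, self.K))
        sV[self.root] = np.zeros((1, S))
        for i in reversed(range(len(self.nodes))):   # preorder
            node = self.nodes[i]
            if node.is_leaf:
                continue
            for c in self.children[i]:
                prod = V[i]
                scale = sV[i]
                for sib in self.children[i]:
                    if sib != c:
                        prod = prod * U[sib]
                        scale = scale + sU[sib]
                R[c], sR[c] = self._rescale(
                    np.broadcast_to(prod, (M, S, self.K)).copy(),
                    np.broadcast_to(scale, (M, S)).copy())
                P = self.tp(self.lengths[c])
                V[c] = np.matmul(R[c], P.transpose(0, 2, 1))
                sV[c] = sR[c].copy()
                V[c], sV[c] = self._rescale(V[c], sV[c])
        self._store.update(R=R, sR=sR, V=V, sV=sV)
        self._outward_stale = False

    def _root_l_ms(self) -> np.ndarray:
        """(M, S) per-combo per-pattern log-likelihoods."""
        if self._stale:
            self._refresh_inward()
        D, sD = self._store["D"], self._store["sD"]
        inner = (self.pis[:, None, :] * D[self.root]).sum(-1)
        return np.log(np.maximum(inner, 1e-320)) + sD[self.root]

    def site_logliks(self) -> np.ndarray:
        """(S,) per-pattern log-likelihoods (mixed over classes and rates)."""
        l_ms = self._root_l_ms()
        return logsumexp(l_ms + self.log_wm[:, None], axis=0)

    def loglik(self) -> float:
        return float(self.site_logliks() @ self.pat.weights)

    def combo_posteriors(self) -> np.ndarray:
        """(M, S) posterior probability of each (class, gamma) combo per
        pattern."""
        l_ms = self._root_l_ms() + self.log_wm[:, None]
        return np.exp(l_ms - logsumexp(l_ms, axis=0, keepdims=True))

    # -- edge-local computations -------------------------------------------

    def ensure_messages(self) -> None:
        if self._stale:
            self._refresh_inward()
        if self._outward_stale:
            self._refresh_outward()

    def edge_loglik_fn(self, i: int) -> Callable[[float], float]:
        """The total log-likelihood as a 1-D function of edge i's length,
        all other edges fixed (uses cached messages)."""
        self.ensure_messages()
        st = self._store
        M, S, K = self.M, self.pat.n_patterns, self.K
        Rpi = st["R"][i] * self.pis[:, None, :]
        Dv = np.broadcast_to(st["D"][i], (M, S, K))
        scale = (np.broadcast_to(st["sD"][i], (M, S)) + st["sR"][i]
                 + self.log_wm[:, None])
        w = self.pat.weights

        def f(t: float) -> float:
            P = self.tp(t)
            X = np.matmul(Rpi, P)
            val = np.maximum((X * Dv).sum(-1), 1e-320)
            return float(logsumexp(np.log(val) + scale, axis=0) @ w)

        return f

    def _recompute_R(self, i: int) -> None:
        """Refresh the outside message of edge i from its parent's current
        outside message and its siblings' current up messages."""
        st = self._store
        M, S, K = self.M, self.pat.n_patterns, self.K
        p = self.parent[i]
        prod = st["V"][p]
        scale = st["sV"][p]
        for sib in self.children[p]:
            if sib != i:
                prod = prod * st["U"][sib]
                scale = scale + st["sU"][sib]
        st["R"][i], st["sR"][i] = self._rescale(
            np.broadcast_to(prod, (M, S, K)).copy(),
            np.broadcast_to(scale, (M, S)).copy())

    def _push_through_edge(self, i: int) -> None:
        """Refresh U[i] and V[i] after edge i's length changed (D[i] and
        R[i] must be current)."""
        st = self._store
        M, S, K = self.M, self.pat.n_patterns, self.K
        P = self.tp(self.lengths[i]).transpose(0, 2, 1)
        U = np.matmul(np.broadcast_to(st["D"][i], (M, S, K)), P)
        sU = np.broadcast_to(st["sD"][i], (M, S)).copy()
        st["U"][i], st["sU"][i] = self._rescale(U, sU)
        V = np.matmul(st["R"][i], P)
        st["V"][i], st["sV"][i] = self._rescale(V, st["sR"][i].copy())

    def optimize_lengths_pass(self, xatol: float = 1e-7) -> float:
        """One exact round-robin pass of branch-length optimization.

        Edges are visited parent-before-children with incremental message
        updates, so each one-dimensional optimization is exact given the
        current other lengths; the total log-likelihood is non-decreasing.
        Returns the log-likelihood after the pass.
        """
        self.ensure_messages()
        for i in reversed(range(len(self.nodes))):   # preorder; root excluded
            if i == self.root:
                continue
            self._recompute_R(i)
            f = self.edge_loglik_fn(i)
            res = minimize_scalar(lambda t: -f(t), bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": xatol})
            if f(self.lengths[i]) < -res.fun:
                self.lengths[i] = float(np.clip(res.x, BRANCH_MIN, BRANCH_MAX))
                self.nodes[i].length = self.lengths[i]
            self._push_through_edge(i)
        self._stale = True
        return self.loglik()

    def set_length(self, i: int, t: float) -> None:
        t = float(np.clip(t, BRANCH_MIN, BRANCH_MAX))
        self.lengths[i] = t
        self.nodes[i].length = t
        self._stale = True

    def set_model(self, model: SubstitutionMixtureModel) -> None:
        if model.n_classes != self.model.n_classes or \
                model.gamma.n_categories != self.model.gamma.n_categories:
            raise LikelihoodError("engine is bound to the mixture dimensions")
        self.model = model
        g = model.gamma
        self.rates = np.array([g.rates[gi] for _, gi in self.combos])
        self.log_wm = np.log(np.maximum(
            np.array([model.weights[c] / g.n_categories for c, _ in self.combos]),
            1e-300))
        self.pis = np.stack([model.profiles[c] for c, _ in self.combos])
        self._stale = True

    # -- expected substitution statistics (for the GTR EM) ------------------

    def edge_pair_posteriors(self) -> list:
        """For every non-root edge, the (M, K, K) pattern-weighted posterior
        joint distribution of the edge's endpoint states (summed over
        patterns, kept separate per combo)."""
        self.ensure_messages()
        st = self._store
        post = self.combo_posteriors()               # (M,S)
        w = self.pat.weights[None, :] * post         # (M,S)
        out = []
        M, S, K = self.M, self.pat.n_patterns, self.K
        for i in range(len(self.nodes)):
            if i == self.root:
                out.append(None)
                continue
            Rpi = st["R"][i] * self.pis[:, None, :]
            Dv = np.broadcast_to(st["D"][i], (M, S, K))
            P = self.tp(self.lengths[i])
            X = np.matmul(Rpi, P)                    # (M,S,K) marginal helper
            denom = np.maximum((X * Dv).sum(-1), 1e-320)  # (M,S)
            coef = w / denom
            F = np.einsum("msi,msj->mij", Rpi * coef[:, :, None], Dv) * P
            out.append(F)
        return out


# ---------------------------------------------------------------------------
# Public one-shot functions (module surface)
# ---------------------------------------------------------------------------

def log_likelihood(alignment: Alignment, tree: Tree,
                   model: SubstitutionMixtureModel,
                   posteriors: bool = False) -> LikelihoodResult:
    """Pruning log-likelihood of an alignment on a binary tree under a
    (possibly site-heterogeneous) mixture model.

    Gaps and ambiguity codes contribute a partial likelihood of one over all
    states; an all-gap column therefore contributes ``log 1 = 0``.
    """
    pat = PatternData(alignment)
    eng = _Engine(pat, tree, model)
    site = pat.expand(eng.site_logliks())
    post = None
    if posteriors:
        combo = eng.combo_posteriors()
        C = model.n_classes
        G = model.gamma.n_categories
        post = pat.expand(combo.reshape(C, G, -1).sum(axis=1))
    return LikelihoodResult(loglik=float(eng.loglik()), site_logliks=site,
                            class_posteriors=post)


def optimize_branch_lengths(alignment: Alignment, tree: Tree,
                            model: SubstitutionMixtureModel,
                            tol: float = 1e-6, max_rounds: int = 20,
                            ) -> tuple[Tree, LikelihoodResult]:
    """Round-robin one-dimensional ML optimization of every branch length.

    Returns a new tree (the input is not modified) and the likelihood at the
    optimum.  The log-likelihood is non-decreasing across passes; passes stop
    when a full pass improves it by less than ``tol``.
    """
    tree = tree.copy()
    pat = PatternData(alignment)
    eng = _Engine(pat, tree, model)
    _optimize_lengths_inplace(eng, tol=tol, max_rounds=max_rounds)
    site = pat.expand(eng.site_logliks())
    return tree, LikelihoodResult(loglik=eng.loglik(), site_logliks=site)


def _optimize_lengths_inplace(eng: _Engine, tol: float = 1e-6,
                              max_rounds: int = 20) -> float:
    cur = eng.loglik()
    if not np.isfinite(cur):
        raise LikelihoodError(
            "non-finite starting likelihood; consider flooring frequencies")
    for _ in range(max_rounds):
        new = eng.optimize_lengths_pass()
        if new - cur < tol:
            cur = max(new, cur)
            break
        cur = new
    return cur


def _optimize_alpha_inplace(eng: _Engine, bounds=(0.05, 50.0)) -> float:
    """Brent search on the gamma shape (log scale), other parameters fixed."""
    base = eng.model

    def nll(log_a: float) -> float:
        eng.set_model(base.with_gamma(float(np.exp(log_a))))
        return -eng.loglik()

    res = minimize_scalar(nll, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-4})
    alpha = float(np.exp(res.x))
    eng.set_model(base.with_gamma(alpha))
    return alpha


# -- GTR exchangeability EM --------------------------------------------------

def _expected_counts(eng: _Engine) -> tuple[np.ndarray, np.ndarray]:
    """Expected substitution counts C[i,j] and state-occupancy times T[i]
    accumulated over all edges, patterns and mixture combos, computed from
    the spectral decomposition (exact conditional expectations)."""
    K = eng.K
    C = np.zeros((K, K))
    T = np.zeros(K)
    decs = eng.model.decompositions()
    pair = eng.edge_pair_posteriors()
    for i in range(len(eng.nodes)):
        if i == eng.root:
            continue
        t = eng.lengths[i]
        F = pair[i]                                   # (M,K,K)
        for m, (c, _) in enumerate(eng.combos):
            dec = decs[c]
            r = eng.rates[m]
            lam = dec.lam * r
            te = t
            P = dec.transition(t * r)
            W = F[m] / np.maximum(P, 1e-320)
            Mkl = dec.U.T @ W @ dec.Uinv.T
            lt = lam * te
            el = np.exp(lt)
            denom = lam[:, None] - lam[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                J = (el[:, None] - el[None, :]) / denom
            same = np.abs(denom) < 1e-12
            J[same] = (te * el[:, None] * np.ones_like(J))[same]
            A = dec.Uinv.T @ (J * Mkl) @ dec.U.T
            Qc = build_rate_matrix(eng.model.exchangeabilities,
                                   eng.model.classes[c][0]) * r
            C += np.maximum(Qc * A, 0.0) * (1 - np.eye(K))
            T += np.maximum(np.diag(A), 0.0)
    return C, T


def _em_exchangeabilities(eng: _Engine, freqs: np.ndarray,
                          iterations: int = 3) -> None:
    """A few EM updates of the shared exchangeabilities (frequencies fixed),
    rebalancing branch lengths is left to the caller."""
    for _ in range(iterations):
        C, T = _expected_counts(eng)
        pi = freqs
        denom = np.outer(T, pi)
        denom = np.maximum(denom + denom.T, 1e-12)
        E = (C + C.T) / denom
        E = 0.5 * (E + E.T)
        np.fill_diagonal(E, 0.0)
        if E.max() <= 0:
            return
        E /= E[np.triu_indices_from(E, 1)].mean()
        model = eng.model
        new = SubstitutionMixtureModel(
            ExchangeabilityMatrix(E), list(model.classes), model.gamma,
            model.alphabet, model.kind)
        eng.model = new
        eng.pis = np.stack([new.profiles[c] for c, _ in eng.combos])
        eng._stale = True


# -- CAT profile EM ----------------------------------------------------------

def _em_profiles(eng: _Engine, state_counts: np.ndarray,
                 iterations: int = 10, tol: float = 1e-3,
                 pseudocount: float = 0.5,
                 update_weights: bool = True) -> float:
    """EM over site-class posteriors for the mixture frequency profiles.

    The M-step reweights observed residue counts per site by the class
    responsibilities (a fast approximation to the full ancestral-state
    expectation; see the methods note).  Returns the final log-likelihood.
    """
    C = eng.model.n_classes
    G = eng.model.gamma.n_categories
    w = eng.pat.weights
    cur = eng.loglik()
    for _ in range(iterations):
        resp = eng.combo_posteriors().reshape(C, G, -1).sum(axis=1)  # (C,S)
        resp_w = resp * w[None, :]
        counts = resp_w @ state_counts + pseudocount                  # (C,K)
        model = eng.model
        profiles = [FrequencyProfile(counts[c]) for c in range(C)]
        if update_weights:
            cls_w = resp_w.sum(axis=1)
            cls_w = np.maximum(cls_w, 1e-6)
            cls_w = cls_w / cls_w.sum()
        else:
            cls_w = model.weights
        new = SubstitutionMixtureModel(
            model.exchangeabilities,
            [(p, cw) for p, cw in zip(profiles, cls_w)],
            model.gamma, model.alphabet, model.kind)
        eng.set_model(new)
        new_ll = eng.loglik()
        if new_ll - cur < tol:
            cur = max(new_ll, cur)
            break
        cur = new_ll
    return cur


def _init_profiles_from_data(pat: PatternData, n_classes: int,
                             seed: int = 0, pseudocount: float = 0.5) -> list:
    """Seed mixture profiles from the residue-count vectors of randomly
    chosen alignment columns (seed-controlled, deterministic)."""
    rng = np.random.default_rng(seed)
    counts = pat.state_counts()
    informative = np.nonzero(counts.sum(axis=1) > 0)[0]
    if len(informative) == 0:
        return [FrequencyProfile.uniform(pat.alphabet.size)
                for _ in range(n_classes)]
    pick = rng.choice(informative, size=min(n_classes, len(informative)),
                      replace=len(informative) < n_classes)
    profs = [FrequencyProfile(counts[i] + pseudocount) for i in pick]
    while len(profs) < n_classes:
        profs.append(FrequencyProfile.uniform(pat.alphabet.size))
    return profs


# ---------------------------------------------------------------------------
# Model / Results pair
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Phylogenetic likelihood model: an alignment observed on a fixed
    binary tree topology under a substitution mixture model.

    Parameters
    ----------
    alignment : Alignment
    tree : Tree
        Binary tree whose leaves cover the alignment's taxa.  Branch lengths
        are starting values for the fit; missing lengths start at 0.1.
    model : SubstitutionMixtureModel or str
        A model object, or a named family ('poisson', 'lg', 'gtr', 'cat',
        'catgtr') built with empirical frequencies from the data.
    """

    def __init__(self, alignment: Alignment, tree: Tree,
                 model: SubstitutionMixtureModel | str = "lg",
                 n_classes: int = 10, gamma_categories: int = 4,
                 alpha: float = 1.0, seed: int = 0):
        self.alignment = alignment
        self.tree = tree.copy()
        self.pat = PatternData(alignment)
        self.seed = seed
        if isinstance(model, str):
            model = self._default_model(model, n_classes, gamma_categories, alpha)
        self.model = model
        self._eng = _Engine(self.pat, self.tree, model)

    def _default_model(self, kind: str, n_classes: int, gamma_categories: int,
                       alpha: float) -> SubstitutionMixtureModel:
        codes = self.alignment.codes()
        K = self.alignment.alphabet.size
        emp = FrequencyProfile.empirical(codes, K)
        kind = kind.lower()
        if kind in ("cat", "catgtr"):
            profiles = _init_profiles_from_data(self.pat, n_classes, self.seed)
            return make_model(kind, self.alignment.alphabet, alpha,
                              gamma_categories, n_classes, profiles=profiles)
        if kind == "poisson":
            return make_model("poisson", self.alignment.alphabet, alpha,
                              gamma_categories)
        return make_model(kind, self.alignment.alphabet, alpha,
                          gamma_categories, frequencies=emp)

    # -- evaluation --------------------------------------------------------

    def loglik(self) -> float:
        return self._eng.loglik()

    def result(self) -> LikelihoodResult:
        site = self.pat.expand(self._eng.site_logliks())
        return LikelihoodResult(self._eng.loglik(), site)

    # -- fitting -----------------------------------------------------------

    def fit(self, branch_lengths: bool = True, shape: bool = True,
            exchangeabilities: bool | None = None,
            profiles: bool | None = None,
            tol: float = 1e-6, max_rounds: int = 20,
            em_iterations: int = 8, outer_rounds: int = 2,
            ) -> "TreeLikelihoodResults":
        """Maximize the likelihood over the requested free parameters.

        ``exchangeabilities`` / ``profiles`` default to whatever the model
        family calls for ('gtr'/'catgtr' estimate exchangeabilities,
        'cat'/'catgtr' estimate profiles).  Optimization alternates
        branch-length passes, gamma-shape search and EM updates.
        """
        kind = self.model.kind
        if exchangeabilities is None:
            exchangeabilities = kind in ("gtr", "catgtr")
        if profiles is None:
            profiles = kind in ("cat", "catgtr")
        eng = self._eng
        history = [eng.loglik()]
        rounds = outer_rounds if (exchangeabilities or profiles or shape) else 1
        for _ in range(rounds):
            if branch_lengths:
                history.append(_optimize_lengths_inplace(eng, tol, max_rounds))
            if shape and eng.model.gamma.n_categories > 1:
                _optimize_alpha_inplace(eng)
                history.append(eng.loglik())
            if profiles:
                history.append(_em_profiles(eng, self.pat.state_counts(),
                                            iterations=em_iterations))
            if exchangeabilities:
                emp = FrequencyProfile.empirical(
                    self.alignment.codes(), self.model.K).values
                if kind in ("gtr",):
                    _em_exchangeabilities(eng, emp, iterations=2)
                else:
                    _em_exchangeabilities(eng, emp, iterations=1)
                history.append(eng.loglik())
        if branch_lengths and rounds > 1:
            history.append(_optimize_lengths_inplace(eng, tol, max_rounds))
        self.model = eng.model
        return TreeLikelihoodResults(self, eng.model, self.tree, history)


class TreeLikelihoodResults:
    """Fit results: the fitted model components, the tree with ML branch
    lengths, per-site log-likelihoods and the optimization trace."""

    def __init__(self, model_obj: TreeLikelihood,
                 submodel: SubstitutionMixtureModel, tree: Tree,
                 history: list):
        self.model_obj = model_obj
        self.submodel = submodel
        self.tree = tree
        self.history = history
        self.loglik = model_obj._eng.loglik()
        self.site_logliks = model_obj.pat.expand(model_obj._eng.site_logliks())

    @property
    def alpha(self) -> float:
        return self.submodel.gamma.alpha

    @property
    def branch_lengths(self) -> dict:
        out = {}
        for n in self.tree.preorder():
            if n.parent is not None:
                key = n.name or f"node_{id(n) % 10000}"
                out[key] = n.length
        return out

    def summary(self) -> str:
        m = self.submodel
        lines = [
            "Tree likelihood fit",
            "=" * 55,
            f"model family:        {m.kind}",
            f"alphabet:            {m.alphabet.name} (K={m.K})",
            f"mixture classes:     {m.n_classes}",
            f"gamma categories:    {m.gamma.n_categories}",
            f"gamma shape (alpha): {m.gamma.alpha:.4f}",
            f"taxa / sites:        {self.model_obj.alignment.n_taxa} / "
            f"{self.model_obj.alignment.length}",
            f"unique patterns:     {self.model_obj.pat.n_patterns}",
            f"log-likelihood:      {self.loglik:.4f}",
            f"tree length:         {self.tree.total_length():.4f}",
            f"monotone fit trace:  {' -> '.join(f'{x:.2f}' for x in self.history)}",
        ]
        return "\n".join(lines)
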