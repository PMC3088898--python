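"""Substitution models for protein (K=20) and recoded (e.g. Dayhoff K=6)
alphabets.

A model is a shared symmetric exchangeability matrix, one or more stationary
frequency profiles (one per mixture class), and a discrete-gamma
distribution of site rates.  One class with the bundled LG exchangeabilities
is LG+F; one class with estimated exchangeabilities is GTR; several classes
sharing uniform exchangeabilities form the finite-mixture analogue of the
CAT model, and with estimated exchangeabilities of CAT-GTR.  Every per-class
rate matrix is normalized to one expected substitution per site at its own
stationary distribution.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO20, DAYHOFF6, Alphabet

FREQ_FLOOR = 1e-8


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

class ExchangeabilityMatrix:
    """K x K symmetric non-negative exchangeabilities with zero diagonal."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ModelError("exchangeability matrix must be square")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ModelError("exchangeability matrix must be symmetric")
        if (values < 0).any():
            raise ModelError("exchangeabilities must be non-negative")
        values = values.copy()
        np.fill_diagonal(values, 0.0)
        off = values + np.eye(len(values))
        if (off <= 0).all(axis=1).any():
            raise ModelError("every state needs at least one positive exchangeability")
        self.values = values

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @classmethod
    def uniform(cls, K: int) -> "ExchangeabilityMatrix":
        return cls(np.ones((K, K)) - np.eye(K))


class FrequencyProfile:
    """A stationary state-frequency vector (floored and renormalized)."""

    def __init__(self, values: np.ndarray, floor: float = FREQ_FLOOR):
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ModelError("frequencies must be non-negative")
        if values.sum() <= 0:
            raise ModelError("frequencies sum to zero")
        values = np.maximum(values, floor)
        self.values = values / values.sum()

    @property
    def size(self) -> int:
        return len(self.values)

    @classmethod
    def uniform(cls, K: int) -> "FrequencyProfile":
        return cls(np.full(K, 1.0 / K))

    @classmethod
    def empirical(cls, codes: np.ndarray, K: int,
                  pseudocount: float = 0.5) -> "FrequencyProfile":
        """Observed state frequencies from an encoded matrix (missing = -1)."""
        counts = np.bincount(codes[codes >= 0].ravel(), minlength=K).astype(float)
        return cls(counts + pseudocount)


@dataclass
class GammaRates:
    """Discrete-gamma among-site rate variation: C equal-probability
    categories, each category rate the mean of its quantile slice, so the
    rates average exactly 1."""

    alpha: float
    rates: np.ndarray

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    @property
    def weights(self) -> np.ndarray:
        C = self.n_categories
        return np.full(C, 1.0 / C)


def discrete_gamma(alpha: float, categories: int = 4) -> GammaRates:
    """Discretize Gamma(alpha, rate=alpha) (mean 1) into equal-probability
    categories using the mean of each quantile slice."""
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if categories < 1:
        raise ModelError("need at least one rate category")
    C = categories
    if C == 1:
        return GammaRates(alpha, np.ones(1))
    edges = gamma_dist.ppf(np.arange(1, C) / C, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], edges * alpha, [np.inf]])  # on rate-1 scale
    # mean of each slice of Gamma(alpha, 1), scaled: E = alpha within slice via
    # the shape alpha+1 incomplete gamma
    upper = gammainc(alpha + 1, bounds[1:])
    lower = gammainc(alpha + 1, bounds[:-1])
    rates = C * (upper - lower)          # already on the mean-1 scale
    rates = rates / rates.mean()         # guard against roundoff
    return GammaRates(alpha, rates)


def build_rate_matrix(e: ExchangeabilityMatrix, f: FrequencyProfile) -> np.ndarray:
    """General time-reversible generator: Q_ij = e_ij f_j (i != j), rows sum
    to zero, scaled so the expected rate -sum_i f_i Q_ii equals 1."""
    if e.size != f.size:
        raise ModelError(f"dimension mismatch: {e.size} vs {f.size}")
    if (f.values <= 0).any():
        raise ModelError("zero frequency; floor frequencies first")
    Q = e.values * f.values[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(f.values * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return Q / mu


def transition_probabilities(Q: np.ndarray, t: float,
                             freqs: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt).  Uses the symmetric-eigendecomposition path when the
    stationary frequencies are supplied and Q is reversible w.r.t. them;
    otherwise falls back to a general matrix exponential."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    if freqs is not None:
        flow = freqs[:, None] * Q
        if np.allclose(flow, flow.T, atol=1e-10):
            dec = _SpectralDecomposition(Q, freqs)
            return dec.transition(t)
    P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


class _SpectralDecomposition:
    """Eigendecomposition of a reversible generator via its symmetrization
    B = D^1/2 Q D^-1/2; P(t) = D^-1/2 V exp(L t) V' D^1/2."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        d = np.sqrt(freqs)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.U = V / d[:, None]         # D^-1/2 V  (right transform)
        self.Uinv = V.T * d[None, :]    # V' D^1/2
        self.freqs = freqs

    def transition(self, t: float) -> np.ndarray:
        P = (self.U * np.exp(self.lam * t)) @ self.Uinv
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# The mixture model
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMixtureModel:
    """Shared exchangeabilities + a list of (frequency profile, weight)
    classes + discrete-gamma rates.

    ``kind`` records the named model family ('poisson', 'lg', 'gtr', 'cat',
    'catgtr') purely for reporting; the likelihood machinery only sees the
    components.
    """

    exchangeabilities: ExchangeabilityMatrix
    classes: list  # list[tuple[FrequencyProfile, float]]
    gamma: GammaRates
    alphabet: Alphabet = AMINO20
    kind: str = "custom"

    def __post_init__(self):
        w = np.array([w for _, w in self.classes], dtype=float)
        if w.sum() <= 0:
            raise ModelError("class weights must sum to a positive value")
        self.classes = [(p, float(wi / w.sum())) for (p, _), wi in zip(self.classes, w)]
        for p, _ in self.classes:
            if p.size != self.exchangeabilities.size:
                raise ModelError("profile size does not match exchangeabilities")
        if self.exchangeabilities.size != self.alphabet.size:
            raise ModelError("model size does not match alphabet")
        self._decomps: list[_SpectralDecomposition] | None = None

    # -- derived quantities ------------------------------------------------

    @property
    def K(self) -> int:
        return self.alphabet.size

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.classes])

    @property
    def profiles(self) -> np.ndarray:
        return np.stack([p.values for p, _ in self.classes])

    def rate_matrix(self, c: int = 0) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.classes[c][0])

    def decompositions(self) -> list:
        if self._decomps is None:
            self._decomps = [
                _SpectralDecomposition(self.rate_matrix(c), self.classes[c][0].values)
                for c in range(self.n_classes)]
        return self._decomps

    def invalidate(self) -> None:
        """Drop cached decompositions after editing components in place."""
        self._decomps = None

    def transition(self, c: int, t: float) -> np.ndarray:
        return self.decompositions()[c].transition(t)

    def with_gamma(self, alpha: float) -> "SubstitutionMixtureModel":
        return SubstitutionMixtureModel(
            self.exchangeabilities, list(self.classes),
            discrete_gamma(alpha, self.gamma.n_categories),
            self.alphabet, self.kind)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SubstitutionMixtureModel({self.kind}, K={self.K}, "
                f"classes={self.n_classes}, alpha={self.gamma.alpha:.3g})")


# ---------------------------------------------------------------------------
# Bundled matrices and factories
# ---------------------------------------------------------------------------

def read_paml_dat(path_or_text: str | Path) -> tuple[ExchangeabilityMatrix, FrequencyProfile]:
    """Read a PAML-layout dat file: 19 lower-triangle exchangeability rows
    followed by the 20 stationary frequencies (any alphabet size works as
    long as the triangle is complete)."""
    text = Path(path_or_text).read_text() if isinstance(path_or_text, Path) \
        else path_or_text
    rows = [[float(x) for x in line.split()] for line in text.splitlines()
            if line.strip()]
    # K-1 lower-triangle rows followed by one row of K frequencies
    K = len(rows)
    tri, freqs = rows[:-1], rows[-1]
    if len(freqs) != K or any(len(r) != i + 1 for i, r in enumerate(tri)):
        raise ModelError("malformed PAML dat layout")
    M = np.zeros((K, K))
    for r, vals in enumerate(tri, start=1):
        M[r, :r] = vals
    M = M + M.T
    return ExchangeabilityMatrix(M), FrequencyProfile(np.array(freqs))


def load_lg() -> tuple[ExchangeabilityMatrix, FrequencyProfile]:
    """The bundled LG amino-acid exchangeabilities and frequencies."""
    text = (importlib.resources.files("streptophylo") / "data" / "lg.dat").read_text()
    return read_paml_dat(text)


def make_model(kind: str, alphabet: Alphabet = AMINO20, alpha: float = 1.0,
               gamma_categories: int = 4, n_classes: int = 10,
               frequencies: FrequencyProfile | None = None,
               profiles: Sequence[FrequencyProfile] | None = None,
               exchangeabilities: ExchangeabilityMatrix | None = None,
               ) -> SubstitutionMixtureModel:
    """Construct a named model.

    kinds: 'poisson' (uniform everything), 'lg' (bundled LG exchangeabilities,
    +F frequencies if given), 'gtr' (estimable exchangeabilities, initialized
    uniform unless provided), 'cat' (n_classes frequency classes, uniform
    exchangeabilities), 'catgtr' (n_classes classes, shared estimable
    exchangeabilities).
    """
    kind = kind.lower()
    K = alphabet.size
    gamma = discrete_gamma(alpha, gamma_categories)
    if kind == "poisson":
        e = ExchangeabilityMatrix.uniform(K)
        f = frequencies or FrequencyProfile.uniform(K)
        classes = [(f, 1.0)]
    elif kind == "lg":
        if K != 20:
            raise ModelError("the LG model is defined on the 20-state alphabet")
        e, f_lg = load_lg()
        classes = [(frequencies or f_lg, 1.0)]
    elif kind == "gtr":
        e = exchangeabilities or ExchangeabilityMatrix.uniform(K)
        classes = [(frequencies or FrequencyProfile.uniform(K), 1.0)]
    elif kind in ("cat", "catgtr"):
        if kind == "cat":
            e = ExchangeabilityMatrix.uniform(K)
        else:
            e = exchangeabilities or ExchangeabilityMatrix.uniform(K)
        if profiles is None:
            profiles = [FrequencyProfile.uniform(K) for _ in range(n_classes)]
        classes = [(p, 1.0 / len(profiles)) for p in profiles]
    else:
        raise ModelError(f"unknown model kind {kind!r}; expected poisson, lg, "
                         "gtr, cat or catgtr")
    return SubstitutionMixtureModel(e, classes, gamma, alphabet, kind)
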