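"""Empirical amino-acid substitution models and transition probabilities.

A reversible model is assembled from a symmetric exchangeability matrix S,
an equilibrium frequency vector pi, and a rate-heterogeneity mixture of
(weight, rate) categories normalized to mean rate 1.  The instantaneous
rate matrix is the GTR-family construction Q_ij = S_ij * pi_j (i != j),
rescaled so the expected substitution rate at equilibrium is one, i.e.
-sum_i pi_i Q_ii = 1, so branch lengths are expected substitutions/site.

LG, WAG and BLOSUM62 are packaged as PAML-style lower-triangle text files
(in the classical A R N D C Q E G H I L K M F P S T W Y V row order) and
re-ordered internally to the package's alphabetical state order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from .io_phylo import AA_LETTERS

__all__ = [
    "SubstitutionModel",
    "RateMatrix",
    "load_model",
    "build_rate_matrix",
    "transition_probs",
    "discretize_gamma",
    "PACKAGED_MODELS",
]

#: Row/column order used by PAML-style .dat files.
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PAML_TO_ALPHA = np.array([AA_LETTERS.index(a) for a in PAML_ORDER])

PACKAGED_MODELS = {"LG": "lg.dat", "WAG": "wag.dat", "BLOSUM62": "blosum62.dat"}


class ModelError(ValueError):
    pass


def discretize_gamma(alpha: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a mean-one gamma rate distribution into ``k`` categories.

    Uses equal-probability bins with category-mean rates (the standard
    discrete-gamma construction): bin boundaries are gamma quantiles and
    each category rate is the conditional mean within its bin, which for
    shape/rate both ``alpha`` is

        r_j = k * [I(alpha+1, alpha*b_{j+1}) - I(alpha+1, alpha*b_j)]

    with I the regularized lower incomplete gamma function.  Returns
    ``(weights, rates)``; rates are renormalized so sum(w*r) == 1 exactly.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ModelError(f"need at least one category, got {k}")
    qs = np.arange(1, k) / k
    # quantiles of Gamma(shape=alpha, rate=alpha)
    bounds = gammaincinv(alpha, qs) / alpha
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1, alpha * edges[1:]))
    lower = gammainc(alpha + 1, alpha * np.where(np.isinf(edges[:-1]), 0, edges[:-1]))
    rates = k * (upper - lower)
    weights = np.full(k, 1.0 / k)
    rates = rates / float(weights @ rates)
    return weights, rates


def _parse_categories(categories) -> tuple[np.ndarray, np.ndarray]:
    if categories is None or categories == "uniform":
        return np.array([1.0]), np.array([1.0])
    if isinstance(categories, dict) and "gamma" in categories:
        g = categories["gamma"]
        return discretize_gamma(float(g["alpha"]), int(g.get("k", 4)))
    if isinstance(categories, str) and categories.startswith("gamma"):
        inner = categories[categories.index("(") + 1 : categories.rindex(")")]
        alpha_s, k_s = inner.split(",")
        return discretize_gamma(float(alpha_s), int(k_s))
    # explicit FreeRate-style list of (weight, rate) pairs or dicts
    ws, rs = [], []
    for item in categories:
        if isinstance(item, dict):
            ws.append(float(item["weight"]))
            rs.append(float(item["rate"]))
        else:
            w, r = item
            ws.append(float(w))
            rs.append(float(r))
    w = np.asarray(ws)
    r = np.asarray(rs)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ModelError(f"category weights sum to {w.sum():.6g}, expected 1")
    if np.any(r < 0):
        raise ModelError("category rates must be nonnegative")
    mean = float(w @ r)
    if abs(mean - 1.0) > 1e-6:
        raise ModelError(
            f"category mean rate is {mean:.6g}; rates must be normalized to mean 1"
        )
    # remove any residual drift so the invariant holds exactly
    return w, r / mean


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model: exchangeabilities S, frequencies pi,
    and a (weights, rates) rate mixture with mean rate 1."""

    name: str
    S: np.ndarray
    pi: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    rates: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.S.shape[0]
        if self.S.shape != (n, n) or self.pi.shape != (n,):
            raise ModelError("S must be square and pi of matching length")
        if not np.allclose(self.S, self.S.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if np.any(self.S < 0) or np.any(np.diag(self.S) != 0):
            raise ModelError("S must be nonnegative with zero diagonal")
        if np.any(self.pi <= 0):
            raise ModelError("all equilibrium frequencies must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ModelError(f"frequencies sum to {self.pi.sum():.10g}")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ModelError("category weights must sum to 1")
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-9:
            raise ModelError("category mean rate must be 1")

    @property
    def n_states(self) -> int:
        return self.S.shape[0]

    @property
    def n_categories(self) -> int:
        return len(self.weights)


def _read_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    values = [float(x) for x in text.split()]
    if len(values) < 190 + 20:
        raise ModelError("model file too short for a 20-state PAML matrix")
    tri, freqs = values[:190], values[190:210]
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    pi = np.array(freqs)
    # permute from PAML order to alphabetical state order
    inv = np.argsort(_PAML_TO_ALPHA)
    S = S[np.ix_(inv, inv)]
    pi = pi[inv]
    return S, pi / pi.sum()


def load_model(name: str, categories="uniform") -> SubstitutionModel:
    """Load a packaged empirical model (LG, WAG, BLOSUM62) or a custom
    PAML-style .dat file path, with a rate-category specification.

    ``categories`` may be ``"uniform"`` (one category, rate 1), a
    ``{"gamma": {"alpha": a, "k": k}}`` mapping (or ``"gamma(a,k)"``), or
    an explicit FreeRate list of (weight, rate) pairs normalized to mean
    rate 1.
    """
    key = name.upper()
    if key in PACKAGED_MODELS:
        text = (
            importlib.resources.files("ancsite.data")
            .joinpath(PACKAGED_MODELS[key])
            .read_text()
        )
        label = key
    else:
        try:
            with open(name) as fh:
                text = fh.read()
        except OSError:
            raise ModelError(
                f"unknown model {name!r}: not packaged "
                f"({sorted(PACKAGED_MODELS)}) and not a readable file"
            ) from None
        label = name
    S, pi = _read_paml_dat(text)
    w, r = _parse_categories(categories)
    return SubstitutionModel(name=label, S=S, pi=pi, weights=w, rates=r)


@dataclass
class RateMatrix:
    """Instantaneous rate matrix Q with its stationary distribution.

    Caches the symmetric eigendecomposition used for P(t) = exp(Q r t):
    with D = diag(sqrt(pi)), B = D Q D^-1 is symmetric, so
    P(t) = D^-1 V exp(L r t) V^T D for B = V L V^T.
    """

    Q: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        d = np.sqrt(self.pi)
        B = (self.Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0
        self._eigval, self._eigvec = np.linalg.eigh(B)
        self._left = self._eigvec.T * d[None, :]  # V^T D
        self._right = self._eigvec / d[:, None]  # D^-1 V


def build_rate_matrix(model: SubstitutionModel) -> RateMatrix:
    """Q_ij = S_ij pi_j off-diagonal, rows summing to zero, rescaled to
    one expected substitution per site per unit branch length."""
    Q = model.S * model.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(model.pi @ np.diag(Q))
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return RateMatrix(Q=Q / mu, pi=model.pi.copy())


def transition_probs(rm: RateMatrix, t: float, r: float = 1.0) -> np.ndarray:
    """Transition probability matrix P(r t) = exp(Q r t).

    Rows sum to 1; entries are clamped into [0, 1] (eigendecomposition
    round-off can produce excursions below ~1e-12).
    """
    if not np.isfinite(t) or t < 0:
        raise ModelError(f"branch length must be finite and nonnegative, got {t}")
    if r < 0:
        raise ModelError(f"category rate must be nonnegative, got {r}")
    P = (rm._right * np.exp(rm._eigval * (t * r))[None, :]) @ rm._left
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
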