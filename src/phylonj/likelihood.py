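"""GTR+I+G substitution model and Felsenstein pruning log-likelihood.

The general time-reversible (GTR) rate matrix is built as Q_ij = r_ij * pi_j
(i != j), with the diagonal set so rows sum to zero, and scaled so the mean
substitution rate at stationarity is 1 (branch lengths are then expected
substitutions per site).  Rate heterogeneity across sites is modelled by a
discrete gamma mixture (mean-1, median-of-category discretization) plus an
invariant-site class: a site is invariant with probability p_inv and
otherwise falls in one of K equiprobable gamma categories.

The tree likelihood P(X | tau) is computed by Felsenstein's pruning
algorithm — a post-order accumulation of per-state partial likelihoods —
with per-node rescaling to avoid underflow.  Gap/missing characters
contribute an all-ones leaf vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .msa import GAP_CODE, Alignment, encode_alignment
from .trees import PhyloTree

__all__ = [
    "GTRParams",
    "RateMatrix",
    "gtr_rate_matrix",
    "transition_probs",
    "site_rates",
    "felsenstein_loglik",
    "assign_branch_lengths",
]

_EXCH_KEYS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class GTRParams:
    """Parameters of the GTR+I+G model.

    exchangeabilities: the six symmetric relative rates (AC, AG, AT, CG, CT,
    GT); base_freqs: stationary nucleotide frequencies (A, C, G, T) summing
    to 1; gamma_shape: shape alpha of the across-site rate distribution
    (``inf`` disables rate heterogeneity); p_inv: proportion of invariant
    sites; n_categories: number of discrete gamma classes.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float = 1.0
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if not np.isclose(self.base_freqs.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if not (self.gamma_shape > 0):
            raise ValueError("gamma shape must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("need at least one gamma category")

    @classmethod
    def jc(cls) -> "GTRParams":
        """Jukes–Cantor preset: equal rates, uniform frequencies, no I+G."""
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape=np.inf,
                   p_inv=0.0, n_categories=1)


@dataclass
class RateMatrix:
    """Normalized GTR generator Q with its stationary distribution."""

    Q: np.ndarray
    pi: np.ndarray
    # symmetric-eigendecomposition cache for fast exp(Qt)
    _evals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._evals is None:
            sq = np.sqrt(self.pi)
            B = (sq[:, None] * self.Q) / sq[None, :]
            evals, V = np.linalg.eigh(0.5 * (B + B.T))
            self._evals = evals
            self._right = V / sq[:, None]       # rows scaled by 1/sqrt(pi)
            self._left = V.T * sq[None, :]      # cols scaled by sqrt(pi)


def gtr_rate_matrix(params: GTRParams) -> RateMatrix:
    """Build the normalized GTR generator from model parameters."""
    r = params.exchangeabilities
    pi = params.base_freqs
    R = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        R[i, j] = R[j, i] = r[k]
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    Q = Q / mu
    return RateMatrix(Q, pi.copy())


def transition_probs(Q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetric eigendecomposition of the GTR generator."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    if t == 0:
        return np.eye(4)
    P = (Q._right * np.exp(Q._evals * t)[None, :]) @ Q._left
    return np.clip(P, 0.0, 1.0)


def site_rates(params: GTRParams) -> np.ndarray:
    """Mean-1 discrete gamma category rates (median-of-category discretization)."""
    K = params.n_categories
    if np.isinf(params.gamma_shape):
        return np.ones(K)
    a = params.gamma_shape
    quantiles = (2 * np.arange(K) + 1) / (2 * K)
    rates = stats.gamma.ppf(quantiles, a=a, scale=1.0 / a)
    return rates / rates.mean()


def felsenstein_loglik(tree: PhyloTree, alignment: Alignment,
                       params: GTRParams) -> float:
    """Log P(X | tau) under GTR+I+G by pruning.

    Per site the likelihood is
    ``p_inv * [site potentially constant] * pi_x + (1 - p_inv) * (1/K) * sum_k L_k``
    where L_k is the pruning likelihood at gamma-category rate r_k.  Gaps are
    missing data (all-ones leaf vectors); a gap-only column contributes log 1.
    Returns ``-inf`` when the data are impossible under the tree.
    """
    tree_labels = set(tree.leaf_labels)
    if tree_labels != set(alignment.labels):
        raise ValueError(
            f"leaf/alignment label mismatch: tree-only={sorted(tree_labels - set(alignment.labels))}, "
            f"alignment-only={sorted(set(alignment.labels) - tree_labels)}")
    if not tree.has_branch_lengths():
        raise ValueError("tree must have branch lengths")

    codes = encode_alignment(alignment).codes
    row_of = {lab: i for i, lab in enumerate(alignment.labels)}
    L = codes.shape[1]
    Q = gtr_rate_matrix(params)
    pi = Q.pi
    rates = site_rates(params)
    K = len(rates)

    # leaf conditional vectors: one-hot, or all-ones for gap
    eye5 = np.vstack([np.eye(4), np.ones(4)])

    dtree = tree.dendropy_tree
    log_per_cat = np.empty((K, L))  # per-category per-site log-likelihood
    for ci, rate in enumerate(rates):
        partial: dict[int, np.ndarray] = {}
        log_scale = np.zeros(L)
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                partial[id(node)] = eye5[codes[row_of[node.taxon.label]]]
                continue
            acc = np.ones((L, 4))
            for child in node.child_nodes():
                t = child.edge.length * rate
                P = transition_probs(Q, t)
                acc = acc * (partial.pop(id(child)) @ P.T)
            mx = acc.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            acc /= safe[:, None]
            log_scale += np.where(mx > 0, np.log(safe), -np.inf)
            partial[id(node)] = acc
        site_l = partial[id(dtree.seed_node)] @ pi
        with np.errstate(divide="ignore"):
            log_per_cat[ci] = np.where(site_l > 0,
                                       np.log(np.maximum(site_l, 1e-300)), -np.inf) + log_scale

    # (1/K) sum_k L_k in log space
    with np.errstate(invalid="ignore"):
        log_var = logsumexp(log_per_cat, axis=0) - np.log(K)
    log_var = np.where(np.all(np.isneginf(log_per_cat), axis=0), -np.inf, log_var)

    p_inv = params.p_inv
    if p_inv > 0:
        const_l = _constant_site_likelihood(codes, pi)
        with np.errstate(divide="ignore"):
            log_a = np.where(const_l > 0, np.log(np.maximum(p_inv * const_l, 1e-300)), -np.inf)
        log_b = np.log1p(-p_inv) + log_var
        logs = np.logaddexp(log_a, log_b)
    else:
        logs = log_var
    return float(logs.sum())


def _constant_site_likelihood(codes: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Per-site sum_x pi_x * [every non-gap observation equals x]."""
    L = codes.shape[1]
    out = np.zeros(L)
    for x in range(4):
        compatible = np.all((codes == x) | (codes == GAP_CODE), axis=0)
        out += pi[x] * compatible
    all_gap = np.all(codes == GAP_CODE, axis=0)
    out[all_gap] = 1.0
    return out


def assign_branch_lengths(topology: PhyloTree, alignment: Alignment,
                          params: GTRParams, mode: str = "fixed",
                          fixed_length: float = 0.1,
                          tol: float = 1e-4, max_sweeps: int = 5) -> PhyloTree:
    """Put branch lengths on a topology.

    ``fixed`` sets every branch to ``fixed_length`` (the cheap default used
    when scoring sampled topologies); ``optimize`` runs round-robin per-branch
    golden-section maximization of the pruning log-likelihood until the
    improvement per sweep drops below ``tol`` or ``max_sweeps`` is reached.
    """
    tree = topology.copy()
    dtree = tree.dendropy_tree
    edges = [e for e in dtree.preorder_edge_iter() if e.head_node.parent_node is not None]
    for e in edges:
        if e.length is None:
            e.length = fixed_length
    if mode == "fixed":
        for e in edges:
            e.length = fixed_length
        return tree
    if mode != "optimize":
        raise ValueError(f"unknown branch length mode: {mode!r}")

    current = felsenstein_loglik(tree, alignment, params)
    for _ in range(max_sweeps):
        start = current
        for e in edges:
            def neg_ll(x, _e=e):
                _e.length = x
                return -felsenstein_loglik(tree, alignment, params)
            res = minimize_scalar(neg_ll, bounds=(1e-8, 10.0), method="bounded",
                                  options={"xatol": 1e-5})
            if -res.fun >= current:
                e.length = float(res.x)
                current = -res.fun
            else:  # keep previous value if the line search did not improve
                e.length = e.length
                current = felsenstein_loglik(tree, alignment, params)
        if current - start < tol:
            break
    return tree
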