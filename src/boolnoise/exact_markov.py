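"""Exact Markov-chain analysis of stochastic Boolean networks (small n).

Any of the noise schemes, under synchronous or per-node-probability
asynchronous updating, defines a Markov chain on the 2^n state space with a
column-stochastic transition matrix M: ``pi_t = M pi_{t-1}``, where column j
holds the exact one-step distribution out of state j.  Because every node's
next value is conditionally independent given the previous full state, each
column is a product measure and can be assembled from the per-node on
probabilities supplied by ``update_kernels.node_on_probability``.

This module is the ground-truth oracle against which the Monte-Carlo
simulator is verified, and the instrument for checking ergodicity claims:
a chain is ergodic when the directed graph on positive transition
probabilities is strongly connected and aperiodic, in which case it has a
unique stationary distribution reached from any initial condition.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .network_io import BooleanNetwork
from .update_kernels import ParameterSet, decode_state, node_on_probability, _as_prob_array

__all__ = [
    "build_transition_matrix",
    "evolve",
    "marginal_activities",
    "check_ergodicity",
    "stationary_distribution",
    "product_distribution",
]

#: refuse to build matrices beyond this many nodes (2^cap columns)
DEFAULT_STATE_CAP = 12


def build_transition_matrix(network: BooleanNetwork, params: ParameterSet,
                            scheme: str = "sync", update_prob=None,
                            cap: int = DEFAULT_STATE_CAP):
    """Exact 2^n x 2^n column-stochastic transition matrix.

    Column j is the one-step distribution out of state j (states indexed by
    the integer encoding, first node = LSB).  For the async scheme each
    node's next-bit law is the mixture ``(1-u_i) . [bit unchanged] +
    u_i . kernel``, with ``u_i`` the per-node update probability.

    Dense ndarray below n=8, sparse CSC otherwise.
    """
    n = network.n
    if n > cap:
        raise ValueError(
            f"refusing to build a 2^{n} x 2^{n} transition matrix "
            f"(n={n} exceeds cap={cap}); raise `cap` explicitly if intended")
    params.validate(network)
    if scheme == "async":
        u = _as_prob_array(0.5 if update_prob is None else update_prob,
                           n, "update probability")
    elif scheme != "sync":
        raise ValueError(f"unknown update scheme {scheme!r}")
    size = 2 ** n
    dense = n < 8
    columns = []
    M = np.zeros((size, size)) if dense else None
    for j in range(size):
        state = decode_state(j, n)
        q = np.array([node_on_probability(network, params, state, i)
                      for i in range(n)])
        if scheme == "async":
            q = u * q + (1 - u) * state
        # column as the product measure over bits, first node = LSB
        col = np.array([1.0])
        for qi in q:
            col = np.concatenate([col * (1 - qi), col * qi])
        if dense:
            M[:, j] = col
        else:
            columns.append(sp.csc_matrix(col[:, None]))
    if dense:
        return M
    return sp.hstack(columns, format="csc")


def product_distribution(q, n: int | None = None) -> np.ndarray:
    """Distribution over 2^n states with independent per-node on-probability
    q_i — the law of the simulator's Bernoulli initial sampling."""
    qarr = np.asarray(q, dtype=float)
    if n is None:
        n = qarr.shape[0]
    qarr = _as_prob_array(q, n, "on-probability")
    pi = np.array([1.0])
    for qi in qarr:
        pi = np.concatenate([pi * (1 - qi), pi * qi])
    return pi


def evolve(M, pi0: np.ndarray, t: int) -> np.ndarray:
    """Push a state distribution forward ``t`` steps: ``M^t pi0``."""
    pi = np.asarray(pi0, dtype=float)
    if pi.shape[0] != M.shape[1]:
        raise ValueError("distribution size does not match the matrix")
    for _ in range(t):
        pi = M @ pi
    return np.asarray(pi).ravel()


def marginal_activities(pi: np.ndarray, n: int | None = None) -> np.ndarray:
    """Per-node on-probabilities (marginals) of a state distribution."""
    pi = np.asarray(pi, dtype=float)
    size = pi.shape[0]
    if n is None:
        n = int(round(np.log2(size)))
    if 2 ** n != size:
        raise ValueError(f"distribution size {size} is not 2^{n}")
    states = np.arange(size)
    return np.array([pi[(states >> i) & 1 == 1].sum() for i in range(n)])


def check_ergodicity(M, tol: float = 0.0) -> str:
    """Classify the chain: ``"ergodic"``, ``"reducible"`` or ``"periodic"``.

    Ergodic = the directed graph on transition probabilities > ``tol`` is
    strongly connected (irreducible) and aperiodic.  A reducible verdict is
    reported even if the chain is also periodic.
    """
    A = M.toarray() if sp.issparse(M) else np.asarray(M)
    # graph convention: edge j -> i when M[i, j] > tol (column = source)
    G = nx.from_numpy_array((A > tol).T, create_using=nx.DiGraph)
    if not nx.is_strongly_connected(G):
        return "reducible"
    if not nx.is_aperiodic(G):
        return "periodic"
    return "ergodic"


def stationary_distribution(M) -> np.ndarray:
    """Unique stationary distribution ``pi = M pi`` of an ergodic chain.

    Raises ``ValueError`` naming the :func:`check_ergodicity` verdict when
    the chain is not ergodic.
    """
    verdict = check_ergodicity(M)
    if verdict != "ergodic":
        raise ValueError(f"chain is not ergodic (verdict: {verdict}); "
                         "no unique stationary distribution")
    size = M.shape[0]
    if sp.issparse(M):
        A = (M - sp.identity(size, format="csc")).tolil()
        A[-1, :] = 1.0
        b = np.zeros(size)
        b[-1] = 1.0
        pi = spsolve(A.tocsc(), b)
    else:
        A = np.asarray(M) - np.eye(size)
        A[-1, :] = 1.0
        b = np.zeros(size)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
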