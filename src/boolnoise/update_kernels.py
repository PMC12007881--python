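"""Stochastic single-step update operators for Boolean networks.

Three noise-injection schemes are implemented, each as a per-node kernel that
maps (previous state, random draws) to the node's next value:

``BNp`` — Boolean network with perturbation.  Node *i* is flipped to the
complement of its current value with probability ``p_i``; otherwise its
deterministic rule fires.

``SDDS`` — generalized stochastic discrete dynamical systems.  Four
propensities per node gate the transition suggested by the rule.  With
``u = S(i)`` and ``v = f_i(S)``: an activation (u=0, v=1) is accepted with
``rho_act``; a degradation (u=1, v=0) with ``rho_deg``; when the rule agrees
with the current value (u = v) the node *keeps* its value with
``rho_keep_off`` / ``rho_keep_on`` and flips otherwise.  The classic SDDS
model is the special case ``rho_keep_off = rho_keep_on = 1``.

``PEW`` — probabilistic edge weights.  Every regulatory edge j -> i carries a
pair ``(p_on, p_off)``: before the rule fires, an input that reads *on* stays
on with probability ``p_on`` (else it is read as off), and an input that
reads *off* stays off with probability ``p_off``.  One Bernoulli draw is made
per edge per time-step and reused across repeated occurrences of the same
variable within a rule.  Fixed nodes have no incoming edges and keep their
constant.

All kernels are pure: they never mutate the input state, and every random
choice comes from the ``numpy.random.Generator`` passed in.  Besides the
scalar kernels, this module provides the closed-form probability
``node_on_probability`` that each kernel sets a node to 1 — the quantity the
exact Markov-chain builder integrates over the state space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .network_io import BooleanNetwork, Edge, extract_edges

__all__ = [
    "BNpParams",
    "SDDSParams",
    "PEWParams",
    "ParameterSet",
    "encode_state",
    "decode_state",
    "encode_states",
    "bnp_node_update",
    "sdds_node_update",
    "pew_node_update",
    "step",
    "node_on_probability",
    "read_params",
    "write_params",
]


# ---------------------------------------------------------------------------
# State encoding: node k <-> bit k (first node = least-significant bit)
# ---------------------------------------------------------------------------

def encode_state(state: Sequence[int]) -> int:
    """Integer code of a binary state vector (first node = LSB)."""
    arr = np.asarray(state, dtype=np.int64)
    return int((arr << np.arange(arr.shape[-1], dtype=np.int64)).sum())


def decode_state(code: int, n: int) -> np.ndarray:
    """Inverse of :func:`encode_state`: length-``n`` 0/1 vector."""
    if not 0 <= code < 2 ** n:
        raise ValueError(f"state code {code} out of range for n={n}")
    return (code >> np.arange(n)) & 1


def encode_states(states: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_state` over rows of an ``(R, n)`` array."""
    arr = np.asarray(states, dtype=np.int64)
    return arr @ (1 << np.arange(arr.shape[-1], dtype=np.int64))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _as_prob_array(values, n: int, what: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(values, dtype=float), (n,)).copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{what} must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class BNpParams:
    """Per-node flip probabilities ``p_i`` for the BNp scheme."""

    p: np.ndarray

    method = "bnp"

    @classmethod
    def uniform(cls, network: BooleanNetwork, p: float) -> "BNpParams":
        return cls(_as_prob_array(p, network.n, "flip probability"))

    def validate(self, network: BooleanNetwork) -> None:
        arr = _as_prob_array(self.p, network.n, "flip probability")
        if arr.shape != (network.n,):
            raise ValueError(f"expected {network.n} flip probabilities, got {arr.shape}")


@dataclass(frozen=True)
class SDDSParams:
    """Per-node propensities (rho_off->on, rho_on->off, rho_off->off, rho_on->on)."""

    act: np.ndarray        # rho_off->on, activation propensity
    deg: np.ndarray        # rho_on->off, degradation propensity
    keep_off: np.ndarray   # rho_off->off
    keep_on: np.ndarray    # rho_on->on

    method = "sdds"

    @classmethod
    def uniform(cls, network: BooleanNetwork, rho: float) -> "SDDSParams":
        n = network.n
        a = _as_prob_array(rho, n, "propensity")
        return cls(a, a.copy(), a.copy(), a.copy())

    @classmethod
    def original(cls, network: BooleanNetwork, act, deg) -> "SDDSParams":
        """Classic SDDS: only activation/degradation propensities, values are
        always preserved when the rule agrees with the current state."""
        n = network.n
        return cls(_as_prob_array(act, n, "activation propensity"),
                   _as_prob_array(deg, n, "degradation propensity"),
                   np.ones(n), np.ones(n))

    def validate(self, network: BooleanNetwork) -> None:
        for name in ("act", "deg", "keep_off", "keep_on"):
            arr = _as_prob_array(getattr(self, name), network.n, f"propensity {name}")
            if arr.shape != (network.n,):
                raise ValueError(f"expected {network.n} values for {name}")


@dataclass(frozen=True)
class PEWParams:
    """Per-edge reliability pairs ``(p_on, p_off)`` keyed by directed edge."""

    weights: Mapping[Edge, tuple[float, float]]

    method = "pew"

    @classmethod
    def uniform(cls, network: BooleanNetwork, p_on: float, p_off: float | None = None) -> "PEWParams":
        if p_off is None:
            p_off = p_on
        return cls({e: (float(p_on), float(p_off)) for e in extract_edges(network)})

    def validate(self, network: BooleanNetwork) -> None:
        edges = extract_edges(network)
        missing = [e for e in edges if tuple(e) not in {tuple(k) for k in self.weights}]
        if missing:
            e = missing[0]
            raise ValueError(f"missing PEW parameters for edge {e.source}->{e.target}")
        for key, (pon, poff) in self.weights.items():
            if not (0 <= pon <= 1 and 0 <= poff <= 1):
                raise ValueError(f"PEW weights for edge {key[0]}->{key[1]} must lie in [0, 1]")

    def edge_weights(self, source: str, target: str) -> tuple[float, float]:
        try:
            pon, poff = self.weights[Edge(source, target)]  # type: ignore[index]
        except KeyError:
            raise ValueError(f"missing PEW parameters for edge {source}->{target}") from None
        if not (0.0 <= pon <= 1.0 and 0.0 <= poff <= 1.0):
            raise ValueError(f"PEW weights for edge {source}->{target} must lie in [0, 1]")
        return pon, poff


ParameterSet = Union[BNpParams, SDDSParams, PEWParams]


# ---------------------------------------------------------------------------
# Scalar kernels
# ---------------------------------------------------------------------------

def _check_node(network: BooleanNetwork, state, i: int) -> np.ndarray:
    if not 0 <= i < network.n:
        raise IndexError(f"node index {i} out of range")
    arr = np.asarray(state)
    if arr.shape != (network.n,):
        raise ValueError(f"state must have shape ({network.n},)")
    return arr


def bnp_node_update(network: BooleanNetwork, params: BNpParams, state, i: int,
                    rng: np.random.Generator) -> int:
    """One BNp draw for node *i*: complement with probability ``p_i``, else
    the deterministic rule value.  Applies to every node, including identity
    and fixed nodes."""
    arr = _check_node(network, state, i)
    p = float(params.p[i])
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"flip probability p[{i}]={p} outside [0, 1]")
    if rng.random() < p:
        return int(1 - arr[i])
    return int(network.rules[i].evaluate(arr, network.index))


def sdds_node_update(network: BooleanNetwork, params: SDDSParams, state, i: int,
                     rng: np.random.Generator) -> int:
    """One generalized-SDDS draw for node *i* (see module docstring)."""
    arr = _check_node(network, state, i)
    u = int(arr[i])
    v = int(network.rules[i].evaluate(arr, network.index))
    if u == 0 and v == 1:
        rho, fires = float(params.act[i]), 1
    elif u == 1 and v == 0:
        rho, fires = float(params.deg[i]), 0
    elif u == 0:
        rho, fires = float(params.keep_off[i]), 0
    else:
        rho, fires = float(params.keep_on[i]), 1
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"propensity {rho} for node {i} outside [0, 1]")
    return fires if rng.random() < rho else 1 - fires


def pew_node_update(network: BooleanNetwork, params: PEWParams, state, i: int,
                    rng: np.random.Generator,
                    edge_draws: Mapping[str, int] | None = None) -> int:
    """One PEW draw for node *i*: noise each distinct input variable of the
    rule through its edge weights, then fire the rule on the noised inputs.

    ``edge_draws`` may supply the noised value (0/1) per source name for this
    time-step; otherwise one Bernoulli draw per incoming edge is taken from
    ``rng`` in the rule's first-occurrence source order.
    """
    arr = _check_node(network, state, i)
    target = network.nodes[i]
    sources = network.rules[i].variables()
    if not sources:  # fixed node: no incoming edges
        return int(network.rules[i].evaluate(arr, network.index))
    noised = arr.copy()
    for src in sources:
        if edge_draws is not None and src in edge_draws:
            noised[network.index[src]] = int(edge_draws[src])
            continue
        pon, poff = params.edge_weights(src, target)
        r = rng.random()
        if arr[network.index[src]] == 1:
            noised[network.index[src]] = 1 if r < pon else 0
        else:
            noised[network.index[src]] = 0 if r < poff else 1
    return int(network.rules[i].evaluate(noised, network.index))


_SCALAR_KERNELS = {
    "bnp": bnp_node_update,
    "sdds": sdds_node_update,
    "pew": pew_node_update,
}


def step(network: BooleanNetwork, params: ParameterSet, state,
         scheme: str = "sync", update_prob=None,
         rng: np.random.Generator | None = None) -> np.ndarray:
    """Advance a single state one time-step.

    Synchronous: every node's next value is computed from the same previous
    state.  Asynchronous: each node is independently selected for update with
    its ``update_prob``; unselected nodes retain their value.  Random draws
    are consumed in node order so seeded runs are reproducible.
    """
    if rng is None:
        rng = np.random.default_rng()
    method = getattr(params, "method", None)
    if method not in _SCALAR_KERNELS:
        raise ValueError(f"unknown parameterization method {method!r}")
    kernel = _SCALAR_KERNELS[method]
    arr = np.asarray(state).copy()
    if arr.shape != (network.n,):
        raise ValueError(f"state must have shape ({network.n},)")
    if scheme == "sync":
        return np.array([kernel(network, params, arr, i, rng)
                         for i in range(network.n)])
    if scheme == "async":
        u = _as_prob_array(0.5 if update_prob is None else update_prob,
                           network.n, "update probability")
        selected = rng.random(network.n) < u
        nxt = arr.copy()
        for i in range(network.n):
            if selected[i]:
                nxt[i] = kernel(network, params, arr, i, rng)
        return nxt
    raise ValueError(f"unknown update scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Closed-form per-node probabilities (exact oracle building block)
# ---------------------------------------------------------------------------

def node_on_probability(network: BooleanNetwork, params: ParameterSet,
                        state, i: int) -> float:
    """Exact probability that the kernel sets node *i* to 1 from ``state``.

    For PEW the probability is obtained by exhaustive enumeration of the
    joint edge-draw outcomes (2^k terms for in-degree k), so it is exact but
    only intended for small in-degrees.
    """
    arr = _check_node(network, state, i)
    method = params.method
    if method == "bnp":
        u = int(arr[i])
        v = int(network.rules[i].evaluate(arr, network.index))
        p = float(params.p[i])
        return p * (1 - u) + (1 - p) * v
    if method == "sdds":
        u = int(arr[i])
        v = int(network.rules[i].evaluate(arr, network.index))
        if u == 0 and v == 1:
            return float(params.act[i])
        if u == 1 and v == 0:
            return 1.0 - float(params.deg[i])
        if u == 0:
            return 1.0 - float(params.keep_off[i])
        return float(params.keep_on[i])
    if method == "pew":
        target = network.nodes[i]
        sources = network.rules[i].variables()
        if not sources:
            return float(network.rules[i].evaluate(arr, network.index))
        k = len(sources)
        if k > 16:
            raise ValueError(f"in-degree {k} too large for exact PEW enumeration")
        total = 0.0
        noised = arr.copy()
        for combo in range(2 ** k):
            prob = 1.0
            for b, src in enumerate(sources):
                bit = (combo >> b) & 1
                pon, poff = params.edge_weights(src, target)
                cur = int(arr[network.index[src]])
                # probability that the noised read of src equals `bit`
                p_read_on = pon if cur == 1 else 1.0 - poff
                prob *= p_read_on if bit == 1 else 1.0 - p_read_on
                noised[network.index[src]] = bit
            if prob > 0.0 and network.rules[i].evaluate(noised, network.index):
                total += prob
        return min(total, 1.0)
    raise ValueError(f"unknown parameterization method {method!r}")


# ---------------------------------------------------------------------------
# Parameter file I/O (tabular text; scalar broadcast allowed)
# ---------------------------------------------------------------------------

def read_params(source, network: BooleanNetwork, method: str) -> ParameterSet:
    """Read a parameter table for ``method`` from a path, file object or CSV
    text.  A bare number broadcasts to all nodes (or all edges for PEW).

    Expected columns: BNp ``node,p``; SDDS
    ``node,rho_act,rho_deg,rho_keep_off,rho_keep_on``; PEW
    ``source,target,p_on,p_off``.
    """
    method = method.lower()
    if isinstance(source, (int, float)):
        return _broadcast_params(float(source), network, method)
    if isinstance(source, str) and "\n" not in source and "," not in source:
        try:
            return _broadcast_params(float(source), network, method)
        except ValueError:
            pass  # treat as a path
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    table = pd.read_csv(source)
    table.columns = [c.strip().lower() for c in table.columns]
    if method == "bnp":
        p = np.zeros(network.n)
        _fill_per_node(p, table, "p", network)
        return BNpParams(p)
    if method == "sdds":
        cols = {name: np.zeros(network.n)
                for name in ("rho_act", "rho_deg", "rho_keep_off", "rho_keep_on")}
        for name, arr in cols.items():
            _fill_per_node(arr, table, name, network)
        return SDDSParams(cols["rho_act"], cols["rho_deg"],
                          cols["rho_keep_off"], cols["rho_keep_on"])
    if method == "pew":
        weights = {}
        for _, row in table.iterrows():
            weights[Edge(str(row["source"]).strip(), str(row["target"]).strip())] = (
                float(row["p_on"]), float(row["p_off"]))
        params = PEWParams(weights)
        params.validate(network)
        return params
    raise ValueError(f"unknown parameterization method {method!r}")


def _broadcast_params(value: float, network: BooleanNetwork, method: str) -> ParameterSet:
    if method == "bnp":
        return BNpParams.uniform(network, value)
    if method == "sdds":
        return SDDSParams.uniform(network, value)
    if method == "pew":
        return PEWParams.uniform(network, value)
    raise ValueError(f"unknown parameterization method {method!r}")


def _fill_per_node(arr: np.ndarray, table: pd.DataFrame, column: str,
                   network: BooleanNetwork) -> None:
    if "node" not in table.columns or column not in table.columns:
        raise ValueError(f"parameter table needs columns 'node' and {column!r}")
    seen = set()
    for _, row in table.iterrows():
        name = str(row["node"]).strip()
        if name not in network.index:
            raise ValueError(f"parameter table names unknown node {name!r}")
        arr[network.index[name]] = float(row[column])
        seen.add(name)
    missing = [x for x in network.nodes if x not in seen]
    if missing:
        raise ValueError(f"parameter table missing node(s): {', '.join(missing)}")


def write_params(params: ParameterSet, network: BooleanNetwork) -> str:
    """Serialize a parameter set to the CSV dialect read by :func:`read_params`."""
    if params.method == "bnp":
        frame = pd.DataFrame({"node": network.nodes, "p": params.p})
    elif params.method == "sdds":
        frame = pd.DataFrame({"node": network.nodes, "rho_act": params.act,
                              "rho_deg": params.deg, "rho_keep_off": params.keep_off,
                              "rho_keep_on": params.keep_on})
    elif params.method == "pew":
        rows = [(e.source, e.target, *params.edge_weights(e.source, e.target))
                for e in extract_edges(network)]
        frame = pd.DataFrame(rows, columns=["source", "target", "p_on", "p_off"])
    else:
        raise ValueError(f"unknown parameterization method {params.method!r}")
    return frame.to_csv(index=False)
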