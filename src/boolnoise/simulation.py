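"""Repeat-averaged trajectory engine.

All repeats of a simulation advance in lockstep as one boolean array of shape
``(repeats, n)``, with one block of random draws per time-step consumed in a
fixed order (async selection first, then kernel draws in node order).  This
makes seeded runs bit-reproducible and keeps the cost of the standard
50,000-repeat, 20-step runs at a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network_io import BooleanNetwork
from .update_kernels import (BNpParams, ParameterSet, PEWParams, SDDSParams,
                             encode_states, _as_prob_array)

__all__ = [
    "SimulationConfig",
    "sample_initial_state",
    "calc_node_activities",
    "get_reached_states",
    "count_pairwise_trans",
]


@dataclass
class SimulationConfig:
    """Settings shared by the trajectory-based operations.

    Parameters
    ----------
    steps:
        Number of time-steps T (the activity series has T+1 rows, row 0
        being the sampled initial states).
    repeats:
        Number of independent trajectories R.
    scheme:
        ``"sync"`` (all nodes recomputed each step) or ``"async"`` (each node
        independently selected with its ``update_prob``; unselected nodes
        keep their value).
    update_prob:
        Per-node selection probabilities for the async scheme (scalar
        broadcasts); ignored for sync.
    init_prob:
        Per-node initial on-probabilities q_i (scalar broadcasts).  Ignored
        when ``initial_states`` is given.
    initial_states:
        Optional explicit list of initial state vectors, assigned to repeats
        round-robin in the order given.
    seed:
        Seed for the single ``numpy`` generator driving the run.
    last_step_only:
        If true, ``calc_node_activities`` returns only the final row.
    """

    steps: int
    repeats: int
    scheme: str = "sync"
    update_prob: float | Sequence[float] | None = None
    init_prob: float | Sequence[float] = 0.5
    initial_states: Sequence[Sequence[int]] | None = None
    seed: int | None = None
    last_step_only: bool = False

    def __post_init__(self):
        if self.steps < 1 or self.repeats < 1:
            raise ValueError("steps and repeats must be >= 1")
        if self.scheme not in ("sync", "async"):
            raise ValueError(f"unknown update scheme {self.scheme!r}")


def sample_initial_state(q, rng: np.random.Generator, n: int | None = None,
                         size: int | None = None) -> np.ndarray:
    """Sample states with each node independently on with probability q_i.

    Returns a single length-n vector, or an ``(size, n)`` batch."""
    qarr = np.asarray(q, dtype=float)
    if n is None:
        if qarr.ndim == 0:
            raise ValueError("n required when q is scalar")
        n = qarr.shape[0]
    qarr = _as_prob_array(q, n, "initial on-probability")
    shape = (n,) if size is None else (size, n)
    return (rng.random(shape) < qarr).astype(np.int8)


# ---------------------------------------------------------------------------
# Batched one-step kernels
# ---------------------------------------------------------------------------

def _rule_values(network: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """(R, n) boolean matrix of deterministic rule outputs."""
    cols = [network.rules[i].evaluate(states, network.index)
            for i in range(network.n)]
    return np.stack(cols, axis=1)


def _kernel_batch(network: BooleanNetwork, params: ParameterSet,
                  states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Next values for all nodes/repeats as if every node updated (sync)."""
    if isinstance(params, BNpParams):
        f = _rule_values(network, states)
        flip = rng.random(states.shape) < params.p
        return np.where(flip, ~states, f)
    if isinstance(params, SDDSParams):
        f = _rule_values(network, states)
        r = rng.random(states.shape)
        # u=0,v=1: on with act;   u=1,v=0: off with deg
        # u=v: keep with keep_off/keep_on, flip otherwise
        nxt_on = np.where(states,
                          np.where(f, r < params.keep_on, ~(r < params.deg)),
                          np.where(f, r < params.act, ~(r < params.keep_off)))
        return nxt_on
    if isinstance(params, PEWParams):
        nxt = np.empty_like(states)
        for i, (name, rule) in enumerate(zip(network.nodes, network.rules)):
            sources = rule.variables()
            if not sources:
                nxt[:, i] = rule.evaluate(states, network.index)
                continue
            src_idx = np.array([network.index[s] for s in sources])
            pon = np.array([params.edge_weights(s, name)[0] for s in sources])
            poff = np.array([params.edge_weights(s, name)[1] for s in sources])
            r = rng.random((states.shape[0], len(sources)))
            inputs = states[:, src_idx]
            noised = np.where(inputs, r < pon, ~(r < poff))
            tmp = states.copy()
            tmp[:, src_idx] = noised
            nxt[:, i] = rule.evaluate(tmp, network.index)
        return nxt
    raise ValueError(f"unknown parameter type {type(params).__name__}")


def _step_batch(network: BooleanNetwork, params: ParameterSet,
                states: np.ndarray, scheme: str, update_prob,
                rng: np.random.Generator) -> np.ndarray:
    if scheme == "async":
        u = _as_prob_array(0.5 if update_prob is None else update_prob,
                           network.n, "update probability")
        selected = rng.random(states.shape) < u
        nxt = _kernel_batch(network, params, states, rng)
        return np.where(selected, nxt, states)
    return _kernel_batch(network, params, states, rng)


# ---------------------------------------------------------------------------
# Trajectory-level operations
# ---------------------------------------------------------------------------

def _initial_batch(network: BooleanNetwork, config: SimulationConfig,
                   rng: np.random.Generator,
                   initial_states=None) -> np.ndarray:
    explicit = initial_states if initial_states is not None else config.initial_states
    if explicit is not None:
        pool = np.asarray(explicit, dtype=np.int8)
        if pool.ndim == 1:
            pool = pool[None, :]
        if pool.shape[0] == 0:
            raise ValueError("initial_states must be nonempty")
        if pool.shape[1] != network.n:
            raise ValueError(f"initial states must have length {network.n}")
        if not np.isin(pool, (0, 1)).all():
            raise ValueError("initial states must be binary")
        idx = np.arange(config.repeats) % pool.shape[0]
        return pool[idx].astype(bool)
    batch = sample_initial_state(config.init_prob, rng, n=network.n,
                                 size=config.repeats)
    return batch.astype(bool)


def _validated(network: BooleanNetwork, params: ParameterSet) -> None:
    params.validate(network)


def calc_node_activities(network: BooleanNetwork, params: ParameterSet,
                         config: SimulationConfig) -> pd.DataFrame:
    """Average activity of every node at every time-step.

    Simulates ``config.repeats`` independent trajectories for
    ``config.steps`` steps and returns a ``(steps+1) x n`` DataFrame whose
    entry at (t, node) is the fraction of repeats with the node on at step t
    (row 0 reports the sampled initial states).  With ``last_step_only`` only
    the final row is returned.  Every entry is an integer multiple of
    1/repeats.
    """
    _validated(network, params)
    rng = np.random.default_rng(config.seed)
    states = _initial_batch(network, config, rng)
    rows = [states.mean(axis=0)]
    for _ in range(config.steps):
        states = _step_batch(network, params, states, config.scheme,
                             config.update_prob, rng)
        rows.append(states.mean(axis=0))
    if config.last_step_only:
        return pd.DataFrame([rows[-1]], index=[config.steps],
                            columns=network.nodes)
    frame = pd.DataFrame(rows, columns=network.nodes)
    frame.index.name = "step"
    return frame


def get_reached_states(network: BooleanNetwork, params: ParameterSet,
                       config: SimulationConfig,
                       initial_states=None) -> np.ndarray:
    """State at step T for each repeat, as an ``(repeats, n)`` 0/1 array.

    Explicit initial states (argument or config) are assigned round-robin
    across repeats; otherwise initial states are sampled from
    ``config.init_prob``.
    """
    _validated(network, params)
    rng = np.random.default_rng(config.seed)
    states = _initial_batch(network, config, rng, initial_states)
    for _ in range(config.steps):
        states = _step_batch(network, params, states, config.scheme,
                             config.update_prob, rng)
    return states.astype(np.int8)


def count_pairwise_trans(network: BooleanNetwork, params: ParameterSet,
                         config: SimulationConfig,
                         states: Sequence[Sequence[int]]) -> pd.DataFrame:
    """Count observed one-step transitions between the given states.

    Every consecutive pair (S_t, S_{t+1}) with both states in ``states`` is
    counted, summed over repeats and steps; (a, b) and (b, a) are separate
    entries and self-transitions are included.  The result is a square count
    DataFrame indexed by the integer encoding of the given states, in the
    order given.  The grand total is at most repeats*steps, with equality
    exactly when no trajectory ever leaves the state list.
    """
    _validated(network, params)
    pool = np.asarray(states, dtype=np.int8)
    if pool.ndim != 2 or pool.shape[1] != network.n:
        raise ValueError(f"states must be an (m, {network.n}) array-like")
    codes = encode_states(pool)
    if len(np.unique(codes)) != len(codes):
        raise ValueError("states must be distinct")
    order = np.argsort(codes)
    sorted_codes = codes[order]  # order[rank] = original position of a code

    rng = np.random.default_rng(config.seed)
    cur = _initial_batch(network, config, rng)
    counts = np.zeros((len(codes), len(codes)), dtype=np.int64)
    cur_codes = encode_states(cur.astype(np.int8))
    for _ in range(config.steps):
        nxt = _step_batch(network, params, cur, config.scheme,
                          config.update_prob, rng)
        nxt_codes = encode_states(nxt.astype(np.int8))
        in_prev = np.isin(cur_codes, sorted_codes)
        in_next = np.isin(nxt_codes, sorted_codes)
        both = in_prev & in_next
        if both.any():
            a = order[np.searchsorted(sorted_codes, cur_codes[both])]
            b = order[np.searchsorted(sorted_codes, nxt_codes[both])]
            np.add.at(counts, (a, b), 1)
        cur, cur_codes = nxt, nxt_codes
    index = pd.Index(codes, name="state")
    return pd.DataFrame(counts, index=index, columns=index)
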