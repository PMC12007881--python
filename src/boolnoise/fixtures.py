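"""Packaged example networks and seeded random generators.

``lac_operon_network`` loads the 13-node lac operon Boolean model shipped
with the package (transcribed from the Veliz-Cuba & Stigler bistability
model; see the rule file header for the variable legend).  The random
generators produce validated networks and method-appropriate parameter sets
for property tests and oracle cross-checks — they are first-class, seeded,
deterministic API, not test scaffolding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .network_io import (And, BooleanExpression, BooleanNetwork, Const, Not,
                         Or, Var, extract_edges, parse_network)
from .update_kernels import BNpParams, ParameterSet, PEWParams, SDDSParams

__all__ = [
    "GeneratorSpec",
    "random_network",
    "random_params",
    "lac_operon_network",
    "lac_contour_params",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ensemble definition for :func:`random_network`.

    ``n`` nodes; regular nodes draw their regulators uniformly without
    replacement (self-regulation allowed), with in-degree ``k`` exactly when
    ``k_fixed`` else uniform on {1..k}.  Each node is independently made an
    identity node with probability ``p_identity`` or a fixed node (constant
    0/1, fair coin) with probability ``p_fixed``.  ``shape`` selects the rule
    form: ``"tree"`` folds the regulators into a random AND/OR tree with each
    leaf negated with probability 1/2 (every regulator appears exactly once,
    so rules are never semantically constant); ``"dnf"`` realises a random
    non-constant truth table over the regulators as a minterm disjunction.
    """

    n: int
    k: int = 2
    k_fixed: bool = False
    p_identity: float = 0.0
    p_fixed: float = 0.0
    shape: str = "tree"
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 1 <= self.k <= self.n:
            raise ValueError("in-degree k must satisfy 1 <= k <= n")
        if self.p_identity + self.p_fixed > 1:
            raise ValueError("p_identity + p_fixed must not exceed 1")
        if self.shape not in ("tree", "dnf"):
            raise ValueError(f"unknown expression shape {self.shape!r}")


def _random_tree(regs: list[str], rng: np.random.Generator) -> BooleanExpression:
    leaves: list[BooleanExpression] = []
    for name in regs:
        leaf: BooleanExpression = Var(name)
        if rng.random() < 0.5:
            leaf = Not(leaf)
        leaves.append(leaf)
    expr = leaves[0]
    for leaf in leaves[1:]:
        op = And if rng.random() < 0.5 else Or
        expr = op(expr, leaf)
    return expr


def _random_dnf(regs: list[str], rng: np.random.Generator) -> BooleanExpression:
    k = len(regs)
    while True:
        table = rng.integers(0, 2, size=2 ** k)
        if 0 < table.sum() < 2 ** k:  # non-constant
            break
    terms = []
    for row in np.flatnonzero(table):
        lits = [Var(regs[b]) if (row >> b) & 1 else Not(Var(regs[b]))
                for b in range(k)]
        terms.append(lits[0] if k == 1 else And(*lits))
    return terms[0] if len(terms) == 1 else Or(*terms)


def random_network(spec: GeneratorSpec) -> BooleanNetwork:
    """Seeded-deterministic random Boolean network matching ``spec``."""
    rng = np.random.default_rng(spec.seed)
    names = [f"x{i + 1}" for i in range(spec.n)]
    rules: list[BooleanExpression] = []
    for i, name in enumerate(names):
        roll = rng.random()
        if roll < spec.p_identity:
            rules.append(Var(name))
            continue
        if roll < spec.p_identity + spec.p_fixed:
            rules.append(Const(int(rng.integers(0, 2))))
            continue
        k = spec.k if spec.k_fixed else int(rng.integers(1, spec.k + 1))
        regs = [names[j] for j in rng.choice(spec.n, size=k, replace=False)]
        builder = _random_tree if spec.shape == "tree" else _random_dnf
        rules.append(builder(regs, rng))
    return BooleanNetwork(names, rules)


def random_params(network: BooleanNetwork, method: str,
                  prange: tuple[float, float] | float = (0.0, 1.0),
                  seed: int | None = None) -> ParameterSet:
    """Seeded-deterministic random parameter set for ``method``.

    ``prange`` is a (low, high) interval sampled uniformly, or a single value
    assigned everywhere (e.g. 0.9 reproduces the all-0.9 worked example)."""
    rng = np.random.default_rng(seed)
    if np.isscalar(prange):
        lo = hi = float(prange)
    else:
        lo, hi = map(float, prange)
    if not (0 <= lo <= hi <= 1):
        raise ValueError("parameter range must lie within [0, 1]")

    def draw(size):
        if lo == hi:
            return np.full(size, lo)
        return rng.uniform(lo, hi, size=size)

    method = method.lower()
    n = network.n
    if method == "bnp":
        return BNpParams(draw(n))
    if method == "sdds":
        return SDDSParams(draw(n), draw(n), draw(n), draw(n))
    if method == "pew":
        edges = extract_edges(network)
        return PEWParams({e: (float(p), float(q))
                          for e, p, q in zip(edges, draw(len(edges)), draw(len(edges)))})
    raise ValueError(f"unknown parameterization method {method!r}")


def lac_operon_network() -> BooleanNetwork:
    """The packaged 13-node lac operon model (identity inputs Ge, Le, Lem)."""
    text = resources.files("boolnoise.data").joinpath("lac_operon.bn").read_text()
    return parse_network(text)


def lac_contour_params(keep_on_le: float, keep_on_lem: float,
                       free_value: float = 0.9) -> SDDSParams:
    """SDDS parameter scheme for the lac operon input-clamping scan.

    Ge is held off (``rho_off->off = 1``); Le and Lem switch on whenever
    possible (``rho_off->on = 1``) and persist with the given
    ``rho_on->on`` values, which are the two scanned knobs controlling how
    reliably each lactose input stays available.  All remaining propensities
    — including every propensity of the ten internal nodes — are
    ``free_value`` (0.9 by default).
    """
    net = lac_operon_network()
    n = net.n
    act = np.full(n, free_value)
    deg = np.full(n, free_value)
    keep_off = np.full(n, free_value)
    keep_on = np.full(n, free_value)
    ge, le, lem = net.index["Ge"], net.index["Le"], net.index["Lem"]
    keep_off[ge] = 1.0
    act[le] = act[lem] = 1.0
    keep_on[le] = float(keep_on_le)
    keep_on[lem] = float(keep_on_lem)
    return SDDSParams(act, deg, keep_off, keep_on)
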