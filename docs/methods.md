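# Methods

## Model

A Boolean network is an ordered set of `n` binary nodes with update rules
`f_i` over the full state vector; the state space is `{0,1}^n`, encoded as
integers with the first node as the least-significant bit. Nodes are
classified by their rule: *regular* (a genuine Boolean function), *identity*
(the rule is the node itself — an input whose value the dynamics never
rewrites), and *fixed* (a constant rule, clamped forever). Rule files use
the comma-separated "targets, factors" dialect with `!`/`&`/`|`,
parentheses and the constants `0`/`1`; identity nodes are declared
explicitly (`G, G`) so that every referenced node has a rule line and
parsing is fully checkable.

### Noise schemes

All three schemes define, for every node, a conditional law of the next bit
given the previous full state. Because these laws are conditionally
independent across nodes (given the previous state), the synchronous chain's
transition matrix is a product measure per column; this is what makes the
exact oracle below possible.

* **BNp** — flip node `i` to `¬S(i)` with probability `p_i`, else apply
  `f_i`. Noise applies to every node, including identity and fixed nodes;
  the per-node probability of landing on 1 is
  `p_i·[S(i)=0] + (1−p_i)·[f_i(S)=1]`.
* **Generalized SDDS** — four propensities per node. With `u = S(i)`,
  `v = f_i(S)`: a rule-driven change `u→v` is accepted with `ρ_off→on` /
  `ρ_on→off`; when `u = v` the value is preserved with `ρ_off→off` /
  `ρ_on→on` and *flipped* otherwise. Setting both preservation propensities
  to 1 recovers the classic SDDS model exactly (verified entrywise against
  an independently coded reference transition matrix).
* **PEW** — per-edge reliabilities `(p_on, p_off)`. Each distinct input
  variable of `f_i` is re-read through its edge noise (on survives with
  `p_on`; off stays off with `p_off`), then `f_i` fires on the noised
  inputs. One Bernoulli draw per edge per step, reused across repeated
  occurrences of a variable inside one rule — parameters, and therefore
  draws, belong to edges, not to occurrences. Identity nodes carry a real,
  noised self-edge; fixed nodes have no incoming edges and keep their
  constant.

### Updating schemes

Synchronous: all nodes recompute from the same previous state.
Asynchronous: each node is independently selected each step with its own
update probability (default 0.5), selected nodes update through the noise
kernel, unselected nodes keep their value. Per-node independent selection
was chosen over pick-one-uniform because the configuration surface exposes a
*per-node* update probability; it also keeps the per-column product form of
the transition matrix, so the exact oracle covers the asynchronous case too.

## Simulation engine

Repeats are simulated in lockstep as a `(repeats, n)` boolean array; each
time-step consumes a fixed-order block of random draws (async selection
first, then kernel draws in node order) from a single seeded
`numpy.random.Generator`. Seeded runs are therefore bit-reproducible, and
the standard 50,000-repeat, 20-step, 13-node run takes about a second.
Activity values are exact multiples of `1/repeats` by construction. The
scalar kernels (`bnp_node_update`, `sdds_node_update`, `pew_node_update`,
`step`) implement the identical laws one node at a time; the test suite
cross-validates scalar kernels, the batched engine and the exact matrix
against each other.

## Convergence criterion

`calc_convergence_time` reports the smallest `t ≥ w` such that for every
node the means of the activity windows `[t−w+1, t]` and `[t−w, t−1]` differ
by strictly less than the threshold (the difference telescopes to
`|A[t] − A[t−w]|/w`). Row 0 of the series (the sampled initial states)
participates in the windows. First-hit semantics: the criterion is not
required to persist afterwards — with a threshold well above the
Monte-Carlo noise floor (`σ ≈ √(0.25/R)·√2/w` per node) the first hit is in
practice the plateau. The threshold must exceed that floor to be
meaningful: at `R = 50,000`, `w = 2` the floor is ≈ 0.0016, so the
conventional 0.02 is comfortably interpretable.

## Exact Markov oracle

For `n` up to a cap (default 12) the full `2^n × 2^n` column-stochastic
transition matrix is assembled column by column from the closed-form
per-node on-probabilities; PEW columns enumerate all joint edge-draw
outcomes of each node (`2^k` terms for in-degree `k`), trading speed for
exactness. Storage is dense below `n = 8`, sparse CSC above. Ergodicity is
classified on the directed graph of positive transition probabilities:
*reducible* if not strongly connected, else *periodic* if not aperiodic,
else *ergodic*. Stationary distributions solve `(M − I)π = 0` with the
normalisation row replacing the last equation, then clip tiny negative
round-off and renormalise; column sums are enforced to 1 within 1e−12.

## Ergodicity properties — what holds and what does not

* **Generalized SDDS**, all propensities in `(0,1)`: every per-node law
  gives both outcomes positive probability in every state, so every entry
  of `M` is positive — the chain is ergodic, unconditionally.
* **PEW**, all `(p_on, p_off)` in `(0,1)`: for networks *without* fixed
  nodes, every rule produced by the generators depends on each of its
  distinct inputs, the noised input vector has full support, and both
  output values are reachable for every node — ergodic. A fixed node's
  constant rule makes half the state space unreachable — reducible. (A
  semantically constant rule such as `B & !B` would behave like a hidden
  fixed node; the random generator never produces one because every
  regulator appears exactly once per rule.)
* **BNp**, all `p_i` in `(0,1)`: ergodicity is *not* guaranteed, contrary
  to the folklore carried over from the perturbation-vector formulation of
  Boolean networks with perturbation. Under the per-node mixture law the
  probability of *keeping* `S(i)` is `(1−p_i)·[f_i(S)=S(i)]`, which is zero
  whenever the rule already negates the node. A one-node counterexample is
  `A, !A`: flip and rule coincide, the node oscillates deterministically
  for every `p`, and the two-state chain has period 2. Two-node negation
  loops similarly create closed periodic classes (`(0,0) ↔ (1,1)` with
  probability 1 in `A, !B / B, !A`), making the chain reducible. On random
  ensembles that admit negation motifs — which real regulatory models do
  (the repressilator is exactly such a loop) — a substantial fraction of
  BNp chains is non-ergodic; the guarantee only returns under the joint
  formulation where a sampled flip set is applied *instead of* any rule
  update, which is a different Markov chain from the per-node law
  implemented here (and stated by the update equation this package
  follows). The exact engine's `check_ergodicity` makes the distinction
  observable instead of assumed.

## Random generators

`random_network` draws, per node: identity with probability `p_identity`,
fixed with `p_fixed` (value a fair coin), else a regular rule over `k`
regulators sampled uniformly without replacement (self-regulation allowed),
`k` uniform on `{1..K}` or exactly `K`. Rule shapes: a random AND/OR fold
over the regulators with each leaf negated with probability 1/2 (default),
or a random non-constant truth table realised as a minterm DNF. These
defaults are meant to produce small, sparse, biologically plausible logic;
they are not a model of any specific organism, and passing ensemble tests
says nothing about densely connected or canalizing-biased networks.
`random_params` draws uniform parameters from a sub-interval of `[0,1]`
(or broadcasts a single value), keyed per node or per edge as the scheme
requires.

## The packaged lac operon model

The 13-node *lac* operon network (10 internal nodes, identity inputs `Ge`,
`Le`, `Lem`) is transcribed from the published bistable Boolean model of
the operon (Veliz-Cuba & Stigler 2011); the rule file header carries the
legend. The transcription reproduces that model's documented behaviour:
with glucose absent and only medium extracellular lactose, both the
induced and the uninduced states are fixed points of the deterministic
synchronous dynamics. Under generalized SDDS with all propensities 0.9 and
initial on-probabilities 0.5, the identity inputs hold 50% activity at
every step and the network relaxes to its stationary activity profile with
a damped transient; the two-window criterion (threshold 0.02, window 2)
places convergence at step 7 on 50,000-repeat series — the last nodes to
settle are `M`, `P` and `Rm`, whose windowed activity still moves by
0.02–0.07 per step around steps 5–6.

## Numerical and design choices

* State encoding: first node = least-significant bit, fixed at parsing
  order; all state lists and count matrices are indexed by this code.
* Explicit initial-state lists are assigned to repeats round-robin in the
  order given — deterministic and covering every provided state.
* Transition counting includes self-transitions and counts `(a,b)` and
  `(b,a)` separately; the grand total equals `repeats × steps` exactly when
  no trajectory leaves the tracked set.
* Monte-Carlo checks in the test suite compare against exact marginals with
  binomial standard errors; tolerance multipliers are family-wise
  (Šidák-corrected) across the number of simultaneous comparisons a test
  performs, because a fixed per-cell 3σ bound over hundreds of cells would
  reject an unbiased simulator by construction.
* A configuration switch to exempt chosen nodes from BNp/SDDS noise exists
  implicitly through per-node parameters (set `p_i = 0` or pin the
  propensities); noise applies to identity and fixed nodes by default.
* The exact-matrix cap (default `n = 12`) and the PEW in-degree cap (16)
  refuse silently-expensive computations with explicit errors; both are
  raisable arguments.

## Known limitations

* The exact oracle is exponential in `n`; the 13-node worked example is
  deliberately analysed by simulation only (its chain would be
  8192 × 8192).
* PEW noise is per-edge, not per-clause: models whose semantics depend on
  clause-level ("hyper-edge") noise are out of scope.
* Binary variables only; multi-level discrete systems are not supported.
* Asynchronous updating is per-node independent selection; pick-exactly-one
  uniform asynchrony is a different chain and is not implemented.
* The BNp ergodicity caveat above: tooling that assumes "noise ⇒ ergodic"
  for BNp will be wrong on negation motifs — use `check_ergodicity` before
  requesting a stationary distribution.
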