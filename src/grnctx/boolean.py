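"""Synchronous Boolean network semantics and fixed-point (attractor) search.

Update rule: a node becomes 1 iff at least one of its activators is 1 and
none of its inhibitors is 1; a node with no regulators holds its current
state; input nodes (the stimulus) stay clamped.  All nodes update
simultaneously.  A cell phenotype is modelled as a *fixed point* of this map:
a state the synchronous update maps to itself.

Checking whether a phenotype can be an attractor means searching over the
unconstrained nodes for an assignment that completes the constrained partial
state into a fixed point.  The search is exhaustive (vectorized over all
2^k completions) up to 12 free nodes and greedy-with-restarts above, in
which case the result is flagged approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from grnctx.network import GRN

EXHAUSTIVE_FREE_LIMIT = 12


class BooleanNet:
    """A fully signed GRN compiled to activator/inhibitor incidence matrices.

    Parameters
    ----------
    grn : network whose every edge is signed '+' or '-'.
    inputs : clamped nodes (the stimulus); they never update.
    """

    update_rule = "any-activator-and-no-inhibitor"

    def __init__(self, grn: GRN, inputs: set[str] | frozenset[str] = frozenset()):
        unknown = [ix for ix in grn.edges.values() if ix.sign == "?"]
        if unknown:
            bad = ", ".join(f"{ix.source}->{ix.target}" for ix in unknown[:5])
            raise ValueError(f"unsigned edges in Boolean network: {bad}")
        self.grn = grn
        self.inputs = frozenset(inputs)
        self.node_order: list[str] = sorted(grn.nodes)
        self._index = {n: i for i, n in enumerate(self.node_order)}
        n = len(self.node_order)
        self.activators = np.zeros((n, n), dtype=bool)  # [i, j]: i activates j
        self.inhibitors = np.zeros((n, n), dtype=bool)
        for ix in grn.edges.values():
            i, j = self._index[ix.source], self._index[ix.target]
            (self.activators if ix.sign == "+" else self.inhibitors)[i, j] = True
        self.has_regulators = (self.activators | self.inhibitors).any(axis=0)
        self.input_mask = np.array([n_ in self.inputs for n_ in self.node_order])

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def state_vector(self, state: dict[str, int]) -> np.ndarray:
        missing = [n for n in self.node_order if n not in state]
        if missing:
            raise ValueError(f"state missing nodes: {missing[:5]}")
        return np.array([bool(state[n]) for n in self.node_order])

    def step(self, s: np.ndarray) -> np.ndarray:
        """One synchronous update of state matrix `s` (…, n_nodes)."""
        s = np.atleast_2d(s)
        act = s @ self.activators
        inh = s @ self.inhibitors
        nxt = (act > 0) & ~(inh > 0)
        hold = ~self.has_regulators | self.input_mask
        return np.where(hold[None, :], s, nxt)

    def locally_stable(self, s: np.ndarray) -> np.ndarray:
        """Boolean matrix: node's next state equals its current state.

        No-regulator nodes hold and inputs are clamped, so both are stable by
        definition.
        """
        s = np.atleast_2d(s)
        return self.step(s) == s


def update_state(net: BooleanNet, state: dict[str, int]) -> dict[str, int]:
    """One synchronous update of a node → {0,1} state mapping."""
    s = net.state_vector(state)
    nxt = net.step(s)[0]
    return {n: int(nxt[i]) for i, n in enumerate(net.node_order)}


@dataclass(frozen=True)
class WitnessResult:
    """Outcome of a constrained fixed-point search."""

    stable: bool  # a fixed point consistent with every constraint exists
    witness: dict  # best full state found (a fixed point iff stable)
    matched: int  # constrained non-input nodes locally stable in the witness
    total: int  # constrained non-input nodes
    exact: bool  # exhaustive search (False: greedy-with-restarts approximation)


def _search_states(
    net: BooleanNet, clamped: dict[str, int], candidates: np.ndarray
) -> tuple[np.ndarray, int, int]:
    """Rank candidate completions; returns (best state, matched, free_ok)."""
    constrained_idx = np.array(
        [net._index[n] for n in clamped if n not in net.inputs], dtype=int
    )
    free_idx = np.array(
        [i for i, n in enumerate(net.node_order) if n not in clamped], dtype=int
    )
    stable = net.locally_stable(candidates)
    matched = (
        stable[:, constrained_idx].sum(axis=1)
        if len(constrained_idx)
        else np.zeros(len(candidates), dtype=int)
    )
    free_stable = (
        stable[:, free_idx].sum(axis=1)
        if len(free_idx)
        else np.full(len(candidates), 0, dtype=int)
    )
    free_ok = free_stable == len(free_idx)
    # primary: all free nodes stable; then constraint matches; then free stability
    score = (
        free_ok.astype(int) * (len(constrained_idx) + 1) * (len(free_idx) + 2)
        + matched * (len(free_idx) + 2)
        + free_stable
    )
    best = int(np.argmax(score))  # first index on ties: deterministic
    return candidates[best], int(matched[best]), bool(free_ok[best])


def _exhaustive_candidates(net: BooleanNet, clamped: dict[str, int]) -> np.ndarray:
    free_idx = [i for i, n in enumerate(net.node_order) if n not in clamped]
    base = np.zeros(net.n_nodes, dtype=bool)
    for n, v in clamped.items():
        base[net._index[n]] = bool(v)
    k = len(free_idx)
    states = np.tile(base, (1 << k, 1))
    if k:
        assign = (np.arange(1 << k)[:, None] >> np.arange(k)) & 1
        states[:, free_idx] = assign.astype(bool)
    return states


def _greedy_candidates(
    net: BooleanNet, clamped: dict[str, int], rng: np.random.Generator, restarts: int, iters: int
) -> np.ndarray:
    """Repair dynamics on free nodes: from random starts, synchronously flip
    unstable free nodes toward their update value."""
    free_idx = np.array([i for i, n in enumerate(net.node_order) if n not in clamped], dtype=int)
    base = np.zeros(net.n_nodes, dtype=bool)
    for n, v in clamped.items():
        base[net._index[n]] = bool(v)
    out = []
    for _ in range(restarts):
        s = base.copy()
        s[free_idx] = rng.integers(0, 2, size=len(free_idx)).astype(bool)
        for _ in range(iters):
            out.append(s.copy())
            nxt = net.step(s[None, :])[0]
            if np.array_equal(nxt[free_idx], s[free_idx]):
                break
            s[free_idx] = nxt[free_idx]
        out.append(s.copy())
    return np.unique(np.array(out), axis=0)


def best_witness(
    net: BooleanNet,
    constraints: dict[str, int],
    free_node_policy: str = "auto",
    seed: int = 0,
    restarts: int = 24,
    iters: int = 50,
) -> WitnessResult:
    """Best completion of a constrained partial state toward a fixed point.

    Constrained nodes (and inputs) are clamped; the free nodes are searched.
    A constrained node counts as matched when it is locally stable at its
    clamped value in the chosen witness.
    """
    clamped = {n: int(v) for n, v in constraints.items() if n in net._index}
    n_free = sum(1 for n in net.node_order if n not in clamped)
    if free_node_policy not in ("auto", "exhaustive", "greedy"):
        raise ValueError(f"unknown free_node_policy {free_node_policy!r}")
    exhaustive = free_node_policy == "exhaustive" or (
        free_node_policy == "auto" and n_free <= EXHAUSTIVE_FREE_LIMIT
    )
    if exhaustive:
        candidates = _exhaustive_candidates(net, clamped)
    else:
        rng = np.random.default_rng(seed)
        candidates = _greedy_candidates(net, clamped, rng, restarts, iters)
    state, matched, free_ok = _search_states(net, clamped, candidates)
    total = sum(1 for n in clamped if n not in net.inputs)
    witness = {n: int(state[i]) for i, n in enumerate(net.node_order)}
    return WitnessResult(
        stable=free_ok and matched == total,
        witness=witness,
        matched=matched,
        total=total,
        exact=exhaustive,
    )


def is_stable(net: BooleanNet, phenotype, free_node_policy: str = "auto", seed: int = 0):
    """Can the phenotype be a stable steady state (attractor)?

    Returns ``(stable, witness_result)``: stable is True iff some assignment
    of the unconstrained nodes makes the full state a fixed point of the
    synchronous update consistent with every constraint.
    """
    state = phenotype.state if hasattr(phenotype, "state") else dict(phenotype)
    res = best_witness(net, state, free_node_policy=free_node_policy, seed=seed)
    return res.stable, res
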