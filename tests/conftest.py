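"""Shared fixtures and an independent brute-force oracle.

The oracle re-implements the update semantics from scratch in plain
dict-based code (no shared machinery with the engine) and enumerates
the exact trajectory distribution over all initial states and update
orders, so engine results can be checked against exact expectations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from tridyn.network import Edge, NetworkSpec, Node


# ---------------------------------------------------------------------------
# Small reference networks
# ---------------------------------------------------------------------------

@pytest.fixture
def chain2() -> NetworkSpec:
    """Clamped stimulus driving a 2-node activation chain, delays 0."""
    return NetworkSpec(
        nodes=[Node("S", role="input", clamp_level=2), Node("A"), Node("B")],
        edges=[Edge("S", "A", "activate"), Edge("A", "B", "activate")],
    )


@pytest.fixture
def chain_inhibit() -> NetworkSpec:
    """Stimulus activating A, which inhibits B."""
    return NetworkSpec(
        nodes=[Node("S", role="input", clamp_level=2), Node("A"), Node("B")],
        edges=[Edge("S", "A", "activate"), Edge("A", "B", "inhibit")],
    )


@pytest.fixture
def delayed_pair() -> NetworkSpec:
    """Stimulus driving a target through a delay-2 edge."""
    return NetworkSpec(
        nodes=[Node("S", role="input", clamp_level=2), Node("T")],
        edges=[Edge("S", "T", "activate", delay=2)],
    )


@pytest.fixture
def lone_node() -> NetworkSpec:
    """A single unregulated ordinary node (decays to control)."""
    return NetworkSpec(nodes=[Node("X")], edges=[])


def make_chain(k: int, delays: list[int] | None = None) -> NetworkSpec:
    """Stimulus S clamped at 2 driving a k-node activation chain."""
    delays = delays or [0] * k
    names = [f"N{i}" for i in range(k)]
    nodes = [Node("S", role="input", clamp_level=2)] + [Node(n) for n in names]
    edges = [Edge("S", names[0], "activate", delay=delays[0])]
    for i in range(1, k):
        edges.append(Edge(names[i - 1], names[i], "activate", delay=delays[i]))
    return NetworkSpec(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_update(current: int, infl: int) -> int:
    if infl > 0:
        return current + 1 if current < 2 else 2
    if infl < 0:
        return current - 1 if current > 0 else 0
    return current - 1 if current > 1 else (current + 1 if current < 1 else 1)


def oracle_trajectory(
    net: NetworkSpec,
    init: dict[str, int],
    orders: list[list[str]],
) -> tuple[tuple[int, ...], ...]:
    """Deterministic trajectory for given initial state and per-step
    update orders, computed with standalone dict-based code."""
    names = net.node_names
    fixed = net.fixed_levels
    rows = [dict(init)]
    state = dict(init)
    for t, order in enumerate(orders, start=1):
        for node in order:
            infl = 0
            for e in net.in_edges(node):
                if e.delay == 0:
                    v = state[e.source]
                elif t - e.delay >= 1:
                    v = rows[t - e.delay][e.source]
                else:
                    v = 1
                infl += (1 if e.sign == "activate" else -1) * (v - 1)
            state[node] = oracle_update(state[node], infl)
        for name, lvl in fixed.items():
            assert state[name] == lvl
        rows.append(dict(state))
    return tuple(tuple(r[n] for n in names) for r in rows)


def oracle_distribution(
    net: NetworkSpec, spread: float, horizon: int
) -> dict[tuple, Fraction]:
    """Exact probability of every trajectory under the initial-state
    distribution and uniform random update orders."""
    p = Fraction(spread).limit_denominator(10**6)
    ordinary = net.ordinary_nodes
    fixed = net.fixed_levels
    probs = {0: p, 1: 1 - 2 * p, 2: p}
    perms = [list(o) for o in itertools.permutations(ordinary)] or [[]]
    perm_prob = Fraction(1, len(perms))
    dist: dict[tuple, Fraction] = {}
    for combo in itertools.product((0, 1, 2), repeat=len(ordinary)):
        p_init = Fraction(1)
        for s in combo:
            p_init *= probs[s]
        if p_init == 0:
            continue
        init = dict(zip(ordinary, combo))
        init.update(fixed)
        for orders in itertools.product(perms, repeat=horizon):
            traj = oracle_trajectory(net, init, list(orders))
            weight = p_init * perm_prob**horizon
            dist[traj] = dist.get(traj, Fraction(0)) + weight
    assert sum(dist.values()) == 1
    return dist


def oracle_mean_sd(dist: dict[tuple, Fraction]) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-step, per-node mean and sd of a trajectory distribution."""
    trajs = np.array([np.array(t, dtype=float) for t in dist], dtype=float)
    weights = np.array([float(w) for w in dist.values()])
    mean = np.tensordot(weights, trajs, axes=1)
    second = np.tensordot(weights, trajs**2, axes=1)
    return mean, np.sqrt(np.maximum(second - mean**2, 0.0))
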