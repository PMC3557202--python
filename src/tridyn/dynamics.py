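"""Single-run asynchronous three-state dynamics.

Each component holds a state in {0, 1, 2}: below control, at control,
above control.  One time step visits every ordinary node once, in a
fresh uniform-random order, and realizes each update immediately, so a
node updated early in the pass is seen at its new state by nodes
updated later in the same pass (at lag 0).  Delayed edges instead read
the regulator's state from snapshots taken at step boundaries.

Transition rule per node per visit: sum the signed influences of its
regulators — an edge contributes ``sign * (regulator_state - 1)``, with
the regulator's state read at the edge's lag — then

* positive sum: shift up one level (saturating at 2),
* negative sum: shift down one level (saturating at 0),
* zero sum: decay one level toward the control state 1.

Unregulated nodes therefore relax to control, and a node whose
activators fall silent decays back to 1.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkSpec

__all__ = ["History", "influence", "update_node", "step", "simulate_run"]

BASELINE = 1  # control state; also the pre-stimulation history fill


class History:
    """Per-node record of states at step boundaries.

    ``state_at_lag(node, d)`` with ``d >= 1`` returns the step-boundary
    snapshot ``d`` steps back; lag 0 is the current (possibly mid-step)
    working state.  Delayed reads never consult the initial row: the
    initial condition marks the instant of stimulation, so anything a
    delayed edge reaches at or before it is pre-stimulation history and
    reads as the control state 1.  A delay-``d`` edge from a clamped
    stimulus therefore leaves its target at baseline for exactly the
    first ``d`` steps.
    """

    def __init__(self, net: NetworkSpec, init: dict[str, int]):
        self._order = list(net.node_names)
        self._index = {name: i for i, name in enumerate(self._order)}
        bad = set(init) ^ set(self._order)
        if bad:
            raise ValueError(f"initial state does not match node set: {sorted(bad)}")
        for name, level in net.fixed_levels.items():
            if init[name] != level:
                raise ValueError(
                    f"fixed node {name!r} initialized at {init[name]}, "
                    f"clamp level is {level}"
                )
        row = np.array([init[n] for n in self._order], dtype=np.int8)
        if not np.isin(row, (0, 1, 2)).all():
            raise ValueError("states must be in {0, 1, 2}")
        # rows[i] = snapshot after step i; rows[0] = initial state
        self._rows: list[np.ndarray] = [row.copy()]
        self.working = row.copy()  # mutated in place during a pass

    @property
    def step_index(self) -> int:
        """Number of completed steps."""
        return len(self._rows) - 1

    def state_at_lag(self, node: str, lag: int) -> int:
        i = self._index[node]
        if lag == 0:
            return int(self.working[i])
        snap = len(self._rows) - lag
        if snap < 1:  # row 0 and earlier: pre-stimulation control
            return BASELINE
        return int(self._rows[snap][i])

    def commit(self) -> None:
        """Snapshot the working state as the end of the current step."""
        self._rows.append(self.working.copy())

    def as_matrix(self) -> np.ndarray:
        """(steps+1) x nodes matrix of committed snapshots."""
        return np.stack(self._rows)


def influence(node: str, net: NetworkSpec, hist: History) -> int:
    """Signed influence sum on ``node`` from its incoming edges.

    Each edge contributes ``sign * (state - 1)`` where the regulator's
    state is read at the edge's delay: lag 0 sees the in-pass working
    state, lag >= 1 reads committed step-boundary snapshots.  A node
    with no regulators has influence 0 (and will decay to control).
    """
    total = 0
    for e in net.in_edges(node):
        total += e.sign_value * (hist.state_at_lag(e.source, e.delay) - 1)
    return total


def update_node(current: int, infl: int) -> int:
    """One-level transition: shift up, shift down, or decay toward 1."""
    if infl > 0:
        return min(current + 1, 2)
    if infl < 0:
        return max(current - 1, 0)
    if current > BASELINE:
        return current - 1
    if current < BASELINE:
        return current + 1
    return current


def step(net: NetworkSpec, hist: History, rng: np.random.Generator) -> None:
    """Advance one step: visit ordinary nodes in a fresh uniform-random
    permutation, realizing each update immediately, then commit the
    resulting snapshot to the history."""
    order = list(net.ordinary_nodes)
    if order:
        perm = rng.permutation(len(order))
    else:
        perm = []
    for k in perm:
        node = order[k]
        new = update_node(hist.state_at_lag(node, 0), influence(node, net, hist))
        hist.working[hist._index[node]] = new
    hist.commit()


def simulate_run(
    net: NetworkSpec,
    init: dict[str, int],
    horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run one cell for ``horizon`` steps.

    Returns a ``(horizon+1) x n_nodes`` int8 matrix whose row 0 is the
    initial state; columns follow ``net.node_names`` order.  The run is
    deterministic given the network, initial state, horizon, and
    generator state.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    hist = History(net, init)
    for _ in range(horizon):
        step(net, hist, rng)
    return hist.as_matrix()
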