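"""Ensemble simulation: many randomized runs averaged per node per step.

A single run is one in-silico cell; averaging thousands of independent
runs with randomized initial states and update orders emulates the
population-level readout of a western blot or RT-PCR measurement.  The
default ensemble size is 5,000 runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkSpec

__all__ = [
    "InitDistribution",
    "EnsembleResult",
    "run_ensemble",
    "replicate_dispersion",
    "DEFAULT_N_RUNS",
    "DEFAULT_HORIZON",
]

DEFAULT_N_RUNS = 5000
DEFAULT_HORIZON = 40


@dataclass(frozen=True)
class InitDistribution:
    """Initial-state distribution centered at the control state.

    Each ordinary node independently starts at 0 with probability
    ``spread``, at 2 with probability ``spread``, and at 1 otherwise,
    so the expected initial state is exactly 1.  Input/clamped nodes
    start at their clamp level.
    """

    spread: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.spread < 0.5:
            raise ValueError("spread must lie in [0, 0.5)")

    def sample(self, net: NetworkSpec, rng: np.random.Generator) -> dict[str, int]:
        fixed = net.fixed_levels
        ordinary = net.ordinary_nodes
        u = rng.random(len(ordinary))  # one block draw per run
        levels = np.where(u < self.spread, 0, np.where(u < 2 * self.spread, 2, 1))
        init = {name: int(lvl) for name, lvl in zip(ordinary, levels)}
        init.update(fixed)
        return {name: init[name] for name in net.node_names}


@dataclass
class EnsembleResult:
    """Per-node, per-step mean and standard deviation over an ensemble.

    ``mean`` and ``sd`` are ``(horizon+1) x n_nodes`` arrays with
    columns in ``nodes`` order; means lie in [0, 2] and clamped columns
    have zero standard deviation.
    """

    nodes: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_runs: int
    master_seed: int
    #: raw per-run trajectories (n_runs, horizon+1, nodes); kept only on request
    runs: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        return self.mean.shape[0] - 1

    def series(self, node: str) -> np.ndarray:
        """Mean trajectory of one node (length horizon+1)."""
        return self.mean[:, self.nodes.index(node)]

    def sd_series(self, node: str) -> np.ndarray:
        return self.sd[:, self.nodes.index(node)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: step, node, mean, sd."""
        steps = np.arange(self.mean.shape[0])
        records = []
        for j, node in enumerate(self.nodes):
            records.append(
                pd.DataFrame(
                    {
                        "step": steps,
                        "node": node,
                        "mean": self.mean[:, j],
                        "sd": self.sd[:, j],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide-format table: one column per node, indexed by step."""
        return pd.DataFrame(
            self.mean,
            columns=self.nodes,
            index=pd.RangeIndex(self.mean.shape[0], name="step"),
        )

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_long_frame().to_csv(fh, sep="\t", index=False)


def _run_seed(master_seed: int, run_index: int) -> np.random.Generator:
    # Counter-based substreams: independent, reproducible, order-free.
    return np.random.default_rng(np.random.SeedSequence((master_seed, run_index)))


def run_ensemble(
    net: NetworkSpec,
    dist: InitDistribution = InitDistribution(),
    n_runs: int = DEFAULT_N_RUNS,
    horizon: int = DEFAULT_HORIZON,
    master_seed: int = 0,
    keep_runs: bool = False,
) -> EnsembleResult:
    """Simulate ``n_runs`` independent cells and average their trajectories.

    Run ``r`` draws its initial state and all its update-order
    permutations from a substream derived deterministically from
    ``(master_seed, r)``, so results are bit-exactly reproducible and
    independent of execution order.  With ``keep_runs`` the raw per-run
    trajectory array is attached to the result.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    nodes = net.node_names
    index = {name: i for i, name in enumerate(nodes)}
    ord_global = [index[name] for name in net.ordinary_nodes]
    n_ord = len(ord_global)
    # in-edges per ordinary node, as (source column, sign, delay)
    in_edges = [
        [(index[e.source], e.sign_value, e.delay) for e in net.in_edges(name)]
        for name in net.ordinary_nodes
    ]

    # Per-run substreams, consumed exactly as simulate_run would:
    # initial-state block first, then one permutation per step.
    traj = np.empty((n_runs, horizon + 1, len(nodes)), dtype=np.int8)
    perms = np.empty((n_runs, horizon, n_ord), dtype=np.int16)
    for r in range(n_runs):
        rng = _run_seed(master_seed, r)
        init = dist.sample(net, rng)
        traj[r, 0, :] = [init[name] for name in nodes]
        for t in range(horizon):
            perms[r, t, :] = rng.permutation(n_ord)

    # All runs advance in lockstep; within a step, visit positions in
    # order and, at each position, batch the runs that update the same
    # node (asynchronous immediate realization, vectorized across runs).
    ones = np.ones(1, dtype=np.int8)
    for t in range(1, horizon + 1):
        working = traj[:, t - 1, :].copy()
        for k in range(n_ord):
            visited = perms[:, t - 1, k]
            for j in range(n_ord):
                rows = np.nonzero(visited == j)[0]
                if rows.size == 0:
                    continue
                col = ord_global[j]
                infl = np.zeros(rows.size, dtype=np.int64)
                for src, sgn, delay in in_edges[j]:
                    if delay == 0:
                        vals = working[rows, src]
                    elif t - delay >= 1:
                        vals = traj[rows, t - delay, src]
                    else:  # pre-stimulation history reads as control
                        vals = ones
                    infl += sgn * (vals.astype(np.int64) - 1)
                cur = working[rows, col].astype(np.int64)
                new = np.where(
                    infl > 0,
                    np.minimum(cur + 1, 2),
                    np.where(infl < 0, np.maximum(cur - 1, 0), cur + np.sign(1 - cur)),
                )
                working[rows, col] = new.astype(np.int8)
        traj[:, t, :] = working

    mean = traj.mean(axis=0, dtype=np.float64)
    sd = traj.std(axis=0, dtype=np.float64)
    return EnsembleResult(
        nodes=list(nodes),
        mean=mean,
        sd=sd,
        n_runs=n_runs,
        master_seed=master_seed,
        runs=traj if keep_runs else None,
    )


def replicate_dispersion(
    net: NetworkSpec,
    dist: InitDistribution = InitDistribution(),
    n_runs: int = DEFAULT_N_RUNS,
    horizon: int = DEFAULT_HORIZON,
    n_replicates: int = 2,
    master_seed: int = 0,
) -> float:
    """Maximum absolute disagreement between replicate ensemble means.

    Runs ``n_replicates`` independent ensembles whose master seeds are
    derived from ``master_seed`` and returns the largest
    ``|mean_i - mean_j|`` over all replicate pairs, steps, and nodes.
    This quantifies how much of an averaged response curve is sampling
    noise: it shrinks roughly as ``1/sqrt(n_runs)``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rep_seeds = np.random.SeedSequence(master_seed).generate_state(n_replicates)
    means = [
        run_ensemble(net, dist, n_runs, horizon, int(s) % (2**31)).mean
        for s in rep_seeds
    ]
    worst = 0.0
    for i in range(n_replicates):
        for j in range(i + 1, n_replicates):
            worst = max(worst, float(np.abs(means[i] - means[j]).max()))
    return worst
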