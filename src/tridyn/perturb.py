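"""In-silico experiments: stimulus clamps, knockouts, edge edits, comparisons.

A :class:`Scenario` is a complete simulation experiment — which network,
which stimulus levels, which perturbations, how many runs, how long —
loadable from a YAML file so every figure-style result is regenerable
from a declarative description plus a seed.

A gene knockout (siRNA silencing) is modeled as clamping the node at 0,
i.e. below-control activity with the graph left intact, so delayed
edges and influence sums through the node's neighbors remain well
defined.  Encoding a measured constraint ("this phosphatase's activity
does not change") is the same mechanism at level 1.  Deleting a
specific interaction (pathway deletion) removes the edge instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .ensemble import (
    DEFAULT_HORIZON,
    DEFAULT_N_RUNS,
    EnsembleResult,
    InitDistribution,
    run_ensemble,
)
from .network import NetworkSpec, parse_network

__all__ = [
    "Perturbation",
    "Scenario",
    "PerturbationError",
    "apply_perturbations",
    "compare_ensembles",
    "load_scenario",
]

_KINDS = ("knockout_node", "clamp_node", "delete_edge", "set_delay")


class PerturbationError(ValueError):
    """Raised when a perturbation cannot be applied to a network."""


@dataclass(frozen=True)
class Perturbation:
    """One network edit.

    kind
        ``knockout_node`` (clamp at 0), ``clamp_node`` (clamp at
        ``level``), ``delete_edge``, or ``set_delay``.
    target
        Node name, or ``(source, target, sign)`` for edge edits.
    level
        Clamp level for ``clamp_node``.
    delay
        New delay for ``set_delay``.
    """

    kind: str
    target: str | tuple[str, str, str]
    level: int | None = None
    delay: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise PerturbationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "clamp_node" and self.level not in (0, 1, 2):
            raise PerturbationError("clamp_node requires level in {0,1,2}")
        if self.kind == "set_delay" and (self.delay is None or self.delay < 0):
            raise PerturbationError("set_delay requires a non-negative delay")
        if self.kind in ("delete_edge", "set_delay"):
            if not (isinstance(self.target, tuple) and len(self.target) == 3):
                raise PerturbationError(
                    f"{self.kind} requires a (source, target, sign) triple"
                )

    @staticmethod
    def knockout(node: str) -> "Perturbation":
        return Perturbation(kind="knockout_node", target=node)

    @staticmethod
    def clamp(node: str, level: int) -> "Perturbation":
        return Perturbation(kind="clamp_node", target=node, level=level)

    @staticmethod
    def delete_edge(source: str, target: str, sign: str) -> "Perturbation":
        return Perturbation(kind="delete_edge", target=(source, target, sign))

    @staticmethod
    def set_delay(source: str, target: str, sign: str, delay: int) -> "Perturbation":
        return Perturbation(kind="set_delay", target=(source, target, sign), delay=delay)


def _find_edge(net: NetworkSpec, triple: tuple[str, str, str]):
    for e in net.edges:
        if (e.source, e.target, e.sign) == triple:
            return e
    raise PerturbationError(f"no edge {triple[0]} {triple[2]} {triple[1]} in network")


def apply_perturbations(
    net: NetworkSpec, perturbations: Sequence[Perturbation]
) -> NetworkSpec:
    """Apply edits in order, returning a new network; ``net`` is untouched.

    Re-clamping an already clamped/input node (including knocking out a
    clamped node) is a conflict and raises rather than silently
    last-winning, so a scenario cannot accidentally override its own
    stimulus.
    """
    nodes = list(net.nodes)
    edges = list(net.edges)
    clamped_here: set[str] = set()
    for p in perturbations:
        if p.kind in ("knockout_node", "clamp_node"):
            name = p.target
            idx = next((i for i, n in enumerate(nodes) if n.name == name), None)
            if idx is None:
                raise PerturbationError(f"unknown node {name!r}")
            if nodes[idx].is_fixed or name in clamped_here:
                raise PerturbationError(
                    f"conflicting clamp on node {name!r} (already fixed)"
                )
            level = 0 if p.kind == "knockout_node" else p.level
            nodes[idx] = replace(nodes[idx], role="clamped", clamp_level=level)
            clamped_here.add(name)
        elif p.kind == "delete_edge":
            e = _find_edge(NetworkSpec(nodes=nodes, edges=edges), p.target)
            edges.remove(e)
        else:  # set_delay
            e = _find_edge(NetworkSpec(nodes=nodes, edges=edges), p.target)
            edges[edges.index(e)] = replace(e, delay=p.delay)
    return NetworkSpec(nodes=nodes, edges=edges)


@dataclass
class Scenario:
    """A complete in-silico experiment."""

    network: str | Path | NetworkSpec
    stimulus: dict[str, int] = field(default_factory=dict)
    perturbations: list[Perturbation] = field(default_factory=list)
    n_runs: int = DEFAULT_N_RUNS
    horizon: int = DEFAULT_HORIZON
    spread: float = 0.1
    seed: int = 0
    name: str = ""

    def resolve_network(self) -> NetworkSpec:
        """Load the network and apply stimulus clamps and perturbations.

        Stimulus entries mark their node as a held ``input`` (e.g. the
        palmitate stimulus held above control for the whole window);
        perturbations are then applied in order.
        """
        if isinstance(self.network, NetworkSpec):
            net = self.network
        else:
            net = parse_network(self.network)
        for node, level in sorted(self.stimulus.items()):
            if net.node(node).is_fixed:
                raise PerturbationError(
                    f"stimulus on {node!r} conflicts with an existing clamp"
                )
            net = net.with_node(node, role="input", clamp_level=level)
        return apply_perturbations(net, self.perturbations)

    def run(self, master_seed: int | None = None) -> EnsembleResult:
        return run_ensemble(
            self.resolve_network(),
            InitDistribution(self.spread),
            n_runs=self.n_runs,
            horizon=self.horizon,
            master_seed=self.seed if master_seed is None else master_seed,
        )


def _perturbation_from_dict(d: dict) -> Perturbation:
    kind = d.get("kind")
    target = d.get("target")
    if isinstance(target, list):
        target = tuple(target)
    return Perturbation(kind=kind, target=target, level=d.get("level"), delay=d.get("delay"))


def load_scenario(path: str | Path, network_dir: str | Path | None = None) -> Scenario:
    """Load a scenario from YAML.

    Keys: ``network`` (path, resolved relative to ``network_dir`` or the
    scenario file's directory), ``stimulus`` (node -> level),
    ``perturbations`` (list of {kind, target, level, delay}),
    ``n_runs``, ``horizon``, ``p`` (initial spread), ``seed``.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    base = Path(network_dir) if network_dir is not None else path.parent
    net_path = Path(data["network"])
    if not net_path.is_absolute():
        net_path = base / net_path
    return Scenario(
        network=net_path,
        stimulus={str(k): int(v) for k, v in (data.get("stimulus") or {}).items()},
        perturbations=[_perturbation_from_dict(d) for d in data.get("perturbations") or []],
        n_runs=int(data.get("n_runs", DEFAULT_N_RUNS)),
        horizon=int(data.get("horizon", DEFAULT_HORIZON)),
        spread=float(data.get("p", 0.1)),
        seed=int(data.get("seed", 0)),
        name=str(data.get("name", path.stem)),
    )


def compare_ensembles(
    ref: EnsembleResult, pert: EnsembleResult, node: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step mean difference (perturbed minus reference) for one node,
    with the pooled Monte-Carlo standard error of the difference."""
    if ref.mean.shape != pert.mean.shape or ref.nodes != pert.nodes:
        raise ValueError("ensembles are not comparable (shape or node mismatch)")
    diff = pert.series(node) - ref.series(node)
    se = np.sqrt(
        ref.sd_series(node) ** 2 / ref.n_runs + pert.sd_series(node) ** 2 / pert.n_runs
    )
    return diff, se
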