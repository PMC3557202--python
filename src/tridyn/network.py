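"""Signed interaction networks with per-edge delays and node roles.

A network is a directed graph over named components (proteins, second
messengers, stimuli).  Each edge carries a sign (``activate`` or
``inhibit``) and a non-negative integer delay in simulation steps; a
delay of ``d`` means the target reads its regulator's state ``d`` steps
in the past, modeling slow processes such as transcription or delayed
kinase activation.  Nodes are ``ordinary`` (dynamic), ``input``
(stimulus held at a fixed level), or ``clamped`` (held fixed to encode a
measured constraint or an in-silico knockout).

File format
-----------
Tab-separated interaction lists, one edge per line::

    # input PA 2
    # clamp PP1 1
    PA	activate	PACT	0
    PACT	activate	PKR

``#``-prefixed header lines declare node roles and clamp levels; the
delay column is optional and defaults to 0.  The writer emits a
canonical, deterministically ordered file so that structurally equal
networks serialize byte-identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "Node",
    "Edge",
    "NetworkSpec",
    "NetworkValidationError",
    "parse_network",
    "write_network",
    "ACTIVATE",
    "INHIBIT",
]

ACTIVATE = "activate"
INHIBIT = "inhibit"
_SIGNS = (ACTIVATE, INHIBIT)
_ROLES = ("ordinary", "input", "clamped")
_STATES = (0, 1, 2)


class NetworkValidationError(ValueError):
    """Raised when a network file or in-memory network is malformed."""


@dataclass(frozen=True)
class Node:
    """A network component.

    Parameters
    ----------
    name
        Unique, non-empty identifier.
    role
        ``ordinary`` nodes evolve dynamically; ``input`` and ``clamped``
        nodes hold ``clamp_level`` at every step.
    clamp_level
        State in {0, 1, 2}; required exactly when the role is ``input``
        or ``clamped``.
    """

    name: str
    role: str = "ordinary"
    clamp_level: int | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise NetworkValidationError("node name must be a non-empty string")
        if self.role not in _ROLES:
            raise NetworkValidationError(
                f"node {self.name!r}: unknown role {self.role!r}"
            )
        fixed = self.role in ("input", "clamped")
        if fixed and self.clamp_level not in _STATES:
            raise NetworkValidationError(
                f"node {self.name!r}: role {self.role!r} requires a clamp level in {{0,1,2}}"
            )
        if not fixed and self.clamp_level is not None:
            raise NetworkValidationError(
                f"node {self.name!r}: ordinary node must not carry a clamp level"
            )

    @property
    def is_fixed(self) -> bool:
        """True for input and clamped nodes (state never updated)."""
        return self.role in ("input", "clamped")


@dataclass(frozen=True)
class Edge:
    """A signed, delayed regulatory interaction."""

    source: str
    target: str
    sign: str
    delay: int = 0

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: unknown sign {self.sign!r}"
            )
        if not isinstance(self.delay, int) or isinstance(self.delay, bool) or self.delay < 0:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: delay must be a non-negative "
                f"integer, got {self.delay!r}"
            )

    @property
    def sign_value(self) -> int:
        """+1 for activation, -1 for inhibition."""
        return 1 if self.sign == ACTIVATE else -1


@dataclass
class NetworkSpec:
    """A validated signed interaction network.

    Nodes are keyed by name; edges reference node names.  Construction
    validates referential integrity, uniqueness, and the duplicate-edge
    rules (no repeated (source, target, sign) triple, and no direct
    activate+inhibit pair between the same ordered node pair — dual
    regulation must be made explicit through intermediate nodes).
    """

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkValidationError(f"duplicate node name(s): {dup}")
        node_set = set(names)
        seen: set[tuple[str, str, str]] = set()
        pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in node_set:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target}: unknown node {endpoint!r}"
                    )
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise NetworkValidationError(
                    f"duplicate edge {e.source} {e.sign} {e.target}"
                )
            pair = (e.source, e.target)
            if pair in pairs and key not in seen:
                other = next(x for x in self.edges if (x.source, x.target) == pair)
                if other.sign != e.sign:
                    raise NetworkValidationError(
                        f"conflicting signs on edge {e.source}->{e.target}; "
                        "use an explicit intermediate node"
                    )
            seen.add(key)
            pairs.add(pair)

    # -- convenience accessors -------------------------------------------------

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def ordinary_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if not n.is_fixed]

    @property
    def fixed_levels(self) -> dict[str, int]:
        """Clamp levels of input/clamped nodes, keyed by name."""
        return {n.name: n.clamp_level for n in self.nodes if n.is_fixed}

    @property
    def max_delay(self) -> int:
        return max((e.delay for e in self.edges), default=0)

    def in_edges(self, target: str) -> list[Edge]:
        return [e for e in self.edges if e.target == target]

    def with_node(self, name: str, **changes) -> "NetworkSpec":
        """Return a copy with one node replaced (pure update)."""
        new_nodes = [
            replace(n, **changes) if n.name == name else n for n in self.nodes
        ]
        if name not in {n.name for n in self.nodes}:
            raise KeyError(name)
        return NetworkSpec(nodes=new_nodes, edges=list(self.edges))

    def structurally_equal(self, other: "NetworkSpec") -> bool:
        """Order-insensitive equality of node and edge sets."""
        return (
            sorted(self.nodes, key=lambda n: n.name)
            == sorted(other.nodes, key=lambda n: n.name)
            and sorted(self.edges, key=lambda e: (e.source, e.target, e.sign))
            == sorted(other.edges, key=lambda e: (e.source, e.target, e.sign))
        )


def _parse_int(token: str, what: str, line_no: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise NetworkValidationError(
            f"line {line_no}: {what} must be an integer, got {token!r}"
        ) from None
    return value


def parse_network(path: Union[str, Path, io.TextIOBase]) -> NetworkSpec:
    """Read a tab-separated interaction file into a :class:`NetworkSpec`.

    Header lines ``# input NAME LEVEL`` and ``# clamp NAME LEVEL``
    declare node roles; ``# node NAME`` declares an isolated ordinary
    node.  Other ``#`` lines are comments.  Edge lines have 3 or 4
    tab-separated fields: ``source  sign  target  [delay]``.

    Raises
    ------
    NetworkValidationError
        On unknown sign tokens, negative/non-integer delays, duplicate
        edges, or clamp declarations without a level — each message
        names the offending line.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()

    declared: dict[str, Node] = {}
    edges: list[Edge] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            fields = line.lstrip("# ").split()
            if fields and fields[0] in ("input", "clamp", "node"):
                keyword = fields[0]
                if keyword == "node":
                    if len(fields) != 2:
                        raise NetworkValidationError(
                            f"line {line_no}: node declaration needs exactly a name"
                        )
                    name = fields[1]
                    role, level = "ordinary", None
                else:
                    if len(fields) != 3:
                        raise NetworkValidationError(
                            f"line {line_no}: {keyword} declaration needs a name and "
                            f"a level in {{0,1,2}}"
                        )
                    name = fields[1]
                    level = _parse_int(fields[2], "clamp level", line_no)
                    if level not in _STATES:
                        raise NetworkValidationError(
                            f"line {line_no}: clamp level must be 0, 1 or 2"
                        )
                    role = "input" if keyword == "input" else "clamped"
                if name in declared:
                    raise NetworkValidationError(
                        f"line {line_no}: node {name!r} declared twice"
                    )
                declared[name] = Node(name=name, role=role, clamp_level=level)
            continue  # plain comment
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise NetworkValidationError(
                f"line {line_no}: expected 3 or 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        source, sign, target = (f.strip() for f in fields[:3])
        if sign not in _SIGNS:
            raise NetworkValidationError(
                f"line {line_no}: unknown sign token {sign!r} "
                f"(expected 'activate' or 'inhibit')"
            )
        delay = 0
        if len(fields) == 4 and fields[3].strip():
            delay = _parse_int(fields[3].strip(), "delay", line_no)
            if delay < 0:
                raise NetworkValidationError(f"line {line_no}: negative delay")
        try:
            edge = Edge(source=source, target=target, sign=sign, delay=delay)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"line {line_no}: {exc}") from None
        if any(
            (e.source, e.target, e.sign) == (edge.source, edge.target, edge.sign)
            for e in edges
        ):
            raise NetworkValidationError(
                f"line {line_no}: duplicate edge {source} {sign} {target}"
            )
        edges.append(edge)

    # Node set = declared nodes plus all edge endpoints (ordinary by default).
    nodes = dict(declared)
    for e in edges:
        for endpoint in (e.source, e.target):
            nodes.setdefault(endpoint, Node(name=endpoint))
    return NetworkSpec(nodes=sorted(nodes.values(), key=lambda n: n.name), edges=edges)


def write_network(net: NetworkSpec, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write ``net`` in canonical form (sorted header, then edges sorted
    lexicographically by source, target, sign).

    ``parse_network(write_network(net))`` is structurally equal to
    ``net``, and structurally equal networks produce byte-identical
    files.  Comments from a parsed file are not preserved.
    """
    lines: list[str] = []
    for n in sorted(net.nodes, key=lambda n: n.name):
        if n.role == "input":
            lines.append(f"# input {n.name} {n.clamp_level}")
        elif n.role == "clamped":
            lines.append(f"# clamp {n.name} {n.clamp_level}")
    connected = {e.source for e in net.edges} | {e.target for e in net.edges}
    for n in sorted(net.nodes, key=lambda n: n.name):
        if n.role == "ordinary" and n.name not in connected:
            lines.append(f"# node {n.name}")
    for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign)):
        lines.append(f"{e.source}\t{e.sign}\t{e.target}\t{e.delay}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)
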