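"""Driver-network topologies and steady-state signal-flow propagation.

A driver network is a conservative flow network: a unit stress signal
:math:`\\Sigma = 1` enters at a single source node, is split among kinase
pathways according to fractional edge capacities, and funnels into a single
output node whose inflow is the relative transcriptional output
:math:`\\phi_{BACH1}`.  At every node the outflow equals the inflow
(steady state, no amplification), so in the untreated network the output
inflow is exactly 1.  Treatment reduces a node's activity multiplicatively;
the unabsorbed inflow is recorded as a node-local loss (the signal surplus
available to compensatory networks).

The canonical topologies are ``N1`` (the anisomycin-stimulated BM1-cell
network with crosstalk between the RAF/ERK, MLK/JNK and TAOK/p38 pathways)
and ``N2`` (the same three pathways with all crosstalk removed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .constants import DEFAULT_SPLITS

__all__ = [
    "TopologyError",
    "NodeSpec",
    "EdgeSpec",
    "SplitParams",
    "FractionTable",
    "NetworkTopology",
    "FlowState",
    "build_n1",
    "build_n2",
    "propagate",
    "conservation_residual",
    "load_topology",
    "load_preset",
]

#: fraction name that always resolves to 1.0 (a single full-flow edge)
UNIT = "unit"

_ROLES = ("source", "kinase", "output")
_KINDS = ("pathway", "crosstalk", "repression")


class TopologyError(ValueError):
    """Raised when a topology or its parameters violate an invariant."""


@dataclass(frozen=True)
class NodeSpec:
    """A network node: the stress source, a kinase, or the output."""

    id: int
    label: str
    role: str = "kinase"

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise TopologyError(f"node ids must be positive, got {self.id}")
        if self.role not in _ROLES:
            raise TopologyError(f"unknown node role {self.role!r}")


@dataclass(frozen=True)
class EdgeSpec:
    """A directed edge carrying a named fraction of the source node's outflow.

    ``repression`` edges are modifiers only: they carry no mass flow and are
    excluded from conservation bookkeeping.
    """

    src: int
    dst: int
    fraction_name: str = UNIT
    kind: str = "pathway"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise TopologyError(f"unknown edge kind {self.kind!r}")


@dataclass(frozen=True)
class SplitParams:
    """Split fractions of the canonical N1/N2 parameterization.

    ``alpha1 + alpha2 + A12 = 1`` partitions the stress signal among the
    RAF, MLK and TAOK pathways; ``alphak + Ak = 1`` (k = 3..6) partitions
    the outflow of each branching kinase between its pathway and its
    crosstalk edge.
    """

    alpha1: float = DEFAULT_SPLITS["alpha1"]
    alpha2: float = DEFAULT_SPLITS["alpha2"]
    alpha3: float = DEFAULT_SPLITS["alpha3"]
    alpha4: float = DEFAULT_SPLITS["alpha4"]
    alpha5: float = DEFAULT_SPLITS["alpha5"]
    alpha6: float = DEFAULT_SPLITS["alpha6"]

    def __post_init__(self) -> None:
        for k in range(1, 7):
            v = getattr(self, f"alpha{k}")
            if not 0.0 <= v <= 1.0:
                raise TopologyError(f"alpha{k}={v} outside [0, 1]")
        if self.alpha1 + self.alpha2 > 1.0 + 1e-12:
            raise TopologyError(
                f"alpha1 + alpha2 = {self.alpha1 + self.alpha2} exceeds 1"
            )

    @property
    def A12(self) -> float:
        return 1.0 - self.alpha1 - self.alpha2

    @property
    def A3(self) -> float:
        return 1.0 - self.alpha3

    @property
    def A4(self) -> float:
        return 1.0 - self.alpha4

    @property
    def A5(self) -> float:
        return 1.0 - self.alpha5

    @property
    def A6(self) -> float:
        return 1.0 - self.alpha6

    def resolve(self, name: str) -> float:
        if name == UNIT:
            return 1.0
        if name.startswith("alpha") and name[5:] in "123456":
            return getattr(self, name)
        if name in ("A12", "A3", "A4", "A5", "A6"):
            return getattr(self, name)
        raise TopologyError(f"unresolved fraction name {name!r}")

    def as_dict(self) -> dict[str, float]:
        return {f"alpha{k}": getattr(self, f"alpha{k}") for k in range(1, 7)}


@dataclass(frozen=True)
class FractionTable:
    """A free-form name -> fraction map for arbitrary (sampled) topologies."""

    values: Mapping[str, float] = field(default_factory=dict)

    def resolve(self, name: str) -> float:
        if name == UNIT:
            return 1.0
        try:
            return float(self.values[name])
        except KeyError:
            raise TopologyError(f"unresolved fraction name {name!r}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class NetworkTopology:
    """An immutable, validated driver-network topology."""

    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    splits: SplitParams | FractionTable
    name: str = "network"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise TopologyError("duplicate node ids")
        for role in ("source", "output"):
            n = sum(1 for nd in self.nodes if nd.role == role)
            if n != 1:
                raise TopologyError(f"expected exactly one {role} node, found {n}")
        known = set(ids)
        for e in self.edges:
            if e.src not in known or e.dst not in known:
                raise TopologyError(f"edge {e.src}->{e.dst} references unknown node")
        for e in self.mass_edges:
            f = self.splits.resolve(e.fraction_name)
            if not 0.0 <= f <= 1.0 + 1e-12:
                raise TopologyError(
                    f"fraction {e.fraction_name}={f} outside [0, 1]"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise TopologyError("mass-carrying edges contain a cycle")
        # outgoing fractions at each node must sum to 1 (conservation)
        for nid in known:
            out = [e for e in self.mass_edges if e.src == nid]
            if out:
                s = sum(self.splits.resolve(e.fraction_name) for e in out)
                if abs(s - 1.0) > 1e-9:
                    raise TopologyError(
                        f"outgoing fractions at node {nid} sum to {s}, not 1"
                    )

    @property
    def mass_edges(self) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.kind != "repression")

    @property
    def repression_edges(self) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.kind == "repression")

    @property
    def source(self) -> NodeSpec:
        return next(n for n in self.nodes if n.role == "source")

    @property
    def output(self) -> NodeSpec:
        return next(n for n in self.nodes if n.role == "output")

    @property
    def has_crosstalk(self) -> bool:
        """True if any crosstalk edge carries a nonzero fraction."""
        return any(
            e.kind == "crosstalk" and self.splits.resolve(e.fraction_name) > 0.0
            for e in self.edges
        )

    def node(self, nid: int) -> NodeSpec:
        for n in self.nodes:
            if n.id == nid:
                return n
        raise KeyError(nid)

    def node_by_label(self, label: str) -> NodeSpec:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def fraction(self, edge: EdgeSpec) -> float:
        return self.splits.resolve(edge.fraction_name)

    def graph(self) -> nx.DiGraph:
        """Directed graph over mass-carrying edges, fractions as weights."""
        g = nx.DiGraph()
        g.add_nodes_from(n.id for n in self.nodes)
        for e in self.mass_edges:
            g.add_edge(e.src, e.dst, fraction=self.fraction(e))
        return g

    def with_splits(self, splits: SplitParams | FractionTable) -> "NetworkTopology":
        return replace(self, splits=splits)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [vars(n) | {} for n in self.nodes],
            "edges": [vars(e) | {} for e in self.edges],
            "splits": self.splits.as_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkTopology":
        nodes = tuple(NodeSpec(**n) for n in d["nodes"])
        edges = tuple(EdgeSpec(**e) for e in d["edges"])
        raw = dict(d.get("splits", {}))
        canonical = {f"alpha{k}" for k in range(1, 7)}
        splits: SplitParams | FractionTable
        if raw and set(raw) <= canonical:
            splits = SplitParams(**raw)
        else:
            splits = FractionTable(raw)
        return cls(nodes=nodes, edges=edges, splits=splits,
                   name=d.get("name", "network"))


@dataclass(frozen=True)
class FlowState:
    """Per-node steady-state inflow/outflow and treatment losses.

    All values are fractions of the total stress input.  ``loss`` is the
    signal a treated node failed to absorb, ``(1 - activity) * inflow``.
    """

    topology: NetworkTopology
    inflow: Mapping[int, float]
    outflow: Mapping[int, float]
    loss: Mapping[int, float]

    @property
    def output_flow(self) -> float:
        return self.inflow[self.topology.output.id]

    @property
    def total_loss(self) -> float:
        return sum(self.loss.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.id,
                "label": n.label,
                "inflow": self.inflow[n.id],
                "outflow": self.outflow[n.id],
                "loss": self.loss[n.id],
            }
            for n in self.topology.nodes
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canonical topologies


def _n1_nodes() -> tuple[NodeSpec, ...]:
    return (
        NodeSpec(1, "signal", "source"),
        NodeSpec(2, "RAF"),
        NodeSpec(3, "MEK"),
        NodeSpec(4, "ERK"),
        NodeSpec(5, "MLK"),
        NodeSpec(6, "JNK"),
        NodeSpec(7, "TAOK"),
        NodeSpec(8, "p38"),
        NodeSpec(9, "BACH1", "output"),
    )


def _n1_edges() -> tuple[EdgeSpec, ...]:
    E = EdgeSpec
    return (
        # signal split among the three pathways
        E(1, 2, "alpha1"),
        E(1, 5, "alpha2"),
        E(1, 7, "A12"),
        # RAF -> MEK -> ERK backbone
        E(2, 3),
        E(3, 4),
        # MLK splits between JNK (pathway) and p38 (crosstalk)
        E(5, 6, "alpha3"),
        E(5, 8, "A3", "crosstalk"),
        # TAOK splits between JNK (crosstalk) and p38 (pathway)
        E(7, 6, "alpha4", "crosstalk"),
        E(7, 8, "A4"),
        # p38 feeds ERK (crosstalk) and the output
        E(8, 4, "A5", "crosstalk"),
        E(8, 9, "alpha5"),
        # ERK feeds JNK (crosstalk) and the output
        E(4, 6, "A6", "crosstalk"),
        E(4, 9, "alpha6"),
        # JNK feeds the output
        E(6, 9),
        # repression of ERK by JNK and TAOK: modifiers, no mass flow
        E(6, 4, UNIT, "repression"),
        E(7, 4, UNIT, "repression"),
    )


def build_n1(splits: SplitParams | None = None) -> NetworkTopology:
    """The 9-node crosstalk topology N1 of the stress-MAPK driver network.

    Three pathways (signal->RAF->MEK->ERK, signal->MLK->JNK,
    signal->TAOK->p38) converge on the BACH1 output node, connected by
    crosstalk edges MLK->p38, TAOK->JNK, p38->ERK and ERK->JNK, plus
    mass-free repression edges JNK-|ERK and TAOK-|ERK.
    """
    return NetworkTopology(
        nodes=_n1_nodes(),
        edges=_n1_edges(),
        splits=splits if splits is not None else SplitParams(),
        name="N1",
    )


def build_n2(splits: SplitParams | None = None) -> NetworkTopology:
    """The crosstalk-free topology N2: three independent pathway chains.

    Built on the N1 scaffold with every crosstalk fraction forced to zero
    (alpha3 = 1, alpha4 = 0, alpha5 = 1, alpha6 = 1), so the same
    propagation engine serves both topologies.  The source split
    (alpha1, alpha2) is kept from ``splits`` if given.
    """
    base = splits if splits is not None else SplitParams()
    n2_splits = replace(base, alpha3=1.0, alpha4=0.0, alpha5=1.0, alpha6=1.0)
    topo = build_n1(n2_splits)
    return replace(topo, name="N2")


# ---------------------------------------------------------------------------
# propagation


def propagate(
    topology: NetworkTopology,
    activity: Mapping[int, float] | None = None,
) -> FlowState:
    """Steady-state flow propagation in topological order.

    Each node's inflow is the fraction-weighted sum of its upstream
    outflows; its outflow is ``activity * inflow`` and the deficit
    ``(1 - activity) * inflow`` is booked as node-local loss.  Untreated
    (all activities 1) the output inflow is exactly 1 by conservation.

    Raw activities outside [0, 1] (possible at high dose with the printed
    dose-response constants) are clamped with a coherence warning.
    """
    activity = dict(activity or {})
    g = topology.graph()
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - validated earlier
        raise TopologyError("topology contains a cycle") from exc

    inflow: dict[int, float] = {n.id: 0.0 for n in topology.nodes}
    outflow: dict[int, float] = dict(inflow)
    loss: dict[int, float] = dict(inflow)
    inflow[topology.source.id] = 1.0

    for nid in order:
        for pred in g.predecessors(nid):
            inflow[nid] += g.edges[pred, nid]["fraction"] * outflow[pred]
        a = activity.get(nid, 1.0)
        if a < 0.0 or a > 1.0:
            warnings.warn(
                f"activity {a:.4g} at node {nid} outside [0, 1]; clamping",
                stacklevel=2,
            )
            a = min(max(a, 0.0), 1.0)
        outflow[nid] = a * inflow[nid]
        loss[nid] = (1.0 - a) * inflow[nid]

    return FlowState(topology=topology, inflow=inflow, outflow=outflow, loss=loss)


def conservation_residual(
    flow: FlowState, losses: Mapping[int, float] | None = None
) -> float:
    """|output_flow + total losses - 1|: zero for any conservative flow."""
    total = sum((losses if losses is not None else flow.loss).values())
    return abs(flow.output_flow + total - 1.0)


# ---------------------------------------------------------------------------
# presets


def load_topology(path) -> NetworkTopology:
    """Load a topology from a JSON config file."""
    with open(path) as fh:
        return NetworkTopology.from_dict(json.load(fh))


def load_preset(name: str) -> NetworkTopology:
    """Load a shipped preset topology (``n1`` or ``n2``) by name."""
    name = name.lower()
    if name not in ("n1", "n2"):
        raise TopologyError(f"unknown topology preset {name!r}")
    ref = resources.files("mapkflow.data").joinpath(f"{name}.json")
    return NetworkTopology.from_dict(json.loads(ref.read_text()))
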