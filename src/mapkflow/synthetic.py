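"""Synthetic inputs: random conserved topologies, noisy readouts, flow oracle.

Everything the package consumes can be generated here, seeded and
reproducible: random driver-network topologies (parallel kinase chains
with Dirichlet-sampled split fractions and optional crosstalk), noisy
replicate BACH1 readouts over a dose grid (multiplicative lognormal noise,
emulating relative qPCR expression against an induced untreated control),
and an independent brute-force flow solver used as the test oracle for the
propagation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import ReadoutTable
from .topology import (
    EdgeSpec,
    FlowState,
    FractionTable,
    NetworkTopology,
    NodeSpec,
    TopologyError,
)
from .treatment import Scenario, bach1_output

__all__ = [
    "SynthConfig",
    "random_topology",
    "random_splits",
    "brute_force_flow_oracle",
    "simulate_readouts",
]

# sub-stream keys so topology sampling and readout noise are independent
_STREAM_TOPOLOGY = 1
_STREAM_NOISE = 2
_STREAM_SPLITS = 3


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generators; ``seed`` is mandatory.

    Readout defaults mirror the measurement structure of the dose-response
    experiments the model was compared against: an 11-point dose grid,
    three independent replicates, multiplicative noise of a few percent.
    """

    seed: int
    n_pathways: int = 3
    depth: int = 2
    crosstalk_density: float = 0.0
    dirichlet_concentration: float = 1.0
    noise_sd: float = 0.05
    n_replicates: int = 3
    dose_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def random_splits(
    config: SynthConfig, alpha1: float | None = None
) -> "SplitParams":
    """Sample canonical N1 split parameters from the simplex.

    (alpha1, alpha2, A12) are jointly Dirichlet; alpha3..alpha6 are uniform
    on [0, 1].  With ``alpha1`` given, only the remaining mass is split.
    """
    from .topology import SplitParams

    rng = config.rng(_STREAM_SPLITS)
    conc = config.dirichlet_concentration
    if alpha1 is None:
        a1, a2, _ = rng.dirichlet([conc] * 3)
    else:
        a1 = alpha1
        a2 = (1.0 - alpha1) * rng.dirichlet([conc] * 2)[0]
    a3, a4, a5, a6 = rng.uniform(0.0, 1.0, size=4)
    return SplitParams(a1, a2, a3, a4, a5, a6)


def random_topology(config: SynthConfig) -> NetworkTopology:
    """Sample a random conserved driver-network topology.

    ``n_pathways`` parallel kinase chains of length ``depth`` run from one
    source to one output.  Crosstalk edges are added between chains from
    shallower to strictly deeper kinases with probability
    ``crosstalk_density`` (keeping the graph acyclic), and every branching
    node's outgoing fractions are Dirichlet-sampled so they sum to one —
    the sampled network is conservation-valid by construction.
    """
    rng = config.rng(_STREAM_TOPOLOGY)
    P, D = config.n_pathways, config.depth
    source_id = 1
    output_id = 2 + P * D

    def kid(p: int, d: int) -> int:
        return 2 + p * D + d

    nodes = [NodeSpec(source_id, "signal", "source")]
    nodes += [
        NodeSpec(kid(p, d), f"kinase_{p}_{d}") for p in range(P) for d in range(D)
    ]
    nodes.append(NodeSpec(output_id, "output", "output"))

    edges: list[tuple[int, int, str]] = []
    for p in range(P):
        edges.append((source_id, kid(p, 0), "pathway"))
        for d in range(D - 1):
            edges.append((kid(p, d), kid(p, d + 1), "pathway"))
        edges.append((kid(p, D - 1), output_id, "pathway"))
    for p in range(P):
        for d in range(D):
            for q in range(P):
                if q == p:
                    continue
                for d2 in range(d + 1, D):
                    if rng.uniform() < config.crosstalk_density:
                        edges.append((kid(p, d), kid(q, d2), "crosstalk"))

    # Dirichlet split at every node over its outgoing edges
    by_src: dict[int, list[int]] = {}
    for i, (src, _, _) in enumerate(edges):
        by_src.setdefault(src, []).append(i)
    fractions: dict[str, float] = {}
    specs: list[EdgeSpec] = []
    conc = config.dirichlet_concentration
    for src, idxs in by_src.items():
        fr = (
            rng.dirichlet([conc] * len(idxs))
            if len(idxs) > 1
            else np.array([1.0])
        )
        for i, f in zip(idxs, fr):
            s, dst, kind = edges[i]
            name = f"w{s}_{dst}"
            fractions[name] = float(f)
            specs.append(EdgeSpec(s, dst, name, kind))

    return NetworkTopology(
        nodes=tuple(nodes),
        edges=tuple(specs),
        splits=FractionTable(fractions),
        name=f"random_{config.seed}",
    )


def brute_force_flow_oracle(
    topology: NetworkTopology,
    activity: Mapping[int, float] | None = None,
) -> FlowState:
    """Solve the node-balance equations as one dense linear system.

    Independent of the topological-order propagation engine: builds
    Y_j = sum_e fraction(e) * a_src * Y_src for every non-source node with
    Y_source = 1, and solves with a direct linear solver.  Intended as the
    test oracle.
    """
    activity = dict(activity or {})
    ids = [n.id for n in topology.nodes]
    pos = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    A = np.eye(n)
    b = np.zeros(n)
    b[pos[topology.source.id]] = 1.0
    clamp = lambda a: min(max(a, 0.0), 1.0)
    for e in topology.mass_edges:
        a_src = clamp(activity.get(e.src, 1.0))
        A[pos[e.dst], pos[e.src]] -= topology.fraction(e) * a_src
    try:
        y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise TopologyError("singular balance system") from exc
    inflow = {nid: float(y[pos[nid]]) for nid in ids}
    outflow = {nid: clamp(activity.get(nid, 1.0)) * inflow[nid] for nid in ids}
    loss = {nid: inflow[nid] - outflow[nid] for nid in ids}
    return FlowState(topology=topology, inflow=inflow, outflow=outflow, loss=loss)


def simulate_readouts(
    topology: NetworkTopology,
    scenario: Scenario,
    config: SynthConfig,
) -> ReadoutTable:
    """Noisy replicate BACH1 readouts of a scenario over the dose grid.

    Each readout is the model output phi(x) times a lognormal factor with
    median 1 and log-sd ``noise_sd`` (relative expression is ratio-scale),
    independently per replicate; ``noise_model='gaussian'`` switches to
    additive noise with the same sd.
    """
    import pandas as pd

    rng = config.rng(_STREAM_NOISE)
    rows = []
    for x in config.dose_grid:
        phi = bach1_output(topology, scenario, float(x))
        for rep in range(config.n_replicates):
            if config.noise_model == "lognormal":
                value = phi * np.exp(config.noise_sd * rng.standard_normal())
            else:
                value = phi + config.noise_sd * rng.standard_normal()
            # detection floor: relative expression is reported strictly positive
            value = max(float(value), 1e-9)
            rows.append(
                {"dose": float(x), "replicate": rep, "expression": value}
            )
    return ReadoutTable(
        pd.DataFrame(rows), scenario=scenario.name, cell_line="synthetic"
    )
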