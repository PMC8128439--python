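"""Dose-response models of BACH1 transcriptional output under kinase inhibition.

A drug at dose fraction ``x`` (of its maximal dose) reduces the activity of
its target node by :math:`\\xi_i(x) = \\Delta_i x / (1 + K_i x)` with
:math:`\\Delta_i = K_i / \\Upsilon_i`, so the absolute signal it removes is
:math:`\\xi_i \\Upsilon_i = K_i x / (1 + K_i x)` regardless of the node's
untreated inflow.  For p38i, MEKi and MLKi the relative output is the
hyperbolic :math:`\\phi = 1/(1 + K_i x)`.  JNK inhibition instead
redirects flow: as JNK activity falls, the crosstalk capacities toward p38
open along Hill functions of the JNK inflow, p38 absorbs two thirds of the
redistributed signal, and only the remaining third is lost to the output.
Multi-drug combinations are additive in the removed signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .topology import NetworkTopology, propagate

__all__ = [
    "DrugSpec",
    "Scenario",
    "DoseResponseCurve",
    "DRUG_PRESETS",
    "SCENARIO_PRESETS",
    "get_scenario",
    "node_inhibition",
    "bach1_hyperbolic",
    "jnk_inflow",
    "hill_redirection",
    "bach1_jnki",
    "bach1_combo",
    "bach1_output",
    "dose_response",
    "max_dose_for_cap",
]

_MODELS = ("hyperbolic", "jnk_redirection")


@dataclass(frozen=True)
class DrugSpec:
    """A kinase inhibitor: its target node and dose-response constant."""

    name: str
    target_node: int
    K: float
    model: str = "hyperbolic"

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be nonnegative, got {self.K}")
        if self.model not in _MODELS:
            raise ValueError(f"unknown dose-response model {self.model!r}")


@dataclass(frozen=True)
class Scenario:
    """A set of drugs applied jointly at a common dose fraction.

    ``inhibition_cap`` records a per-kinase inhibition ceiling (0.3 for the
    low-dose 4D-MAPKi regimen); it annotates the scenario and drives
    :func:`max_dose_for_cap`, it does not truncate dose grids.
    """

    name: str
    drugs: tuple[DrugSpec, ...]
    inhibition_cap: float | None = None

    def __post_init__(self) -> None:
        targets = [d.target_node for d in self.drugs]
        if len(set(targets)) != len(targets):
            raise ValueError("scenario drugs must target distinct nodes")

    def drug(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Predicted relative BACH1 output over a dose grid."""

    doses: np.ndarray
    phi: np.ndarray
    scenario: str
    topology: str
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.doses,
                "phi_bach1": self.phi,
                "suppression_pct": 100.0 * (1.0 - self.phi),
                "scenario": self.scenario,
                "topology": self.topology,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


P38I = DrugSpec("p38i", target_node=8, K=C.K_P38)
MEKI = DrugSpec("meki", target_node=3, K=C.K_MEK)
JNKI = DrugSpec("jnki", target_node=6, K=C.K_JNK, model="jnk_redirection")
MLKI = DrugSpec("mlki", target_node=5, K=C.K_MLK)

DRUG_PRESETS: dict[str, DrugSpec] = {d.name: d for d in (P38I, MEKI, JNKI, MLKI)}

SCENARIO_PRESETS: dict[str, Scenario] = {
    "p38i": Scenario("p38i", (P38I,)),
    "meki": Scenario("meki", (MEKI,)),
    "jnki": Scenario("jnki", (JNKI,)),
    "mlki": Scenario("mlki", (MLKI,)),
    "4d_mapki": Scenario(
        "4d_mapki", (P38I, MEKI, JNKI, MLKI), inhibition_cap=C.FOUR_D_DOSE_CAP
    ),
}


def get_scenario(name: str) -> Scenario:
    """Look up a preset scenario (p38i, meki, jnki, mlki, 4d_mapki)."""
    try:
        return SCENARIO_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; presets: {sorted(SCENARIO_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# elementary dose-response pieces


def node_inhibition(drug: DrugSpec, x: float, untreated_inflow: float) -> float:
    """Fractional activity reduction xi at the drug's target node.

    xi(x) = (K/Y) x / (1 + K x); the removed signal xi * Y equals
    K x / (1 + K x) exactly.  Values above 1 are returned raw with a
    coherence warning (the closed forms are phenomenological).
    """
    if untreated_inflow <= 0:
        raise ValueError("untreated inflow must be positive (Delta undefined)")
    delta = drug.K / untreated_inflow
    xi = delta * x / (1.0 + drug.K * x)
    if xi > 1.0:
        warnings.warn(
            f"{drug.name}: xi={xi:.4g} exceeds 1 at x={x:.4g} "
            f"(inflow {untreated_inflow:.4g})",
            stacklevel=2,
        )
    return xi


def bach1_hyperbolic(K: float, x) :
    """phi = 1 / (1 + K x), the single-drug hyperbolic output model."""
    return 1.0 / (1.0 + K * np.asarray(x, dtype=float))


def jnk_inflow(
    topology: NetworkTopology,
    x: float,
    mlki_active: bool = False,
    k3: float = C.K_JNK,
    k_mlk: float = C.K_MLK,
) -> float:
    """JNK (node 6) inflow under JNKi at dose x, via flow propagation.

    The untreated inflow is rebalanced first when MLKi is co-applied
    (node-5 activity scaled by 1/(1 + K4 x)), then attenuated by the JNK
    inactivation factor 1/(1 + K3 x).
    """
    jnk = topology.node_by_label("JNK").id
    activity = {}
    if mlki_active:
        activity[topology.node_by_label("MLK").id] = 1.0 / (1.0 + k_mlk * x)
    rebalanced = propagate(topology, activity).inflow[jnk]
    return rebalanced / (1.0 + k3 * x)


def hill_redirection(gamma: float, y6: float) -> float:
    """Crosstalk capacity toward p38, Gamma = 1 / (1 + (gamma * Y6)^4).

    A steep Hill switch: as JNK inflow Y6 falls under treatment the
    MLK->p38 and TAOK->p38 capacities open toward 1.
    """
    if y6 < 0:
        raise ValueError("Y6 must be nonnegative")
    return 1.0 / (1.0 + (gamma * y6) ** 4)


def _eps6(
    topology: NetworkTopology, x: float, mlki_active: bool = False
) -> float:
    """Exported fraction of the JNKi-redistributed signal (see surplus)."""
    y0 = jnk_inflow(topology, 0.0, mlki_active=mlki_active)
    yx = jnk_inflow(topology, x, mlki_active=mlki_active)
    gain = sum(
        hill_redirection(g, yx) - hill_redirection(g, y0)
        for g in (C.GAMMA3, C.GAMMA4)
    )
    return C.JNK_EXPORT_FRACTION * gain


def bach1_jnki(topology: NetworkTopology, x: float) -> float:
    """Relative BACH1 output under single-agent JNKi.

    On a crosstalk topology, phi = 1 - eps6(x): p38 absorbs two thirds of
    the flow redirected away from JNK, so only the exported third reduces
    the output.  Without crosstalk there is no redirection route and the
    whole removed signal K3 x/(1 + K3 x) is lost, which collapses to the
    hyperbolic form 1/(1 + K3 x).
    """
    if not topology.has_crosstalk:
        return float(bach1_hyperbolic(C.K_JNK, x))
    phi = 1.0 - _eps6(topology, x)
    return float(min(max(phi, 0.0), 1.0))


def bach1_combo(topology: NetworkTopology, scenario: Scenario, x: float) -> float:
    """Additive multi-drug output: phi = max(0, 1 - sum_i K_i x/(1+K_i x)).

    Each drug removes xi_i * Y_i = K_i x / (1 + K_i x) of signal; effects
    add as a first approximation.  The JNKi term enters in the same
    hyperbolic form (its constant K3); the redirection machinery is the
    single-agent JNKi model only.
    """
    if len({d.target_node for d in scenario.drugs}) != len(scenario.drugs):
        raise ValueError("scenario drugs must target distinct nodes")
    removed = sum(d.K * x / (1.0 + d.K * x) for d in scenario.drugs)
    return float(max(0.0, 1.0 - removed))


def bach1_output(topology: NetworkTopology, scenario: Scenario, x: float) -> float:
    """Relative BACH1 output under a scenario at dose fraction x.

    Dispatches to the single-drug hyperbolic model, the JNKi redirection
    model, or the additive combination model.
    """
    if not scenario.drugs or x == 0:
        # untreated: conservation fixes the output at 1
        return float(propagate(topology).output_flow)
    if len(scenario.drugs) == 1:
        drug = scenario.drugs[0]
        if drug.model == "jnk_redirection":
            return bach1_jnki(topology, x)
        return float(bach1_hyperbolic(drug.K, x))
    return bach1_combo(topology, scenario, x)


def dose_response(
    topology: NetworkTopology,
    scenario: Scenario,
    grid,
) -> DoseResponseCurve:
    """Evaluate the scenario's output model across a sorted dose grid."""
    doses = np.asarray(grid, dtype=float)
    if doses.ndim != 1 or np.any(doses < 0) or np.any(doses > 1):
        raise ValueError("dose grid must be one-dimensional within [0, 1]")
    if np.any(np.diff(doses) < 0):
        raise ValueError("dose grid must be sorted ascending")
    phi = np.array([bach1_output(topology, scenario, float(x)) for x in doses])
    meta = {}
    if (
        any(d.model == "jnk_redirection" for d in scenario.drugs)
        and len(scenario.drugs) == 1
        and not topology.has_crosstalk
    ):
        meta["variant"] = "no-crosstalk: full JNK surplus exported"
    return DoseResponseCurve(
        doses=doses, phi=phi, scenario=scenario.name,
        topology=topology.name, metadata=meta,
    )


def max_dose_for_cap(
    drug: DrugSpec, untreated_inflow: float, cap: float
) -> float:
    """Largest dose fraction keeping target inhibition xi at or below cap.

    Solves xi(x*) = cap analytically: x* = cap / (Delta - K cap) with
    Delta = K / Y.  Raises if the cap is unreachable (Delta <= K cap).
    """
    if not 0.0 <= cap < 1.0:
        raise ValueError("cap must lie in [0, 1)")
    if untreated_inflow <= 0:
        raise ValueError("untreated inflow must be positive")
    if cap == 0.0:
        return 0.0
    delta = drug.K / untreated_inflow
    denom = delta - drug.K * cap
    if denom <= 0:
        raise ValueError(
            f"inhibition cap {cap} unreachable for {drug.name}: "
            f"Delta={delta:.4g} <= K*cap={drug.K * cap:.4g}"
        )
    return cap / denom
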