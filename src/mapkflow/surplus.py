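"""Surplus accounting and compensatory-network activation.

Inhibiting a kinase leaves part of the stress signal unabsorbed at its
upstream node.  That surplus — a fraction of the total input Sigma — can
spill into a compensatory kinase network (CKN, e.g. PI3K/AKT) once it
exceeds the CKN's activation threshold.  The per-drug surpluses are:

* MEKi  -> RAF surplus      eps_RAF(x) = K2 x / (1 + K2 x)
* MLKi  -> raw-signal surplus eps_SIG(x) = K4 x / (1 + K4 x)
* p38i  -> node-8 surplus   eps_8(x)   = K1 x / (1 + K1 x)
* JNKi  -> node-6 surplus   eps_6(x), the exported third of the flow
  redirected away from JNK (Hill-gated crosstalk toward p38)

The node-6 and node-8 surpluses are exported through the upstream MLK and
TAOK kinases in proportion to the crosstalk capacities, giving the
per-kinase view used to judge CKN activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .topology import NetworkTopology
from .treatment import Scenario, _eps6, hill_redirection, jnk_inflow

__all__ = [
    "SurplusReport",
    "ThresholdPolicy",
    "surplus_raf",
    "surplus_signal",
    "surplus_node8",
    "surplus_node6",
    "allocate_upstream_surplus",
    "total_surplus",
    "compensatory_activation",
]

#: surplus component names, in the reporting order of the 4D regimen
COMPONENTS = ("eps_raf", "eps_sig", "eps_mlk", "eps_taok")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Activation threshold of a compensatory network, as a fraction of Sigma.

    The default 0.3 reflects the observed AKT-activation threshold (minimal
    response until ERK inhibition reaches roughly 30%); it is a policy
    parameter, not a fitted constant.
    """

    theta: float = C.DEFAULT_THETA

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")


@dataclass(frozen=True)
class SurplusReport:
    """Per-kinase surplus fractions at one dose, plus activation flags."""

    x: float
    eps_raf: float = 0.0
    eps_sig: float = 0.0
    eps_mlk: float = 0.0
    eps_taok: float = 0.0
    eps_node6: float = 0.0
    eps_node8: float = 0.0
    activation: dict | None = None

    @property
    def total(self) -> float:
        return self.eps_raf + self.eps_sig + self.eps_mlk + self.eps_taok

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPONENTS}


def surplus_raf(x, k2: float = C.K_MEK):
    """RAF surplus under MEKi (identical under 4D-MAPKi): K2 x/(1 + K2 x)."""
    x = np.asarray(x, dtype=float)
    return k2 * x / (1.0 + k2 * x)


def surplus_signal(x, k4: float = C.K_MLK):
    """Unabsorbed stress signal upstream of MLK under MLKi: K4 x/(1 + K4 x)."""
    x = np.asarray(x, dtype=float)
    return k4 * x / (1.0 + k4 * x)


def surplus_node8(x, k1: float = C.K_P38):
    """Surplus at node 8 under p38i: K1 x/(1 + K1 x).

    Combines the surplus generated at p38 itself with the redirected flow
    it can no longer absorb; equals 1 - phi of the p38i hyperbolic model.
    """
    x = np.asarray(x, dtype=float)
    return k1 * x / (1.0 + k1 * x)


def surplus_node6(
    topology: NetworkTopology, x: float, mlki_active: bool = False
) -> float:
    """Exported JNKi surplus eps_6(x).

    One third of the flow redirected away from JNK — the part p38 cannot
    absorb: eps_6 = (1/3)[Gamma3(x) + Gamma4(x) - Gamma3(0) - Gamma4(0)],
    with Gamma_k evaluated at the treated JNK inflow Y6(x).
    """
    return _eps6(topology, x, mlki_active=mlki_active)


def allocate_upstream_surplus(
    topology: NetworkTopology,
    x: float,
    mlki_active: bool = False,
    include_jnki: bool = True,
    include_p38i: bool = True,
) -> tuple[float, float]:
    """Split the node-6 and node-8 surpluses onto MLK and TAOK.

    eps_MLK  = eps6 * Gamma3(x) + alpha4 * eps8
    eps_TAOK = eps6 * (1 - Gamma3(x)) + A4 * eps8

    Gamma3 is the (treated) MLK->p38 crosstalk capacity, so the allocation
    follows each pathway's share of the redirected flow; the sum is exactly
    eps6 + eps8.
    """
    eps6 = (
        surplus_node6(topology, x, mlki_active=mlki_active)
        if include_jnki
        else 0.0
    )
    eps8 = float(surplus_node8(x)) if include_p38i else 0.0
    y6 = jnk_inflow(topology, x, mlki_active=mlki_active)
    gamma3 = hill_redirection(C.GAMMA3, y6)
    alpha4 = topology.splits.resolve("alpha4")
    a4 = topology.splits.resolve("A4")
    eps_mlk = eps6 * gamma3 + alpha4 * eps8
    eps_taok = eps6 * (1.0 - gamma3) + a4 * eps8
    return eps_mlk, eps_taok


def _report_at(
    topology: NetworkTopology, scenario: Scenario, x: float
) -> SurplusReport:
    names = {d.name for d in scenario.drugs}
    mlki = "mlki" in names
    jnki = "jnki" in names
    p38i = "p38i" in names
    eps6 = surplus_node6(topology, x, mlki_active=mlki) if jnki else 0.0
    eps8 = float(surplus_node8(x)) if p38i else 0.0
    if jnki or p38i:
        eps_mlk, eps_taok = allocate_upstream_surplus(
            topology, x, mlki_active=mlki, include_jnki=jnki, include_p38i=p38i
        )
    else:
        eps_mlk = eps_taok = 0.0
    return SurplusReport(
        x=x,
        eps_raf=float(surplus_raf(x)) if "meki" in names else 0.0,
        eps_sig=float(surplus_signal(x)) if mlki else 0.0,
        eps_mlk=eps_mlk,
        eps_taok=eps_taok,
        eps_node6=eps6,
        eps_node8=eps8,
    )


def total_surplus(
    topology: NetworkTopology,
    scenario: Scenario,
    grid,
    policy: ThresholdPolicy | None = None,
) -> pd.DataFrame:
    """Per-dose surplus components, total, and activation flags over a grid.

    Components corresponding to drugs absent from the scenario are zero.
    The total is the sum of the four exported components (RAF, Signal,
    MLK, TAOK); the node-6/node-8 intermediates are reported alongside.
    """
    policy = policy or ThresholdPolicy()
    rows = []
    for x in np.asarray(grid, dtype=float):
        rep = _report_at(topology, scenario, float(x))
        rep = compensatory_activation(rep, policy)
        row = {
            "dose": rep.x,
            **rep.components(),
            "eps_node6": rep.eps_node6,
            "eps_node8": rep.eps_node8,
            "total": rep.total,
        }
        row.update(
            {f"activated_{k.removeprefix('eps_')}": v
             for k, v in rep.activation.items() if k != "any"}
        )
        row["any_activated"] = rep.activation["any"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["scenario"] = scenario.name
    df.attrs["topology"] = topology.name
    df.attrs["theta"] = policy.theta
    return df


def compensatory_activation(
    report: SurplusReport, policy: ThresholdPolicy | None = None
) -> SurplusReport:
    """Flag each compensatory network whose surplus reaches the threshold."""
    policy = policy or ThresholdPolicy()
    flags = {
        name: bool(value >= policy.theta)
        for name, value in report.components().items()
    }
    flags["any"] = any(flags.values())
    return SurplusReport(
        x=report.x,
        eps_raf=report.eps_raf,
        eps_sig=report.eps_sig,
        eps_mlk=report.eps_mlk,
        eps_taok=report.eps_taok,
        eps_node6=report.eps_node6,
        eps_node8=report.eps_node8,
        activation=flags,
    )
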