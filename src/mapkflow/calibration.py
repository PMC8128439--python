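"""Estimation of dose-response constants K from BACH1 readout tables.

The readouts emulate qPCR-style relative-expression measurements: BACH1
expression in drug-treated cells relative to the stress-induced untreated
control, a few replicates per dose.  The single-drug model
phi(x) = 1/(1 + K x) (and the additive combination model for multi-drug
tables) is fitted by bounded nonlinear least squares to the per-dose mean
expression, with multiple starting points so the estimator is
deterministic given the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .treatment import Scenario

__all__ = ["ReadoutTable", "FitResult", "fit_hyperbolic_K", "fit_scenario"]

_MULTISTART = (0.1, 1.0, 10.0)
_XTOL = 1e-10


class CalibrationError(ValueError):
    """Raised for invalid readout tables or unidentifiable fits."""


@dataclass(frozen=True)
class ReadoutTable:
    """Replicate BACH1-expression readouts across a dose grid.

    ``data`` holds columns ``dose`` (fraction of maximal dose in [0, 1]),
    ``replicate`` (integer index) and ``expression`` (relative to the
    induced untreated control, positive).
    """

    data: pd.DataFrame
    scenario: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        required = {"dose", "replicate", "expression"}
        missing = required - set(self.data.columns)
        if missing:
            raise CalibrationError(f"readout table missing columns {missing}")
        d = self.data
        bad_dose = d.index[(d["dose"] < 0) | (d["dose"] > 1)]
        if len(bad_dose):
            raise CalibrationError(
                f"row {bad_dose[0]}: dose {d.loc[bad_dose[0], 'dose']} outside [0, 1]"
            )
        bad_expr = d.index[~(d["expression"] > 0)]
        if len(bad_expr):
            raise CalibrationError(
                f"row {bad_expr[0]}: expression "
                f"{d.loc[bad_expr[0], 'expression']} must be positive"
            )

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose"].unique())

    def dose_means(self) -> pd.Series:
        """Mean expression per dose, the fitting target."""
        return self.data.groupby("dose")["expression"].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scenario: str = "", cell_line: str = "") -> "ReadoutTable":
        return cls(pd.read_csv(path), scenario=scenario, cell_line=cell_line)


@dataclass(frozen=True)
class FitResult:
    """Estimated dose-response constants with uncertainty and diagnostics."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    rmse: float
    converged: bool
    n_obs: int
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def K(self) -> float:
        """The estimate, for single-constant fits."""
        if len(self.estimates) != 1:
            raise AttributeError("multiple constants fitted; use .estimates")
        return next(iter(self.estimates.values()))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "estimates": self.estimates,
                "stderr": self.stderr,
                "rmse": self.rmse,
                "converged": self.converged,
                "n_obs": self.n_obs,
                "fixed": self.fixed,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _nls(residual_fn, k0: np.ndarray, n_params: int):
    """Bounded least squares with multi-start over a log-spaced grid."""
    best = None
    # the boundary K=0 (no effect) is included so flat data fits exactly
    starts = [k0] + [np.full(n_params, s) for s in (0.0, *_MULTISTART)]
    for start in starts:
        sol = least_squares(
            residual_fn, start, bounds=(0.0, np.inf), xtol=_XTOL, ftol=_XTOL,
            gtol=_XTOL,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    return best


def _stderr(sol, n_obs: int, n_params: int) -> np.ndarray:
    dof = n_obs - n_params
    if dof <= 0:
        return np.full(n_params, np.nan)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def fit_hyperbolic_K(
    table: ReadoutTable, log_scale: bool = False
) -> FitResult:
    """Fit phi(x) = 1/(1 + K x) to the per-dose mean expression.

    K is box-constrained to [0, inf).  With ``log_scale`` the residuals are
    taken on log expression (ratio-scale loss); the default matches the
    reporting scale of relative-expression figures.
    """
    means = table.dose_means()
    if len(means) < 3:
        raise CalibrationError(
            f"need >= 3 distinct doses to fit K, got {len(means)}"
        )
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)

    def residual(k):
        model = 1.0 / (1.0 + k[0] * x)
        if log_scale:
            return np.log(np.clip(model, 1e-12, None)) - np.log(y)
        return model - y

    sol = _nls(residual, np.array([1.0]), 1)
    rmse = math.sqrt(np.mean(sol.fun**2))
    return FitResult(
        estimates={"K": float(sol.x[0])},
        stderr={"K": float(_stderr(sol, len(x), 1)[0])},
        rmse=rmse,
        converged=bool(sol.success),
        n_obs=len(x),
    )


def fit_scenario(
    table: ReadoutTable,
    scenario: Scenario,
    free: tuple[str, ...] | None = None,
    log_scale: bool = False,
) -> FitResult:
    """Joint fit of the additive combination model against a readout table.

    ``free`` names the drugs whose constants are estimated; the others are
    held at the scenario's values.  Free constants are initialized at the
    scenario values (the additive objective is symmetric under permuting
    the K's, so the start anchors each estimate to its drug).
    """
    names = [d.name for d in scenario.drugs]
    free = tuple(free) if free is not None else tuple(names)
    unknown = set(free) - set(names)
    if unknown:
        raise CalibrationError(f"free drugs {unknown} not in scenario")
    means = table.dose_means()
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    informative = int(np.sum(x > 0))
    if informative < len(free):
        raise CalibrationError(
            f"unidentifiable: {len(free)} free constants but only "
            f"{informative} nonzero doses"
        )
    fixed = {d.name: d.K for d in scenario.drugs if d.name not in free}
    k0 = np.array([scenario.drug(name).K for name in free])

    def residual(k):
        ks = dict(zip(free, k)) | fixed
        removed = sum(ks[n] * x / (1.0 + ks[n] * x) for n in names)
        model = np.clip(1.0 - removed, 0.0, None)
        if log_scale:
            return np.log(np.clip(model, 1e-12, None)) - np.log(y)
        return model - y

    sol = least_squares(
        residual, k0, bounds=(0.0, np.inf), xtol=_XTOL, ftol=_XTOL, gtol=_XTOL
    )
    rmse = math.sqrt(np.mean(sol.fun**2))
    se = _stderr(sol, len(x), len(free))
    return FitResult(
        estimates={n: float(v) for n, v in zip(free, sol.x)},
        stderr={n: float(s) for n, s in zip(free, se)},
        rmse=rmse,
        converged=bool(sol.success),
        n_obs=len(x),
        fixed=fixed,
    )
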