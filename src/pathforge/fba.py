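"""Linear-programming flux analysis.

Implements both formulations of the flux balance problem: maximize an
objective flux under an uptake cap (primal) and minimize the uptake flux
under an objective floor (swapped), plus the trade-off curve tying the
two together and yield normalization.  The two formulations trace the
same curve: the optimum of the primal lies inside the feasible region of
the swapped problem, and its minimal uptake reproduces the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .netcore import MetabolicNetwork, stoichiometric_matrix

__all__ = ["FluxState", "maximize_flux", "minimize_uptake", "tradeoff_curve", "yields"]

#: Default solver feasibility tolerance, surfaced for reproducibility.
FEASIBILITY_TOL = 1e-9


@dataclass
class FluxState:
    """Result of one flux optimization."""

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: str = "infeasible"  # optimal | infeasible | unbounded
    formulation: str = "max_objective"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _bounds(network: MetabolicNetwork, extra: Mapping[str, tuple] | None):
    extra = extra or {}
    out = []
    for r in network.reactions:
        lb, ub = r.flux_lb, r.flux_ub
        if r.id in extra:
            lb, ub = extra[r.id]
        out.append((None if lb == -np.inf else lb, None if ub == np.inf else ub))
    return out


def _solve(network, c, bounds, formulation, objective_index, l1_tiebreak=False):
    S = stoichiometric_matrix(network, rows="dependent")
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 3:
        return FluxState(status="unbounded", formulation=formulation)
    if res.status != 0:
        return FluxState(status="infeasible", formulation=formulation)
    v = res.x
    if l1_tiebreak:
        v = _l1_tiebreak(S, c, bounds, res.x)
    state = FluxState(
        fluxes={r.id: float(v[j]) for j, r in enumerate(network.reactions)},
        objective_value=float(v[objective_index]),
        status="optimal",
        formulation=formulation,
    )
    resid = np.abs(S @ v)
    if resid.size and resid.max() > 1e-6:  # guard: solver returned junk
        state.status = "infeasible"
    return state


def _l1_tiebreak(S, c, bounds, v_opt):
    """Among optima of the primary LP, pick the minimum-||v||_1 vertex.

    Splits v = p - q with p, q >= 0 and pins the primary objective to its
    optimum.  Off by default; selects a deterministic representative when
    alternate optima exist.
    """
    n = S.shape[1]
    obj_val = float(c @ v_opt)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    A_pin = np.hstack([c, -np.asarray(c)]).reshape(1, -1)
    A_eq = np.vstack([A_eq, A_pin])
    b_eq = np.append(b_eq, obj_val)
    split_bounds = []
    for lb, ub in bounds:
        split_bounds.append((0, None if ub is None else max(ub, 0)))
    for lb, ub in bounds:
        split_bounds.append((0, None if lb is None else max(-lb, 0)))
    res = linprog(np.ones(2 * n), A_eq=A_eq, b_eq=b_eq, bounds=split_bounds, method="highs")
    if res.status != 0:
        return v_opt
    return res.x[:n] - res.x[n:]


def maximize_flux(
    network: MetabolicNetwork,
    objective_id: str | None = None,
    extra_bounds: Mapping[str, tuple] | None = None,
    l1_tiebreak: bool = False,
) -> FluxState:
    """Maximize a reaction flux subject to steady state and bounds.

    An unbounded problem is reported as such (``status="unbounded"``),
    never silently truncated.
    """
    objective_id = objective_id or network.objective_id
    if objective_id not in network.reaction_ids:
        raise KeyError(f"unknown objective reaction {objective_id!r}")
    j = network.reaction_ids.index(objective_id)
    c = np.zeros(len(network.reactions))
    c[j] = -1.0
    return _solve(network, c, _bounds(network, extra_bounds), "max_objective", j,
                  l1_tiebreak=l1_tiebreak)


def minimize_uptake(
    network: MetabolicNetwork,
    uptake_id: str | None = None,
    objective_floor: float = 0.0,
    objective_id: str | None = None,
    extra_bounds: Mapping[str, tuple] | None = None,
    l1_tiebreak: bool = False,
) -> FluxState:
    """Minimize the uptake flux while holding the objective above a floor.

    The swapped formulation: the former objective becomes the constraint
    ``v_objective >= objective_floor`` and the former capped uptake
    becomes the minimization target.
    """
    uptake_id = uptake_id or network.uptake_id
    objective_id = objective_id or network.objective_id
    for rid, what in ((uptake_id, "uptake"), (objective_id, "objective")):
        if rid not in network.reaction_ids:
            raise KeyError(f"unknown {what} reaction {rid!r}")
    if not np.isfinite(objective_floor):
        raise ValueError(f"objective_floor must be finite, got {objective_floor}")
    j_up = network.reaction_ids.index(uptake_id)
    j_obj = network.reaction_ids.index(objective_id)
    bounds = _bounds(network, extra_bounds)
    lb, ub = bounds[j_obj]
    if ub is not None and objective_floor > ub:
        return FluxState(status="infeasible", formulation="min_uptake")
    bounds[j_obj] = (max(objective_floor, lb if lb is not None else -np.inf), ub)
    c = np.zeros(len(network.reactions))
    c[j_up] = 1.0
    state = _solve(network, c, bounds, "min_uptake", j_obj, l1_tiebreak=l1_tiebreak)
    return state


def tradeoff_curve(
    network: MetabolicNetwork,
    uptake_id: str | None = None,
    objective_id: str | None = None,
    grid: Sequence[float] = (),
) -> pd.DataFrame:
    """Trace the uptake/objective trade-off over a grid of uptake caps.

    For every cap the objective is maximized; a second pass then
    minimizes the uptake at the achieved objective.  Columns: ``cap``,
    ``uptake``, ``objective``, ``uptake_swapped``, ``objective_swapped``.
    """
    uptake_id = uptake_id or network.uptake_id
    objective_id = objective_id or network.objective_id
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("cap grid must be sorted ascending")
    rows = []
    for cap in grid:
        up_rxn = network.reaction(uptake_id)
        st = maximize_flux(network, objective_id,
                           extra_bounds={uptake_id: (up_rxn.flux_lb, cap)})
        if not st.optimal:
            raise RuntimeError(f"primal formulation failed at cap {cap}: {st.status}")
        st2 = minimize_uptake(network, uptake_id, objective_floor=st.objective_value,
                              objective_id=objective_id)
        if not st2.optimal:
            raise RuntimeError(f"swapped formulation failed at cap {cap}: {st2.status}")
        rows.append(
            {
                "cap": cap,
                "uptake": st.fluxes[uptake_id],
                "objective": st.objective_value,
                "uptake_swapped": st2.fluxes[uptake_id],
                "objective_swapped": st2.fluxes[objective_id],
            }
        )
    return pd.DataFrame(rows)


def yields(flux_state: FluxState, uptake_id: str) -> dict[str, float]:
    """Per-reaction yields ``v_k / v_uptake``; errors on zero uptake flux."""
    v_in = flux_state.fluxes.get(uptake_id)
    if v_in is None:
        raise KeyError(f"uptake reaction {uptake_id!r} not in flux state")
    if v_in == 0:
        raise ZeroDivisionError("uptake flux is zero; yields undefined")
    return {rid: v / v_in for rid, v in flux_state.fluxes.items()}
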