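"""Thermodynamic feasibility analysis.

Feasible states are concentration assignments ``y = ln x`` satisfying the
linear inequalities ``g = g0 + RT * S^T y <= 0`` for every
forward-directed reaction (``>= 0`` for reverse).  On top of that
polytope this module computes per-variable admissible ranges, the
Max-min Driving Force state (the assignment that pushes the least
negative ΔG as far from zero as possible) and ΔG sweeps over a single
metabolite.

Sign convention: forward-feasible means ``ΔG <= 0``; ``B`` is the
maximum (least negative) ΔG over the directed reactions, and the MDF
problem minimizes ``B``.  Water/proton activities are assumed to be
absorbed into ``g0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .netcore import MetabolicNetwork
from .thermokin import GAS_CONSTANT

__all__ = [
    "ThermoData",
    "ThermoState",
    "reaction_gibbs",
    "variable_ranges",
    "max_min_driving_force",
    "dg_sweep",
    "directions_from_fluxes",
]


@dataclass
class ThermoData:
    """Standard free energies, temperature and log-concentration bounds.

    ``fixed_y`` clamps metabolites to exact log-concentrations (clamped
    metabolites override their box bounds).  ``rt`` is derived as
    ``R * temperature``.
    """

    dg0: dict[str, float]
    temperature: float = 298.15
    y_lb: dict[str, float] = field(default_factory=dict)
    y_ub: dict[str, float] = field(default_factory=dict)
    fixed_y: dict[str, float] = field(default_factory=dict)

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    @classmethod
    def from_network(
        cls,
        network: MetabolicNetwork,
        dg0: Mapping[str, float] | None = None,
        temperature: float = 298.15,
        fixed: Mapping[str, float] | None = None,
        clamp_independent: bool = True,
    ) -> "ThermoData":
        """Build thermodynamic data from a network's annotations.

        ``dg0`` defaults to the per-reaction ``dg0`` fields; box bounds
        come from the metabolite concentration boxes.  ``fixed`` maps
        metabolite ids to concentrations (mol/L) to clamp; when
        ``clamp_independent`` is set, independent metabolites with a
        network-level default concentration are clamped too.
        """
        d = {r.id: r.dg0 for r in network.reactions if r.dg0 is not None}
        if dg0:
            d.update({k: float(v) for k, v in dg0.items()})
        fixed_y = {}
        if clamp_independent:
            for mid, x in getattr(network, "default_concentrations", {}).items():
                if network.metabolite(mid).role == "independent":
                    fixed_y[mid] = math.log(x)
        for mid, x in (fixed or {}).items():
            fixed_y[mid] = math.log(x)
        return cls(
            dg0=d,
            temperature=temperature,
            y_lb={m.id: math.log(m.conc_lb) for m in network.metabolites},
            y_ub={m.id: math.log(m.conc_ub) for m in network.metabolites},
            fixed_y=fixed_y,
        )


@dataclass
class ThermoState:
    """A feasible (or infeasible) thermodynamic assignment."""

    y: dict[str, float]
    g: dict[str, float]
    B: float
    status: str  # feasible | infeasible

    @property
    def concentrations(self) -> dict[str, float]:
        return {m: math.exp(v) for m, v in self.y.items()}


def reaction_gibbs(
    thermo: ThermoData, network: MetabolicNetwork, y: Mapping[str, float]
) -> dict[str, float]:
    """Per-reaction ΔG at the log-concentration assignment ``y``.

    ``g_i = g0_i + RT * sum_j s_ij * y_j`` for every reaction with a
    standard free energy.
    """
    out = {}
    for r in network.reactions:
        if r.id not in thermo.dg0:
            continue
        try:
            out[r.id] = thermo.dg0[r.id] + thermo.rt * sum(
                s * y[m] for m, s in r.stoich.items()
            )
        except KeyError as e:
            raise KeyError(f"no log-concentration for metabolite {e.args[0]!r} "
                           f"in reaction {r.id!r}") from None
    return out


def directions_from_fluxes(fluxes: Mapping[str, float], tol: float = 1e-9) -> dict[str, str]:
    """Map a flux vector to per-reaction directions (forward/reverse/off)."""
    return {
        rid: "forward" if v > tol else ("reverse" if v < -tol else "off")
        for rid, v in fluxes.items()
    }


# ---------------------------------------------------------------------- #
def _polytope(thermo: ThermoData, network: MetabolicNetwork, directions: Mapping[str, str]):
    """Assemble the inequality system A y <= b plus box bounds over all metabolites.

    Returns (ids, A, b, bounds, directed) where ``directed`` lists
    (reaction, orientation_sign) for reactions participating in the
    driving-force constraints.
    """
    ids = network.metabolite_ids
    idx = {m: i for i, m in enumerate(ids)}
    rows, rhs, directed = [], [], []
    for r in network.reactions:
        d = directions.get(r.id, "off")
        if d == "off":
            continue
        if d not in ("forward", "reverse"):
            raise ValueError(f"direction for {r.id!r} must be forward/reverse/off, got {d!r}")
        if r.id not in thermo.dg0:
            raise KeyError(f"no dg0 for directed reaction {r.id!r}")
        sign = 1.0 if d == "forward" else -1.0
        row = np.zeros(len(ids))
        for m, s in r.stoich.items():
            row[idx[m]] = sign * thermo.rt * s
        rows.append(row)
        rhs.append(-sign * thermo.dg0[r.id])
        directed.append((r.id, sign))
    bounds = []
    for m in ids:
        if m in thermo.fixed_y:
            bounds.append((thermo.fixed_y[m], thermo.fixed_y[m]))
        else:
            bounds.append((thermo.y_lb[m], thermo.y_ub[m]))
    A = np.array(rows) if rows else np.zeros((0, len(ids)))
    return ids, A, np.array(rhs), bounds, directed


def variable_ranges(
    thermo: ThermoData,
    network: MetabolicNetwork,
    directions: Mapping[str, str],
) -> pd.DataFrame:
    """Admissible [min, max] for each log-concentration and each reaction ΔG.

    Each bound is the optimum of an LP over the feasibility polytope.
    Returns a tidy frame with columns ``kind`` (metabolite/reaction),
    ``id``, ``min``, ``max``; raises if the direction pattern is
    infeasible.
    """
    ids, A, b, bounds, _ = _polytope(thermo, network, directions)
    idx = {m: i for i, m in enumerate(ids)}
    n = len(ids)

    def _opt(c):
        res = linprog(c, A_ub=A if A.size else None, b_ub=b if A.size else None,
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"infeasible direction pattern (LP status {res.status})")
        return float(res.fun)

    rows = []
    for m in ids:
        c = np.zeros(n)
        c[idx[m]] = 1.0
        rows.append({"kind": "metabolite", "id": m, "min": _opt(c), "max": -_opt(-c)})
    for r in network.reactions:
        if r.id not in thermo.dg0:
            continue
        c = np.zeros(n)
        for m, s in r.stoich.items():
            c[idx[m]] = thermo.rt * s
        g0 = thermo.dg0[r.id]
        rows.append({"kind": "reaction", "id": r.id,
                     "min": g0 + _opt(c), "max": g0 - _opt(-c)})
    return pd.DataFrame(rows)


def max_min_driving_force(
    thermo: ThermoData,
    network: MetabolicNetwork,
    directions: Mapping[str, str],
) -> ThermoState:
    """Solve the Max-min Driving Force problem.

    Minimizes ``B`` subject to ``g_i <= B`` for every directed reaction
    (reverse reactions enter with flipped sign) and the concentration
    box, maximizing the magnitude of the minimal driving force.  Returns
    the optimizing assignment; ``status="feasible"`` iff ``B <= 0``.
    """
    ids, A, b, bounds, directed = _polytope(thermo, network, directions)
    if not directed:
        raise ValueError("max_min_driving_force needs at least one directed reaction")
    n = len(ids)
    # Variables: y (n) then B.  Constraint rows: A y - B <= b  (i.e. g_i <= B).
    A_ext = np.hstack([A, -np.ones((A.shape[0], 1))])
    c = np.zeros(n + 1)
    c[-1] = 1.0
    res = linprog(c, A_ub=A_ext, b_ub=b, bounds=bounds + [(None, None)], method="highs")
    if res.status != 0:
        return ThermoState(y={}, g={}, B=float("nan"), status="infeasible")
    y = {m: float(res.x[i]) for i, m in enumerate(ids)}
    g = reaction_gibbs(thermo, network, y)
    B = float(res.x[-1])
    return ThermoState(y=y, g=g, B=B, status="feasible" if B <= 1e-9 else "infeasible")


def dg_sweep(
    thermo: ThermoData,
    network: MetabolicNetwork,
    metabolite_id: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """ΔG of every reaction as one metabolite's concentration is swept.

    All other metabolites must be clamped (via ``fixed_y``); reactions
    that do not involve the swept metabolite yield constant columns.
    Grid values outside the declared box are computed anyway with a
    warning.  Columns: ``conc``, one ΔG column per reaction, ``B``.
    """
    if metabolite_id not in network.metabolite_ids:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    free = [
        m.id for m in network.metabolites
        if m.id != metabolite_id and m.id not in thermo.fixed_y
    ]
    if free:
        raise ValueError(f"all non-swept metabolites must be fixed; free: {free}")
    m = network.metabolite(metabolite_id)
    rows = []
    for x in grid:
        if not (m.conc_lb <= x <= m.conc_ub):
            warnings.warn(
                f"sweep value {x:g} outside declared bounds of {metabolite_id!r}",
                stacklevel=2,
            )
        y = dict(thermo.fixed_y)
        y[metabolite_id] = math.log(x)
        g = reaction_gibbs(thermo, network, y)
        rows.append({"conc": x, **g, "B": max(g.values())})
    return pd.DataFrame(rows)
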