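"""Power-law dynamic models and their steady-state analysis.

A :class:`PowerLawModel` attaches to every reaction a rate law
``v = alpha * prod_j x_j**g_j`` whose kinetic orders are assembled from a
bounded kinetic part plus the thermodynamic contribution
``-s * theta/(1-theta)`` of the reaction's distance to equilibrium.  For
S-systems (one net production and one net consumption term per dependent
variable) steady states are solved exactly as a linear system in log
space, which also yields analytic logarithmic gains and parametric
sensitivities.  Simulation integrates in log coordinates, preserving
positivity; stability uses the log-space Jacobian (similar to the
linear-space one through a positive diagonal, so the verdict is
identical).
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .netcore import MetabolicNetwork, NetworkValidationError, ReferenceState, stoichiometric_matrix
from .thermokin import kinetic_order

__all__ = [
    "RateLaw",
    "PowerLawModel",
    "SensitivityReport",
    "NotSSystemError",
    "build_model",
    "rate_constants",
    "ln_rate_constants",
    "steady_state",
    "simulate",
    "log_gains",
    "parameter_sensitivities",
    "stability",
    "sensitivity_report",
    "feedback_stability_margin",
    "MARGIN_CAP",
]

#: Magnitude above which a feedback order is declared effectively unbounded.
MARGIN_CAP = 1e6


class NotSSystemError(ValueError):
    """The model lacks the one-production/one-consumption structure needed
    for the exact log-linear solution."""


class RateLaw:
    """One power-law rate: ``v = alpha * prod_j x_j**orders[j]``.

    The rate constant is stored as ``ln_alpha`` so that strongly
    near-equilibrium parameterizations (whose alpha overflows a float)
    remain representable; ``alpha`` is a convenience property.
    """

    def __init__(self, alpha: float | None = None, orders: dict[str, float] | None = None,
                 kinetic_parts: dict[str, float] | None = None, theta: float = 0.0,
                 keq: float = 1.0, ln_alpha: float | None = None,
                 stoich: dict[str, float] | None = None):
        if ln_alpha is None:
            if alpha is None or not alpha > 0:
                raise ValueError(f"rate constant must be positive, got {alpha}")
            ln_alpha = math.log(alpha)
        self.ln_alpha = float(ln_alpha)
        self.orders = dict(orders or {})
        self.kinetic_parts = dict(kinetic_parts or {})
        self.theta = float(theta)
        self.keq = float(keq)
        self.stoich = dict(stoich or {})

    @property
    def alpha(self) -> float:
        return math.exp(self.ln_alpha)

    @alpha.setter
    def alpha(self, value: float) -> None:
        if not value > 0:
            raise ValueError(f"rate constant must be positive, got {value}")
        self.ln_alpha = math.log(value)

    def log_value(self, x: Mapping[str, float]) -> float:
        return self.ln_alpha + sum(
            g * math.log(x[mid]) for mid, g in self.orders.items() if g != 0.0
        )

    def value(self, x: Mapping[str, float]) -> float:
        return math.exp(self.log_value(x))

    def __repr__(self):  # pragma: no cover
        return (f"RateLaw(ln_alpha={self.ln_alpha!r}, orders={self.orders!r}, "
                f"theta={self.theta!r}, keq={self.keq!r})")


@dataclass
class PowerLawModel:
    """A complete power-law model over a network's dependent variables."""

    dependent_ids: list[str]
    independent_ids: list[str]
    reaction_ids: list[str]
    rates: dict[str, RateLaw]
    stoich: np.ndarray  # dependent rows x reactions
    reference: ReferenceState

    def copy(self) -> "PowerLawModel":
        return PowerLawModel(
            dependent_ids=list(self.dependent_ids),
            independent_ids=list(self.independent_ids),
            reaction_ids=list(self.reaction_ids),
            rates={rid: _copy.deepcopy(r) for rid, r in self.rates.items()},
            stoich=self.stoich.copy(),
            reference=_copy.deepcopy(self.reference),
        )

    # -- evaluation ---------------------------------------------------- #
    def concentrations(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        x = dict(self.reference.concentrations)
        if overrides:
            x.update(overrides)
        return x

    def rate_values(self, x: Mapping[str, float]) -> dict[str, float]:
        return {rid: self.rates[rid].value(x) for rid in self.reaction_ids}

    def is_s_system(self) -> bool:
        for i in range(len(self.dependent_ids)):
            row = self.stoich[i]
            if np.sum(row > 0) != 1 or np.sum(row < 0) != 1:
                return False
        return True

    def validate(self, rtol: float = 1e-9) -> None:
        """Check rate-law invariants: order decomposition and reference reproduction."""
        out = []
        for rid, rl in self.rates.items():
            t = rl.theta
            tc = t / (1.0 - t) if t > 0 else 0.0
            j = self.reaction_ids.index(rid)
            for mid, g in rl.orders.items():
                kp = rl.kinetic_parts.get(mid, 0.0)
                if rl.stoich:
                    s = rl.stoich.get(mid, 0.0)
                else:
                    i = self.dependent_ids.index(mid) if mid in self.dependent_ids else None
                    s = self.stoich[i, j] if i is not None else 0.0
                expected = kp - s * tc
                if abs(g - expected) > 1e-12 + 1e-12 * abs(expected):
                    out.append(f"reaction {rid!r}, metabolite {mid!r}: order {g} != "
                               f"kinetic part {kp} - s*theta/(1-theta) = {expected}")
        x0 = self.reference.concentrations
        for rid, v0 in self.reference.fluxes.items():
            if rid not in self.rates:
                continue
            v = self.rates[rid].value(x0)
            if abs(v - v0) > rtol * abs(v0):
                out.append(f"reaction {rid!r}: rate at reference {v:.12g} != flux {v0:.12g}")
        if out:
            raise NetworkValidationError(out)

    # -- serialization ------------------------------------------------- #
    def to_dict(self) -> dict:
        return {
            "dependent_ids": self.dependent_ids,
            "independent_ids": self.independent_ids,
            "reaction_ids": self.reaction_ids,
            "rates": {
                rid: {
                    "ln_alpha": r.ln_alpha,
                    "orders": r.orders,
                    "kinetic_parts": r.kinetic_parts,
                    "theta": r.theta,
                    "keq": r.keq,
                    "stoich": r.stoich,
                }
                for rid, r in self.rates.items()
            },
            "stoich": self.stoich.tolist(),
            "reference": self.reference.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PowerLawModel":
        return cls(
            dependent_ids=list(d["dependent_ids"]),
            independent_ids=list(d["independent_ids"]),
            reaction_ids=list(d["reaction_ids"]),
            rates={
                rid: RateLaw(
                    ln_alpha=(float(r["ln_alpha"]) if "ln_alpha" in r
                              else math.log(float(r["alpha"]))),
                    orders={k: float(v) for k, v in r["orders"].items()},
                    kinetic_parts={k: float(v) for k, v in r.get("kinetic_parts", {}).items()},
                    theta=float(r.get("theta", 0.0)),
                    keq=float(r.get("keq", 1.0)),
                    stoich={k: float(v) for k, v in r.get("stoich", {}).items()},
                )
                for rid, r in d["rates"].items()
            },
            stoich=np.asarray(d["stoich"], dtype=float),
            reference=ReferenceState.from_dict(d["reference"]),
        )


@dataclass
class SensitivityReport:
    """Collected systemic responses of one model."""

    log_gains: dict[tuple[str, str], float]
    sensitivities: dict[tuple[str, str], float]
    eigenvalues: list[complex]
    stable: bool
    margin: float


# ---------------------------------------------------------------------- #
# Construction
# ---------------------------------------------------------------------- #
def rate_constants(
    reference: ReferenceState, orders: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Rate constants from the reference state:
    ``ln alpha_i = ln |v_i|0 - sum_j g_ij ln |x_j|0``."""
    return {rid: math.exp(v) for rid, v in ln_rate_constants(reference, orders).items()}


def ln_rate_constants(
    reference: ReferenceState, orders: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Log rate constants (overflow-safe form of :func:`rate_constants`)."""
    out = {}
    for rid, g in orders.items():
        v0 = reference.fluxes.get(rid)
        if v0 is None or not v0 > 0:
            raise ValueError(f"reaction {rid!r}: positive reference flux required, got {v0}")
        ln_a = math.log(v0)
        for mid, gj in g.items():
            x0 = reference.concentrations.get(mid)
            if x0 is None or not x0 > 0:
                raise ValueError(f"metabolite {mid!r}: positive reference concentration "
                                 f"required, got {x0}")
            ln_a -= gj * math.log(x0)
        out[rid] = ln_a
    return out


def build_model(
    network: MetabolicNetwork,
    reference: ReferenceState,
    kinetic_parts: Mapping[tuple[str, str], float] | None = None,
    theta: Mapping[str, float] | None = None,
    keq: Mapping[str, float] | None = None,
) -> PowerLawModel:
    """Assemble a power-law model from a network and a reference state.

    Total orders come from the kinetic/thermodynamic decomposition; rate
    constants are fixed so every rate reproduces its reference flux.
    ``kinetic_parts`` is keyed ``(reaction_id, metabolite_id)`` and must
    cover all stoichiometric participants and modifiers (the network
    annotation left by the fixture generators is used as a default).
    """
    network.validate()
    if kinetic_parts is None:
        kinetic_parts = getattr(network, "kinetic_parts", None)
        if kinetic_parts is None:
            raise ValueError("kinetic_parts required (network carries no annotation)")
    theta = {**reference.theta, **(theta or {})}
    keq = {**reference.keq, **(keq or {})}
    ref = ReferenceState(
        fluxes=dict(reference.fluxes),
        concentrations=dict(reference.concentrations),
        theta={rid: theta.get(rid, 0.0) for rid in (set(theta) | set(reference.theta))},
        keq={rid: keq.get(rid, 1.0) for rid in (set(keq) | set(reference.keq))},
    )
    ref.validate(network)

    orders: dict[str, dict[str, float]] = {}
    kparts: dict[str, dict[str, float]] = {}
    for r in network.reactions:
        t = theta.get(r.id, 0.0)
        og, kg = {}, {}
        for mid, s in r.stoich.items():
            key = (r.id, mid)
            if key not in kinetic_parts:
                raise ValueError(f"missing kinetic part for {key}")
            kp = float(kinetic_parts[key])
            og[mid] = kinetic_order(kp, s, theta_value=t).total
            kg[mid] = kp
        for mid in r.modifiers:
            key = (r.id, mid)
            if key not in kinetic_parts:
                raise ValueError(f"missing kinetic part for modifier {key}")
            og[mid] = kg[mid] = float(kinetic_parts[key])
        orders[r.id] = og
        kparts[r.id] = kg

    ln_alphas = ln_rate_constants(ref, orders)
    model = PowerLawModel(
        dependent_ids=network.dependent_ids,
        independent_ids=network.independent_ids,
        reaction_ids=network.reaction_ids,
        rates={
            rid: RateLaw(
                ln_alpha=ln_alphas[rid],
                orders=orders[rid],
                kinetic_parts=kparts[rid],
                theta=theta.get(rid, 0.0),
                keq=keq.get(rid, 1.0),
                stoich=dict(network.reaction(rid).stoich),
            )
            for rid in network.reaction_ids
        },
        stoich=stoichiometric_matrix(network, rows="dependent"),
        reference=ref,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------- #
# Log-linear steady states
# ---------------------------------------------------------------------- #
def _s_system_terms(model: PowerLawModel) -> list[tuple[int, float, int, float]]:
    """Per dependent variable: (production reaction idx, coeff, consumption idx, coeff)."""
    terms = []
    for i in range(len(model.dependent_ids)):
        row = model.stoich[i]
        pos = np.flatnonzero(row > 0)
        neg = np.flatnonzero(row < 0)
        if len(pos) != 1 or len(neg) != 1:
            raise NotSSystemError(
                f"dependent variable {model.dependent_ids[i]!r} has {len(pos)} production "
                f"and {len(neg)} consumption terms; exact log-linear solution needs 1+1"
            )
        terms.append((int(pos[0]), float(row[pos[0]]), int(neg[0]), float(-row[neg[0]])))
    return terms


def _log_linear_system(model: PowerLawModel, y_ind: Mapping[str, float]):
    """Build ``A @ y_dep = b`` for the S-system steady state.

    Equation per dependent variable: ln(sp*vp) = ln(sc*vc).
    Returns (A, b, terms).
    """
    terms = _s_system_terms(model)
    dep = model.dependent_ids
    dep_idx = {m: j for j, m in enumerate(dep)}
    n = len(dep)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i, (p, sp, c, sc) in enumerate(terms):
        rp = model.rates[model.reaction_ids[p]]
        rc = model.rates[model.reaction_ids[c]]
        b[i] = (math.log(sc) + rc.ln_alpha) - (math.log(sp) + rp.ln_alpha)
        for mid, g in rp.orders.items():
            if mid in dep_idx:
                A[i, dep_idx[mid]] += g
            else:
                b[i] -= g * y_ind[mid]
        for mid, g in rc.orders.items():
            if mid in dep_idx:
                A[i, dep_idx[mid]] -= g
            else:
                b[i] += g * y_ind[mid]
    return A, b, terms


def _independent_y(model: PowerLawModel, independent_values: Mapping[str, float] | None):
    x = dict(model.reference.concentrations)
    if independent_values:
        x.update(independent_values)
    return {m: math.log(x[m]) for m in model.independent_ids}


def steady_state(
    model: PowerLawModel,
    independent_values: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Steady-state dependent concentrations.

    Exact log-linear solve for S-systems; otherwise a damped root search
    on the log-rate balance that must reach ``||xdot||_inf <= 1e-10``.
    Raises on a singular (structurally undetermined) system.
    """
    y_ind = _independent_y(model, independent_values)
    try:
        A, b, _ = _log_linear_system(model, y_ind)
    except NotSSystemError:
        return _steady_state_numeric(model, y_ind)
    try:
        y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise NetworkValidationError(
            ["singular log-linear system: steady state structurally undetermined"]
        )
    return {m: math.exp(y[j]) for j, m in enumerate(model.dependent_ids)}


def _steady_state_numeric(model: PowerLawModel, y_ind: Mapping[str, float]):
    dep = model.dependent_ids
    x_ind = {m: math.exp(v) for m, v in y_ind.items()}

    def f(y):
        x = {**x_ind, **{m: math.exp(y[j]) for j, m in enumerate(dep)}}
        v = np.array([model.rates[r].value(x) for r in model.reaction_ids])
        return model.stoich @ v

    y0 = np.log([model.reference.concentrations[m] for m in dep])
    sol = root(f, y0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(f(sol.x))) > 1e-10:
        raise RuntimeError(f"steady-state root search failed: {sol.message}")
    return {m: math.exp(sol.x[j]) for j, m in enumerate(dep)}


def simulate(
    model: PowerLawModel,
    x0: Mapping[str, float],
    t_grid: Sequence[float],
    independent_values: Mapping[str, float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the model in log space over ``t_grid``.

    ``x0`` gives initial dependent concentrations (must be positive).
    Returns a frame with a ``time`` column and one column per dependent
    variable.
    """
    dep = model.dependent_ids
    for m in dep:
        if not x0[m] > 0:
            raise ValueError(f"initial concentration of {m!r} must be positive")
    x_ind = {m: math.exp(v) for m, v in _independent_y(model, independent_values).items()}

    def rhs(t, y):
        x = {**x_ind, **{m: math.exp(y[j]) for j, m in enumerate(dep)}}
        v = np.array([model.rates[r].value(x) for r in model.reaction_ids])
        return np.exp(-y) * (model.stoich @ v)

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), np.log([x0[m] for m in dep]),
        t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else t_grid[0]}: "
                           f"{sol.message}")
    out = pd.DataFrame({"time": sol.t})
    for j, m in enumerate(dep):
        out[m] = np.exp(sol.y[j])
    return out


# ---------------------------------------------------------------------- #
# Gains and sensitivities
# ---------------------------------------------------------------------- #
def _solve_response(model, rhs_grad, independent_values=None):
    y_ind = _independent_y(model, independent_values)
    A, _, terms = _log_linear_system(model, y_ind)
    try:
        dy = np.linalg.solve(A, rhs_grad)
    except np.linalg.LinAlgError:
        raise NetworkValidationError(["singular log-linear system"])
    return dy


def log_gains(
    model: PowerLawModel,
    independent_id: str,
    independent_values: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Logarithmic gains of every dependent variable and flux with respect
    to one independent variable (analytic, from the log-linear solve)."""
    if independent_id not in model.independent_ids:
        raise KeyError(f"{independent_id!r} is not an independent variable")
    y_ind = _independent_y(model, independent_values)
    A, _, terms = _log_linear_system(model, y_ind)
    n = len(model.dependent_ids)
    grad = np.zeros(n)
    for i, (p, _, c, _) in enumerate(terms):
        gp = model.rates[model.reaction_ids[p]].orders.get(independent_id, 0.0)
        gc = model.rates[model.reaction_ids[c]].orders.get(independent_id, 0.0)
        grad[i] = gc - gp
    try:
        dy = np.linalg.solve(A, grad)
    except np.linalg.LinAlgError:
        raise NetworkValidationError(["singular log-linear system"])
    out = {m: float(dy[j]) for j, m in enumerate(model.dependent_ids)}
    dep_idx = {m: j for j, m in enumerate(model.dependent_ids)}
    for rid in model.reaction_ids:
        g = model.rates[rid].orders
        out[rid] = float(
            g.get(independent_id, 0.0)
            + sum(gj * dy[dep_idx[m]] for m, gj in g.items() if m in dep_idx)
        )
    return out


def parameter_sensitivities(
    model: PowerLawModel,
    reaction_id: str,
    independent_values: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Sensitivities of dependent variables and fluxes to one rate constant."""
    if reaction_id not in model.reaction_ids:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    y_ind = _independent_y(model, independent_values)
    A, _, terms = _log_linear_system(model, y_ind)
    r_idx = model.reaction_ids.index(reaction_id)
    n = len(model.dependent_ids)
    grad = np.zeros(n)
    for i, (p, _, c, _) in enumerate(terms):
        # Equation i reads ln(sp*ap) + gp.y = ln(sc*ac) + gc.y, solved as
        # A y = b with b = ln(sc*ac) - ln(sp*ap).
        if c == r_idx:
            grad[i] += 1.0
        if p == r_idx:
            grad[i] -= 1.0
    try:
        dy = np.linalg.solve(A, grad)
    except np.linalg.LinAlgError:
        raise NetworkValidationError(["singular log-linear system"])
    out = {m: float(dy[j]) for j, m in enumerate(model.dependent_ids)}
    dep_idx = {m: j for j, m in enumerate(model.dependent_ids)}
    for rid in model.reaction_ids:
        g = model.rates[rid].orders
        out[rid] = float(
            (1.0 if rid == reaction_id else 0.0)
            + sum(gj * dy[dep_idx[m]] for m, gj in g.items() if m in dep_idx)
        )
    return out


# ---------------------------------------------------------------------- #
# Stability
# ---------------------------------------------------------------------- #
def _jacobian(model: PowerLawModel, x_dep: Mapping[str, float],
              independent_values=None) -> np.ndarray:
    """Log-space Jacobian at a steady state:
    ``J = diag(1/x_d) S diag(v) G`` restricted to dependent columns."""
    dep = model.dependent_ids
    x = model.concentrations(independent_values)
    x.update(x_dep)
    v = np.array([model.rates[r].value(x) for r in model.reaction_ids])
    G = np.zeros((len(model.reaction_ids), len(dep)))
    for k, rid in enumerate(model.reaction_ids):
        for j, m in enumerate(dep):
            G[k, j] = model.rates[rid].orders.get(m, 0.0)
    xd = np.array([x[m] for m in dep])
    return (model.stoich * v[None, :]) @ G / xd[:, None]


def _routh_hurwitz(coeffs: np.ndarray) -> bool | None:
    """Routh-Hurwitz verdict for monic polynomials of degree <= 3, else None."""
    c = coeffs / coeffs[0]
    n = len(c) - 1
    if n == 1:
        return c[1] > 0
    if n == 2:
        return c[1] > 0 and c[2] > 0
    if n == 3:
        a1, a2, a3 = c[1], c[2], c[3]
        return a1 > 0 and a3 > 0 and a1 * a2 > a3
    return None


def stability(
    model: PowerLawModel,
    independent_values: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, bool]:
    """Eigenvalues of the log-space Jacobian at steady state and the
    stability flag (all real parts < 0).

    For systems of dimension <= 3 the Routh-Hurwitz determinant
    conditions are evaluated as well and must agree with the eigenvalue
    verdict (checked unless the leading eigenvalue is numerically on the
    imaginary axis).
    """
    x_dep = steady_state(model, independent_values)
    J = _jacobian(model, x_dep, independent_values)
    eig = np.linalg.eigvals(J)
    lead = float(np.max(eig.real))
    stable = lead < 0
    rh = _routh_hurwitz(np.poly(J))
    if rh is not None and abs(lead) > 1e-9 and rh != stable:
        raise AssertionError(
            f"Routh-Hurwitz verdict {rh} disagrees with eigenvalues (leading {lead:g})"
        )
    return eig, stable


def sensitivity_report(
    model: PowerLawModel,
    margin_reaction: str | None = None,
    margin_metabolite: str | None = None,
) -> SensitivityReport:
    """Collect gains, sensitivities, eigenvalues and (optionally) the
    feedback margin of one model into a single report."""
    gains = {}
    for ind in model.independent_ids:
        for target, val in log_gains(model, ind).items():
            gains[(target, ind)] = val
    sens = {}
    for rid in model.reaction_ids:
        for target, val in parameter_sensitivities(model, rid).items():
            sens[(target, rid)] = val
    eig, stable = stability(model)
    margin = math.inf
    if margin_reaction is not None and margin_metabolite is not None:
        margin = feedback_stability_margin(model, margin_reaction, margin_metabolite)
    return SensitivityReport(
        log_gains=gains, sensitivities=sens,
        eigenvalues=list(eig), stable=stable, margin=margin,
    )


def _with_feedback_magnitude(model: PowerLawModel, reaction_id: str,
                             metabolite_id: str, magnitude: float) -> PowerLawModel:
    """Copy of the model with the designated feedback order set to
    ``-magnitude``, alpha readjusted to keep the reference steady state."""
    m = model.copy()
    rl = m.rates[reaction_id]
    rl.orders[metabolite_id] = -magnitude
    rl.kinetic_parts[metabolite_id] = -magnitude
    x0 = m.reference.concentrations
    v0 = m.reference.fluxes[reaction_id]
    rl.ln_alpha = math.log(v0) - sum(g * math.log(x0[j]) for j, g in rl.orders.items())
    return m


def feedback_stability_margin(
    model: PowerLawModel,
    reaction_id: str,
    metabolite_id: str,
    cap: float = MARGIN_CAP,
    rtol: float = 1e-6,
) -> float:
    """Critical magnitude of a feedback order at which stability is lost.

    Scans the magnitude upward (geometric steps) and bisects the leading
    eigenvalue's zero crossing to relative tolerance ``rtol``; returns
    ``inf`` if no crossing is found below ``cap``.  Raises if the system
    is already unstable with the loop removed.
    """
    current = model.rates[reaction_id].orders.get(metabolite_id, 0.0)
    if current > 0:
        raise ValueError(f"designated order ({reaction_id!r}, {metabolite_id!r}) "
                         f"is not a feedback (negative) order: {current}")

    def lead(mag: float) -> float:
        m = _with_feedback_magnitude(model, reaction_id, metabolite_id, mag)
        x_dep = steady_state(m)
        return float(np.max(np.linalg.eigvals(_jacobian(m, x_dep)).real))

    if lead(0.0) >= 0:
        raise ValueError("model is unstable already at feedback magnitude 0")
    lo, hi = 0.0, 1.0
    while lead(hi) < 0:
        lo, hi = hi, hi * 2.0
        if hi > cap:
            return math.inf
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if lead(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
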