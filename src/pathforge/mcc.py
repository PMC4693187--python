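"""Mathematically controlled comparison of pathway designs.

A comparison pits a reference model against an alternative that differs
in a declared set of reactions.  *Internal equivalence* freezes every
parameter outside the changed reactions; *external equivalence* spends
the remaining freedom making the two systems look the same from the
outside (same fluxes, same boundary concentrations, same selected
gains).  For the interior-reaction theta family the thermodynamic
consistency constraints fix two of the four degrees of freedom and the
flux-invariance condition a third, leaving theta itself as the design
axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bst import (
    PowerLawModel,
    feedback_stability_margin,
    log_gains,
    parameter_sensitivities,
    stability,
    steady_state,
)
from .netcore import make_unbranched_pathway
from .thermokin import RT_DEFAULT, dg_from_theta, min_enzyme

__all__ = [
    "EquivalenceSpec",
    "ThermoConsistency",
    "internal_equivalence",
    "thermo_consistency",
    "consistency_factor",
    "theta_equivalence",
    "external_equivalence",
    "compare",
    "design_sweep",
    "monte_carlo_compare",
]


@dataclass
class EquivalenceSpec:
    """Which parameters may differ between reference and alternative."""

    changed_reaction_ids: set[str]
    free_parameters: list[tuple[str, str]]
    matched_properties: list = field(default_factory=list)

    def check_internal(self, reference: PowerLawModel, alternative: PowerLawModel,
                       tol: float = 0.0) -> list[str]:
        """List every parameter outside the changed reactions that differs."""
        out = []
        for rid in reference.reaction_ids:
            if rid in self.changed_reaction_ids:
                continue
            a, b = reference.rates[rid], alternative.rates.get(rid)
            if b is None:
                out.append(f"reaction {rid!r} missing from alternative")
                continue
            if abs(a.ln_alpha - b.ln_alpha) > tol:
                out.append(f"alpha of {rid!r} differs")
            for mid in set(a.orders) | set(b.orders):
                if abs(a.orders.get(mid, 0.0) - b.orders.get(mid, 0.0)) > tol:
                    out.append(f"order ({rid!r}, {mid!r}) differs")
        return out


def internal_equivalence(reference: PowerLawModel, changed: set[str]) -> EquivalenceSpec:
    """Freeze all parameters outside ``changed``; enumerate the free ones.

    For each changed reaction the free parameters are its distance to
    equilibrium, the kinetic part of every stoichiometric participant,
    and the rate constant.
    """
    unknown = set(changed) - set(reference.reaction_ids)
    if unknown:
        raise KeyError(f"changed reactions not in model: {sorted(unknown)}")
    if not reference.reaction_ids:
        raise ValueError("empty model")
    free: list[tuple[str, str]] = []
    for rid in reference.reaction_ids:
        if rid not in changed:
            continue
        rl = reference.rates[rid]
        free.append((rid, "theta"))
        j = reference.reaction_ids.index(rid)
        for mid in rl.orders:
            i = reference.dependent_ids.index(mid) if mid in reference.dependent_ids else None
            if i is not None and reference.stoich[i, j] != 0:
                free.append((rid, f"kinetic_part:{mid}"))
        free.append((rid, "alpha"))
    return EquivalenceSpec(changed_reaction_ids=set(changed), free_parameters=free)


# ---------------------------------------------------------------------- #
# Thermodynamic consistency of an interior reaction
# ---------------------------------------------------------------------- #
def _interior_structure(model: PowerLawModel, reaction_id: str):
    """Locate substrate, product and the downstream consumer of a 1:1
    interior reaction."""
    j = model.reaction_ids.index(reaction_id)
    col = model.stoich[:, j]
    subs = np.flatnonzero(col < 0)
    prods = np.flatnonzero(col > 0)
    if len(subs) != 1 or len(prods) != 1:
        raise ValueError(f"{reaction_id!r} is not a 1:1 interior reaction")
    sub = model.dependent_ids[subs[0]]
    prod = model.dependent_ids[prods[0]]
    consumers = np.flatnonzero(model.stoich[prods[0], :] < 0)
    if len(consumers) != 1:
        raise ValueError(f"product {prod!r} must have exactly one consuming reaction")
    down = model.reaction_ids[consumers[0]]
    return sub, prod, down


@dataclass
class ThermoConsistency:
    """The constraint pair tying an interior reaction's parameters to its
    thermodynamics.

    ``order_sum``: the downstream order of the product must equal the sum
    of the reaction's kinetic parts.  ``ln_alpha``: the rate constant is
    pinned to the downstream one through the equilibrium relation
    (``ln a_i = ln a_down + (gk_sub + theta/(1-theta)) * ln(theta*keq)``).
    A parameterization satisfying both makes the steady state obey
    ``y_prod - y_sub = ln(theta*keq)``.
    """

    reaction_id: str
    substrate: str
    product: str
    downstream_id: str
    g_downstream: float
    theta: float
    keq: float
    degenerate: bool = False  # theta == 0: irreversible case, no constraint

    def gk_product(self, gk_substrate: float) -> float:
        return self.g_downstream - gk_substrate

    def ln_alpha(self, gk_substrate: float, ln_alpha_downstream: float) -> float:
        t = self.theta / (1.0 - self.theta)
        return ln_alpha_downstream + (gk_substrate + t) * math.log(self.theta * self.keq)

    def residuals(self, model: PowerLawModel) -> tuple[float, float]:
        rl = model.rates[self.reaction_id]
        gk_s = rl.kinetic_parts[self.substrate]
        gk_p = rl.kinetic_parts[self.product]
        r1 = self.g_downstream - (gk_s + gk_p)
        if self.degenerate:
            return r1, 0.0
        r2 = rl.ln_alpha - self.ln_alpha(
            gk_s, model.rates[self.downstream_id].ln_alpha
        )
        return r1, r2


def thermo_consistency(model: PowerLawModel, reaction_id: str) -> ThermoConsistency:
    """Constraint set making an interior reaction's parameters consistent
    with its distance to equilibrium (degenerate for theta = 0)."""
    sub, prod, down = _interior_structure(model, reaction_id)
    rl = model.rates[reaction_id]
    return ThermoConsistency(
        reaction_id=reaction_id,
        substrate=sub,
        product=prod,
        downstream_id=down,
        g_downstream=model.rates[down].orders[prod],
        theta=rl.theta,
        keq=rl.keq,
        degenerate=(rl.theta == 0.0),
    )


def consistency_factor(model: PowerLawModel, reaction_id: str) -> float:
    """The log-gain transfer factor ``g_sub / (g_down - g_prod)`` of an
    interior reaction; equals 1 under the consistency constraints."""
    sub, prod, down = _interior_structure(model, reaction_id)
    rl = model.rates[reaction_id]
    return rl.orders[sub] / (model.rates[down].orders[prod] - rl.orders[prod])


# ---------------------------------------------------------------------- #
# Theta equivalence (the interior-reaction design family)
# ---------------------------------------------------------------------- #
def theta_equivalence(
    reference: PowerLawModel,
    theta: float,
    keq: float,
    reaction_id: str = "v2",
) -> PowerLawModel:
    """Member of the theta family externally equivalent to an irreversible
    reference.

    The rate constant is scaled by ``(theta/keq)**(-theta/(1-theta))``
    (reducing to the reference as theta -> 0+); the kinetic parts are
    then re-solved from the flux-invariance and order-sum constraints, so
    the returned model carries the reference flux exactly and shares its
    downstream steady state, while the substrate of the changed reaction
    moves onto the equilibrium relation ``y_prod - y_sub = ln(theta*keq)``.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if reference.rates[reaction_id].theta != 0.0:
        raise ValueError("reference must be the irreversible (theta = 0) model")
    sub, prod, down = _interior_structure(reference, reaction_id)
    t = theta / (1.0 - theta)
    rl_ref = reference.rates[reaction_id]
    ln_alpha_hat = rl_ref.ln_alpha - t * math.log(theta / keq)

    if abs(math.log(theta * keq)) < 1e-9:
        raise ValueError(
            "theta*keq = 1 makes the equilibrium relation degenerate "
            "(substrate and product coincide); pick a different theta")
    v0 = reference.reference.fluxes[reaction_id]
    g_down = reference.rates[down].orders[prod]
    y_prod = math.log(reference.reference.concentrations[prod])
    y_sub = y_prod - math.log(theta * keq)
    # Flux invariance + order-sum constraint pin the total orders.
    g_sub_total = (math.log(v0) - ln_alpha_hat - g_down * y_prod) / (y_sub - y_prod)
    g_prod_total = g_down - g_sub_total

    model = reference.copy()
    rl = model.rates[reaction_id]
    rl.theta, rl.keq, rl.ln_alpha = theta, keq, ln_alpha_hat
    rl.orders[sub] = g_sub_total
    rl.orders[prod] = g_prod_total
    rl.kinetic_parts[sub] = g_sub_total - t
    rl.kinetic_parts[prod] = g_prod_total + t
    model.reference.theta[reaction_id] = theta
    model.reference.keq[reaction_id] = keq

    ss = steady_state(model)
    model.reference.concentrations.update(ss)
    x = model.concentrations()
    model.reference.fluxes = {r: model.rates[r].value(x) for r in model.reaction_ids}
    return model


# ---------------------------------------------------------------------- #
# External equivalence by solving for free parameters
# ---------------------------------------------------------------------- #
def _property_value(model: PowerLawModel, cond) -> float:
    kind = cond[0]
    if kind == "flux":
        ss = steady_state(model)
        return model.rates[cond[1]].value(model.concentrations(ss))
    if kind == "concentration":
        return steady_state(model)[cond[1]]
    if kind == "log_gain":
        return log_gains(model, cond[2])[cond[1]]
    if kind == "sensitivity":
        return parameter_sensitivities(model, cond[2])[cond[1]]
    raise ValueError(f"unknown property kind {kind!r}")


def external_equivalence(
    reference: PowerLawModel,
    alternative: PowerLawModel,
    matched: Sequence[tuple],
    free_parameters: Sequence[tuple[str, str]] | None = None,
) -> tuple[PowerLawModel, dict[tuple[str, str], float]]:
    """Solve free rate constants of the alternative so the matched
    properties coincide with the reference's.

    ``matched`` lists property specs (``("flux", rid)``,
    ``("concentration", mid)``, ``("log_gain", target, independent)``);
    their target values are computed on the reference at its own steady
    state.  ``free_parameters`` defaults to the alphas of every reaction
    whose parameters differ.  Redundant-but-consistent condition sets are
    accepted; inconsistent or genuinely over-determined ones raise.
    """
    if free_parameters is None:
        free_parameters = [
            (rid, "alpha")
            for rid in alternative.reaction_ids
            if alternative.rates[rid].orders != reference.rates[rid].orders
            or alternative.rates[rid].ln_alpha != reference.rates[rid].ln_alpha
        ]
    free_parameters = list(free_parameters)
    if not matched:
        return alternative.copy(), {}
    targets = np.array([_property_value(reference, c) for c in matched])

    def apply(p):
        m = alternative.copy()
        for (rid, name), val in zip(free_parameters, p):
            if name != "alpha":
                raise ValueError(f"only alpha parameters are solvable, got {name!r}")
            m.rates[rid].ln_alpha = val
        return m

    def resid(p):
        m = apply(p)
        return np.array([_property_value(m, c) for c in matched]) - targets

    p0 = np.array([alternative.rates[rid].ln_alpha for rid, _ in free_parameters])
    sol = least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.max(np.abs(sol.fun)) > 1e-8:
        raise ValueError(
            "matched conditions are inconsistent or over-determined "
            f"(max residual {np.max(np.abs(sol.fun)):g})"
        )
    solved = apply(sol.x)
    ss = steady_state(solved)
    solved.reference.concentrations.update(ss)
    x = solved.concentrations()
    solved.reference.fluxes = {r: solved.rates[r].value(x) for r in solved.reaction_ids}
    return solved, {fp: math.exp(v) for fp, v in zip(free_parameters, sol.x)}


# ---------------------------------------------------------------------- #
# Comparison reports
# ---------------------------------------------------------------------- #
def _named_property(model: PowerLawModel, spec) -> float:
    kind = spec[0]
    if kind in ("flux", "concentration", "log_gain", "sensitivity"):
        return _property_value(model, spec)
    if kind == "margin":
        return feedback_stability_margin(model, spec[1], spec[2])
    if kind == "leading_eigenvalue":
        eig, _ = stability(model)
        return float(np.max(eig.real))
    raise ValueError(f"unknown property kind {kind!r}")


def compare(
    reference: PowerLawModel,
    alternative: PowerLawModel,
    properties: Sequence[tuple],
    criterion: Callable[[tuple, float, float], str] | None = None,
) -> pd.DataFrame:
    """Evaluate named properties on both systems at their own steady states.

    Verdicts require an explicit ``criterion(spec, ref, alt) -> str``;
    without one the verdict column reports "equal" only for matching
    values and stays blank otherwise (no implicit fitness function).
    """
    rows = []
    for spec in properties:
        rv = _named_property(reference, spec)
        av = _named_property(alternative, spec)
        if criterion is not None:
            verdict = criterion(spec, rv, av)
        else:
            verdict = "equal" if np.isclose(rv, av, rtol=1e-9, atol=1e-12) else ""
        rows.append(
            {
                "property": ":".join(str(s) for s in spec),
                "reference": rv,
                "alternative": av,
                "difference": av - rv,
                "ratio": (av / rv) if rv not in (0.0,) else float("nan"),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# Case-3 design sweep
# ---------------------------------------------------------------------- #
def design_sweep(
    n: int = 3,
    theta_profiles: Mapping[str, Sequence[float]] | None = None,
    feedback_strengths: Sequence[float] = (0.0, -0.5, -1.0, -2.0),
    kcat: float = 1.0,
    rt: float = RT_DEFAULT,
) -> pd.DataFrame:
    """Sweep pathway designs over distance-to-equilibrium profiles and
    feedback strengths.

    Each design is an unbranched pathway of length ``n`` with the given
    per-step theta profile (equilibrium constants are set to ``1/theta``
    so the reference concentrations stay anchored at 1).  Reported per
    design: total minimal enzyme at the reference flux, the feedback
    stability margin, the responsiveness gain ``|L(x_n, demand)|`` and
    the margin-weighted responsiveness.
    """
    from .bst import build_model

    if theta_profiles is None:
        theta_profiles = {
            "economic": [0.0] * n,
            "responsive": [0.0] + [0.9] * (n - 1),
            "mixed": [0.45] * n,
        }
    rows = []
    for name, profile in theta_profiles.items():
        if len(profile) != n:
            raise ValueError(f"profile {name!r} must have {n} entries")
        for fb in feedback_strengths:
            theta = {i + 1: float(t) for i, t in enumerate(profile)}
            keq = {i + 1: (1.0 / t if t > 0 else 1.0) for i, t in enumerate(profile)}
            net, ref = make_unbranched_pathway(n=n, feedback_order=fb, theta=theta, keq=keq)
            model = build_model(net, ref)
            cost = 0.0
            for i, t in enumerate(profile):
                v0 = ref.fluxes[f"v{i + 1}"]
                cost += (min_enzyme(v0, kcat, dg_from_theta(t, rt), rt)
                         if t > 0 else v0 / kcat)
            cost += ref.fluxes[f"v{n + 1}"] / kcat  # demand step, irreversible
            margin = feedback_stability_margin(model, "v1", f"X{n}" if n > 1 else "X1")
            gains = log_gains(model, f"X{n + 1}")
            resp = abs(gains[f"X{n}"])
            rows.append(
                {
                    "design": name,
                    "theta_profile": "/".join(f"{t:g}" for t in profile),
                    "feedback": fb,
                    "enzyme_cost": cost,
                    "margin": margin,
                    "responsiveness": resp,
                    "margin_x_feedback": margin * abs(fb) if math.isfinite(margin) else math.inf,
                }
            )
    return pd.DataFrame(rows)


def monte_carlo_compare(
    reference_factory: Callable[[np.random.Generator], PowerLawModel],
    alternative_factory: Callable[[np.random.Generator], PowerLawModel],
    prop: tuple,
    n_samples: int = 100,
    seed: int = 0,
    better: Callable[[float, float], bool] = lambda r, a: abs(a) < abs(r),
) -> float:
    """Statistical controlled comparison: fraction of random draws where
    the alternative outperforms the reference on one property."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_samples):
        r = _named_property(reference_factory(rng), prop)
        a = _named_property(alternative_factory(rng), prop)
        wins += bool(better(r, a))
    return wins / n_samples
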