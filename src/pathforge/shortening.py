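"""Thermodynamic shortening: pooling of near-equilibrium metabolites.

Reactions are partitioned by distance to equilibrium; metabolites coupled
by near-equilibrium reactions collapse into pools defined by an
integer-valued basis of the left null space of the equilibrium
stoichiometric block.  Bound metabolites are eliminated through the
equilibrium constraints (``ln x_b = F ln x_f + ln gamma``), and the
remaining far-from-equilibrium rates are rewritten in pool coordinates,
yielding a reduced power-law model whose systemic properties are the
``theta -> 1`` limits of the full model's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy

from .netcore import ReferenceState
from .bst import PowerLawModel, RateLaw, steady_state

__all__ = [
    "PoolReduction",
    "partition_reactions",
    "pool_matrix",
    "split_metabolites",
    "eliminate_bound",
    "reduce_model",
    "limit_check",
    "DEFAULT_THETA_THRESHOLD",
]

#: Reactions with theta at or above this are treated as equilibrated.
DEFAULT_THETA_THRESHOLD = 0.99


@dataclass
class PoolReduction:
    """Bookkeeping of one thermodynamic shortening step."""

    eq_reaction_ids: list[str]
    irr_reaction_ids: list[str]
    seq: np.ndarray
    sirr: np.ndarray
    c: np.ndarray                      # pools x dependent metabolites
    pool_ids: list[str]
    free_ids: list[str]
    bound_ids: list[str]
    f_matrix: np.ndarray               # bound x free exponents
    gamma: np.ndarray                  # per-bound-metabolite multiplier
    shares: dict[str, float] = field(default_factory=dict)  # metabolite -> share coefficient
    reduced: PowerLawModel | None = None
    notes: list[str] = field(default_factory=list)


def partition_reactions(
    model: PowerLawModel, theta_threshold: float = DEFAULT_THETA_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split reactions into near-equilibrium and far-from-equilibrium sets
    by thresholding their reference ``theta``."""
    if not 0.0 <= theta_threshold < 1.0:
        raise ValueError(f"theta_threshold must lie in [0, 1), got {theta_threshold}")
    eq = [rid for rid in model.reaction_ids if model.rates[rid].theta >= theta_threshold]
    irr = [rid for rid in model.reaction_ids if rid not in eq]
    return eq, irr


def pool_matrix(seq: np.ndarray) -> np.ndarray:
    """Integer basis of the left null space of the equilibrium block.

    Rows are normalized to smallest non-negative integers (pools read as
    literal metabolite sums) and ordered lexicographically by support.
    An empty equilibrium block yields the identity (reduction is the
    identity map).
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    n = seq.shape[0]
    if seq.size == 0 or seq.shape[1] == 0:
        return np.eye(n)
    basis = sympy.Matrix(seq).T.nullspace()
    if not basis:
        raise ValueError("left null space is zero-dimensional: no pools possible")
    rows = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(e, rational=True))[1] for e in vec]
        scaled = vec * sympy.lcm([sympy.Integer(d) for d in denoms])
        ints = [sympy.Integer(e) for e in scaled]
        g = sympy.gcd([e for e in ints if e != 0])
        ints = [int(e / g) for e in ints]
        first = next(e for e in ints if e != 0)
        if first < 0:
            ints = [-e for e in ints]
        rows.append(ints)
    rows = _make_nonnegative(rows)
    rows.sort(key=lambda r: (tuple(i for i, e in enumerate(r) if e != 0), tuple(r)))
    C = np.array(rows, dtype=float)
    if np.max(np.abs(C @ seq)) > 0:
        raise AssertionError("pooling matrix does not annihilate the equilibrium block")
    return C


def _make_nonnegative(rows: list[list[int]]) -> list[list[int]]:
    """Best-effort integer recombination so every row is non-negative."""
    rows = [list(r) for r in rows]
    for i, r in enumerate(rows):
        if min(r) >= 0:
            continue
        fixed = False
        for j, other in enumerate(rows):
            if i == j:
                continue
            for c in range(1, 8):
                cand = [a + c * b for a, b in zip(r, other)]
                if min(cand) >= 0 and any(cand):
                    rows[i] = cand
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise ValueError(
                "could not normalize a pooling row to non-negative coefficients; "
                "the equilibrium block does not define simple concentration pools"
            )
    return rows


def split_metabolites(
    seq: np.ndarray, metabolite_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Choose free and bound metabolites for the equilibrium constraints.

    Picks as many bound metabolites as there are equilibrium reactions so
    that the bound block of ``Seq^T`` is invertible, preferring
    later-declared metabolites (pathway tail) as bound; falls back to
    column-pivoted selection when the greedy choice is singular.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    n_eq = seq.shape[1]
    ids = list(metabolite_ids)
    if n_eq == 0:
        return ids, []
    if np.linalg.matrix_rank(seq) < n_eq:
        raise ValueError("equilibrium constraints are not independent "
                         "(Seq lacks full column rank)")
    chosen: list[int] = []
    # Greedy reverse-declaration-order selection keeping the bound block full-rank.
    for i in reversed(range(len(ids))):
        trial = chosen + [i]
        sub = seq[trial, :]
        if np.linalg.matrix_rank(sub) == len(trial):
            chosen = trial
        if len(chosen) == n_eq:
            break
    if len(chosen) < n_eq:
        raise ValueError("no invertible free/bound split exists")
    bound = sorted(chosen)
    free = [i for i in range(len(ids)) if i not in bound]
    return [ids[i] for i in free], [ids[i] for i in bound]


def eliminate_bound(
    seq: np.ndarray,
    split: tuple[Sequence[str], Sequence[str]],
    keq: Sequence[float],
    metabolite_ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Bound-metabolite elimination map ``ln x_b = F ln x_f + ln gamma``.

    ``F = (Seq_b^T)^-1 (-Seq_f^T)`` and ``ln gamma = (Seq_b^T)^-1 ln keq``.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    ids = list(metabolite_ids)
    free_ids, bound_ids = (list(split[0]), list(split[1]))
    fi = [ids.index(m) for m in free_ids]
    bi = [ids.index(m) for m in bound_ids]
    Sb_T = seq[bi, :].T
    Sf_T = seq[fi, :].T
    try:
        inv = np.linalg.inv(Sb_T)
    except np.linalg.LinAlgError:
        raise ValueError("bound block of Seq^T is singular")
    F = inv @ (-Sf_T)
    ln_gamma = inv @ np.log(np.asarray(keq, dtype=float))
    return np.exp(ln_gamma), F


# ---------------------------------------------------------------------- #
def reduce_model(
    model: PowerLawModel,
    theta_threshold: float = DEFAULT_THETA_THRESHOLD,
    eq_ids: Sequence[str] | None = None,
) -> tuple[PoolReduction, PowerLawModel]:
    """Thermodynamically shorten a power-law model.

    Near-equilibrium reactions (``theta >= theta_threshold``, or an
    explicit ``eq_ids`` override) are removed; their metabolites collapse
    into pools; every remaining rate is rewritten in pool coordinates by
    substituting the equilibrium share of each pooled metabolite
    (``x_j = share_j * p``), which folds into the rate constant.  Returns
    the bookkeeping object and the reduced model.
    """
    dep = model.dependent_ids
    if eq_ids is not None:
        eq = list(eq_ids)
        irr = [r for r in model.reaction_ids if r not in eq]
    else:
        eq, irr = partition_reactions(model, theta_threshold)
    r_idx = {r: j for j, r in enumerate(model.reaction_ids)}
    seq = model.stoich[:, [r_idx[r] for r in eq]] if eq else np.zeros((len(dep), 0))
    sirr = model.stoich[:, [r_idx[r] for r in irr]]

    if not eq:
        red = PoolReduction(
            eq_reaction_ids=[], irr_reaction_ids=irr, seq=seq, sirr=sirr,
            c=np.eye(len(dep)), pool_ids=list(dep), free_ids=list(dep),
            bound_ids=[], f_matrix=np.zeros((0, len(dep))), gamma=np.zeros(0),
            reduced=model.copy(),
        )
        return red, red.reduced

    C = pool_matrix(seq)
    free_ids, bound_ids = split_metabolites(seq, dep)
    keq_vec = [model.rates[r].keq for r in eq]
    gamma, F = eliminate_bound(seq, (free_ids, bound_ids), keq_vec, dep)

    # Equilibrium ratio of each dependent metabolite to its pool's free
    # reference metabolite; constant only when the elimination exponents are
    # unit, which is what makes the pooled system a power law again.
    ratios = {m: 1.0 for m in free_ids}
    notes = []
    for bi, m in enumerate(bound_ids):
        row = F[bi]
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if len(nz) != 1 or abs(row[nz[0]] - 1.0) > 1e-12:
            raise ValueError(
                f"bound metabolite {m!r} depends on several free metabolites or with "
                f"non-unit exponent; pooled rates would not stay power laws"
            )
        ratios[m] = float(gamma[bi]) * ratios[free_ids[nz[0]]]

    # Pool variables: keep the metabolite id for singleton rows, else p1, p2, ...
    pool_ids, shares = [], {}
    counter = 0
    pool_of: dict[str, tuple[int, float]] = {}
    for pi, row in enumerate(C):
        members = [dep[j] for j in np.flatnonzero(row)]
        if len(members) == 1 and row[dep.index(members[0])] == 1.0:
            pid = members[0]
        else:
            counter += 1
            pid = f"p{counter}"
        pool_ids.append(pid)
        denom = sum(C[pi, dep.index(m)] * ratios[m] for m in members)
        for m in members:
            shares[m] = ratios[m] / denom   # x_m = shares[m] * p
            pool_of[m] = (pi, shares[m])
    unpooled = [m for m in dep if m not in pool_of]
    if unpooled:
        raise ValueError(f"metabolites not covered by any pool: {unpooled}")
    if bound_ids and any(model.rates[r].orders.get(m) for r in irr for m in bound_ids):
        notes.append("pooled metabolites appear in far-from-equilibrium rates; "
                     "their orders were rewritten through the elimination map")

    # Rewrite the far-from-equilibrium rates over pool coordinates.
    red_rates: dict[str, RateLaw] = {}
    for rid in irr:
        rl = model.rates[rid]
        ln_alpha = rl.ln_alpha
        orders: dict[str, float] = {}
        kparts: dict[str, float] = {}
        for mid, g in rl.orders.items():
            if mid in pool_of:
                pi, share = pool_of[mid]
                pid = pool_ids[pi]
                orders[pid] = orders.get(pid, 0.0) + g
                kparts[pid] = kparts.get(pid, 0.0) + rl.kinetic_parts.get(mid, g)
                ln_alpha += g * math.log(share)
            else:
                orders[mid] = g
                kparts[mid] = rl.kinetic_parts.get(mid, g)
        red_rates[rid] = RateLaw(
            ln_alpha=ln_alpha, orders=orders, kinetic_parts=kparts,
            theta=rl.theta, keq=rl.keq,
        )

    red_stoich = C @ sirr
    reduced = PowerLawModel(
        dependent_ids=pool_ids,
        independent_ids=list(model.independent_ids),
        reaction_ids=list(irr),
        rates=red_rates,
        stoich=red_stoich,
        reference=ReferenceState(
            fluxes={r: model.reference.fluxes[r] for r in irr},
            concentrations={
                **{m: model.reference.concentrations[m] for m in model.independent_ids},
                **{pid: 1.0 for pid in pool_ids},  # placeholder, fixed below
            },
            theta={r: model.rates[r].theta for r in irr},
            keq={r: model.rates[r].keq for r in irr},
        ),
    )
    # Anchor the reduced reference at the reduced model's own steady state.
    ss = steady_state(reduced)
    reduced.reference.concentrations.update(ss)
    x = reduced.concentrations()
    reduced.reference.fluxes = {r: reduced.rates[r].value(x) for r in irr}

    red = PoolReduction(
        eq_reaction_ids=eq, irr_reaction_ids=irr, seq=seq, sirr=sirr, c=C,
        pool_ids=pool_ids, free_ids=free_ids, bound_ids=bound_ids,
        f_matrix=F, gamma=gamma, shares=shares, reduced=reduced, notes=notes,
    )
    return red, reduced


def limit_check(
    model_family: Callable[[float], PowerLawModel],
    prop_full: Callable[[PowerLawModel], float],
    theta_grid: Sequence[float],
    prop_reduced: Callable[[PowerLawModel], float] | None = None,
    reduced: PowerLawModel | None = None,
    **reduce_kwargs,
) -> pd.DataFrame:
    """Convergence of a systemic property toward its shortened-model limit.

    Evaluates ``prop_full`` on ``model_family(theta)`` over the grid and
    compares with the property of the reduced model (computed from the
    family member at the largest theta unless ``reduced`` is supplied).
    Columns: ``theta``, ``full``, ``reduced``, ``abs_error``,
    ``monotone`` (single flag column, True when errors are non-increasing
    along the ascending grid).
    """
    theta_grid = sorted(theta_grid)
    if reduced is None:
        _, reduced = reduce_model(model_family(theta_grid[-1]), **reduce_kwargs)
    s_bar = (prop_reduced or prop_full)(reduced)
    rows = []
    for t in theta_grid:
        s = prop_full(model_family(t))
        rows.append({"theta": t, "full": s, "reduced": s_bar, "abs_error": abs(s - s_bar)})
    df = pd.DataFrame(rows)
    err = df["abs_error"].to_numpy()
    df["monotone"] = bool(np.all(np.diff(err) <= 1e-12 + 1e-6 * err[:-1]))
    return df
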