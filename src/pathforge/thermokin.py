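"""Scalar maps between reaction thermodynamics and kinetic orders.

All functions work on a single reaction at a time.  The distance to
equilibrium is ``theta = exp(dg / rt)``; the net forward rate of any
enzyme can be factored as ``kcat * et * (regulatory factors) * (1 - theta)``,
so ``1 - theta`` is the fraction of the maximal rate available as net
flux.  The kinetic order of a rate with respect to a stoichiometric
participant splits into a bounded kinetic part and an unbounded
thermodynamic part ``-s * theta / (1 - theta)``.

Energies are kJ/mol throughout; ``rt`` defaults to R*T at 298.15 K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "RT_DEFAULT",
    "EnzymeSpec",
    "OrderDecomposition",
    "theta",
    "dg_from_theta",
    "thermodynamic_factor",
    "dg_at_fraction",
    "thermo_contribution",
    "kinetic_order",
    "effective_vmax",
    "min_enzyme",
    "elasticity_oracle",
]

#: Gas constant, kJ/(mol*K).
GAS_CONSTANT = 8.314e-3

#: R*T at 298.15 K, kJ/mol (~2.48).
RT_DEFAULT = GAS_CONSTANT * 298.15

# Advisory bound for kinetic parts of allosteric enzymes.
_KINETIC_PART_BOUND = 4.0


@dataclass(frozen=True)
class EnzymeSpec:
    """Forward catalytic constant and enzyme amount; ``vmax = kcat * et``."""

    kcat: float
    et: float

    def __post_init__(self):
        if not self.kcat > 0:
            raise ValueError(f"kcat must be > 0, got {self.kcat}")
        if self.et < 0:
            raise ValueError(f"et must be >= 0, got {self.et}")

    @property
    def vmax(self) -> float:
        return self.kcat * self.et


@dataclass(frozen=True)
class OrderDecomposition:
    """A kinetic order split into kinetic and thermodynamic contributions."""

    kinetic_part: float
    thermo_part: float
    s: float
    theta: float

    @property
    def total(self) -> float:
        return self.kinetic_part + self.thermo_part


def theta(dg: float, rt: float = RT_DEFAULT) -> float:
    """Distance to equilibrium, ``exp(dg / rt)``."""
    if not rt > 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    return math.exp(dg / rt)


def dg_from_theta(t: float, rt: float = RT_DEFAULT) -> float:
    """Inverse of :func:`theta`: the ΔG at which the distance to equilibrium is ``t``."""
    if not t > 0:
        raise ValueError(f"theta must be > 0, got {t}")
    return rt * math.log(t)


def thermodynamic_factor(dg: float, rt: float = RT_DEFAULT) -> float:
    """The factor ``1 - theta`` in [0, 1); requires forward feasibility (dg <= 0)."""
    if dg > 0:
        raise ValueError(f"dg must be <= 0 for a net forward reaction, got {dg}")
    return 1.0 - theta(dg, rt)


def dg_at_fraction(fraction: float, rt: float = RT_DEFAULT) -> float:
    """ΔG at which the enzyme reaches the given fraction of its maximal rate.

    Solves ``1 - theta == fraction``, i.e. ``rt * ln(1 - fraction)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    return rt * math.log(1.0 - fraction)


def thermo_contribution(dg: float, rt: float = RT_DEFAULT) -> float:
    """Magnitude ``theta / (1 - theta)`` of the thermodynamic contribution
    to a kinetic order; diverges as dg -> 0-."""
    if dg >= 0:
        raise ValueError(f"dg must be < 0, got {dg}")
    t = theta(dg, rt)
    return t / (1.0 - t)


def kinetic_order(
    kinetic_part: float, s: float, dg: float | None = None,
    rt: float = RT_DEFAULT, theta_value: float | None = None,
) -> OrderDecomposition:
    """Total kinetic order of a stoichiometric participant.

    ``total = kinetic_part - s * theta/(1-theta)``; ``s`` is the signed
    stoichiometric coefficient.  Either ``dg`` or ``theta_value`` selects
    the operating point; ``theta_value=0`` gives the irreversible case.
    """
    if theta_value is None:
        if dg is None:
            raise ValueError("provide dg or theta_value")
        t = theta(dg, rt)
    else:
        t = theta_value
    if not 0.0 <= t < 1.0:
        raise ValueError(f"theta must lie in [0, 1), got {t}")
    if abs(kinetic_part) > _KINETIC_PART_BOUND:
        warnings.warn(
            f"kinetic part {kinetic_part} exceeds the advisory magnitude bound "
            f"{_KINETIC_PART_BOUND} for allosteric rate laws",
            stacklevel=2,
        )
    tc = t / (1.0 - t) if t > 0 else 0.0
    return OrderDecomposition(kinetic_part=kinetic_part, thermo_part=-s * tc, s=s, theta=t)


def effective_vmax(enzyme: EnzymeSpec, dg: float, rt: float = RT_DEFAULT) -> float:
    """Effective maximal rate ``kcat * et * (1 - theta)`` at the given ΔG."""
    return enzyme.vmax * thermodynamic_factor(dg, rt)


def min_enzyme(flux: float, kcat: float, dg: float, rt: float = RT_DEFAULT) -> float:
    """Minimal enzyme amount sustaining ``flux``: ``flux / (kcat * (1 - theta))``."""
    if dg >= 0:
        raise ValueError(f"dg must be < 0 to carry forward flux, got {dg}")
    if not flux > 0:
        raise ValueError(f"flux must be > 0, got {flux}")
    if not kcat > 0:
        raise ValueError(f"kcat must be > 0, got {kcat}")
    return flux / (kcat * thermodynamic_factor(dg, rt))


def elasticity_oracle(
    rate_fn: Callable[[Sequence[float]], float],
    x0: Sequence[float],
    index: int,
    rel_step: float = 1e-6,
) -> float:
    """Numerical log-log slope of a black-box rate at ``x0``.

    Central difference of ``ln v`` with respect to ``ln x[index]`` using a
    multiplicative step of ``exp(rel_step)``.  Serves as the independent
    oracle for analytic kinetic-order decompositions.
    """
    x0 = np.asarray(x0, dtype=float)
    v0 = rate_fn(x0)
    if not v0 > 0:
        raise ValueError(f"rate must be positive at x0, got {v0}")
    up, dn = x0.copy(), x0.copy()
    up[index] *= math.exp(rel_step)
    dn[index] *= math.exp(-rel_step)
    vu, vd = rate_fn(up), rate_fn(dn)
    if not (vu > 0 and vd > 0):
        raise ValueError("rate must stay positive in the finite-difference stencil")
    return (math.log(vu) - math.log(vd)) / (2.0 * rel_step)
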