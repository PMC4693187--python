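"""Network data model, model file I/O, and fixture generators.

The central object is :class:`MetabolicNetwork`, a validated container of
metabolites and reactions from which the stoichiometric matrix is derived.
Metabolites are either *dependent* (they receive a differential equation)
or *independent* (clamped values, no mass balance).  A
:class:`ReferenceState` records a steady-state operating point: fluxes,
concentrations, per-reaction distances to equilibrium ``theta`` and
apparent equilibrium constants ``keq``, tied together by the consistency
relation ``prod_j x_j**s_ij = theta_i * keq_i``.

Two fixture generators are provided: an unbranched pathway of configurable
length with end-product inhibition, and the three-reaction ammonia
assimilation network (GDH vs. GS/GOGAT).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ReferenceState",
    "NetworkValidationError",
    "load_network",
    "save_network",
    "load_model",
    "save_model",
    "stoichiometric_matrix",
    "make_unbranched_pathway",
    "make_ammonia_network",
    "ammonia_defaults",
    "DEFAULT_CONC_LB",
    "DEFAULT_CONC_UB",
]

# Default concentration box, mol/L (0.1 uM .. 10 mM), overridable per metabolite.
DEFAULT_CONC_LB = 1e-7
DEFAULT_CONC_UB = 1e-2

# Relative tolerance for the theta/keq reference-state consistency check.
_REF_RTOL = 1e-9


class NetworkValidationError(ValueError):
    """Raised when a network or reference state violates its invariants.

    ``violations`` lists every violated invariant, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class Metabolite:
    """A chemical species with a role and a concentration box.

    ``role`` is ``"dependent"`` (balanced, receives an ODE) or
    ``"independent"`` (clamped).  Concentrations are in mol/L and the box
    must admit logarithms: ``0 < conc_lb < conc_ub``.
    """

    id: str
    name: str = ""
    role: str = "dependent"
    conc_lb: float = DEFAULT_CONC_LB
    conc_ub: float = DEFAULT_CONC_UB

    def validate(self) -> list[str]:
        out = []
        if self.role not in ("dependent", "independent"):
            out.append(f"metabolite {self.id!r}: role must be dependent/independent, got {self.role!r}")
        if not (self.conc_lb > 0):
            out.append(f"metabolite {self.id!r}: conc_lb must be > 0, got {self.conc_lb}")
        elif not (self.conc_ub > self.conc_lb):
            out.append(f"metabolite {self.id!r}: conc_ub must exceed conc_lb ({self.conc_lb} >= {self.conc_ub})")
        return out


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry, flux bounds and optional data.

    ``stoich`` maps metabolite id to a signed coefficient (negative for
    substrates, positive for products; zeros are not stored).  ``modifiers``
    maps metabolite id to a regulatory sign (+1 activator, -1 inhibitor)
    for species that affect the rate without appearing in the
    stoichiometry.  ``dg0`` is the standard free energy in kJ/mol.
    """

    id: str
    stoich: Mapping[str, float]
    flux_lb: float = 0.0
    flux_ub: float = 1000.0
    dg0: float | None = None
    modifiers: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> list[str]:
        out = []
        if self.flux_lb > self.flux_ub:
            out.append(f"reaction {self.id!r}: flux_lb {self.flux_lb} > flux_ub {self.flux_ub}")
        if not self.stoich:
            out.append(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in self.stoich.values()):
            out.append(f"reaction {self.id!r}: zero stoichiometric coefficient stored")
        overlap = set(self.stoich) & set(self.modifiers)
        if overlap:
            out.append(f"reaction {self.id!r}: modifiers overlap stoichiometry: {sorted(overlap)}")
        for m, s in self.modifiers.items():
            if s not in (-1, 1):
                out.append(f"reaction {self.id!r}: modifier {m!r} sign must be +1/-1, got {s}")
        return out

    @property
    def substrates(self) -> list[str]:
        return [m for m, s in self.stoich.items() if s < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, s in self.stoich.items() if s > 0]


@dataclass
class MetabolicNetwork:
    """Ordered lists of metabolites and reactions plus optional annotations."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    uptake_id: str | None = None

    # ------------------------------------------------------------------ #
    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def dependent_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.role == "dependent"]

    @property
    def independent_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.role == "independent"]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def validate(self) -> None:
        """Check every invariant; raise :class:`NetworkValidationError` listing all violations."""
        out: list[str] = []
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                out.append(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            out.extend(m.validate())
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                out.append(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            out.extend(r.validate())
            for mid in list(r.stoich) + list(r.modifiers):
                if mid not in seen_m and mid not in self._met_index:
                    out.append(f"reaction {r.id!r} references undeclared metabolite {mid!r}")
        for attr in ("objective_id", "uptake_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self._rxn_index:
                out.append(f"{attr} {rid!r} does not name a declared reaction")
        if out:
            raise NetworkValidationError(out)

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        d = {
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "role": m.role,
                    "conc_lb": m.conc_lb,
                    "conc_ub": m.conc_ub,
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoich": dict(r.stoich),
                    "flux_lb": r.flux_lb,
                    "flux_ub": r.flux_ub,
                    **({"dg0": r.dg0} if r.dg0 is not None else {}),
                    **({"modifiers": dict(r.modifiers)} if r.modifiers else {}),
                }
                for r in self.reactions
            ],
        }
        if self.objective_id is not None:
            d["objective_id"] = self.objective_id
        if self.uptake_id is not None:
            d["uptake_id"] = self.uptake_id
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetabolicNetwork":
        for key in ("metabolites", "reactions"):
            if key not in d:
                raise NetworkValidationError([f"model JSON missing top-level key {key!r}"])
        mets = [
            Metabolite(
                id=str(m["id"]),
                name=str(m.get("name", "")),
                role=str(m.get("role", "dependent")),
                conc_lb=float(m.get("conc_lb", DEFAULT_CONC_LB)),
                conc_ub=float(m.get("conc_ub", DEFAULT_CONC_UB)),
            )
            for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                id=str(r["id"]),
                stoich={str(k): float(v) for k, v in r["stoich"].items()},
                flux_lb=float(r.get("flux_lb", 0.0)),
                flux_ub=float(r.get("flux_ub", 1000.0)),
                dg0=(float(r["dg0"]) if r.get("dg0") is not None else None),
                modifiers={str(k): int(v) for k, v in r.get("modifiers", {}).items()},
            )
            for r in d["reactions"]
        ]
        net = cls(
            metabolites=mets,
            reactions=rxns,
            objective_id=d.get("objective_id"),
            uptake_id=d.get("uptake_id"),
        )
        net.validate()
        return net


@dataclass
class ReferenceState:
    """A steady-state operating point.

    For every reaction that has both ``theta`` and ``keq`` set, the
    concentrations must satisfy ``prod_j x_j**s_ij == theta_i * keq_i``
    to relative tolerance 1e-9, and ``0 <= theta < 1`` for
    forward-operating reactions.
    """

    fluxes: dict[str, float]
    concentrations: dict[str, float]
    theta: dict[str, float] = field(default_factory=dict)
    keq: dict[str, float] = field(default_factory=dict)

    def validate(self, network: MetabolicNetwork) -> None:
        out: list[str] = []
        for rid, t in self.theta.items():
            if not (0.0 <= t < 1.0):
                out.append(f"reaction {rid!r}: theta must lie in [0, 1), got {t}")
        for rid in set(self.theta) & set(self.keq):
            t, k = self.theta[rid], self.keq[rid]
            if t == 0.0:
                continue  # the mass-action quotient constraint degenerates
            rxn = network.reaction(rid)
            try:
                q = math.prod(self.concentrations[m] ** s for m, s in rxn.stoich.items())
            except KeyError as e:
                out.append(f"reaction {rid!r}: reference concentration missing for {e.args[0]!r}")
                continue
            if abs(q - t * k) > _REF_RTOL * abs(t * k):
                out.append(
                    f"reaction {rid!r}: mass-action quotient {q:.12g} != theta*keq {t * k:.12g}"
                )
        if out:
            raise NetworkValidationError(out)

    def to_dict(self) -> dict:
        return {
            "fluxes": dict(self.fluxes),
            "concentrations": dict(self.concentrations),
            "theta": dict(self.theta),
            "keq": dict(self.keq),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceState":
        return cls(
            fluxes={str(k): float(v) for k, v in d.get("fluxes", {}).items()},
            concentrations={str(k): float(v) for k, v in d.get("concentrations", {}).items()},
            theta={str(k): float(v) for k, v in d.get("theta", {}).items()},
            keq={str(k): float(v) for k, v in d.get("keq", {}).items()},
        )


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def load_network(path, format: str = "json") -> MetabolicNetwork:
    """Load a validated network from a model file.

    ``format="json"`` reads the documented model schema (only the
    ``metabolites``/``reactions`` blocks and top-level ids are used here;
    see :func:`load_model` for the full document).  ``format="sbml"``
    imports stoichiometry and flux bounds only and requires cobrapy.
    """
    if format == "json":
        net, _ = load_model(path)
        return net
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def load_model(path) -> tuple[MetabolicNetwork, dict]:
    """Load a full model document: ``(network, extras)``.

    ``extras`` carries the optional blocks of the schema:
    ``reference_state`` (a :class:`ReferenceState`), ``thermodynamics``
    (raw mapping) and ``kinetics`` (raw mapping).
    """
    try:
        with open(path) as fh:
            d = json.load(fh)
    except FileNotFoundError:
        raise FileNotFoundError(f"model file not found: {path}")
    net = MetabolicNetwork.from_dict(d)
    extras: dict = {}
    if "reference_state" in d:
        ref = ReferenceState.from_dict(d["reference_state"])
        ref.validate(net)
        extras["reference_state"] = ref
    if "thermodynamics" in d:
        extras["thermodynamics"] = d["thermodynamics"]
    if "kinetics" in d:
        extras["kinetics"] = d["kinetics"]
    return net, extras


def save_network(network: MetabolicNetwork, path, reference: ReferenceState | None = None,
                 kinetics: Mapping | None = None, thermodynamics: Mapping | None = None) -> None:
    """Write a network (and optional extra blocks) to the JSON schema."""
    network.validate()
    d = network.to_dict()
    if reference is not None:
        d["reference_state"] = reference.to_dict()
    if kinetics is not None:
        d["kinetics"] = dict(kinetics)
    if thermodynamics is not None:
        d["thermodynamics"] = dict(thermodynamics)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)
        fh.write("\n")


save_model = save_network


def _load_sbml(path) -> MetabolicNetwork:
    # Optional interop path: stoichiometry + bounds only.
    try:
        import cobra.io
    except ImportError as e:  # pragma: no cover
        raise ImportError("SBML import requires cobrapy") from e
    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(id=m.id, name=m.name or "", role="dependent")
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoich={m.id: float(c) for m, c in r.metabolites.items()},
            flux_lb=float(r.lower_bound),
            flux_ub=float(r.upper_bound),
        )
        for r in model.reactions
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    net.validate()
    return net


# ---------------------------------------------------------------------- #
# Stoichiometric matrix
# ---------------------------------------------------------------------- #
def stoichiometric_matrix(network: MetabolicNetwork, rows: str = "dependent") -> np.ndarray:
    """Return the stoichiometric matrix S (metabolites x reactions).

    Row order follows metabolite declaration order (restricted to
    dependent metabolites for ``rows="dependent"``); column order follows
    reaction declaration order.
    """
    if rows == "all":
        ids = network.metabolite_ids
    elif rows == "dependent":
        ids = network.dependent_ids
    else:
        raise ValueError(f"rows must be 'dependent' or 'all', got {rows!r}")
    idx = {m: i for i, m in enumerate(ids)}
    S = np.zeros((len(ids), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for m, s in r.stoich.items():
            if m in idx:
                S[idx[m], j] = s
    return S


# ---------------------------------------------------------------------- #
# Fixture generators
# ---------------------------------------------------------------------- #
def make_unbranched_pathway(
    n: int = 3,
    feedback_order: float = -0.5,
    theta: Mapping[int, float] | None = None,
    keq: Mapping[int, float] | None = None,
    kinetic_parts: Mapping[tuple[int, str], float] | None = None,
    flux: float = 1.0,
) -> tuple[MetabolicNetwork, ReferenceState]:
    """Build the unbranched pathway fixture ``X0 -> X1 -> ... -> Xn -> (demand)``.

    ``X0`` (supply) and ``X{n+1}`` (demand signal) are independent; the
    interior metabolites are dependent.  Reaction ``v1`` carries the
    end-product feedback from ``Xn`` with kinetic order ``feedback_order``
    (for ``n == 1`` the feedback target is the product of v1 itself, so
    the order is folded into the kinetic part instead of a modifier).

    ``theta``/``keq`` map step number (1-based, steps 1..n) to the
    distance to equilibrium and apparent equilibrium constant of that
    step; the demand reaction is always irreversible.  ``kinetic_parts``
    maps ``(step, metabolite_id)`` to the non-thermodynamic part of the
    kinetic order and overrides the defaults (0.5 for substrates, 0.0 for
    products, 1.0 for the demand signal).

    The reference state is constructed so the mass-action quotient of
    every step equals ``theta * keq`` exactly, anchored at 1.0 mol/L
    where that leaves freedom, with all fluxes equal to ``flux``.
    """
    if n < 1:
        raise ValueError(f"pathway length n must be >= 1, got {n}")
    theta = dict(theta or {})
    keq = dict(keq or {})
    for i, t in theta.items():
        if not (0.0 <= t < 1.0):
            raise ValueError(f"step {i}: theta must be in [0, 1), got {t}")

    wide = dict(conc_lb=1e-9, conc_ub=1e6)  # fixture anchors at 1.0 mol/L
    mets = [Metabolite(id="X0", role="independent", **wide)]
    mets += [Metabolite(id=f"X{i}", role="dependent", **wide) for i in range(1, n + 1)]
    mets += [Metabolite(id=f"X{n + 1}", name="demand signal", role="independent", **wide)]

    from .thermokin import RT_DEFAULT  # local import to avoid a cycle

    rxns = []
    for i in range(1, n + 1):
        t = theta.get(i, 0.0)
        k = keq.get(i, 1.0)
        rxns.append(
            Reaction(
                id=f"v{i}",
                stoich={f"X{i - 1}": -1.0, f"X{i}": 1.0},
                flux_lb=0.0,
                flux_ub=1000.0,
                dg0=-RT_DEFAULT * math.log(k),
                modifiers=(
                    {f"X{n}": -1} if (i == 1 and feedback_order != 0.0 and n > 1) else {}
                ),
            )
        )
    rxns.append(Reaction(id=f"v{n + 1}", stoich={f"X{n}": -1.0},
                         modifiers={f"X{n + 1}": 1}))

    net = MetabolicNetwork(
        metabolites=mets, reactions=rxns,
        objective_id=f"v{n + 1}", uptake_id="v1",
    )
    net.validate()

    # Reference concentrations: x_i = theta_i*keq_i*x_{i-1} where the step is
    # reversible, anchored at 1.0 where the quotient constraint is inactive.
    conc = {"X0": 1.0}
    for i in range(1, n + 1):
        t = theta.get(i, 0.0)
        conc[f"X{i}"] = t * keq.get(i, 1.0) * conc[f"X{i - 1}"] if t > 0 else 1.0
    conc[f"X{n + 1}"] = 1.0
    for mid, x in conc.items():
        m = net.metabolite(mid)
        if not (m.conc_lb <= x <= m.conc_ub):
            raise ValueError(
                f"theta/keq choice forces {mid} reference concentration {x:g} "
                f"outside bounds [{m.conc_lb:g}, {m.conc_ub:g}]"
            )

    ref = ReferenceState(
        fluxes={r.id: flux for r in rxns},
        concentrations=conc,
        theta={f"v{i}": theta.get(i, 0.0) for i in range(1, n + 1)},
        keq={f"v{i}": keq.get(i, 1.0) for i in range(1, n + 1)},
    )
    ref.validate(net)

    kp = default_kinetic_parts(net, n=n, feedback_order=feedback_order)
    if kinetic_parts:
        for (step, mid), g in kinetic_parts.items():
            kp[(f"v{step}", mid)] = float(g)
    net.kinetic_parts = kp  # attached annotation used by model builders
    return net, ref


def default_kinetic_parts(net: MetabolicNetwork, n: int, feedback_order: float) -> dict:
    """Default kinetic parts for the unbranched fixture: 0.5 per substrate,
    0.0 per product, unit order for the demand signal, ``feedback_order``
    for the end-product loop."""
    kp: dict[tuple[str, str], float] = {}
    for r in net.reactions:
        for mid, s in r.stoich.items():
            kp[(r.id, mid)] = 0.5 if s < 0 else 0.0
        for mid in r.modifiers:
            kp[(r.id, mid)] = 1.0
    if feedback_order != 0.0:
        if n > 1:
            kp[("v1", f"X{n}")] = float(feedback_order)
        else:
            kp[("v1", "X1")] = float(feedback_order)  # product inhibition form
    return kp


# ---------------------------------------------------------------------- #
# Ammonia assimilation fixture
# ---------------------------------------------------------------------- #
_AMMONIA_STOICH = {
    "GDH": {"AKG": -1.0, "NH3": -1.0, "NADPH": -1.0, "GLU": 1.0, "NADP": 1.0},
    "GS": {"GLU": -1.0, "NH3": -1.0, "ATP": -1.0, "GLN": 1.0, "ADP": 1.0, "Pi": 1.0},
    "GOGAT": {"GLN": -1.0, "AKG": -1.0, "NADPH": -1.0, "GLU": 2.0, "NADP": 1.0},
}


def ammonia_defaults() -> dict:
    """Shipped default ΔG° and concentrations for the ammonia fixture.

    These are synthetic, user-supplied placeholder values chosen to
    reproduce the qualitative structure of the case study; replace them
    with literature data for quantitative work.
    """
    with resources.files("pathforge.data").joinpath("ammonia_defaults.json").open() as fh:
        return json.load(fh)


def make_ammonia_network(
    dg0: Mapping[str, float] | None = None,
    conc: Mapping[str, float] | None = None,
    atp_coupling: bool = False,
) -> MetabolicNetwork:
    """Build the ammonia assimilation network (GDH vs. GS/GOGAT).

    Reactions::

        GDH:   AKG + NH3 + NADPH -> GLU + NADP
        GS:    GLU + NH3 + ATP   -> GLN + ADP + Pi
        GOGAT: GLN + AKG + NADPH -> 2 GLU + NADP

    GLU and GLN are dependent; NH3, AKG and the cofactors are clamped
    independent variables whose values come from ``conc`` (defaults ship
    with the package).  A GLU demand reaction ``vGLU`` closes the mass
    balance and is set as the objective.

    With ``atp_coupling=True`` the adenylates become dependent, an ATP
    regeneration reaction ``vATP`` (bounded) is added and the objective
    ``vbio`` consumes GLU + ATP, so flux analysis can see the ATP cost of
    the GS/GOGAT route.
    """
    defaults = ammonia_defaults()
    dg0 = {**defaults["dg0"], **(dg0 or {})}
    conc = {**defaults["concentrations"], **(conc or {})}
    missing = [r for r in ("GDH", "GS", "GOGAT") if dg0.get(r) is None]
    if missing:
        raise ValueError(f"missing dg0 entry for reactions: {missing}")

    dep = {"GLU", "GLN"}
    if atp_coupling:
        dep |= {"ATP", "ADP", "Pi"}
    all_mets = ["GLU", "GLN", "NH3", "AKG", "ATP", "ADP", "Pi", "NADPH", "NADP"]
    mets = [
        Metabolite(
            id=m,
            role="dependent" if m in dep else "independent",
            conc_lb=DEFAULT_CONC_LB,
            conc_ub=DEFAULT_CONC_UB if m != "AKG" else 1e-2,
        )
        for m in all_mets
    ]
    rxns = [
        Reaction(id=rid, stoich=dict(st), flux_lb=0.0, flux_ub=1000.0, dg0=float(dg0[rid]))
        for rid, st in _AMMONIA_STOICH.items()
    ]
    if atp_coupling:
        rxns.append(Reaction(id="vATP", stoich={"ADP": -1.0, "Pi": -1.0, "ATP": 1.0},
                             flux_lb=0.0, flux_ub=10.0))
        rxns.append(Reaction(id="vbio",
                             stoich={"GLU": -1.0, "ATP": -1.0, "ADP": 1.0, "Pi": 1.0},
                             flux_lb=0.0, flux_ub=1000.0))
        objective = "vbio"
    else:
        rxns.append(Reaction(id="vGLU", stoich={"GLU": -1.0}, flux_lb=0.0, flux_ub=1000.0))
        objective = "vGLU"

    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id=objective)
    net.validate()
    net.default_concentrations = dict(conc)  # annotation consumed by the TFA helpers
    return net
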