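# pathforge

Constraint-based flux analysis, thermodynamic feasibility analysis and
power-law (BST) dynamic modeling of small metabolic networks, wired into a
single workflow:

1. **FBA** (`pathforge.fba`) — linear-programming flux analysis in both the
   max-objective and min-uptake formulations, trade-off curves, yields.
2. **TFA** (`pathforge.tfa`) — thermodynamic feasibility constraints
   `ΔG = ΔG° + RT·Sᵀ·ln x ≤ 0`, admissible concentration/ΔG ranges, the
   Max-min Driving Force, and ΔG sweeps over a chosen metabolite.
3. **Thermo-kinetics** (`pathforge.thermokin`) — scalar maps between ΔG and
   kinetics: distance to equilibrium θ, the (1−θ) factor, effective Vmax,
   minimal enzyme, and the decomposition of kinetic orders into bounded
   kinetic parts plus the thermodynamic contribution −s·θ/(1−θ), with a
   numerical elasticity oracle.
4. **BST** (`pathforge.bst`) — power-law models built from a network plus a
   reference state, exact log-linear steady states for S-systems,
   simulation in log space, logarithmic gains, parametric sensitivities,
   Routh–Hurwitz/eigenvalue stability, and feedback stability margins.
5. **Thermodynamic shortening** (`pathforge.shortening`) — pooling of
   metabolites connected by near-equilibrium reactions via the left null
   space of the equilibrium stoichiometric block, equilibrium elimination
   of bound metabolites, and reduced models whose properties are the
   θ→1⁻ limits of the full model's.
6. **MCC** (`pathforge.mcc`) — mathematically controlled comparison:
   internal/external equivalence, thermodynamic consistency constraints,
   the θ-equivalence family, comparison reports and the economic-vs-
   responsive design sweep.
7. **Fixtures** (`pathforge.netcore`) — the network data model, JSON I/O,
   and generators for an unbranched pathway with end-product inhibition
   and the ammonia assimilation network (GDH vs. GS/GOGAT).

Units: concentrations in mol/L, energies in kJ/mol, natural logarithms
throughout; `RT = 8.314e-3 · 298.15 ≈ 2.48 kJ/mol` by default. Default
concentration bounds are 0.1 µM – 10 mM, overridable per metabolite.

## CLI

```bash
pathforge fba max --model m.json --cap 10 --out flux.tsv
pathforge fba tradeoff --model m.json --caps 1,2,5 --out curve.tsv
pathforge tfa mdf --model m.json --fix NH3=1e-3 --out mdf.tsv
pathforge tfa sweep --model m.json --sweep GLN --grid 1e-6:1e-2:50 --out sweep.tsv
pathforge thermo --dg -5 --rt 2.479
pathforge bst steady-state|gains|stability|margin --model m.json --out out.tsv
pathforge shorten --model m.json --threshold 0.99 --out reduced.json --report red.tsv
pathforge mcc compare --reference ref.json --alt alt.json --out report.tsv
pathforge case ammonia --out results/ammonia
pathforge case unbranched --out results/unbranched
```

Every command writes tab-separated tables plus a `manifest.json`
(inputs, options, seed, version); repeated runs are byte-identical.

## Model JSON schema

Top-level keys:

```jsonc
{
  "metabolites": [
    {"id": "X1", "name": "", "role": "dependent|independent",
     "conc_lb": 1e-7, "conc_ub": 1e-2}
  ],
  "reactions": [
    {"id": "v1", "stoich": {"X0": -1, "X1": 1},   // negative = substrate
     "flux_lb": 0, "flux_ub": 1000,
     "dg0": -5.0,                                  // kJ/mol, optional
     "modifiers": {"X3": -1}}                      // regulators not in stoich
  ],
  "objective_id": "v4", "uptake_id": "v1",         // optional
  "reference_state": {                             // optional
    "fluxes": {"v1": 1.0}, "concentrations": {"X1": 1.0},
    "theta": {"v1": 0.0}, "keq": {"v1": 1.0}
  },
  "kinetics": {                                    // optional
    "kinetic_parts": {"v1": {"X0": 0.5, "X1": 0.0, "X3": -0.5}}
  },
  "thermodynamics": {}                             // optional free-form block
}
```

Water/proton activities are assumed absorbed into `dg0`. Independent
metabolites are clamped values (no exchange reactions). SBML import
(`load_network(path, format="sbml")`) reads stoichiometry and bounds only.

The shipped ammonia defaults (`src/pathforge/data/ammonia_defaults.json`)
are synthetic, user-supplied placeholder values; replace them with curated
thermodynamic data for quantitative work.

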