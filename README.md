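# gfd — gas-fermentation strain design for 2,3-butanediol

`gfd` is an in-silico metabolic engineering pipeline for the gas-fermenting
acetogen *Clostridium autoethanogenum*, aimed at designing strains that
overproduce 2,3-butanediol (2,3-BDO) while losing less carbon as CO₂. It is
written for systems-biology practitioners who want the whole workflow —
stoichiometric model QC, flux balance/variability analysis of CO/H₂
feeding, MUST-set intervention enumeration, ensemble kinetic validation and
exact nonparametric screening — as a tested, scriptable Python library.

## What it computes

**Constraint-based layer.** A metabolic network (packaged 70-reaction /
62-metabolite acetogen core model, or any SBML/TSV model) is checked for
consistency (no internal flux and no ATP-maintenance flux with all
exchanges closed), validated against measured gas-fermentation rate tables
by FBA/FVA (max c·v s.t. S·v = 0, lb ≤ v ≤ ub), and scanned over CO×H₂
uptake grids. With CO as the sole substrate the theoretical yield is

    11 CO + 5 H₂O → C₄H₁₀O₂ + 7 CO₂

(two-thirds of the carbon lost to CO₂), while CO + H₂ feeding supports
4 CO + 7 H₂ → C₄H₁₀O₂ + 2 H₂O with no CO₂ loss.

**Strain design.** Flux ranges of the wild type (maximal-growth phenotype)
and of a 2,3-BDO-overproducing phenotype are compared reaction by reaction:
fluxes that must rise (MUST-U), fall (MUST-L) or vanish (MUST-X) become
candidate up-/down-regulations and knockouts. All 1–3-member combinations
are scored by the guaranteed minimum BDO export when forced, and the top
500 are ranked.

**Kinetic layer.** Every core reaction is decomposed into reversible
elementary mass-action steps; per-step reversibilities R_i are sampled with
∏(1/R_i) = exp(−ΔG/RT) inside thermodynamically admissible ΔG ranges, and
rate constants are solved so each member reproduces the reference steady
state exactly. Locally stable members form an ensemble (default 18); each
intervention is simulated at low/medium/high enzyme fold changes
(1.1/1.3/1.5 up, 0.9/0.7/0.5 down, 0 = knockout) across all members, and
the paired 2,3-BDO gains are tested with the exact one-sided Wilcoxon
signed-rank test (all 2ⁿ sign assignments) under per-order Bonferroni
correction at α = 0.01.

## Worked example

```python
from gfd.fixtures import core_network_fixture
from gfd.fba import max_product_stoichiometry
from gfd.design import (DesignSpec, wt_flux_ranges, overproducer_flux_ranges,
                        must_sets, enumerate_interventions)

net = core_network_fixture()
y = max_product_stoichiometry(net, "EX_bdoh", {"EX_co": (-50.0, 0.0)})
print(f"CO per BDO: {y.substrate_per_product['EX_co']:.1f}   CO2 per BDO: {y.co2_per_product:.1f}")

spec = DesignSpec(max_order=1, top_k=5)
wt = wt_flux_ranges(net, spec)
op = overproducer_flux_ranges(net, spec)
m = must_sets(wt, op)
for i, s in enumerate(enumerate_interventions(net, spec, m, wt, op), 1):
    print(f"{i}  {s.key()[0]:12s} guaranteed BDO >= {s.score:.3f} mmol/gCDW/h")
```

prints

```
CO per BDO: 11.0   CO2 per BDO: 7.0
1  ACLDC:up     guaranteed BDO >= 4.183 mmol/gCDW/h
2  ACLS:up      guaranteed BDO >= 4.183 mmol/gCDW/h
3  BTDDx:up     guaranteed BDO >= 4.183 mmol/gCDW/h
4  ACAFDOR:down guaranteed BDO >= 0.000 mmol/gCDW/h
5  ACALDy:down  guaranteed BDO >= 0.000 mmol/gCDW/h
```

The first line is the stoichiometric ceiling on CO-only feeding: 11 mol CO
consumed and 7 mol CO₂ released per mol of 2,3-BDO. The ranked list says
that forcing any single step of the acetolactate branch (ACLS → ACLDC →
BTDDx) to its overproducer flux range guarantees ≈4.2 mmol/gCDW/h of BDO
at the CO/H₂ = 20/33 design point, while relieving competing drains alone
(ACAFDOR, ACALDy down) guarantees nothing by itself — stoichiometry cannot
distinguish them from the ethanol route without the kinetic screen.

A command-line interface mirrors the library: `gfd qc`, `gfd validate`,
`gfd scan`, `gfd design`, `gfd synth`, `gfd ensemble build`, `gfd screen`
(see `gfd --help`).

## Layout

| module | contents |
|---|---|
| `gfd.model` | network/metabolite/reaction types, SBML + TSV + gas-table I/O |
| `gfd.fixtures` | packaged acetogen core network and validation rate table |
| `gfd.fba` | FBA/FVA, consistency QC, condition validation, gas scans, yields |
| `gfd.design` | MUST-set classification and intervention enumeration |
| `gfd.kinetics` | elementary decomposition, thermodynamic sampling, ODE steady states, stability, ensembles |
| `gfd.screen` | fold-change grids, exact signed-rank + Bonferroni screen, H₂ saturation scan |
| `gfd.synth` | reference states, training conditions, oracle toy networks |

See `docs/methods.md` for the modeling assumptions and numerical choices.
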