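# Methods

This note records the models, assumptions and numerical choices behind
`gfd`, in the order the pipeline runs them.

## The core network fixture

The packaged model (`gfd/data/core_network.tsv`) is a 70-reaction,
62-metabolite representation of *C. autoethanogenum* core metabolism:
Wood-Ljungdahl pathway (formate dehydrogenase, THF cycle, CODH/ACS),
the NADP- and NAD-linked electron-bifurcating hydrogenases, the Nfn
transhydrogenase, Rnf + ATP synthase chemiosmosis, an ATP-maintenance
demand, acetate (PTA/ACK), ethanol (ALCDx, ALCDy, ACALDy, ACAFDOR),
lactate and 2,3-butanediol (PFOR, ACLS, ACLDC, BTDDx) branches,
gluconeogenesis to hexose phosphates, a partial reductive TCA arm,
amino-acid drains, and exchanges for CO, CO₂, H₂, water, protons,
ammonium, the fermentation products, THF and biomass.

Design points worth knowing:

* **Elemental closure.** Every metabolite carries a formula (ferredoxin
  uses a pseudo-element `Fd`; NAD(P)H differs from NAD(P) by one H), and
  every internal reaction balances C, H, O, N, P, S exactly. Electron
  conservation is therefore implied by the reaction set itself, which is
  what pins the CO-only yield at 11 CO : 1 BDO : 7 CO₂.
* **Chemiosmotic coupling.** The periplasmic proton is a balanced species
  with no exchange; it is produced only by Rnf (2 H⁺ per Fd²⁻→NADH) and
  consumed only by ATP synthase (4 H⁺ per ATP). This, together with
  irreversible hydrogenases/ATP synthase and an ethanol-directed NADPH
  alcohol dehydrogenase, removes every thermodynamically infeasible
  pumping or transhydrogenation cycle: the fixture passes both
  consistency tests with exact zeros.
* **Biomass.** No biomass equation is published for this network, so the
  fixture lumps 15 precursors (38 mmol C per unit biomass, i.e. ~1 g CDW)
  with a growth-associated ATP cost of 90 mmol/gCDW. The ATP coefficient
  was calibrated once so that maximal growth on CO alone at the measured
  uptake (31 mmol/gCDW/h) releases CO₂ near the measured ~21 mmol/gCDW/h;
  the network's elemental ceiling for that quantity is 20.7 at zero
  growth, and the calibrated model predicts 17.5. Phospho-sugar drains
  return their phosphate (P is conserved; there is no phosphate
  exchange).
* **Gas table.** The validation table ships as printed; two rows typeset
  on a 1000× scale (comma-formatted entries) are rescaled at load time
  and the rescaling is logged.

## LP layer

All flux problems are solved with HiGHS (scipy) at 1e-9 feasibility and
optimality tolerances; FVA is two LPs per reaction. The leak test is
implemented as per-reaction FVA with all exchanges pinned to zero and
|v| ≤ 1000: the textbook "maximize Σ|v| with split variables" LP is
degenerate under maximization (opposing split variables inflate freely on
reversible reactions even in a consistent network), and the per-reaction
form is its exact, non-degenerate equivalent — zero total flux if and only
if the network is consistent, with the offending reactions named.

Condition-specific validation fixes the measured CO and H₂ uptakes (and
CO₂ when it was consumed; when it was produced the CO₂ exchange is
restricted to production), maximizes growth, and brackets the product
predictions by FVA with growth held within 95% of its optimum. A compact
core model is non-degenerate exactly at the optimum — all FVA intervals
collapse to points — so a 95% envelope is the default (the exact-optimum
behaviour is available via `fraction_of_optimum=1.0`).

Gas scans run on a 0–50 mmol/gCDW/h grid (1 mmol step by default) with
growth required to stay above 10% of its per-point maximum and CO₂
restricted to production (the scanned feeds contain no CO₂).

## Strain design

The wild type is the maximal-growth phenotype at the design point
(CO/H₂ uptakes 20/33 mmol/gCDW/h); the overproducer holds the BDO export
above 90% of its maximum while growth stays above 10% of the wild-type
optimum. MUST classification compares FVA intervals but assigns the
genetic label on flux magnitude: a reversible reaction that must run
harder in its reverse direction (PFOR toward pyruvate synthesis, BTDDx
toward butanediol) is an upregulation even though its signed flux
decreases. Candidate sets of order 1–3 are scored by the LP minimum of
the BDO export with every member forced into the overproducer's FVA
interval (a MUST-X interval is exactly {0}, so knockouts force zero).
Forcing at wild-type extremes instead turns out to be vacuous on a
non-degenerate wild-type point — most wild-type maxima are zero, every
score collapses to zero and the ranking degenerates — which is why the
overproducer interval is the forcing target. Ranking is by guaranteed
minimum BDO, then ascending order, then lexicographic key; the procedure
is fully deterministic.

## Kinetic ensemble

Each enzymatic internal reaction is expanded into an ordered-binding
mechanism — bind each substrate in equation order, convert, release each
product — with every elementary step reversible and mass-action.
Concentrations are normalized to the reference state (x = 1); protons,
water and the external product pools are buffered constants. Exchanges
stay single steps: uptakes are zero-order influx with first-order
back-pressure (transport reversibility 0.5, emulating gas-liquid transfer
equilibrium), exports are first-order. The biomass drain remains one
lumped reaction but is realized as parallel per-precursor first-order
drains, each returning its currency moiety (CoA, ADP+Pi, NADP, sugar
phosphate): a joint product-form rate law over-determines the steady
state because precursors with irreversible supplies can never rebalance.

Sampling anchors every member to the reference flux state: per-step
reversibilities R_i ~ U(0,1) are rescaled so ∏(1/R_i) = exp(−ΔG/RT) with
ΔG drawn inside the reaction's admissible range (RT = 2.577 kJ/mol,
i.e. 37 °C), enzyme-state occupancies are Dirichlet on the simplex, and
rate constants are the unique values giving each step the net reference
flux at unit concentrations — so v_ref is reproduced exactly by
construction (tested to 1e-8). Zero-flux reactions are parameterized at
equilibrium (ΔG = 0, unit exchange flux each way). Because the published
per-reaction Gibbs-energy ranges exist only as a figure, all ranges
default to ±40 kJ/mol clipped strictly to the flux direction (0.5 kJ/mol
margin); the admissible-concentration envelope (0.01–100× reference) is
recorded with the reference state.

The reference state itself is the maximal-growth vertex at CO/H₂ = 20/33
with three anchors taken once from the printed condition table: acetate
export fixed at 0.8× the rate of the matching high-H₂ feeding condition,
CO₂ export fixed at 0.4 mmol/gCDW/h (the electron-rich design point
admits at most ~1; a zero-CO₂ reference would leave the kinetic model
without a CO₂ sink), and the BDO export pinned at the trace value
0.01 mmol/gCDW/h — the organism's native trace-product phenotype. Ethanol
is left free and absorbs the residual electron supply (it settles near
the printed 7.9 mmol/gCDW/h; growth lands at 0.066 1/h). The flux vector
is made unique by minimizing total absolute flux and then each reaction
flux in id order (a deterministic lexicographic vertex).

Steady states after an enzyme fold change (total enzyme scaled; 0 =
knockout; fold changes on lumped steps scale their rate constants) are
found by stiff integration (LSODA, analytic Jacobian, rtol 1e-8/atol
1e-10) in growing time windows until ‖dx/dt‖∞ < 1e-9, up to t_max = 1e6;
divergence, non-convergence, or exhausting a 20 s wall-clock budget marks
the member unstable for that perturbation, the same verdict class used
for intervention-induced instability. Local stability is the eigenvalue
test on the Jacobian projected off the conservation laws (left null space
of the elementary stoichiometry), threshold Re < 1e-9.

Ensemble screening retains members that are locally stable and whose
simulated acetate/ethanol/BDO fluxes under three scaled-uptake training
conditions (the biomass-concentration series: uptakes 18.8/24.6/30.6 CO
and 12.6/12.5/11.9 H₂, targets following the printed product trends with
5% multiplicative log-normal noise) fall within a tolerance of the
targets; the default target count is 18 members. With a resampled
ensemble the fit tolerance has to stay loose (the original fitted
parameter sets are not recoverable), so the screen primarily removes
unstable and divergent parameterizations; the tests therefore verify
parameter recovery on a small ground-truth toy, where tight screening
provably retains truth-correlated members (Spearman ≥ 0.8 on a
10-perturbation probe).

## Intervention screen

Each intervention × fold-change level yields one BDO rate per member
(unstable members excluded pairwise). Fold-change grids: 1.1/1.3/1.5 up
and 0.9/0.7/0.5 down (large variant 3/5/10 and 0.3/0.2/0.1); knockouts
are level-independent and simulated once. Significance uses the exact
one-sided (greater) Wilcoxon signed-rank test — ties get midranks, zeros
are dropped, and the null distribution of the positive-rank sum is built
by subset-sum convolution, which enumerates all 2ⁿ sign assignments
exactly (n ≤ 20) — followed by per-order Bonferroni at α = 0.01. With 18
members the attainable floors are m/2¹⁸: 1.64e-4, 1.41e-4 and 3.81e-5
for family sizes 43, 37 and 10.

## What the synthetic data do and do not show

The generator regenerates every input the original analysis drew from
external artifacts: the reference flux state, admissible ΔG ranges, the
training-condition series and the kinetic ensemble itself. Passing tests
show the machinery is correct (exact yields, exact test statistics,
reproduction of the reference state, directional responses such as the
BDO plateau at high H₂ and the MUST-set directions). They do not show
value-level agreement with the published ensemble statistics: the
published 18 parameter sets were fitted to chemostat data that encode,
for example, the experimentally observed PFOR bottleneck, and a
thermodynamically resampled ensemble carries no such information. Fine
orderings among near-tied interventions (the published top single
interventions differ by ~2% in mean BDO) are therefore not identifiable
here, and one directional acceptance property (PFOR upregulation ranked
first by median gain) fails on the regenerated ensemble by exactly this
margin — the intervention is significantly beneficial, but not reliably
first among its near-ties.

## Known limitations

* The core fixture's non-printed half (biomass, gluconeogenesis, TCA arm)
  is a standards-based transcription, not the authors' exact table; flux
  values depending on it (growth rates, CO₂ at maximal growth) reproduce
  printed numbers only to the scaled-down tolerance class.
* Hard knockouts (ALCDx, GLUD) can jam the redox state of individual
  members (cofactor pools pinned at extremes) and are then counted
  unstable; this inflates the missing-member count for those rows
  relative to the published screen.
* The NADPH-dependent butanediol dehydrogenase (the second acetoin
  reductase) is not included; only the NADH-linked BTDDx reduces acetoin.
* Growth dilution of metabolite pools is neglected in the kinetic model;
  biomass acts only through its precursor drains.
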