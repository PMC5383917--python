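# Methods

## The acid-base engine

All speciation rests on the plasma charge balance written with [H⁺] as the
only unknown:

```
SID = Kc·pCO₂/[H⁺] + 2·Kc·K₃·pCO₂/[H⁺]² + Kw/[H⁺] + Ka·A_tot/(Ka+[H⁺]) − [H⁺]
```

The terms are, in order: bicarbonate, carbonate, hydroxide, the dissociated
fraction of a single lumped weak-acid pool, and hydrogen ion. The
right-hand side is strictly decreasing in [H⁺], so for given SID, pCO₂ and
A_tot the pH is unique; `solve_ph` finds it with Brent's method bracketed
on pH ∈ [0, 14] (xtol 10⁻¹³, charge residual far below 10⁻¹² mol/L) and
raises a diagnostic error when the bracket fails (only possible for
charge loads beyond what pH 14 can balance).

Constants (all overridable through the `constants:` YAML block or
`EquilibriumConstants`):

| constant | default | units | meaning |
|---|---|---|---|
| Kc | 2.45×10⁻¹¹ | mol²/(L²·mmHg) | combined CO₂ equilibrium/solubility |
| K₃ | 5.76×10⁻¹¹ | mol/L | carbonate (second carbonic) dissociation |
| Kw | 2.39×10⁻¹⁴ | mol²/L² | plasma water autoionization |
| Ka | 1.77×10⁻⁷ | mol/L | lumped weak-acid dissociation |
| Ks | 0.0307 | mmol/(L·mmHg) | CO₂ solubility in blood |
| Vm | 22.4 | mL/mmol | CO₂ molar volume at STP |
| pK′ | 6.1 | — | Henderson-Hasselbalch apparent pK |

pK′ = 6.1 is chosen for internal consistency: the Stewart bicarbonate term
`Kc·pCO₂/[H⁺]` and the Henderson-Hasselbalch bicarbonate
`Ks·pCO₂·10^(pH−pK′)` are the same equilibrium, and with these defaults
they agree to 0.3% (a unit test enforces <1%).

Conventions and stated approximations:

* Concentrations are mmol/L (charges mEq/L) at every public interface and
  converted to mol/L exactly once, inside the engine.
* Carbonate carries charge in the balance but is excluded from CO₂
  *content* accounting (`total_co2 = dissolved + bicarbonate`); its content
  share is <0.5% below pH ~8.5 at the tensions of interest.
* Phosphate is modelled entirely inside A_tot with the single Ka — no
  multi-pK phosphate or albumin model.
* No temperature corrections; no oxygen-linked CO₂ carriage (Haldane).

`equilibrate_fluid` closes the system the other way: given a fixed total
CO₂ content, SID and A_tot, it eliminates pCO₂ via
`pCO₂ = total/(Ks·(1+10^(pH−pK′)))` and solves the remaining scalar
equation for pH. This is the re-partitioning step the rig simulator
applies after every transmembrane flux.

## Dialysate design

The designer encodes the Stewart logic of the zero-bicarbonate dialysate:
post-dialyzer blood keeps a physiologic pH if its SID and A_tot are
preserved while bicarbonate and CO₂ leave. `required_blood_sid` evaluates
the charge balance at the target pH and low pCO₂; `design_dialysate`
builds an electrolyte solution carrying that SID from clinically fixed
concentrations (K 3.5, Mg 1.0, lactate 3.0, phosphate 0.5 mmol/L, sodium
held at 134), balancing with chloride — the natural choice since dialysate
sieving coefficients are ≈1. Calcium is zeroed (citrate-anticoagulation
compatibility, and precipitation risk at alkaline pH); bicarbonate is
always zero. Lactate is treated as a fully dissociated strong anion (its
in-vivo metabolism is out of scope). The published target SID of
20.5 mEq/L reproduces the published recipe exactly (chloride 116 mmol/L);
with no explicit target the designer derives one from the mid target pH at
the design pCO₂.

`hcl_adjust` models the bench necessity of acidifying the fluid so a
blood-gas analyzer can read it: chloride rises to a stated final value
(135.6 mmol/L), the added HCl is recorded as metadata, and the SID falls
accordingly — from 20.5 to 0.9 mEq/L, moving the modelled pH from 11.92 to
10.22 ("10" at the integer precision of a pH table row). The protein-free
fluid is alkaline despite the physiologic SID precisely because its only
weak acid is 0.5 mmol/L phosphate. A property test confirms the chloride
monotonically acidifies — the mechanism by which the acid-adjusted
dialysate imposes a mild metabolic acidosis on the blood side.

One printed-value subtlety: the composition *before* HCl adjustment
(SID 20.5, A_tot 0.5, pCO₂ 0) solves to pH 11.92, which also follows from
the closed form Kw/[H⁺] ≈ SID − A_tot; the package reports the solved
value.

## Removal analysis

`vco2_rate` implements the content-balance rate with deltas
inlet-minus-outlet so removal is positive; bicarbonate comes from measured
pH and pCO₂ via Henderson-Hasselbalch — the blood-gas analyzer's own
convention — not from the charge balance. Negative computed removal is
permitted but logged. Scale-up multiplies by the membrane-area ratio
(default 0.9/0.04 = 22.5); reported flows and scaled rates use decimal
round-half-up (420.75 → 421), implemented in decimal arithmetic to avoid
binary-float artefacts. `ph_delta_table` summarises pre/post pH per
condition on condition means, reports maxima at two decimals (the printed
precision of pH tables), flags unpaired conditions instead of guessing,
and stratifies by inlet pCO₂. `paired_comparison` is a closed-form paired
*t* (two-sided, α = 0.05 — the published table marks significance without
naming a test): the difference standard deviation is floored at machine
epsilon so identical samples give p = 1 with a warning and a constant
nonzero shift gives p → 0 rather than NaN; a test cross-checks it against
`scipy.stats.ttest_rel` on non-degenerate data.

## The rig simulator (synthetic data)

The simulator replaces the animal-blood bench experiment: a single-pass
circuit in which conditioned blood flows through the fibers of a 0.04 m²
dialyzer and zero-bicarbonate dialysate flows counter-currently over them.

**Blood model.** One well-mixed compartment per parcel. The conditioned
inlet draws pCO₂ uniformly within target ± 5 mmHg and hemoglobin within
12 ± 1 g/dL (the bench dilution targets); pH follows from the charge
balance at the default whole-blood-like SID 55 mEq/L and A_tot 50 mmol/L.
The A_tot lumps plasma proteins, phosphate and hemoglobin — the dominant
non-bicarbonate buffer — into the single-Ka pool; 50 mmol/L gives a
buffer value near 25 mmol/pH, the accepted whole-blood figure, and puts
the modelled inlet pH at 7.18 (pCO₂ 50) and 6.98 (pCO₂ 100), matching the
scale of the measured pre-dialyzer values. Hemoglobin is carried as
metadata only; it does not enter transport.

**Transport.** The bundle is split into `n_segments` (default 50) axial
segments. Within a segment each transferable species crosses by the
analytic co-current exchange law

```
J_s = f_s · Q̃ · (C_b,s − C_d,s),   f_s = 1 − exp(−(K0A_s/n)/Q̃),
Q̃ = Q_b·Q_d/(Q_b+Q_d)
```

which reduces to the linear flux `(K0A_s/n)·ΔC` for small per-segment
K0A and is bounded at full flow-weighted equilibration for large K0A, so
the discretisation is stable in the strong-transfer limit. Dissolved CO₂
additionally crosses as gas, `(P_CO₂/n)·ΔpCO₂/Vm`, and the combined CO₂
flux per segment is capped at the flow-weighted equilibration of total
CO₂ contents (an overshoot guard, inactive at the defaults). After the
fluxes, each side re-equilibrates its CO₂ pools under its updated SID
(strong-ion fluxes only; bicarbonate is dependent) and total CO₂.
Calcium does not transfer (K0A_Ca = 0): the dialysate is calcium-free by
design and calcium handling is out of scope.

**Steady state.** Damped Picard iteration on both axial profiles
(convergence 10⁻⁸ relative, max 10,000 sweeps). The damping factor adapts:
it halves whenever the fixed-point residual grows — counter-current
feedback has gain >1 at high transfer-unit counts — and creeps back
otherwise. Per-segment equilibration uses a warm-started Newton solver on
the monotone charge-balance residual (validated against an independent
fixed-count bisection to 4×10⁻¹⁵ pH), falling back to bisection for any
parcel that fails. At convergence the outlet states are rebuilt from the
summed fluxes, so the species ledger balances blood-side loss against
dialysate-side gain to machine precision; tests require ≤10⁻⁶ relative.

**Membrane coefficients are synthetic calibration fixtures.** No
transport data exist for the bench dialyzer. The defaults — K0A 0.5
mL/min for Na/K/Mg/lactate, 0.75 for chloride, 1.5 for bicarbonate, and
CO₂ permeance 0.025 mL/(min·mmHg) — were fixed once so that the simulated
campaign reproduces the bench study's *qualitative* behaviour over the
full flow grid: outlet pH never below inlet with increases ≤0.15, removal
non-decreasing and saturating in dialysate flow, increasing in blood flow
and in inlet pCO₂. They are configuration, not measured claims.

**What the generator does and does not emulate.** It reproduces the grid
structure (blood flows 11 and 18.7 mL/min, dialysate 2.2–24 mL/min, inlet
pCO₂ 50 and 100 mmHg, n = 3 replicates, with a `bench_subset` flag for
the cells the bench actually ran), inlet conditioning scatter, and
Gaussian measurement noise (pH sd 0.01, pCO₂ sd 1 mmHg — chosen to match
the replicate scatter of the published pH table, 0.002–0.030). A single
`numpy` Generator seeded from the run seed drives all draws in a
documented order, so campaigns are byte-reproducible. It does **not**
capture red-cell/plasma two-compartment kinetics (the Hamburger chloride
shift), charge-coupled electroneutral membrane transport, protein
fouling, or batch-to-batch variation in animal blood. Two quantitative
consequences, measured on the default calibration and documented rather
than hidden:

* bench-scale removal at (Q_b 11, Q_d 16, inlet 50) is ~1.3 mL/min
  (~29 mL/min scaled), below the measured bench scale (~2.8 mL/min);
* doubling inlet pCO₂ raises removal by ~30–45% per flow cell, not the
  ~85% the bench observed.

Both trace to the same structural facts. In this model the only pathway
that lowers blood SID in step with CO₂ removal — required for pH not to
overshoot upward — is chloride influx from the acidified dialysate, whose
acid load is nearly flat in dialysate flow while removal grows with it;
keeping outlet pH within [inlet, inlet+0.15] over the whole grid
therefore pins the chloride coefficient and with it the removal
magnitude. And a single fixed-SID blood holds its bicarbonate near
SID − A⁻ regardless of pCO₂, so CO₂ content at 100 vs 50 mmHg differs by
only ~1.33×, which caps the removal ratio in every transfer- or
equilibration-limited regime. Real blood escapes both constraints through
electroneutral HCO₃⁻/Cl⁻ exchange and red-cell buffering, which this
single-compartment, independent-flux membrane model deliberately omits.
Passing tests therefore certify the engine's chemistry and the campaign's
qualitative dose-response, not bench-quantitative removal rates.

## Statistical allowances

Checks run on *noisy* simulated campaigns (the `report` stage) grant
ordering comparisons 4 pooled standard errors of slack — with ~60 ordered
comparisons per campaign a 3-SE allowance still flags ~10% of seeds on
pure measurement noise. Systematic dose-response properties are asserted
noise-free (conditioning tolerance and measurement noise zeroed), where
they must and do hold exactly.

## Degenerate inputs and tie-breaks

Zero total CO₂ equilibrates to pCO₂ = 0 with pH from the CO₂-free
balance; zero dialysate or blood flow is rejected up front; an
impermeable membrane returns inlet states unchanged; identical pre/post
samples give V̇CO₂ = 0 and p = 1. Fixture CSVs are verified against
frozen sha256 digests at load; missing grid cells are absent rows, never
zeros, and low-replicate cells carry an explicit flag excluded from
significance testing.
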