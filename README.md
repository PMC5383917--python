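# respdial

Physicochemical acid-base modelling and CO₂-removal analysis for
**respiratory hemodialysis** — removing carbon dioxide from blood with an
ordinary hemodialyzer and a bicarbonate-free dialysate instead of a
membrane lung.

## The problem

Hypercapnic patients (ARDS on ultra-protective ventilation, COPD
exacerbations) need CO₂ cleared from the bloodstream. Conventional
extracorporeal CO₂ removal targets *dissolved* CO₂, which is <10% of the
blood's CO₂ content; most CO₂ travels as bicarbonate. A dialyzer fed with
a zero-bicarbonate dialysate removes the bicarbonate itself — but naïvely
stripping bicarbonate causes metabolic acidosis.

Stewart's physicochemical framework resolves the design problem: plasma pH
is determined by the strong ion difference (SID), the CO₂ tension and the
total weak-acid pool A_tot, with bicarbonate a *dependent* variable,

```
SID = Kc·pCO₂/[H⁺] + 2·Kc·K₃·pCO₂/[H⁺]² + Kw/[H⁺] + Ka·A_tot/(Ka+[H⁺]) − [H⁺]
```

so a dialysate that preserves the blood's SID and A_tot lets bicarbonate
leave without dropping pH. Bicarbonate content itself follows
Henderson-Hasselbalch, `[HCO₃⁻] = Ks·pCO₂·10^(pH−pK′)`, and the removal
rate across the dialyzer is

```
V̇CO₂ = (Δ[HCO₃⁻] + ΔpCO₂·Ks) · Q_b · V_m        [mL STP/min]
```

with deltas taken inlet-minus-outlet, `Q_b` the blood flow in L/min,
`Ks = 0.0307 mmol/(L·mmHg)` and `V_m = 22.4 mL/mmol`. Bench measurements
on a 0.04 m² dialyzer project to a clinical 0.9 m² device by the
membrane-area ratio 0.9/0.04 = 22.5.

## What the package provides

* `respdial.chemistry` — the Stewart engine: forward charge balance,
  unique-root pH solving, Henderson-Hasselbalch speciation, and
  closed-system re-equilibration of a fixed CO₂ content.
* `respdial.dialysate` — the zero-bicarbonate dialysate designer: derive
  the target SID from a post-dialyzer blood condition, balance chloride
  against clinically fixed ions, apply the HCl acidification, and report
  the modelled dialysate pH.
* `respdial.removal` — V̇CO₂ from paired pre/post blood gases,
  bench↔clinical scale-up, pH-delta summaries, paired *t* statistics.
* `respdial.rig` — a synthetic single-pass bench rig: counter-current
  segmented dialyzer with per-species mass transfer and CO₂ gas
  permeation, generating replicate blood-gas datasets with measurement
  noise.
* `respdial.fixtures` — the published dialysate recipe and pre/post pH
  grid as checksummed packaged CSVs.
* `respdial.cli` — `respdial design-dialysate | ph | vco2 | simulate |
  report`.

## Worked example

```python
from pathlib import Path
from respdial.io import RunConfig
from respdial.report import run_report

run_report(RunConfig(outdir=Path("demo"), bench_subset=True, seed=1))
print(Path("demo/summary.txt").read_text())
```

prints

```
respdial 0.1.0 report

designed dialysate SID: 20.5 mEq/L (pH 11.92 at pCO2 0)
after HCl adjustment:   0.9 mEq/L (pH 10.22, reported 10 at integer precision)

published pH grid: max pH increase 0.08 (qb11_qd24_in100)
  inlet 50 mmHg stratum: max 0.07 (qb11_qd16_in50)
  inlet 100 mmHg stratum: max 0.08 (qb11_qd24_in100)

simulated campaign checks:
  [PASS] VCO2 non-decreasing in dialysate flow (4 SE slack)
  [PASS] outlet pH never below inlet pH (4 SE slack)
  [PASS] pH increase <= 0.15 (4 SE slack)
  [PASS] VCO2 increases with blood flow (4 SE slack)
  [PASS] doubling inlet pCO2 raises VCO2 by 28%
```

Reading the numbers: balancing chloride against the clinically fixed ions
(Na 134, K 3.5, Mg 1.0, lactate 3.0, phosphate 0.5 mmol/L) for a target
SID of 20.5 mEq/L gives chloride 116 mmol/L; because the fluid has almost
no weak acid, its modelled pH is strongly alkaline. Acidifying with HCl to
chloride 135.6 mmol/L (so a blood-gas analyzer can read it) drops the SID
to 0.9 mEq/L and the modelled pH to 10.22 — 10 at the integer precision a
pH meter row reports. The pH-grid analysis of the packaged bench table
finds the largest post-minus-pre blood pH increase, 0.08, at blood flow
11 mL/min, inlet pCO₂ 100 mmHg, dialysate flow 24 mL/min (0.07 within the
50 mmHg conditions), and no condition with a pH drop. The simulated
campaign (`demo/gases.csv`, `demo/removal.csv`) reproduces those
behaviours: removal grows and saturates with dialysate flow, grows with
blood flow and with inlet pCO₂, and outlet pH never falls below inlet.

The same steps are available from the shell:

```bash
respdial design-dialysate --out dialysate.csv
respdial simulate --out gases.csv --bench-subset --seed 1
respdial vco2 --in gases.csv --out removal.csv
```

## Limitations

The rig simulator's membrane coefficients are synthetic calibration
fixtures (no transport data exist for the bench dialyzer), and the blood
is a single well-mixed compartment with a lumped single-pK′ buffer pool;
see `docs/methods.md` for what the model does and does not capture.
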