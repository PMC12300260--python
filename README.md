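# sultpbpk

Pediatric physiologically based pharmacokinetic (PBPK) modelling of
intravenous acetaminophen (APAP) with explicit sulfotransferase (SULT)
enzyme ontogeny.

Acetaminophen is cleared in the liver by three enzyme families —
glucuronidation (UGT1A1/1A9/2B15), sulfation (SULT1A1/1A3/1E1/2A1) and
oxidation (six CYPs) — plus renal filtration. In neonates the UGT and CYP
routes are immature and sulfation dominates, which makes neonatal exposure,
and its sensitivity to anything that perturbs SULT activity, qualitatively
different from older children and adults. This package is for modellers and
clinical pharmacologists who want an open, testable implementation of that
analysis: how enzyme-abundance ontogeny propagates through in vitro–in vivo
extrapolation (IVIVE) into age-dependent clearance, plasma exposure, and
drug–drug-interaction (DDI) risk.

## What it computes

1. **Ontogeny regression** (`sultpbpk.ontogeny`). Enzyme abundance
   *A*(age) in pmol/mg cytosolic protein is modelled by candidate forms
   (exponential, Hill, logistic, two- and three-phase piecewise-linear)
   fitted by unweighted least squares with free breakpoints; the Akaike
   information criterion, AIC = *n* ln(RSS/*n*) + 2(*k*+1), selects the form.
   The fitted three-phase curves for SULT1A1, SULT1A3, SULT2A1 and SULT1B1
   ship as the built-in library, e.g. for SULT1A1:
   *A* = 107.8 + 88.6·age below 1.83 y, 370.1 + 6.99·(age−1.83) up to
   12.6 y, then a 445.2 plateau.

2. **IVIVE clearance** (`sultpbpk.ivive`). Per-pathway intrinsic clearance
   CLint,*i* = Vmax,*i*·rel*ᵢ*(age) / (Km,*i* + Cu), scaled by protein per
   gram of liver (microsomal or cytosolic pool), liver weight, and an
   empirical hepatic scalar, enters the well-stirred liver model
   CLh = Q·fu·CLint/(Q + fu·CLint); renal clearance scales the adult value
   by a GFR maturation fraction. A single middle-out calibration factor
   anchors the adult clearance to the compound's reference CL_IV.

3. **Population simulation** (`sultpbpk.engine`). A minimal PBPK model
   dA/dt = R_in(t) − [CLh(C) + CLr]·C with V = Vss·BW, integrated per
   subject over repeated infusion trials with log-normal inter-individual
   variability on pathway activity and Vss.

4. **NCA verification** (`sultpbpk.nca`). Cmax, AUC(0–∞), AUC(0–τ) by
   linear-up/log-down trapezoid with terminal-slope extrapolation, compared
   against observed clinical summaries with the fold-error rule
   (predicted/observed within 0.5–2.0).

5. **DDI sensitivity** (`sultpbpk.sensitivity`). Km (competitive
   inhibition) and Vmax (mechanism-based inhibition/induction) sweeps on the
   SULT pathways, reported as AUC and Cmax ratios per age group.

## Worked example

```python
import sultpbpk as sp
from sultpbpk.engine import pediatric_regimen
from sultpbpk.nca import population_exposure

model = sp.PBPKModel(sp.apap())          # compound + default physiology

# pathway contributions to total clearance in a 7-day-old neonate
breakdown = model.clearance.fm_breakdown(7 / 365.25)
print({k: f"{100*v:.1f}%" for k, v in breakdown.fm_by_category().items()})

# neonatal trial simulation: 12.5 mg/kg 15-min infusions Q4h for 48 h,
# 10 trials x 2 subjects
regimen = pediatric_regimen("neonate", "table")
pop = model.simulate_population("neonate", regimen, 2, trials=10, seed=1)
print(population_exposure(pop, tau=regimen.interval).round(2))
```

prints

```
{'SULT': '59.4%', 'UGT': '27.7%', 'CYP': '4.2%', 'renal': '8.7%'}
population parameter  value   sd   low  high statistic
   neonate      cmax  25.11 1.92 22.36 28.36    median
   neonate       auc  66.04 4.97 58.51 73.08    median
```

Sulfation carries ~59% of neonatal APAP clearance (glucuronidation ~28%,
oxidation and renal excretion minor), and the simulated neonatal steady-state
exposure (median Cmax 25.1 µg/mL, AUC(0–τ) 66.0 µg·h/mL) sits within
1.3-fold of the observed clinical medians (19.9 µg/mL and 65.6 µg·h/mL).
By age 7 the balance inverts: glucuronidation reaches ~47% and sulfation
falls to ~38%.

The same workflows are available from the shell:

```bash
sultpbpk fm --ages 0.02,1,7,25
sultpbpk verify --seed 0 --convention table
sultpbpk sensitivity --pathway SULT1A1 --parameter km
sultpbpk ontogeny-fit abundance.csv --forms piecewise3,hill
```

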