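# ebpr

Analysis toolkit for enhanced biological phosphorus removal (EBPR) cultures:
measurement-to-metabolism inference for enriched polyphosphate-accumulating
organism (PAO) cultures run in sequencing batch reactors (SBRs), plus a
synthetic reactor generator that provides exact ground truth for every
estimator in the package.

## The science

PAOs remove phosphorus from wastewater through a two-stage storage metabolism.
Anaerobically — with acetate present but no electron acceptor — they take up
acetate and store it as polyhydroxyalkanoates (PHB and PHV), paying the ATP
cost from two internal reserves: hydrolysis of poly-phosphate (released to the
medium as orthophosphate) and glycolysis of stored glycogen. Aerobically they
burn the PHA to regrow, replenish glycogen, and take phosphate back up into
poly-P — more than they released, which is what removes P from the water.

How much of the anaerobic ATP comes from poly-P versus glycogen is not fixed.
A culture rich in poly-P shows the classical PAO signature (high P release per
acetate, little glycogen use); the same organisms, stripped of poly-P, shift
to a glycogen-driven metabolism that looks like their nominal competitors, the
glycogen-accumulating organisms (GAOs). The influent phosphorus-to-carbon
(P/C) ratio sets where on this continuum a culture sits, and the shift is
gradual and reversible rather than a switch between two discrete phenotypes.

The package turns routine measurements into the quantities that describe this
continuum:

- **`ebpr.chemistry`** — medium recipes (salt masses per litre) to molar
  acetate carbon, theoretical COD, ammonium, phosphate and the influent P/C
  ratio, from chemical formulas alone.
- **`ebpr.polyp`** — two independent poly-P estimators: from the ash content
  of the sludge (poly-P dominates the inorganic solids above a small baseline)
  and from the reactor's steady-state P balance, with a cross-validation
  verdict and the assumptions to suspect when they disagree.
- **`ebpr.biomass`** — active biomass by difference (VSS minus storage
  polymers), elemental compositions, degrees of reduction, and C-mol unit
  conversions; all rates and ratios are normalized per C-mol active biomass.
- **`ebpr.cycles`** — cycle-test analysis: maximum acetate-uptake and
  P-release rates from initial linear segments, endogenous (maintenance) P
  release from the substrate-free anaerobic tail, and the anaerobic
  stoichiometric ratios (P/HAc, gly/HAc, PHB/HAc, PHV/HAc) from begin/end
  panels, corrected for maintenance release.
- **`ebpr.shift`** — the metabolic-shift model: the ATP-source partition
  `alpha` computed from P/HAc and gly/HAc, and a two-end-member mixing model
  that places any observed stoichiometry at a coefficient `lam` between the
  poly-P-depleted and poly-P-saturated patterns measured on the same culture.
  Carbon and electron closure are reported as residuals, never enforced.
- **`ebpr.synthetic`** — a semi-mechanistic SBR simulator (2.5 L working
  volume, 1.25 L exchange, 6-h cycles, SRT 8 d; the 12-h HRT *emerges* from
  that geometry). It produces noiseless or noisy cycle tests and multi-phase
  long-term trajectories with exact internal mass ledgers, so every estimator
  can be validated against known truth.
- **`ebpr.reference`** — published kinetic/stoichiometric reference values for
  a long-term clade-IIC PAO enrichment across influent P/C ratios, used to
  anchor the mixing-model end members and as consistency fixtures.

## Worked example

Simulate to steady state at the enrichment condition, run one cycle test with
2% measurement noise, and analyze it (`examples/analyze_cycle.py`):

```python
from ebpr import (NoiseModel, SBRConfig, analyze_cycle,
                  simulate_cycle, simulate_to_steady_state)

config = SBRConfig()
steady, _ = simulate_to_steady_state(config, phase_schedule=[(0, 0.64)])
res = simulate_cycle(steady[0].state, config, phosphate_mmol=0.64,
                     noise=NoiseModel(seed=7))
rates, stoich = analyze_cycle(res.profile)
```

Output:

```text
                     estimated   true
qSA  (C-mmol/C-mol/h):   192.2    198.0
qP   (P-mmol/C-mol/h):    77.7     81.0
mP   (P-mmol/C-mol/h):    1.83     2.50
P/HAc   (P-mol/C-mol):    0.42     0.41
gly/HAc (C-mol/C-mol):    0.73     0.78
PHB/HAc (C-mol/C-mol):    1.06     1.05
PHV/HAc (C-mol/C-mol):    0.19     0.19
```

Driving the reactor through the six-phase influent-P schedule
(`examples/simulate_sbr.py`) shows the shift and its reversibility:

```text
phase  P/C    cycles  ISS/TSS  polyP/X (P-mol/C-mol)  effluent P (mmol/L)
  0   0.051    319    0.319        0.145               0.000
  1   0.038    300    0.252        0.102               0.000
  2   0.076    309    0.424        0.229               0.000
  3   0.114     46    0.489        0.300               0.212
  4   0.038    349    0.252        0.102               0.000
  5   0.051    289    0.319        0.145               0.000
```

The ash fraction of the solids rises monotonically with influent P/C and
returns to its earlier values when the dose steps back down; phosphate breaks
through to the effluent only once poly-P storage saturates at the highest
dose.

The other examples: `examples/characterize_influent.py` (medium recipe to
molar composition), `examples/estimate_polyp.py` (the two poly-P routes and
their cross-check), `examples/shift_analysis.py` (alpha and lam across the
published reference conditions).

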