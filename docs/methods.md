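# Methods note

This note documents the models implemented in `ebpr`, the assumptions they
make, the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that affect
results. All empirical numbers quoted here are computed by the test suite or
by `scripts/acceptance.py`.

## 1. Influent chemistry (`ebpr.chemistry`)

A medium is a list of salts with mass concentrations (mg/L). Molarities are
derived from parsed chemical formulas and a fixed atomic-mass table (IUPAC
2021 standard atomic weights, abridged to two decimals — enough for recipes
stated in whole milligrams, and bit-stable across platforms). The formula
grammar supports element counts, one level of parenthesised groups with a
multiplier, and one trailing `.nH2O` hydrate suffix; nested parentheses are
rejected. The grammar is sized to mineral-salt recipes, which is why it is
hand-written rather than pulled from a general chemistry library.

Theoretical COD uses registered full-oxidation stoichiometries (acetate in
its common salt forms: 2 mol O2 per mol); other organics require an explicit
`o2_per_mol`. The built-in acetate medium (860 mg/L sodium acetate
trihydrate, 107 mg/L NH4Cl, Mg/Ca/K salts, phosphate dosed by molarity)
characterizes to 12.64 C-mmol/L acetate, 404 mg/L COD and 2.00 N-mmol/L. The
influent P/C ratio is rounded to 3 decimals by default — the precision the
phase schedule is tabulated at.

The six-phase phosphate schedule (0.64, 0.48, 0.96, 1.44, 0.48, 0.64
P-mmol/L) maps to influent P/C ratios 0.051, 0.038, 0.076, 0.114, 0.038,
0.051 P-mol/C-mol.

## 2. Poly-P estimators (`ebpr.polyp`)

**Ash route.** Poly-P with its Mg/K counterions dominates the inorganic
suspended solids (ISS) above the small baseline ash of ordinary biomass:

    polyP [mg P/L] = (ISS − f_ISSb,TSS/(1 − f_ISSb,TSS) · VSS) · f_P,ppISS

Defaults: `f_ISSb,TSS = 0.025` (baseline ash fraction of non-EBPR biomass)
and `f_P,ppISS = 0.31`, the phosphorus mass fraction of the repeating unit
`(PO3)3MgK` (computed: 0.3094). The constructor rejects an `f_P,ppISS`
inconsistent with the configured repeating-unit formula by more than 0.005.

**Mass-balance route.** At steady state the P retained in the sludge equals
SRT/HRT times the influent-to-effluent P drop; subtracting organically bound
biomass P (`f_P,bVSS = 0.023` mg P/mg VSS) leaves poly-P.

Both estimators clamp negative results to zero and attach a flag
(`below_ash_baseline`, `balance_inconsistent`) instead of raising: transient
or depleted panels are legitimate inputs. `cross_validate` reports the
relative discrepancy against the mean of the two and, on failure at the 10%
default tolerance, the assumptions to suspect (effluent solids, chemical P
precipitation, counterion composition, baseline constants).

## 3. Biomass accounting (`ebpr.biomass`)

Active biomass is VSS minus PHB, PHV and glycogen — unbiodegradable
endogenous residue is neglected. The elemental composition
CH2.09O0.54N0.20P0.015 (26.02 g/C-mol) converts mass to C-mol; glycogen uses
the anhydroglucose unit (27.02 g/C-mol), PHB and PHV their polyester monomer
formulas (21.52 and 20.02 g/C-mol). Degrees of reduction follow
γ = 4 + h − 2o − 3n + 5p per C-mol (acetate 4.0, glycogen 4.0, PHB 4.5,
PHV 4.8). Undefined ratios (zero denominators) are reported as `None`, never
as 0.

## 4. Cycle-test analysis (`ebpr.cycles`)

Rates come from initial linear segments. The fit window is the longest
initial run of samples with linear-fit R² ≥ 0.98 while acetate stays above
10% of its initial value (minimum 3 points; if nothing passes R², the
shortest window is reported best-effort with its R²). The P-release fit is
restricted to the same acetate-present window so post-exhaustion maintenance
release cannot dilute the slope. The maintenance rate itself is fitted on the
tail where acetate is below 5% of its initial value; glycogen maintenance is
deliberately not estimated (the per-cycle change is below assay resolution).

Stoichiometric ratios come from begin/end deltas of the anaerobic phase. The
measured P release is corrected by subtracting the extrapolated maintenance
release over the post-exhaustion interval, using the fitted uptake slope to
locate the exhaustion time; on noiseless data this correction is exact.
Negative polymer formation is flagged and reported as measured, not clipped.

## 5. Metabolic-shift model (`ebpr.shift`)

Two complementary summaries:

- **ATP partition.** `alpha = y_pp·(P/HAc) / (y_pp·(P/HAc) + y_gly·(gly/HAc))`
  with `y_pp = 1` mol ATP per P-mol poly-P and `y_gly = 0.5` mol ATP per
  C-mol glycogen (glycolysis to PHA precursors without net redox turnover).
  Both yields are configurable.
- **Mixing model.** An observed stoichiometry vector (P/HAc, gly/HAc,
  PHB/HAc, PHV/HAc) is fitted as `lam·s_pao + (1−lam)·s_gao`. The default end
  members are measured on the same reference culture: the poly-P-stripped
  batch condition (0.01, 1.01, 1.22, 0.32) and the highest influent-P/C
  condition (0.61, 0.66, 0.97, 0.12). The least-squares `lam` is closed-form
  (projection onto the difference vector, optionally weighted), clipped to
  [0, 1]; per-ratio residuals are returned. Tests verify the closed form
  against a 10001-point grid search.

Carbon closure books CO2 as `1 + gly/HAc − PHB/HAc − PHV/HAc`; a negative
value flags a carbon-infeasible stoichiometry. The electron residual is the
degree-of-reduction imbalance of substrates versus products. Both are
reported, never enforced — measured stoichiometries do not close exactly.

## 6. Synthetic SBR generator (`ebpr.synthetic`)

### What it emulates

A 2.5-L SBR with 1.25 L exchanged per 6-h cycle (2.25 h anaerobic including
5 min sparge and 5 min feed, 2.25 h aerobic, 1.5 h settle/decant), SRT 8 d
enforced by wasting `cycle/(SRT·24) = 1/32` of every particulate pool per
cycle. The HRT is never set; it emerges as `cycle · V/Vex = 12 h`.

Per cycle:

- **Feed** mixes soluble species with the influent at the exchange fraction;
  solids stay.
- **Anaerobic phase**: zero-order acetate uptake at
  `qsa_max = 198 C-mmol/(C-mol·h)` with the stoichiometry given by the
  mixing model at the state's current `lam`, which is tied to the
  poly-P/glycogen ratio `r` by the saturating map `lam = r/(r + 0.3)`.
  Uptake stops at acetate exhaustion or a storage-pool limit; if poly-P runs
  out mid-uptake the metabolism shifts gracefully to the depleted end member.
  After exhaustion, maintenance P release at `m_p = 2.5 P-mmol/(C-mol·h)`.
- **Aerobic phase** is balance closure, not kinetics: PHA is consumed,
  glycogen is replenished toward a buffer target (3 cycles of anaerobic
  demand), net growth takes `y_net = 0.30` C-mol biomass per C-mol acetate
  fed through, the carbon remainder is oxidized; organic P follows the VSS at
  `f_P,bVSS`, and the remaining soluble P refills poly-P up to a capacity of
  0.30 P-mol per C-mol active biomass. Only the anaerobic phase is analysed
  upstream, so aerobic kinetic detail would add parameters without adding
  testable structure.

Emitted panels reconstruct ISS as baseline ash plus poly-P ash — the exact
inverse of the ash-route estimator — and the organic-P ledger uses the same
`f_P,bVSS` convention as the mass-balance estimator. Consequently, at steady
state both estimators agree on noiseless panels by construction (observed
maximum relative discrepancy 3.4e-5 across the six phase steady states),
which is what makes their 1%-agreement check a test of the estimators rather
than of the generator.

### Parameter defaults and rationale

| parameter | default | why |
|---|---|---|
| `qsa_max` | 198 C-mmol/(C-mol·h) | peak uptake rate of the reference enrichment |
| `m_p` | 2.5 P-mmol/(C-mol·h) | order of the measured endogenous release |
| `y_net` | 0.30 C-mol/C-mol | net observable yield; sets steady-state biomass |
| `gly_buffer_cycles` | 3.0 | glycogen store large enough to never bind in normal cycles |
| `polyp_cap` | 0.30 P-mol/C-mol | storage ceiling near the highest measured poly-P content |
| `lam_anchor` | 0.3 | poly-P/glycogen ratio at which the metabolism is half-shifted |
| noise `rsd` | 0.02 | routine wet-chemistry relative precision |

`y_net`, `gly_buffer_cycles`, `polyp_cap` and `lam_anchor` are generator
choices, not measured constants; they were fixed before the estimator tests
were written and are not tuned to them.

### What it does not emulate

No Monod saturation by default (`ks_hac` exists but defaults to zero-order),
no temperature or pH dependence, no competing populations (a GAO fraction is
represented only implicitly through the mixing continuum), no settling
losses, no nitrification, no aerobic-phase kinetics (closure only), and no
sampling artifacts other than multiplicative Gaussian noise.

### Randomness and determinism

All randomness enters through one seeded `numpy` generator and perturbs only
the *emitted* measurements (multiplicative Gaussian, truncated at zero); the
true state stays exact, which is what makes the generator usable as an
oracle. Identical seeds give bit-identical fixtures (`make_fixtures`).

### Numerical choices

- Steady state is declared when the per-cycle relative change of every pool —
  including soluble phosphate — falls below `tol = 1e-6`. Soluble P must be
  in the criterion: at the highest dose the poly-P pool pins at its capacity
  ceiling long before the effluent settles.
- The anaerobic profile is emitted as the exact piecewise-linear trajectory
  (uptake segment to the stop time, then maintenance release if acetate was
  exhausted, flat otherwise), sampled every 5 min; the aerobic tail is a
  coarse linear interpolation every 15 min, sufficient for the begin/end
  bookkeeping that is all the analysis uses.
- Per-cycle phosphorus and carbon ledgers close to machine precision and are
  asserted in the tests.

## 7. Limitations

- The mixing model is a two-end-member projection; real cultures can move off
  the line (the measured reference rows leave residuals of up to ~0.2 on
  individual ratios, reported by `mixing_fit`).
- The maintenance-rate estimate under noise is the weakest number in the
  pipeline: a small slope over a short tail. The test suite asserts exact
  recovery on noiseless data and bounds only qSA/qP and `lam` recovery under
  noise.
- The steady-state P-balance estimator is undefined off steady state; during
  phase transitions only the ash route is meaningful.
- The ash route inherits the counterion assumption through `f_P,ppISS`;
  cultures with different granule chemistry need that constant re-derived
  from their repeating-unit formula.
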