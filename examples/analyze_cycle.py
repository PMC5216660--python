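"""Analyze one anaerobic/aerobic cycle test end to end.

Simulates the reactor to steady state at the enrichment condition, emits one
cycle test with 2% measurement noise, and runs the full estimation pipeline:
kinetic rates from the initial linear segments, maintenance release from the
substrate-free tail, and stoichiometric ratios from the begin/end panels.
"""

from ebpr import (
    NoiseModel,
    SBRConfig,
    analyze_cycle,
    simulate_cycle,
    simulate_to_steady_state,
)

config = SBRConfig()
steady, _ = simulate_to_steady_state(config, phase_schedule=[(0, 0.64)])
res = simulate_cycle(steady[0].state, config, phosphate_mmol=0.64,
                     noise=NoiseModel(seed=7))

rates, stoich = analyze_cycle(res.profile)
print("                     estimated   true")
print(f"qSA  (C-mmol/C-mol/h): {rates.qsa_max.per_cmol:7.1f}  {res.true_qsa:7.1f}")
print(f"qP   (P-mmol/C-mol/h): {rates.qp_max.per_cmol:7.1f}  {res.true_qp:7.1f}")
if rates.m_p is not None:
    print(f"mP   (P-mmol/C-mol/h): {rates.m_p.per_cmol:7.2f}  {res.true_m_p:7.2f}")
print(f"P/HAc   (P-mol/C-mol): {stoich.p_hac:7.2f}  {res.true_stoichiometry.p_hac:7.2f}")
print(f"gly/HAc (C-mol/C-mol): {stoich.gly_hac:7.2f}  {res.true_stoichiometry.gly_hac:7.2f}")
print(f"PHB/HAc (C-mol/C-mol): {stoich.phb_hac:7.2f}  {res.true_stoichiometry.phb_hac:7.2f}")
print(f"PHV/HAc (C-mol/C-mol): {stoich.phv_hac:7.2f}  {res.true_stoichiometry.phv_hac:7.2f}")
print()
print("At 2% analytic noise the pipeline recovers qSA, qP and the ratios")
print("within a few percent; the maintenance rate is the least certain")
print("number (a small slope over a short tail), but correcting for it")
print("still keeps P/HAc from absorbing the endogenous release.")
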