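"""Characterize the acetate enrichment medium across the influent-P schedule.

The medium recipe is fixed except for the phosphate dose; everything molar
(acetate carbon, COD, ammonium, the P/C ratio that labels each experimental
phase) is derived from the salt formulas.
"""

from ebpr import PHASE_PHOSPHATE_MMOL, acetate_medium, characterize_medium

base = characterize_medium(acetate_medium(PHASE_PHOSPHATE_MMOL[0]))
print(f"acetate carbon : {base.hac:6.2f} C-mmol/L")
print(f"theoretical COD: {base.cod:6.1f} mg O2/L")
print(f"ammonium       : {base.tn:6.2f} N-mmol/L")
print()
print("phase  PO4 dose (P-mmol/L)  influent P/C (P-mol/C-mol)")
for phase, dose in sorted(PHASE_PHOSPHATE_MMOL.items()):
    inf = characterize_medium(acetate_medium(dose))
    print(f"  {phase}        {dose:5.2f}                {inf.pc_ratio:6.3f}")
print()
print("Only the phosphate dose changes between phases: a ~3x range in the")
print("influent P/C ratio at constant carbon and nitrogen loading.")
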