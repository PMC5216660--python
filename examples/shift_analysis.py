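"""Place measured anaerobic stoichiometries on the poly-P/glycogen continuum.

As the biomass poly-P content rises, the anaerobic stoichiometry slides from
a glycogen-dominated (GAO-like) pattern toward the classical poly-P-driven
PAO pattern.  Two summaries quantify the position: the ATP-source partition
alpha and the mixing coefficient lam against the two measured end members.
"""

from ebpr import AnaerobicStoichiometry, analyze_shift
from ebpr.reference import ENRICHMENT_STUDY

print("condition   polyP/X   P/HAc   alpha    lam   CO2/HAc")
for _, row in ENRICHMENT_STUDY.iterrows():
    s = AnaerobicStoichiometry(p_hac=row.p_hac, gly_hac=row.gly_hac,
                               phb_hac=row.phb_hac, phv_hac=row.phv_hac)
    res = analyze_shift(s)
    print(f"{row.condition:10s}   {row.polyp_x:5.2f}   {row.p_hac:5.2f}"
          f"   {res.alpha:5.3f}  {res.lam:5.3f}   {res.residuals['co2_hac']:5.2f}")
print()
print("alpha climbs from ~2% (poly-P-stripped culture: nearly all anaerobic")
print("ATP from glycolysis) to ~65% at the highest influent P/C, and lam")
print("tracks the same shift; the culture moves along a continuum rather")
print("than switching between two discrete phenotypes.")
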