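"""Published reference values for the enriched clade-IIC PAO culture.

Anaerobic kinetic and stoichiometric parameters measured on a long-term
"Candidatus Accumulibacter phosphatis" clade IIC enrichment across influent
P/C ratios, plus the poly-P-depleted batch condition of the same culture.
These rows anchor the mixing-model end members and serve as
internal-consistency fixtures for the analysis code; they are printed values
(2-decimal ratios) and carry the corresponding rounding.

Columns
-------
pc_influent : influent P/C ratio, P-mol/C-mol (NaN for the depleted batch)
iss_tss     : initial ash fraction of the solids, mg/mg
polyp_x     : poly-P per active biomass, P-mol/C-mol
phv_phb, phv_hac, phb_hac, p_hac, gly_hac : anaerobic ratios (C- or P-mol basis)
qsa_gvss, qp_gvss : maximum rates, mmol/(gVSS·h)
qsa_cmol, qp_cmol : the same rates, mmol/(C-mol active biomass·h)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ENRICHMENT_STUDY", "PHASE_PC_RATIOS"]

ENRICHMENT_STUDY = pd.DataFrame(
    {
        "condition": ["depleted", "phase1a", "phase1b", "phase0_5", "phase2", "phase3"],
        "pc_influent": [np.nan, 0.038, 0.038, 0.051, 0.077, 0.11],
        "iss_tss": [0.07, 0.27, 0.29, 0.31, 0.40, 0.53],
        "polyp_x": [0.01, 0.09, 0.11, 0.12, 0.16, 0.29],
        "phv_phb": [0.27, 0.19, 0.16, 0.15, 0.14, 0.12],
        "phv_hac": [0.32, 0.26, 0.19, 0.16, 0.14, 0.12],
        "phb_hac": [1.22, 1.35, 1.17, 1.07, 1.00, 0.97],
        "p_hac": [0.01, 0.19, 0.30, 0.33, 0.50, 0.61],
        "gly_hac": [1.01, 1.22, 0.86, 1.02, 0.89, 0.66],
        "qsa_gvss": [2.3, 3.5, 5.5, 6.0, 5.8, 4.9],
        "qp_gvss": [np.nan, 0.9, 1.7, 1.9, 3.1, 3.2],
        "qsa_cmol": [81.0, 121.0, 188.0, 198.0, 177.0, 157.0],
        "qp_cmol": [0.0, 31.0, 56.0, 64.0, 95.0, 103.0],
    }
)

# Influent P/C schedule of the six experimental phases (P-mol/C-mol).
PHASE_PC_RATIOS = {0: 0.051, 1: 0.038, 2: 0.076, 3: 0.114, 4: 0.038, 5: 0.051}
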