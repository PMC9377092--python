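"""Screening-arm statistics: median-viability drug ranking with hit
calling, xenograft tumor volumes and growth rate, and the pathway-score
versus drug-sensitivity correlation."""

import numpy as np
import pandas as pd

from qpopkit import growth_rate, pathway_sensitivity_correlation, screen_rank, tumor_volume
from qpopkit.screen import TumorMeasurement

# single-dose screen: drugs x cell lines viability matrix
rng = np.random.default_rng(0)
lines = [f"PDXO{i}" for i in range(1, 15)]
mat = pd.DataFrame(rng.uniform(0.6, 1.1, (6, 14)),
                   index=["sorafenib", "lenvatinib", "oxaliplatin",
                          "bortezomib", "ixazomib", "dinaciclib"],
                   columns=lines)
for potent in ("bortezomib", "ixazomib", "dinaciclib"):
    mat.loc[potent] = rng.uniform(0.05, 0.45, 14)
res = screen_rank(mat)
print("drugs reducing median viability below 50%:", ", ".join(res.hits))

# tumor growth from caliper diameters, V = pi/6 * A^2 * B
print(f"\ntumor volume for A=10 mm, B=20 mm: {tumor_volume(10, 20):.1f} mm^3")
series = [TumorMeasurement(day=d, A=5 + 0.4 * d, B=7 + 0.5 * d) for d in range(0, 22, 3)]
fit = growth_rate(series)
print(f"growth rate: {fit.slope:.1f} mm^3/day (95% CI {fit.ci_low:.1f}..{fit.ci_high:.1f})")

# basal pathway activity vs combination sensitivity across lines
tab = pd.DataFrame(
    {
        "pathway_score": [0.8, 1.2, 1.6, 2.1, 2.6, 3.2],
        "ic50_uM": [0.04, 0.07, 0.06, 0.12, 0.16, 0.21],
    },
    index=[f"PDXO{i}" for i in range(1, 7)],
)
r, p = pathway_sensitivity_correlation(tab)
print(f"pathway score vs IC50: Pearson r = {r:.3f} (p = {p:.4f})")
# a positive r means lines with higher basal pathway activity need more
# drug, i.e. the pathway marks relative resistance to the combination.
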