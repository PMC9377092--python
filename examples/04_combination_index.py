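"""Chou-Talalay validation of a candidate pair: simulate single-agent and
fixed-ratio combination dose-response series, fit median-effect curves and
compute CI and DRI across the fraction-affected range."""

import numpy as np

from qpopkit import ci_dose_ladder, combination_index, fit_fixed_ratio_combo, fit_median_effect
from qpopkit.dose_response import DoseResponsePoint
from qpopkit.simulate import GroundTruthModel, simulate_dose_response_series

gamma = np.zeros((2, 2))
gamma[0, 1] = gamma[1, 0] = 2.0  # planted synergy
model = GroundTruthModel(
    "PDXO1", {"ixazomib": (0.1, 1.5), "dinaciclib": (0.01, 1.5)}, gamma, noise_sd=0.02
)
ratio = (0.9, 0.1)  # fixed dose ratio, e.g. from the QPOP optimum concentrations

mk = lambda df: [DoseResponsePoint(r.dose_uM, r.viability, r.replicate) for r in df.itertuples()]
curve_a = fit_median_effect(mk(simulate_dose_response_series(
    model, "ixazomib", ci_dose_ladder(0.1), seed=1)))
curve_b = fit_median_effect(mk(simulate_dose_response_series(
    model, "dinaciclib", ci_dose_ladder(0.01), seed=2)))
combo = fit_fixed_ratio_combo(mk(simulate_dose_response_series(
    model, ("ixazomib", "dinaciclib"), ci_dose_ladder(0.1 / ratio[0]),
    ratio=ratio, seed=3)), ratio)

profile = combination_index(curve_a, curve_b, combo, ratio,
                            fa_grid=np.round(np.arange(0.2, 0.81, 0.1), 10))
print("fa    CI     DRI(ixa)  DRI(dina)")
for fa, ci, da, db in zip(profile.fa_grid, profile.ci_values, profile.dri_a, profile.dri_b):
    print(f"{fa:.1f}  {ci:5.3f}   {da:6.2f}    {db:6.2f}")
# CI < 1 indicates synergy; DRI > 1 means the drug needs less dose in
# combination than alone for the same effect.
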