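"""Fit median-effect and four-parameter-logistic curves to a simulated
single-agent dose-response series and extract the ICx design anchors."""

import numpy as np

from qpopkit import (
    ci_dose_ladder,
    fit_four_param_logistic,
    fit_median_effect,
    inhibitory_concentration,
)
from qpopkit.dose_response import DoseResponsePoint
from qpopkit.simulate import GroundTruthModel, default_dose_ladder, simulate_dose_response_series

model = GroundTruthModel(
    "PDXO1", {"ixazomib": (0.1, 1.5), "dinaciclib": (0.01, 1.5)},
    np.zeros((2, 2)), noise_sd=0.02,
)
mk = lambda df: [DoseResponsePoint(r.dose_uM, r.viability, r.replicate) for r in df.itertuples()]

# median-effect fit on serial dilutions bracketing the expected IC50: the
# linearized logit fit is unstable when doses far above the IC50 measure
# mostly noise, so the bracketing ladder is the recommended protocol
bracketed = simulate_dose_response_series(
    model, "ixazomib", ci_dose_ladder(0.1), replicates=5, seed=1
)
curve = fit_median_effect(mk(bracketed))
print(f"median-effect fit: Dm = {curve.Dm:.4f} uM, m = {curve.m:.3f}, "
      f"r2 = {curve.r2:.4f} ({curve.n_points} informative points)")
for x in (10, 20, 50):
    print(f"  IC{x} = {inhibitory_concentration(curve, x):.4f} uM")

# 4PL on the full screen ladder (1e-4 .. 100 uM), as used for IC50 tables
screen = simulate_dose_response_series(
    model, "ixazomib", default_dose_ladder(), replicates=5, seed=1
)
fourpl = fit_four_param_logistic(mk(screen))
print(f"4PL fit: IC50 = {fourpl.ic50:.4f} uM, hill = {fourpl.hill:.3f}, r2 = {fourpl.r2:.4f}")
# Dm and the 4PL IC50 agree for a full-range inhibitor; IC10/IC20 are the
# concentrations assigned to coded levels 0 and +1 of the design.
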