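"""Build the nine-drug orthogonal array composite design and map its coded
levels to IC0/IC10/IC20 concentrations."""

import numpy as np

from qpopkit import compose_oacd, map_design_to_concentrations
from qpopkit.simulate import dose_specs_from_panel

design = compose_oacd(9)
print(f"runs: {design.n_runs}  "
      f"(three-level block: {design.block_labels.count('three_level')}, "
      f"two-level block: {design.block_labels.count('two_level')})")
X = design.model_matrix()
print(f"second-order model matrix: {X.shape[0]} x {X.shape[1]}, "
      f"rank {np.linalg.matrix_rank(X)}")

specs = dose_specs_from_panel()
conc = map_design_to_concentrations(design, specs)
print("\nfirst three runs in uM (level -1 = drug absent):")
print(conc.head(3).round(4).to_string())

# 155 combinations support all 55 coefficients of the quadratic surface,
# against 3^9 = 19683 runs for the full three-level factorial.
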