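"""Head-shape morphometrics: GPA, the RRPP shape regression, disparity
and ontogenetic trajectories.

Aligns the 20-landmark configurations of every fish x stage with
generalized Procrustes analysis, then asks which factors structure shape:
centroid size (allometry), cross type, age, and family nested in cross,
with permutation inference on reduced-model residuals (RRPP).
"""

import numpy as np
import pandas as pd

from charrdev import simulate as sim
from charrdev.morphometry import (
    disparity_test,
    gpa,
    head_shape_terms,
    rrpp_regression,
    trajectory_analysis,
)

design = sim.SimDesign(n_offspring_per_family=15)
params = sim.default_params(design)
roster = sim.generate_design(design, seed=0)
traits = sim.simulate_traits(roster, params, design, seed=3)
configs, _ = sim.simulate_landmarks(roster, traits, params, design, seed=4,
                                    include_curves=False)

res = gpa(configs)
print(f"GPA converged in {res.n_iterations} iterations "
      f"({res.aligned.shape[0]} specimens x {res.aligned.shape[1]} landmarks)")

ids = np.asarray(res.specimen_ids)
meta_tr = traits[["id", "cross", "family"]].drop_duplicates().set_index("id")
meta = pd.DataFrame({
    "id": ids,
    "size": res.centroid_sizes,
    "cross": meta_tr.loc[ids, "cross"].to_numpy(),
    "family": meta_tr.loc[ids, "family"].to_numpy(),
    "age": np.asarray(res.stages, float),
})

table = rrpp_regression(res.flat, head_shape_terms(meta), n_perm=499, seed=5)
print("\nRRPP regression on the Procrustes coordinates:")
print(table.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

stage3 = np.asarray(res.stages, float) == design.stages[2]
disp = disparity_test(res.flat[stage3], meta.loc[stage3, "cross"].to_numpy(),
                      n_perm=499, seed=6)
print("\nDisparity (Procrustes variance) at the third stage:")
print(disp.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

traj = trajectory_analysis(res.flat, meta["cross"].to_numpy(),
                           np.asarray(res.stages, float), n_perm=199, seed=7,
                           subjects=ids)
print("\nOntogenetic trajectory differences:")
print(traj.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

print("\nBy construction the generator ties shape to size only: log(size) "
      "should dominate the variance table (low p), while cross type, its "
      "interactions, the disparity contrasts and the trajectory contrasts "
      "stay indistinguishable from noise.")
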