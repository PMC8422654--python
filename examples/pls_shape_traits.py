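"""Two-block PLS between head shape and the P-matrix traits.

For each cross type, finds the paired directions in (traits, aligned
shape coordinates at the onset of exogeneous feeding) that maximize
between-block covariance, tests the score correlation r by permutation,
and compares effect sizes between crosses with two-sample Z statistics.
"""

import numpy as np

from charrdev import simulate as sim
from charrdev.morphometry import gpa
from charrdev.pls import compare_pls, pls_permutation, two_block_pls

design = sim.SimDesign()
params = sim.default_params(design)
roster = sim.generate_design(design, seed=0)
traits = sim.simulate_traits(roster, params, design, seed=13)
configs, _ = sim.simulate_landmarks(roster, traits, params, design, seed=14,
                                    include_curves=False)

res = gpa(configs)
stage3 = np.asarray(res.stages, float) == design.stages[2]
ids3 = np.asarray(res.specimen_ids)[stage3]
flat3 = res.flat[stage3]

wide = sim.traits_wide(traits).set_index("id")
results = {}
print(f"{'cross':5s} {'r':>6s} {'p':>7s} {'Z':>6s}   leading trait loadings")
for cross in design.cross_types:
    sel = wide.loc[ids3, "cross"].to_numpy() == cross
    x = wide.loc[ids3[sel], list(sim.TRAITS)].to_numpy(float)
    x = x / x.mean(axis=0)
    r = pls_permutation(two_block_pls(x, flat3[sel], label=cross),
                        x, flat3[sel], n_perm=999, seed=17)
    results[cross] = r
    top = np.argsort(-np.abs(r.loadings1))[:2]
    lead = ", ".join(f"{sim.TRAITS[j]}={r.loadings1[j]:+.2f}" for j in top)
    print(f"{cross:5s} {r.r:6.2f} {r.p:7.3f} {r.z:6.2f}   {lead}")

print()
for a, b in (("PL", "SB"), ("PL", "F1"), ("SB", "F1")):
    z, p = compare_pls(results[a], results[b])
    print(f"effect-size difference {a} vs {b}: Z = {z:+.2f}, p = {p:.3f}")

print("\nShape covaries strongly with the size and growth traits in every "
      "cross (the generator injects a shared allometric axis), so r is "
      "high and the loadings are dominated by the standard-length traits. "
      "Effect sizes standardize each r against its own permutation null, "
      "so the cross with the tightest shape-trait coupling stands out in "
      "the pairwise two-sample Z comparisons.")
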