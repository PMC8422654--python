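"""Polynomial random regression of growth, compared with the truth.

Fits per-cross quadratic growth curves (log10 standard length against
thermal age scaled to [0, 1] over 445-1100 degree-days) with family- and
individual-level random effects, then prints the posterior modes and 95%
credible intervals next to the generating coefficients.
"""

from charrdev import simulate as sim
from charrdev.growth_behaviour import fit_growth
from charrdev.mixed_models import ChainSettings

design = sim.SimDesign()
params = sim.default_params(design)
roster = sim.generate_design(design, seed=0)
traits = sim.simulate_traits(roster, params, design, seed=7)

growth = traits[traits["trait"] == "log_sl"].rename(
    columns={"stage": "age", "value": "log_length"}
)
growth["age"] = growth["age"].astype(float)

fit = fit_growth(growth, chain=ChainSettings(2500, 500, 4, seed=1))

print(f"{'cross':5s} {'term':10s} {'truth':>7s} {'mode':>7s}  95% CrI")
for cross in design.cross_types:
    for term, truth in zip(("intercept", "slope", "quadratic"),
                           params.growth_poly[cross]):
        row = fit.table.query("cross == @cross and term == @term").iloc[0]
        print(f"{cross:5s} {term:10s} {truth:7.3f} {row['mode']:7.3f}  "
              f"[{row['lo']:.3f}, {row['hi']:.3f}]")

print("\nThe slower, more decelerating growth of the SB-like cross and the "
      "hybrids (smaller slope, more negative quadratic term) is recovered; "
      "each generating coefficient should sit inside its credible interval.")
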