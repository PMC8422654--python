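"""Repeatability of feeding behaviour, latent and data scale.

Fits a probit mixed model to the repeated binary feeding trials of each
cross, forms the latent-scale repeatability R = V_ind / (V_ind + V_res)
per posterior draw, and transforms it to the observed (data) scale by
integrating the inverse link over the individual-effect distribution —
the Jensen's-inequality-aware transformation.
"""

import numpy as np

from charrdev import simulate as sim
from charrdev.growth_behaviour import probit_observed_mean, repeatability
from charrdev.mixed_models import ChainSettings, RandomTerm, fit_binary, posterior_mode

design = sim.SimDesign()
params = sim.default_params(design)
roster = sim.generate_design(design, seed=0)
records, truth = sim.simulate_behaviour(roster, params, design, seed=21)

print(f"{'cross':5s} {'R true':>7s} {'R latent [95% CrI]':>22s} "
      f"{'R data':>7s} {'P(feed)':>8s}")
for ci, cross in enumerate(design.cross_types):
    sub = records[records["cross"] == cross]
    fit = fit_binary(
        sub["fed"].to_numpy(), np.ones((len(sub), 1)),
        random=[RandomTerm("individual", sub["id"].to_numpy())],
        chain=ChainSettings(4000, 800, 6, seed=30 + ci),
        fixed_names=["intercept"],
    )
    est = repeatability(fit, "binary", trait="feeding propensity", cross=cross)
    prop = probit_observed_mean(
        fit.fixed_draws("intercept"), fit.G["individual"][:, 0, 0], 1.0
    )
    print(f"{cross:5s} {truth[cross]['latent_R_feed']:7.2f} "
          f"{est.latent_mode:7.2f} [{est.latent_lo:.2f}, {est.latent_hi:.2f}] "
          f"{est.data_mode:7.2f} {posterior_mode(prop):8.2f}")

print("\nOnly the PL-like cross is generated with consistent individual "
      "differences (latent R = 0.4); its data-scale R is smaller than the "
      "latent R because thresholding a latent Gaussian discards variance. "
      "The other crosses' estimates should hug zero with CrI lower bounds "
      "at zero.")
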