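"""Generate a miniature synthetic world and inspect its structure.

Builds a 4-country lattice world with districts, states, populations and
smooth covariate surfaces, simulates a latent antibiotic-usage surface
with known covariate effects and Matérn×AR1 residual structure, and
prints a few summaries of what was generated.
"""

import numpy as np

from abxgeo import geostat, synthetic

cfg = synthetic.WorldConfig(n_countries=4, cells_per_country=16,
                            n_districts_per_country=4, years=(2000, 2007),
                            n_covariates=2, income_split=0.25, seed=1)
world = synthetic.generate_world(cfg)
print(f"world: {world.n_cells} cells, {world.n_years} years, "
      f"{len(world.units('district'))} districts")
print(f"high-income countries: {world.hic_countries()}")

gp = geostat.GPHyperparams(spatial_range=3.0, marginal_sd=0.8, ar1_rho=0.7)
usage = synthetic.simulate_latent_usage(world, beta=[0.5, -0.3], gp_params=gp, seed=2)
print(f"usage surface: min={usage.min():.3f}, mean={usage.mean():.3f}, "
      f"max={usage.max():.3f}")
# the surface is the true probability that a child with LRTI symptoms in
# that cell-year received an antibiotic; the model will try to recover it

surveys = synthetic.simulate_surveys(world, usage,
                                     synthetic.SurveyDesign(n_point_surveys=20,
                                                            n_polygon_surveys=5),
                                     seed=3)
pooled = surveys["k"].sum() / surveys["N"].sum()
print(f"{len(surveys)} survey records; pooled crude usage {pooled:.3f} "
      f"(population-mean truth {np.mean(usage):.3f})")
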