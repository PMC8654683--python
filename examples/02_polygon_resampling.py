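"""Resample polygon-referenced survey records to point locations.

Admin-referenced survey rounds only report a district; the usage model
needs cell-referenced counts. Population-weighted K-means places point
records inside the district and the counts are apportioned by cluster
population share — conserving the totals exactly.
"""

from abxgeo import geo, geostat, synthetic

world = synthetic.generate_world(synthetic.WorldConfig(
    n_countries=4, cells_per_country=16, n_districts_per_country=4,
    years=(2000, 2007), n_covariates=2, seed=1))
gp = geostat.GPHyperparams(3.0, 0.8, 0.7)
usage = synthetic.simulate_latent_usage(world, [0.5, -0.3], gp, seed=2)
surveys = synthetic.simulate_surveys(world, usage,
                                     synthetic.SurveyDesign(10, 8), seed=3)

points = geo.resample_polygon_records(surveys, world, quantum=500.0, seed=4)
poly = surveys[surveys["location_type"] == "district"]
print(f"{len(poly)} polygon records -> "
      f"{len(points) - (len(surveys) - len(poly))} point records")
print(f"total N conserved: {surveys['N'].sum()} == {points['N'].sum()}")
print(f"total k conserved: {surveys['k'].sum()} == {points['k'].sum()}")
# conservation is exact by construction (largest-remainder apportionment)
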