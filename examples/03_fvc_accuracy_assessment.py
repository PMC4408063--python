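"""Map fractional vegetation cover and assess it against a field survey.

Unmixes a simulated scene, sums the vegetation-class abundances into an
FVC map, classifies it into the six cover categories, and evaluates the
map against a simulated 30-plot survey (plots sized to the pixel
footprint, 0.05 measurement noise) with RMSE and R^2.
"""

from selsmm import (SelsmmConfig, SimulationConfig, area_proportions,
                    classify_fvc, evaluate_fvc_map, fvc_from_abundance,
                    simulate_field_plots, simulate_scene, unmix_image_selsmm)

truth = simulate_scene(SimulationConfig(seed=42))
abund, _ = unmix_image_selsmm(truth.cube, truth.library,
                              SelsmmConfig(eta=0.35))
fvc_map = classify_fvc(fvc_from_abundance(abund, truth.library))

print("area proportions by cover category:")
table = area_proportions(fvc_map)
for _, row in table.iterrows():
    print(f"  {row.category:>14s}: {row.pixels:5d} px  {row.percent:6.2f} %")
print(f"  (percent total: {table['percent'].sum():.1f})")

plots = simulate_field_plots(truth, count=30, field_noise_sd=0.05, seed=43)
result = evaluate_fvc_map(fvc_map, plots)
print(f"\nsurvey evaluation over N={result.n_pairs} plots:")
print(f"  RMSE = {result.rmse:.3f}   R^2 = {result.r_squared:.3f}")
print(f"  estimated = {result.slope:.3f} * measured + {result.intercept:.3f}"
      f"   (p = {result.p_value:.2e})")

# RMSE is the root mean square difference between the mapped cover and the
# plot measurements; R^2 is the squared correlation between them, i.e. how
# much of the survey's variation the map explains.
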