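"""Attribute pollution days to input factors by variable deletion.

Generates a panel with a planted influential variable — one city is kept
efficient solely through input IN04 — then runs the deletion scan and
shows that the scan recovers exactly that (city, variable) pair.
"""

from haze_ccdea import classify_factors, count_changed_cities, influence_scan
from haze_ccdea.synthetic import PlantedPanelConfig, gen_dea_instance

panel = gen_dea_instance(PlantedPanelConfig(planted_influencer=(7, 4)), seed=11)
records = influence_scan(panel, alphas=[0.8, 0.9, 0.95], mode="single")

print("Cities whose stochastic efficiency changed, per deleted variable and alpha:")
print(count_changed_cities(records, level="single").to_string())
print()
for city, by_alpha in classify_factors(records).items():
    for alpha, names in sorted(by_alpha.items()):
        print(f"{city}: influenced by {', '.join(names)} at risk level {alpha}")
print("\nA flag means deleting that input changed the city's efficiency — the "
      "constraint it contributed was the binding one, so the factor matters "
      "for that city's pollution days. The scan recovers the planted pair "
      "(DMU07, IN04); DMU01/IN01 and DMU02/IN02 flag too because those "
      "frontier cities hold the strict minimum of their dedicated input, the "
      "same mechanism on the efficient side of the frontier.")
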