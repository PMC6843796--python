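"""Sweep the chance-constrained DEA efficiency across risk levels.

Builds a random 13-city panel (14 stochastic inputs, 1 output) and prints
each city's stochastic efficiency 1/theta at the standard risk-level grid.
Efficiency 1 means the city sits on (or, thanks to the probabilistic
slack, cannot be distinguished from) the best-practice frontier; values
below 1 appear only once the risk level exceeds 0.5 and the constraints
relax enough for other cities' convex combinations to dominate.
"""

import pandas as pd

from haze_ccdea import efficiency_profile, random_panel

panel = random_panel(seed=2, n_dmus=13, m_inputs=14, s_outputs=1, cv=0.1)

rows = []
for o, city in enumerate(panel.dmu_ids):
    for res in efficiency_profile(panel, o):
        rows.append({"city": city, "alpha": res.alpha,
                     "efficiency": round(res.efficiency, 4)})
table = pd.DataFrame(rows).pivot(index="city", columns="alpha", values="efficiency")
print(table.to_string())
changing = table.index[(table.min(axis=1) < 1.0)]
print(f"\nCities whose efficiency drops as the risk level grows: "
      f"{', '.join(changing)} — their pollution-day performance is sensitive "
      "to the modelled input/output uncertainty; all others stay efficient at "
      "every risk level.")
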