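"""Compare tooth-arrangement variants: normal vs displaced vs inclined.

Deviations from the normal occlusal scheme (vestibular displacement or
inclination of tooth blocks) redistribute the base stresses and can only
shorten the predicted service life; inclined blocks tend to multiply the
number of disjoint hazard zones.
"""

import json

from rcdlife import (ArchParameters, FoundationSpec, LoadCase, Scenario,
                     compare_arrangements)
from rcdlife.geometry import ArrangementSpec

params = ArchParameters(mesh_size=2.5, element_order=1)
cases = [LoadCase(("I",), "symmetric", 100.0),
         LoadCase(("I",), "asymmetric-right", 100.0),
         LoadCase(("II",), "symmetric", 100.0),
         LoadCase(("II",), "asymmetric-right", 100.0)]
foundation = FoundationSpec()


def scenario(arrangement=None):
    return Scenario(params=params, foundation=foundation, cases=cases,
                    arrangement=arrangement or ArrangementSpec())


report = compare_arrangements({
    "normal": scenario(),
    "displaced": scenario(ArrangementSpec(displacement={"I": (2.0, 1.0)})),
    "inclined": scenario(ArrangementSpec(inclination={"I": 12.0,
                                                      "II": 12.0})),
})

print("ranking (shortest predicted life first):", report.ranking)
for name, entry in report.entries.items():
    print(f"\n{name}: min life {entry['min_years']:.3g} years, "
          f"life ratio vs normal {entry['life_ratio_vs_reference']:.3g}, "
          f"hazard zones {entry['max_hazard_zones']}")
    print("  max base stress per case [MPa]:",
          json.dumps({k: round(v, 3)
                      for k, v in entry["max_base_stress_MPa"].items()}))
print("\nAt this load level the synthetic base stays below the fatigue "
      "limit, so lives cap at 1e9 cycles; the stress table still shows how "
      "arrangement deviations shift and raise the base stresses.")
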