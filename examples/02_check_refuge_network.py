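"""Design-principle screening of the demo fishery-refuge network.

Loads the bundled 12-refuge demo network along the 200-km corridor and the
eleven priority-species profiles, then checks habitat representation,
replication, corridor coverage, size adequacy, larval connectivity,
recovery duration, and compactness.
"""

from corridorplan.fixtures import (
    corridor_baseline,
    demo_network,
    habitat_rasters,
    profiles_from_frame,
    species_profiles,
)
from corridorplan.refuges import check_network, dispersal_distance, min_refuge_area

profiles = profiles_from_frame(species_profiles())
report = check_network(
    demo_network(), profiles, habitat_rasters(), corridor_baseline(),
    resolution=2.0, cell_area=4.0,
)

for name, check in report.checks.items():
    print(f"{name:15s} {'PASS' if check.passed else 'FAIL'}")
print("all principles satisfied:", report.all_pass)

# the two size rules behind the size-adequacy verdict:
coney = next(p for p in profiles if p.species_id == "gulf_coney")
print(f"\ngulf coney needs a refuge of >= {min_refuge_area(coney)} km^2 (its home range)")
murex = next(p for p in profiles if p.species_id == "pink_murex_snail")
print(f"pink murex snail (PLD {murex.pld_weeks} wk) larvae reach "
      f"{dispersal_distance(murex.pld_weeks)} km: refuge gaps must stay below that")
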