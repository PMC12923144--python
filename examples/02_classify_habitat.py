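"""Three-axis habitat classification for a species.

A species is placed along distance-to-bottom (from its habitat label),
distance-to-coast (share of occurrences in the 0-800 m coastal zone) and
distance-to-surface (depth-zone membership from its depth range).
"""

import marisdm
from marisdm.d3os import SpeciesProfile, classify_bottom, classify_coast, classify_vertical

world = marisdm.make_world(seed=1)
species = marisdm.make_species(
    world, habitat_label="benthopelagic", depth_range=(50, 900)
)
records = marisdm.harmonize(
    marisdm.sample_occurrences(world, species, n=300, seed=3)
)

profile = SpeciesProfile(
    taxon_id=species.taxon_id,
    habitat_label=species.habitat_label,
    depth_min=species.depth_min,
    depth_max=species.depth_max,
)
profile.bottom_class = classify_bottom(profile.habitat_label)
profile.coast_class = classify_coast(records, world.partition.coastal_zone)
profile.vertical_classes = classify_vertical(profile, records, world.bathymetry)

print(f"habitat label     : {profile.habitat_label}")
print(f"distance to bottom: {profile.bottom_class}")
print(f"distance to coast : {profile.coast_class}")
print(f"depth zones       : {sorted(profile.vertical_classes)}")
print(
    "(benthopelagic maps to demersal; the 50-900 m depth range straddles the",
    "800 m coastal/bathyal boundary, so both sea-floor zones are kept)",
)
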