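"""Biogeographical (BR) and potential (PR) range construction.

With an expert range map: BR = map + 1 degree, PR = map + 10 degrees, both
clipped to the touched ocean basin and stripped of land. Without one, the
range is derived from occurrences intersected with biogeographic provinces
(keeping provinces holding > 3.3% of records). Occurrence flags are then
refreshed against the BR.
"""

import marisdm
from marisdm.d3os import SpeciesProfile, classify_bottom
from marisdm.ranges import build_from_erm, derive_range, reflag_by_range, spatial_thin

world = marisdm.make_world(seed=1)
species = marisdm.make_species(world, habitat_label="pelagic")
records = marisdm.harmonize(marisdm.sample_occurrences(world, species, n=500, seed=2))

# expert-map route
erm = marisdm.make_erm(species, world)
with_erm = build_from_erm(erm, world.ocean, species.taxon_id)
print(f"ERM route   : BR {with_erm.br_area_km2/1e6:.2f} Mkm^2, "
      f"PR {with_erm.pr_area_km2/1e6:.2f} Mkm^2")

# occurrence + province route
profile = SpeciesProfile(species.taxon_id, "pelagic")
profile.bottom_class = classify_bottom("pelagic")
thinned = spatial_thin(records, seed=4)
derived = derive_range(thinned, profile, world.partition, world.ocean)
print(f"derived route: BR {derived.br_area_km2/1e6:.2f} Mkm^2, "
      f"PR {derived.pr_area_km2/1e6:.2f} Mkm^2")

flagged = reflag_by_range(records, with_erm)
n1 = int((flagged["flag"] == 1).sum())
n0 = int((flagged["flag"] == 0).sum())
print(f"re-flagging : {n1} verified, {n0} erroneous "
      "(records outside the BR, including all land points)")
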