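"""Recovering planted hydration sites in a synthetic binding pocket.

Builds the toy pocket (a rigid cavity with two attractive wells inside a
6 Å spherical move region), runs a GCNCMC/MD campaign, clusters the
visited solvent positions with 2.4 Å average-linkage clustering and
matches the clusters against the planted well minima with the 1.4 Å
crystallographic threshold.
"""

import numpy as np

from gcncmc import (AdamsParameters, CampaignConfig, NCMCProtocol,
                    cluster_hydration_sites, make_toy_pocket,
                    match_to_reference, run_campaign)

system, region, references = make_toy_pocket(seed=1)
print(f"move region: sphere, radius {region.radius} Å; "
      f"{len(references)} planted sites")

cfg = CampaignConfig(
    method="gcncmc", region=region, adams=AdamsParameters(B=-4.0),
    iterations=500, md_steps=10, seed=101,
    protocol=NCMCProtocol(n_pert=9, n_prop=10))
stats = run_campaign(cfg, system)
occ = np.array([f.region_count for f in stats.frames], float)
print(f"mean occupancy of the region after burn-in: {occ[200:].mean():.2f}")

report = cluster_hydration_sites(stats.frames[200:], align=False)
matches = match_to_reference(report, references, threshold=1.4)
for site_idx, ref_idx, dist in matches:
    site = report.sites[site_idx]
    print(f"planted site {ref_idx}: recovered at {dist:.2f} Å "
          f"(cluster occupancy {site.occupancy:.2f})")

print("\nEvery planted well should be matched well inside 1.4 Å; extra "
      "low-occupancy clusters are transient solvent positions.")
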