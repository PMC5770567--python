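"""Interleaflet registration: are ordered regions vertically aligned?

The overlap metric is the area fraction of raster cells whose two leaflet
states agree. Identical maps give 1, complementary maps 0, and two
independent leaflets with ordered fractions f give f^2 + (1-f)^2 — about
0.57 at f = 0.31 and 0.50 at f = 0.46, the uncorrelated baseline.
"""

import numpy as np

from nanodomain import (LatticeGasParams, generate_lattice_gas,
                        periodic_voronoi, local_composition,
                        assign_ordered_sites, rasterize_states,
                        interleaflet_overlap, random_state_map)

# uncorrelated baseline from Bernoulli rasters
for f in (0.31, 0.46):
    vals = [interleaflet_overlap(random_state_map((200, 200), f, seed=s))
            for s in range(20)]
    print(f"independent leaflets, f = {f:.2f}: overlap = "
          f"{np.mean(vals):.3f} (closed form {f * f + (1 - f) ** 2:.3f})")

# a demixed bilayer with interleaflet coupling registers its domains
for label, lam in (("uncoupled leaflets", 0.0),
                   ("coupled leaflets  ", 1.0)):
    frame = generate_lattice_gas(LatticeGasParams(
        lattice_side=32, coupling=1.1, interleaflet_coupling=lam,
        sweeps=3000, seed=3))
    per_leaf = {}
    for name, leaf in frame.leaflets.items():
        tess = periodic_voronoi(leaf.xy, frame.box)
        conc = local_composition(tess, leaf.species, {"sat"})
        flags = assign_ordered_sites(conc,
                                     float((leaf.species == "sat").mean()))
        per_leaf[name] = (tess, flags)
    smap = rasterize_states(per_leaf["upper"][1], per_leaf["lower"][1],
                            per_leaf["upper"][0], per_leaf["lower"][0],
                            frame.upper.xy, frame.lower.xy, cell_size=0.5)
    print(f"demixed bilayer, {label}: overlap = "
          f"{interleaflet_overlap(smap):.3f}")

print("\nCoupled domains overlap far above the uncorrelated baseline — the "
      "signature\nthat distinguishes coexisting phases from independent "
      "fluctuations.")
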