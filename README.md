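# nanodomain

Lateral-heterogeneity analysis for lipid bilayers: tools for telling
**nanoscale domains of coexisting phases** apart from **composition
fluctuations** in two-leaflet lipid mixtures.

Mixtures of a saturated lipid, an unsaturated lipid and (optionally)
cholesterol can sit in one fluid phase with transient local enrichment, or
separate into coexisting phases (liquid-ordered/liquid-disordered, or
gel/fluid). Both produce nanoscale clusters enriched in the
ordered-phase-forming species, so telling them apart needs quantitative
structure and dynamics, not snapshots. `nanodomain` implements the analysis
chain that makes the call, plus a lattice-gas generator that produces
configurations with controlled demixing so every estimator can be validated
against a known answer.

## What it computes

Given per-frame leaflet configurations (reference site per lipid, species
label, periodic box; optionally chain sites and heights):

- **Tessellation** — periodic 2D Voronoi diagram per leaflet: area per lipid
  `A_L`, first-shell neighbours, shared-edge lengths.
- **Ordered clusters** — a site is *ordered* when the local concentration of
  the ordered species (saturated lipid + cholesterol) in its first neighbour
  shell strictly exceeds the leaflet mean; connected components on the
  periodic Delaunay graph give clusters with area, equivalent-circle radius
  `R = sqrt(A/pi)`, composition `C_i`, and normalized boundary length
  `L = perimeter / (2*sqrt(pi*A))` (1 for a disc, large for ragged shapes).
- **Registration** — the interleaflet overlap: the area fraction of a shared
  raster on which the two leaflets' ordered/disordered states agree.
  Identical maps give 1, complementary maps 0, and independent leaflets with
  ordered fractions f give `f^2 + (1-f)^2` (0.57 at f = 0.31, 0.50 at
  f = 0.46) — the uncorrelated baseline.
- **Correlations** — in-plane 2D RDF `g(r)` with minimum-image distances;
  correlation length from `g(r) = a0*exp(-r/xi) + a1` (the fit refuses when
  an exponential is not statistically supported); static structure factor
  `S(q) = |sum_n exp(-i q.r_n)|^2 / N` on box-commensurate wave vectors with
  radial averaging; local-density correlation time `tau`; windowed 2D
  density maps and their persistence.
- **Order & geometry** — chain orientational order
  `S_z = <(3 cos^2 theta - 1)/2>` from the site *n-1* to *n+1* chain vectors;
  leaflet surface interpolation on a 0.4 nm grid with binomial smoothing;
  Monge-gauge principal and mean curvature `H = (c1+c2)/2`; lateral diffusion
  `D` from the Einstein relation on in-plane MSD.
- **Phase classifier** — combines RDF decay shape (short-range exponential
  vs long-range linear), overlap, persistence and `xi` into a
  `one_phase` / `near_critical` / `two_phase` verdict with all thresholds
  explicit and every evidence component stored.

## Worked example

`examples/` holds one short script per capability. The registration example:

```bash
python examples/03_interleaflet_registration.py
```

prints

```
independent leaflets, f = 0.31: overlap = 0.572 (closed form 0.572)
independent leaflets, f = 0.46: overlap = 0.504 (closed form 0.503)
demixed bilayer, uncoupled leaflets: overlap = 0.728
demixed bilayer, coupled leaflets  : overlap = 0.981
```

The first two lines are the uncorrelated baseline: with no interleaflet
correlation the overlap is fully determined by the ordered-area fractions.
A demixed bilayer with interleaflet coupling sits far above it (0.98) —
its domains are in register, the hallmark of coexisting phases rather than
independent fluctuations.

The full chain, `python examples/06_full_pipeline.py`, simulates a demixed
and a mixed trajectory and prints the verdicts (`two_phase` with overlap
0.977 and persistence 0.92; `one_phase` with overlap at the 0.52 baseline),
together with the per-bilayer observables (`A_L` ordered/disordered, `C_i`,
`S_z`, `D_i` where available).

## Command line

A thin CLI wraps the library for batch use:

```bash
nanodomain simulate --config run.yaml --seed 1 --out frames/
nanodomain analyze  --config run.yaml --seed 1 --out results/
nanodomain classify --out results/
nanodomain report   --out results/
```

The YAML config names a source (synthetic lattice-gas parameters, the flat
CSV+JSON frame format, or GRO/XTC files with a residue-to-species map) and
analysis settings; see `nanodomain.pipeline.DEFAULT_ANALYSIS`.

## Layout

```
src/nanodomain/     frame, synthetic, tessellation, clustering,
                    registration, correlations, order_geometry, pipeline, cli
tests/              pytest suite (unit, property and acceptance tests)
examples/           one narrative script per capability
docs/methods.md     models, estimators, defaults, limitations
```
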