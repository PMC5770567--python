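# Methods

This note records the models behind `nanodomain`, the defaults and why they
were chosen, and what the synthetic generators do and do not emulate.

## The scientific problem

A two-component (or three-component, with cholesterol) lipid bilayer near
its miscibility transition shows nanoscale lateral heterogeneity of two
qualitatively different kinds: *composition fluctuations* — transient local
enrichment within a single phase — and *domains of a coexisting second
phase*. Both appear as clusters enriched in the saturated lipid (and
cholesterol), so the distinction must come from quantitative signatures:
the range of in-plane density correlations, the registration of ordered
regions across the two leaflets, the persistence of density patterns in
time, and cluster morphology. The package computes these signatures and
combines them into an explicit phase-state call.

## Synthetic configurations (the lattice gas)

MD trajectories are replaced by a two-leaflet lattice gas on a triangular
lattice (so that jittered Voronoi cells are hexagonal, like fluid-bilayer
packing). The Hamiltonian, in units of kT,

    E = J * (number of unlike nearest-neighbour pairs within each leaflet)
      - lam * (number of vertically adjacent site pairs whose binary
               ordered/disordered labels agree),

is sampled with composition-conserving exchange (Kawasaki) moves —
conserved composition is the physically essential property of a lipid
mixture, which rules out label-flip dynamics. Exchanges swap two randomly
chosen sites of one leaflet (long-range exchange); this preserves
composition exactly while equilibrating the conserved mixture in sweep
counts feasible on a desktop, and the equilibrium ensemble is identical to
that of nearest-neighbour exchange.

For the ternary mixture the cholesterol-like label has full affinity with
the saturated-like label (their pair energy is 0 instead of J); the
interleaflet term acts on the binary ordered/disordered relabeling
(saturated + sterol = ordered), so it is well defined for ternary mixtures.

Mapping to the Ising model (J_Ising = J/2) puts the 50/50 demixing point of
the triangular lattice at J_c = ln(3)/2 ≈ 0.55; the default study
conditions are J = 0.2 (mixed), 0.3–0.6 (growing fluctuations), and
J = 1.1 with lam = 1.0 (demixed, registered domains). Defaults: 60/40
saturated/unsaturated composition (70/70/60 with cholesterol divides as
0.35/0.35/0.30), lattice spacing 0.8 nm (≈ 0.55 nm² per site, a fluid-phase
area per lipid), positional jitter 0.15 lattice units.

What the generator does *not* emulate: real chain packing and its
temperature dependence, hydrodynamics, any mapping from J to kelvin,
sterol-specific geometry, or off-lattice density fluctuations. Passing
tests therefore validate the *estimators and their contracts* on inputs
with known statistical structure; they do not certify force-field-level
realism.

Other generators provide known-answer inputs for individual estimators:
straight chains whose direction distribution has an exact prescribed mean
orientational order; analytic surfaces (plane, spherical cap, sinusoid)
with closed-form mean curvature; independent 2D Brownian walkers with
per-species diffusion coefficients (per-axis step variance 2 D dt, both
wrapped and unwrapped coordinates kept).

All generators take an explicit integer seed and are bit-reproducible given
it; the Monte Carlo kernel derives per-chunk seeds from the root seed with
a fixed affine map, so trajectory snapshots are reproducible individually.

## Tessellation

The leaflet is tessellated on the torus by replicating all sites into the
3x3 block of periodic images, running Qhull (scipy) on the replicated set,
and keeping the central cells. Full replication was preferred over a
margin heuristic: it removes the need to prove no cell touches the
replication frontier, at a cost that is negligible below ~10^4 sites per
leaflet. Cell areas tile the box to better than 1e-6 relative (asserted on
every call); the first-shell neighbour graph equals the periodic Delaunay
adjacency (tested directly).

Exactly cocircular quadruples (perfect square lattices) are broken by a
deterministic site-indexed perturbation of 1e-9 nm before tessellating;
ridges shorter than 1e-7 nm are discarded as corner contacts left over
from the tie-break. Neighbour lists keep one entry per Voronoi ridge, so in
very small boxes one neighbour can appear through two periodic images with
two distinct shared edges — exactly what the boundary metric needs.

"First surrounding shell" always means Voronoi/Delaunay adjacency, not a
distance cutoff, consistent with the tessellation already computed. The
Voronoi sites are whatever per-lipid reference site the frame supplies
(lattice site, centre of mass, or a headgroup bead through the trajectory
adapter); all species are included as sites by default.

## Ordered clusters

A site is ordered when the fraction of ordered species among {site + first
shell} *strictly* exceeds the leaflet-wide mean concentration of those
species — strict, so a homogeneous leaflet yields zero ordered sites
(ties are not ordered). For ternary mixtures the ordered concentration is
the summed fraction of saturated lipid and cholesterol, thresholded at the
summed mean.

Clusters are connected components of the ordered-site subgraph on the
periodic adjacency; singletons are allowed, and components may wind around
the box. Per cluster the package reports: area (sum of member Voronoi
cells), equivalent-circle radius R = sqrt(A/pi) (the paper-facing radius;
a gyration radius would also be computable but the equivalent-circle
definition is the default), composition, per-species mean areas, the raw
Voronoi-edge perimeter, and the normalized boundary length
L = perimeter / (2 sqrt(pi A)).

Two geometric facts discovered while validating L are worth recording:

1. **The isoperimetric bound L >= 1 only applies to clusters contractible
   in the plane.** A band wound around the periodic box encloses area with
   less boundary than any disc (a measured example: L = 0.98). Clusters
   are therefore tested for nontrivial winding (minimum-image walk over the
   cluster adjacency; any closing edge whose accumulated offsets disagree
   by a box period reveals winding) and carry a `wraps` flag; the L >= 1
   invariant is asserted for non-wrapping clusters.
2. **On a hexagonal tessellation L has a floor above 1.** Every cluster
   boundary is a path in the honeycomb edge graph, whose straightest lines
   zigzag with length factor 2/sqrt(3) ≈ 1.155 per unit distance in every
   direction; the most compact ≥500-site droplet measures L ≈ 1.21 and a
   Euclidean disc cut L ≈ 1.29 (both cross-validated against a 0.02 nm
   rasterization oracle). Compact domains on these tessellations therefore
   score ≈ 1.2, not 1.0, and ragged fluctuations several times that; the
   *contrast* between the two is the meaningful signal.

Size-distribution outputs take a configurable floor (default 5 sites) to
suppress shot noise; raw per-cluster tables always retain everything.

## Registration

The two leaflets' Voronoi diagrams differ, so states are compared on a
shared raster (default cell 0.5 nm, with a convergence test halving the
cell): each raster cell takes the state of the Voronoi cell containing its
centre, per leaflet. The default overlap is the **state-agreement
fraction**. Its anchors are exact: 1 for identical maps, 0 for
complementary maps, and f1 f2 + (1-f1)(1-f2) for independent leaflets —
0.57 at f = 0.31 and 0.50 at f = 0.46. An alternative reading of overlap
(aligned ordered area divided by ordered area) gives f, not
f^2 + (1-f)^2, for independent leaflets, and is inconsistent with those
printed anchor values; it is still computed and reported as
`overlap_clusters` so both conventions are available. The interleaflet 2D
RDF (cross-RDF of the two leaflets' site sets after in-plane projection)
provides the complementary distance-resolved view: > 1 at small r for
registered, < 1 for anti-registered leaflets.

## Correlations

**RDF.** Periodic minimum-image pair distances, ring-area x mean-density
normalization so a Poisson pattern gives exactly 1; self-pairs excluded;
default bin 0.1 nm; r_max capped at half the shorter box edge. Because the
lattice-gas positions are nearly crystalline, same-species RDFs carry the
packing structure of *all* sites; the optional reference normalization
divides by the all-site RDF bin-wise, leaving the pure label correlation
(exactly 1 for randomly assigned labels). The pipeline uses this label
correlation for lattice-gas input; for fluid MD-like input the raw RDF
with a fit range starting beyond the nearest-neighbour peak (default
r >= 1 nm) serves the same purpose.

**Correlation length.** Nonlinear least squares of a0 exp(-r/xi) + a1,
multi-start over xi. The fit *refuses* to report xi when (a) the
exponential does not beat a constant in an F-test at alpha = 0.05, or
(b) the fitted xi is below the bin width (decay inside one bin is
unresolvable). Refusal is a flagged outcome, never a fabricated number.

**Structure factor.** Direct sum S(q) = |sum exp(-i q.r)|^2 / N on the
box-commensurate grid q = 2 pi (n/Lx, m/Ly) (computed as an outer-product
matrix product, so no gridding error), q = 0 excluded, radial average in
bins of one grid step. Convention note: with q = 2 pi n / L a peak at q
corresponds to a real-space period of 2 pi / q; under the alternative
q = n/L convention all peak positions shift by 2 pi. The FFT of a gridded
density is kept as an independent cross-check route; it coincides with the
direct sum (to 1e-8) exactly when scatterers sit on the FFT grid, so the
dual-route test snaps points to a commensurate grid first.

**Correlation time.** Local density on a 20x20 grid over consecutive
frames; mean-subtracted per-cell series; autocorrelation averaged over
cells, normalized to C(0) = 1; single-exponential fit over lags 1..9 by
default (10 frames). Degenerate inputs are flagged: zero variance ->
`static` (tau infinite), C(dt) < 0.05 -> `unresolved` (decay faster than
the frame spacing). For Brownian particles the exact autocorrelation is
the product of two per-axis triangular-window Gaussian integrals; its
early-time sqrt(t) decay means the fitted tau is roughly *half* of
l^2/(4D) in the resolvable regime, so validation compares the estimator
against that exact integral put through the same fit protocol (and checks
the l^2/D scaling), not against the l^2/(4D) shorthand.

**Density maps.** Per-window mean number density on a configurable grid;
windows tile the trajectory without overlap; the map integral equals the
mean particle count per frame. Persistence is summarized as the contrast
(coefficient of variation) of the longest-window map divided by the mean
contrast of the shortest-window maps: near 1 for a static pattern,
near 1/sqrt(window ratio) for patterns that average out.

## Order and geometry

**Chain order.** For each internal chain site n the segment vector is
site(n+1) - site(n-1) ("all sites" therefore means all internal sites —
terminal beads have no such vector); the per-site contribution
(3 cos^2 theta - 1)/2 is averaged over sites, both chains and lipids;
sterol-like species are excluded by default; chains with fewer than three
sites are skipped and counted. S_z is bounded in [-0.5, 1] and the bounds
are asserted.

**Surface and curvature.** Scattered reference sites are interpolated onto
a periodic grid (default 0.4 nm): either Delaunay-based linear
interpolation on the 3x3-tiled point set (default; smooth for scattered
sites) or bilinear on binned means. The grid is smoothed with a separable
1-4-6-4-1 binomial kernel with periodic wrap (default 2 passes;
mean-preserving; per-axis gain cos^4(pi f h) per pass — about 1.6%
amplitude loss at a 20 nm wavelength on a 0.4 nm grid). Curvature comes
from periodic central differences in the Monge gauge; principal curvatures
are c = H ± sqrt(H^2 - K); the sign convention is fixed so a surface
bulging toward +z has positive H (flipping z negates H). Each leaflet is
fitted separately; a bilayer midplane surface can be formed by averaging
the two leaflet grids.

**Diffusion.** Einstein relation on in-plane MSD of *unwrapped*
coordinates (wrapped-only input is an error instructing unwrapping):
time-origin- and ensemble-averaged via the FFT algorithm, centre-of-mass
motion removed per frame (making the estimate exactly invariant to a
uniform drift), slope from weighted least squares over a configurable lag
window. The default window is the middle third of lags; the weights
(T - m)/m^2 approximate the inverse variance of the time-averaged MSD at
lag m. Validation uses an earlier window (5–30% of lags), where the MSD
sampling error — relative standard deviation roughly
sqrt(2 m / (N (T - m))) — keeps the recovered D within a few percent at
the trajectory sizes used (10^3 particles x 10^3 frames). D is reported in
cm^2/s (1 nm^2/ns = 1e-5 cm^2/s), matching the unit diffusion tables are
printed in.

## Phase classifier

All thresholds are engineering choices, explicit in `ClassifierConfig`:

- *Long-range decay*: a straight line fit on r in [2 nm, 0.8 r_max] beats
  the exponential by small-sample-corrected AIC, **and** its slope is
  significantly negative (3 standard errors) **and** the total drop across
  the window exceeds 0.05 — without the last two guards a flat noisy
  profile trivially "prefers" the 2-parameter line. An exponential whose
  fitted xi exceeds half the fit window (with a predicted drop > 0.05)
  also counts as long-range, since no curvature is resolved within the
  observation window.
- `two_phase` = long-range decay AND overlap > 0.7 AND persistence >= 0.8.
  The 0.7 overlap threshold marks the strong-correlation regime that
  separates registered domains from the uncorrelated 0.50–0.57 baseline.
- `near_critical` = short-range decay but xi > 3x the mean inter-lipid
  spacing (or long-range decay without the overlap/persistence evidence).
- otherwise `one_phase`. Missing evidence withholds the verdict rather
  than guessing, and every verdict stores the evidence it was derived
  from, so the label is re-derivable.

The pipeline analyses the final 10% of frames in detail by default (the
tail of an equilibrated run), with density maps and area-fraction series
over all frames; analysis problem sizes in the test suite (lattice side
28–32, 1.5–3k sweeps, 5 seeds per condition) were chosen as the smallest
at which the subcritical correlation-length ordering and the
demixed/mixed contrasts are statistically stable.

## Known limitations

- The lattice-gas coupling scale has no temperature calibration; only
  orderings and contrasts across couplings are meaningful.
- The L floor of ≈ 1.2 for compact clusters is a property of hexagonal
  tessellations (see above), so absolute boundary-length values are not
  comparable across tessellation types — only ratios within one analysis.
- The correlation-time estimator assumes density changes little between
  consecutive frames; with the default 10-frame protocol, tau outside
  roughly [dt, 10 dt] is flagged rather than estimated.
- `D_i` and `S_z` appear in the pipeline summary only when the input
  carries dynamics (unwrapped trajectories) or chain sites; lattice-gas
  Monte Carlo has neither, and the summary marks them absent rather than
  inventing values.
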