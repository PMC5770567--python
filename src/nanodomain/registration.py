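"""Interleaflet registration (overlap) of ordered regions.

The two leaflets generally have different Voronoi diagrams, so their
ordered/disordered states are compared on a shared regular raster: each
raster cell takes the state of the Voronoi cell containing its centre, per
leaflet. The default overlap is the *state-agreement* fraction — the area
fraction of cells whose two leaflet states agree (ordered-ordered or
disordered-disordered). It is 1 for identical maps, 0 for exactly
complementary ones, and f1*f2 + (1-f1)(1-f2) for statistically independent
leaflets with ordered fractions f1, f2 (0.57 at f=0.31, 0.50 at f=0.46).

A second variant, ``overlap_clusters``, is the ordered-area-ratio reading
(ordered-and-aligned area over ordered area, averaged over the two
leaflets); it equals f for independent leaflets and is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .tessellation import VoronoiTessellation
from .correlations import RadialProfile, cross_rdf2d

__all__ = ["StateMap", "rasterize_states", "interleaflet_overlap",
           "overlap_clusters", "random_state_map", "interleaflet_rdf"]


@dataclass
class StateMap:
    """Binary ordered/disordered raster per leaflet on a shared grid."""

    upper: np.ndarray        # (nx, ny) bool
    lower: np.ndarray        # (nx, ny) bool
    cell_size: tuple[float, float]
    box: tuple[float, float]
    time: float = 0.0

    def __post_init__(self):
        self.upper = np.asarray(self.upper, dtype=bool)
        self.lower = np.asarray(self.lower, dtype=bool)
        if self.upper.shape != self.lower.shape:
            raise ValueError("leaflet rasters must share dimensions")

    @property
    def ordered_fractions(self) -> tuple[float, float]:
        return float(self.upper.mean()), float(self.lower.mean())


def _owner_states(xy: np.ndarray, flags: np.ndarray, box, centers: np.ndarray
                  ) -> np.ndarray:
    # owner of a raster cell = nearest site under the periodic metric,
    # which is exactly the Voronoi cell containing the centre
    tree = cKDTree(np.mod(xy, box), boxsize=box)
    _, owner = tree.query(centers)
    return flags[owner]


def rasterize_states(flags_upper: np.ndarray, flags_lower: np.ndarray,
                     tess_upper: VoronoiTessellation,
                     tess_lower: VoronoiTessellation,
                     xy_upper: np.ndarray, xy_lower: np.ndarray,
                     cell_size: float = 0.5, time: float = 0.0) -> StateMap:
    """Sample per-site ordered flags of both leaflets onto one raster."""
    if tess_upper.box != tess_lower.box:
        raise ValueError("both leaflets must share the same box")
    lx, ly = tess_upper.box
    if cell_size > min(lx, ly) / 4:
        raise ValueError("cell_size too coarse: must be <= box/4")
    nx = max(4, int(round(lx / cell_size)))
    ny = max(4, int(round(ly / cell_size)))
    x = (np.arange(nx) + 0.5) * (lx / nx)
    y = (np.arange(ny) + 0.5) * (ly / ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    up = _owner_states(xy_upper, np.asarray(flags_upper, bool), (lx, ly),
                       centers).reshape(nx, ny)
    lo = _owner_states(xy_lower, np.asarray(flags_lower, bool), (lx, ly),
                       centers).reshape(nx, ny)
    return StateMap(upper=up, lower=lo, cell_size=(lx / nx, ly / ny),
                    box=(lx, ly), time=time)


def interleaflet_overlap(state_map: StateMap) -> float:
    """State-agreement overlap in [0, 1]; symmetric in the leaflets."""
    return float(np.mean(state_map.upper == state_map.lower))


def overlap_clusters(state_map: StateMap) -> float:
    """Ordered-area-ratio overlap: aligned ordered area / ordered area,
    averaged over the two leaflets. NaN when a leaflet has no ordered area."""
    up, lo = state_map.upper, state_map.lower
    aligned = np.sum(up & lo)
    vals = []
    for m in (up, lo):
        tot = np.sum(m)
        vals.append(aligned / tot if tot else np.nan)
    return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan


def random_state_map(shape: tuple[int, int], f_upper: float,
                     f_lower: float | None = None, seed: int = 0,
                     box: tuple[float, float] | None = None) -> StateMap:
    """Two independent Bernoulli rasters — the uncorrelated-leaflet null
    model used to anchor the overlap scale."""
    if f_lower is None:
        f_lower = f_upper
    rng = np.random.default_rng(seed)
    up = rng.random(shape) < f_upper
    lo = rng.random(shape) < f_lower
    if box is None:
        box = (float(shape[0]), float(shape[1]))
    return StateMap(upper=up, lower=lo,
                    cell_size=(box[0] / shape[0], box[1] / shape[1]), box=box)


def interleaflet_rdf(xy_upper: np.ndarray, xy_lower: np.ndarray,
                     box: tuple[float, float], bin_width: float = 0.1,
                     r_max: float | None = None) -> RadialProfile:
    """In-plane 2D RDF between upper- and lower-leaflet site sets.

    Both leaflets are projected onto the bilayer plane; there are no
    self-pairs, so the r -> 0 bin is well defined. Values > 1 at small r
    indicate registration, < 1 antiregistration.
    """
    return cross_rdf2d(xy_upper, xy_lower, box, bin_width=bin_width,
                       r_max=r_max)
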