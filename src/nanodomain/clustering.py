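"""Ordered-cluster detection and morphology on a tessellated leaflet.

A site is *ordered* when the concentration of the ordered-phase-forming
species (saturated lipid, plus sterol in ternary mixtures) in its local
environment — the site plus its first Voronoi shell — strictly exceeds the
leaflet-wide mean concentration of those species. Ordered sites are grouped
into clusters by connectivity on the periodic Delaunay graph; each cluster
gets an area (sum of member Voronoi cells), an equivalent-circle radius, a
composition, and a boundary length normalized by the perimeter of the circle
of equal area (1 for a disc, larger for rough shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .tessellation import VoronoiTessellation, area_per_species

__all__ = [
    "local_composition", "assign_ordered_sites", "group_clusters",
    "boundary_length", "cluster_radius", "cluster_wraps",
    "weighted_mean_radius", "ClusterSet", "area_fraction_timeseries",
    "detect_plateau",
]


def local_composition(tess: VoronoiTessellation, labels: np.ndarray,
                      ordered_species: Iterable[str]) -> np.ndarray:
    """Fraction of ordered species among each site and its first shell."""
    ordered_species = set(ordered_species)
    if not ordered_species:
        raise ValueError("ordered_species must be a nonempty set of labels")
    labels = np.asarray(labels)
    if len(labels) != tess.n:
        raise ValueError("labels must align with tessellation sites")
    is_ord = np.isin(labels, sorted(ordered_species)).astype(float)
    out = np.empty(tess.n)
    for i, nb in enumerate(tess.neighbor_sets()):
        shell = np.append(nb, i)
        out[i] = is_ord[shell].mean()
    return out


def assign_ordered_sites(local_conc: np.ndarray, global_mean: float) -> np.ndarray:
    """Flag sites whose local ordered concentration strictly exceeds the
    leaflet mean (ties are disordered, so a homogeneous leaflet has none)."""
    if not (0.0 < global_mean < 1.0):
        raise ValueError("global mean concentration must lie in (0, 1)")
    return np.asarray(local_conc) > global_mean


@dataclass
class ClusterSet:
    """Ordered clusters of one leaflet at one time point."""

    members: list                    # per cluster: int array of site ids
    table: pd.DataFrame              # per cluster metrics
    ordered_flags: np.ndarray        # (n,) bool
    ordered_area_fraction: float
    leaflet_area: float
    time: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def _cluster_components(flags: np.ndarray, tess: VoronoiTessellation) -> list[np.ndarray]:
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    pos = -np.ones(tess.n, dtype=int)
    pos[idx] = np.arange(len(idx))
    rows, cols = [], []
    for i in idx:
        for j in np.unique(tess.neighbors[i]):
            if flags[j]:
                rows.append(pos[i])
                cols.append(pos[j])
    adj = csr_matrix((np.ones(len(rows), bool), (rows, cols)),
                     shape=(len(idx), len(idx)))
    n_comp, lab = connected_components(adj, directed=False)
    return [idx[lab == c] for c in range(n_comp)]


def boundary_length(member_ids: Sequence[int], tess: VoronoiTessellation
                    ) -> tuple[float, float]:
    """(normalized boundary length, raw perimeter in nm) of one cluster.

    The perimeter is the sum of Voronoi edge lengths between member and
    non-member sites (periodic edges included with multiplicity); it is
    normalized by 2*sqrt(pi*A), the circumference of the circle of equal
    area. A cluster covering the whole leaflet has zero perimeter and an
    undefined (NaN) normalized length.
    """
    member_ids = np.asarray(member_ids, dtype=int)
    if len(member_ids) == 0:
        raise ValueError("cluster must be nonempty")
    inside = np.zeros(tess.n, dtype=bool)
    inside[member_ids] = True
    perim = 0.0
    for i in member_ids:
        nbs = tess.neighbors[i]
        lens = tess.edge_lengths[i]
        perim += lens[~inside[nbs]].sum()
    area = tess.areas[member_ids].sum()
    if perim == 0.0:
        return np.nan, 0.0
    return perim / (2.0 * np.sqrt(np.pi * area)), perim


def cluster_wraps(member_ids: Sequence[int], tess: VoronoiTessellation) -> bool:
    """True when the cluster winds around the periodic box.

    Walks the cluster's adjacency assigning each member an unwrapped offset
    from the first site via minimum-image steps; any closing edge whose
    offsets disagree by a full box period reveals nontrivial winding. The
    planar isoperimetric bound (normalized boundary length >= 1) applies
    only to non-wrapping clusters — a band wound around the torus encloses
    area with less boundary than any disc.
    """
    member_ids = np.asarray(member_ids, dtype=int)
    if tess.sites is None or len(member_ids) < 2:
        return False
    box = np.asarray(tess.box)
    inside = np.zeros(tess.n, dtype=bool)
    inside[member_ids] = True
    offset = {int(member_ids[0]): np.zeros(2)}
    stack = [int(member_ids[0])]
    while stack:
        u = stack.pop()
        for v in np.unique(tess.neighbors[u]):
            v = int(v)
            if not inside[v]:
                continue
            delta = tess.sites[v] - tess.sites[u]
            delta -= box * np.round(delta / box)   # minimum image
            cand = offset[u] + delta
            if v not in offset:
                offset[v] = cand
                stack.append(v)
            elif np.any(np.round((cand - offset[v]) / box) != 0):
                return True
    return False


def cluster_radius(area: float) -> float:
    """Equivalent-circle radius R = sqrt(A/pi), nm."""
    return float(np.sqrt(area / np.pi))


def weighted_mean_radius(areas: Sequence[float]) -> float:
    """Area-weighted mean equivalent-circle radius over clusters."""
    a = np.asarray(areas, dtype=float)
    if len(a) == 0:
        return np.nan
    return float(np.sum(a * np.sqrt(a / np.pi)) / a.sum())


def group_clusters(flags: np.ndarray, tess: VoronoiTessellation,
                   labels: np.ndarray | None = None,
                   time: float = 0.0) -> ClusterSet:
    """Group ordered sites into connected components of the periodic
    Delaunay adjacency (clusters may wrap the box; singletons allowed)."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != tess.n:
        raise ValueError("flags must align with tessellation sites")
    comps = _cluster_components(flags, tess)
    leaflet_area = tess.areas.sum()
    species = (np.unique(labels).tolist() if labels is not None else [])
    rows = []
    for cid, ids in enumerate(comps):
        area = float(tess.areas[ids].sum())
        l_norm, perim = boundary_length(ids, tess)
        row = {"cluster": cid, "n_sites": len(ids), "area": area,
               "radius": cluster_radius(area), "l_norm": l_norm,
               "perimeter": perim, "wraps": cluster_wraps(ids, tess)}
        if labels is not None:
            lab = np.asarray(labels)[ids]
            for sp in species:
                row[f"frac_{sp}"] = float(np.mean(lab == sp))
            ai = area_per_species(tess, labels, subset=ids)
            for sp in species:
                row[f"area_{sp}"] = float(ai.loc[sp, "mean_area"]) \
                    if ai.loc[sp, "present"] else np.nan
        rows.append(row)
    cols = ["cluster", "n_sites", "area", "radius", "l_norm", "perimeter",
            "wraps"]
    cols += [f"frac_{sp}" for sp in species] + [f"area_{sp}" for sp in species]
    table = pd.DataFrame(rows, columns=cols)
    ordered_area = float(tess.areas[flags].sum())
    return ClusterSet(members=comps, table=table, ordered_flags=flags,
                      ordered_area_fraction=ordered_area / leaflet_area,
                      leaflet_area=leaflet_area, time=time)


def area_fraction_timeseries(flags_per_frame: Sequence[np.ndarray],
                             tess_per_frame: Sequence[VoronoiTessellation],
                             times: Sequence[float] | None = None) -> pd.DataFrame:
    """Ordered-area fraction per frame."""
    fracs = []
    for flags, tess in zip(flags_per_frame, tess_per_frame):
        fracs.append(tess.areas[np.asarray(flags, bool)].sum() / tess.areas.sum())
    t = np.arange(len(fracs)) if times is None else np.asarray(times)
    return pd.DataFrame({"time": t, "ordered_area_fraction": fracs})


def detect_plateau(series: Sequence[float], tail_fraction: float = 1 / 3,
                   slope_tol: float = 5e-3) -> dict:
    """Least-squares slope of the final stretch of a time series.

    Returns the slope per frame, its standard error and a ``plateau`` flag
    (|slope| below ``slope_tol`` per frame).
    """
    y = np.asarray(series, dtype=float)
    k = max(3, int(len(y) * tail_fraction))
    tail = y[-k:]
    x = np.arange(k, dtype=float)
    slope, intercept = np.polyfit(x, tail, 1)
    resid = tail - (slope * x + intercept)
    denom = np.sum((x - x.mean()) ** 2)
    se = np.sqrt(np.sum(resid ** 2) / max(k - 2, 1) / denom)
    return {"slope": float(slope), "stderr": float(se),
            "plateau": bool(abs(slope) < slope_tol),
            "n_tail": k}
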