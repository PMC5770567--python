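"""In-plane correlations: 2D RDFs, correlation length and time, structure
factor, and windowed density maps.

Conventions
-----------
* RDFs use periodic minimum-image distances and are normalized by ring area
  times mean density, so an ideal (Poisson) point pattern gives g(r) = 1.
* The correlation length xi comes from a nonlinear fit of
  ``g(r) = a0 * exp(-r/xi) + a1``; the fit *refuses* to report xi when the
  exponential is not statistically better than a constant (F-test).
* Wave vectors are commensurate with the box, q = 2*pi*(n/Lx, m/Ly), so a
  structure-factor peak at q corresponds to a real-space period 2*pi/q.
  (Under the alternative q = n/L convention all peak positions would be
  smaller by 2*pi.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "RadialProfile", "rdf2d", "cross_rdf2d",
    "CorrelationFit", "fit_correlation_length", "fit_linear_decay",
    "SpectrumProfile", "structure_factor", "structure_factor_fft",
    "TimeCorrelation", "density_time_correlation",
    "DensityMap", "density_map", "map_contrast",
]


# ---------------------------------------------------------------- RDF

@dataclass
class RadialProfile:
    """Binned radial distribution function."""

    r: np.ndarray          # bin centres, nm
    g: np.ndarray
    counts: np.ndarray     # ordered pair counts per bin
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "g": self.g, "count": self.counts})

    def sigma(self) -> np.ndarray:
        """Counting standard error of g per bin for a same-set profile.

        Bins hold *ordered* pair counts (each unordered pair twice), so the
        count variance is 2x Poisson.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.where(self.g > 0, self.counts / self.g, np.nan)
        return np.where(np.isfinite(expected) & (expected > 0),
                        np.sqrt(2.0 * np.maximum(self.counts, 1)) / expected,
                        np.nan)


def _rdf_bins(box, bin_width, r_max):
    lx, ly = box
    if r_max is None:
        r_max = 0.5 * min(lx, ly)
    if r_max > 0.5 * min(lx, ly) + 1e-12:
        raise ValueError("r_max exceeds half the box: minimum image violated")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    return edges


def _pair_counts(xy, box, edges):
    tree = cKDTree(xy, boxsize=box)
    cum = tree.count_neighbors(tree, edges) - len(xy)  # drop i == i
    return np.diff(cum).astype(float)


def rdf2d(xy: np.ndarray, box: tuple[float, float], bin_width: float = 0.1,
          r_max: float | None = None,
          reference_xy: np.ndarray | None = None) -> RadialProfile:
    """Same-set 2D RDF with periodic minimum image; self-pairs excluded.

    Normalization: ordered pair counts divided by n * (n-1)/A * ring area,
    so a Poisson pattern gives 1 in every bin.

    ``reference_xy`` (e.g. the full site set a species subset was drawn
    from) switches to the *label-correlation* normalization: the subset RDF
    divided bin-wise by the reference RDF. This removes positional packing
    structure common to all species — randomly assigned labels then give
    exactly flat g = 1 even on near-crystalline configurations.
    """
    xy = np.mod(np.asarray(xy, dtype=float), box)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 sites")
    edges = _rdf_bins(box, bin_width, r_max)
    counts = _pair_counts(xy, box, edges)
    area = box[0] * box[1]
    ring = np.pi * np.diff(edges ** 2)
    g = counts / (n * (n - 1) / area * ring)
    if reference_xy is not None:
        ref = np.mod(np.asarray(reference_xy, dtype=float), box)
        m = len(ref)
        ref_counts = _pair_counts(ref, box, edges)
        g_ref = ref_counts / (m * (m - 1) / area * ring)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(g_ref > 0, g / g_ref, np.nan)
    r = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=r, g=g, counts=counts, bin_width=bin_width)


def cross_rdf2d(xy_a: np.ndarray, xy_b: np.ndarray, box: tuple[float, float],
                bin_width: float = 0.1, r_max: float | None = None
                ) -> RadialProfile:
    """RDF between two distinct point sets (e.g. the two leaflets)."""
    xy_a = np.mod(np.asarray(xy_a, dtype=float), box)
    xy_b = np.mod(np.asarray(xy_b, dtype=float), box)
    if len(xy_a) == 0 or len(xy_b) == 0:
        raise ValueError("both point sets must be nonempty")
    edges = _rdf_bins(box, bin_width, r_max)
    ta = cKDTree(xy_a, boxsize=box)
    tb = cKDTree(xy_b, boxsize=box)
    cum = ta.count_neighbors(tb, edges)
    counts = np.diff(cum).astype(float)
    area = box[0] * box[1]
    ring = np.pi * np.diff(edges ** 2)
    g = counts / (len(xy_a) * len(xy_b) / area * ring)
    r = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=r, g=g, counts=counts, bin_width=bin_width)


# ------------------------------------------------- correlation length

@dataclass
class CorrelationFit:
    """Result of the exponential-decay fit g(r) = a0 exp(-r/xi) + a1."""

    xi: float
    a0: float
    a1: float
    success: bool
    p_value: float            # F-test of exponential vs constant
    rss: float
    fit_range: tuple[float, float]
    message: str = ""
    covariance: np.ndarray | None = None


def _exp_model(r, a0, xi, a1):
    return a0 * np.exp(-r / xi) + a1


def fit_correlation_length(profile: RadialProfile,
                           fit_range: tuple[float, float] = (1.0, None),
                           alpha: float = 0.05) -> CorrelationFit:
    """Nonlinear least squares for the correlation length.

    Multi-start over xi; refuses (``success=False``) when the exponential
    does not beat a constant at level ``alpha``, when fewer than 5 bins lie
    in range, or when the optimizer fails.
    """
    lo, hi = fit_range
    hi = profile.r.max() if hi is None else hi
    mask = (profile.r >= lo) & (profile.r <= hi) & np.isfinite(profile.g)
    r, g = profile.r[mask], profile.g[mask]
    if len(r) < 5:
        raise ValueError("need at least 5 bins in the fit range")
    rng_span = max(r.max() - r.min(), profile.bin_width)
    best = None
    for xi0 in (0.1 * rng_span, 0.3 * rng_span, rng_span, 3 * rng_span):
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, r, g, p0=[max(g[0] - g[-1], 1e-3), xi0, g[-1]],
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((g - _exp_model(r, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss, pcov)
    if best is None:
        return CorrelationFit(np.nan, np.nan, np.nan, False, np.nan, np.nan,
                              (lo, hi), message="optimizer failed to converge")
    (a0, xi, a1), rss, pcov = best
    rss0 = float(np.sum((g - g.mean()) ** 2))
    dof = len(r) - 3
    if dof <= 0 or rss <= 0:
        p = 0.0
    else:
        f_stat = max((rss0 - rss) / 2.0, 0.0) / (rss / dof)
        p = float(stats.f.sf(f_stat, 2, dof))
    ok = p <= alpha and xi > profile.bin_width  # sub-bin decay is unresolvable
    msg = "" if ok else (f"exponential not preferred over constant (p={p:.3g})"
                         if p > alpha else "decay length below bin resolution")
    return CorrelationFit(xi=float(xi), a0=float(a0), a1=float(a1),
                          success=bool(ok), p_value=p, rss=rss,
                          fit_range=(lo, hi), message=msg, covariance=pcov)


def fit_linear_decay(profile: RadialProfile,
                     fit_range: tuple[float, float] = (2.0, None)) -> dict:
    """Straight-line fit g(r) = b0 + b1 r on the configured range.

    Long-range (linear) decay with negative slope is the phase-separated
    signature; short-range (exponential) decay marks a single phase.
    """
    lo, hi = fit_range
    hi = 0.8 * profile.r.max() if hi is None else hi
    mask = (profile.r >= lo) & (profile.r <= hi) & np.isfinite(profile.g)
    r, g = profile.r[mask], profile.g[mask]
    if len(r) < 3:
        raise ValueError("need at least 3 bins in the fit range")
    b1, b0 = np.polyfit(r, g, 1)
    resid = g - (b0 + b1 * r)
    rss = float(np.sum(resid ** 2))
    dof = max(len(r) - 2, 1)
    se_b1 = float(np.sqrt(rss / dof / np.sum((r - r.mean()) ** 2)))
    return {"b0": float(b0), "b1": float(b1), "rss": rss, "se_b1": se_b1,
            "n": int(len(r)), "fit_range": (lo, hi)}


# ---------------------------------------------------- structure factor

@dataclass
class SpectrumProfile:
    """Radially averaged static structure factor on commensurate q."""

    q: np.ndarray              # radial bin centres, 1/nm
    s: np.ndarray
    s2d: np.ndarray            # (2M+1, 2M+1) grid, q=0 at centre
    qx: np.ndarray
    qy: np.ndarray
    q_resolution: float        # 1/nm, one grid step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q, "S": self.s})

    def peak(self, q_min: float = 0.0) -> tuple[float, float]:
        """(q, S) of the largest radial peak with q > q_min."""
        sel = self.q > q_min
        i = int(np.nanargmax(np.where(sel, self.s, -np.inf)))
        return float(self.q[i]), float(self.s[i])


def structure_factor(xy: np.ndarray, box: tuple[float, float],
                     q_max: float = 3.0) -> SpectrumProfile:
    """S(q) = |sum_n exp(-i q.r_n)|^2 / N on the commensurate grid
    q = 2 pi (n/Lx, m/Ly), radially averaged in bins of one grid step.

    The q = 0 forward-scattering term is excluded from the radial profile.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 scatterers")
    lx, ly = box
    mx = max(1, int(np.floor(q_max * lx / (2 * np.pi))))
    my = max(1, int(np.floor(q_max * ly / (2 * np.pi))))
    qx = 2 * np.pi * np.arange(-mx, mx + 1) / lx
    qy = 2 * np.pi * np.arange(-my, my + 1) / ly
    phx = np.exp(-1j * np.outer(qx, xy[:, 0]))
    phy = np.exp(-1j * np.outer(qy, xy[:, 1]))
    f = phx @ phy.T  # F[m1, m2] = sum_n exp(-i (qx_m1 x_n + qy_m2 y_n))
    s2d = (f.real ** 2 + f.imag ** 2) / n

    dq = 2 * np.pi / max(lx, ly)
    qq = np.hypot(qx[:, None], qy[None, :])
    mask = qq > 1e-12          # exclude q = 0
    nbins = int(np.ceil(qq[mask].max() / dq))
    idx = np.minimum((qq[mask] / dq).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=s2d[mask], minlength=nbins)
    cnts = np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        s_rad = sums / cnts
    centres = (np.arange(nbins) + 0.5) * dq
    keep = cnts > 0
    return SpectrumProfile(q=centres[keep], s=s_rad[keep], s2d=s2d,
                           qx=qx, qy=qy, q_resolution=dq)


def structure_factor_fft(grid_counts: np.ndarray, box: tuple[float, float],
                         n_scatterers: int | None = None) -> np.ndarray:
    """|FFT of a gridded point density|^2 / N on commensurate q.

    For scatterers snapped to the grid this equals the direct sum exactly;
    it is the independent cross-check route, not the default implementation.
    Returns the unshifted 2D array indexed like ``np.fft.fft2`` output.
    """
    c = np.asarray(grid_counts, dtype=float)
    n = c.sum() if n_scatterers is None else n_scatterers
    f = np.fft.fft2(c)
    return (f.real ** 2 + f.imag ** 2) / n


# ------------------------------------------------- correlation time

@dataclass
class TimeCorrelation:
    """Local-density autocorrelation and its single-exponential decay time."""

    lags: np.ndarray          # ns
    c: np.ndarray             # normalized, c[0] = 1
    tau: float                # ns; inf when static, nan when unresolved
    status: str               # "ok" | "static" | "unresolved" | "no_decay"
    grid: tuple[int, int]


def density_time_correlation(frames_xy, box: tuple[float, float],
                             dt: float, grid: tuple[int, int] = (20, 20),
                             n_lags: int = 9) -> TimeCorrelation:
    """Correlation time of the local density on a coarse grid.

    The local density is sampled on ``grid`` cells in each frame; the
    autocorrelation of the mean-subtracted per-cell series, averaged over
    cells and normalized to C(0) = 1, is fit by exp(-t/tau) over lags
    1..n_lags. The default protocol (20 x 20 cells, 10 frames -> 9 lags)
    assumes density changes little between consecutive frames.
    """
    frames_xy = [np.asarray(f, dtype=float) for f in frames_xy]
    n_frames = len(frames_xy)
    if n_frames < n_lags + 1:
        raise ValueError("need at least n_lags + 1 frames")
    gx, gy = grid
    dens = np.empty((n_frames, gx * gy))
    for t, xy in enumerate(frames_xy):
        h, _, _ = np.histogram2d(xy[:, 0] % box[0], xy[:, 1] % box[1],
                                 bins=grid, range=[[0, box[0]], [0, box[1]]])
        dens[t] = h.ravel()
    delta = dens - dens.mean(axis=0)
    c0 = np.mean(delta ** 2)
    lags = np.arange(n_lags + 1) * dt
    if c0 < 1e-12:
        return TimeCorrelation(lags=lags, c=np.ones(n_lags + 1), tau=np.inf,
                               status="static", grid=grid)
    c = np.empty(n_lags + 1)
    for k in range(n_lags + 1):
        c[k] = np.mean(delta[: n_frames - k] * delta[k:]) / c0
    if c[1] < 0.05:
        return TimeCorrelation(lags=lags, c=c, tau=np.nan,
                               status="unresolved", grid=grid)
    if np.min(c[1:]) > 0.95:
        return TimeCorrelation(lags=lags, c=c, tau=np.inf,
                               status="no_decay", grid=grid)
    try:
        popt, _ = optimize.curve_fit(lambda t, tau: np.exp(-t / tau),
                                     lags[1:], c[1:], p0=[max(dt, 1e-6)],
                                     bounds=(1e-9, np.inf), maxfev=5000)
        tau = float(popt[0])
        status = "ok"
    except (RuntimeError, ValueError):
        tau, status = np.nan, "unresolved"
    return TimeCorrelation(lags=lags, c=c, tau=tau, status=status, grid=grid)


# ------------------------------------------------------ density maps

@dataclass
class DensityMap:
    """Time-averaged 2D number density (1/nm^2) over one window."""

    density: np.ndarray
    window: tuple[int, int]       # frame index range [start, stop)
    start_time: float
    duration: float               # ns
    cell_area: float              # nm^2
    mean_count: float             # mean particle count per frame

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)


def map_contrast(dmap: DensityMap) -> float:
    """Coefficient of variation of the map — 0 for a flat map."""
    mu = dmap.density.mean()
    return float(dmap.density.std() / mu) if mu > 0 else np.nan


def density_map(frames_xy, box: tuple[float, float], dt: float,
                window_frames: int, grid_spacing: float = 1.0
                ) -> list[DensityMap]:
    """Per-window mean density maps; windows tile the frames, no overlap."""
    frames_xy = [np.asarray(f, dtype=float) for f in frames_xy]
    if window_frames < 1 or window_frames > len(frames_xy):
        raise ValueError("window must fit within the trajectory")
    lx, ly = box
    nx = max(2, int(round(lx / grid_spacing)))
    ny = max(2, int(round(ly / grid_spacing)))
    cell_area = (lx / nx) * (ly / ny)
    maps = []
    n_windows = len(frames_xy) // window_frames
    for w in range(n_windows):
        lo = w * window_frames
        acc = np.zeros((nx, ny))
        for xy in frames_xy[lo: lo + window_frames]:
            h, _, _ = np.histogram2d(xy[:, 0] % lx, xy[:, 1] % ly,
                                     bins=(nx, ny),
                                     range=[[0, lx], [0, ly]])
            acc += h
        acc /= window_frames
        maps.append(DensityMap(density=acc / cell_area,
                               window=(lo, lo + window_frames),
                               start_time=lo * dt,
                               duration=window_frames * dt,
                               cell_area=cell_area,
                               mean_count=float(acc.sum())))
    return maps
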