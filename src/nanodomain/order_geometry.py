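"""Chain orientational order, leaflet surface fitting, mean curvature, and
lateral diffusion.

Order parameter
---------------
For each internal chain site n the segment vector runs from site n-1 to
site n+1; with theta its angle to the leaflet normal, the per-site
contribution is P2(cos theta) = (3 cos^2 theta - 1)/2, averaged over sites,
chains and lipids (sterol-like species excluded by default). S_z is 1 for
chains along the normal, -0.5 for in-plane chains, 0 for isotropic ones.

Curvature
---------
Leaflet reference sites are interpolated onto a regular periodic grid
(default 0.4 nm), smoothed with a separable 1-4-6-4-1 binomial kernel, and
differentiated with periodic central differences in the Monge gauge. Sign
convention: a surface bulging toward +z has positive mean curvature H;
principal curvatures satisfy c1 >= c2 and H = (c1 + c2)/2.

Diffusion
---------
The Einstein relation on in-plane mean-squared displacement: MSD(dt) is
time-origin- and ensemble-averaged (FFT algorithm), and D = slope/4 from a
straight-line fit over the middle third of the lag range by default.
Requires unwrapped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import convolve1d

from .synthetic import CM2_S_PER_NM2_NS

__all__ = ["OrderResult", "chain_order", "SurfaceGrid", "fit_surface",
           "binomial_smooth", "CurvatureField", "curvature",
           "lateral_diffusion", "msd"]


# ------------------------------------------------------------- order

@dataclass
class OrderResult:
    per_lipid: np.ndarray      # (n_included,) mean P2 per lipid
    mean: float
    std: float
    n_lipids: int
    n_skipped: int
    excluded_species: tuple


def chain_order(chains, normal_axis: int = 2,
                species: np.ndarray | None = None,
                excluded_species: tuple = ("chol",)) -> OrderResult:
    """Chain orientational order parameter S_z.

    Parameters
    ----------
    chains : array (n, n_chains, k, 3) or sequence of per-lipid arrays
        Ordered chain-site coordinates; chains with fewer than 3 sites are
        skipped (counted in ``n_skipped``).
    species : optional per-lipid labels, used to exclude sterols.
    """
    if isinstance(chains, np.ndarray) and chains.ndim == 4:
        chains = list(chains)
    per_lipid = []
    n_skipped = 0
    for li, lipid in enumerate(chains):
        if species is not None and species[li] in excluded_species:
            continue
        vals = []
        for chain in np.asarray(lipid, dtype=float):
            if len(chain) < 3:
                n_skipped += 1
                continue
            seg = chain[2:] - chain[:-2]          # site n+1 minus site n-1
            norm = np.linalg.norm(seg, axis=1)
            good = norm > 0
            cos_t = seg[good, normal_axis] / norm[good]
            vals.append(0.5 * (3.0 * cos_t ** 2 - 1.0))
        if vals:
            per_lipid.append(float(np.mean(np.concatenate(vals))))
    per_lipid = np.asarray(per_lipid)
    if per_lipid.size and (per_lipid.min() < -0.5 - 1e-9
                           or per_lipid.max() > 1.0 + 1e-9):
        raise RuntimeError("S_z outside [-0.5, 1]: corrupt chain input")
    return OrderResult(
        per_lipid=per_lipid,
        mean=float(per_lipid.mean()) if per_lipid.size else np.nan,
        std=float(per_lipid.std()) if per_lipid.size else np.nan,
        n_lipids=len(per_lipid), n_skipped=n_skipped,
        excluded_species=tuple(excluded_species))


# ----------------------------------------------------------- surface

@dataclass
class SurfaceGrid:
    """Height field z(x, y) on a regular periodic grid covering the box."""

    z: np.ndarray
    box: tuple[float, float]
    spacing: tuple[float, float]
    smoothing_passes: int = 0

    @property
    def shape(self):
        return self.z.shape


_BINOMIAL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def binomial_smooth(z: np.ndarray, passes: int = 2) -> np.ndarray:
    """Separable 1-4-6-4-1 filter with periodic wrap; mean-preserving."""
    out = np.asarray(z, dtype=float)
    for _ in range(passes):
        out = convolve1d(out, _BINOMIAL, axis=0, mode="wrap")
        out = convolve1d(out, _BINOMIAL, axis=1, mode="wrap")
    return out


def fit_surface(points: np.ndarray, box: tuple[float, float],
                grid_spacing: float = 0.4, smoothing_passes: int = 2,
                method: str = "linear") -> SurfaceGrid:
    """Interpolate scattered reference sites (x, y, z) onto a periodic grid.

    ``method='linear'`` triangulates the 3x3-tiled point set (smooth for
    scattered sites); ``'binned'`` bins z means per cell and fills gaps by
    smoothing. The grid covers the box exactly (spacing adjusted to fit).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise ValueError("need >= 4 points of shape (n, 3)")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    lx, ly = box
    nx = max(5, int(round(lx / grid_spacing)))
    ny = max(5, int(round(ly / grid_spacing)))
    gx = np.arange(nx) * (lx / nx)
    gy = np.arange(ny) * (ly / ny)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    xy = np.mod(points[:, :2], (lx, ly))
    zv = points[:, 2]
    if method == "linear":
        shifts = np.array([(dx * lx, dy * ly) for dx in (-1, 0, 1)
                           for dy in (-1, 0, 1)])
        tiled = (xy[None] + shifts[:, None]).reshape(-1, 2)
        interp = LinearNDInterpolator(tiled, np.tile(zv, 9))
        grid = interp(np.column_stack([xx.ravel(), yy.ravel()]))
        grid = grid.reshape(nx, ny)
        if np.any(~np.isfinite(grid)):  # numerically outside hull: fall back
            grid = np.where(np.isfinite(grid), grid, zv.mean())
    elif method == "binned":
        sums, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(nx, ny),
                                    range=[[0, lx], [0, ly]], weights=zv)
        cnts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(nx, ny),
                                    range=[[0, lx], [0, ly]])
        with np.errstate(invalid="ignore"):
            grid = sums / cnts
        # diffuse into empty cells, keeping observed means fixed
        filled = np.where(cnts > 0, grid, zv.mean())
        for _ in range(20):
            sm = binomial_smooth(filled, 1)
            filled = np.where(cnts > 0, grid, sm)
        grid = filled
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    grid = binomial_smooth(grid, smoothing_passes)
    return SurfaceGrid(z=grid, box=(lx, ly), spacing=(lx / nx, ly / ny),
                       smoothing_passes=smoothing_passes)


# --------------------------------------------------------- curvature

@dataclass
class CurvatureField:
    c1: np.ndarray      # larger principal curvature, 1/nm
    c2: np.ndarray
    h: np.ndarray       # mean curvature (c1 + c2)/2
    k_gauss: np.ndarray


def _periodic_derivatives(z, hx, hy):
    zx = (np.roll(z, -1, 0) - np.roll(z, 1, 0)) / (2 * hx)
    zy = (np.roll(z, -1, 1) - np.roll(z, 1, 1)) / (2 * hy)
    zxx = (np.roll(z, -1, 0) - 2 * z + np.roll(z, 1, 0)) / hx ** 2
    zyy = (np.roll(z, -1, 1) - 2 * z + np.roll(z, 1, 1)) / hy ** 2
    zxy = (np.roll(np.roll(z, -1, 0), -1, 1) - np.roll(np.roll(z, -1, 0), 1, 1)
           - np.roll(np.roll(z, 1, 0), -1, 1)
           + np.roll(np.roll(z, 1, 0), 1, 1)) / (4 * hx * hy)
    return zx, zy, zxx, zyy, zxy


def curvature(surface: SurfaceGrid) -> CurvatureField:
    """Principal and mean curvature of a Monge-gauge height field.

    Central finite differences with periodic wrap; bulging toward +z gives
    positive H, and flipping z -> -z negates H everywhere.
    """
    z = surface.z
    if z.shape[0] < 5 or z.shape[1] < 5:
        raise ValueError("grid must be at least 5x5")
    hx, hy = surface.spacing
    zx, zy, zxx, zyy, zxy = _periodic_derivatives(z, hx, hy)
    w = 1.0 + zx ** 2 + zy ** 2
    # standard Monge-gauge H has the opposite sign for an upward bulge;
    # negate to make "bulge toward +z" positive
    h = -((1 + zy ** 2) * zxx - 2 * zx * zy * zxy + (1 + zx ** 2) * zyy) \
        / (2 * w ** 1.5)
    k = (zxx * zyy - zxy ** 2) / w ** 2
    disc = np.sqrt(np.maximum(h ** 2 - k, 0.0))
    c1 = h + disc
    c2 = h - disc
    return CurvatureField(c1=c1, c2=c2, h=(c1 + c2) / 2.0, k_gauss=k)


# --------------------------------------------------------- diffusion

def msd(unwrapped: np.ndarray) -> np.ndarray:
    """Time-origin-averaged in-plane MSD per lag (FFT algorithm).

    ``unwrapped``: (n_frames, n_particles, 2), *unwrapped* coordinates.
    Returns MSD for lags 0..n_frames-1 averaged over particles.
    """
    x = np.asarray(unwrapped, dtype=float)
    n_t = x.shape[0]
    if np.all(x == x[0]):          # immobile input: exactly zero, no fp dust
        return np.zeros(n_t)
    # per particle & axis: S1 recursion + autocorrelation by FFT
    nfft = 1 << (2 * n_t - 1).bit_length()
    fts = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fts * np.conj(fts), n=nfft, axis=0)[:n_t].real
    acf = acf.sum(axis=2)                       # over x, y
    sq = (x ** 2).sum(axis=2)                   # (n_t, n)
    ss = np.concatenate([sq, np.zeros((1, sq.shape[1]))])
    sumsq = 2 * sq.sum(axis=0)
    s1 = np.empty_like(acf)
    for m in range(n_t):
        sumsq = sumsq - ss[m - 1] - ss[n_t - m]
        s1[m] = sumsq / (n_t - m)
    return (s1 - 2 * acf / (n_t - np.arange(n_t))[:, None]).mean(axis=1)


def lateral_diffusion(unwrapped: np.ndarray, dt_ns: float,
                      species: np.ndarray | None = None,
                      fit_window: tuple[float, float] = (1 / 3, 2 / 3)
                      ) -> pd.DataFrame:
    """Lateral diffusion coefficients from the Einstein relation.

    The ensemble-mean displacement (centre-of-mass motion) is removed per
    frame, so the estimate is exactly invariant to a uniform drift. The MSD
    slope comes from weighted least squares over the fit window, with
    weights ~ (T - m)/m^2 approximating the inverse variance of the
    time-origin-averaged MSD at lag m. D = slope/4.

    Returns a table per species with D in cm^2/s; ``unwrapped`` must be
    unwrapped coordinates of shape (n_frames, n, 2) with n_frames >= 10.
    """
    x = np.asarray(unwrapped, dtype=float)
    if x.ndim != 3 or x.shape[2] != 2:
        raise ValueError("unwrapped must have shape (n_frames, n, 2); "
                         "wrapped-only input must be unwrapped first")
    n_t = x.shape[0]
    if n_t < 10:
        raise ValueError("need at least 10 frames")
    x = x - x.mean(axis=1, keepdims=True)     # drop centre-of-mass motion
    if species is None:
        species = np.zeros(x.shape[1], dtype=int)
    species = np.asarray(species)
    lo = max(1, int(n_t * fit_window[0]))
    hi = max(lo + 2, int(n_t * fit_window[1]))
    lags = np.arange(n_t) * dt_ns
    mm = np.arange(n_t)
    rows = []
    for sp in np.unique(species):
        m = msd(x[:, species == sp, :])
        w = np.sqrt(n_t - mm[lo:hi]) / mm[lo:hi]
        slope, intercept = np.polyfit(lags[lo:hi], m[lo:hi], 1, w=w)
        resid = float(np.sqrt(np.mean(
            (m[lo:hi] - (slope * lags[lo:hi] + intercept)) ** 2)))
        d_nm = slope / 4.0
        rows.append({"species": sp, "D_cm2_s": d_nm * CM2_S_PER_NM2_NS,
                     "D_nm2_ns": d_nm, "intercept": float(intercept),
                     "rms_residual": resid, "lag_lo": lo, "lag_hi": hi})
    return pd.DataFrame(rows).set_index("species")
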