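"""Synthetic bilayer configurations with controlled statistical structure.

This module generates the inputs the analysis modules assume, at desk scale:

* a two-leaflet lattice-gas mixture on a triangular lattice, evolved with
  composition-conserving (Kawasaki) Monte Carlo, whose demixing is tuned by a
  like/unlike coupling ``J`` (in kT) and an interleaflet coupling ``lam``;
* straight hydrocarbon chains with a prescribed population-mean orientational
  order parameter;
* analytic height fields (plane, spherical cap, sinusoid) with closed-form
  mean curvature for validating the surface/curvature estimators;
* independent 2D Brownian trajectories with species-dependent diffusion
  coefficients.

Every generator takes an explicit integer seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._mc import run_kawasaki
from .frame import BilayerFrame, Leaflet, wrap

__all__ = [
    "SPECIES_NAMES", "ORDERED_SPECIES", "LatticeGasParams",
    "generate_lattice_gas", "generate_lattice_gas_trajectory",
    "generate_chains", "AnalyticSurface", "generate_surface",
    "BrownianTrajectory", "generate_brownian_trajectory",
    "CM2_S_PER_NM2_NS",
]

#: species codes 0, 1, 2 -> labels. "sat" is the saturated (ordered-phase
#: forming) lipid, "unsat" the unsaturated one, "chol" the sterol-like label.
SPECIES_NAMES = ("sat", "unsat", "chol")

#: labels counted as ordered-phase forming in the binary relabeling
ORDERED_SPECIES = frozenset({"sat", "chol"})

_ORDMAP = np.array([1, 0, 1], dtype=np.int8)  # sat, unsat, chol

#: 1 cm^2/s expressed in nm^2/ns is 1e5; its inverse converts back.
CM2_S_PER_NM2_NS = 1e-5


@dataclass
class LatticeGasParams:
    """Conditions for one lattice-gas configuration.

    Parameters
    ----------
    lattice_side : int
        Sites per dimension (must be even for periodic row offsets).
    species_fractions : sequence of float
        Per-species fractions, 2 or 3 entries summing to 1. Order is
        (sat, unsat[, chol]).
    coupling : float
        Like/unlike nearest-neighbour interaction J/kT >= 0. On the
        triangular lattice the 50/50 binary mixture demixes near J ~ 0.55
        (Ising mapping J_c = ln(3)/2); off-critical mixtures a little above.
    interleaflet_coupling : float
        lam/kT >= 0 favouring agreement of the binary ordered label across
        leaflets at the same site.
    sweeps : int
        Monte Carlo sweeps (1 sweep = one attempted exchange per site).
    seed : int
        RNG seed; all randomness (initial labels, MC, jitter) derives from it.
    jitter : float
        Positional noise amplitude in lattice units, in [0, 0.5).
    lattice_spacing : float
        nm per lattice unit. The default 0.8 nm gives ~0.55 nm^2 per site,
        a fluid-bilayer area per lipid.
    """

    lattice_side: int = 32
    species_fractions: Sequence[float] = (0.6, 0.4)
    coupling: float = 0.0
    interleaflet_coupling: float = 0.0
    sweeps: int = 1000
    seed: int = 0
    jitter: float = 0.15
    lattice_spacing: float = 0.8

    def __post_init__(self):
        fr = np.asarray(self.species_fractions, dtype=float)
        if fr.ndim != 1 or len(fr) not in (2, 3):
            raise ValueError("species_fractions must have 2 or 3 entries")
        if np.any(fr < 0):
            raise ValueError("species fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1 within 1e-9")
        if self.coupling < 0 or self.interleaflet_coupling < 0:
            raise ValueError("couplings must be nonnegative")
        if self.sweeps < 0:
            raise ValueError("sweeps must be >= 0")
        if not (0 <= self.jitter < 0.5):
            raise ValueError("jitter must be in [0, 0.5)")
        if self.lattice_side < 4 or self.lattice_side % 2:
            raise ValueError("lattice_side must be even and >= 4")
        self.species_fractions = tuple(fr)

    @property
    def n_species(self) -> int:
        return len(self.species_fractions)

    @property
    def n_sites(self) -> int:
        return self.lattice_side ** 2

    @property
    def box(self) -> tuple[float, float]:
        a = self.lattice_spacing
        side = self.lattice_side
        return (side * a, side * a * np.sqrt(3) / 2)


def triangular_lattice(side: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-offset triangular lattice: positions (N, 2) and neighbours (N, 6)."""
    i, j = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    i = i.ravel()
    j = j.ravel()
    x = (i + 0.5 * (j % 2)) * spacing
    y = j * spacing * np.sqrt(3) / 2
    pos = np.column_stack([x, y])

    def idx(ii, jj):
        return (ii % side) * side + (jj % side)

    odd = (j % 2).astype(bool)
    shift = np.where(odd, 1, 0)  # offset of the diagonal neighbours
    nbrs = np.empty((side * side, 6), dtype=np.int64)
    nbrs[:, 0] = idx(i - 1, j)
    nbrs[:, 1] = idx(i + 1, j)
    nbrs[:, 2] = idx(i - 1 + shift, j - 1)
    nbrs[:, 3] = idx(i + shift, j - 1)
    nbrs[:, 4] = idx(i - 1 + shift, j + 1)
    nbrs[:, 5] = idx(i + shift, j + 1)
    return pos, nbrs


def _interaction_matrix(n_species: int, coupling: float) -> np.ndarray:
    m = coupling * (1.0 - np.eye(3))
    if n_species == 3:
        # sterol-like label has full affinity with the saturated-like label
        m[0, 2] = m[2, 0] = 0.0
    return m


def _initial_species(params: LatticeGasParams, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(params.species_fractions) * params.n_sites).astype(int)
    while counts.sum() < params.n_sites:
        counts[int(np.argmax(np.asarray(params.species_fractions) * params.n_sites
                             - counts))] += 1
    spec = np.empty((2, params.n_sites), dtype=np.int8)
    base = np.repeat(np.arange(params.n_species, dtype=np.int8), counts)
    for leaf in range(2):
        spec[leaf] = rng.permutation(base)
    return spec


def _kernel_seed(seed: int, stream: int) -> int:
    return int((seed * 1_000_003 + 7919 * stream + 1) % (2 ** 31 - 1))


def _frame_from_state(params: LatticeGasParams, pos: np.ndarray,
                      spec: np.ndarray, rng: np.random.Generator,
                      time: float = 0.0) -> BilayerFrame:
    names = np.asarray(SPECIES_NAMES[: params.n_species])
    box = params.box
    amp = params.jitter * params.lattice_spacing
    leaves = {}
    for leaf, key in enumerate(("upper", "lower")):
        xy = pos + rng.uniform(-amp, amp, size=pos.shape)
        leaves[key] = Leaflet(xy=wrap(xy, box), species=names[spec[leaf]])
    return BilayerFrame(upper=leaves["upper"], lower=leaves["lower"],
                        box=box, time=time,
                        meta={"generator": "lattice_gas",
                              "coupling": params.coupling,
                              "interleaflet_coupling": params.interleaflet_coupling,
                              "seed": params.seed,
                              "lattice_side": params.lattice_side,
                              "lattice_spacing": params.lattice_spacing,
                              "species_fractions": list(params.species_fractions)})


def _check_conserved(spec: np.ndarray, counts0: np.ndarray) -> None:
    for leaf in range(2):
        counts = np.bincount(spec[leaf], minlength=3)
        if not np.array_equal(counts, counts0[leaf]):
            raise RuntimeError(
                "internal error: composition not conserved by exchange moves")


def generate_lattice_gas(params: LatticeGasParams) -> BilayerFrame:
    """Sample one two-leaflet configuration by Kawasaki Monte Carlo.

    Species counts are exactly conserved (exchange moves only); the returned
    frame is deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pos, nbrs = triangular_lattice(params.lattice_side, params.lattice_spacing)
    spec = _initial_species(params, rng)
    counts0 = np.stack([np.bincount(spec[leaf], minlength=3) for leaf in range(2)])
    m = _interaction_matrix(params.n_species, params.coupling)
    run_kawasaki(spec, nbrs, _ORDMAP, m, params.interleaflet_coupling,
                 params.sweeps, _kernel_seed(params.seed, 0))
    _check_conserved(spec, counts0)
    return _frame_from_state(params, pos, spec, rng)


def generate_lattice_gas_trajectory(params: LatticeGasParams, n_frames: int,
                                    sweeps_per_frame: int,
                                    frame_time_ns: float = 1.0) -> list[BilayerFrame]:
    """Equilibrate for ``params.sweeps`` sweeps, then record ``n_frames``
    snapshots separated by ``sweeps_per_frame`` sweeps of the same dynamics."""
    rng = np.random.default_rng(params.seed)
    pos, nbrs = triangular_lattice(params.lattice_side, params.lattice_spacing)
    spec = _initial_species(params, rng)
    counts0 = np.stack([np.bincount(spec[leaf], minlength=3) for leaf in range(2)])
    m = _interaction_matrix(params.n_species, params.coupling)
    run_kawasaki(spec, nbrs, _ORDMAP, m, params.interleaflet_coupling,
                 params.sweeps, _kernel_seed(params.seed, 0))
    frames = []
    for k in range(n_frames):
        if k > 0:
            run_kawasaki(spec, nbrs, _ORDMAP, m, params.interleaflet_coupling,
                         sweeps_per_frame, _kernel_seed(params.seed, k))
        _check_conserved(spec, counts0)
        frames.append(_frame_from_state(params, pos, spec, rng,
                                        time=k * frame_time_ns))
    return frames


def generate_chains(n_lipids: int, target_sz: float, sites_per_chain: int = 4,
                    seed: int = 0, n_chains: int = 2,
                    bond_length: float = 0.47) -> np.ndarray:
    """Straight chains whose population-mean order parameter equals target.

    Each chain is a straight run of ``sites_per_chain`` sites along a unit
    direction drawn from a two-component mixture whose mean of
    P2(cos theta) = (3 cos^2 theta - 1)/2 equals ``target_sz`` exactly:
    for targets >= 0, a fraction ``target_sz`` of chains is aligned with +z
    and the rest isotropic; for targets < 0, a fraction ``-2*target_sz`` lies
    in-plane and the rest isotropic.

    Returns an array of shape (n_lipids, n_chains, sites_per_chain, 3), nm.
    """
    if not (-0.5 <= target_sz <= 1.0):
        raise ValueError("target_sz must lie in [-0.5, 1]")
    if sites_per_chain < 3:
        raise ValueError("sites_per_chain must be >= 3")
    rng = np.random.default_rng(seed)
    n_total = n_lipids * n_chains
    u = rng.normal(size=(n_total, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pick = rng.random(n_total)
    if target_sz >= 0:
        aligned = pick < target_sz
        u[aligned] = [0.0, 0.0, 1.0]
    else:
        inplane = pick < (-2.0 * target_sz)
        phi = rng.uniform(0, 2 * np.pi, size=int(inplane.sum()))
        u[inplane] = np.column_stack([np.cos(phi), np.sin(phi),
                                      np.zeros_like(phi)])
    steps = np.arange(sites_per_chain)[None, :, None] * bond_length
    sites = u[:, None, :] * steps  # (n_total, k, 3)
    return sites.reshape(n_lipids, n_chains, sites_per_chain, 3)


@dataclass
class AnalyticSurface:
    """A sampled height field plus its closed-form mean curvature.

    Sign convention: a surface bulging toward +z has positive H.
    """

    z: np.ndarray          # (nx, ny) heights, nm
    h_true: np.ndarray     # (nx, ny) mean curvature, 1/nm
    box: tuple[float, float]
    spacing: tuple[float, float]
    interior: np.ndarray = None  # bool mask where h_true is exact & smooth

    def __post_init__(self):
        if self.interior is None:
            self.interior = np.ones_like(self.z, dtype=bool)


def _surface_grid(box, grid_spacing):
    lx, ly = box
    nx = max(8, int(round(lx / grid_spacing)))
    ny = max(8, int(round(ly / grid_spacing)))
    x = np.arange(nx) * (lx / nx)
    y = np.arange(ny) * (ly / ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return xx, yy, (lx / nx, ly / ny)


def generate_surface(kind: str, box: tuple[float, float] = (40.0, 40.0),
                     grid_spacing: float = 0.4, *, z0: float = 0.0,
                     radius: float = 10.0, rho_max: float | None = None,
                     amplitude: float = 0.5, wavelength: float = 20.0,
                     ) -> AnalyticSurface:
    """Analytic test surfaces: ``plane``, ``sphere_cap`` or ``sinusoid``.

    ``sphere_cap``: a cap of the given radius centred in the box, occupying
    in-plane radius ``rho_max`` (default 0.6 * radius); flat outside. |H| on
    the cap is 1/radius. ``sinusoid``: z = amplitude * sin(2 pi x /
    wavelength); requires amplitude * k < 1.
    """
    xx, yy, spacing = _surface_grid(box, grid_spacing)
    if kind == "plane":
        z = np.full_like(xx, z0)
        return AnalyticSurface(z=z, h_true=np.zeros_like(xx), box=box,
                               spacing=spacing)
    if kind == "sphere_cap":
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        if rho_max is None:
            rho_max = 0.6 * radius
        if rho_max >= radius:
            raise ValueError("rho_max must be < radius")
        cx, cy = box[0] / 2, box[1] / 2
        rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
        inside = rho2 < rho_max ** 2
        z = np.full_like(xx, z0)
        z[inside] = (z0 + np.sqrt(radius ** 2 - rho2[inside])
                     - np.sqrt(radius ** 2 - rho_max ** 2))
        h = np.where(inside, 1.0 / radius, 0.0)
        # exact only away from the cap rim where slope is discontinuous
        interior = rho2 < (0.7 * rho_max) ** 2
        return AnalyticSurface(z=z, h_true=h, box=box, spacing=spacing,
                               interior=interior)
    if kind == "sinusoid":
        k = 2 * np.pi / wavelength
        if abs(amplitude * k) >= 1:
            raise ValueError("require amplitude * wavenumber < 1")
        z = z0 + amplitude * np.sin(k * xx)
        zx = amplitude * k * np.cos(k * xx)
        # Monge gauge, +z-bulge positive: H = -z_xx / (2 (1+z_x^2)^{3/2})
        h = amplitude * k ** 2 * np.sin(k * xx) / (2 * (1 + zx ** 2) ** 1.5)
        return AnalyticSurface(z=z, h_true=h, box=box, spacing=spacing)
    raise ValueError(f"unknown surface kind: {kind!r}")


@dataclass
class BrownianTrajectory:
    """Independent 2D Brownian walkers; wrapped and unwrapped coordinates."""

    unwrapped: np.ndarray   # (n_frames, n, 2), nm
    species: np.ndarray     # (n,)
    box: tuple[float, float]
    dt_ns: float
    d_nm2_ns: dict          # species -> input D in nm^2/ns

    @property
    def wrapped(self) -> np.ndarray:
        return np.mod(self.unwrapped, np.asarray(self.box))

    @property
    def n_frames(self) -> int:
        return self.unwrapped.shape[0]


def generate_brownian_trajectory(n_per_species: dict[str, int],
                                 d_per_species: dict[str, float],
                                 dt_ns: float, n_frames: int,
                                 box: tuple[float, float] = (40.0, 40.0),
                                 seed: int = 0) -> BrownianTrajectory:
    """Gaussian steps with per-step in-plane MSD = 4 D dt per particle.

    ``d_per_species`` is in cm^2/s (the unit diffusion tables are printed
    in); internally converted to nm^2/ns.
    """
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    if set(n_per_species) != set(d_per_species):
        raise ValueError("species keys of counts and D must match")
    rng = np.random.default_rng(seed)
    labels, sigmas = [], []
    d_nm = {}
    for sp, n in n_per_species.items():
        d_cm = d_per_species[sp]
        if d_cm < 0:
            raise ValueError("D must be nonnegative")
        d = d_cm / CM2_S_PER_NM2_NS  # nm^2/ns
        d_nm[sp] = d
        labels += [sp] * n
        sigmas += [np.sqrt(2 * d * dt_ns)] * n
    labels = np.asarray(labels)
    sigmas = np.asarray(sigmas)[None, :, None]
    n = len(labels)
    start = rng.uniform([0, 0], box, size=(n, 2))
    steps = rng.normal(size=(n_frames - 1, n, 2)) * sigmas
    traj = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    return BrownianTrajectory(unwrapped=traj, species=labels, box=tuple(box),
                              dt_ns=dt_ns, d_nm2_ns=d_nm)
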