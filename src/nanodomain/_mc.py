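"""Numba kernel for the conserved-composition (Kawasaki) lattice-gas sampler.

The Hamiltonian, in units of kT:

    E = sum over leaflets of sum over nearest-neighbour pairs  M[s_i, s_j]
        - lam * (number of vertically adjacent site pairs whose binary
                 ordered/disordered relabelings agree)

``M`` is a symmetric species interaction matrix (J on unlike pairs by
default, with the sterol-like/saturated-like affinity folded in), ``lam``
couples the two leaflets through the ordered-label agreement.  Moves are
composition-conserving exchanges of two randomly chosen sites within one
leaflet (long-range Kawasaki exchange), accepted by Metropolis.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kawasaki", "lattice_energy"]


@njit(cache=True)
def run_kawasaki(spec, nbrs, ordmap, M, lam, sweeps, seed):  # pragma: no cover - jitted
    """Evolve ``spec`` (shape (2, N), int8 species codes) in place.

    One sweep = N attempted exchanges. Deterministic given ``seed``.
    """
    np.random.seed(seed)
    n_sites = spec.shape[1]
    n_nbr = nbrs.shape[1]
    for _ in range(sweeps):
        for _ in range(n_sites):
            leaf = 0 if np.random.random() < 0.5 else 1
            a = np.random.randint(n_sites)
            b = np.random.randint(n_sites)
            sa = spec[leaf, a]
            sb = spec[leaf, b]
            if sa == sb:
                continue
            d_e = 0.0
            for t in range(n_nbr):
                nb = nbrs[a, t]
                if nb != b:
                    sn = spec[leaf, nb]
                    d_e += M[sb, sn] - M[sa, sn]
            for t in range(n_nbr):
                nb = nbrs[b, t]
                if nb != a:
                    sn = spec[leaf, nb]
                    d_e += M[sa, sn] - M[sb, sn]
            if lam != 0.0:
                other = 1 - leaf
                oa = ordmap[spec[other, a]]
                ob = ordmap[spec[other, b]]
                before = 0.0
                after = 0.0
                if ordmap[sa] == oa:
                    before += 1.0
                if ordmap[sb] == ob:
                    before += 1.0
                if ordmap[sb] == oa:
                    after += 1.0
                if ordmap[sa] == ob:
                    after += 1.0
                d_e += -lam * (after - before)
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                spec[leaf, a] = sb
                spec[leaf, b] = sa


@njit(cache=True)
def lattice_energy(spec, nbrs, ordmap, M, lam):  # pragma: no cover - jitted
    """Total energy (kT units); each intra-leaflet pair counted once."""
    n_sites = spec.shape[1]
    n_nbr = nbrs.shape[1]
    e = 0.0
    for leaf in range(2):
        for i in range(n_sites):
            si = spec[leaf, i]
            for t in range(n_nbr):
                j = nbrs[i, t]
                if j > i:
                    e += M[si, spec[leaf, j]]
    for i in range(n_sites):
        if ordmap[spec[0, i]] == ordmap[spec[1, i]]:
            e -= lam
    return e
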