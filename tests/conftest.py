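import numpy as np
import pytest

from nanodomain import LatticeGasParams, generate_lattice_gas
from nanodomain.synthetic import triangular_lattice


@pytest.fixture(scope="session")
def mixed_frame():
    """Small ideally mixed lattice-gas frame (J = 0)."""
    params = LatticeGasParams(lattice_side=20, species_fractions=(0.6, 0.4),
                              coupling=0.0, sweeps=200, seed=11)
    return generate_lattice_gas(params)


@pytest.fixture(scope="session")
def jittered_lattice():
    """(positions, box, lattice neighbours) of a jittered triangular lattice."""
    side = 40
    rng = np.random.default_rng(7)
    pos, nbrs = triangular_lattice(side, 1.0)
    box = (float(side), side * np.sqrt(3) / 2)
    pos = np.mod(pos + rng.uniform(-0.15, 0.15, pos.shape), box)
    return pos, box, nbrs


def write_gro_fixture(path, n_side=2):
    """Hand-written coarse-grained bilayer GRO file: two leaflets of
    n_side^2 lipids each, alternating two residue types, straight chains."""
    lines = ["synthetic bilayer fixture", ""]
    coords = []
    n_atom = 0
    n_lip = 2 * n_side * n_side
    for li in range(n_lip):
        res = li + 1
        resname = "LIPA" if li % 2 == 0 else "LIPB"
        upper = li < n_lip // 2
        k = li % (n_lip // 2)
        x = 1.0 + (k % n_side) * 2.0
        y = 1.0 + (k // n_side) * 2.0
        zref = 3.5 if upper else 1.5
        atoms = [("REF", x, y, zref)]
        sgn = 1.0 if upper else -1.0
        for c, pref in enumerate("AB"):
            for kk in range(3):
                atoms.append((f"C{kk + 1}{pref}", x + 0.05 * c, y,
                              zref - sgn * (0.4 + 0.3 * kk)))
        for name, ax, ay, az in atoms:
            n_atom += 1
            coords.append(f"{res:5d}{resname:<5s}{name:>5s}{n_atom:5d}"
                          f"{ax:8.3f}{ay:8.3f}{az:8.3f}")
    lines[1] = str(n_atom)
    lines += coords
    lines.append("  8.00000  8.00000  5.00000")
    path.write_text("\n".join(lines) + "\n")
    return path


TOPOLOGY_MAP = {
    "LIPA": {"species": "sat", "ref_site": "REF",
             "chains": [["C1A", "C2A", "C3A"], ["C1B", "C2B", "C3B"]]},
    "LIPB": {"species": "unsat", "ref_site": "REF",
             "chains": [["C1A", "C2A", "C3A"], ["C1B", "C2B", "C3B"]]},
}
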