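"""Ordered-site assignment, connectivity grouping, and cluster morphology."""

import numpy as np
import pytest

import nanodomain as nd
from nanodomain import (local_composition, assign_ordered_sites,
                        group_clusters, boundary_length, cluster_radius,
                        weighted_mean_radius)
from nanodomain.tessellation import periodic_voronoi
from nanodomain.synthetic import triangular_lattice, LatticeGasParams, \
    generate_lattice_gas


def rect_lattice_tess(nx=10, ny=10, sx=1.0, sy=0.9):
    """Rectangular lattice (unambiguous 4-neighbour Voronoi adjacency)."""
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack([i.ravel() * sx, j.ravel() * sy])
    box = (nx * sx, ny * sy)
    return periodic_voronoi(xy, box), xy, box


def flood_fill_components(flags, neighbor_sets):
    """Brute-force connected components over flagged sites."""
    seen = set()
    comps = []
    for start in np.flatnonzero(flags):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for v in neighbor_sets[u]:
                if flags[v] and v not in comp:
                    stack.append(int(v))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestLocalComposition:
    def test_pure_leaflet_everywhere_one(self):
        tess, xy, _ = rect_lattice_tess()
        labels = np.full(tess.n, "sat")
        conc = local_composition(tess, labels, {"sat"})
        assert np.all(conc == 1.0)

    def test_checkerboard_shell_enumeration(self):
        """On a 4-neighbour lattice a checkerboard gives 1/5 at ordered
        centres and 4/5 at disordered centres (5-site shell by hand)."""
        tess, xy, _ = rect_lattice_tess()
        i = np.round(xy[:, 0]).astype(int)
        j = np.round(xy[:, 1] / 0.9).astype(int)
        labels = np.where((i + j) % 2 == 0, "sat", "unsat")
        conc = local_composition(tess, labels, {"sat"})
        assert np.all(np.isin(np.round(conc, 10), [0.2, 0.8]))
        assert np.all(conc[labels == "sat"] == pytest.approx(0.2))
        assert np.all(conc[labels == "unsat"] == pytest.approx(0.8))

    def test_random_labels_unbiased(self):
        rng = np.random.default_rng(0)
        tess, _, _ = rect_lattice_tess(40, 40)
        half = tess.n // 2
        labels = rng.permutation(["sat"] * half + ["unsat"] * half)
        conc = local_composition(tess, labels, {"sat"})
        assert conc.mean() == pytest.approx(0.5, abs=0.01)

    def test_empty_ordered_set_rejected(self):
        tess, _, _ = rect_lattice_tess(5, 5)
        with pytest.raises(ValueError):
            local_composition(tess, np.full(tess.n, "sat"), set())


class TestOrderedAssignment:
    def test_homogeneous_leaflet_has_zero_ordered_sites(self):
        tess, _, _ = rect_lattice_tess()
        labels = np.full(tess.n, "sat")
        conc = local_composition(tess, labels, {"sat"})
        flags = assign_ordered_sites(conc, 0.999999)
        # all local concentrations equal 1, but the strict > on a pure
        # system's mean (1) flags nothing
        assert not np.any(assign_ordered_sites(conc, 1.0 - 1e-12) & (conc <= 1.0 - 1e-12))
        assert not np.any(conc > 1.0)

    def test_pure_patch_in_sea_flags_patch_plus_fringe(self):
        """Enumerated 20x20 toy lattice: a 4x4 saturated patch in an
        unsaturated sea flags the patch and its adjacency fringe only."""
        tess, xy, _ = rect_lattice_tess(20, 20)
        i = np.round(xy[:, 0]).astype(int)
        j = np.round(xy[:, 1] / 0.9).astype(int)
        patch = (i >= 8) & (i < 12) & (j >= 8) & (j < 12)
        labels = np.where(patch, "sat", "unsat")
        conc = local_composition(tess, labels, {"sat"})
        gmean = patch.mean()
        flags = assign_ordered_sites(conc, gmean)
        # hand enumeration: with gmean = 16/400, a site is flagged iff at
        # least one saturated lipid sits in its 5-site shell — the patch
        # plus its 4-neighbour fringe
        grid = patch.reshape(20, 20)
        exp = grid.copy()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            exp |= np.roll(grid, (di, dj), (0, 1))
        assert np.array_equal(flags, exp.ravel())

    def test_minority_random_labels_flagged_fraction_band(self):
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tess, _, _ = rect_lattice_tess(30, 30)
            labels = np.where(rng.random(tess.n) < 0.31, "sat", "unsat")
            conc = local_composition(tess, labels, {"sat"})
            flags = assign_ordered_sites(conc, float((labels == "sat").mean()))
            fractions.append(flags.mean())
        assert 0.2 < np.mean(fractions) < 0.5

    def test_invalid_global_mean_rejected(self):
        with pytest.raises(ValueError):
            assign_ordered_sites(np.array([0.5]), 0.0)


class TestGrouping:
    def test_two_separated_patches_are_two_clusters(self):
        tess, xy, _ = rect_lattice_tess(20, 20)
        i = np.round(xy[:, 0]).astype(int)
        j = np.round(xy[:, 1] / 0.9).astype(int)
        flags = (((i < 3) & (j < 3)) | ((i >= 10) & (i < 13) & (j >= 10)
                                        & (j < 13)))
        cset = group_clusters(flags, tess)
        assert cset.n_clusters == 2

    def test_stripe_across_boundary_is_one_cluster(self):
        tess, xy, _ = rect_lattice_tess(20, 20)
        i = np.round(xy[:, 0]).astype(int)
        flags = (i <= 1) | (i >= 18)   # wraps periodically
        cset = group_clusters(flags, tess)
        assert cset.n_clusters == 1

    def test_random_flags_match_flood_fill_oracle(self, jittered_lattice):
        pos, box, _ = jittered_lattice
        tess = periodic_voronoi(pos, box)
        rng = np.random.default_rng(4)
        flags = rng.random(tess.n) < 0.3
        cset = group_clusters(flags, tess)
        oracle = flood_fill_components(flags, tess.neighbor_sets())
        ours = {frozenset(map(int, m)) for m in cset.members}
        assert ours == oracle

    def test_ordered_plus_disordered_area_is_leaflet_area(self, mixed_frame):
        tess = periodic_voronoi(mixed_frame.upper.xy, mixed_frame.box)
        labels = mixed_frame.upper.species
        conc = local_composition(tess, labels, {"sat"})
        flags = assign_ordered_sites(conc, float((labels == "sat").mean()))
        ordered = tess.areas[flags].sum()
        disordered = tess.areas[~flags].sum()
        assert ordered + disordered == pytest.approx(
            mixed_frame.box[0] * mixed_frame.box[1], rel=1e-9)


class TestBoundary:
    def test_single_hexagonal_cell_closed_form(self):
        pos, _ = triangular_lattice(12, 1.0)
        box = (12.0, 12 * np.sqrt(3) / 2)
        tess = periodic_voronoi(pos, box)
        l_norm, perim = boundary_length([30], tess)
        s = 1 / np.sqrt(3)   # hexagon side for unit lattice spacing
        expected = 6 * s / (2 * np.sqrt(np.pi * 1.5 * np.sqrt(3) * s ** 2))
        assert l_norm == pytest.approx(expected, rel=1e-6)
        assert l_norm == pytest.approx(1.0501, abs=2e-4)

    def test_compact_droplet_frozen_oracle_value(self, jittered_lattice):
        """Most compact ~550-site droplet (hexagonal graph ball): L ~ 1.23,
        the honeycomb zigzag floor (2/sqrt(3)) times the hexagon shape
        ratio. Frozen from the 0.02 nm rasterization oracle."""
        pos, box, nbrs = jittered_lattice
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import dijkstra
        n = len(pos)
        adj = csr_matrix((np.ones(6 * n),
                          (np.repeat(np.arange(n), 6), nbrs.ravel())),
                         shape=(n, n))
        dist = dijkstra(adj, unweighted=True, indices=[20 * 40 + 20]).ravel()
        ids = np.flatnonzero(dist <= 13)
        assert len(ids) >= 500
        tess = periodic_voronoi(pos, box)
        l_norm, _ = boundary_length(ids, tess)
        assert 2 / np.sqrt(3) <= l_norm <= 1.30

    def test_dendritic_cluster_is_rough(self, jittered_lattice):
        pos, box, _ = jittered_lattice
        tess = periodic_voronoi(pos, box)
        rng = np.random.default_rng(2)
        sets = tess.neighbor_sets()
        flags = np.zeros(tess.n, bool)
        cur = 0
        flags[0] = True
        for _ in range(300):
            nxt = sets[cur]
            cur = int(nxt[rng.integers(len(nxt))])
            flags[cur] = True
        l_norm, _ = boundary_length(np.flatnonzero(flags), tess)
        assert l_norm > 2.0

    def test_isoperimetric_bound_on_random_flags(self, jittered_lattice):
        """L >= 1 for every cluster contractible in the plane; a cluster
        wound around the torus may beat the planar disc bound and is
        excluded by its wraps flag."""
        pos, box, _ = jittered_lattice
        tess = periodic_voronoi(pos, box)
        rng = np.random.default_rng(8)
        flags = rng.random(tess.n) < 0.35
        cset = group_clusters(flags, tess)
        table = cset.table.dropna(subset=["l_norm"])
        assert np.all(table.loc[~table.wraps, "l_norm"] >= 1.0)

    def test_wrap_detection_flags_periodic_band(self):
        tess, xy, _ = rect_lattice_tess(20, 20)
        i = np.round(xy[:, 0]).astype(int)
        j = np.round(xy[:, 1] / 0.9).astype(int)
        band = (j >= 5) & (j <= 7)            # winds around x
        blob = (i >= 3) & (i <= 7) & (j >= 12) & (j <= 16)
        cset = group_clusters(band | blob, tess)
        by_size = cset.table.sort_values("n_sites")
        assert list(by_size.wraps) == [False, True]

    def test_whole_leaflet_cluster_flagged_undefined(self):
        tess, _, _ = rect_lattice_tess(6, 6)
        l_norm, perim = boundary_length(np.arange(tess.n), tess)
        assert np.isnan(l_norm) and perim == 0.0


class TestRadiusAndTimeseries:
    def test_unit_radius_for_area_pi(self):
        assert cluster_radius(np.pi) == pytest.approx(1.0)

    def test_area_weighted_mean_radius_arithmetic(self):
        # R = sqrt(A/pi): 25 -> 2.8209, 100 -> 5.6419; weighted by area
        expected = (25 * np.sqrt(25 / np.pi) + 100 * np.sqrt(100 / np.pi)) / 125
        assert weighted_mean_radius([25.0, 100.0]) == pytest.approx(expected)
        assert expected == pytest.approx(5.078, abs=1e-3)

    def test_mean_radius_nondecreasing_in_coupling(self):
        radii = []
        for coupling in (0.2, 0.6, 1.1):
            vals = []
            for seed in range(3):
                frame = generate_lattice_gas(LatticeGasParams(
                    lattice_side=20, coupling=coupling, sweeps=1200,
                    seed=seed))
                tess = periodic_voronoi(frame.upper.xy, frame.box)
                labels = frame.upper.species
                conc = local_composition(tess, labels, {"sat"})
                flags = assign_ordered_sites(
                    conc, float((labels == "sat").mean()))
                cset = group_clusters(flags, tess)
                vals.append(weighted_mean_radius(cset.table.area.values))
            radii.append(np.mean(vals))
        assert radii[0] <= radii[1] <= radii[2]

    def test_static_frames_constant_series(self, mixed_frame):
        tess = periodic_voronoi(mixed_frame.upper.xy, mixed_frame.box)
        labels = mixed_frame.upper.species
        conc = local_composition(tess, labels, {"sat"})
        flags = assign_ordered_sites(conc, float((labels == "sat").mean()))
        df = nd.area_fraction_timeseries([flags] * 5, [tess] * 5)
        assert df.ordered_area_fraction.nunique() == 1
        stats = nd.detect_plateau(df.ordered_area_fraction, tail_fraction=1.0)
        assert stats["plateau"]
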