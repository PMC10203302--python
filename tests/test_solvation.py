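"""Probe-grid microsolvation: maps, site extraction, placement, LIE scoring."""

import numpy as np
import pytest
from types import SimpleNamespace

from conformerge.params import COULOMB_KCAL_A
from conformerge.solvation import (
    CLASH_CLAMP_KCAL,
    MicrosolvComplex,
    SolvationMap,
    SolventProbe,
    compare_ensembles,
    energy_map,
    find_sites,
    lie_energy,
    place_probes,
)

from conftest import make_cluster_solute


def single_atom_solute(charge=0.0, radius=1.5):
    return SimpleNamespace(
        positions=np.zeros((1, 3)),
        charges=np.array([charge]),
        vdw_radii=np.array([radius]),
        elements=["C"],
    )


def random_map(seed, shape=(9, 9, 9)):
    rng = np.random.default_rng(seed)
    return SolvationMap(
        origin_A=np.zeros(3),
        spacing_A=1.0,
        energy_kcal=rng.normal(-1.0, 1.5, shape),
        best_orientation=np.zeros(shape, dtype=np.int32),
        rotations=np.eye(3)[None, :, :],
    )


def brute_force_sites(m, threshold, min_sep):
    """Independent enumeration: scan every voxel's in-bounds 26-neighborhood
    for local minima, then greedy separation by ascending energy."""
    e = m.energy_kcal
    nx, ny, nz = e.shape
    cands = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if e[i, j, k] >= threshold:
                    continue
                is_min = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if (di, dj, dk) == (0, 0, 0) or not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                                continue
                            if e[ii, jj, kk] < e[i, j, k]:
                                is_min = False
                if is_min:
                    cands.append((e[i, j, k], i, j, k))
    cands.sort()
    out = []
    for energy, i, j, k in cands:
        p = m.voxel_position((i, j, k))
        if all(np.linalg.norm(p - q) >= min_sep for q in out):
            out.append(p)
    return out


class TestEnergyMap:
    def test_ion_dipole_closed_form(self):
        """Map minimum at distance d from a point charge matches the optimal
        head-on orientation of a two-site dipole probe (Coulomb only)."""
        solute = single_atom_solute(charge=1.0)
        l, dq = 1.0, 0.3
        probe = SolventProbe(
            "dipole",
            np.array([[0, 0, -l / 2], [0, 0, l / 2]]),
            np.array([0.5, 0.5]),
            np.array([dq, -dq]),
            np.array([0.0, 0.0]),
        )
        m = energy_map(solute, probe, spacing_A=0.5, margin_A=6.0, n_orient=64, seed=0)
        d = 5.0
        idx = tuple(np.round((np.array([d, 0, 0]) - m.origin_A) / m.spacing_A).astype(int))
        e_opt = COULOMB_KCAL_A * (-dq) / (d - l / 2) + COULOMB_KCAL_A * dq / (d + l / 2)
        # discrete orientations cannot beat the optimum, only approach it
        assert m.energy_kcal[idx] >= e_opt - 1e-9
        assert m.energy_kcal[idx] == pytest.approx(e_opt, rel=0.06)

    def test_clamp_at_atom_center(self):
        solute = single_atom_solute()
        probe = SolventProbe.acetonitrile()
        m = energy_map(solute, probe, spacing_A=0.5, margin_A=3.0, n_orient=8, seed=0)
        center_idx = tuple(np.round((-m.origin_A) / m.spacing_A).astype(int))
        assert m.energy_kcal[center_idx] == CLASH_CLAMP_KCAL

    def test_far_field_decay_of_neutral_solute(self):
        """50 Å from a neutral solute the probe interaction is negligible."""
        from conformerge.solvation import _pair_tables, _probe_energy

        solute = single_atom_solute(charge=0.0)
        probe = SolventProbe.acetonitrile()
        sigma, eps, qq, clash = _pair_tables(solute, probe)
        e = _probe_energy(probe.site_offsets + np.array([50.0, 0, 0]), solute.positions, sigma, eps, qq, clash)
        assert abs(e) < 0.01

    def test_oversized_grid_rejected(self):
        solute = single_atom_solute()
        with pytest.raises(ValueError, match="reduce margin"):
            energy_map(solute, SolventProbe.acetonitrile(), spacing_A=0.25, margin_A=40.0)

    def test_deeper_charge_lowers_local_minimum(self):
        probe = SolventProbe.acetonitrile()
        m_weak = energy_map(single_atom_solute(charge=0.5), probe, spacing_A=0.5, margin_A=4.0, n_orient=16, seed=1)
        m_strong = energy_map(single_atom_solute(charge=1.0), probe, spacing_A=0.5, margin_A=4.0, n_orient=16, seed=1)
        assert m_strong.energy_kcal.min() < m_weak.energy_kcal.min()


class TestFindSites:
    def test_all_above_threshold_gives_no_sites(self):
        m = random_map(0)
        m.energy_kcal = np.abs(m.energy_kcal)
        assert find_sites(m, -1.5) == []

    def test_two_constructed_wells(self):
        m = random_map(1)
        m.energy_kcal = np.zeros((11, 11, 11))
        for center, depth in (((2, 5, 5), -5.0), ((8, 5, 5), -4.0)):
            idx = np.indices((11, 11, 11)).reshape(3, -1).T
            d2 = np.sum((idx - np.array(center)) ** 2, axis=1).reshape(11, 11, 11)
            m.energy_kcal += depth * np.exp(-d2 / 4.0)
        m.best_orientation = np.zeros((11, 11, 11), dtype=np.int32)
        sites = find_sites(m, -1.5, min_separation_A=3.5)
        assert len(sites) == 2
        positions = sorted(tuple(np.round(s.position_A).astype(int)) for s in sites)
        assert positions == [(2, 5, 5), (8, 5, 5)]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, seed):
        m = random_map(seed)
        got = [s.position_A for s in find_sites(m, -1.5, 2.5)]
        expect = brute_force_sites(m, -1.5, 2.5)
        assert len(got) == len(expect)
        for g, x in zip(got, expect):
            assert np.allclose(g, x)

    def test_site_count_monotone_in_threshold_and_separation(self):
        m = random_map(7, shape=(12, 12, 12))
        n_loose = len(find_sites(m, -0.5, 2.0))
        n_strict = len(find_sites(m, -2.5, 2.0))
        assert n_strict <= n_loose
        n_near = len(find_sites(m, -1.0, 1.5))
        n_far = len(find_sites(m, -1.0, 4.0))
        assert n_far <= n_near

    def test_site_energies_below_threshold(self):
        m = random_map(3)
        for s in find_sites(m, -1.5):
            assert s.energy_kcal < -1.5


class TestPlacementAndLIE:
    def test_no_sites_gives_zero_energy(self):
        solute = single_atom_solute()
        cx = place_probes(solute, [], SolventProbe.acetonitrile())
        assert cx.n_sites == 0
        assert cx.e_interaction_kcal == 0.0
        assert lie_energy(cx) == 0.0

    def test_single_site_energy_is_pair_energy(self):
        solute = single_atom_solute(charge=1.0)
        probe = SolventProbe.acetonitrile()
        m = energy_map(solute, probe, spacing_A=0.5, margin_A=5.0, n_orient=16, seed=2)
        sites = find_sites(m, -1.5, 3.5)
        cx = place_probes(solute, sites[:1], probe)
        assert cx.n_sites == 1
        assert cx.e_interaction_kcal == pytest.approx(cx.per_probe_energy_kcal[0])
        assert lie_energy(cx) == pytest.approx(cx.e_interaction_kcal, abs=1e-9)
        # relaxation can only improve on the voxel energy (small tolerance
        # for the placement being off-grid)
        assert cx.per_probe_energy_kcal[0] <= sites[0].energy_kcal + 0.5

    def test_lie_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        solute = SimpleNamespace(
            positions=rng.normal(0, 3, (8, 3)),
            charges=rng.uniform(-0.5, 0.5, 8),
            vdw_radii=np.full(8, 1.6),
            elements=["C"] * 8,
        )
        probe = SolventProbe.acetonitrile()
        centers = np.array([[8.0, 0, 0], [0, 9.0, 0]])
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(2, rng=np.random.default_rng(1)).as_matrix()
        cx = MicrosolvComplex(solute, probe, centers, rots, 2, 0.0)
        got = lie_energy(cx)

        # independent scalar double loop
        from conformerge.params import lj_epsilon

        expect = 0.0
        for c, rot in zip(centers, rots):
            for s in range(3):
                sp = c + rot @ probe.site_offsets[s]
                for a in range(8):
                    r = float(np.linalg.norm(sp - solute.positions[a]))
                    sig = (probe.site_radii[s] + solute.vdw_radii[a]) * 2 ** (-1 / 6)
                    ep = np.sqrt(probe.site_epsilons[s] * lj_epsilon("C"))
                    expect += 4 * ep * ((sig / r) ** 12 - (sig / r) ** 6)
                    expect += COULOMB_KCAL_A * probe.site_charges[s] * solute.charges[a] / r
        assert got == pytest.approx(expect, rel=1e-9)

    def test_locality_additivity_of_distant_subcomplexes(self):
        rng = np.random.default_rng(6)
        solute = SimpleNamespace(
            positions=rng.normal(0, 2, (5, 3)),
            charges=rng.uniform(-0.4, 0.4, 5),
            vdw_radii=np.full(5, 1.6),
            elements=["C"] * 5,
        )
        probe = SolventProbe.acetonitrile()
        centers = np.array([[7.0, 0, 0], [0, 0, 8.0], [-7.5, 1.0, 0]])
        rots = np.array([np.eye(3)] * 3)
        whole = lie_energy(MicrosolvComplex(solute, probe, centers, rots, 3, 0.0))
        parts = sum(
            lie_energy(MicrosolvComplex(solute, probe, centers[i : i + 1], rots[i : i + 1], 1, 0.0))
            for i in range(3)
        )
        assert whole == pytest.approx(parts, rel=1e-12)


class TestEnsembleComparison:
    def test_exposed_sites_beat_buried_sites(self):
        """Accessible polar surface yields more solvation sites and a more
        favorable total interaction energy than the same polar groups buried
        behind a blocker shell."""
        probe = SolventProbe.acetonitrile()
        results = {}
        for name, exposed in (("exposed", True), ("buried", False)):
            c = make_cluster_solute(exposed)
            m = energy_map(c, probe, spacing_A=0.5, margin_A=3.0, n_orient=12, seed=3)
            sites = find_sites(m, -1.5, 3.5)
            results[name] = place_probes(c, sites, probe)
        assert results["exposed"].n_sites >= results["buried"].n_sites
        assert results["exposed"].e_interaction_kcal < results["buried"].e_interaction_kcal

    def test_identical_groups_zero_difference(self):
        solute = single_atom_solute()
        probe = SolventProbe.acetonitrile()
        cx = MicrosolvComplex(solute, probe, np.array([[6.0, 0, 0]]), np.eye(3)[None], 1, -2.0)
        out = compare_ensembles([cx, cx], [cx, cx])
        assert out["group_a"]["e_interaction_mean_kcal"] == out["group_b"]["e_interaction_mean_kcal"]
        assert out["group_a"]["n"] == 2 and out["group_b"]["n"] == 2

    def test_singleton_group_warns_nan_sem(self):
        solute = single_atom_solute()
        probe = SolventProbe.acetonitrile()
        cx = MicrosolvComplex(solute, probe, np.empty((0, 3)), np.empty((0, 3, 3)), 0, 0.0)
        with pytest.warns(UserWarning, match="singleton"):
            out = compare_ensembles([cx], [cx, cx])
        assert np.isnan(out["group_a"]["e_interaction_sem_kcal"])
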