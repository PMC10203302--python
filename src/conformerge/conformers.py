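"""Reduced-representation peptide conformers and dihedral Monte-Carlo sampling.

A peptide is modeled with its backbone heavy atoms (N, CA, C, O), one
unified side-chain pseudo-atom per residue (element code ``X``), and one
dye-marker pseudo-atom (element code ``D``) on each of two flagged residues.
This stand-in replaces an all-atom force-field model: it keeps collision
cross sections, marker-marker distances, and relative energies meaningful at
desk scale while making no claim to a transferable force field.

Conformations are generated by simulated-annealing Metropolis Monte Carlo
over backbone (phi, psi) and marker-linker torsions with a
heat / plateau / cool / hold temperature profile and a two-level branching
tree (``n_roots`` cycles chained from the start, then ``n_children`` cycles
chained from each root). Every leaf is energy-minimized by steepest descent
switching to conjugate gradient.

Torsion moves are applied as rigid rotations of the downstream atom set
about the bond axis, which is exactly equivalent to rebuilding the chain
from internal coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import COULOMB_KCAL_A, lj_epsilon, vdw_radius

__all__ = [
    "Conformer",
    "Ensemble",
    "AnnealingSchedule",
    "build_peptide",
    "score_energy",
    "anneal_sample",
    "mc_segment",
    "minimize_conformer",
    "marker_distance",
    "radius_of_gyration",
    "read_pdb",
    "write_pdb",
]

KB_KCAL = 0.0019872041  # kcal mol^-1 K^-1

# Backbone geometry (Å, degrees): standard peptide values
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_X = 2.0   # CA -> unified side-chain pseudo-atom
_B_X_D = 5.0    # side-chain pseudo-atom -> dye marker offset
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.8
_A_CA_X_D = 110.0

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_CANONICAL_TORSIONS = {
    "helix": (-57.0, -47.0),
    "extended": (-135.0, 135.0),
}


@dataclass
class Conformer:
    """Atomic model: coordinates plus per-atom radius/charge annotations.

    ``donor_marker`` / ``acceptor_marker`` index the two dye pseudo-atoms.
    ``energy_kcal`` and ``ccs_A2`` are attached by the scoring / CCS stages.
    ``torsions`` holds the internal-coordinate state for conformers built by
    :func:`build_peptide`; conformers read from PDB have none.
    """

    elements: list[str]
    names: list[str]
    residue_index: np.ndarray
    positions: np.ndarray
    vdw_radii: np.ndarray
    charges: np.ndarray
    bonds: list[tuple[int, int]]
    donor_marker: int | None = None
    acceptor_marker: int | None = None
    energy_kcal: float | None = None
    ccs_A2: float | None = None
    label: str = ""
    torsions: dict | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Conformer":
        return Conformer(
            elements=list(self.elements),
            names=list(self.names),
            residue_index=self.residue_index.copy(),
            positions=self.positions.copy(),
            vdw_radii=self.vdw_radii.copy(),
            charges=self.charges.copy(),
            bonds=list(self.bonds),
            donor_marker=self.donor_marker,
            acceptor_marker=self.acceptor_marker,
            energy_kcal=self.energy_kcal,
            ccs_A2=self.ccs_A2,
            label=self.label,
            torsions={k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in self.torsions.items()}
            if self.torsions
            else None,
        )


@dataclass
class Ensemble:
    """Ordered conformer collection with generator provenance."""

    conformers: list[Conformer]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]


@dataclass
class AnnealingSchedule:
    """Temperature profile and branching of the annealing tree.

    One cycle: linear heat to ``t_max_K`` over ``heat_steps``, plateau,
    linear cool to 0 K, hold. Defaults are a 1/100-scale version of a
    5000/395000/50000/50000-step protocol, sized for interactive use; the
    full-scale counts are reachable through configuration.
    """

    heat_steps: int = 50
    plateau_steps: int = 3950
    cool_steps: int = 500
    hold_steps: int = 500
    t_max_K: float = 1500.0
    n_roots: int = 10
    n_children: int = 5

    def __post_init__(self):
        for name in ("heat_steps", "plateau_steps", "cool_steps", "hold_steps", "n_roots", "n_children"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_max_K <= 0:
            raise ValueError("t_max_K must be > 0")

    @property
    def total_steps(self) -> int:
        return self.heat_steps + self.plateau_steps + self.cool_steps + self.hold_steps

    def temperature(self, step: int) -> float:
        """Temperature at a 0-based step of one cycle."""
        h, p, c = self.heat_steps, self.plateau_steps, self.cool_steps
        if step < h:
            return self.t_max_K * (step + 1) / h
        if step < h + p:
            return self.t_max_K
        if step < h + p + c:
            return self.t_max_K * (1.0 - (step - h - p + 1) / c)
        return 0.0


# ---------------------------------------------------------------------------
# Geometry


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom D bonded to c, with angle b-c-D and torsion a-b-c-D."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        tmp = np.array([0.0, 1.0, 0.0]) if abs(bc[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
        n = np.cross(bc, tmp)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    return (
        c
        - bond * math.cos(ang) * bc
        + bond * math.sin(ang) * math.cos(tor) * m
        + bond * math.sin(ang) * math.sin(tor) * n
    )


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


def _build_coordinates(sequence, phis, psis, marker_sites, marker_chis):
    n_res = len(sequence)
    elements, names, resi, pos_list, bonds = [], [], [], [], []

    def add(el, name, ri, p):
        elements.append(el)
        names.append(name)
        resi.append(ri)
        pos_list.append(np.asarray(p, dtype=float))
        return len(pos_list) - 1

    idx = {}
    for i in range(n_res):
        if i == 0:
            iN = add("N", "N", 0, [0.0, 0.0, 0.0])
            iCA = add("C", "CA", 0, [_B_N_CA, 0.0, 0.0])
            # global frame of the first residue is arbitrary
            c0 = _place_atom(np.array([0.0, 1.0, 0.0]), pos_list[iN], pos_list[iCA], _B_CA_C, _A_N_CA_C, 0.0)
            iC = add("C", "C", 0, c0)
        else:
            pN, pCA, pC = idx[(i - 1, "N")], idx[(i - 1, "CA")], idx[(i - 1, "C")]
            iN = add("N", "N", i, _place_atom(pos_list[pN], pos_list[pCA], pos_list[pC], _B_C_N, _A_CA_C_N, psis[i - 1]))
            iCA = add("C", "CA", i, _place_atom(pos_list[pCA], pos_list[pC], pos_list[iN], _B_N_CA, _A_C_N_CA, 180.0))
            iC = add("C", "C", i, _place_atom(pos_list[pC], pos_list[iN], pos_list[iCA], _B_CA_C, _A_N_CA_C, phis[i]))
        idx[(i, "N")], idx[(i, "CA")], idx[(i, "C")] = iN, iCA, iC
        bonds += [(iN, iCA), (iCA, iC)]
        if i > 0:
            bonds.append((idx[(i - 1, "C")], iN))

    for i in range(n_res):
        iN, iCA, iC = idx[(i, "N")], idx[(i, "CA")], idx[(i, "C")]
        iO = add("O", "O", i, _place_atom(pos_list[iN], pos_list[iCA], pos_list[iC], _B_C_O, _A_CA_C_O, psis[i] + 180.0))
        bonds.append((iC, iO))
        idx[(i, "O")] = iO
        # tetrahedral side-chain direction out of the N-CA-C plane
        uN = pos_list[iN] - pos_list[iCA]
        uC = pos_list[iC] - pos_list[iCA]
        uN /= np.linalg.norm(uN)
        uC /= np.linalg.norm(uC)
        bis = uN + uC
        bis /= np.linalg.norm(bis)
        nrm = np.cross(uN, uC)
        nrm /= np.linalg.norm(nrm)
        iX = add("X", "XS", i, pos_list[iCA] + _B_CA_X * (-bis * math.sqrt(1 / 3) + nrm * math.sqrt(2 / 3)))
        bonds.append((iCA, iX))
        idx[(i, "X")] = iX

    markers = []
    for k, site in enumerate(marker_sites):
        iN, iCA, iX = idx[(site, "N")], idx[(site, "CA")], idx[(site, "X")]
        pD = _place_atom(pos_list[iN], pos_list[iCA], pos_list[iX], _B_X_D, _A_CA_X_D, marker_chis[k])
        iD = add("D", "DM1" if k == 0 else "DM2", site, pD)
        bonds.append((iX, iD))
        markers.append(iD)

    return elements, names, np.array(resi), np.array(pos_list), bonds, markers


def _assign_charges(names, residue_index, charge_residues):
    """Backbone dipole charges (+/-0.4 e); +1 e on protonation-site pseudo-atoms."""
    q = np.zeros(len(names))
    for i, nm in enumerate(names):
        if nm in ("C", "CA"):
            q[i] = 0.4
        elif nm in ("O", "N"):
            q[i] = -0.4
    for res in charge_residues:
        sel = [i for i, nm in enumerate(names) if nm == "XS" and residue_index[i] == res]
        if not sel:
            raise ValueError(f"no side-chain site on residue {res} for protonation")
        q[sel[0]] += 1.0
    return q


def build_peptide(
    sequence: str,
    conformation: str = "helix",
    seed: int = 0,
    marker_residues: tuple[int, int] | None = None,
    charge_residues: tuple[int, ...] = (),
    label: str = "",
) -> Conformer:
    """Build a reduced-representation peptide in a canonical conformation.

    Parameters
    ----------
    sequence
        One-letter amino-acid string (length >= 2, standard residues).
    conformation
        ``helix`` (phi=-57°, psi=-47°), ``extended`` (phi=-135°, psi=135°) or
        ``coil`` (seeded random torsions).
    marker_residues
        The two dye attachment sites (default: the termini). Each carries a
        marker pseudo-atom 5 Å out along the side-chain vector, standing in
        for the dye chromophore center used for distance measurements.
    charge_residues
        Residues whose side-chain pseudo-atom gets +1 e, emulating the
        protonation sites of a chosen charge state.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have >= 2 residues")
    bad = set(sequence) - _STANDARD_AA
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    n_res = len(sequence)
    if marker_residues is None:
        marker_residues = (0, n_res - 1)
    if len(set(marker_residues)) != 2:
        raise ValueError("exactly 2 distinct marker attachment sites required")
    for r in tuple(marker_residues) + tuple(charge_residues):
        if not 0 <= r < n_res:
            raise ValueError(f"residue index {r} out of range")

    rng = np.random.default_rng(seed)
    if conformation in _CANONICAL_TORSIONS:
        phi0, psi0 = _CANONICAL_TORSIONS[conformation]
        phis = np.full(n_res, phi0)
        psis = np.full(n_res, psi0)
    elif conformation == "coil":
        phis = rng.uniform(-180.0, 0.0, n_res)
        psis = rng.uniform(-180.0, 180.0, n_res)
    else:
        raise ValueError(f"unknown conformation {conformation!r}")
    marker_chis = np.array([180.0, 180.0])

    elements, names, resi, positions, bonds, markers = _build_coordinates(
        sequence, phis, psis, marker_residues, marker_chis
    )
    return Conformer(
        elements=elements,
        names=names,
        residue_index=resi,
        positions=positions,
        vdw_radii=np.array([vdw_radius(el) for el in elements]),
        charges=_assign_charges(names, resi, charge_residues),
        bonds=bonds,
        donor_marker=markers[0],
        acceptor_marker=markers[1],
        label=label or f"{sequence[:4]}-{conformation}-s{seed}",
        torsions={
            "sequence": sequence,
            "phis": phis.astype(float),
            "psis": psis.astype(float),
            "marker_sites": tuple(marker_residues),
            "marker_chis": marker_chis.astype(float),
            "charge_residues": tuple(charge_residues),
        },
    )


def _rebuild(conf: Conformer) -> None:
    st = conf.torsions
    *_, positions, _, _ = _build_coordinates(
        st["sequence"], st["phis"], st["psis"], st["marker_sites"], st["marker_chis"]
    )
    conf.positions = positions


# ---------------------------------------------------------------------------
# Energy


_HB_R0 = 2.9     # Å, O...N optimum
_HB_W = 0.3      # Å, well width
_HB_DEPTH = 1.0  # kcal/mol
CLASH_PENALTY_KCAL = 1e6


class _EnergyModel:
    """Precomputed pair lists for fast repeated evaluation on one topology."""

    def __init__(self, conf: Conformer):
        import scipy.sparse as sp
        from scipy.sparse.csgraph import shortest_path

        n = conf.n_atoms
        rows = [b[0] for b in conf.bonds] + [b[1] for b in conf.bonds]
        cols = [b[1] for b in conf.bonds] + [b[0] for b in conf.bonds]
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        dist = shortest_path(adj, method="D", unweighted=True, directed=False)
        mask = np.triu(dist >= 3, k=1)  # nonbonded: bond-path separation >= 3
        self.ii, self.jj = np.nonzero(mask)
        eps = np.array([lj_epsilon(el) for el in conf.elements])
        r = conf.vdw_radii
        self.sigma = (r[self.ii] + r[self.jj]) * 2.0 ** (-1.0 / 6.0)
        self.eps = np.sqrt(eps[self.ii] * eps[self.jj])
        self.qq = COULOMB_KCAL_A * conf.charges[self.ii] * conf.charges[self.jj]

        # backbone H-bond pairs: carbonyl O ... amide N, >= 3 residues apart
        o_idx = np.array([i for i, nm in enumerate(conf.names) if nm == "O"], dtype=int)
        n_idx = np.array([i for i, nm in enumerate(conf.names) if nm == "N"], dtype=int)
        self.hb_o = np.empty(0, dtype=int)
        self.hb_n = np.empty(0, dtype=int)
        self.hb_c = np.empty(0, dtype=int)
        if o_idx.size and n_idx.size:
            c_of_res = {int(conf.residue_index[i]): i for i, nm in enumerate(conf.names) if nm == "C"}
            sep = np.abs(conf.residue_index[o_idx][:, None] - conf.residue_index[n_idx][None, :])
            po, pn = np.nonzero(sep >= 3)
            if po.size and all(int(conf.residue_index[i]) in c_of_res for i in o_idx):
                self.hb_o = o_idx[po]
                self.hb_n = n_idx[pn]
                self.hb_c = np.array([c_of_res[int(conf.residue_index[i])] for i in self.hb_o])

    def energy(self, pos: np.ndarray) -> float:
        d = np.linalg.norm(pos[self.ii] - pos[self.jj], axis=1)
        if d.size and d.min() < 0.1:
            return CLASH_PENALTY_KCAL
        sr6 = (self.sigma / d) ** 6
        e = float(np.sum(4.0 * self.eps * (sr6 * sr6 - sr6)) + np.sum(self.qq / d))
        if self.hb_o.size:
            po = pos[self.hb_o]
            pn = pos[self.hb_n]
            von = pn - po
            r = np.linalg.norm(von, axis=1)
            near = r < _HB_R0 + 4 * _HB_W
            if np.any(near):
                vco = po[near] - pos[self.hb_c][near]
                cosang = np.einsum("ij,ij->i", vco, von[near]) / (
                    np.linalg.norm(vco, axis=1) * r[near]
                )
                w = np.clip(cosang, 0.0, 1.0) ** 2
                e += float(np.sum(-_HB_DEPTH * np.exp(-(((r[near] - _HB_R0) / _HB_W) ** 2)) * w))
        return e


_MODEL_CACHE: dict[int, tuple[tuple, _EnergyModel]] = {}


def _energy_model(conf: Conformer) -> _EnergyModel:
    key = (conf.n_atoms, tuple(conf.bonds), conf.charges.tobytes(), conf.vdw_radii.tobytes())
    hit = _MODEL_CACHE.get(id(conf))
    if hit is not None and hit[0] == key:
        return hit[1]
    # topology-level cache shared across copies
    for k, (tkey, model) in list(_MODEL_CACHE.items()):
        if tkey == key:
            _MODEL_CACHE[id(conf)] = (key, model)
            return model
    if len(_MODEL_CACHE) > 64:
        _MODEL_CACHE.clear()
    model = _EnergyModel(conf)
    _MODEL_CACHE[id(conf)] = (key, model)
    return model


def score_energy(conf: Conformer, warn_clash: bool = True) -> float:
    """Stand-in conformational energy, kcal/mol.

    Sum over nonbonded pairs (bond-path separation >= 3 bonds) of 12-6
    Lennard-Jones (per-element sigma/epsilon derived from vdW radii) and
    Coulomb (dielectric 1, in vacuo) terms, plus a backbone hydrogen-bond
    well: for every carbonyl O / amide N pair at least three residues apart,
    a Gaussian distance well of depth 1 kcal/mol centered at 2.9 Å weighted
    by the squared cosine of the C=O...N alignment angle.

    Atom pairs closer than 0.1 Å yield a large finite clash penalty (with a
    warning) rather than an overflowing LJ value.
    """
    e = _energy_model(conf).energy(conf.positions)
    if e >= CLASH_PENALTY_KCAL and warn_clash:
        warnings.warn("overlapping atoms (r < 0.1 Å): clash penalty applied", stacklevel=2)
    return e


# ---------------------------------------------------------------------------
# Torsion moves as downstream rotations


def _atom_index_map(conf: Conformer) -> dict:
    m = {}
    for i, (nm, ri) in enumerate(zip(conf.names, conf.residue_index)):
        m[(int(ri), nm)] = i
    return m


def _torsion_axes(conf: Conformer):
    """Per torsion-vector entry: (atom_a, atom_b, downstream index array).

    Vector layout: [phi_0..phi_{n-1}, psi_0..psi_{n-1}, chi_donor, chi_acceptor].
    """
    st = conf.torsions
    n_res = len(st["sequence"])
    idx = _atom_index_map(conf)
    resi = conf.residue_index
    names = conf.names
    axes = []
    marker_sites = st["marker_sites"]
    marker_atoms = [conf.donor_marker, conf.acceptor_marker]
    for i in range(n_res):  # phi_i: axis N_i -> CA_i
        down = [
            j
            for j in range(conf.n_atoms)
            if resi[j] > i or (resi[j] == i and names[j] in ("C", "O", "XS", "DM1", "DM2"))
        ]
        axes.append((idx[(i, "N")], idx[(i, "CA")], np.array(down, dtype=int)))
    for i in range(n_res):  # psi_i: axis CA_i -> C_i
        down = [
            j
            for j in range(conf.n_atoms)
            if resi[j] > i or (resi[j] == i and names[j] == "O")
        ]
        axes.append((idx[(i, "CA")], idx[(i, "C")], np.array(down, dtype=int)))
    for k, site in enumerate(marker_sites):  # chi_k: axis CA -> XS, moves only the marker
        axes.append((idx[(site, "CA")], idx[(site, "XS")], np.array([marker_atoms[k]], dtype=int)))
    return axes


def _rotate_about_axis(pos, a, b, indices, angle_rad):
    axis = pos[b] - pos[a]
    axis = axis / np.linalg.norm(axis)
    p = pos[indices] - pos[b]
    cos, sin = math.cos(angle_rad), math.sin(angle_rad)
    pos[indices] = (
        p * cos
        + np.cross(axis, p) * sin
        + np.outer(p @ axis, axis) * (1.0 - cos)
        + pos[b]
    )


def _torsion_vector(st) -> np.ndarray:
    return np.concatenate([st["phis"], st["psis"], st["marker_chis"]])


def _set_torsion_vector(st, v) -> None:
    n = len(st["phis"])
    st["phis"] = np.asarray(v[:n], dtype=float)
    st["psis"] = np.asarray(v[n : 2 * n], dtype=float)
    st["marker_chis"] = np.asarray(v[2 * n :], dtype=float)


class _MCState:
    """Mutable sampler state: positions, torsion vector, energy."""

    def __init__(self, conf: Conformer):
        self.conf = conf.copy()
        self.axes = _torsion_axes(self.conf)
        self.model = _energy_model(self.conf)
        self.v = _torsion_vector(self.conf.torsions)
        self.energy = self.model.energy(self.conf.positions)

    def step(self, k: int, delta_deg: float, beta: float, rng) -> bool:
        a, b, down = self.axes[k]
        pos = self.conf.positions
        saved = pos[down].copy()
        _rotate_about_axis(pos, a, b, down, math.radians(delta_deg))
        e_new = self.model.energy(pos)
        de = e_new - self.energy
        if de <= 0 or (np.isfinite(beta) and rng.random() < math.exp(-min(de * beta, 700.0))):
            self.energy = e_new
            self.v[k] += delta_deg
            return True
        pos[down] = saved
        return False

    def finalize(self) -> Conformer:
        out = self.conf.copy()
        _set_torsion_vector(out.torsions, self.v)
        _rebuild(out)  # exact rebuild removes accumulated rotation round-off
        out.energy_kcal = self.model.energy(out.positions)
        return out


def _step_sigma(temp_K: float, t_max_K: float) -> float:
    """Gaussian torsion step width: 10° at t_max, scaled with sqrt(T), floored
    at 1° so the 0 K hold phase still quenches downhill."""
    return max(10.0 * math.sqrt(max(temp_K, 0.0) / t_max_K), 1.0)


def mc_segment(
    conf: Conformer,
    n_steps: int,
    temperature_K: float,
    seed: int = 0,
    t_ref_K: float = 1500.0,
) -> tuple[Conformer, float]:
    """Fixed-temperature Metropolis MC; returns (final conformer, acceptance rate)."""
    if conf.torsions is None:
        raise ValueError("sampling requires a conformer with torsion state (use build_peptide)")
    rng = np.random.default_rng(seed)
    state = _MCState(conf)
    beta = np.inf if temperature_K <= 0 else 1.0 / (KB_KCAL * temperature_K)
    sigma = _step_sigma(temperature_K, t_ref_K)
    n_acc = 0
    for _ in range(n_steps):
        k = int(rng.integers(0, state.v.size))
        if state.step(k, sigma * rng.standard_normal(), beta, rng):
            n_acc += 1
    return state.finalize(), n_acc / max(n_steps, 1)


def _anneal_cycle(conf: Conformer, schedule: AnnealingSchedule, rng) -> Conformer:
    state = _MCState(conf)
    h, p = schedule.heat_steps, schedule.plateau_steps
    plateau_accepts = 0
    for step in range(schedule.total_steps):
        temp = schedule.temperature(step)
        beta = np.inf if temp <= 0 else 1.0 / (KB_KCAL * temp)
        sigma = _step_sigma(temp, schedule.t_max_K)
        k = int(rng.integers(0, state.v.size))
        if state.step(k, sigma * rng.standard_normal(), beta, rng) and h <= step < h + p:
            plateau_accepts += 1
    if plateau_accepts == 0 and p >= 50:
        raise RuntimeError(
            "zero acceptance during the annealing plateau: step size or energy surface pathological"
        )
    return state.finalize()


class _TorsionEvaluator:
    """Energy as a function of the torsion vector, evaluated by incremental
    downstream rotations (exactly equivalent to a rebuild; periodically
    re-synchronized against round-off)."""

    def __init__(self, conf: Conformer):
        self.conf = conf
        self.axes = _torsion_axes(conf)
        self.model = _energy_model(conf)
        self.v = _torsion_vector(conf.torsions)
        self._n_rot = 0

    def energy_at(self, v_new: np.ndarray) -> float:
        pos = self.conf.positions
        for k in np.nonzero(v_new != self.v)[0]:
            a, b, down = self.axes[k]
            _rotate_about_axis(pos, a, b, down, math.radians(v_new[k] - self.v[k]))
            self._n_rot += 1
        self.v = v_new.copy()
        if self._n_rot > 500:
            _set_torsion_vector(self.conf.torsions, self.v)
            _rebuild(self.conf)
            self._n_rot = 0
        return self.model.energy(self.conf.positions)


def minimize_conformer(
    conf: Conformer,
    max_evals: int = 5000,
    switch_after: int = 1000,
    grad_h_deg: float = 0.5,
    tol: float = 1e-4,
) -> Conformer:
    """Torsion-space minimization: steepest descent with backtracking line
    search for the first ``switch_after`` energy evaluations, then
    Polak-Ribière conjugate gradient. Uphill steps are never accepted, so
    the returned energy is <= the input energy.
    """
    if conf.torsions is None:
        raise ValueError("minimization requires a conformer with torsion state")
    work = conf.copy()
    ev = _TorsionEvaluator(work)
    st = work.torsions
    model = ev.model
    evals = [0]

    def f(v):
        evals[0] += 1
        return ev.energy_at(v)

    def grad(v, f0):
        g = np.zeros_like(v)
        for i in range(v.size):
            vp = v.copy()
            vp[i] += grad_h_deg
            g[i] = (f(vp) - f0) / grad_h_deg
        return g

    v = _torsion_vector(st)
    e = f(v)
    g = grad(v, e)
    d = -g
    while evals[0] < max_evals and np.linalg.norm(g) >= tol:
        step = 5.0
        improved = False
        dn = max(np.linalg.norm(d), 1e-12)
        for _ in range(20):
            if evals[0] >= max_evals:
                break
            e_try = f(v + step * d / dn)
            if e_try < e:
                v = v + step * d / dn
                e = e_try
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        g_prev, g = g, grad(v, e)
        if evals[0] < switch_after:
            d = -g
        else:
            beta_pr = max(0.0, float(g @ (g - g_prev)) / max(float(g_prev @ g_prev), 1e-12))
            d = -g + beta_pr * d
            if float(d @ g) >= 0:
                d = -g
    _set_torsion_vector(st, v)
    _rebuild(work)
    work.energy_kcal = model.energy(work.positions)
    return work


def anneal_sample(
    start: Conformer,
    schedule: AnnealingSchedule,
    seed: int = 0,
    minimize_max_evals: int = 5000,
    minimize_switch_after: int = 1000,
) -> Ensemble:
    """Branching simulated-annealing search; returns n_roots * n_children leaves.

    ``n_roots`` chained annealing cycles run from ``start``; from each root a
    chain of ``n_children`` further cycles produces leaves, each energy-
    minimized. Per-branch RNG streams derive from the master seed through
    SeedSequence spawn keys (a counter scheme), so results are bit-for-bit
    reproducible for a given (start, schedule, seed).
    """
    if start.torsions is None:
        raise ValueError("annealing requires a conformer with torsion state (use build_peptide)")
    leaves: list[Conformer] = []
    current = start
    roots = []
    for r in range(schedule.n_roots):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, r)))
        current = _anneal_cycle(current, schedule, rng)
        roots.append(current)
    for r, root in enumerate(roots):
        child = root
        for c in range(schedule.n_children):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, r, c)))
            child = _anneal_cycle(child, schedule, rng)
            leaf = minimize_conformer(child, max_evals=minimize_max_evals, switch_after=minimize_switch_after)
            leaf.label = f"{start.label}/r{r:03d}c{c:03d}"
            leaves.append(leaf)
    return Ensemble(
        conformers=leaves,
        provenance={
            "generator": "anneal_sample",
            "seed": seed,
            "schedule": vars(schedule).copy(),
            "start_label": start.label,
        },
    )


# ---------------------------------------------------------------------------
# Measurements


def marker_distance(conf: Conformer) -> float:
    """Euclidean donor-acceptor marker distance, Å."""
    if conf.donor_marker is None or conf.acceptor_marker is None:
        raise ValueError("marker atoms are not set on this conformer")
    return float(np.linalg.norm(conf.positions[conf.donor_marker] - conf.positions[conf.acceptor_marker]))


def radius_of_gyration(conf: Conformer) -> float:
    c = conf.positions.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((conf.positions - c) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# PDB I/O — dialect: the occupancy column carries the per-atom vdW radius and
# the B-factor column the partial charge; marker indices, energy, CCS and the
# label are serialized in REMARK 250 lines.


def write_pdb(conf: Conformer, path) -> None:
    lines = []
    if conf.label:
        lines.append(f"REMARK 250 CONFORMERGE LABEL {conf.label}")
    if conf.donor_marker is not None and conf.acceptor_marker is not None:
        lines.append(f"REMARK 250 CONFORMERGE MARKERS {conf.donor_marker + 1} {conf.acceptor_marker + 1}")
    if conf.energy_kcal is not None:
        lines.append(f"REMARK 250 CONFORMERGE ENERGY {conf.energy_kcal:.6f}")
    if conf.ccs_A2 is not None:
        lines.append(f"REMARK 250 CONFORMERGE CCS {conf.ccs_A2:.4f}")
    for i in range(conf.n_atoms):
        x, y, z = conf.positions[i]
        el = conf.elements[i]
        record = "HETATM" if el == "D" else "ATOM  "
        lines.append(
            f"{record}{i + 1:5d} {conf.names[i][:4]:<4s} ALA A{int(conf.residue_index[i]) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{conf.vdw_radii[i]:6.2f}{conf.charges[i]:6.2f}"
            f"          {el[:2]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path) -> Conformer:
    """Read a conformer in the dialect written by :func:`write_pdb`.

    Bonds are re-inferred from interatomic distances, which suffices for the
    reduced representation; marker bonds (5 Å offsets) are restored from the
    REMARK annotations instead.
    """
    elements, names, resi, pos, radii, charges = [], [], [], [], [], []
    donor = acceptor = None
    energy = ccs = None
    label = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("REMARK 250 CONFORMERGE"):
                parts = line.split()
                tag = parts[3]
                if tag == "MARKERS":
                    donor, acceptor = int(parts[4]) - 1, int(parts[5]) - 1
                elif tag == "ENERGY":
                    energy = float(parts[4])
                elif tag == "CCS":
                    ccs = float(parts[4])
                elif tag == "LABEL":
                    label = parts[4]
            elif line[:6] in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
                    occ = line[54:60].strip()
                    bfac = line[60:66].strip()
                    el = line[76:78].strip()
                    ri = int(line[22:26]) - 1
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
                if not el:
                    el = "".join(ch for ch in name if ch.isalpha())[:1]
                    warnings.warn(f"{path}:{lineno}: element inferred from atom name", stacklevel=2)
                elements.append(el.upper())
                names.append(name)
                resi.append(ri)
                pos.append([x, y, z])
                radii.append(float(occ) if occ else vdw_radius(el))
                charges.append(float(bfac) if bfac else 0.0)
    if not elements:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    positions = np.array(pos)
    rad = np.array(radii)
    n = len(elements)
    bonds = []
    for i in range(n):
        if i + 1 >= n:
            break
        d = np.linalg.norm(positions[i + 1 :] - positions[i], axis=1)
        cut = np.maximum(1.15 * (rad[i] + rad[i + 1 :]) * 0.55, 1.8)
        for j in np.nonzero(d < cut)[0]:
            bonds.append((i, int(i + 1 + j)))
    for m in (donor, acceptor):
        if m is not None and not any(m in b for b in bonds):
            # reattach the marker to its nearest non-marker atom
            others = [k for k in range(n) if k not in (donor, acceptor)]
            j = min(others, key=lambda k: np.linalg.norm(positions[m] - positions[k]))
            bonds.append((min(m, j), max(m, j)))
    return Conformer(
        elements=elements,
        names=names,
        residue_index=np.array(resi),
        positions=positions,
        vdw_radii=rad,
        charges=np.array(charges),
        bonds=bonds,
        donor_marker=donor,
        acceptor_marker=acceptor,
        energy_kcal=energy,
        ccs_A2=ccs,
        label=label,
    )
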