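"""Probe-grid microsolvation scoring.

A rigid solvent probe (by default a 3-site acetonitrile-like model) is swept
over a grid around the solute; each voxel stores the minimum over sampled
probe orientations of the probe-solute nonbonded energy (Lennard-Jones +
Coulomb). Favorable solvation sites are the separated local minima below an
energy threshold (default -1.5 kcal/mol); explicit probes are placed at the
sites in their map-minimizing orientation, locally relaxed, and the complex
scored with a linear interaction energy (LIE): the direct probe-solute
nonbonded sum, excluding probe-probe terms.

This is a direct-energetics stand-in for trajectory-based grid solvation
analysis: it locates favorable sites and ranks conformers by interaction
energy on its own energy scale, and does not attempt trajectory-averaged
thermodynamics (no entropy terms, no solvent-solvent structure). The bulk
solvent-solvent reference energy is carried as metadata so per-site energies
can be compared against the cost of leaving bulk solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.spatial.distance import cdist

from .ccs import _rotation_matrices
from .params import COULOMB_KCAL_A

__all__ = [
    "SolventProbe",
    "SolvationMap",
    "SolvationSite",
    "MicrosolvComplex",
    "energy_map",
    "find_sites",
    "place_probes",
    "lie_energy",
    "compare_ensembles",
]

CLASH_CLAMP_KCAL = 50.0
_CLASH_FRACTION = 0.7
MAX_VOXELS = 10_000_000
ACN_SELF_ENERGY_KCAL = -7.006  # bulk acetonitrile solvent-solvent reference


@dataclass(frozen=True)
class SolventProbe:
    """Rigid multi-site solvent probe.

    ``site_offsets`` are Å from the probe center; net charge must vanish.
    ``reference_self_energy_kcal`` is the bulk solvent-solvent interaction
    energy used to judge whether a site is competitive with bulk solvation.
    """

    name: str
    site_offsets: np.ndarray
    site_radii: np.ndarray
    site_charges: np.ndarray
    site_epsilons: np.ndarray
    reference_self_energy_kcal: float = 0.0

    def __post_init__(self):
        off = np.atleast_2d(np.asarray(self.site_offsets, dtype=float))
        object.__setattr__(self, "site_offsets", off)
        for nm in ("site_radii", "site_charges", "site_epsilons"):
            object.__setattr__(self, nm, np.atleast_1d(np.asarray(getattr(self, nm), dtype=float)))
        if off.shape[0] < 1:
            raise ValueError("probe needs >= 1 site")
        if abs(float(self.site_charges.sum())) > 1e-6:
            raise ValueError("probe net charge must be ~0")

    @classmethod
    def acetonitrile(cls) -> "SolventProbe":
        """3-site collinear CH3-C≡N model: united methyl, nitrile C, N.

        Geometry 1.46 Å C-C and 1.17 Å C≡N; small positive charges on the
        carbons balanced by the nitrile nitrogen, giving the molecule its
        dipole along the axis.
        """
        return cls(
            name="acetonitrile-3site",
            site_offsets=np.array([[0.0, 0.0, -1.46], [0.0, 0.0, 0.0], [0.0, 0.0, 1.17]]),
            site_radii=np.array([2.0, 1.7, 1.55]),
            site_charges=np.array([0.269, 0.129, -0.398]),
            site_epsilons=np.array([0.12, 0.10, 0.16]),
            reference_self_energy_kcal=ACN_SELF_ENERGY_KCAL,
        )


@dataclass
class SolvationMap:
    """Voxel grid of minimum-over-orientation probe interaction energies."""

    origin_A: np.ndarray
    spacing_A: float
    energy_kcal: np.ndarray          # 3-D array
    best_orientation: np.ndarray     # 3-D int array into ``rotations``
    rotations: np.ndarray            # (n_orient, 3, 3)
    probe_name: str = ""

    @property
    def shape(self):
        return self.energy_kcal.shape

    def voxel_position(self, idx) -> np.ndarray:
        return self.origin_A + np.asarray(idx, dtype=float) * self.spacing_A

    def write_dx(self, path) -> None:
        """Export as an OpenDX-style scalar grid (text)."""
        nx, ny, nz = self.shape
        o = self.origin_A
        d = self.spacing_A
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
            fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = self.energy_kcal.ravel()
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.4f}" for v in flat[i : i + 3]) + "\n")


@dataclass
class SolvationSite:
    position_A: np.ndarray
    energy_kcal: float
    orientation: np.ndarray  # (3, 3) rotation of the probe at the minimum
    occupied: bool = False


@dataclass
class MicrosolvComplex:
    """A conformer plus explicitly placed solvent probes."""

    conformer: object
    probe: SolventProbe
    probe_positions: np.ndarray   # (k, 3) centers
    probe_rotations: np.ndarray   # (k, 3, 3)
    n_sites: int
    e_interaction_kcal: float
    per_probe_energy_kcal: list[float] = field(default_factory=list)


def _pair_tables(conf, probe: SolventProbe):
    """Per (site, atom) LJ sigma/epsilon and Coulomb products."""
    r_at = np.asarray(conf.vdw_radii, dtype=float)
    q_at = np.asarray(conf.charges, dtype=float)
    from .params import lj_epsilon

    eps_at = np.array([lj_epsilon(el) for el in conf.elements])
    sigma = (probe.site_radii[:, None] + r_at[None, :]) * 2.0 ** (-1.0 / 6.0)
    eps = np.sqrt(probe.site_epsilons[:, None] * eps_at[None, :])
    qq = COULOMB_KCAL_A * probe.site_charges[:, None] * q_at[None, :]
    clash = _CLASH_FRACTION * (probe.site_radii[:, None] + r_at[None, :])
    return sigma, eps, qq, clash


def _probe_energy(site_pos, atom_pos, sigma, eps, qq, clash):
    """Energy of one probe pose: site_pos (S,3) vs atom_pos (A,3).

    Returns the clamp value when any site-atom pair is inside the clash
    radius."""
    d = np.linalg.norm(site_pos[:, None, :] - atom_pos[None, :, :], axis=2)
    if np.any(d < clash):
        return CLASH_CLAMP_KCAL
    sr6 = (sigma / d) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)) + np.sum(qq / d))


def energy_map(
    conf,
    probe: SolventProbe,
    spacing_A: float = 0.5,
    margin_A: float = 4.0,
    n_orient: int = 32,
    seed: int = 0,
) -> SolvationMap:
    """Probe interaction-energy grid around a conformer.

    Each voxel stores min over ``n_orient`` seeded quasi-random probe
    orientations of the probe-solute nonbonded energy; poses with any
    site-atom distance below 0.7x the radius sum clamp to +50 kcal/mol.
    """
    if not 0.25 <= spacing_A <= 1.0:
        raise ValueError("spacing must be in [0.25, 1.0] Å")
    pos = np.asarray(conf.positions, dtype=float)
    lo = pos.min(axis=0) - margin_A
    hi = pos.max(axis=0) + margin_A
    counts = np.ceil((hi - lo) / spacing_A).astype(int) + 1
    if int(np.prod(counts)) > MAX_VOXELS:
        raise ValueError(f"grid of {int(np.prod(counts))} voxels exceeds {MAX_VOXELS}: reduce margin/spacing")
    axes = [lo[k] + np.arange(counts[k]) * spacing_A for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    n_vox = centers.shape[0]

    rots = _rotation_matrices(n_orient, seed)
    sigma, eps, qq, clash = _pair_tables(conf, probe)
    best_e = np.full(n_vox, np.inf)
    best_o = np.zeros(n_vox, dtype=np.int32)
    chunk = max(1, 4_000_000 // max(pos.shape[0], 1))
    for o in range(n_orient):
        offs = probe.site_offsets @ rots[o].T  # (S, 3)
        e_o = np.zeros(n_vox)
        for s in range(offs.shape[0]):
            pts = centers + offs[s]
            for start in range(0, n_vox, chunk):
                sl = slice(start, min(start + chunk, n_vox))
                d = cdist(pts[sl], pos)
                with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                    sr6 = (sigma[s] / d) ** 6
                    e = np.sum(4.0 * eps[s] * (sr6 * sr6 - sr6) + qq[s] / d, axis=1)
                e[np.any(d < clash[s], axis=1)] = np.inf  # clash clamps the pose
                e_o[sl] += e
        e_o = np.minimum(np.where(np.isfinite(e_o), e_o, CLASH_CLAMP_KCAL), CLASH_CLAMP_KCAL)
        take = e_o < best_e
        best_e[take] = e_o[take]
        best_o[take] = o
    return SolvationMap(
        origin_A=lo,
        spacing_A=spacing_A,
        energy_kcal=best_e.reshape(counts),
        best_orientation=best_o.reshape(counts),
        rotations=rots,
        probe_name=probe.name,
    )


def find_sites(
    m: SolvationMap,
    threshold_kcal: float = -1.5,
    min_separation_A: float = 3.5,
) -> list[SolvationSite]:
    """Separated local minima of the map below the energy threshold.

    Local minima (26-neighborhood) with energy below ``threshold_kcal`` are
    accepted greedily in ascending energy order subject to a pairwise
    center separation of at least ``min_separation_A``. Deterministic; an
    empty list is a valid result.
    """
    e = m.energy_kcal
    local_min = e <= ndimage.minimum_filter(e, size=3, mode="nearest")
    cand = np.argwhere(local_min & (e < threshold_kcal))
    if cand.size == 0:
        return []
    energies = e[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], energies))
    accepted: list[SolvationSite] = []
    accepted_pos: list[np.ndarray] = []
    for k in order:
        p = m.voxel_position(cand[k])
        if all(np.linalg.norm(p - q) >= min_separation_A for q in accepted_pos):
            idx = tuple(cand[k])
            accepted.append(
                SolvationSite(
                    position_A=p,
                    energy_kcal=float(e[idx]),
                    orientation=m.rotations[m.best_orientation[idx]],
                )
            )
            accepted_pos.append(p)
    return accepted


def place_probes(
    conf,
    sites: list[SolvationSite],
    probe: SolventProbe,
    max_shift_A: float = 1.0,
) -> MicrosolvComplex:
    """Place one probe per site at its map-minimizing orientation, then relax
    each probe by a short rigid-body translation (bounded by 1 Å).

    Sites whose probe cannot escape a steric clash are skipped with a
    warning. The complex energy is the LIE sum over placed probes.
    """
    sigma, eps, qq, clash = _pair_tables(conf, probe)
    atom_pos = np.asarray(conf.positions, dtype=float)
    positions, rotations, energies = [], [], []
    for site in sites:
        offs = probe.site_offsets @ site.orientation.T

        def pose_energy(shift, _offs=offs):
            return _probe_energy(site.position_A + shift + _offs, atom_pos, sigma, eps, qq, clash)

        res = optimize.minimize(
            pose_energy,
            np.zeros(3),
            method="L-BFGS-B",
            bounds=[(-max_shift_A, max_shift_A)] * 3,
            options={"maxiter": 40},
        )
        shift = res.x if res.fun <= pose_energy(np.zeros(3)) else np.zeros(3)
        e = pose_energy(shift)
        if e >= CLASH_CLAMP_KCAL:
            warnings.warn(f"probe at site {site.position_A.round(2)} clashes; site skipped", stacklevel=2)
            continue
        if any(np.linalg.norm(site.position_A + shift - p) <= 2.5 for p in positions):
            warnings.warn("probe overlaps a previously placed probe; site skipped", stacklevel=2)
            continue
        site.occupied = True
        positions.append(site.position_A + shift)
        rotations.append(site.orientation)
        energies.append(e)
    return MicrosolvComplex(
        conformer=conf,
        probe=probe,
        probe_positions=np.array(positions).reshape(-1, 3),
        probe_rotations=np.array(rotations).reshape(-1, 3, 3),
        n_sites=len(positions),
        e_interaction_kcal=float(np.sum(energies)) if energies else 0.0,
        per_probe_energy_kcal=[float(x) for x in energies],
    )


def lie_energy(x: MicrosolvComplex) -> float:
    """Linear interaction energy: direct LJ + Coulomb sum over all probe
    sites and solute atoms, excluding probe-probe terms. kcal/mol."""
    if x.n_sites == 0:
        return 0.0
    sigma, eps, qq, clash = _pair_tables(x.conformer, x.probe)
    atom_pos = np.asarray(x.conformer.positions, dtype=float)
    total = 0.0
    for center, rot in zip(x.probe_positions, x.probe_rotations):
        total += _probe_energy(center + x.probe.site_offsets @ rot.T, atom_pos, sigma, eps, qq, clash)
    return float(total)


def compare_ensembles(a: list[MicrosolvComplex], b: list[MicrosolvComplex]) -> dict:
    """Group summary of site counts and interaction energies.

    Reports per-group mean ± SEM for ``n_sites`` and ``e_interaction_kcal``
    and a Wilcoxon rank-sum statistic for the energy difference. Singleton
    groups get an undefined (NaN) SEM with a warning.
    """
    if not a or not b:
        raise ValueError("both groups must be non-empty")

    def summarize(group):
        ns = np.array([x.n_sites for x in group], dtype=float)
        es = np.array([x.e_interaction_kcal for x in group])
        if len(group) < 2:
            warnings.warn("singleton group: SEM undefined", stacklevel=3)
            sem_n = sem_e = float("nan")
        else:
            sem_n = float(ns.std(ddof=1) / np.sqrt(len(group)))
            sem_e = float(es.std(ddof=1) / np.sqrt(len(group)))
        return {
            "n": len(group),
            "n_sites_mean": float(ns.mean()),
            "n_sites_sem": sem_n,
            "e_interaction_mean_kcal": float(es.mean()),
            "e_interaction_sem_kcal": sem_e,
        }

    out = {"group_a": summarize(a), "group_b": summarize(b)}
    ea = [x.e_interaction_kcal for x in a]
    eb = [x.e_interaction_kcal for x in b]
    if len(a) >= 2 and len(b) >= 2 and (np.std(ea) > 0 or np.std(eb) > 0):
        stat = stats.mannwhitneyu(ea, eb, alternative="two-sided")
        out["rank_sum"] = {"statistic": float(stat.statistic), "p_value": float(stat.pvalue)}
    else:
        out["rank_sum"] = {"statistic": float("nan"), "p_value": float("nan")}
    return out
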