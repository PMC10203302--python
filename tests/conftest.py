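"""Shared fixtures: lightweight conformers and synthetic solute clusters."""

from __future__ import annotations

import numpy as np
import pytest
from types import SimpleNamespace

from conformerge.conformers import Conformer


def make_point_conformer(label: str, r_da: float, energy: float | None = None, ccs: float | None = None) -> Conformer:
    """Minimal two-marker conformer for cascade/selection tests: the two dye
    markers sit ``r_da`` Å apart; energy and CCS are attached directly."""
    return Conformer(
        elements=["D", "D"],
        names=["DM1", "DM2"],
        residue_index=np.array([0, 1]),
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(r_da)]]),
        vdw_radii=np.array([2.2, 2.2]),
        charges=np.zeros(2),
        bonds=[],
        donor_marker=0,
        acceptor_marker=1,
        energy_kcal=energy,
        ccs_A2=ccs,
        label=label,
    )


def make_cluster_solute(exposed: bool, shell_radius: float = 10.0, n_shell: int = 60):
    """Synthetic solute cluster for microsolvation ordering tests.

    Identical composition in both variants (4-atom polar core inside a
    weakly interacting blocker shell); ``exposed`` moves the +-0.6 e charges
    from the inaccessible core onto accessible shell atoms.
    """
    core = np.array([[0, 0, 0], [3.2, 0, 0], [0, 3.2, 0], [0, 0, 3.2]], float)
    idx = np.arange(n_shell) + 0.5
    phi = np.arccos(1 - 2 * idx / n_shell)
    theta = np.pi * (1 + 5**0.5) * idx
    shell = shell_radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    ) + core.mean(axis=0)
    pos = np.vstack([core, shell])
    q = np.zeros(4 + n_shell)
    if exposed:
        q[4:12] = [0.6, -0.6] * 4
    else:
        q[:4] = [0.6, -0.6, 0.6, -0.6]
    return SimpleNamespace(
        positions=pos,
        charges=q,
        vdw_radii=np.array([1.6] * 4 + [2.0] * n_shell),
        elements=["C"] * 4 + ["H"] * n_shell,
    )


@pytest.fixture
def coil_50_atoms():
    """Seeded 50-atom random-walk cluster used for CCS cross-checks."""
    rng = np.random.default_rng(42)
    return SimpleNamespace(
        positions=np.cumsum(rng.normal(0, 2.0, (50, 3)), axis=0),
        vdw_radii=np.full(50, 1.7),
    )
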