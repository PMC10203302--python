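"""Collision cross sections: Monte-Carlo projection approximation and
traveling-wave ion-mobility (TWIM) calibration.

The projection approximation (PA) estimates the momentum-transfer collision
cross section of an ion as the orientation-averaged area of its projection,
each atom contributing a disk of radius (vdW radius + probe radius). The PA
systematically underestimates CCS for large ions relative to trajectory
methods; an explicit ``scale_factor`` (default 1.0) is provided for users
who want to apply a published PA-to-trajectory rescaling.

TWIM calibration follows the standard power-law protocol: reference CCS
values of calibrant ions (e.g. poly-DL-alanine) are charge- and
reduced-mass-normalized, regressed log-log against corrected drift time, and
the fit inverted for the analyte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "CCSResult",
    "CalibrantTable",
    "CalibrationFit",
    "pa_ccs",
    "pa_ccs_grid",
    "ccs_distribution",
    "twim_calibrate",
]

N2_MASS_DA = 28.0134


@dataclass
class CCSResult:
    ccs_A2: float
    n_orientations: int
    std_error_A2: float
    probe_radius_A: float
    scale_factor: float = 1.0


@dataclass
class CalibrantTable:
    """Calibrant rows: m/z (Th), charge, reference CCS (Å²), drift time (ms)."""

    mz: np.ndarray
    charge: np.ndarray
    ccs_ref_A2: np.ndarray
    drift_time_ms: np.ndarray
    gas_mass_Da: float = N2_MASS_DA

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.ccs_ref_A2 = np.asarray(self.ccs_ref_A2, dtype=float)
        self.drift_time_ms = np.asarray(self.drift_time_ms, dtype=float)
        n = self.mz.size
        if not (self.charge.size == self.ccs_ref_A2.size == self.drift_time_ms.size == n):
            raise ValueError("calibrant columns differ in length")
        if n < 3:
            raise ValueError("need >= 3 calibrants")
        for arr, nm in ((self.mz, "mz"), (self.charge, "charge"), (self.ccs_ref_A2, "ccs"), (self.drift_time_ms, "drift")):
            if np.any(arr <= 0):
                raise ValueError(f"calibrant {nm} values must be positive")

    @classmethod
    def from_csv(cls, path, gas_mass_Da: float = N2_MASS_DA) -> "CalibrantTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        cols = {c.lower(): c for c in df.columns}
        return cls(
            df[cols["mz"]].to_numpy(),
            df[cols["charge"]].to_numpy(),
            df[cols["ccs_ref_a2"]].to_numpy(),
            df[cols["drift_time_ms"]].to_numpy(),
            gas_mass_Da=gas_mass_Da,
        )


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    edc_delay_coeff: float = 0.0
    drift_range_ms: tuple[float, float] = (0.0, np.inf)


# ---------------------------------------------------------------------------
# Projection approximation


def _rotation_matrices(n: int, seed: int) -> np.ndarray:
    """Quasi-uniform rotation sequence: Shoemake's mapping of a seeded Sobol
    sequence in the unit cube to uniform random rotations."""
    sob = qmc.Sobol(d=3, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(max(n, 2))))
    u = sob.random_base2(m)[:n]
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(q).as_matrix()


def _collision_disks(conf, probe_radius_A: float):
    pos = np.asarray(conf.positions, dtype=float)
    radii = np.asarray(conf.vdw_radii, dtype=float) + probe_radius_A
    if pos.shape[0] < 1 or np.any(radii <= 0):
        raise ValueError("conformer needs >= 1 atom with positive collision radius")
    return pos, radii


def pa_ccs(
    conf,
    probe_radius_A: float = 1.0,
    n_orientations: int = 300,
    seed: int = 0,
    n_points: int = 10_000,
    scale_factor: float = 1.0,
) -> CCSResult:
    """Monte-Carlo projection-approximation CCS, Å².

    Averages over ``n_orientations`` quasi-random rotations the projected
    area of the union of collision disks (atom radius + ``probe_radius_A``),
    each area estimated by uniform rejection sampling of ``n_points`` points
    in the projected bounding box. The standard error is the spread of the
    per-orientation areas over sqrt(n_orientations); it shrinks as
    1/sqrt(n_orientations). ``scale_factor`` multiplies the mean.
    """
    if n_orientations < 10:
        raise ValueError("n_orientations must be >= 10")
    pos, radii = _collision_disks(conf, probe_radius_A)
    rots = _rotation_matrices(n_orientations, seed)
    rng = np.random.default_rng(seed + 1)
    r2 = radii**2
    areas = np.empty(n_orientations)
    for k in range(n_orientations):
        xy = pos @ rots[k].T[:, :2]  # project onto the plane normal to the beam
        lo = xy.min(axis=0) - radii.max()
        hi = xy.max(axis=0) + radii.max()
        box = np.prod(hi - lo)
        pts = rng.uniform(lo, hi, size=(n_points, 2))
        d2 = np.sum((pts[:, None, :] - xy[None, :, :]) ** 2, axis=2)
        hits = np.any(d2 <= r2[None, :], axis=1)
        areas[k] = box * hits.mean()
    mean = float(areas.mean()) * scale_factor
    se = float(areas.std(ddof=1) / np.sqrt(n_orientations)) * scale_factor
    return CCSResult(mean, n_orientations, se, probe_radius_A, scale_factor)


def pa_ccs_grid(
    conf,
    probe_radius_A: float = 1.0,
    n_orientations: int = 40,
    seed: int = 0,
    grid_spacing_A: float = 0.05,
) -> float:
    """Deterministic rasterization reference for the projected-area average.

    Same rotation sequence as :func:`pa_ccs`; each projection is rasterized
    on a square grid and the union area counted cell by cell. Exact up to
    O(spacing) discretization; used as an independent cross-check of the
    rejection-sampling estimator.
    """
    pos, radii = _collision_disks(conf, probe_radius_A)
    rots = _rotation_matrices(n_orientations, seed)
    areas = np.empty(n_orientations)
    for k in range(n_orientations):
        xy = pos @ rots[k].T[:, :2]
        lo = xy.min(axis=0) - radii.max() - grid_spacing_A
        hi = xy.max(axis=0) + radii.max() + grid_spacing_A
        nx = int(np.ceil((hi[0] - lo[0]) / grid_spacing_A))
        ny = int(np.ceil((hi[1] - lo[1]) / grid_spacing_A))
        covered = np.zeros((nx, ny), dtype=bool)
        for (cx, cy), r in zip(xy, radii):
            i0 = max(int((cx - r - lo[0]) / grid_spacing_A), 0)
            i1 = min(int((cx + r - lo[0]) / grid_spacing_A) + 2, nx)
            j0 = max(int((cy - r - lo[1]) / grid_spacing_A), 0)
            j1 = min(int((cy + r - lo[1]) / grid_spacing_A) + 2, ny)
            gx = lo[0] + (np.arange(i0, i1) + 0.5) * grid_spacing_A
            gy = lo[1] + (np.arange(j0, j1) + 0.5) * grid_spacing_A
            sub = (gx[:, None] - cx) ** 2 + (gy[None, :] - cy) ** 2 <= r * r
            covered[i0:i1, j0:j1] |= sub
        areas[k] = covered.sum() * grid_spacing_A**2
    return float(areas.mean())


def ccs_distribution(
    ensemble,
    probe_radius_A: float = 1.0,
    n_orientations: int = 300,
    seed: int = 0,
    n_points: int = 10_000,
    scale_factor: float = 1.0,
) -> list[CCSResult | None]:
    """Per-conformer PA CCS for an ensemble; attaches ``ccs_A2`` to each
    conformer. Failures are reported (None in the output) without aborting
    the batch. Deterministic given ``seed``; order preserved."""
    conformers = list(ensemble)
    if not conformers:
        raise ValueError("empty ensemble")
    results: list[CCSResult | None] = []
    failures = []
    for i, conf in enumerate(conformers):
        try:
            res = pa_ccs(conf, probe_radius_A, n_orientations, seed, n_points, scale_factor)
        except Exception as exc:  # keep the batch alive
            failures.append((i, str(exc)))
            results.append(None)
            continue
        conf.ccs_A2 = res.ccs_A2
        results.append(res)
    if failures:
        warnings.warn(f"pa_ccs failed for {len(failures)} conformer(s): {failures[:3]}", stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# TWIM calibration


def _reduced_mass(mz, z, gas_mass):
    m_ion = mz * z
    return m_ion * gas_mass / (m_ion + gas_mass)


def fit_calibration(table: CalibrantTable, edc_delay_coeff: float = 0.0) -> CalibrationFit:
    """Power-law TWIM calibration: ln(CCS') = a ln(t') + b.

    CCS' = CCS_ref * sqrt(mu) / z removes the charge and reduced-mass
    dependence; t' = t_D - c sqrt(m/z) corrects the post-mobility flight
    delay (instrument EDC coefficient c, default 0)."""
    t_prime = table.drift_time_ms - edc_delay_coeff * np.sqrt(table.mz)
    if np.any(t_prime <= 0):
        raise ValueError("corrected drift times must be positive; check edc_delay_coeff")
    mu = _reduced_mass(table.mz, table.charge, table.gas_mass_Da)
    ccs_prime = table.ccs_ref_A2 * np.sqrt(mu) / table.charge
    x, y = np.log(t_prime), np.log(ccs_prime)
    a, b = np.polyfit(x, y, 1)
    yhat = a * x + b
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if a <= 0:
        raise ValueError("calibration slope is non-positive; drift times inconsistent with CCS")
    if r2 < 0.98:
        warnings.warn(f"poor calibration: r^2 = {r2:.4f} < 0.98", stacklevel=2)
    return CalibrationFit(float(a), float(b), r2, edc_delay_coeff, (float(t_prime.min()), float(t_prime.max())))


def twim_calibrate(
    table: CalibrantTable,
    analyte_mz: float,
    analyte_charge: int,
    analyte_drift_ms: float,
    edc_delay_coeff: float = 0.0,
) -> float:
    """Calibrated analyte CCS (Å²) from its drift time.

    Warns when the analyte drift time falls outside the calibrated range
    (extrapolation)."""
    fit = fit_calibration(table, edc_delay_coeff)
    t_prime = analyte_drift_ms - edc_delay_coeff * np.sqrt(analyte_mz)
    if t_prime <= 0:
        raise ValueError("corrected analyte drift time must be positive")
    lo, hi = fit.drift_range_ms
    if not lo <= t_prime <= hi:
        warnings.warn("analyte drift time outside calibrated range: extrapolating", stacklevel=2)
    mu = _reduced_mass(analyte_mz, analyte_charge, table.gas_mass_Da)
    ccs_prime = np.exp(fit.slope * np.log(t_prime) + fit.intercept)
    return float(ccs_prime * analyte_charge / np.sqrt(mu))
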