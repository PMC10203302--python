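"""Differential ion-mobility (DMS/FAIMS) ionogram analysis.

An ionogram is an intensity-versus-compensation-voltage (CV) trace for one
selected species. Adding a volatile gas modifier (e.g. acetonitrile) shifts
the optimal CV of ions that cluster with the modifier; the magnitude of the
shift with modifier concentration is used here as an empirical, qualitative
clustering-propensity ranking. No attempt is made to predict CV from ion
structure or transport theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Ionogram",
    "Peak",
    "PeakSet",
    "detect_peaks",
    "cv_shift_series",
    "simulate_ionogram",
]

_CV_LIMIT_V = 100.0


@dataclass
class Ionogram:
    cv_V: np.ndarray
    intensity: np.ndarray
    modifier_mol_percent: float = 0.0
    dispersion_voltage_kV: float = 4.5
    species_label: str = ""

    def __post_init__(self):
        self.cv_V = np.asarray(self.cv_V, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.cv_V.ndim != 1 or self.cv_V.size < 3:
            raise ValueError("ionogram needs >= 3 CV points")
        if not np.all(np.diff(self.cv_V) > 0):
            raise ValueError("CV grid must be strictly increasing")
        if self.cv_V[0] < -_CV_LIMIT_V or self.cv_V[-1] > _CV_LIMIT_V:
            raise ValueError("CV grid must lie within [-100, 100] V")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "Ionogram":
        """Read a two-column (cv_V, intensity) CSV; '# key: value' header
        lines may carry modifier/DV/species metadata."""
        import pandas as pd

        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
        df = pd.read_csv(path, comment="#")
        return cls(
            df.iloc[:, 0].to_numpy(),
            df.iloc[:, 1].to_numpy(),
            modifier_mol_percent=float(meta.get("modifier_mol_percent", 0.0)),
            dispersion_voltage_kV=float(meta.get("dispersion_voltage_kV", 4.5)),
            species_label=meta.get("species", ""),
        )


@dataclass(frozen=True)
class Peak:
    cv_V: float
    height: float
    fwhm_V: float
    area: float


@dataclass
class PeakSet:
    peaks: list[Peak]
    smooth_fwhm_V: float
    min_prominence_fraction: float

    def __len__(self):
        return len(self.peaks)

    @property
    def dominant(self) -> Peak | None:
        return max(self.peaks, key=lambda p: p.height) if self.peaks else None


def _interp_half_crossing(cv, y, i_peak, half, direction):
    i = i_peak
    while 0 < i < cv.size - 1 and y[i] > half:
        i += direction
    j = i - direction
    if y[i] == y[j]:
        return cv[i]
    frac = (y[j] - half) / (y[j] - y[i])
    return cv[j] + frac * (cv[i] - cv[j])


def detect_peaks(
    iono: Ionogram,
    smooth_fwhm_V: float = 0.5,
    min_prominence_fraction: float = 0.05,
) -> PeakSet:
    """Peak detection: Gaussian smoothing, prominence-gated local maxima,
    FWHM from interpolated half-height crossings (model-agnostic, so
    asymmetric peaks are handled without assuming a Gaussian shape)."""
    if not 0 < min_prominence_fraction < 1:
        raise ValueError("min_prominence_fraction must be in (0, 1)")
    cv, y = iono.cv_V, iono.intensity
    dv = float(np.median(np.diff(cv)))
    sigma_bins = smooth_fwhm_V / 2.3548 / dv
    ys = gaussian_filter1d(y, sigma_bins) if sigma_bins > 0 else y.copy()
    if ys.max() <= 0:
        return PeakSet([], smooth_fwhm_V, min_prominence_fraction)
    idx, props = signal.find_peaks(ys, prominence=min_prominence_fraction * ys.max())
    peaks = []
    for i in idx:
        # refine the apex by a parabola through the three points around it
        if 0 < i < cv.size - 1:
            denom = ys[i - 1] - 2 * ys[i] + ys[i + 1]
            delta = 0.5 * (ys[i - 1] - ys[i + 1]) / denom if denom != 0 else 0.0
            apex = cv[i] + np.clip(delta, -1, 1) * dv
        else:
            apex = cv[i]
        half = ys[i] / 2.0
        left = _interp_half_crossing(cv, ys, i, half, -1)
        right = _interp_half_crossing(cv, ys, i, half, +1)
        fwhm = max(right - left, dv)
        lo = np.searchsorted(cv, apex - 2 * fwhm)
        hi = np.searchsorted(cv, apex + 2 * fwhm)
        area = float(np.trapezoid(y[lo:hi], cv[lo:hi]))
        peaks.append(Peak(float(apex), float(ys[i]), float(fwhm), area))
    peaks.sort(key=lambda p: p.cv_V)
    return PeakSet(peaks, smooth_fwhm_V, min_prominence_fraction)


def cv_shift_series(
    series: list[Ionogram],
    smooth_fwhm_V: float = 0.5,
    min_prominence_fraction: float = 0.05,
) -> dict:
    """Dominant-peak CV shift versus modifier concentration.

    Returns the per-concentration dominant CV, the shift relative to the
    lowest concentration, and a least-squares slope (V per mol %). A larger
    |slope| indicates a stronger clustering propensity with the modifier;
    the ranking is qualitative. Concentrations whose dominant peak is
    missing are reported as gaps and excluded from the fit.
    """
    if len(series) < 2:
        raise ValueError("need ionograms at >= 2 modifier concentrations")
    labels = {io.species_label for io in series}
    if len(labels) > 1:
        raise ValueError(f"mixed species labels in series: {sorted(labels)}")
    ordered = sorted(series, key=lambda io: io.modifier_mol_percent)
    conc, cv_dom, gaps = [], [], []
    for io in ordered:
        ps = detect_peaks(io, smooth_fwhm_V, min_prominence_fraction)
        if ps.dominant is None:
            gaps.append(io.modifier_mol_percent)
            continue
        conc.append(io.modifier_mol_percent)
        cv_dom.append(ps.dominant.cv_V)
    conc = np.asarray(conc)
    cv_dom = np.asarray(cv_dom)
    if conc.size < 2:
        raise ValueError("fewer than 2 concentrations with a detectable dominant peak")
    shift = cv_dom - cv_dom[0]
    slope, intercept = np.polyfit(conc, cv_dom, 1)
    return {
        "species": ordered[0].species_label,
        "concentration_mol_percent": conc.tolist(),
        "dominant_cv_V": cv_dom.tolist(),
        "shift_V": shift.tolist(),
        "slope_V_per_molpct": float(slope),
        "intercept_V": float(intercept),
        "gaps": gaps,
    }


def simulate_ionogram(
    base_cv_V: float = 8.0,
    shift_slope_V_per_molpct: float = 12.0,
    width_V: float = 0.4,
    height: float = 1000.0,
    noise_sd: float = 0.0,
    concentration_mol_percent: float = 0.0,
    seed: int = 0,
    extra_peaks: list[tuple[float, float, float]] | None = None,
    cv_range_V: tuple[float, float] = (-20.0, 30.0),
    n_points: int = 1001,
    species_label: str = "",
) -> Ionogram:
    """Synthetic ionogram: Gaussian peak(s) whose center shifts linearly with
    modifier concentration, plus seeded Gaussian noise (floored at zero).

    ``extra_peaks`` adds (base_cv, height, width) components subject to the
    same shift slope. Deterministic given ``seed``.
    """
    if width_V <= 0:
        raise ValueError("width_V must be > 0")
    if concentration_mol_percent < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    cv = np.linspace(cv_range_V[0], cv_range_V[1], n_points)
    shift = shift_slope_V_per_molpct * concentration_mol_percent
    y = height * np.exp(-((cv - base_cv_V - shift) ** 2) / (2 * width_V**2))
    for b, h, w in extra_peaks or []:
        y += h * np.exp(-((cv - b - shift) ** 2) / (2 * w**2))
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0, noise_sd, cv.size), 0, None)
    return Ionogram(cv, y, concentration_mol_percent, species_label=species_label)
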