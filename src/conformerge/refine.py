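"""Constraint-cascade ensemble refinement.

Candidate conformers are filtered in three stages mirroring the integrative
workflow: (1) a force-field-energy percentile cutoff, (2) matching of each
conformer's calculated CCS to experimental ion-mobility peak windows, and
(3) selection of the k structures whose marker-marker distance best agrees
with the experimental FRET distance — either closest in absolute terms or
closest from below (used when the FRET distance is suspected to be
overestimated). The final report quantifies the signed overestimation of the
experimental distance relative to the selected-structure mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conformers import Conformer, Ensemble, marker_distance

__all__ = [
    "CCSPeak",
    "ExperimentalConstraints",
    "RefinementResult",
    "energy_filter",
    "ccs_match",
    "distance_select",
    "overestimation_report",
    "run_cascade",
]


@dataclass(frozen=True)
class CCSPeak:
    label: str
    ccs_A2: float
    tolerance_fraction: float = 0.02

    def __post_init__(self):
        if self.ccs_A2 <= 0:
            raise ValueError("peak CCS must be > 0")
        if not 0 < self.tolerance_fraction <= 0.2:
            raise ValueError("tolerance_fraction must be in (0, 0.2]")

    @property
    def window(self) -> tuple[float, float]:
        return self.ccs_A2 * (1 - self.tolerance_fraction), self.ccs_A2 * (1 + self.tolerance_fraction)


@dataclass
class ExperimentalConstraints:
    """Per-ion experimental restraints: IM peak CCS windows plus one FRET
    donor-acceptor distance with its uncertainty."""

    ccs_peaks: list[CCSPeak]
    r_da_A: float
    r_da_sigma_A: float = 0.0
    selection_rule: str = "closest"
    k_select: int = 5

    def __post_init__(self):
        if self.selection_rule not in ("closest", "closest_below"):
            raise ValueError("selection_rule must be 'closest' or 'closest_below'")
        if self.k_select < 1:
            raise ValueError("k_select must be >= 1")
        if self.r_da_A <= 0:
            raise ValueError("r_da_A must be > 0")


@dataclass
class RefinementResult:
    selected: dict[str, list[Conformer]]
    mean_r_calc_A: dict[str, float]
    overestimation_percent: dict[str, float]
    stage_counts: dict[str, int] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)


def energy_filter(ensemble: Ensemble, fraction: float) -> Ensemble:
    """Retain the ceil(fraction * N) lowest-energy conformers.

    The cutoff is a rank percentile (scale-free), not a fraction of the
    energy range. Output preserves input order; rank ties break by label.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    confs = list(ensemble)
    for c in confs:
        if c.energy_kcal is None:
            raise ValueError(f"conformer {c.label!r} has no energy score")
    n_keep = int(np.ceil(fraction * len(confs)))
    order = sorted(range(len(confs)), key=lambda i: (confs[i].energy_kcal, confs[i].label))
    keep = set(order[:n_keep])
    return Ensemble(
        conformers=[c for i, c in enumerate(confs) if i in keep],
        provenance={**ensemble.provenance, "energy_filter_fraction": fraction},
    )


def ccs_match(ensemble: Ensemble, peaks: list[CCSPeak]) -> tuple[dict[str, list[Conformer]], list[Conformer]]:
    """Assign each conformer to every peak whose CCS window contains its
    calculated CCS. Returns (per-peak groups, unassigned conformers); a
    conformer inside two overlapping windows appears in both groups."""
    groups: dict[str, list[Conformer]] = {p.label: [] for p in peaks}
    unassigned: list[Conformer] = []
    for c in ensemble:
        if c.ccs_A2 is None:
            raise ValueError(f"conformer {c.label!r} has no calculated CCS")
        hit = False
        for p in peaks:
            lo, hi = p.window
            if lo <= c.ccs_A2 <= hi:
                groups[p.label].append(c)
                hit = True
        if not hit:
            unassigned.append(c)
    if all(not g for g in groups.values()):
        raise ValueError("constraints inconsistent with ensemble: no conformer matches any CCS peak")
    return groups, unassigned


def distance_select(
    group: list[Conformer],
    r_exp_A: float,
    rule: str = "closest",
    k: int = 5,
) -> list[Conformer]:
    """Select k conformers by agreement of the marker distance with r_exp.

    ``closest``: the k smallest |r_calc - r_exp|. ``closest_below``: among
    conformers with r_calc < r_exp, the k largest r_calc; if fewer than k
    qualify, the remainder is filled by the ``closest`` rule with a warning.
    Ties break deterministically by label.
    """
    if not group:
        raise ValueError("empty conformer group")
    r_calc = {c.label: marker_distance(c) for c in group}
    if rule == "closest":
        ranked = sorted(group, key=lambda c: (abs(r_calc[c.label] - r_exp_A), c.label))
        return ranked[:k]
    if rule != "closest_below":
        raise ValueError(f"unknown selection rule {rule!r}")
    below = [c for c in group if r_calc[c.label] < r_exp_A]
    ranked_below = sorted(below, key=lambda c: (-r_calc[c.label], c.label))
    selected = ranked_below[:k]
    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} conformer(s) below r_exp={r_exp_A}: "
            "filling the remainder by the 'closest' rule",
            stacklevel=2,
        )
        chosen = {c.label for c in selected}
        rest = sorted(
            (c for c in group if c.label not in chosen),
            key=lambda c: (abs(r_calc[c.label] - r_exp_A), c.label),
        )
        selected += rest[: k - len(selected)]
    return selected


def overestimation_report(r_exp_A: float, selected: list[Conformer]) -> float:
    """Signed overestimation of the experimental distance in percent:
    100 (r_exp - mean(r_calc)) / r_exp. Positive means the experiment
    exceeds the model mean."""
    if r_exp_A <= 0:
        raise ValueError("r_exp must be > 0")
    if not selected:
        raise ValueError("empty selection")
    mean_r = float(np.mean([marker_distance(c) for c in selected]))
    return 100.0 * (r_exp_A - mean_r) / r_exp_A


def run_cascade(
    ensemble: Ensemble,
    constraints: ExperimentalConstraints,
    energy_fraction: float = 0.2,
) -> RefinementResult:
    """Full refinement cascade: energy percentile filter -> CCS peak match ->
    FRET distance selection -> overestimation report, with per-stage counts.
    Deterministic; stage errors propagate with the stage name attached."""
    counts = {"input": len(ensemble)}
    try:
        filtered = energy_filter(ensemble, energy_fraction)
    except ValueError as exc:
        raise ValueError(f"energy_filter: {exc}") from exc
    counts["energy_filter"] = len(filtered)
    try:
        groups, unassigned = ccs_match(filtered, constraints.ccs_peaks)
    except ValueError as exc:
        raise ValueError(f"ccs_match: {exc}") from exc
    selected: dict[str, list[Conformer]] = {}
    mean_r: dict[str, float] = {}
    over: dict[str, float] = {}
    for peak in constraints.ccs_peaks:
        group = groups[peak.label]
        counts[f"ccs_match[{peak.label}]"] = len(group)
        if not group:
            warnings.warn(f"no conformer matched CCS peak {peak.label!r}", stacklevel=2)
            continue
        try:
            sel = distance_select(group, constraints.r_da_A, constraints.selection_rule, constraints.k_select)
        except ValueError as exc:
            raise ValueError(f"distance_select[{peak.label}]: {exc}") from exc
        selected[peak.label] = sel
        counts[f"selected[{peak.label}]"] = len(sel)
        mean_r[peak.label] = float(np.mean([marker_distance(c) for c in sel]))
        over[peak.label] = overestimation_report(constraints.r_da_A, sel)
    return RefinementResult(
        selected=selected,
        mean_r_calc_A=mean_r,
        overestimation_percent=over,
        stage_counts=counts,
        unassigned=[c.label for c in unassigned],
    )
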