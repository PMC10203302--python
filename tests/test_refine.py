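"""Constraint cascade: energy percentile filter, CCS windowing, distance
selection, overestimation reporting."""

import numpy as np
import pytest

from conformerge.conformers import Ensemble, marker_distance
from conformerge.refine import (
    CCSPeak,
    ExperimentalConstraints,
    ccs_match,
    distance_select,
    energy_filter,
    overestimation_report,
    run_cascade,
)

from conftest import make_point_conformer


def make_ensemble(specs):
    """specs: iterable of (label, r_da, energy, ccs)."""
    return Ensemble(conformers=[make_point_conformer(*s) for s in specs])


class TestEnergyFilter:
    def test_20_percent_of_5000_is_1000(self):
        rng = np.random.default_rng(0)
        ens = make_ensemble(
            (f"c{i:04d}", 50.0, float(e), 600.0) for i, e in enumerate(rng.normal(0, 10, 5000))
        )
        kept = energy_filter(ens, 0.20)
        assert len(kept) == 1000

    def test_identity_at_full_fraction(self):
        ens = make_ensemble((f"c{i}", 50.0, float(i), 600.0) for i in range(7))
        assert [c.label for c in energy_filter(ens, 1.0)] == [c.label for c in ens]

    def test_rank_property(self):
        rng = np.random.default_rng(1)
        ens = make_ensemble((f"c{i:03d}", 50.0, float(e), 600.0) for i, e in enumerate(rng.uniform(0, 100, 200)))
        kept = energy_filter(ens, 0.3)
        kept_labels = {c.label for c in kept}
        dropped = [c for c in ens if c.label not in kept_labels]
        assert max(c.energy_kcal for c in kept) <= min(c.energy_kcal for c in dropped)

    def test_unscored_conformer_raises(self):
        ens = make_ensemble([("a", 50.0, None, 600.0), ("b", 50.0, 1.0, 600.0)])
        with pytest.raises(ValueError, match="energy"):
            energy_filter(ens, 0.5)


class TestCCSMatch:
    def test_window_arithmetic(self):
        peak = CCSPeak("P", 600.0, 0.02)  # window [588, 612]
        ens = make_ensemble([("in", 50.0, 1.0, 606.0), ("out", 50.0, 1.0, 612.5)])
        groups, unassigned = ccs_match(ens, [peak])
        assert [c.label for c in groups["P"]] == ["in"]
        assert [c.label for c in unassigned] == ["out"]

    def test_disjoint_windows_have_empty_intersection(self):
        peaks = [CCSPeak("lo", 560.0, 0.02), CCSPeak("hi", 630.0, 0.02)]
        ens = make_ensemble([(f"c{i}", 50.0, 1.0, ccs) for i, ccs in enumerate([555, 565, 625, 640])])
        groups, _ = ccs_match(ens, peaks)
        assert not ({c.label for c in groups["lo"]} & {c.label for c in groups["hi"]})

    def test_two_cluster_assignment_accuracy(self):
        """Planted two-population ensemble (centers 560/630, sigma 5): at
        least 95% of conformers land in their own peak's window."""
        rng = np.random.default_rng(7)
        specs, truth = [], {}
        for i in range(150):
            ccs = float(rng.normal(560, 5))
            specs.append((f"a{i:03d}", 50.0, 1.0, ccs))
            truth[f"a{i:03d}"] = "lo"
        for i in range(150):
            ccs = float(rng.normal(630, 5))
            specs.append((f"b{i:03d}", 50.0, 1.0, ccs))
            truth[f"b{i:03d}"] = "hi"
        groups, _ = ccs_match(make_ensemble(specs), [CCSPeak("lo", 560.0, 0.03), CCSPeak("hi", 630.0, 0.03)])
        correct = sum(1 for lbl in ("lo", "hi") for c in groups[lbl] if truth[c.label] == lbl)
        assert correct >= 0.95 * 300

    def test_nothing_matches_raises(self):
        ens = make_ensemble([("a", 50.0, 1.0, 100.0)])
        with pytest.raises(ValueError, match="inconsistent"):
            ccs_match(ens, [CCSPeak("P", 600.0, 0.02)])


class TestDistanceSelect:
    @staticmethod
    def group():
        return [make_point_conformer(f"r{int(r)}", r) for r in (60.0, 66.0, 70.0, 75.0, 80.0)]

    def test_closest_below_enumeration(self):
        sel = distance_select(self.group(), 71.5, "closest_below", 2)
        assert sorted(marker_distance(c) for c in sel) == [66.0, 70.0]

    def test_closest_enumeration(self):
        sel = distance_select(self.group(), 71.5, "closest", 2)
        assert sorted(marker_distance(c) for c in sel) == [70.0, 75.0]

    def test_k_exceeding_group_returns_all(self):
        assert len(distance_select(self.group(), 71.5, "closest", 10)) == 5

    def test_closest_below_shortfall_falls_back_with_warning(self):
        group = [make_point_conformer("lo", 60.0), make_point_conformer("hi1", 80.0), make_point_conformer("hi2", 85.0)]
        with pytest.warns(UserWarning, match="closest"):
            sel = distance_select(group, 65.0, "closest_below", 2)
        assert sorted(marker_distance(c) for c in sel) == [60.0, 80.0]

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            distance_select([], 70.0, "closest", 5)


class TestOverestimation:
    def test_reference_values(self):
        sel_72 = [make_point_conformer("a", 71.7)]
        assert overestimation_report(77.5, sel_72) == pytest.approx(7.5, abs=0.1)
        sel_66 = [make_point_conformer("b", 66.5)]
        assert overestimation_report(77.5, sel_66) == pytest.approx(14.1, abs=0.15)

    def test_zero_when_mean_equals_experiment(self):
        assert overestimation_report(70.0, [make_point_conformer("a", 70.0)]) == pytest.approx(0.0)

    def test_signed_negative_when_model_exceeds_experiment(self):
        assert overestimation_report(60.0, [make_point_conformer("a", 66.0)]) == pytest.approx(-10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            overestimation_report(-1.0, [make_point_conformer("a", 50.0)])
        with pytest.raises(ValueError):
            overestimation_report(70.0, [])


def planted_ensemble(seed=0, n_decoys=500, r_exp=77.5):
    """500 decoys plus 5 planted conformers per CCS peak: planted members sit
    in the lowest energy quintile, inside the peak window, with marker
    distances nearest the experimental value."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_decoys):
        specs.append(
            (f"decoy{i:03d}", float(rng.uniform(30, 90)), float(rng.uniform(100, 200)), float(rng.uniform(400, 800)))
        )
    planted = {"C1": [], "C2": []}
    for label, center in (("C1", 560.0), ("C2", 630.0)):
        for j in range(5):
            name = f"plant-{label}-{j}"
            specs.append(
                (name, float(r_exp - 0.5 + 0.1 * j), 90.0 + j, float(center + rng.uniform(-5, 5)))
            )
            planted[label].append(name)
    return make_ensemble(specs), planted


class TestCascade:
    def test_planted_recovery(self):
        ens, planted = planted_ensemble(seed=3)
        cons = ExperimentalConstraints(
            ccs_peaks=[CCSPeak("C1", 560.0, 0.02), CCSPeak("C2", 630.0, 0.02)],
            r_da_A=77.5,
            selection_rule="closest",
            k_select=5,
        )
        res = run_cascade(ens, cons, 0.20)
        for label in ("C1", "C2"):
            recovered = set(c.label for c in res.selected[label]) & set(planted[label])
            assert len(recovered) >= 4

    def test_matches_brute_force_enumeration(self):
        """On a small ensemble the cascade equals direct enumeration of the
        stage predicates."""
        rng = np.random.default_rng(11)
        ens = make_ensemble(
            (f"c{i:03d}", float(rng.uniform(40, 90)), float(rng.uniform(0, 50)), float(rng.uniform(500, 700)))
            for i in range(120)
        )
        cons = ExperimentalConstraints(
            ccs_peaks=[CCSPeak("P", 600.0, 0.05)], r_da_A=70.0, selection_rule="closest", k_select=5
        )
        res = run_cascade(ens, cons, 0.25)
        # independent brute force
        confs = sorted(ens, key=lambda c: (c.energy_kcal, c.label))
        kept = confs[: int(np.ceil(0.25 * len(confs)))]
        lo, hi = 600.0 * 0.95, 600.0 * 1.05
        group = [c for c in kept if lo <= c.ccs_A2 <= hi]
        expect = sorted(group, key=lambda c: (abs(marker_distance(c) - 70.0), c.label))[:5]
        assert {c.label for c in res.selected["P"]} == {c.label for c in expect}
        assert res.mean_r_calc_A["P"] == pytest.approx(np.mean([marker_distance(c) for c in expect]))

    def test_stage_counts_monotone_and_predicates_hold(self):
        ens, _ = planted_ensemble(seed=5)
        cons = ExperimentalConstraints(
            ccs_peaks=[CCSPeak("C1", 560.0, 0.02), CCSPeak("C2", 630.0, 0.02)], r_da_A=77.5, k_select=5
        )
        res = run_cascade(ens, cons, 0.20)
        n_energy = res.stage_counts["energy_filter"]
        assert n_energy <= res.stage_counts["input"]
        energy_cut = sorted(c.energy_kcal for c in ens)[n_energy - 1]
        for peak in cons.ccs_peaks:
            assert res.stage_counts[f"ccs_match[{peak.label}]"] <= n_energy
            assert res.stage_counts[f"selected[{peak.label}]"] <= cons.k_select
            lo, hi = peak.window
            for c in res.selected[peak.label]:
                assert c.energy_kcal <= energy_cut
                assert lo <= c.ccs_A2 <= hi

    def test_permutation_invariance(self):
        ens, _ = planted_ensemble(seed=9)
        rng = np.random.default_rng(2)
        shuffled = list(ens)
        rng.shuffle(shuffled)
        cons = ExperimentalConstraints(ccs_peaks=[CCSPeak("C1", 560.0, 0.02)], r_da_A=77.5, k_select=5)
        a = run_cascade(ens, cons, 0.2)
        b = run_cascade(Ensemble(conformers=shuffled), cons, 0.2)
        assert {c.label for c in a.selected["C1"]} == {c.label for c in b.selected["C1"]}

    def test_composition_identity_with_trivial_constraints(self):
        ens = make_ensemble((f"c{i}", 40.0 + i, 1.0 + i, 600.0) for i in range(10))
        cons = ExperimentalConstraints(
            ccs_peaks=[CCSPeak("all", 600.0, 0.2)], r_da_A=50.0, selection_rule="closest", k_select=10
        )
        res = run_cascade(ens, cons, 1.0)
        assert len(res.selected["all"]) == 10
        mean_r = np.mean([marker_distance(c) for c in ens])
        assert res.overestimation_percent["all"] == pytest.approx(100 * (50.0 - mean_r) / 50.0)
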