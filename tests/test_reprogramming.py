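"""Reprogramming score, hit calling, and dose comparisons."""

import pytest
from hypothesis import given, strategies as st

import episcreen as ep
from episcreen.dose_response import CurveFit
from episcreen.reprogramming import reprogramming_score
from episcreen.screen_model import Arm

from test_dose_response import profile_from_viability

DOSES5 = [10000, 1000, 100, 10, 1]


def pair(mono_viab, combo_viab, doses=None, compound="X1"):
    doses = doses or DOSES5[: len(mono_viab)]
    mono = profile_from_viability(doses, mono_viab, compound=compound,
                                  arm=Arm.PRETREAT_ONLY)
    combo = profile_from_viability(doses, combo_viab, compound=compound,
                                   arm=Arm.PRETREAT_PLUS_COMBO)
    return mono, combo


def result(compound, cell_line, score, qc_pass=True, best_dose=100.0):
    return ep.ReprogrammingResult(
        cell_line=cell_line, compound_id=compound, score=score, best_dose=best_dose,
        per_dose_deltas=((best_dose, score),), qc_pass=qc_pass,
        hit=score > 30 and qc_pass,
    )


class TestScore:
    def test_sensitization_phenotype(self):
        # pretreatment alone harmless at 1000 nM; the combination halves viability
        mono, combo = pair([100, 100, 98, 97, 96], [55, 50, 95, 96, 96])
        r = reprogramming_score(mono, combo)
        assert r.score == pytest.approx(50.0)
        assert r.best_dose == 1000
        assert r.hit

    def test_identical_profiles_score_zero(self):
        mono, combo = pair([90, 80, 70, 60, 50], [90, 80, 70, 60, 50])
        r = reprogramming_score(mono, combo)
        assert r.score == 0.0
        assert not r.hit

    def test_max_over_doses(self):
        mono, combo = pair([95, 90, 85, 40, 20], [93, 70, 60, 35, 18])
        r = reprogramming_score(mono, combo)
        deltas = dict(r.per_dose_deltas)
        assert [deltas[d] for d in DOSES5] == pytest.approx([2, 20, 25, 5, 2])
        assert r.score == pytest.approx(25.0)
        assert r.best_dose == 100  # third dose of the ladder

    def test_ties_resolve_to_lowest_dose(self):
        mono, combo = pair([100, 100, 100], [60, 60, 100], doses=[1000, 100, 10])
        r = reprogramming_score(mono, combo)
        assert r.score == pytest.approx(40.0)
        assert r.best_dose == 100

    def test_unshared_doses_are_dropped(self):
        mono = profile_from_viability([1000, 100, 10], [90, 80, 70],
                                      arm=Arm.PRETREAT_ONLY)
        combo = profile_from_viability([1000, 100], [60, 75],
                                       arm=Arm.PRETREAT_PLUS_COMBO)
        r = reprogramming_score(mono, combo)
        assert set(dict(r.per_dose_deltas)) == {1000, 100}
        assert r.score == pytest.approx(30.0)

    def test_no_shared_doses_is_an_error(self):
        mono = profile_from_viability([1000], [90], arm=Arm.PRETREAT_ONLY)
        combo = profile_from_viability([10], [60], arm=Arm.PRETREAT_PLUS_COMBO)
        with pytest.raises(ep.ValidationError, match="shared"):
            reprogramming_score(mono, combo)

    def test_arm_mismatch_is_an_error(self):
        mono, combo = pair([90], [60])
        with pytest.raises(ep.ValidationError, match="arm"):
            reprogramming_score(combo, mono)

    @given(
        st.lists(
            st.tuples(st.floats(-20, 120), st.floats(-20, 120)),
            min_size=1, max_size=5,
        )
    )
    def test_antisymmetry_under_arm_swap(self, viab_pairs):
        doses = DOSES5[: len(viab_pairs)]
        mono_v = [a for a, _ in viab_pairs]
        combo_v = [b for _, b in viab_pairs]
        mono, combo = pair(mono_v, combo_v, doses=doses)
        fwd = reprogramming_score(mono, combo)
        swapped_mono = profile_from_viability(doses, combo_v, arm=Arm.PRETREAT_ONLY)
        swapped_combo = profile_from_viability(doses, mono_v,
                                               arm=Arm.PRETREAT_PLUS_COMBO)
        rev = reprogramming_score(swapped_mono, swapped_combo)
        fwd_deltas, rev_deltas = dict(fwd.per_dose_deltas), dict(rev.per_dose_deltas)
        assert all(fwd_deltas[d] == -rev_deltas[d] for d in doses)
        assert fwd.score == -min(rev_deltas.values())
        assert abs(fwd.score) <= 140.0  # bounded by the clamp range


class TestHitCalling:
    def test_threshold_is_strict(self):
        matrix = ep.call_hits([result("X1", "A", 30.0), result("X2", "A", 30.01)])
        assert not matrix.entries[("X1", "A")].hit
        assert matrix.entries[("X2", "A")].hit
        assert matrix.hits_per_cell_line == {"A": 1}

    def test_qc_gate_blocks_hits(self):
        matrix = ep.call_hits([result("X1", "A", 45.0, qc_pass=False)])
        assert not matrix.entries[("X1", "A")].hit

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ep.ValidationError, match="duplicate"):
            ep.call_hits([result("X1", "A", 10), result("X1", "A", 20)])

    def test_raising_threshold_never_adds_hits(self):
        results = [result(f"X{i}", "A", s) for i, s in
                   enumerate([5, 15, 25, 31, 35, 45, 55, 80])]
        counts = [
            ep.call_hits(results, threshold=t).hit_count()
            for t in [0, 10, 20, 30, 40, 50, 60, 90]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_per_class_tallies_use_library(self, library):
        by_id = {r.compound_id: r for r in library}
        results = [result("VOR", "A", 50), result("JQ1", "A", 50),
                   result("AZA", "A", 10)]
        matrix = ep.call_hits(results, library=library)
        assert matrix.hits_per_class == {"HDAC": 1, "BRD": 1}
        assert by_id["VOR"].target_class == "HDAC"

    def test_untested_pairs_are_marked(self):
        matrix = ep.call_hits([result("X1", "A", 50), result("X1", "B", 10),
                               result("X2", "A", 10)])
        assert not matrix.is_tested("X2", "B")
        frame = matrix.to_frame()
        assert frame.loc["X2", "B"] is None or frame.loc["X2", "B"] != frame.loc["X2", "B"]


class TestDoseComparison:
    def test_sensitizing_below_cytotoxic(self):
        fit = CurveFit(e0=100, emax=0, ic50=1000.0, hill_slope=1.0,
                       r_squared=0.99, converged=True)
        cmp = ep.sensitizing_vs_cytotoxic_dose(result("X1", "A", 50, best_dose=10.0), fit)
        assert cmp.sensitizing_below_cytotoxic is True
        assert cmp.ratio == pytest.approx(100.0)

    def test_non_converged_fit_is_indeterminate(self):
        fit = CurveFit(e0=100, emax=90, ic50=None, hill_slope=None,
                       r_squared=None, converged=False)
        cmp = ep.sensitizing_vs_cytotoxic_dose(result("X1", "A", 50), fit)
        assert cmp.sensitizing_below_cytotoxic is None
        assert cmp.ratio is None

    def test_holds_for_all_planted_sensitizers(self, noiseless_screen):
        # the simulator plants sensitization two dilutions below the mono IC50
        results, _ = ep.analyze_screen(
            noiseless_screen.raw_plates, noiseless_screen.layouts
        )
        norm = ep.normalize_screen(noiseless_screen.raw_plates, noiseless_screen.layouts)
        profiles = ep.aggregate_all_profiles(norm, noiseless_screen.layouts)
        truth = noiseless_screen.truth
        checked = 0
        for r in results:
            t = truth.entries[(r.cell_line, r.compound_id)]
            if not t.is_sensitizer:
                continue
            mono = profiles[(r.cell_line, r.compound_id, Arm.PRETREAT_ONLY)]
            cmp = ep.sensitizing_vs_cytotoxic_dose(r, ep.fit_curve(mono))
            assert cmp.sensitizing_below_cytotoxic is True
            checked += 1
        assert checked >= 1
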