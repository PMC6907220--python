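"""Generative model: Hill curves, passaging dynamics, full-screen simulation."""

import pytest
from hypothesis import given, strategies as st

import episcreen as ep
from episcreen.screen_model import Arm, WellKind, layout_to_csv, raw_to_csv
from episcreen.synthetic_screen import _passage_one_cycle


class TestHillViability:
    def test_baseline_midpoint_and_shoulder(self):
        assert ep.hill_viability(0, 100, 0, 100, 1) == 100.0
        for slope in (0.5, 1, 2, 4):
            assert ep.hill_viability(100, 100, 0, 100, slope) == pytest.approx(50.0)
        assert ep.hill_viability(300, 100, 0, 100, 1) == pytest.approx(25.0)

    @given(
        doses=st.lists(st.floats(0, 1e6), min_size=2, max_size=6),
        ic50=st.floats(0.1, 1e5),
        slope=st.floats(0.2, 5),
        emax=st.floats(0, 50),
    )
    def test_monotone_non_increasing(self, doses, ic50, slope, emax):
        doses = sorted(doses)
        viab = [ep.hill_viability(d, 100, emax, ic50, slope) for d in doses]
        assert all(a >= b - 1e-9 for a, b in zip(viab, viab[1:]))

    @pytest.mark.parametrize("kwargs", [{"ic50": 0}, {"slope": -1}, {"dose": -1}])
    def test_invalid_parameters(self, kwargs):
        args = {"dose": 10.0, "e0": 100.0, "emax": 0.0, "ic50": 100.0, "slope": 1.0}
        args.update(kwargs)
        with pytest.raises(ep.ValidationError):
            ep.hill_viability(**args)


class TestPassaging:
    def test_one_cycle_exchanges_three_quarters_and_halves_cells(self):
        state = ep.simulate_passage(ep.PassageState(), 1)
        assert state.old_media_fraction == pytest.approx(0.25)
        assert state.cells == pytest.approx(0.5)
        assert state.total_volume == pytest.approx(40.0)

    def test_zero_cycles_is_identity(self):
        fresh = ep.PassageState()
        assert ep.simulate_passage(fresh, 0) == fresh

    def test_two_cycles_compose(self):
        state = ep.simulate_passage(ep.PassageState(), 2)
        assert state.old_media_fraction == pytest.approx(0.0625)
        assert state.cells == pytest.approx(0.25)

    @given(cycles=st.integers(0, 12))
    def test_stepwise_agrees_with_closed_form(self, cycles):
        stepped = ep.simulate_passage(ep.PassageState(), cycles)
        closed = ep.passage_closed_form(cycles)
        assert stepped.old_media_fraction == pytest.approx(
            closed.old_media_fraction, rel=1e-12
        )
        assert stepped.cells == pytest.approx(closed.cells, rel=1e-12)
        assert stepped.drug_concentration == pytest.approx(
            closed.drug_concentration, rel=1e-12, abs=1e-15
        )

    def test_drug_reaches_and_holds_nominal(self):
        # drug-free well refilled with nominal-dose media converges to nominal
        state = ep.PassageState(drug_concentration=0.0)
        concs = []
        for _ in range(10):
            state = ep.simulate_passage(state, 1, fresh_drug=1.0)
            concs.append(state.drug_concentration)
        assert all(b >= a for a, b in zip(concs, concs[1:]))
        assert concs[-1] == pytest.approx(1.0, abs=1e-5)
        # already at nominal: stays there exactly
        steady = ep.simulate_passage(ep.PassageState(), 3, fresh_drug=1.0)
        assert steady.drug_concentration == pytest.approx(1.0)

    def test_negative_cycles_rejected(self):
        with pytest.raises(ep.ValidationError):
            ep.simulate_passage(ep.PassageState(), -1)

    def test_single_cycle_steps_conserve_volume(self):
        state = _passage_one_cycle(ep.PassageState(), fresh_drug=1.0)
        assert state.total_volume == 40.0


class TestSimulateScreen:
    def test_default_screen_well_counts(self, library):
        config = ep.SimConfig(seed=2, library=library)
        screen = ep.simulate_screen(config, ep.default_ground_truth(config))
        # 4 cell lines x 2 arms x 2 replicates
        assert len(screen.layouts) == len(screen.raw_plates) == 16
        for layout, raw in zip(screen.layouts, screen.raw_plates):
            kinds = [a.kind for a in layout.assignments.values()]
            assert kinds.count(WellKind.COMPOUND) == 60 * 5
            assert kinds.count(WellKind.NEG_CONTROL) == 16
            assert kinds.count(WellKind.POS_CONTROL) == 16
            assert len(raw.readings) == 60 * 5 + 32
            ep.validate_plate_pair(layout, raw)

    def test_default_noise_passes_qc(self, small_screen):
        norm = ep.normalize_screen(small_screen.raw_plates, small_screen.layouts)
        assert all(p.qc.passed for p in norm)

    def test_same_seed_is_byte_identical(self, small_config):
        truth = ep.default_ground_truth(small_config, n_sensitizers=3)
        a = ep.simulate_screen(small_config, truth)
        b = ep.simulate_screen(small_config, truth)
        assert [layout_to_csv(x) for x in a.layouts] == [layout_to_csv(x) for x in b.layouts]
        assert [raw_to_csv(x) for x in a.raw_plates] == [raw_to_csv(x) for x in b.raw_plates]

    def test_different_seeds_differ(self, small_config, library):
        truth = ep.default_ground_truth(small_config, n_sensitizers=3)
        other = ep.SimConfig(seed=12, cell_lines=small_config.cell_lines,
                             library=library[:10])
        a = ep.simulate_screen(small_config, truth)
        b = ep.simulate_screen(other, truth)
        assert raw_to_csv(a.raw_plates[0]) != raw_to_csv(b.raw_plates[0])

    def test_truth_must_cover_all_pairs(self, small_config):
        truth = ep.default_ground_truth(small_config, n_sensitizers=3)
        del truth.entries[("LINE-A", small_config.library[0].compound_id)]
        with pytest.raises(ep.ValidationError, match="missing"):
            ep.simulate_screen(small_config, truth)

    def test_zero_noise_normalization_recovers_viabilities(self, noiseless_screen):
        norm = ep.normalize_screen(noiseless_screen.raw_plates, noiseless_screen.layouts)
        truth = noiseless_screen.truth
        for plate, layout in zip(norm, noiseless_screen.layouts):
            for well, a in layout.assignments.items():
                if a.kind is not WellKind.COMPOUND:
                    continue
                t = truth.entries[(layout.cell_line, a.compound_id)]
                v = (
                    t.mono_viability(a.dose)
                    if layout.arm is Arm.PRETREAT_ONLY
                    else t.combo_viability(a.dose, truth.combo_baseline)
                )
                assert plate.viability[well] == pytest.approx(v, abs=1e-9)

    def test_zero_noise_scores_equal_planted_effects(self, noiseless_screen):
        results, _ = ep.analyze_screen(noiseless_screen.raw_plates,
                                       noiseless_screen.layouts)
        truth = noiseless_screen.truth
        doses = ep.build_dose_series(10000, 5, 10).concentrations
        for r in results:
            t = truth.entries[(r.cell_line, r.compound_id)]
            expected = truth.expected_score(r.cell_line, r.compound_id, doses)
            assert r.score == pytest.approx(expected, abs=1e-9)
            if t.is_sensitizer:
                assert r.score == pytest.approx(t.sensitization_effect, abs=1e-9)
                assert r.best_dose == t.sensitizing_dose


class TestRecovery:
    def test_perfect_and_empty_calls(self, small_screen):
        results, matrix = ep.analyze_screen(small_screen.raw_plates,
                                            small_screen.layouts)
        rec = ep.evaluate_recovery(matrix, small_screen.truth)
        n_sens = sum(t.is_sensitizer for t in small_screen.truth.entries.values())
        assert rec.tp + rec.fn == n_sens
        assert rec.precision == 1.0 and rec.recall == 1.0
        no_hits = ep.call_hits(results, threshold=1e9)
        rec0 = ep.evaluate_recovery(no_hits, small_screen.truth)
        assert rec0.recall == 0.0

    def test_coverage_mismatch_rejected(self, small_screen):
        _, matrix = ep.analyze_screen(small_screen.raw_plates, small_screen.layouts)
        truth = ep.GroundTruth(entries=dict(list(small_screen.truth.entries.items())[:3]))
        with pytest.raises(ep.ValidationError, match="different"):
            ep.evaluate_recovery(matrix, truth)


class TestSynergySimulation:
    def test_independence_grid_scores_zero(self):
        g = ep.simulate_synergy_grid(
            "L", "X1", epi_doses=[1000, 100, 10], combo_doses=[2, 1, 0.5],
        )
        scored = ep.excess_grid(g)
        assert scored.summary_score == pytest.approx(0.0, abs=1e-10)

    def test_planted_excess_recovered(self):
        g = ep.simulate_synergy_grid(
            "L", "X1", epi_doses=[10.0], combo_doses=[0.01], excess=0.15,
        )
        scored = ep.excess_grid(g)
        assert scored.summary_score == pytest.approx(15.0, abs=0.01)
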