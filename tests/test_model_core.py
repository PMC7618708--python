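"""Unit-level behavior of the lattice transcription model."""

import math

import numpy as np
import pytest

from polterm.model_core import (PolState, SimCounters, SimParams, UnitState,
                                advance_unit, entrainment_factor,
                                processivity, pt_hazard, simulate_unit,
                                step_probabilities)


def unit_with(params, positions):
    pols = [PolState(p, p, 0.0) for p in positions]
    return UnitState(params, polymerases=pols,
                     twist=[0.0] * max(0, len(pols) - 1))


class TestPtHazard:
    @pytest.mark.parametrize("kw, expected", [
        (dict(p_pt=0.0), 0.0),
        (dict(p_pt=0.1, v_bar=50, pt_distance=2000), 0.0025),
        (dict(p_pt=1.0, v_bar=50, pt_distance=6750), 1.0 * 50 / 6750),
    ])
    def test_hazard_formula(self, kw, expected):
        assert pt_hazard(SimParams(**kw)) == pytest.approx(expected)

    def test_per_step_probability_scale(self):
        p = SimParams(p_pt=0.1, v_bar=50, pt_distance=2000)
        assert pt_hazard(p) * p.dt == pytest.approx(1.0e-5)

    def test_cumulative_hazard_over_region_equals_p_pt(self):
        # transit of the PT region at v_bar accumulates exactly p_pt
        for ppt, dist in [(0.3, 2000), (0.7, 6750)]:
            p = SimParams(p_pt=ppt, pt_distance=dist)
            assert pt_hazard(p) * dist / p.v_bar == pytest.approx(ppt)


class TestEntrainment:
    @pytest.mark.parametrize("length, expected", [
        (0, 0.0), (2000, 1.0), (1000, 0.5), (5000, 1.0)])
    def test_linear_ramp(self, length, expected):
        p = SimParams(ler_length=2000)
        assert entrainment_factor(length, p) == pytest.approx(expected)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            entrainment_factor(-1, SimParams())

    def test_no_ler_means_full_entrainment(self):
        assert entrainment_factor(1, SimParams(ler_length=0)) == 1.0


class TestStepProbabilities:
    def test_neutral_template_velocity_contract(self):
        p = SimParams()
        unit = unit_with(p, [3500])
        pf, pb, ps = step_probabilities(unit.polymerases[0], unit, None, p)
        assert pf - pb == pytest.approx(p.v_bar * p.dt)
        assert pf + pb + ps == pytest.approx(1.0)

    def test_steric_exclusion_blocks_forward(self):
        p = SimParams()
        unit = unit_with(p, [1038, 1000])  # downstream neighbor 38 nt ahead
        pf, _, _ = step_probabilities(unit.polymerases[1], unit, None, p)
        assert pf == 0.0

    def test_no_backtrack_off_template(self):
        p = SimParams()
        unit = unit_with(p, [1])
        _, pb, _ = step_probabilities(unit.polymerases[0], unit, None, p)
        assert pb == 0.0

    def test_structure_signal_biases_forward(self):
        p = SimParams()
        unit = unit_with(p, [3500])
        fold = np.zeros(p.gene_length)
        fold[3500 - 12:3500] = 1.0   # folded RNA just behind the enzyme
        pf1, pb1, _ = step_probabilities(unit.polymerases[0], unit, None, p)
        pf2, pb2, _ = step_probabilities(unit.polymerases[0], unit, fold, p)
        assert pf2 - pb2 > pf1 - pb1


class TestAdvanceUnit:
    def test_forced_initiation(self, scripted_rng):
        p = SimParams()
        unit = UnitState(p)
        advance_unit(unit, None, p, scripted_rng([0.0, 0.9, 0.9]))
        assert unit.counters.initiations == 1
        assert [pol.position for pol in unit.polymerases] == [1]

    def test_promoter_occupied_blocks_initiation(self, scripted_rng):
        p = SimParams()
        unit = unit_with(p, [10])   # within the footprint
        advance_unit(unit, None, p,
                     scripted_rng([0.0, 0.9, 0.9, 0.9, 0.9]))
        assert unit.counters.initiations == 0

    def test_forced_completion(self, scripted_rng):
        p = SimParams()
        unit = unit_with(p, [p.gene_length - 1])
        advance_unit(unit, None, p,
                     scripted_rng([0.99, 0.0, 0.5, 0.5, 0.5]))
        assert unit.counters.productive == 1
        assert unit.polymerases == []

    def test_forced_premature_termination(self, scripted_rng):
        p = SimParams(p_pt=0.1, pt_distance=2000, initiation_prob=0.0)
        unit = unit_with(p, [500])
        advance_unit(unit, None, p,
                     scripted_rng([0.99, 0.99, 0.5, 0.0, 0.5]))
        assert unit.counters.non_productive == 1
        assert unit.polymerases == []

    def test_no_termination_beyond_pt_distance(self, scripted_rng):
        p = SimParams(p_pt=0.1, pt_distance=2000, initiation_prob=0.0)
        unit = unit_with(p, [2500])
        advance_unit(unit, None, p,
                     scripted_rng([0.99, 0.99, 0.5, 0.0, 0.5]))
        assert unit.counters.non_productive == 0
        assert len(unit.polymerases) == 1

    def test_velocity_calibration_single_polymerase(self):
        # neutral template, no collisions, no termination: empirical mean
        # velocity within 5% of v_bar over >= 1e4 steps
        p = SimParams(initiation_prob=1.0, initiation_interval=1e6)
        unit = UnitState(p)
        rng = np.random.default_rng(42)
        n_steps = 20_000
        for _ in range(n_steps):
            advance_unit(unit, None, p, rng)
        assert len(unit.polymerases) == 1
        v = (unit.polymerases[0].position - 1) / (n_steps * p.dt)
        assert v == pytest.approx(p.v_bar, rel=0.05)

    def test_steric_invariant_held_under_traffic(self):
        # dense initiation; the unit state validates gaps every step
        p = SimParams(gene_length=400, pt_distance=400, ler_length=100,
                      initiation_interval=0.4)
        unit = UnitState(p)
        rng = np.random.default_rng(7)
        for _ in range(4000):
            advance_unit(unit, None, p, rng)
            unit.check()
        assert unit.counters.initiations > 2


class TestSimulateUnit:
    def test_conservation_exact(self):
        o = simulate_unit(SimParams(sim_time=120.0, p_pt=0.3), seed=5)
        assert o.counters.initiations == (o.counters.productive
                                          + o.counters.non_productive
                                          + o.engaged_final)

    def test_occupancy_accounts_for_all_residence_time(self):
        # a single polymerase engaged for the whole run accrues exactly
        # sim_time of residence
        p = SimParams(sim_time=60.0, initiation_prob=1.0,
                      initiation_interval=1e6)
        o = simulate_unit(p, seed=5)
        assert o.engaged_final == 1
        assert o.raw_occupancy.sum() == pytest.approx(60.0, abs=2 * p.dt)
        assert (o.raw_occupancy >= 0).all()

    def test_seed_determinism(self):
        p = SimParams(sim_time=80.0, p_pt=0.2)
        a = simulate_unit(p, seed=11)
        b = simulate_unit(p, seed=11)
        assert a.counters == b.counters
        assert np.array_equal(a.raw_occupancy, b.raw_occupancy)
        assert a.mean_pol_count == b.mean_pol_count

    def test_different_seeds_differ(self):
        p = SimParams(sim_time=80.0)
        a = simulate_unit(p, seed=1)
        b = simulate_unit(p, seed=2)
        assert not np.array_equal(a.raw_occupancy, b.raw_occupancy)

    def test_no_pt_gives_processivity_one(self):
        o = simulate_unit(SimParams(sim_time=300.0, p_pt=0.0), seed=3)
        assert o.processivity == 1.0

    def test_normalized_profile_sums_to_one(self):
        o = simulate_unit(SimParams(sim_time=120.0), seed=3)
        assert o.occupancy_profile.sum() == pytest.approx(1.0)

    def test_productive_output_non_increasing_in_p_pt(self):
        means = []
        for ppt in [0.0, 0.5, 1.0]:
            prod = [simulate_unit(
                SimParams(sim_time=240.0, p_pt=ppt, pt_distance=7000),
                seed=50 + s).counters.productive for s in range(8)]
            means.append(np.mean(prod))
        assert means[0] > means[1] > means[2]


class TestProcessivity:
    @pytest.mark.parametrize("prod, nonprod, expected", [
        (90, 10, 0.9), (7, 0, 1.0), (0, 5, 0.0)])
    def test_formula(self, prod, nonprod, expected):
        c = SimCounters(productive=prod, non_productive=nonprod)
        assert processivity(c) == pytest.approx(expected)

    def test_undefined_raises(self):
        with pytest.raises(ValueError):
            processivity(SimCounters())


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        dict(p_pt=1.5), dict(initiation_prob=-0.1), dict(dt=0.0),
        dict(pt_distance=8000), dict(footprint=7000)])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimParams(**kw)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            SimParams.from_dict({"gene_legnth": 7000})
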