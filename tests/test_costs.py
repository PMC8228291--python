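"""Cost engine: printed figures, brute-force oracle, structural properties."""

import numpy as np
import pytest

import tierdx
from tierdx.cohort import CohortValidationError
from tierdx.costs import round_eur


def brute_force_cost(levels, pathway):
    """Independent per-patient loop over tiers: tests, cost, diagnoses."""
    tests = [0] * pathway.n_tiers
    cost = 0.0
    diagnosed = 0
    for lv in levels:
        for t, tier in enumerate(pathway.tiers, start=1):
            tests[t - 1] += 1
            cost += tier.unit_cost
            if lv in pathway.cumulative_detects(t):
                diagnosed += 1
                break
    return tuple(tests), cost, diagnosed


def random_pathway(rng, max_level):
    """Random pathway: shuffled levels partitioned into disjoint tiers."""
    levels = list(rng.permutation(np.arange(1, max_level + 1)))
    n_tiers = int(rng.integers(1, max_level + 1))
    cuts = sorted(rng.choice(np.arange(1, max_level), size=n_tiers - 1, replace=False)) if n_tiers > 1 else []
    pieces = np.split(np.array(levels), cuts)
    tiers = tuple(
        tierdx.TierDefinition(
            label=f"t{i}",
            unit_cost=float(rng.uniform(0, 5000)),
            detects=frozenset(int(x) for x in piece),
        )
        for i, piece in enumerate(pieces)
        if piece.size
    )
    return tierdx.PathwayModel(name="random", tiers=tiers)


class TestStandardPathways:
    def test_structure(self, pathways):
        assert pathways.exome_first.n_tiers == 1
        assert pathways.exome_first.detects_all == {1, 2, 3}
        assert pathways.reference.cumulative_detects(2) == {1, 2}
        assert 3 not in pathways.reference.detects_all
        assert pathways.panels_then_exome.detects_all == {1, 2, 3}

    def test_zero_unit_cost_keeps_diagnoses(self, cohort):
        free = tierdx.standard_pathways(unit_cost=0.0)
        res = tierdx.apply_pathway(cohort, free.panels_then_exome)
        assert res.total_cost == 0.0
        assert res.n_diagnosed == 27
        assert res.cost_per_diagnosis == 0.0

    def test_overlapping_detection_sets_rejected(self):
        t1 = tierdx.TierDefinition("a", 1.0, frozenset({1}))
        t2 = tierdx.TierDefinition("b", 1.0, frozenset({1, 2}))
        with pytest.raises(CohortValidationError, match="disjoint"):
            tierdx.PathwayModel("bad", (t1, t2))


class TestApplyPathwayReferenceCohort:
    def test_two_step_panels(self, cohort, pathways):
        res = tierdx.apply_pathway(cohort, pathways.reference)
        assert res.tests_per_tier == (72, 51)
        assert round_eur(res.total_cost) == 254_947.02
        assert res.n_diagnosed == 25
        assert round_eur(res.cost_per_diagnosis) == 10_197.88

    def test_panels_then_exome(self, cohort, pathways):
        res = tierdx.apply_pathway(cohort, pathways.panels_then_exome)
        assert res.tests_per_tier == (72, 51, 47)
        assert round_eur(res.total_cost) == 352_365.80
        assert res.n_diagnosed == 27
        assert round_eur(res.cost_per_diagnosis) == 13_050.59

    def test_exome_first(self, cohort, pathways):
        res = tierdx.apply_pathway(cohort, pathways.exome_first)
        assert res.tests_per_tier == (72,)
        assert round_eur(res.total_cost) == 149_237.28
        assert res.n_diagnosed == 27
        assert round_eur(res.cost_per_diagnosis, 3) == 5_527.307

    def test_tests_per_tier_non_increasing_and_start_at_n(self, cohort, pathways):
        for p in pathways:
            res = tierdx.apply_pathway(cohort, p)
            assert res.tests_per_tier[0] == cohort.n
            assert all(
                a >= b for a, b in zip(res.tests_per_tier, res.tests_per_tier[1:])
            )


class TestIncremental:
    def test_panels_then_exome_icer(self, cohort, pathways):
        ref = tierdx.apply_pathway(cohort, pathways.reference)
        inc = tierdx.incremental(
            tierdx.apply_pathway(cohort, pathways.panels_then_exome), ref
        )
        assert round_eur(inc.delta_cost) == 97_418.78
        assert inc.delta_diagnoses == 2
        assert round_eur(inc.icer) == 48_709.39
        assert not inc.dominant

    def test_exome_first_dominates(self, cohort, pathways):
        ref = tierdx.apply_pathway(cohort, pathways.reference)
        inc = tierdx.incremental(tierdx.apply_pathway(cohort, pathways.exome_first), ref)
        assert round_eur(inc.delta_cost) == -105_709.74
        assert inc.delta_diagnoses == 2
        assert inc.dominant
        assert inc.icer is None

    def test_self_comparison_is_null(self, cohort, pathways):
        res = tierdx.apply_pathway(cohort, pathways.reference)
        inc = tierdx.incremental(res, res)
        assert (inc.delta_cost, inc.delta_diagnoses) == (0.0, 0)
        assert inc.icer is None
        assert not inc.dominant

    def test_mismatched_cohort_sizes_rejected(self, cohort, pathways):
        small = tierdx.Cohort(list(cohort.records[:10]))
        with pytest.raises(CohortValidationError, match="sizes"):
            tierdx.incremental(
                tierdx.apply_pathway(small, pathways.exome_first),
                tierdx.apply_pathway(cohort, pathways.reference),
            )


class TestCostProperties:
    def test_agrees_with_brute_force_on_random_cohorts(self, rng):
        for _ in range(100):
            max_level = int(rng.integers(1, 5))
            n = int(rng.integers(1, 60))
            levels = rng.integers(0, max_level + 1, size=n)
            pathway = random_pathway(rng, max_level)
            res = tierdx.apply_pathway(levels, pathway)
            tests, cost, diagnosed = brute_force_cost(levels, pathway)
            assert res.tests_per_tier == tests
            assert res.total_cost == pytest.approx(cost, rel=1e-12)
            assert res.n_diagnosed == diagnosed

    def test_conservation_of_patients(self, rng, pathways):
        for _ in range(20):
            levels = rng.integers(0, 4, size=int(rng.integers(1, 80)))
            for p in pathways:
                res = tierdx.apply_pathway(levels, p)
                expected = int(np.isin(levels, list(p.detects_all)).sum())
                assert res.n_diagnosed == expected

    def test_exome_first_total_cost_is_n_times_unit_cost(self, rng, pathways):
        levels = rng.integers(0, 4, size=55)
        res = tierdx.apply_pathway(levels, pathways.exome_first)
        assert res.total_cost == pytest.approx(55 * tierdx.UNIT_COST_EUR)

    def test_adding_a_tier_never_decreases_cost_or_diagnoses(self, cohort, pathways):
        base = tierdx.apply_pathway(cohort, pathways.reference)
        extended = tierdx.apply_pathway(cohort, pathways.panels_then_exome)
        assert extended.total_cost >= base.total_cost
        assert extended.n_diagnosed >= base.n_diagnosed

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_scale_equivariance_of_money_quantities(self, cohort, scale):
        base = tierdx.standard_pathways(unit_cost=tierdx.UNIT_COST_EUR)
        scaled = tierdx.standard_pathways(unit_cost=tierdx.UNIT_COST_EUR * scale)
        for pb, ps in zip(base, scaled):
            rb = tierdx.apply_pathway(cohort, pb)
            rs = tierdx.apply_pathway(cohort, ps)
            assert rs.total_cost == pytest.approx(rb.total_cost * scale)
            assert rs.cost_per_diagnosis == pytest.approx(rb.cost_per_diagnosis * scale)
        ib = tierdx.incremental(
            tierdx.apply_pathway(cohort, base.panels_then_exome),
            tierdx.apply_pathway(cohort, base.reference),
        )
        isc = tierdx.incremental(
            tierdx.apply_pathway(cohort, scaled.panels_then_exome),
            tierdx.apply_pathway(cohort, scaled.reference),
        )
        assert isc.delta_cost == pytest.approx(ib.delta_cost * scale)
        assert isc.icer == pytest.approx(ib.icer * scale)

    def test_zero_diagnoses_marks_cost_per_diagnosis_undefined(self, pathways):
        res = tierdx.apply_pathway(np.zeros(8, dtype=int), pathways.exome_first)
        assert res.n_diagnosed == 0
        assert res.cost_per_diagnosis is None
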