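"""Age grouping, count-matched subsampling, and trend regression checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xoinfer.age import (
    AgeGroupAssignment,
    age_trend_pipeline,
    assign_age_groups,
    fit_age_trend,
    stratified_subsample,
)
from xoinfer.core import EstimateRecord, HSParameters, IntervalData
from xoinfer.simulate import simulate_crossover_positions


class TestGrouping:
    def test_eight_even_groups_with_distinct_ages(self):
        ages = {f"m{i}": 20.0 + i * 0.25 for i in range(800)}
        groups = assign_age_groups(ages, k=8)
        assert [len(g.member_ids) for g in groups] == [100] * 8
        assert groups[0].age_high <= groups[1].age_low

    def test_single_group_is_whole_input(self):
        ages = {f"m{i}": float(i) for i in range(10)}
        groups = assign_age_groups(ages, k=1)
        assert len(groups) == 1 and len(groups[0].member_ids) == 10

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            assign_age_groups({"a": 1.0, "b": 1.0, "c": 2.0}, k=3)

    def test_assignment_deterministic(self):
        ages = {f"m{i}": float(i % 13) for i in range(200)}
        a = assign_age_groups(ages, k=4)
        b = assign_age_groups(ages, k=4)
        assert [g.member_ids for g in a] == [g.member_ids for g in b]

    @given(
        ages=st.lists(
            st.floats(min_value=20.0, max_value=140.0, allow_nan=False),
            min_size=24,
            max_size=80,
        ),
        k=st.integers(2, 6),
    )
    @settings(max_examples=40, deadline=None)
    def test_groups_partition_input_even_with_ties(self, ages, k):
        named = {f"m{i}": round(a, 0) for i, a in enumerate(ages)}  # force ties
        if k > len(set(named.values())):
            return
        groups = assign_age_groups(named, k=k)
        seen = [m for g in groups for m in g.member_ids]
        assert sorted(seen) == sorted(named)  # nothing dropped or duplicated


class TestSubsampling:
    def _two_groups(self):
        ids_a = [f"a{i}" for i in range(15)]
        ids_b = [f"b{i}" for i in range(16)]
        counts = {}
        for i, m in enumerate(ids_a):
            counts[m] = 0 if i < 10 else 1  # {0: 10, 1: 5}
        for i, m in enumerate(ids_b):
            counts[m] = 0 if i < 7 else 1  # {0: 7, 1: 9}
        groups = [
            AgeGroupAssignment(1, 20.0, 34.0, ids_a),
            AgeGroupAssignment(2, 100.0, 115.0, ids_b),
        ]
        return groups, counts

    def test_min_tally_sets_subset_size(self):
        groups, counts = self._two_groups()
        draws = stratified_subsample(groups, counts, repeats=3, seed=1)
        for draw in draws:
            for members in draw.values():
                assert len(members) == 12  # n(0)=7 + n(1)=5
                tally = {x: 0 for x in (0, 1)}
                for m in members:
                    tally[counts[m]] += 1
                assert tally == {0: 7, 1: 5}

    def test_tallies_identical_across_groups_all_repeats(self):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(400)]
        ages = {m: float(rng.integers(20, 120)) for m in ids}
        counts = {m: int(rng.poisson(1.0)) for m in ids}
        groups = assign_age_groups(ages, k=4)
        draws = stratified_subsample(groups, counts, repeats=10, seed=2)
        for draw in draws:
            tallies = []
            for members in draw.values():
                t = {}
                for m in members:
                    t[counts[m]] = t.get(counts[m], 0) + 1
                tallies.append(t)
            assert all(t == tallies[0] for t in tallies)

    def test_without_replacement_within_repeat(self):
        groups, counts = self._two_groups()
        for draw in stratified_subsample(groups, counts, repeats=5, seed=3):
            for members in draw.values():
                assert len(members) == len(set(members))

    def test_identical_groups_return_full_groups(self):
        ids_a = [f"a{i}" for i in range(6)]
        ids_b = [f"b{i}" for i in range(6)]
        counts = {m: 1 for m in ids_a + ids_b}
        ages = {m: 20.0 + i for i, m in enumerate(ids_a)}
        ages.update({m: 100.0 + i for i, m in enumerate(ids_b)})
        groups = assign_age_groups(ages, k=2)
        draws = stratified_subsample(groups, counts, repeats=1, seed=0)
        assert sorted(draws[0][1]) == ids_a

    def test_single_group_rejected(self):
        groups = assign_age_groups({"a": 1.0, "b": 2.0}, k=1)
        with pytest.raises(ValueError):
            stratified_subsample(groups, {"a": 1, "b": 1})


class TestTrend:
    def _record(self, nu, p, se=0.1):
        return EstimateRecord("group", nu, p, se, se / 50, -1.0, 100)

    def test_constant_estimates_zero_slope(self):
        ests = [(30.0 + 10 * i, self._record(8.0, 0.07)) for i in range(5)]
        out = fit_age_trend(ests)
        tr = out["trend"].set_index("parameter")
        assert tr.loc["escape", "slope"] == 0.0
        assert tr.loc["escape", "r_squared"] == 0.0

    def test_declining_escape_detected(self):
        rng = np.random.default_rng(6)
        ests = [
            (40.0 + 8 * i, self._record(8.0, 0.09 - 0.005 * i + rng.normal(0, 1e-4)))
            for i in range(8)
        ]
        tr = fit_age_trend(ests)["trend"].set_index("parameter")
        assert tr.loc["escape", "slope"] < 0
        assert tr.loc["escape", "p_value"] < 0.05

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            fit_age_trend([(30.0, self._record(8, 0.05))] * 2)

    def test_confidence_intervals_from_se(self):
        out = fit_age_trend([(30.0 + i, self._record(8.0, 0.07, se=0.2)) for i in range(3)])
        g = out["groups"]
        interf = g[g["parameter"] == "interference"].iloc[0]
        assert interf["ci_high"] - interf["ci_low"] == pytest.approx(2 * 1.96 * 0.2)


def test_pipeline_recovers_declining_escape():
    """End-to-end: simulated p declining with age over 4 groups on one
    chromosome; the matched-subsampling pipeline finds a negative slope."""
    rng = np.random.default_rng(77)
    intervals = {}
    ages = {}
    mid = 0
    for g in range(4):
        age = 36.0 + 18.0 * g
        params = HSParameters(10.0, 0.10 - 0.02 * g)
        _, pos, _ = simulate_crossover_positions(params, 1.0, 2000, rng)
        for x in pos:
            intervals[f"m{mid}"] = IntervalData(tuple(x), 1.0)
            ages[f"m{mid}"] = age + float(rng.uniform(-6, 6))
            mid += 1
    out = age_trend_pipeline(intervals, ages, k=4, repeats=3, seed=1)
    tr = out["trend"].set_index("parameter")
    assert tr.loc["escape", "slope"] < 0
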