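"""Catchments, busyness, deployment simulation, scenario comparison."""



import numpy as np
import pandas as pd
import pytest

from emsloc.errors import ParameterError
from emsloc.evaluate import (assign_catchments, busyness_index,
                             calibrate_busy_prob, compare_scenarios,
                             simulate_response, summarize)
from emsloc.network import distance_to_time
from emsloc.optimize import LocationSet, brute_force_optimum, fitness

from conftest import random_instance


class TestCatchments:
    def test_single_site_takes_every_area(self, small_od):
        cat = assign_catchments(LocationSet.from_sites([0]), small_od,
                                np.ones(len(small_od)))
        assert len(cat) == 1
        assert sorted(cat[0].area_ids) == sorted(small_od.index)

    def test_hand_assignment(self, toy_od):
        od, w = toy_od
        cat = assign_catchments(LocationSet.from_sites([1, 2]), od, w)
        by_site = {c.site_id: c for c in cat}
        assert by_site[1].area_ids == ["A"]  # 1000 < 4000
        assert by_site[2].area_ids == ["B"]  # 2000 < 5000

    @pytest.mark.parametrize("seed", range(10))
    def test_person_distance_sums_to_fitness_exactly(self, seed, small_od,
                                                     small_city):
        w = small_city.areas.table["observed_cases"]
        rng = np.random.default_rng(seed)
        sites = rng.choice(small_od.columns, size=rng.integers(1, 6),
                           replace=False)
        s = LocationSet.from_sites(sites)
        cat = assign_catchments(s, small_od, w)
        total = float(np.sum([c.person_distance for c in cat]))
        assert total == fitness(s, small_od, w)  # bit-exact decomposition
        assert sum(len(c.area_ids) for c in cat) == len(small_od)

    def test_busyness_is_linear_in_weights(self, small_od, small_city):
        w = small_city.areas.table["observed_cases"]
        s = LocationSet.from_sites([0, 3, 5])
        b1 = busyness_index(assign_catchments(s, small_od, w))
        b2 = busyness_index(assign_catchments(s, small_od, 2 * w))
        assert np.allclose(b2["person_distance"], 2 * b1["person_distance"])
        assert np.allclose(b2["case_count"], 2 * b1["case_count"])

    def test_empty_catchment_has_zero_index(self, toy_od):
        od, _ = toy_od
        cat = assign_catchments(LocationSet.from_sites([1, 2]), od, [5, 0])
        by_site = {c.site_id: c for c in cat}
        assert by_site[2].person_distance == 0.0


class TestSimulateResponse:
    def test_no_busyness_means_all_rank_one(self, small_od, small_city):
        w = small_city.areas.table["observed_cases"]
        s = LocationSet.from_sites([0, 2, 4])
        rec = simulate_response(w, s, small_od, busy_prob=0.0, seed=1)
        assert (rec["responding_rank"] == 1).all()
        assert summarize(rec)["pct_rank1"] == 100.0
        # mean time equals the case-weighted nearest distance / speed
        dmin = small_od[[0, 2, 4]].min(axis=1)
        want = float((w * distance_to_time(dmin, 30.0)).sum() / w.sum())
        assert summarize(rec)["mean_response_time_s"] == pytest.approx(want)

    def test_single_unit_always_responds(self, small_od, small_city):
        w = small_city.areas.table["observed_cases"]
        rec = simulate_response(w, LocationSet.from_sites([3]), small_od,
                                busy_prob=0.5, seed=2)
        assert (rec["responding_rank"] == 1).all()

    def test_rank1_share_matches_busy_probability(self, small_od,
                                                  small_city):
        # with many units the nearest responds iff it is free:
        # P(rank 1) = 1 - busy_prob, the calibration identity
        busy = calibrate_busy_prob(0.678)
        assert busy == pytest.approx(0.322)
        cases = pd.DataFrame({"area_id": np.resize(small_od.index.to_numpy(),
                                                   10_000)})
        s = LocationSet.from_sites(small_od.columns)
        rec = simulate_response(cases, s, small_od, busy_prob=busy, seed=3)
        share = summarize(rec)["pct_rank1"] / 100
        assert share == pytest.approx(0.678, abs=0.015)

    def test_duplicate_slots_occupy_consecutive_ranks(self, small_od,
                                                      small_city):
        w = small_city.areas.table["observed_cases"]
        s = LocationSet(((0, 0), (0, 1), (5, 0)))
        rec = simulate_response(w, s, small_od, busy_prob=0.9, seed=4)
        # ranks 1 and 2 are the same site at the same distance
        r12 = rec[rec["responding_rank"] <= 2]
        near = small_od[[0, 5]].min(axis=1)
        for row in r12.itertuples():
            assert row.response_distance_m == pytest.approx(
                small_od.loc[row.area_id, row.site_id])

    def test_rank_histogram_conserves_cases(self, small_od, small_city):
        w = small_city.areas.table["observed_cases"]
        s = LocationSet.from_sites([0, 1, 2, 3])
        rec = simulate_response(w, s, small_od, busy_prob=0.4, seed=5)
        summ = summarize(rec)
        assert sum(summ["rank_histogram"].values()) == summ["n_cases"]
        assert summ["n_cases"] == int(w.sum())


class TestSummarize:
    def test_two_case_mean(self):
        rec = pd.DataFrame({
            "responding_rank": [1, 1],
            "response_distance_m": [500.0, 1000.0],
            "response_time_s": [60.0, 120.0],
        })
        assert summarize(rec)["mean_response_time_s"] == 90.0

    def test_empty_records_rejected(self):
        with pytest.raises(ParameterError):
            summarize(pd.DataFrame(columns=["responding_rank",
                                            "response_time_s",
                                            "response_distance_m"]))


class TestCompareScenarios:
    def test_identical_scenarios_have_zero_deltas(self, small_od,
                                                  small_city):
        w = small_city.areas.table["observed_cases"]
        s = LocationSet.from_sites([1, 4, 6])
        rep = compare_scenarios(s, s, w, small_od, w, busy_prob=0.3, seed=6)
        assert rep["delta"]["mean_response_time_s"] == 0.0
        assert rep["delta"]["pct_rank1"] == 0.0
        assert rep["delta"]["fitness_person_m"] == 0.0

    def test_exact_optimum_never_worse_on_nearest_distance(self):
        od, w = random_instance(9, n_areas=40, n_sites=8)
        best, _ = brute_force_optimum(od, w, 3)
        rng = np.random.default_rng(9)
        cur = LocationSet.from_sites(rng.choice(od.columns, 3,
                                                replace=False))
        rep = compare_scenarios(cur, best, w, od, w, busy_prob=0.0, seed=9)
        assert rep["delta"]["fitness_person_m"] <= 0.0
        assert rep["delta"]["mean_nearest_time_s"] <= 1e-9

    def test_report_reproduces_bit_exactly(self, small_od, small_city):
        w = small_city.areas.table["observed_cases"]
        a = LocationSet.from_sites([0, 2])
        b = LocationSet.from_sites([1, 3])
        r1 = compare_scenarios(a, b, w, small_od, w, busy_prob=0.322, seed=8)
        r2 = compare_scenarios(a, b, w, small_od, w, busy_prob=0.322, seed=8)
        assert r1 == r2
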