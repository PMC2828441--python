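"""Synthetic-city generator: structure, conservation and determinism."""

import numpy as np
import pandas as pd
import pytest

from emsloc import synthetic as sc
from emsloc.errors import CalibrationError, ParameterError, StateError
from emsloc.network import count_points_in_polygons
from emsloc.regression import niigata_demand_model


def _bfs_component(graph, start):
    """Flood-fill connectivity oracle, independent of networkx algorithms."""
    seen, frontier = {start}, [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.adj[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


class TestRoadGraph:
    def test_unperturbed_unit_grid(self):
        g = sc.generate_road_graph(2, 2, 1000, 0, 0, seed=1)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 4
        assert all(d["length_m"] == 1000 for _, _, d in g.edges(data=True))

    def test_grid_edge_count(self):
        g = sc.generate_road_graph(5, 5, 500, 0, 0, seed=1)
        assert g.number_of_nodes() == 25
        assert g.number_of_edges() == 5 * 4 + 5 * 4  # r(c-1) + c(r-1)

    def test_removal_keeps_connectivity(self):
        g = sc.generate_road_graph(10, 10, 500, 0.2, 0.1, seed=7)
        assert len(_bfs_component(g, 0)) == 100
        # 180 base edges, 10% targeted for removal, re-insertions possible
        assert 162 <= g.number_of_edges() <= 180
        assert all(d["length_m"] > 0 for _, _, d in g.edges(data=True))

    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=1, n_cols=5), dict(edge_removal_frac=0.4),
        dict(jitter_frac=0.6), dict(spacing_m=-5),
    ])
    def test_invalid_parameters(self, kwargs):
        base = dict(n_rows=4, n_cols=4, spacing_m=100.0)
        with pytest.raises(ParameterError):
            sc.generate_road_graph(**{**base, **kwargs}, seed=0)


class TestCensusAreas:
    def test_single_area_is_bounding_box(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=2)
        areas = sc.generate_census_areas(g, 1, seed=3)
        assert len(areas) == 1
        assert areas.polygons[0].bounds == (0, 0, 200, 200)
        assert tuple(areas.table.loc[0, ["centroid_x", "centroid_y"]]) \
            == (100, 100)

    def test_partition_conserves_box_area(self):
        g = sc.generate_road_graph(5, 5, 400, 0.1, 0, seed=2)
        areas = sc.generate_census_areas(g, 4, seed=3)
        xmin, ymin, xmax, ymax = g.graph["bbox"]
        box_area = (xmax - xmin) * (ymax - ymin)
        total = sum(p.area for p in areas.polygons.values())
        assert total == pytest.approx(box_area, rel=1e-6)

    def test_centroids_are_envelope_centres(self):
        g = sc.generate_road_graph(6, 6, 300, 0, 0, seed=5)
        areas = sc.generate_census_areas(g, 20, seed=5)
        for aid, poly in areas.polygons.items():
            xmin, ymin, xmax, ymax = poly.bounds
            assert areas.table.loc[aid, "centroid_x"] == (xmin + xmax) / 2
            assert areas.table.loc[aid, "centroid_y"] == (ymin + ymax) / 2


class TestDemographics:
    def test_population_conserved_and_nested(self, small_city):
        tab = small_city.areas.table
        assert tab["pop_total"].sum() == 25_000
        assert (tab["pop_80_over"] <= tab["pop_65_over"]).all()
        assert (tab[["pop_0_4", "pop_15_64", "pop_65_over",
                     "companies_5plus"]] >= 0).all().all()

    def test_single_area_holds_everyone(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=1)
        areas = sc.generate_census_areas(g, 1, seed=1)
        areas = sc.populate_demographics(areas, 1000, seed=4)
        assert areas.table["pop_total"].iloc[0] == 1000

    def test_age_sex_table_matches_aggregates(self, small_city):
        agg = small_city.areas.age_sex.groupby("area_id")["count"].sum()
        assert (agg.sort_index()
                == small_city.areas.table["pop_total"].sort_index()).all()

    def test_profile_must_sum_to_one(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=1)
        areas = sc.generate_census_areas(g, 2, seed=1)
        bad = sc.japan_age_profile() * 2
        with pytest.raises(ParameterError):
            sc.populate_demographics(areas, 100, age_profile=bad, seed=0)


class TestCaseCounts:
    def test_printed_model_mean_rounds_to_count(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=1)
        areas = sc.generate_census_areas(g, 2, seed=1)
        areas.table["pop_0_4"] = [0, 100]
        areas.table["pop_15_64"] = [0, 1000]
        areas.table["pop_80_over"] = [0, 50]
        areas.table["companies_5plus"] = [0, 10]
        model = niigata_demand_model()
        areas = sc.simulate_case_counts(areas, model, noise_sd=0.0, seed=0)
        # all-zero predictors: mean -0.268, floored to 0; printed formula
        # at (100, 1000, 50, 10) gives 30.762 -> 31
        assert list(areas.table["observed_cases"]) == [0, 31]

    def test_same_seed_same_counts(self, small_city):
        again = sc.generate_city(
            seed=11, n_rows=10, n_cols=10, spacing_m=500.0,
            n_areas=60, total_pop=25_000, n_sites=8, slots_per_site=2,
            n_admin=4, scatter_points=True)
        pd.testing.assert_series_equal(
            again.areas.table["observed_cases"],
            small_city.areas.table["observed_cases"])
        pd.testing.assert_frame_equal(again.case_points,
                                      small_city.case_points)

    def test_poisson_family_counts_nonnegative(self):
        city = sc.generate_city(seed=21, n_rows=6, n_cols=6, n_areas=30,
                                total_pop=12_000, n_sites=4,
                                slots_per_site=1, n_admin=2,
                                noise_family="poisson")
        assert (city.areas.table["observed_cases"] >= 0).all()
        assert city.areas.table["observed_cases"].sum() > 0


class TestNoiseCalibration:
    def test_closed_form_at_half(self, small_city):
        model = small_city.model
        sd = sc.calibrate_noise_to_r2(small_city.areas, model, 0.5)
        mu = model.predict(small_city.areas.table, clip_negative=False)
        assert sd == pytest.approx(np.std(mu), rel=1e-12)

    def test_vanishes_as_r2_approaches_one(self, small_city):
        sd = sc.calibrate_noise_to_r2(small_city.areas, small_city.model,
                                      0.9999)
        assert sd < 0.02 * sc.calibrate_noise_to_r2(
            small_city.areas, small_city.model, 0.5)

    def test_constant_mean_is_degenerate(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=1)
        areas = sc.generate_census_areas(g, 3, seed=1)
        for col in ["pop_0_4", "pop_15_64", "pop_80_over",
                    "companies_5plus"]:
            areas.table[col] = 5
        with pytest.raises(CalibrationError):
            sc.calibrate_noise_to_r2(areas, niigata_demand_model(), 0.7)


class TestCasePoints:
    def test_round_trip_recovers_counts(self, small_city):
        counts, unassigned = count_points_in_polygons(
            small_city.case_points, small_city.areas.polygons)
        assert unassigned == 0
        expected = small_city.areas.table["observed_cases"]
        assert (counts.sort_index() == expected.sort_index()).all()

    def test_points_lie_inside_their_polygon(self, small_city):
        pts = small_city.case_points
        some = pts.groupby("area_id").head(2)
        from shapely.geometry import Point
        for rec in some.itertuples():
            assert small_city.areas.polygons[rec.area_id].covers(
                Point(rec.x, rec.y))

    def test_requires_simulated_counts(self):
        g = sc.generate_road_graph(3, 3, 100, 0, 0, seed=1)
        areas = sc.generate_census_areas(g, 2, seed=1)
        with pytest.raises(StateError):
            sc.scatter_case_points(areas, seed=0)


class TestCandidateSites:
    def test_study_scale_slot_count(self):
        g = sc.generate_road_graph(8, 8, 500, 0, 0, seed=1)
        sites = sc.place_candidate_sites(g, 35, 5, seed=2)
        assert int(sites["max_slots"].sum()) == 175

    def test_sites_snap_to_graph_nodes(self):
        g = sc.generate_road_graph(6, 6, 500, 0.2, 0, seed=3)
        sites = sc.place_candidate_sites(g, 10, 2, seed=4)
        for rec in sites.itertuples():
            assert rec.x == g.nodes[rec.node]["x"]
            assert rec.y == g.nodes[rec.node]["y"]
        assert sites.index.is_unique

    def test_too_many_sites_rejected(self):
        g = sc.generate_road_graph(2, 2, 500, 0, 0, seed=1)
        with pytest.raises(ParameterError):
            sc.place_candidate_sites(g, 5, 1, seed=0)
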