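"""Nearest-facility assignment, bypass and distance tables, hub lines."""

import math

import numpy as np
import pandas as pd
import pytest

from geoaccess import (
    SyntheticConfig,
    ValidationError,
    assign_nearest,
    bypass_table,
    distance_summary,
    gen_enrollees,
    gen_facilities,
    hub_lines,
    summarise_bypass_counts,
    summarise_distance_rows,
    datasets,
)


def facility_frame(rows):
    return pd.DataFrame(
        [
            {
                "id": fid,
                "name": fid,
                "level": "secondary",
                "nhis_accredited": True,
                "lga": "L",
                "x": x,
                "y": y,
            }
            for fid, x, y in rows
        ]
    )


def enrollee_frame(rows):
    return pd.DataFrame(
        [{"id": eid, "x": x, "y": y, "used_facility_id": fid} for eid, x, y, fid in rows]
    )


class TestAssignNearest:
    def test_single_facility_used_is_not_bypassing(self):
        fac = facility_frame([("F1", 3.0, 4.0)])
        enr = enrollee_frame([("E1", 0.0, 0.0, "F1")])
        a = assign_nearest(enr, fac)
        row = a.iloc[0]
        assert row["nearest_facility_id"] == "F1"
        assert row["nearest_distance"] == pytest.approx(5.0)
        assert row["used_distance"] == pytest.approx(5.0)
        assert not row["bypassed"]

    def test_using_the_farther_facility_is_bypassing(self):
        fac = facility_frame([("F1", 3.0, 0.0), ("F2", 4.0, 0.0)])
        enr = enrollee_frame([("E1", 0.0, 0.0, "F2")])
        a = assign_nearest(enr, fac)
        row = a.iloc[0]
        assert row["bypassed"]
        assert row["nearest_distance"] == pytest.approx(3.0)
        assert row["used_distance"] == pytest.approx(4.0)

    def test_tie_resolves_to_smallest_id_and_is_not_bypassing(self):
        fac = facility_frame([("FB", 1.0, 0.0), ("FA", -1.0, 0.0)])
        enr = enrollee_frame([("E1", 0.0, 0.0, "FB")])
        a = assign_nearest(enr, fac)
        row = a.iloc[0]
        assert row["nearest_facility_id"] == "FA"  # lexicographic tie-break
        assert not row["bypassed"]  # used facility is co-nearest

    def test_unresolvable_used_id_names_the_enrollee(self):
        fac = facility_frame([("F1", 0.0, 0.0)])
        enr = enrollee_frame([("E9", 1.0, 1.0, "NOPE")])
        with pytest.raises(ValidationError, match="E9"):
            assign_nearest(enr, fac)

    def test_accredited_only_filters_candidates(self):
        fac = facility_frame([("F1", 1.0, 0.0), ("F2", 10.0, 0.0)])
        fac.loc[fac["id"] == "F1", "nhis_accredited"] = False
        enr = enrollee_frame([("E1", 0.0, 0.0, "F2")])
        a = assign_nearest(enr, fac, accredited_only=True)
        assert a.iloc[0]["nearest_facility_id"] == "F2"
        assert not a.iloc[0]["bypassed"]
        b = assign_nearest(enr, fac, accredited_only=False)
        assert b.iloc[0]["nearest_facility_id"] == "F1"
        assert b.iloc[0]["bypassed"]

    def test_empty_candidate_set_is_error(self):
        fac = facility_frame([("F1", 0.0, 0.0)])
        fac["nhis_accredited"] = False
        enr = enrollee_frame([("E1", 1.0, 1.0, "F1")])
        with pytest.raises(ValidationError, match="candidate"):
            assign_nearest(enr, fac)

    def test_matches_brute_force_scan(self, rng):
        m = 50
        fac = facility_frame(
            [(f"F{j:03d}", x, y) for j, (x, y) in enumerate(rng.uniform(0, 1e4, (m, 2)))]
        )
        used = rng.integers(0, m, 1000)
        enr = enrollee_frame(
            [
                (f"E{i:04d}", x, y, f"F{used[i]:03d}")
                for i, (x, y) in enumerate(rng.uniform(0, 1e4, (1000, 2)))
            ]
        )
        a = assign_nearest(enr, fac)
        fxy = fac[["x", "y"]].to_numpy()
        ids = fac["id"].to_numpy()
        for i in range(0, 1000, 37):  # spot-check a deterministic subsample
            ex, ey = enr.loc[i, "x"], enr.loc[i, "y"]
            d = [math.hypot(ex - fx, ey - fy) for fx, fy in fxy]
            jmin = int(np.argmin(d))
            assert a.loc[i, "nearest_distance"] == pytest.approx(d[jmin], rel=1e-9)
            assert a.loc[i, "nearest_facility_id"] == ids[jmin]
            assert a.loc[i, "used_distance"] == pytest.approx(
                d[int(used[i])], rel=1e-9
            )

    def test_nearest_never_farther_than_used(self, sim_pair):
        _, fac, enr = sim_pair
        a = assign_nearest(enr, fac)
        assert (a["nearest_distance"] <= a["used_distance"] + 1e-6).all()
        not_bypassed = a[~a["bypassed"]]
        assert np.allclose(
            not_bypassed["nearest_distance"], not_bypassed["used_distance"], atol=1e-6
        )


class TestHubLines:
    def test_zero_enrollees_empty_collection(self):
        fac = facility_frame([("F1", 0.0, 0.0)])
        enr = enrollee_frame([]).reindex(columns=["id", "x", "y", "used_facility_id"])
        a = pd.DataFrame(
            columns=[
                "enrollee_id",
                "nearest_facility_id",
                "nearest_distance",
                "used_facility_id",
                "used_distance",
                "bypassed",
            ]
        )
        assert hub_lines(a, enr, fac, which="used") == []

    def test_line_length_matches_stored_distance(self, sim_pair):
        _, fac, enr = sim_pair
        a = assign_nearest(enr, fac)
        for which in ("nearest", "used"):
            feats = hub_lines(a, enr, fac, which=which)
            assert len(feats) == len(enr)
            for f in feats[::17]:
                (x1, y1), (x2, y2) = f["geometry"]["coordinates"]
                assert f["properties"]["distance_m"] == pytest.approx(
                    math.hypot(x2 - x1, y2 - y1), rel=1e-6
                )

    def test_invalid_which_rejected(self, sim_pair):
        _, fac, enr = sim_pair
        a = assign_nearest(enr, fac)
        with pytest.raises(ValidationError):
            hub_lines(a, enr, fac, which="both")


class TestBypassTable:
    def test_published_counts_reproduce_printed_percentages(self):
        table = summarise_bypass_counts(datasets.bypass_counts())
        total = table[table["facility_id"] == "Total"].iloc[0]
        assert total["n_patrons"] == 431
        assert total["n_bypassed"] == 405
        assert total["pct_bypassed"] == 94.0
        assert total["pct_non_bypassed"] == 6.0
        teju = table[table["facility_id"] == "Teju"].iloc[0]
        assert teju["pct_bypassed"] == 98.3
        poly = table[table["facility_id"] == "Doctor's Polyclinic"].iloc[0]
        assert poly["pct_bypassed"] == 66.7

    def test_counts_are_conserved(self, sim_pair):
        _, fac, enr = sim_pair
        a = assign_nearest(enr, fac)
        table = bypass_table(a)
        body = table[table["facility_id"] != "Total"]
        total = table[table["facility_id"] == "Total"].iloc[0]
        assert body["n_patrons"].sum() == len(enr) == total["n_patrons"]
        assert (body["n_bypassed"] + body["n_non_bypassed"]).equals(body["n_patrons"])
        assert body["n_bypassed"].sum() == total["n_bypassed"]

    def test_everyone_using_nearest_gives_zero_percent(self):
        fac = facility_frame([("F1", 0.0, 0.0), ("F2", 100.0, 0.0)])
        enr = enrollee_frame(
            [("E1", 1.0, 0.0, "F1"), ("E2", 99.0, 0.0, "F2"), ("E3", 2.0, 1.0, "F1")]
        )
        table = bypass_table(assign_nearest(enr, fac))
        assert (table["pct_bypassed"] == 0.0).all()


class TestDistanceSummary:
    def test_published_rows_reproduce_column_means(self):
        table = summarise_distance_rows(datasets.distance_rows())
        mean_row = table.iloc[-1]
        assert mean_row["facility_id"] == "Average"
        assert mean_row["shortest_km"] == 1.096
        assert mean_row["longest_km"] == 5.914

    def test_single_patron_single_facility(self):
        fac = facility_frame([("F1", 2000.0, 0.0)])
        enr = enrollee_frame([("E1", 0.0, 0.0, "F1")])
        table = distance_summary(assign_nearest(enr, fac))
        assert list(table["shortest_km"]) == [2.000, 2.000]
        assert list(table["longest_km"]) == [2.000, 2.000]

    def test_matches_brute_force_group_scan(self, sim_pair):
        _, fac, enr = sim_pair
        a = assign_nearest(enr, fac)
        table = distance_summary(a).set_index("facility_id")
        from geoaccess import round_half_up

        for fid, grp in a.groupby("used_facility_id"):
            assert table.loc[fid, "shortest_km"] == round_half_up(
                grp["used_distance"].min() / 1000.0, 3
            )
            assert table.loc[fid, "longest_km"] == round_half_up(
                grp["used_distance"].max() / 1000.0, 3
            )
        assert (table["shortest_km"] <= table["longest_km"]).all()


class TestJitterDrivenBypass:
    def test_zero_jitter_rational_choosers_do_not_bypass(self):
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=seed, n_facilities=60, n_enrollees=60,
                decay_lambda=1.0, jitter_min=0.0, jitter_max=0.0,
            )
            fac = gen_facilities(cfg)
            enr = gen_enrollees(cfg, fac)
            a = assign_nearest(enr, fac)
            assert a["bypassed"].mean() == 0.0

    def test_landmark_jitter_creates_apparent_bypassing(self):
        rates = []
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=seed, n_facilities=60, n_enrollees=60, decay_lambda=1.0
            )
            fac = gen_facilities(cfg)
            enr = gen_enrollees(cfg, fac)
            rates.append(assign_nearest(enr, fac)["bypassed"].mean())
        assert np.mean(rates) > 0.0
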