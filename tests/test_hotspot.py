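"""Grid aggregation, the Gi* formula, BH-FDR and confidence binning."""

import math

import numpy as np
import pandas as pd
import pytest

from geoaccess import (
    StudyArea,
    ValidationError,
    aggregate_to_grid,
    assign_bins,
    bh_fdr,
    default_band,
    gi_star,
    hotspot_analysis,
)


def cells_1d(counts, spacing=1.0):
    return pd.DataFrame(
        {
            "cell_id": range(len(counts)),
            "center_x": np.arange(len(counts)) * spacing,
            "center_y": np.zeros(len(counts)),
            "count": counts,
        }
    )


def gi_star_reference(cells, band):
    """Independent direct evaluation of the Gi* formula with explicit loops."""
    x = cells["count"].to_numpy(dtype=float)
    cx = cells["center_x"].to_numpy(dtype=float)
    cy = cells["center_y"].to_numpy(dtype=float)
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)
    out = []
    for i in range(n):
        wsum = w2sum = wx = 0.0
        for j in range(n):
            d = math.hypot(cx[i] - cx[j], cy[i] - cy[j])
            if d <= band + 1e-9:
                wsum += 1.0
                w2sum += 1.0
                wx += x[j]
        den = s * math.sqrt((n * w2sum - wsum * wsum) / (n - 1))
        out.append((wx - xbar * wsum) / den if den > 0 else 0.0)
    return np.array(out)


class TestAggregateToGrid:
    def test_four_points_at_cell_centers(self):
        area = StudyArea.square(4.0)
        pts = [(0.5, 0.5), (1.5, 0.5), (0.5, 1.5), (1.5, 1.5)]
        cells = aggregate_to_grid(pts, area, cell_size=1.0)
        assert len(cells) == 4
        assert (cells["count"] == 1).all()

    def test_count_conservation(self, rng):
        area = StudyArea.square(100.0)
        pts = rng.uniform(0, 10, size=(200, 2))
        cells = aggregate_to_grid(pts, area, cell_size=2.5)
        assert cells["count"].sum() == 200

    def test_zero_count_cells_kept(self):
        area = StudyArea.square(16.0)
        cells = aggregate_to_grid([(0.5, 0.5)], area, cell_size=1.0)
        assert len(cells) == 16
        assert cells["count"].sum() == 1

    def test_shared_edge_point_goes_to_larger_index(self):
        area = StudyArea.square(4.0)
        cells = aggregate_to_grid([(1.0, 0.5)], area, cell_size=1.0)
        hit = cells[cells["count"] == 1].iloc[0]
        assert (hit["ix"], hit["iy"]) == (1, 0)

    def test_counts_match_brute_force_assignment(self, rng):
        area = StudyArea.square(10_000.0)
        pts = rng.uniform(0, 100, size=(500, 2))
        s = 7.3
        cells = aggregate_to_grid(pts, area, cell_size=s)
        x0, y0, _, _ = area.bounds
        brute = {}
        for px, py in pts:
            key = (int((px - x0) // s), int((py - y0) // s))
            brute[key] = brute.get(key, 0) + 1
        for _, c in cells.iterrows():
            assert c["count"] == brute.get((c["ix"], c["iy"]), 0)

    def test_no_cells_inside_area_is_error(self):
        ring = [(0, 0), (1, 0), (1, 1), (0, 1)]
        area = StudyArea.from_polygon(ring)
        # a huge cell centred far outside the unit square polygon
        with pytest.raises(ValidationError):
            aggregate_to_grid([(0.5, 0.5)], area, cell_size=100.0)


class TestGiStar:
    def test_constant_surface_is_error(self):
        with pytest.raises(ValidationError, match="equal"):
            gi_star(cells_1d([3, 3, 3, 3]), band=1.0)

    def test_1d_toy_matches_direct_formula(self):
        cells = cells_1d([0, 0, 10, 0, 0])
        got = gi_star(cells, band=1.0)
        ref = gi_star_reference(cells, band=1.0)
        np.testing.assert_allclose(got["gi_z"].to_numpy(), ref, rtol=1e-12)
        # the centre cell attains the maximum (tied with its neighbours,
        # whose one-cell band captures the same mass)
        assert got["gi_z"].iloc[2] == got["gi_z"].max()

    def test_random_grid_matches_direct_formula(self, rng):
        cells = pd.DataFrame(
            {
                "cell_id": range(36),
                "center_x": np.tile(np.arange(6.0), 6),
                "center_y": np.repeat(np.arange(6.0), 6),
                "count": rng.integers(0, 12, 36),
            }
        )
        got = gi_star(cells, band=1.5)
        ref = gi_star_reference(cells, band=1.5)
        np.testing.assert_allclose(got["gi_z"].to_numpy(), ref, rtol=1e-12)

    def test_global_band_is_degenerate_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            gi_star(cells_1d([1, 2, 3]), band=100.0)

    def test_centering_identity(self, rng):
        x = rng.integers(0, 10, 25).astype(float)
        assert abs((x - x.mean()).sum()) < 1e-9

    def test_permuting_cells_permutes_outputs(self, rng):
        cells = cells_1d([0, 1, 8, 2, 0, 3])
        perm = rng.permutation(len(cells))
        shuffled = cells.iloc[perm].reset_index(drop=True)
        a = gi_star(cells, band=1.0)["gi_z"].to_numpy()
        b = gi_star(shuffled, band=1.0)["gi_z"].to_numpy()
        np.testing.assert_allclose(b, a[perm], rtol=1e-12)

    def test_p_raw_is_two_sided_normal_tail(self):
        got = gi_star(cells_1d([0, 0, 10, 0, 0]), band=1.0)
        from scipy.stats import norm

        z = got["gi_z"].to_numpy()
        np.testing.assert_allclose(
            got["p_raw"].to_numpy(), 2 * norm.sf(np.abs(z)), rtol=1e-9
        )


class TestBHFDR:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # each p_(i)·n/i = 0.04; the running minimum caps them all at 0.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_step_up_against_manual_formula(self, rng):
        p = rng.uniform(0, 1, 50)
        order = np.argsort(p)
        n = len(p)
        adj_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        manual = np.empty(n)
        manual[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), manual, rtol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestAssignBins:
    @pytest.mark.parametrize(
        "z,p,expected",
        [(4.0, 0.001, 3), (-2.0, 0.2, 0), (-3.1, 0.004, -3), (1.7, 0.07, 1), (2.1, 0.03, 2)],
    )
    def test_bin_rule(self, z, p, expected):
        cells = pd.DataFrame({"gi_z": [z], "p_adj": [p]})
        assert assign_bins(cells)["bin"].iloc[0] == expected

    def test_sign_follows_z(self):
        cells = pd.DataFrame({"gi_z": [-4.0, 4.0], "p_adj": [0.001, 0.001]})
        assert list(assign_bins(cells)["bin"]) == [-3, 3]


class TestDefaultBand:
    def test_2x2_unit_grid(self):
        cells = pd.DataFrame(
            {"center_x": [0.0, 1.0, 0.0, 1.0], "center_y": [0.0, 0.0, 1.0, 1.0]}
        )
        assert default_band(cells) == pytest.approx(1.0)

    def test_collinear_hand_case(self):
        cells = pd.DataFrame({"center_x": [0.0, 1.0, 5.0], "center_y": [0.0, 0.0, 0.0]})
        assert default_band(cells) == pytest.approx(4.0)

    def test_matches_brute_force_max_nn(self, rng):
        centers = rng.uniform(0, 100, size=(40, 2))
        cells = pd.DataFrame({"center_x": centers[:, 0], "center_y": centers[:, 1]})
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert default_band(cells) == pytest.approx(d.min(axis=1).max(), rel=1e-12)


class TestHotspotPipeline:
    def test_adjusted_p_and_bins_present_and_consistent(self, sim_pair):
        cfg, fac, _ = sim_pair
        cells, params = hotspot_analysis(fac, cfg.area)
        assert (cells["p_adj"] >= cells["p_raw"] - 1e-15).all()
        nonzero = cells[cells["bin"] != 0]
        assert (nonzero["p_adj"] < 0.10).all()
        assert (np.sign(nonzero["gi_z"]) == np.sign(nonzero["bin"])).all()
        assert params.band >= params.cell_size
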