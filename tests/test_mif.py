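"""Phenotype calling, region partition, densities, Dunn's test, proximity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathomics import mif


def neg_profile(**overrides):
    p = {m: False for m in mif.REQUIRED_MARKERS}
    p.update(overrides)
    return p


class TestCallPhenotype:
    def test_nk_definition(self):
        assert mif.call_phenotype(neg_profile(CD16=True, CD56=True)) == "NK"

    def test_treg_takes_priority_over_cd4t(self):
        markers = neg_profile(CD3=True, CD4=True, FOXP3=True)
        assert mif.call_phenotype(markers) == "Treg"
        assert mif.call_phenotype(neg_profile(CD3=True, CD4=True)) == "CD4T"

    def test_nkt_requires_cd3_positive(self):
        assert mif.call_phenotype(neg_profile(CD3=True, CD56=True)) == "NKT"

    def test_double_positive_before_monocyte_and_macrophage(self):
        markers = neg_profile(CD11b=True, CD68=True)
        assert mif.call_phenotype(markers) == "CD11b_CD68"
        assert mif.call_phenotype(neg_profile(CD68=True)) == "Macrophage"
        assert mif.call_phenotype(neg_profile(CD11b=True)) == "Monocyte"

    def test_all_negative_falls_through_to_other(self):
        assert mif.call_phenotype(neg_profile()) == "other"

    def test_missing_marker_rejected_by_name(self):
        markers = neg_profile()
        del markers["CD56"]
        with pytest.raises(KeyError, match="CD56"):
            mif.call_phenotype(markers)

    @pytest.mark.parametrize("phenotype", [p for p in mif.PHENOTYPES])
    def test_canonical_profiles_round_trip(self, phenotype):
        assert mif.call_phenotype(mif.markers_for_phenotype(phenotype)) == phenotype

    def test_vectorized_calls_match_scalar(self):
        rng = np.random.default_rng(0)
        rows = [{m: bool(rng.random() < 0.3) for m in mif.REQUIRED_MARKERS}
                for _ in range(100)]
        df = pd.DataFrame(rows)
        df["x_um"] = 0.0
        df["y_um"] = 0.0
        called = mif.call_phenotypes(df)
        for i, row in enumerate(rows):
            assert called["phenotype"].iloc[i] == mif.call_phenotype(row)


def cells_at(points):
    df = pd.DataFrame(points, columns=["x_um", "y_um"])
    df["phenotype"] = "CD8T"
    return df


class TestPartitionRegions:
    def test_straight_border_band_assignment(self):
        border = mif.BorderAnnotation(coords=[(0, -1000), (0, 1000)],
                                      tumor_side="right")
        cells = cells_at([(300, 0), (600, 0), (-600, 0)])
        out, _ = mif.partition_regions(cells, border, 500.0)
        assert list(out["region"]) == ["IM", "TN", "NLT"]

    @pytest.mark.parametrize("seed", range(3))
    def test_labels_match_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xs = np.sort(rng.uniform(0, 2000, 6))
        ys = rng.uniform(500, 1500, 6)
        border = mif.BorderAnnotation(coords=list(zip(xs, ys)), tumor_side="right")
        pts = rng.uniform(0, 2000, size=(200, 2))
        out, _ = mif.partition_regions(cells_at(pts), border, 500.0)

        # oracle: distance via dense sampling along every border segment
        dense = []
        for (x0, y0), (x1, y1) in zip(border.coords[:-1], border.coords[1:]):
            ts = np.linspace(0, 1, 2000)
            dense.append(np.column_stack([x0 + ts * (x1 - x0), y0 + ts * (y1 - y0)]))
        dense = np.vstack(dense)
        for i, (x, y) in enumerate(pts):
            d = np.sqrt(((dense - (x, y)) ** 2).sum(axis=1)).min()
            lab = out["region"].iloc[i]
            if abs(d - 500.0) < 2.0:
                continue  # oracle resolution at the band edge
            if d <= 500.0:
                assert lab == "IM"
            else:
                assert lab in ("TN", "NLT")
            assert out["border_distance_um"].iloc[i] == pytest.approx(d, abs=1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-800, 800, size=(80, 2))
        border = mif.BorderAnnotation(coords=[(-900, -100), (0, 50), (900, -200)],
                                      tumor_side="left")
        out0, _ = mif.partition_regions(cells_at(pts), border, 500.0)

        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -456.0])
        pts2 = pts @ rot.T + shift
        border2 = mif.BorderAnnotation(
            coords=[tuple(np.asarray(c) @ rot.T + shift) for c in border.coords],
            tumor_side="left",
        )
        out2, _ = mif.partition_regions(cells_at(pts2), border2, 500.0)
        assert list(out0["region"]) == list(out2["region"])

    def test_closed_polygon_interior_is_tumor(self):
        border = mif.BorderAnnotation(
            coords=[(0, 0), (3000, 0), (3000, 3000), (0, 3000), (0, 0)], closed=True
        )
        cells = cells_at([(1500, 1500), (1500, 100), (1500, 4000), (1500, 3400)])
        out, _ = mif.partition_regions(cells, border, 500.0)
        assert list(out["region"]) == ["TN", "IM", "NLT", "IM"]

    def test_degenerate_border_rejected(self):
        with pytest.raises(ValueError, match="zero length|degenerate"):
            mif.BorderAnnotation(coords=[(5, 5), (5, 5)])

    def test_region_counts_sum_to_total(self, mif_field):
        cells, border = mif_field
        out, _ = mif.partition_regions(cells, border, 500.0)
        for ph in ("NK", "CD8T", "Macrophage"):
            total = (out["phenotype"] == ph).sum()
            per_region = sum(((out["phenotype"] == ph) & (out["region"] == r)).sum()
                             for r in ("TN", "IM", "NLT"))
            assert per_region == total


class TestRegionDensity:
    def _partition(self, areas):
        border = mif.BorderAnnotation(coords=[(0, 0), (0, 1)], tumor_side="right")
        return mif.RegionPartition(border=border, region_areas_mm2=areas)

    def test_simple_arithmetic(self):
        cells = cells_at([(i, 0) for i in range(50)])
        cells["region"] = "TN"
        part = self._partition({"TN": 0.5, "IM": 1.0, "NLT": 1.0})
        out = mif.region_density(cells, part, "CD8T")
        assert out["TN"] == pytest.approx(100.0)
        assert out["IM"] == 0.0

    def test_absent_phenotype_is_zero_and_zero_area_absent(self):
        cells = cells_at([(0, 0)])
        cells["region"] = "TN"
        part = self._partition({"TN": 1.0, "IM": 0.0, "NLT": 1.0})
        out = mif.region_density(cells, part, "NK")
        assert out["TN"] == 0.0
        assert out["IM"] is None

    def test_poisson_field_density_within_sampling_band(self, mif_field):
        cells, border = mif_field
        out, part = mif.partition_regions(
            cells, border, 500.0, field_bounds=(0, 0, 2000, 2000)
        )
        lam = 300.0  # macrophage density used by the generator
        d = mif.region_density(out, part, "Macrophage")
        for region in ("TN", "IM", "NLT"):
            a = part.region_areas_mm2[region]
            assert d[region] == pytest.approx(lam, abs=3 * np.sqrt(lam / a))


class TestDunnTest:
    def test_identical_groups_are_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = mif.dunn_test([g, g, g])
        assert np.allclose(out["z"], 0.0)
        assert (out["p_adj"] == 1.0).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        c = rng.normal(3, 1, 20)   # 3 SD shift
        out = mif.dunn_test([a, b, c], labels=["a", "b", "c"])
        row = out[(out["a"] == "a") & (out["b"] == "c")].iloc[0]
        assert row["p_adj"] < 0.01

    def test_matches_rank_mean_formula_oracle(self):
        groups = [np.array([1.0, 5.0, 8.0, 2.0, 9.0]),
                  np.array([3.0, 3.0, 7.0, 10.0, 4.0]),
                  np.array([6.0, 11.0, 12.0, 2.0, 13.0])]
        out = mif.dunn_test(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie = ((counts**3 - counts).sum()) / (12 * (n - 1))
        var = n * (n + 1) / 12 - tie
        r = [ranks[:5].mean(), ranks[5:10].mean(), ranks[10:].mean()]
        z01 = (r[0] - r[1]) / np.sqrt(var * (1 / 5 + 1 / 5))
        assert out["z"].iloc[0] == pytest.approx(z01, abs=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            mif.dunn_test([np.array([1.0]), np.array([1.0, 2.0])])


class TestNearestNeighbor:
    def _table(self, sources, targets):
        rows = [{"x_um": x, "y_um": y, "phenotype": "CD8T"} for x, y in sources]
        rows += [{"x_um": x, "y_um": y, "phenotype": "NK"} for x, y in targets]
        return pd.DataFrame(rows)

    def test_nearest_target_wins(self):
        cells = self._table([(0, 0)], [(100, 0), (250, 0)])
        res = mif.nearest_neighbor(cells, "CD8T", "NK")
        assert res.mean_um == pytest.approx(100.0)
        assert len(res.retained_um) == 1

    def test_distance_over_300_um_eliminated(self):
        cells = self._table([(0, 0)], [(400, 0)])
        res = mif.nearest_neighbor(cells, "CD8T", "NK")
        assert len(res.retained_um) == 0
        assert res.mean_um is None

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        sources = rng.uniform(0, 1500, size=(150, 2))
        targets = rng.uniform(0, 1500, size=(150, 2))
        cells = self._table(sources, targets)
        res = mif.nearest_neighbor(cells, "CD8T", "NK")
        brute = np.array([np.sqrt(((targets - s) ** 2).sum(axis=1)).min()
                          for s in sources])
        assert np.allclose(np.sort(res.distances_um), np.sort(brute))
        assert res.mean_um == pytest.approx(brute[brute <= 300].mean())

    def test_shrinking_dmax_shrinks_retained_set(self):
        rng = np.random.default_rng(4)
        cells = self._table(rng.uniform(0, 1000, (50, 2)),
                            rng.uniform(0, 1000, (50, 2)))
        r300 = mif.nearest_neighbor(cells, "CD8T", "NK", max_distance_um=300)
        r100 = mif.nearest_neighbor(cells, "CD8T", "NK", max_distance_um=100)
        assert len(r100.retained_um) <= len(r300.retained_um)
        assert set(np.round(r100.retained_um, 9)) <= set(np.round(r300.retained_um, 9))

    def test_no_targets_rejected(self):
        cells = self._table([(0, 0)], [])
        with pytest.raises(ValueError, match="target"):
            mif.nearest_neighbor(cells, "CD8T", "NK")


class TestDensityCorrelation:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"NK": x, "cDC": 2 * x})
        rho, p = mif.density_correlation(df)
        assert rho.loc["NK", "cDC"] == pytest.approx(1.0)

    def test_matches_rank_then_correlate_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((12, 3)), columns=["a", "b", "c"])
        rho, _ = mif.density_correlation(df)
        ra = stats.rankdata(df["a"])
        rb = stats.rankdata(df["b"])
        assert rho.loc["a", "b"] == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-12)

    def test_constant_column_reported_absent(self):
        df = pd.DataFrame({"a": np.arange(8.0), "b": np.ones(8)})
        rho, _ = mif.density_correlation(df)
        assert np.isnan(rho.loc["a", "b"])

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3]})
        with pytest.raises(ValueError, match="4 samples"):
            mif.density_correlation(df)

    def test_null_pairs_rarely_exceed_half(self):
        big = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.random((16, 2)), columns=["a", "b"])
            rho, _ = mif.density_correlation(df)
            if abs(rho.loc["a", "b"]) >= 0.5:
                big += 1
        assert big <= 10  # |ρ| ≥ 0.5 at n=16 under the null is ~5%
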