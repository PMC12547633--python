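"""Hotspot rasterization and species exposure tables against brute-force
oracles."""

import numpy as np
import pytest
from shapely.geometry import box

from cumex.exposure import (
    Hotspot,
    HotspotSet,
    normalize_species,
    rasterize_hotspots,
    read_hotspots_geojson,
    species_mean_exposure,
    species_trend_exposure,
    write_hotspots_geojson,
)
from cumex.grid import MetricLayer
from cumex.trends import TrendLayer


def _cell_box(grid, i, j):
    lon0, lat0, lon1, lat1 = grid.cell_bounds(i, j)
    return box(lon0, lat0, lon1, lat1)


class TestRasterize:
    def test_polygon_covering_one_sea_cell(self, coastal_grid):
        # cell (0, 4) is strictly sea
        hs = HotspotSet([Hotspot("one_cell", _cell_box(coastal_grid, 0, 4))])
        masks = rasterize_hotspots(hs, coastal_grid)["one_cell"]
        assert masks["sea"].sum() == 1 and masks["sea"][0, 4]
        assert not masks["land"].any()

    def test_subcell_island_in_sea_cell_has_empty_land_mask(self, coastal_grid):
        lon0, lat0, lon1, lat1 = coastal_grid.cell_bounds(2, 4)
        cx, cy = (lon0 + lon1) / 2, (lat0 + lat1) / 2
        hs = HotspotSet([Hotspot("islet", box(cx - 0.1, cy - 0.1, cx + 0.1, cy + 0.1))])
        masks = rasterize_hotspots(hs, coastal_grid)["islet"]
        assert not masks["land"].any()
        assert masks["sea"].sum() == 1

    def test_matches_exhaustive_intersection_oracle(self, coastal_grid, rng):
        hotspots = []
        for k in range(5):
            cx = rng.uniform(0.0, 6.0)
            cy = rng.uniform(-40.0, -35.0)
            w, h = rng.uniform(0.4, 2.5, 2)
            hotspots.append(Hotspot(f"s{k}", box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)))
        masks = rasterize_hotspots(HotspotSet(hotspots), coastal_grid)
        sea_role = coastal_grid.role_mask("sea")
        land_role = coastal_grid.role_mask("land")
        for h in hotspots:
            hit = np.zeros(coastal_grid.shape, bool)
            for i in range(coastal_grid.nlat):
                for j in range(coastal_grid.nlon):
                    hit[i, j] = h.geometry.intersection(_cell_box(coastal_grid, i, j)).area > 0
            np.testing.assert_array_equal(masks[h.species]["sea"], hit & sea_role)
            np.testing.assert_array_equal(masks[h.species]["land"], hit & land_role)

    def test_shrinking_never_grows_mask(self, coastal_grid):
        big = box(0.2, -39.8, 4.8, -36.2)
        for frac in (1.0, 0.6, 0.3, 0.05):
            shrunk = box(
                big.bounds[0], big.bounds[1],
                big.bounds[0] + frac * (big.bounds[2] - big.bounds[0]),
                big.bounds[1] + frac * (big.bounds[3] - big.bounds[1]),
            )
            m_big = rasterize_hotspots(
                HotspotSet([Hotspot("s", big)]), coastal_grid
            )["s"]
            m_small = rasterize_hotspots(
                HotspotSet([Hotspot("s", shrunk)]), coastal_grid
            )["s"]
            for env in ("sea", "land"):
                assert not (m_small[env] & ~m_big[env]).any()

    def test_center_rule(self, coastal_grid):
        # polygon nicking the corner of a cell: intersects yes, centre no
        lon0, lat0, _, _ = coastal_grid.cell_bounds(1, 4)
        nick = box(lon0 - 0.2, lat0 - 0.2, lon0 + 0.2, lat0 + 0.2)
        hs = HotspotSet([Hotspot("nick", nick)])
        inter = rasterize_hotspots(hs, coastal_grid, rule="intersects")["nick"]
        cent = rasterize_hotspots(hs, coastal_grid, rule="center")["nick"]
        assert inter["sea"].sum() == 4
        assert cent["sea"].sum() == 0

    def test_geojson_roundtrip(self, coastal_grid, tmp_path):
        hs = HotspotSet(
            [
                Hotspot("a", _cell_box(coastal_grid, 0, 4), iucn="EN"),
                Hotspot("b", _cell_box(coastal_grid, 1, 5)),
            ]
        )
        path = tmp_path / "hs.geojson"
        write_hotspots_geojson(hs, path)
        back = read_hotspots_geojson(path)
        assert back.species_names == ["a", "b"]
        assert back.hotspots[0].iucn == "EN"
        for ha, hb in zip(hs, back):
            assert ha.geometry.equals(hb.geometry)

    def test_duplicate_species_merged_on_read(self, coastal_grid, tmp_path):
        hs = HotspotSet([Hotspot("a", _cell_box(coastal_grid, 0, 4))])
        path = tmp_path / "hs.geojson"
        import json

        from shapely.geometry import mapping

        features = [
            {"type": "Feature", "properties": {"species": "a", "season": s},
             "geometry": mapping(_cell_box(coastal_grid, 0, 4 + k))}
            for k, s in enumerate(["breeding", "non-breeding"])
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
        back = read_hotspots_geojson(path)
        assert len(back) == 1
        assert back.hotspots[0].geometry.area == pytest.approx(2.0)


def _mask_dict(grid, cells_by_species, env="sea"):
    out = {}
    for sp, cells in cells_by_species.items():
        m = np.zeros(grid.shape, bool)
        for i, j in cells:
            m[i, j] = True
        out[sp] = {"sea": m & grid.role_mask("sea"), "land": m & grid.role_mask("land")}
    return out


class TestSpeciesMeanExposure:
    def test_uniform_layer_mean_independent_of_mask_size(self, sea_grid):
        layer = MetricLayer("MHW", "intensity", np.full(sea_grid.shape, 2.0), "degC", sea_grid)
        masks = _mask_dict(sea_grid, {"big": [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)],
                                      "small": [(3, 3)]})
        table = species_mean_exposure([layer], masks)
        assert (table["mean_value"] == 2.0).all()

    def test_cumulative_and_contributions(self, sea_grid):
        mhw = MetricLayer("MHW", "intensity", np.full(sea_grid.shape, 1.0), "degC", sea_grid)
        wind = MetricLayer("wind_sea", "intensity", np.full(sea_grid.shape, 3.0), "m/s", sea_grid)
        masks = _mask_dict(sea_grid, {"sp": [(0, 0), (1, 1)]})
        table = species_mean_exposure([mhw, wind], masks).set_index("event_type")
        assert table.loc["MHW", "cumulative"] == pytest.approx(4.0)
        assert table.loc["MHW", "contribution"] == pytest.approx(0.25)
        assert table.loc["wind_sea", "contribution"] == pytest.approx(0.75)

    def test_empty_land_mask_gives_missing_rows(self, sea_grid):
        hw = MetricLayer("HW", "intensity", np.full(sea_grid.shape, 1.0), "degC", sea_grid)
        masks = _mask_dict(sea_grid, {"marine_only": [(0, 0)]})  # all-sea grid
        table = species_mean_exposure([hw], masks)
        assert table["mean_value"].isna().all()
        assert table["cumulative"].isna().all()

    def test_matches_masked_mean_oracle(self, coastal_grid, rng):
        layers = []
        for etype in ("MHW", "wind_sea"):
            vals = rng.normal(2, 1, size=coastal_grid.shape)
            vals[rng.uniform(size=coastal_grid.shape) < 0.2] = np.nan
            layers.append(MetricLayer(etype, "duration", vals, "days", coastal_grid))
        cells = {f"s{k}": [(int(a), int(b)) for a, b in rng.integers(0, 5, (6, 2))]
                 for k in range(3)}
        masks = _mask_dict(coastal_grid, cells)
        table = species_mean_exposure(layers, masks)
        for row in table.itertuples():
            mask = masks[row.species][row.environment]
            sel = layers[0].values if row.event_type == "MHW" else layers[1].values
            sel = sel[mask]
            sel = sel[np.isfinite(sel)]
            if sel.size:
                assert row.mean_value == pytest.approx(sel.mean())
            else:
                assert np.isnan(row.mean_value)

    def test_contributions_sum_to_one(self, coastal_grid, rng):
        layers = [
            MetricLayer(et, "frequency", rng.uniform(0.5, 3, size=coastal_grid.shape),
                        "days/year", coastal_grid)
            for et in ("HW", "wind_land", "precip")
        ]
        masks = _mask_dict(coastal_grid, {"sp": [(0, 0), (0, 1), (1, 2)]})
        table = species_mean_exposure(layers, masks)
        land = table[table.environment == "land"]
        assert land["contribution"].sum() == pytest.approx(1.0)


class TestNormalizeSpecies:
    def test_single_species_normalizes_to_one(self, sea_grid):
        layer = MetricLayer("MHW", "intensity", np.full(sea_grid.shape, 2.0), "degC", sea_grid)
        table = normalize_species(
            species_mean_exposure([layer], _mask_dict(sea_grid, {"sp": [(0, 0)]}))
        )
        assert (table["normalized"] == 1.0).all()

    def test_two_to_four_gives_half_and_one(self, sea_grid):
        vals = np.full(sea_grid.shape, 2.0)
        vals[2:, :] = 4.0
        layer = MetricLayer("MHW", "intensity", vals, "degC", sea_grid)
        masks = _mask_dict(sea_grid, {"lo": [(0, 0)], "hi": [(3, 3)]})
        table = normalize_species(species_mean_exposure([layer], masks)).set_index("species")
        assert table.loc["lo", "normalized"] == pytest.approx(0.5)
        assert table.loc["hi", "normalized"] == pytest.approx(1.0)

    def test_group_max_oracle_and_exactly_one_max(self, coastal_grid, rng):
        layers = [
            MetricLayer(et, m, rng.uniform(1, 5, size=coastal_grid.shape), "u", coastal_grid)
            for et in ("MHW", "wind_sea")
            for m in ("intensity", "duration")
        ]
        cells = {f"s{k}": [(int(a), int(b)) for a, b in rng.integers(0, 5, (4, 2))]
                 for k in range(4)}
        table = normalize_species(species_mean_exposure(layers, _mask_dict(coastal_grid, cells)))
        for (_, _), grp in table.groupby(["environment", "metric"]):
            per_species = grp.groupby("species")["normalized"].first()
            per_species = per_species[np.isfinite(per_species)]
            if per_species.empty:
                continue
            assert per_species.max() == pytest.approx(1.0)
            assert (per_species <= 1.0 + 1e-12).all()
            cums = grp.groupby("species")["cumulative"].first()
            np.testing.assert_allclose(per_species, cums.dropna() / cums.max())


def _filtered_layer(grid, slope, event_type="MHW", metric="frequency"):
    slope = np.asarray(slope, float)
    p = np.where(np.isfinite(slope), 0.01, np.nan)
    return TrendLayer(event_type, metric, slope, p, np.full(grid.shape, 31), grid,
                      "days/year/year", filtered=True, alpha=0.05)


class TestSpeciesTrendExposure:
    def test_no_retained_cells_zero_convention(self, sea_grid):
        nanf = np.full(sea_grid.shape, np.nan)
        masks = _mask_dict(sea_grid, {"sp": [(0, 0), (1, 1)]})
        table = species_trend_exposure([_filtered_layer(sea_grid, nanf)], masks)
        row = table.iloc[0]
        assert row["adjusted_mean"] == 0.0
        assert row["coverage_pct"] == 0.0
        assert row["cumulative"] == 0.0

    def test_pixel_count_adjustment_example(self, sea_grid):
        """10-cell hotspot, 5 retained cells of slope 2: mean 2, adjusted 0.2,
        coverage 50%."""
        slope = np.full(sea_grid.shape, np.nan)
        cells = [(i, j) for i in range(3) for j in range(4)][:10]
        for i, j in cells[:5]:
            slope[i, j] = 2.0
        masks = _mask_dict(sea_grid, {"sp": cells})
        table = species_trend_exposure([_filtered_layer(sea_grid, slope)], masks)
        row = table.iloc[0]
        assert row["mean_slope"] == pytest.approx(2.0)
        assert row["adjusted_mean"] == pytest.approx(0.2)
        assert row["coverage_pct"] == pytest.approx(50.0)

    def test_matches_masked_tally_oracle(self, coastal_grid, rng):
        layers = []
        for etype in ("MHW", "wind_sea"):
            slope = np.where(
                rng.uniform(size=coastal_grid.shape) < 0.5,
                rng.uniform(0.1, 2.0, size=coastal_grid.shape),
                np.nan,
            )
            layers.append(_filtered_layer(coastal_grid, slope, etype))
        cells = {f"s{k}": [(int(a), int(b)) for a, b in rng.integers(0, 5, (8, 2))]
                 for k in range(3)}
        masks = _mask_dict(coastal_grid, cells)
        table = species_trend_exposure(layers, masks)
        for row in table.itertuples():
            mask = masks[row.species][row.environment]
            n_total = mask.sum()
            if n_total == 0:
                assert np.isnan(row.adjusted_mean)
                continue
            ly = layers[0] if row.event_type == "MHW" else layers[1]
            ret = mask & np.isfinite(ly.slope)
            if ret.sum():
                assert row.mean_slope == pytest.approx(ly.slope[ret].mean())
                assert row.adjusted_mean == pytest.approx(ly.slope[ret].mean() / n_total)
            else:
                assert row.adjusted_mean == 0.0
            assert row.coverage_pct == pytest.approx(100.0 * ret.sum() / n_total)
            union = mask & (np.isfinite(layers[0].slope) | np.isfinite(layers[1].slope))
            assert row.union_coverage_pct == pytest.approx(100.0 * union.sum() / n_total)

    def test_contributions_sum_to_one_when_positive(self, sea_grid, rng):
        layers = [
            _filtered_layer(sea_grid, rng.uniform(0.5, 2, size=sea_grid.shape), et)
            for et in ("MHW", "wind_sea")
        ]
        masks = _mask_dict(sea_grid, {"sp": [(0, 0), (2, 2), (3, 1)]})
        table = species_trend_exposure(layers, masks)
        sea = table[table.environment == "sea"]
        assert sea["contribution"].sum() == pytest.approx(1.0)
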