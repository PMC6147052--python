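"""Rule-based peatland mapping: pixel rules, majority resampling, area
tabulation and class collapsing."""

import numpy as np
import pandas as pd
import pytest

from peatflux import refdata, synth
from peatflux.mapgen import (
    CLASS_CODES, NODATA, UPLAND, WATER,
    RasterStack, build_peatland_map, classify_arrays, classify_pixel,
    collapse_classes, majority_resample, pcm_polygon_areas, tabulate_areas,
)


class TestClassifyPixel:
    @pytest.mark.parametrize(
        "prob,lc,tam,canopy,water,expected",
        [
            (0.7, 210, 0.05, 60.0, False, CLASS_CODES["forested_bog"]),
            (0.2, 81, 0.15, 5.0, False, CLASS_CODES["open_poor_fen"]),
            (0.9, 210, 0.30, 80.0, False, CLASS_CODES["forested_rich_fen"]),
            (0.3, 210, 0.0, 0.0, False, UPLAND),
            (0.9, 81, 0.5, 90.0, True, WATER),
            (0.6, 210, 0.10, 30.0, False, CLASS_CODES["treed_poor_fen"]),
            (0.6, 210, 0.25, 30.0, False, CLASS_CODES["treed_poor_fen"]),
            (0.6, 210, 0.251, 30.0, False, CLASS_CODES["treed_rich_fen"]),
            (np.nan, 210, 0.1, 30.0, False, NODATA),
        ],
    )
    def test_rule_application(self, prob, lc, tam, canopy, water, expected):
        assert classify_pixel(prob, lc, tam, canopy, water) == expected

    def test_total_and_deterministic_over_fuzz(self, rng):
        """Every random input maps to exactly one valid code, twice."""
        n = 100_000
        prob = rng.uniform(-0.1, 1.1, n)
        prob[rng.random(n) < 0.01] = np.nan
        lc = rng.integers(0, 250, n)
        tam = rng.uniform(0, 1, n)
        canopy = rng.uniform(0, 100, n)
        water = rng.random(n) < 0.05
        shape = (200, 500)
        args = [a.reshape(shape) for a in (prob, lc, tam, canopy, water)]
        out1 = classify_arrays(*args)
        out2 = classify_arrays(*args)
        valid = set(CLASS_CODES.values())
        assert set(np.unique(out1)) <= valid
        assert np.array_equal(out1, out2)

    def test_vector_matches_scalar(self, rng):
        n = 2_000
        prob = rng.uniform(0, 1, n)
        lc = rng.choice([81, 210], n)
        tam = rng.uniform(0, 1, n)
        canopy = rng.uniform(0, 100, n)
        water = rng.random(n) < 0.1
        vec = classify_arrays(prob.reshape(40, 50), lc.reshape(40, 50),
                              tam.reshape(40, 50), canopy.reshape(40, 50),
                              water.reshape(40, 50)).ravel()
        scalar = np.array([
            classify_pixel(prob[i], lc[i], tam[i], canopy[i], water[i])
            for i in range(n)
        ])
        assert np.array_equal(vec, scalar)


def brute_force_majority(fine, factor, nodata=NODATA):
    h, w = fine.shape
    H, W = -(-h // factor), -(-w // factor)
    out = np.full((H, W), nodata, dtype=fine.dtype)
    for i in range(H):
        for j in range(W):
            block = fine[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            vals = block[block != nodata]
            if vals.size == 0:
                continue
            codes, counts = np.unique(vals, return_counts=True)
            out[i, j] = codes[counts == counts.max()].min()
    return out


class TestMajorityResample:
    def test_uniform_block(self):
        fine = np.full((8, 8), 3, dtype=np.uint8)
        assert np.array_equal(majority_resample(fine, 8), [[3]])

    def test_majority_wins(self, rng):
        fine = np.full((8, 8), 1, dtype=np.uint8)
        idx = rng.choice(64, 24, replace=False)
        fine.ravel()[idx] = 2  # counts {1: 40, 2: 24}
        assert majority_resample(fine, 8)[0, 0] == 1

    def test_tie_goes_to_lowest_code(self):
        fine = np.array([[2, 2], [5, 5]], dtype=np.uint8)
        assert majority_resample(fine, 2)[0, 0] == 2

    def test_all_nodata_block(self):
        fine = np.full((4, 4), NODATA, dtype=np.uint8)
        assert majority_resample(fine, 4)[0, 0] == NODATA

    def test_nodata_never_outvotes_data(self):
        fine = np.full((4, 4), NODATA, dtype=np.uint8)
        fine[0, 0] = 7
        assert majority_resample(fine, 4)[0, 0] == 7

    @pytest.mark.parametrize("shape,factor", [((60, 60), 3), ((300, 300), 8), ((37, 53), 5)])
    def test_matches_brute_force_oracle(self, rng, shape, factor):
        fine = rng.integers(0, 11, shape).astype(np.uint8)
        fine[rng.random(shape) < 0.05] = NODATA
        got = majority_resample(fine, factor)
        assert np.array_equal(got, brute_force_majority(fine, factor))


class TestBuildPeatlandMap:
    def test_no_evidence_gives_upland_or_water(self):
        shape = (10, 10)
        stack = RasterStack(
            peat_prob=np.zeros(shape), tamarack_frac=np.zeros(shape),
            canopy_closure=np.zeros(shape), landcover_code=np.full(shape, 210),
            water_mask=np.eye(10, dtype=bool), ecozone_id=np.ones(shape, int),
        )
        out = build_peatland_map(stack)
        assert set(np.unique(out)) <= {UPLAND, WATER}

    def test_agrees_with_rule_oracle(self, small_landscape):
        stack, oracle = small_landscape
        built = build_peatland_map(stack)
        assert (built == oracle).mean() >= 0.99

    def test_single_cell_stack(self):
        stack = RasterStack(
            peat_prob=np.array([[0.9]]), tamarack_frac=np.array([[0.30]]),
            canopy_closure=np.array([[80.0]]), landcover_code=np.array([[210]]),
            water_mask=np.array([[False]]), ecozone_id=np.array([[1]]),
        )
        assert build_peatland_map(stack)[0, 0] == CLASS_CODES["forested_rich_fen"]

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            RasterStack(
                peat_prob=np.zeros((4, 4)), tamarack_frac=np.zeros((4, 4)),
                canopy_closure=np.zeros((4, 4)), landcover_code=np.zeros((4, 4)),
                water_mask=np.zeros((4, 4), bool), ecozone_id=np.zeros((5, 5), int),
            )

    def test_fine_landcover_resampled_first(self, small_landscape):
        stack, _ = small_landscape
        h, w = stack.shape
        fine = np.broadcast_to(
            stack.landcover_code[:, None, :, None], (h, 2, w, 2)
        ).reshape(2 * h, 2 * w).copy()
        built = build_peatland_map(stack, landcover_fine=fine, fine_factor=2)
        assert np.array_equal(built, build_peatland_map(stack))


class TestAreas:
    def test_cell_counting(self):
        cmap = np.full((4, 4), CLASS_CODES["open_bog"], dtype=np.uint8)
        zones = np.ones((4, 4), int)
        tab = tabulate_areas(cmap, zones, 0.0625)
        assert tab["area_km2"].sum() == pytest.approx(1.0)

    def test_total_area_conserved(self, small_landscape, rng):
        stack, oracle = small_landscape
        tab = tabulate_areas(oracle, stack.ecozone_id, 0.0625)
        assert tab["area_km2"].sum() == pytest.approx(oracle.size * 0.0625)
        assert tab["cells"].sum() == oracle.size

    def test_collapse_preserves_peatland_area(self, small_landscape):
        stack, oracle = small_landscape
        tab = tabulate_areas(oracle, stack.ecozone_id)
        three = collapse_classes(tab, "nine_to_three")
        two = collapse_classes(three, "three_to_two")
        peat9 = tab[tab["class_code"].between(1, 9)]["area_km2"].sum()
        peat3 = three[three["class"].isin(["bog", "poor_fen", "rich_fen"])]["area_km2"].sum()
        peat2 = two[two["class"].isin(["bog", "fen"])]["area_km2"].sum()
        assert peat3 == pytest.approx(peat9)
        assert peat2 == pytest.approx(peat9)

    def test_published_bog_subtotals(self):
        """Collapsing the expanded national areas reproduces the printed
        bog total: 365.2 + 86.7 + 81.2 = 533.1 (10^3 km2)."""
        exp = refdata.AREAS_EXPANDED
        bog = exp[["forested_bog", "treed_bog", "open_bog"]].to_numpy().sum()
        # published table covers primary ecozones plus the minor ones above
        table = exp.melt(id_vars="ecozone", var_name="class", value_name="area_km2")
        collapsed = collapse_classes(table.assign(
            **{"class": table["class"]}), "nine_to_three")
        assert collapsed[collapsed["class"] == "bog"]["area_km2"].sum() == pytest.approx(bog)
        assert bog == pytest.approx(533.1, abs=0.3)

    def test_three_to_two_merges_fens(self):
        tab = pd.DataFrame({"ecozone": ["z"] * 3,
                            "class": ["bog", "poor_fen", "rich_fen"],
                            "area_km2": [5.0, 2.0, 1.0]})
        two = collapse_classes(tab, "three_to_two").set_index("class")["area_km2"]
        assert two["bog"] == 5.0 and two["fen"] == 3.0


class TestPCMPolygonAreas:
    def test_single_polygon_product(self):
        polys = pd.DataFrame([{"ecozone": "z", "area_km2": 100.0,
                               "pct_bog": 30.0, "pct_fen": 0.0}])
        out = pcm_polygon_areas(polys).set_index("class")["area_km2"]
        assert out["bog"] == pytest.approx(30.0)

    def test_summation_across_polygons(self):
        polys = pd.DataFrame([
            {"ecozone": "z", "area_km2": 50.0, "pct_bog": 0.0, "pct_fen": 10.0},
            {"ecozone": "z", "area_km2": 50.0, "pct_bog": 0.0, "pct_fen": 10.0},
        ])
        out = pcm_polygon_areas(polys)
        assert out.set_index("class")["area_km2"]["fen"] == pytest.approx(10.0)

    def test_zero_percentages(self):
        polys = pd.DataFrame([{"ecozone": "z", "area_km2": 10.0,
                               "pct_bog": 0.0, "pct_fen": 0.0}])
        assert (pcm_polygon_areas(polys)["area_km2"] == 0).all()

    def test_oversum_warns_and_bounds_enforced(self):
        polys = pd.DataFrame([{"ecozone": "z", "area_km2": 10.0,
                               "pct_bog": 70.0, "pct_fen": 40.0}])
        with pytest.warns(UserWarning):
            pcm_polygon_areas(polys)
        bad = pd.DataFrame([{"ecozone": "z", "area_km2": 10.0,
                             "pct_bog": 120.0, "pct_fen": 0.0}])
        with pytest.raises(ValueError):
            pcm_polygon_areas(bad)
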