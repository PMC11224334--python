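"""Community and range metrics: richness, dominance, range indicators, rates,
centroids, fragmentation, trait regressions and the signed-rank shift test."""

import numpy as np
import pandas as pd
import pytest

import fishcast as fc
from fishcast.grid import SpatialGrid
from fishcast.projection import ProjectionCube


def planar_grid(nrow=6, ncol=8, d=10.0):
    """Toy grid with exact planar km coordinates and unit-free areas."""
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    n = nrow * ncol
    return SpatialGrid(
        cell_id=np.arange(n),
        lon=cc.ravel().astype(float),
        lat=rr.ravel().astype(float),
        x=cc.ravel() * d,
        y=rr.ravel() * d,
        cell_area=np.full(n, d * d),
        depth=np.full(n, 100.0),
        shape=(nrow, ncol),
        res=1.0,
    )


def toy_cube(grid, species, periods, prob=None, biomass=None, presence=None):
    S, n, P = len(species), grid.n_cells, len(periods)
    return ProjectionCube(
        species=list(species),
        grid=grid,
        periods=list(periods),
        occurrence_probability=np.full((S, n, P), 0.5) if prob is None else prob,
        combined_log_cpue=biomass,
        presence=presence,
    )


class TestRichness:
    def test_direct_sum_example(self):
        g = planar_grid(2, 2)
        prob = np.stack([np.full((4, 1), v) for v in (0.2, 0.3, 0.5)])
        cube = toy_cube(g, ["a", "b", "c"], ["present"], prob=prob)
        assert np.allclose(fc.richness_map(cube), 1.0)

    def test_saturated_and_empty_bounds(self):
        g = planar_grid(2, 2)
        S = 107
        ones = toy_cube(g, [f"s{i}" for i in range(S)], ["p"], prob=np.ones((S, 4, 1)))
        assert np.allclose(fc.richness_map(ones), S)
        zeros = toy_cube(g, ["a", "b"], ["p"], prob=np.zeros((2, 4, 1)))
        assert np.allclose(fc.richness_map(zeros), 0.0)

    def test_additive_over_disjoint_species_subsets(self):
        g = planar_grid(3, 3)
        rng = np.random.default_rng(0)
        prob = rng.uniform(size=(6, 9, 2))
        cube = toy_cube(g, list("abcdef"), ["p", "q"], prob=prob)
        first = toy_cube(g, list("abc"), ["p", "q"], prob=prob[:3])
        second = toy_cube(g, list("def"), ["p", "q"], prob=prob[3:])
        assert np.allclose(
            fc.richness_map(cube), fc.richness_map(first) + fc.richness_map(second)
        )

    def test_out_of_range_probability_rejected(self):
        g = planar_grid(2, 2)
        cube = toy_cube(g, ["a"], ["p"], prob=np.full((1, 4, 1), 1.5))
        with pytest.raises(ValueError):
            fc.richness_map(cube)


class TestDominance:
    def test_single_species_dominates_fully(self):
        g = planar_grid(2, 2)
        b = np.zeros((2, 4, 1))
        b[0] = 3.0
        cube = toy_cube(g, ["a", "b"], ["p"], biomass=b)
        pct, dom = fc.dominance_map(cube)
        assert np.allclose(pct[:, 0], 100.0)
        assert (dom[:, 0] == 0).all()

    def test_direct_ratio_and_tie_break(self):
        g = planar_grid(1, 1)
        b = np.array([[[3.0]], [[1.0]]])
        cube = toy_cube(g, ["a", "b"], ["p"], biomass=b)
        pct, dom = fc.dominance_map(cube)
        assert pct[0, 0] == pytest.approx(75.0)
        assert dom[0, 0] == 0
        tie = toy_cube(g, ["a", "b"], ["p"], biomass=np.array([[[2.0]], [[2.0]]]))
        _, dom_t = fc.dominance_map(tie)
        assert dom_t[0, 0] == 0  # species-identifier order wins ties

    def test_zero_total_missing(self):
        g = planar_grid(1, 2)
        b = np.zeros((2, 2, 1))
        b[0, 0, 0] = 1.0
        cube = toy_cube(g, ["a", "b"], ["p"], biomass=b)
        pct, dom = fc.dominance_map(cube)
        assert np.isnan(pct[1, 0]) and dom[1, 0] == -1

    def test_matches_brute_force_max_over_sum(self):
        g = planar_grid(4, 5)
        rng = np.random.default_rng(1)
        b = rng.uniform(0, 2, (5, 20, 2))
        cube = toy_cube(g, list("abcde"), ["p", "q"], biomass=b)
        pct, _ = fc.dominance_map(cube)
        assert np.allclose(pct, 100 * b.max(axis=0) / b.sum(axis=0), atol=1e-12)

    def test_dominance_floor_with_all_species_present(self):
        g = planar_grid(3, 3)
        rng = np.random.default_rng(2)
        b = rng.uniform(0.5, 1.5, (4, 9, 1))
        pct, _ = fc.dominance_map(toy_cube(g, list("abcd"), ["p"], biomass=b))
        assert (pct >= 100 / 4 - 1e-9).all()


class TestDominanceAreaShare:
    def test_full_and_split_dominance(self):
        g = planar_grid(2, 2)
        b = np.zeros((2, 4, 1))
        b[0] = 2.0
        cube = toy_cube(g, ["a", "b"], ["p"], biomass=b)
        _, dom = fc.dominance_map(cube)
        share = fc.dominance_area_share(dom, cube)
        assert share.loc["a", "p"] == pytest.approx(100.0)
        b[0, :2, 0], b[1, :2, 0] = 0.0, 5.0  # species b wins half the cells
        _, dom = fc.dominance_map(toy_cube(g, ["a", "b"], ["p"], biomass=b))
        share = fc.dominance_area_share(dom, toy_cube(g, ["a", "b"], ["p"], biomass=b))
        assert share["p"].tolist() == pytest.approx([50.0, 50.0])

    def test_area_weighting(self):
        g = planar_grid(1, 3)
        g.cell_area[:] = [10.0, 10.0, 80.0]
        b = np.zeros((2, 3, 1))
        b[0, :2, 0] = 1.0
        b[1, 2, 0] = 1.0
        cube = toy_cube(g, ["a", "b"], ["p"], biomass=b)
        _, dom = fc.dominance_map(cube)
        share = fc.dominance_area_share(dom, cube)
        assert share.loc["a", "p"] == pytest.approx(20.0)
        assert share.loc["b", "p"] == pytest.approx(80.0)

    def test_shares_sum_to_100(self, cube):
        _, dom = fc.dominance_map(cube)
        share = fc.dominance_area_share(dom, cube)
        sums = share.sum(axis=0)
        assert np.allclose(sums[sums > 0], 100.0, atol=1e-9)


class TestRangeAndCore:
    def test_core_is_top_decile_of_distinct_values(self):
        g = planar_grid(10, 10)
        vals = np.arange(1.0, 101.0)
        b = vals[None, :, None].copy()
        pres = np.ones((1, 100, 1), dtype=bool)
        cube = toy_cube(g, ["a"], ["present"], biomass=b, presence=pres)
        out = fc.range_and_core(cube)
        # 90th percentile (linear interpolation) of 1..100 = 90.1 -> 10 cells
        assert out.loc[0, "core_range_km2"] == pytest.approx(10 * 100.0)
        assert out.loc[0, "core_biomass"] == pytest.approx(sum(range(91, 101)))

    def test_uniform_biomass_degenerate_core_equals_range(self):
        g = planar_grid(4, 4)
        b = np.full((1, 16, 1), 2.0)
        pres = np.ones((1, 16, 1), dtype=bool)
        out = fc.range_and_core(toy_cube(g, ["a"], ["present"], biomass=b, presence=pres))
        assert out.loc[0, "core_range_km2"] == out.loc[0, "range_km2"]

    def test_future_doubling_never_shrinks_core(self):
        g = planar_grid(5, 5)
        rng = np.random.default_rng(3)
        base = rng.uniform(0.1, 1.0, 25)
        b = np.stack([base, 2 * base], axis=1)[None, :, :]
        pres = np.ones((1, 25, 2), dtype=bool)
        out = fc.range_and_core(
            toy_cube(g, ["a"], ["present", "future"], biomass=b, presence=pres)
        )
        core = out.set_index("period")["core_range_km2"]
        assert core["future"] >= core["present"]

    def test_core_never_exceeds_range(self, cube):
        out = fc.range_and_core(cube)
        ok = out.dropna(subset=["core_range_km2"])
        assert (ok["core_range_km2"] <= ok["range_km2"] + 1e-9).all()

    def test_empty_present_range_missing_core(self):
        g = planar_grid(2, 2)
        b = np.zeros((1, 4, 2))
        b[0, :, 1] = 1.0
        pres = b > 0
        out = fc.range_and_core(toy_cube(g, ["a"], ["present", "f"], biomass=b, presence=pres))
        assert out["core_range_km2"].isna().all()


class TestRateOfChange:
    def test_constant_series_zero_slope(self):
        slope, pct = fc.rate_of_change([5.0, 5.0, 5.0], [2010, 2050, 2100])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert pct == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_series(self):
        years = np.array([2010, 2030, 2050, 2070, 2090])
        vals = 100.0 + (years - 2010) * 1.0
        slope, pct = fc.rate_of_change(vals, years)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert pct == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_on_noisy_series(self):
        rng = np.random.default_rng(4)
        years = np.arange(2010, 2101, 10, dtype=float)
        vals = 3.0 + 0.25 * (years - 2010) + rng.normal(0, 1, years.size)
        slope, _ = fc.rate_of_change(vals, years)
        Xd = np.column_stack([np.ones_like(years), years])
        expect = np.linalg.solve(Xd.T @ Xd, Xd.T @ vals)[1]
        assert slope == pytest.approx(expect, abs=1e-9)

    def test_zero_present_value_percentage_missing(self):
        slope, pct = fc.rate_of_change([0.0, 10.0], [2010, 2100])
        assert np.isfinite(slope) and np.isnan(pct)

    def test_single_period_rejected(self):
        with pytest.raises(ValueError):
            fc.rate_of_change([1.0], [2010])


class TestCentroidShift:
    def test_symmetric_square_centroid_at_centre(self):
        g = planar_grid(5, 5)
        pres = np.zeros((1, 25, 1), dtype=bool)
        block = g.raster(np.arange(25)).copy()
        sel = np.isin(block, [6, 7, 11, 12])  # 2x2 block
        pres[0, sel.ravel(), 0] = True
        cube = toy_cube(g, ["a"], ["present"], presence=pres)
        out = fc.centroid_shift(cube)
        xs = g.x[sel.ravel()]
        ys = g.y[sel.ravel()]
        assert out.loc[0, "centroid_x_km"] == pytest.approx(xs.mean())
        assert out.loc[0, "centroid_y_km"] == pytest.approx(ys.mean())

    def test_pure_northward_translation_rate(self):
        g = planar_grid(12, 4, d=1.0)
        periods = ["present", "S:2030", "S:2050"]
        pres = np.zeros((1, g.n_cells, 3), dtype=bool)
        base_rows = np.array([0, 1])
        for k, shift_km in enumerate([0, 2, 4]):  # 10 km north per decade, d=1 km rows
            rows = base_rows + shift_km
            sel = np.isin(g.raster(np.arange(g.n_cells)) // 4, rows)
            pres[0, sel.ravel(), k] = True
        cube = toy_cube(g, ["a"], periods, presence=pres)
        out = fc.centroid_shift(cube)
        assert out.loc[0, "north_km_per_yr"] == pytest.approx(0.1, abs=1e-9)
        assert out.loc[0, "east_km_per_yr"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_biomass_weighted_equals_unweighted(self):
        g = planar_grid(4, 4)
        pres = np.zeros((1, 16, 1), dtype=bool)
        pres[0, [5, 6, 9, 10], 0] = True
        b = np.where(pres, 3.0, 0.0)
        cube = toy_cube(g, ["a"], ["present"], biomass=b, presence=pres)
        uw = fc.centroid_shift(cube, weighted=False)
        w = fc.centroid_shift(cube, weighted=True)
        assert uw.loc[0, "centroid_x_km"] == pytest.approx(w.loc[0, "centroid_x_km"])
        assert uw.loc[0, "centroid_y_km"] == pytest.approx(w.loc[0, "centroid_y_km"])

    def test_empty_period_left_missing(self):
        g = planar_grid(3, 3)
        pres = np.zeros((1, 9, 2), dtype=bool)
        pres[0, 4, 1] = True
        cube = toy_cube(g, ["a"], ["present", "S:2030"], presence=pres)
        out = fc.centroid_shift(cube)
        assert np.isnan(out.loc[0, "centroid_x_km"])
        assert np.isfinite(out.loc[1, "centroid_x_km"])


def flood_fill_components(raster):
    """Brute-force 8-connected component count (oracle)."""
    seen = np.zeros_like(raster, dtype=bool)
    n = 0
    H, W = raster.shape
    for i in range(H):
        for j in range(W):
            if raster[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if 0 <= x < H and 0 <= y < W and raster[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
    return n


class TestFragmentation:
    def test_single_block(self):
        g = planar_grid(4, 4)
        pres = np.zeros(16, dtype=bool)
        pres[[5, 6, 9, 10]] = True
        out = fc.fragmentation(pres, g)
        assert out.n_polygons == 1
        assert out.mean_polygon_area_km2 == pytest.approx(4 * 100.0)
        assert np.isnan(out.mean_interpolygon_distance_km)

    def test_two_cells_three_apart_distance(self):
        g = planar_grid(1, 6, d=7.0)
        pres = np.zeros(6, dtype=bool)
        pres[[1, 4]] = True
        out = fc.fragmentation(pres, g)
        assert out.n_polygons == 2
        assert out.mean_interpolygon_distance_km == pytest.approx(3 * 7.0)

    def test_diagonal_cells_are_one_polygon(self):
        g = planar_grid(3, 3)
        pres = np.zeros(9, dtype=bool)
        pres[[0, 4, 8]] = True  # main diagonal
        assert fc.fragmentation(pres, g).n_polygons == 1

    def test_empty_range(self):
        g = planar_grid(3, 3)
        out = fc.fragmentation(np.zeros(9, dtype=bool), g)
        assert out.n_polygons == 0
        assert np.isnan(out.mean_polygon_area_km2)

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        g = planar_grid(12, 12)
        for _ in range(40):
            pres = rng.uniform(size=144) < 0.35
            expect = flood_fill_components(g.raster(pres))
            assert fc.fragmentation(pres, g).n_polygons == expect


class TestTraitEffects:
    def test_exact_binary_effect_recovered(self):
        rng = np.random.default_rng(6)
        n = 40
        traits = pd.DataFrame(
            {"habitat": np.where(np.arange(n) % 2 == 0, "demersal", "pelagic")},
            index=[f"s{i}" for i in range(n)],
        )
        rates = pd.Series(
            np.where(traits["habitat"] == "pelagic", 2.0, 0.0), index=traits.index
        )
        out = fc.trait_effects(rates, traits)
        assert len(out) == 1
        assert out.iloc[0]["coef"] == pytest.approx(2.0, abs=1e-9)

    def test_pure_noise_traits_mostly_yield_empty_models(self):
        empties = 0
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            idx = [f"s{i}" for i in range(50)]
            traits = pd.DataFrame(
                {f"t{j}": rng.normal(size=50) for j in range(4)}, index=idx
            )
            rates = pd.Series(rng.normal(size=50), index=idx)
            out = fc.trait_effects(rates, traits)
            empties += int(len(out) == 0)
        assert empties >= 7

    def test_backward_path_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(7)
        n = 60
        idx = [f"s{i}" for i in range(n)]
        traits = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            },
            index=idx,
        )
        rates = pd.Series(
            1.5 * traits["x1"].to_numpy() + rng.normal(0, 1.0, n), index=idx
        )
        out = fc.trait_effects(rates, traits)

        # independent greedy backward elimination with explicit linear algebra
        active = ["x1", "x2", "x3"]
        from scipy import stats

        while active:
            X = np.column_stack([np.ones(n)] + [traits[c].to_numpy() for c in active])
            coef, *_ = np.linalg.lstsq(X, rates.to_numpy(), rcond=None)
            resid = rates.to_numpy() - X @ coef
            dof = n - X.shape[1]
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            tvals = coef / np.sqrt(np.diag(cov))
            pvals = 2 * stats.t.sf(np.abs(tvals), dof)
            worst = int(np.argmax(pvals[1:]))
            if pvals[1:][worst] < 0.05:
                break
            active.pop(worst)
        assert sorted(out["term"]) == sorted(active)

    def test_aliased_terms_rejected(self):
        idx = [f"s{i}" for i in range(20)]
        x = np.random.default_rng(8).normal(size=20)
        traits = pd.DataFrame({"x1": x, "x2": 2 * x}, index=idx)
        rates = pd.Series(x, index=idx)
        with pytest.raises(ValueError, match="aliased|rank"):
            fc.trait_effects(rates, traits)

    def test_categorical_block_dropped_as_unit(self):
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(60)]
        traits = pd.DataFrame(
            {
                "zoo": rng.choice(["Arctic", "Boreal", "temperate"], 60),
                "x": rng.normal(size=60),
            },
            index=idx,
        )
        rates = pd.Series(3.0 * traits["x"].to_numpy() + rng.normal(0, 0.5, 60), index=idx)
        out = fc.trait_effects(rates, traits)
        blocks = set(out["block"])
        assert "x" in blocks
        # the zoo dummies either all present or all absent
        zoo_terms = [t for t in out["term"] if t.startswith("zoo[")]
        assert len(zoo_terms) in (0, 2)


class TestShiftTest:
    def test_six_positive_values_exact(self):
        p = fc.shift_test(np.array([0.3, 1.2, 0.7, 2.0, 0.1, 0.5]))
        assert p == pytest.approx(2 / 2**6, abs=1e-12)

    def test_symmetric_pairs_null_centre(self):
        p = fc.shift_test(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_zeros_dropped_and_all_zero_missing(self):
        assert np.isnan(fc.shift_test(np.zeros(5)))
        p = fc.shift_test(np.array([0.0, 0.0, 0.4, 0.9, 1.1, 0.2, 0.6, 0.8]))
        assert p == pytest.approx(2 / 2**6, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        v = np.array(
            [3, -1, 2, 5, -2.5, 4, 1.5, -0.5, 6, 2.2, -3.3, 0.7, 1.1, 4.4, -1.7]
        )
        from scipy.stats import wilcoxon

        exact = wilcoxon(v, method="exact").pvalue
        approx = wilcoxon(v, method="approx").pvalue
        assert abs(exact - approx) <= 0.01
        assert fc.shift_test(v) == pytest.approx(exact)
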