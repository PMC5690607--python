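"""Risk sets, attribution and richness maps, climate-velocity exposure."""

import numpy as np
import pandas as pd
import pytest

from extrisk import (
    Grid,
    RangeAtlas,
    attribution_map,
    build_risk_sets,
    mean_velocity_per_species,
    overlay_product,
    richness_map,
    velocity_exceedance,
    zonal_stat,
)


def _grid(n_rows=4, n_cols=4, values=None, kind="continuous"):
    vals = np.zeros((n_rows, n_cols)) if values is None else np.asarray(values, float)
    return Grid(values=vals, resolution=1.0, origin=(0.0, float(vals.shape[0])), kind=kind)


class TestRiskSets:
    def _assessment(self, rows):
        ids = [r[0] for r in rows]
        prob = pd.Series([r[1] for r in rows], index=ids)
        status = pd.Series([r[2] for r in rows], index=ids)
        return build_risk_sets(prob, status, threshold=0.5)

    def test_actual_but_not_predicted(self):
        a = self._assessment([("s1", 0.2, "VU")])
        row = a.table.loc["s1"]
        assert row.actual and row.actual_or_potential
        assert not (row.predicted or row.latent or row.dd_predicted)

    def test_dd_predicted_membership_chain(self):
        a = self._assessment([("s1", 0.9, "DD")])
        row = a.table.loc["s1"]
        assert row.dd_predicted and row.latent and row.predicted and row.actual_or_potential
        assert not row.actual

    def test_lc_predicted_is_latent_not_dd(self):
        a = self._assessment([("s1", 0.9, "LC")])
        row = a.table.loc["s1"]
        assert row.latent and row.predicted and not row.dd_predicted

    def test_nesting_invariant_random(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 100
            ids = [f"s{i}" for i in range(n)]
            prob = pd.Series(r.random(n), index=ids)
            status = pd.Series(r.choice(["LC", "NT", "VU", "EN", "CR", "DD"], size=n), index=ids)
            a = build_risk_sets(prob, status, threshold=0.4)
            a.check_nesting()  # raises on violation
            t = a.table
            assert (t.dd_predicted <= t.latent).all()
            assert (t.latent <= t.predicted).all()
            assert (t.predicted <= t.actual_or_potential).all()

    def test_strict_threshold_rule(self):
        a = self._assessment([("s1", 0.5, "LC")])
        assert not a.table.loc["s1", "predicted"]  # exceeding read strictly

    def test_missing_probability_excluded_with_warning(self, caplog):
        prob = pd.Series([0.9, np.nan], index=["s1", "s2"])
        status = pd.Series(["LC", "LC"], index=["s1", "s2"])
        with caplog.at_level("WARNING"):
            a = build_risk_sets(prob, status, threshold=0.5)
        assert list(a.table.index) == ["s1"]

    def test_narrow_latent_set_config(self):
        prob = pd.Series([0.9], index=["s1"])
        status = pd.Series(["DD"], index=["s1"])
        a = build_risk_sets(prob, status, threshold=0.5, latent_statuses={"LC", "NT"})
        assert a.table.loc["s1", "dd_predicted"]
        assert not a.table.loc["s1", "latent"]


class TestAttributionMap:
    def test_single_species_constant_map(self):
        g = _grid()
        atlas = RangeAtlas(cells={"A": np.array([[0, 0], [1, 1]])}, grid=g)
        m = attribution_map(pd.Series({"A": 0.7}), atlas)
        assert m.values[0, 0] == 0.7 and m.values[1, 1] == 0.7
        assert np.isnan(m.values[3, 3])

    def test_overlap_averages(self):
        g = _grid()
        atlas = RangeAtlas(cells={"A": np.array([[0, 0]]), "B": np.array([[0, 0], [0, 1]])},
                           grid=g)
        m = attribution_map(pd.Series({"A": 0.2, "B": 0.4}), atlas)
        assert m.values[0, 0] == pytest.approx(0.3)
        assert m.values[0, 1] == pytest.approx(0.4)

    def test_conservation_identity_random_atlases(self, rng):
        for _ in range(10):
            g = _grid(6, 6)
            cells = {
                f"s{i}": np.unique(rng.integers(0, 6, size=(rng.integers(1, 10), 2)), axis=0)
                for i in range(8)
            }
            atlas = RangeAtlas(cells=cells, grid=g)
            scores = pd.Series(rng.random(8), index=list(cells))
            m = attribution_map(scores, atlas)
            count = np.zeros(g.shape)
            for sid in atlas.species:
                count[atlas[sid][:, 0], atlas[sid][:, 1]] += 1
            lhs = np.nansum(m.values * count)
            rhs = sum(scores[s] * atlas.n_cells(s) for s in atlas.species)
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestRichness:
    def test_overlap_counts(self):
        g = _grid()
        atlas = RangeAtlas(cells={"A": np.array([[0, 0], [0, 1]]),
                                  "B": np.array([[0, 1], [0, 2]])}, grid=g)
        m = richness_map(atlas, ["A", "B"])
        assert m.values[0, 1] == 2 and m.values[0, 0] == 1 and m.values[0, 2] == 1

    def test_empty_subset_zero_grid(self):
        g = _grid()
        atlas = RangeAtlas(cells={"A": np.array([[0, 0]])}, grid=g)
        assert np.all(richness_map(atlas, []).values == 0)

    def test_conservation_identity(self, rng):
        g = _grid(5, 5)
        cells = {f"s{i}": np.unique(rng.integers(0, 5, size=(rng.integers(1, 8), 2)), axis=0)
                 for i in range(6)}
        atlas = RangeAtlas(cells=cells, grid=g)
        m = richness_map(atlas, list(cells))
        assert m.values.sum() == sum(atlas.n_cells(s) for s in atlas.species)


class TestVelocity:
    def test_mean_over_range(self):
        g = _grid(values=[[0.4, 0.6], [1.0, 2.0]])
        atlas = RangeAtlas(cells={"A": np.array([[0, 0], [0, 1]]),
                                  "B": np.array([[1, 1]])}, grid=g)
        v = mean_velocity_per_species(g, atlas)
        assert v["A"] == pytest.approx(0.5)
        assert v["B"] == 2.0
        # delegation identity with the zonal statistic
        assert v["A"] == zonal_stat(g, atlas["A"], "mean")

    def test_exceedance_fractions(self):
        ids = ["a", "b", "c"]
        prob = pd.Series([0.9, 0.9, 0.9], index=ids)
        status = pd.Series(["VU", "VU", "VU"], index=ids)
        vel = pd.Series([0.4, 0.6, 1.2], index=ids)
        a = build_risk_sets(prob, status, threshold=0.5, velocities=vel)
        tab = velocity_exceedance(a, thresholds=(0.0, 0.5, 1.0))
        actual = tab[tab.risk_set == "actual"].set_index("threshold_km_per_yr")
        assert actual.at[0.5, "fraction"] == pytest.approx(2 / 3)
        assert actual.at[1.0, "fraction"] == pytest.approx(1 / 3)
        assert actual.at[0.0, "fraction"] == 1.0  # any nonnegative velocity


class TestOverlay:
    def test_high_high_class_and_partition(self, rng):
        vel = _grid(6, 6, rng.random((6, 6)) + 0.1)
        rich = _grid(6, 6, rng.integers(0, 20, (6, 6)).astype(float))
        class_grid, table = overlay_product(vel, rich)
        assert table["n_cells"].sum() == 36
        hh = (class_grid.values == 8).sum()  # 3*2+2 = high velocity, high richness
        assert hh == table.set_index("class_code").at[8, "n_cells"]

    def test_all_zero_richness_lowest_class(self):
        vel = _grid(3, 3, np.arange(9).reshape(3, 3) + 1.0)
        rich = _grid(3, 3, np.zeros((3, 3)))
        class_grid, table = overlay_product(vel, rich)
        assert set(np.unique(class_grid.values)) <= {0.0, 3.0, 6.0}  # richness class 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay_product(_grid(3, 3), _grid(4, 4))


class TestOnSyntheticWorld:
    def test_attribution_and_risk_products_integrate(self, small_data, small_fit):
        model, res = small_fit
        scores = res.attribution_scores("mean_human_density")
        assert scores.between(0, 1).all()
        amap = res.attribution_map("mean_human_density", small_data.atlas)
        assert np.nanmax(amap.values) <= 1.0
        assessment = res.risk_sets(velocity_grid=small_data.rasters["velocity"],
                                   atlas=small_data.atlas)
        assessment.check_nesting()
        assert assessment.table["mean_velocity"].notna().all()
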