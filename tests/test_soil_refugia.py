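"""WHC deltas against random background points and the refugia statistics."""

import numpy as np
import pandas as pd
import pytest

from nichetrack.io_formats import WHCGrid
from nichetrack.soil_refugia import (LocalityOmitted, coarse_fraction_tests,
                                     refugia_tests, species_whc_deltas,
                                     specimen_whc_deltas, whc_delta)
from nichetrack.synthetic_data import gen_tree

from conftest import make_record


def uniform_grid(value=100.0, nodata_cells=(), size=80, cell=0.02,
                 x0=-121.0, y0=37.0):
    vals = np.full((size, size), float(value))
    for r, c in nodata_cells:
        vals[r, c] = -9999.0
    return WHCGrid(size, size, x0, y0, cell, -9999.0, vals)


CENTER = make_record(specimen_id="c", lat=37.8, lon=-120.2)


class TestWhcDelta:
    def test_uniform_grid_zero_delta(self):
        d = whc_delta(CENTER, uniform_grid(100.0), seed=1)
        assert d.delta == pytest.approx(0.0)
        assert d.n_valid_random == 100

    def test_depressed_occupied_cell(self):
        g = uniform_grid(100.0)
        cell = g.cell_of(CENTER.lon, CENTER.lat)
        g.values[cell] = 80.0
        d = whc_delta(CENTER, g, seed=1)
        # a few background points may land in the occupied cell itself
        assert d.delta == pytest.approx(-20.0, abs=1.0)
        assert d.occupied_whc == 80.0

    def test_deterministic_under_seed(self):
        g = uniform_grid(100.0)
        rng = np.random.default_rng(0)
        g.values += rng.uniform(-30, 30, g.values.shape)
        a = whc_delta(CENTER, g, seed=7)
        b = whc_delta(CENTER, g, seed=7)
        assert a == b

    def test_occupied_nodata_omits_locality(self):
        g = uniform_grid(100.0)
        cell = g.cell_of(CENTER.lon, CENTER.lat)
        g.values[cell] = -9999.0
        with pytest.raises(LocalityOmitted):
            whc_delta(CENTER, g, seed=1)

    def test_nodata_background_points_skipped_and_counted(self):
        g = uniform_grid(100.0)
        g.values[:, :40] = -9999.0  # western half missing
        rec = make_record(specimen_id="e", lat=37.8, lon=-120.05)
        d = whc_delta(rec, g, seed=3)
        assert 0 < d.n_valid_random < 100

    def test_background_mean_unbiased_for_disk_average(self):
        """Monte-Carlo background means converge on the brute-force average
        of all grid cells inside the 20 km disk (area-uniform sampling)."""
        rng = np.random.default_rng(9)
        g = uniform_grid(150.0)
        g.values += rng.normal(0, 20, g.values.shape)
        # brute-force oracle: average every cell centre within 20 km
        lat0, lon0 = CENTER.lat, CENTER.lon
        vals = []
        for r in range(g.nrows):
            for c in range(g.ncols):
                y = g.yllcorner + (g.nrows - 1 - r + 0.5) * g.cellsize
                x = g.xllcorner + (c + 0.5) * g.cellsize
                dy = (y - lat0) * 110.574
                dx = (x - lon0) * 111.320 * np.cos(np.radians(lat0))
                if dx * dx + dy * dy <= 20.0 ** 2:
                    vals.append(g.values[r, c])
        disk_mean = float(np.mean(vals))
        bg = [whc_delta(CENTER, g, seed=s).background_mean_whc
              for s in range(200)]
        se = np.std(bg, ddof=1) / np.sqrt(len(bg))
        # the oracle ignores partial cell-disk overlap at the rim, worth
        # about sigma * sqrt(n_rim)/n_disk on a fixed field realization
        assert abs(np.mean(bg) - disk_mean) < 3 * se + 1.5

    def test_omitted_accounting(self):
        g = uniform_grid(100.0)
        cell = g.cell_of(-120.2, 37.8)
        g.values[cell] = -9999.0
        recs = [make_record(specimen_id="a", lat=37.8, lon=-120.2),
                make_record(specimen_id="b", lat=37.9, lon=-120.3)]
        deltas, omitted = specimen_whc_deltas(recs, g, seed=0)
        assert len(deltas) + len(omitted) == 2
        assert omitted == ["a"]


class TestSpeciesAggregation:
    def test_single_specimen_species_mean(self):
        g = uniform_grid(100.0)
        cell = g.cell_of(CENTER.lon, CENTER.lat)
        g.values[cell] = 95.0
        deltas, _ = specimen_whc_deltas([CENTER], g, seed=0)
        out = species_whc_deltas(deltas, [CENTER])
        assert out.mean_delta_mm.iloc[0] == pytest.approx(-5.0, abs=0.5)

    def test_symmetric_deltas_average_to_zero(self):
        from nichetrack.soil_refugia import WHCDelta
        recs = [make_record(specimen_id=f"s{i}") for i in range(3)]
        deltas = [WHCDelta(f"s{i}", 100, 100 + d, -d, 100)
                  for i, d in enumerate([-10, 0, 10])]
        out = species_whc_deltas(deltas, recs)
        assert out.mean_delta_mm.iloc[0] == pytest.approx(0.0)


def _annual_niche(species, temp, cwd):
    return pd.DataFrame([{"species": s, "kind": "annual", "tmean_c_mean": t,
                          "cwd_mm_mean": c} for s, t, c in zip(species, temp, cwd)])


class TestRefugiaTests:
    def test_all_negative_deltas_sign_test(self):
        tree = gen_tree(8, 1)
        sp = tree.tip_labels
        deltas = pd.DataFrame({"species": sp,
                               "mean_delta_mm": -np.arange(1.0, 9.0)})
        rng = np.random.default_rng(2)
        niche = _annual_niche(sp, 15 + rng.standard_normal(8),
                              400 + 50 * rng.standard_normal(8))
        out = refugia_tests(deltas, niche, tree)
        assert out["sign_test"].k == out["sign_test"].n == 8

    def test_species_set_mismatch_rejected(self):
        tree = gen_tree(8, 1)
        sp = tree.tip_labels
        deltas = pd.DataFrame({"species": sp[:-1] + ["ghost"],
                               "mean_delta_mm": np.arange(8.0)})
        niche = _annual_niche(sp, np.arange(8.0), np.arange(8.0))
        with pytest.raises(ValueError, match="species sets"):
            refugia_tests(deltas, niche, tree)

    def test_planted_delta_temperature_slope_recovered(self):
        """Deltas built as 2 * temperature + noise: PGLS slope positive."""
        tree = gen_tree(14, 3)
        sp = tree.tip_labels
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(20):
            temp = 12 + 3 * rng.standard_normal(14)
            deltas = pd.DataFrame({
                "species": sp,
                "mean_delta_mm": 2.0 * temp - 30 + rng.standard_normal(14)})
            niche = _annual_niche(sp, temp, 300 + 40 * rng.standard_normal(14))
            fit = refugia_tests(deltas, niche, tree)["pgls_temperature"]
            hits += fit.beta[1] > 0
        assert hits >= 19

    def test_null_slope_ci_covers_zero(self):
        """No delta-temperature relation: the 95% interval covers 0 at
        roughly the nominal rate."""
        from scipy import stats as ss
        tree = gen_tree(14, 5)
        sp = tree.tip_labels
        from nichetrack.phylo_comparative import simulate_bm
        rng = np.random.default_rng(6)
        cover = 0
        reps = 200
        for _ in range(reps):
            temp = dict(zip(sp, simulate_bm(tree, 1, rng)[:, 0]))
            deltas = pd.DataFrame({
                "species": sp,
                "mean_delta_mm": simulate_bm(tree, 1, rng)[:, 0]})
            niche = _annual_niche(sp, [temp[s] for s in sp], np.arange(14.0))
            fit = refugia_tests(deltas, niche, tree)["pgls_temperature"]
            tcrit = ss.t.ppf(0.975, fit.df_resid)
            lo = fit.beta[1] - tcrit * fit.se[1]
            hi = fit.beta[1] + tcrit * fit.se[1]
            cover += lo <= 0.0 <= hi
        assert abs(cover / reps - 0.95) < 0.05


class TestCoarseFraction:
    def test_constant_fraction_zero_slope(self):
        tree = gen_tree(8, 2)
        sp = tree.tip_labels
        soils = pd.DataFrame([{"species": s, "site_id": f"{s}_1",
                               "coarse_fraction_pct": 40.0} for s in sp])
        rng = np.random.default_rng(3)
        niche = _annual_niche(sp, 15 + rng.standard_normal(8),
                              300 + 30 * rng.standard_normal(8))
        out = coarse_fraction_tests(soils, niche, tree)
        assert out["pgls_temperature"].beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_input_order_invariance(self):
        tree = gen_tree(8, 2)
        sp = tree.tip_labels
        rng = np.random.default_rng(4)
        soils = pd.DataFrame([{"species": s, "site_id": f"{s}_{k}",
                               "coarse_fraction_pct": float(rng.uniform(10, 70))}
                              for s in sp for k in range(3)])
        niche = _annual_niche(sp, 15 + rng.standard_normal(8),
                              300 + 30 * rng.standard_normal(8))
        a = coarse_fraction_tests(soils, niche, tree)
        b = coarse_fraction_tests(soils.iloc[::-1].reset_index(drop=True),
                                  niche.iloc[::-1].reset_index(drop=True), tree)
        assert a["pgls_temperature"].beta == pytest.approx(
            b["pgls_temperature"].beta)

    def test_planted_slope_recovered_within_factor(self):
        """Generator slope -5 %/degC: median estimate within +-50%."""
        from nichetrack.synthetic_data import (ScenarioSpec, gen_field_soils,
                                               gen_specimens)
        slopes = []
        for seed in range(20):
            spec = ScenarioSpec(n_species=14, n_specimens_per_species=2,
                                coarse_slope_pct_per_degc=-5.0, seed=seed)
            tree = gen_tree(14, seed)
            _, _, sp_table = gen_specimens(tree, spec)
            soils = gen_field_soils(sp_table, spec)
            niche = _annual_niche(sp_table.species,
                                  sp_table.annual_tmean_c,
                                  np.arange(14.0) * 10 + 200)
            fit = coarse_fraction_tests(soils, niche, tree)["pgls_temperature"]
            slopes.append(fit.beta[1])
        med = np.median(slopes)
        assert -7.5 < med < -2.5
        assert np.mean(np.array(slopes) < 0) >= 0.95
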