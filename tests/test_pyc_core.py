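"""Inventory arithmetic: Eq.-level emissions, brute-force oracle
equivalence, linearity, and aggregation identities."""

import numpy as np
import pytest

from pycfire import (
    CombustionParams,
    PyCFactorTable,
    aggregate_regional,
    compute_cell_emissions,
    default_pft_taxonomy,
    generate_impulse_bundle,
    pyc_co2_ratio,
    regional_shares,
    run_inventory,
)
from pycfire.grid_core import COMPONENTS, FUEL_CATEGORIES, LANDCOVERS

from conftest import make_bundle, tiny_grid

WOODY_FRACS = {"1h": 0.045, "10h": 0.075, "100h": 0.21, "1000h": 0.67}
CAT_OF = {"1h": "NWF", "10h": "FWF", "100h": "FWF", "1000h": "CWF"}


class TestComputeCellEmissions:
    def test_hand_unit_tracking_oracle(self):
        """1000 gC/m² over 1e6 m² at CC 0.8, EF 1650, DMCC 0.45, P 0.1
        gives 8.0000e8 gC CO2-C and 8.0000e7 gC PyC."""
        co2c, pyc = compute_cell_emissions(
            fl=1000.0, ba=1e6, cc=0.8, ef=1650.0, dmcc=0.45, p_pyc=0.1
        )
        assert co2c == pytest.approx(8.0000e8, rel=1e-6)
        assert pyc == pytest.approx(8.0000e7, rel=1e-6)

    @pytest.mark.parametrize("kw", [{"ba": 0.0}, {"cc": 0.0}])
    def test_no_fire_or_no_combustion_gives_zero(self, kw):
        base = dict(fl=1000.0, ba=1e6, cc=0.8, ef=1650.0, dmcc=0.45, p_pyc=0.1)
        co2c, pyc = compute_cell_emissions(**{**base, **kw})
        assert co2c == 0.0 and pyc == 0.0

    def test_zero_dmcc_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_cell_emissions(1000.0, 1e6, 0.8, 1650.0, 0.0, 0.1)


def brute_force_inventory(bundle, grid, taxonomy, params, factors):
    """Independent quadruple-loop implementation of the inventory.

    Plain Python loops over year × cell × PFT × time-lag class with its
    own percentile, CC-scaling, allocation and partition arithmetic.
    """
    years = bundle.years
    pfts = bundle.pfts
    nlat, nlon = grid.shape
    bf = bundle.burned_fraction.values
    bm = bundle.biomass.values
    sm = bundle.soil_moisture.values
    cov = bundle.pft_cover.values
    comp_idx = {c: k for k, c in enumerate(COMPONENTS)}
    lc_idx = {lc: i for i, lc in enumerate(LANDCOVERS)}

    totals = {lc: np.zeros(len(years)) for lc in LANDCOVERS}
    totals_co2 = {lc: np.zeros(len(years)) for lc in LANDCOVERS}
    for iy in range(len(years)):
        for i in range(nlat):
            for j in range(nlon):
                series = sm[:, i, j]
                lo, hi = np.percentile(series, 5), np.percentile(series, 95)
                for ip, pft in enumerate(pfts):
                    lc = taxonomy.landcover[pft]
                    cls = taxonomy.bioclimatic_class[pft]
                    class_cov = sum(
                        cov[k, i, j]
                        for k, q in enumerate(pfts)
                        if taxonomy.landcover[q] == lc
                    )
                    if class_cov <= 0:
                        continue
                    share = cov[ip, i, j] / class_cov
                    ba = bf[iy, lc_idx[lc], i, j] * grid.cell_area[i, j] * share
                    wood = (
                        bm[iy, ip, comp_idx["aboveground_sapwood"], i, j]
                        + bm[iy, ip, comp_idx["aboveground_heartwood"], i, j]
                    )
                    fine = (
                        bm[iy, ip, comp_idx["leaf"], i, j]
                        + bm[iy, ip, comp_idx["fruit"], i, j]
                    )
                    for tl, frac in WOODY_FRACS.items():
                        fl = wood * frac + (fine if tl == "1h" else 0.0)
                        cat = CAT_OF[tl]
                        if hi > lo:
                            x = min(max((sm[iy, i, j] - lo) / (hi - lo), 0.0), 1.0)
                            x = 1.0 - x  # dry_max
                        else:
                            x = 0.5
                        cc = params.cc_min[cat] + x * (params.cc_max[cat] - params.cc_min[cat])
                        co2c = (
                            fl / params.dmcc[cls] * ba * cc * params.ef_co2[cls]
                            * 1e-3 * 12.0 / 44.0
                        )
                        totals_co2[lc][iy] += co2c
                        totals[lc][iy] += co2c * factors.p_pyc[cat]
    return totals, totals_co2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_nested_loop_oracle(self, taxonomy, params, pyc_factors, seed):
        """Vectorized inventory equals the explicit quadruple loop ≤1e-10."""
        rng = np.random.default_rng(seed)
        grid = tiny_grid(2, 4)  # ≤ 8 cells
        pfts = list(rng.choice(list(taxonomy.pft_ids), size=3, replace=False))
        bundle = make_bundle(grid, taxonomy, rng, years=(2000, 2001), pfts=pfts)
        result = run_inventory(bundle, grid, taxonomy, params=params, pyc_factors=pyc_factors)
        oracle_pyc, oracle_co2 = brute_force_inventory(
            bundle, grid, taxonomy, params, pyc_factors
        )
        for lc in LANDCOVERS:
            got = result.national_pyc_tgc(lc).values * 1e12
            np.testing.assert_allclose(got, oracle_pyc[lc], rtol=1e-10, atol=1e-6)
            got_co2 = result.national_co2c_tgc(lc).values * 1e12
            np.testing.assert_allclose(got_co2, oracle_co2[lc], rtol=1e-10, atol=1e-6)


class TestLinearity:
    def test_doubling_burned_fraction_doubles_pyc(self, taxonomy, params, pyc_factors):
        rng = np.random.default_rng(4)
        grid = tiny_grid(2, 4)
        bundle = make_bundle(grid, taxonomy, rng)
        base = run_inventory(bundle, grid, taxonomy, params=params, pyc_factors=pyc_factors)
        bundle.burned_fraction.values[:] *= 2.0
        doubled = run_inventory(bundle, grid, taxonomy, params=params, pyc_factors=pyc_factors)
        np.testing.assert_allclose(
            doubled.national_pyc_tgc().values, 2.0 * base.national_pyc_tgc().values, rtol=1e-12
        )

    def test_single_term_scenario_equals_cell_arithmetic(self, taxonomy, params, pyc_factors):
        """One cell, one PFT, leaf-only biomass: national total equals
        compute_cell_emissions on that single (PFT, NWF) term."""
        bundle, grid, tax = generate_impulse_bundle(
            2000, (1, 1), years=(1999, 2001),
            biomass_means={"leaf": 500.0},
        )
        # restrict cover to one PFT
        bundle.pft_cover.values[:] = 0.0
        pfts = bundle.pfts
        bundle.pft_cover.values[pfts.index("BoNE")] = 0.5
        result = run_inventory(bundle, grid, tax, params=params, pyc_factors=pyc_factors)

        iy = 2000 - 1999
        sm = bundle.soil_moisture.values[:, 1, 1]
        lo, hi = np.percentile(sm, 5), np.percentile(sm, 95)
        x = 1.0 - min(max((sm[iy] - lo) / (hi - lo), 0.0), 1.0)
        cc = params.cc_min["NWF"] + x * (params.cc_max["NWF"] - params.cc_min["NWF"])
        co2c, pyc = compute_cell_emissions(
            fl=500.0,
            ba=0.01 * grid.cell_area[1, 1],
            cc=cc,
            ef=params.ef_co2["boreal"],
            dmcc=params.dmcc["boreal"],
            p_pyc=pyc_factors.p_pyc["NWF"],
        )
        assert float(result.national_pyc_tgc("forest").sum()) * 1e12 == pytest.approx(
            float(pyc), rel=1e-10
        )

    def test_pyc_equals_co2c_times_factor_per_category(self, taxonomy, params, pyc_factors):
        rng = np.random.default_rng(5)
        grid = tiny_grid(2, 4)
        bundle = make_bundle(grid, taxonomy, rng)
        result = run_inventory(bundle, grid, taxonomy, params=params, pyc_factors=pyc_factors)
        for cat in FUEL_CATEGORIES:
            pyc = result.pyc_national.sel(fuel_category=cat).values
            co2 = result.co2c_national.sel(fuel_category=cat).values
            np.testing.assert_allclose(pyc, co2 * pyc_factors.p_pyc[cat], rtol=1e-12)

    def test_pyc_below_co2c_when_factors_below_one(self, small_scenario):
        bundle, grid, tax = small_scenario
        result = run_inventory(bundle, grid, tax)
        assert (result.pyc_grid.values <= result.co2c_grid.values + 1e-30).all()


class TestAggregation:
    def test_regional_sums_partition_national(self, small_scenario):
        bundle, grid, tax = small_scenario
        result = run_inventory(bundle, grid, tax)
        regional = aggregate_regional(result, grid)
        np.testing.assert_allclose(
            regional.sum("region").sel(landcover="forest").values,
            result.national_pyc_tgc("forest").values,
            rtol=1e-9,
        )

    def test_impulses_in_distinct_regions_stay_separate(self):
        bundle, grid, tax = generate_impulse_bundle(2000, (3, 3), years=(1999, 2001))
        # region of (3,3) on the 4x4 default layout is the hotspot corner
        result = run_inventory(bundle, grid, tax)
        regional = aggregate_regional(result, grid)
        r = int(grid.region_id[3, 3])
        total = float(regional.sel(landcover="forest").sum())
        in_region = float(regional.sel(landcover="forest", region=r).sum())
        assert in_region == pytest.approx(total, rel=1e-12)
        assert total > 0

    def test_single_region_share_is_one(self):
        bundle, grid, tax = generate_impulse_bundle(2000, (3, 3), years=(1999, 2001))
        result = run_inventory(bundle, grid, tax)
        regional = aggregate_regional(result, grid)
        shares = regional_shares(regional, "forest")
        assert shares.max() == pytest.approx(1.0, rel=1e-12)


class TestPyCCO2Ratio:
    def test_single_category_ratio_equals_factor(self, params):
        """Leaf-only fuel puts everything in NWF, so the ratio is P_PyC_NWF."""
        factors = PyCFactorTable.default()
        bundle, grid, tax = generate_impulse_bundle(
            2000, (1, 1), years=(1999, 2001), biomass_means={"leaf": 400.0}
        )
        result = run_inventory(bundle, grid, tax, params=params, pyc_factors=factors)
        ratio = pyc_co2_ratio(result)
        assert ratio.loc[2000, "forest"] == pytest.approx(factors.p_pyc["NWF"], rel=1e-12)

    def test_zero_fire_year_reported_missing(self):
        bundle, grid, tax = generate_impulse_bundle(2000, (1, 1), years=(1999, 2001))
        result = run_inventory(bundle, grid, tax)
        ratio = pyc_co2_ratio(result)
        assert np.isnan(ratio.loc[1999, "forest"])
        assert np.isfinite(ratio.loc[2000, "forest"])

    def test_ratio_bounded_by_extreme_factors(self, small_scenario, pyc_factors):
        bundle, grid, tax = small_scenario
        result = run_inventory(bundle, grid, tax)
        ratio = pyc_co2_ratio(result)["forest"].dropna()
        assert (ratio >= min(pyc_factors.p_pyc.values()) - 1e-12).all()
        assert (ratio <= max(pyc_factors.p_pyc.values()) + 1e-12).all()
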