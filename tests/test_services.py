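"""Ecosystem-service models: Budyko water yield, USLE retention, carbon
stocks, habitat quality."""

import numpy as np
import pytest

from landes.grids import Grid
from landes.services import (BiophysicalTable, ThreatSpec,
                             budyko_aet_fraction, carbon_storage,
                             compute_service_stack, default_biophysical_table,
                             habitat_degradation, habitat_quality, ls_factor,
                             rainfall_erosivity, soil_conservation,
                             water_yield)
from conftest import make_lu


@pytest.fixture(scope="module")
def bio():
    return default_biophysical_table()


def _single_cell_setup(P, pet, kc_class="forest", awc=0.1, root=750.0):
    shape = (1, 1)
    lu = make_lu(np.full(shape, 1))  # forest: Kc = 1.0
    grids = dict(
        precip=Grid(np.full(shape, float(P))),
        pet=Grid(np.full(shape, float(pet))),
        awc=Grid(np.full(shape, awc)),
        root=Grid(np.full(shape, root)),
    )
    return lu, grids


class TestWaterYield:
    def test_energy_limited_limit(self, bio):
        lu, g = _single_cell_setup(P=400.0, pet=0.0)
        wy = water_yield(g["precip"], g["pet"], g["awc"], g["root"], lu, bio)
        assert wy.values[0, 0] == pytest.approx(400.0)

    def test_water_limited_limit(self, bio):
        lu, g = _single_cell_setup(P=100.0, pet=1e9)
        wy = water_yield(g["precip"], g["pet"], g["awc"], g["root"], lu, bio)
        assert wy.values[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_omega_two(self, bio):
        # P=500, Kc*PET=1000, AWC_eff=0.1*750=75, Z=5 -> omega=2
        # AET/P = 3 - sqrt(5); Y = 500*(sqrt(5)-2) = 118.0339887...
        lu, g = _single_cell_setup(P=500.0, pet=1000.0)
        wy = water_yield(g["precip"], g["pet"], g["awc"], g["root"], lu, bio,
                         Z=5.0)
        assert wy.values[0, 0] == pytest.approx(500.0 * (np.sqrt(5) - 2.0),
                                                abs=1e-9)

    def test_bounds_on_random_draws(self, bio):
        rng = np.random.default_rng(0)
        n = 10000
        phi = rng.uniform(0, 50, n)
        omega = rng.uniform(1.25, 10.0, n)
        aet = budyko_aet_fraction(phi, omega)
        assert np.all(aet >= -1e-12) and np.all(aet <= 1 + 1e-9)

    def test_zero_precip_yields_zero(self, bio):
        lu, g = _single_cell_setup(P=0.0, pet=500.0)
        wy = water_yield(g["precip"], g["pet"], g["awc"], g["root"], lu, bio)
        assert wy.values[0, 0] == 0.0

    def test_negative_input_rejected(self, bio):
        lu, g = _single_cell_setup(P=-5.0, pet=100.0)
        with pytest.raises(ValueError):
            water_yield(g["precip"], g["pet"], g["awc"], g["root"], lu, bio)


class TestErosivity:
    def test_zero_precipitation(self):
        months = [Grid(np.zeros((3, 3))) for _ in range(12)]
        assert np.all(rainfall_erosivity(months).values == 0.0)

    def test_doubling_increases(self):
        rng = np.random.default_rng(1)
        months = [Grid(rng.uniform(5, 40, (4, 4))) for _ in range(12)]
        r1 = rainfall_erosivity(months)
        r2 = rainfall_erosivity([Grid(2 * g.values) for g in months])
        assert np.all(r2.values > r1.values)

    def test_uniform_months_scalar_oracle(self):
        P = 240.0
        months = [Grid(np.full((2, 2), P / 12)) for _ in range(12)]
        r = rainfall_erosivity(months)
        expect = 12 * 1.735 * 10 ** (1.5 * np.log10((P / 12) ** 2 / P)
                                     - 0.8188)
        assert r.values[0, 0] == pytest.approx(expect, rel=1e-12)


class TestLSFactor:
    def test_flat_plane_minimal_constant(self):
        ls = ls_factor(Grid(np.full((10, 10), 500.0), cell_size=100.0))
        assert np.allclose(ls.values, ls.values[0, 0])
        assert ls.values.min() >= 0.0

    def test_steeper_ramp_larger_ls(self):
        cols = np.arange(20) * 100.0
        ramp5 = Grid(np.tile(0.05 * cols, (20, 1)), cell_size=100.0)
        ramp10 = Grid(np.tile(0.10 * cols, (20, 1)), cell_size=100.0)
        assert np.all(ls_factor(ramp10).values > ls_factor(ramp5).values)

    def test_interior_cell_scalar_oracle(self):
        # uniform 10% ramp, 100 m cells; second column receives one cell
        # of upslope area from the column above it in drainage order
        cell = 100.0
        cols = np.arange(20) * cell
        dem = Grid(np.tile(0.10 * cols, (20, 1)), cell_size=cell)
        ls = ls_factor(dem)
        grad = 0.10
        theta = np.arctan(grad)
        sin_t = np.sin(theta)
        s = 16.8 * sin_t - 0.5
        beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
        m = beta / (1.0 + beta)
        # column 0 (ridge of the flow, drains westward... the lowest column
        # receives from upslope; pick the top-of-slope column: zero inflow
        area_in = 0.0
        num = (area_in + cell**2) ** (m + 1) - area_in ** (m + 1)
        den = cell ** (m + 2) * 22.13**m
        assert ls.values[10, 19] == pytest.approx(num / den * s, rel=1e-9)


class TestSoilConservation:
    def _grids(self, R, K, LS):
        shape = (1, 1)
        return (Grid(np.full(shape, R)), Grid(np.full(shape, K)),
                Grid(np.full(shape, LS)))

    def test_no_retention_when_cp_one(self):
        import pandas as pd
        table = default_biophysical_table().table.copy()
        table.loc[:, "usle_C"] = 1.0
        table.loc[:, "usle_P"] = 1.0
        bio1 = BiophysicalTable(table)
        R, K, LS = self._grids(100.0, 0.3, 2.0)
        sc = soil_conservation(R, K, LS, make_lu([[0]]), bio1)
        assert sc.values[0, 0] == 0.0

    def test_full_retention_when_c_zero(self):
        table = default_biophysical_table().table.copy()
        table.loc[:, "usle_C"] = 0.0
        bio0 = BiophysicalTable(table)
        R, K, LS = self._grids(100.0, 0.3, 2.0)
        sc = soil_conservation(R, K, LS, make_lu([[0]]), bio0)
        assert sc.values[0, 0] == pytest.approx(60.0)

    def test_arithmetic(self):
        table = default_biophysical_table().table.copy()
        table.loc["cropland", "usle_C"] = 0.2
        table.loc["cropland", "usle_P"] = 0.5
        bio = BiophysicalTable(table)
        R, K, LS = self._grids(100.0, 0.3, 2.0)
        sc = soil_conservation(R, K, LS, make_lu([[0]]), bio)
        assert sc.values[0, 0] == pytest.approx(54.0)

    def test_retention_bounded_by_rkls(self, bundle60, bio):
        from landes.services import rainfall_erosivity, ls_factor
        R = rainfall_erosivity(bundle60.precip_monthly)
        LS = ls_factor(bundle60.dem)
        sc = soil_conservation(R, bundle60.soil_erodibility_K, LS,
                               bundle60.landuse_t0, bio)
        rkls = (R.values * bundle60.soil_erodibility_K.values * LS.values)
        assert np.all(sc.values >= -1e-9)
        assert np.all(sc.values <= rkls + 1e-9)

    def test_out_of_range_cover_factor_rejected(self):
        table = default_biophysical_table().table.copy()
        table.loc["cropland", "usle_C"] = 1.5
        with pytest.raises(ValueError):
            BiophysicalTable(table)


class TestCarbonStorage:
    def test_arithmetic_oracle(self):
        table = default_biophysical_table().table.copy()
        table.loc["grassland", ["c_above", "c_below", "c_soil", "c_dead"]] = \
            [2.0, 1.0, 5.0, 0.5]
        bio = BiophysicalTable(table)
        lu = make_lu(np.full((10, 1), 2), cell_size=100.0)  # 1 ha cells
        cs = carbon_storage(lu, bio)
        assert cs.valid_values.sum() == pytest.approx(85.0)

    def test_all_zero_pools(self):
        table = default_biophysical_table().table.copy()
        table.loc[:, ["c_above", "c_below", "c_soil", "c_dead"]] = 0.0
        cs = carbon_storage(make_lu([[0, 1]]), BiophysicalTable(table))
        assert cs.valid_values.sum() == 0.0

    def test_linear_in_cell_area(self):
        bio = default_biophysical_table()
        lu1 = make_lu(np.full((5, 5), 1), cell_size=1000.0)
        lu2 = make_lu(np.full((5, 5), 1), cell_size=np.sqrt(2) * 1000.0)
        total1 = carbon_storage(lu1, bio).valid_values.sum()
        total2 = carbon_storage(lu2, bio).valid_values.sum()
        assert total2 == pytest.approx(2 * total1)


class TestHabitatDegradation:
    def test_no_threats_zero(self):
        lu = make_lu(np.ones((5, 5)))
        assert np.all(habitat_degradation(lu, []).values == 0.0)

    def test_insensitive_class_untouched(self):
        lu = make_lu(np.ones((5, 5)))  # forest everywhere
        src = lu.like(np.zeros((5, 5)))
        src.values[0, 0] = 1
        threat = ThreatSpec("x", src, max_dist_m=10000.0, weight=1.0,
                            sensitivity={"forest": 0.0})
        assert np.all(habitat_degradation(lu, [threat]).values == 0.0)

    def test_linear_decay_halfway(self):
        lu = make_lu(np.ones((1, 5)), cell_size=1000.0)
        src = lu.like(np.zeros((1, 5)))
        src.values[0, 0] = 1
        threat = ThreatSpec("x", src, max_dist_m=4000.0, weight=1.0,
                            decay="linear", sensitivity={"forest": 1.0})
        D = habitat_degradation(lu, [threat])
        assert D.values[0, 2] == pytest.approx(0.5)  # d = d_max/2

    def test_exponential_decay_constant(self):
        lu = make_lu(np.ones((1, 3)), cell_size=1000.0)
        src = lu.like(np.zeros((1, 3)))
        src.values[0, 0] = 1
        threat = ThreatSpec("x", src, max_dist_m=2000.0, weight=1.0,
                            sensitivity={"forest": 1.0})
        D = habitat_degradation(lu, [threat])
        assert D.values[0, 1] == pytest.approx(np.exp(-2.99 / 2))

    def test_empty_threat_warns_and_contributes_zero(self):
        lu = make_lu(np.ones((3, 3)))
        src = lu.like(np.zeros((3, 3)))
        threat = ThreatSpec("ghost", src, max_dist_m=1000.0, weight=1.0,
                            sensitivity={"forest": 1.0})
        with pytest.warns(UserWarning, match="ghost"):
            D = habitat_degradation(lu, [threat])
        assert np.all(D.values == 0.0)


class TestHabitatQuality:
    def test_no_degradation_returns_suitability(self, bio):
        lu = make_lu([[1, 4]])  # forest H=1, urban H=0
        D = lu.like(np.zeros((1, 2)))
        q = habitat_quality(lu, D, bio)
        assert q.values[0, 0] == 1.0 and q.values[0, 1] == 0.0

    @pytest.mark.parametrize("z", [1.0, 2.0, 2.5, 4.0])
    def test_half_saturation_identity(self, bio, z):
        lu = make_lu([[1]])
        D = lu.like(np.full((1, 1), 0.37))
        q = habitat_quality(lu, D, bio, k_half=0.37, z=z)
        assert q.values[0, 0] == pytest.approx(0.5)

    def test_scalar_evaluation(self):
        table = default_biophysical_table().table.copy()
        table.loc["forest", "habitat"] = 0.8
        bio = BiophysicalTable(table)
        lu = make_lu([[1]])
        D = lu.like(np.ones((1, 1)))
        q = habitat_quality(lu, D, bio, k_half=0.5, z=2.5)
        expect = 0.8 * (1 - 1 / (0.5**2.5 + 1))
        assert q.values[0, 0] == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.1202, abs=5e-5)

    def test_strictly_decreasing_in_degradation(self, bio):
        lu = make_lu(np.full((1, 10), 1))
        d_vals = np.linspace(0, 2, 10).reshape(1, 10)
        q = habitat_quality(lu, lu.like(d_vals), bio, k_half=0.5)
        assert np.all(np.diff(q.values[0]) < 0)


class TestServiceStack:
    def test_contract_run(self, bundle60):
        stack = compute_service_stack(
            bundle60.landuse_t0, bundle60.precip_annual,
            bundle60.precip_monthly, bundle60.pet, bundle60.dem,
            bundle60.awc, bundle60.root_depth, bundle60.soil_erodibility_K,
            dist_road=bundle60.dist_road)
        stack.validate()
        assert np.all(stack.wy.values <= bundle60.precip_annual.values + 1e-9)

    def test_doubling_precip_increases_yield(self, bundle60):
        args = (bundle60.pet, bundle60.awc, bundle60.root_depth,
                bundle60.landuse_t0, default_biophysical_table())
        wy1 = water_yield(bundle60.precip_annual, *args)
        double = bundle60.precip_annual.like(2 * bundle60.precip_annual.values)
        wy2 = water_yield(double, *args)
        assert wy2.valid_values.sum() > wy1.valid_values.sum()

    def test_urbanizing_grassland_lowers_habitat_quality(self, bundle60):
        bio = default_biophysical_table()
        lu = bundle60.landuse_t0
        urbanized = make_lu(np.where(lu.values == 2, 4, lu.values),
                            nodata_mask=lu.nodata_mask.copy(),
                            cell_size=lu.cell_size, origin=lu.origin)
        def hq_mean(m):
            from landes.services import default_threats
            D = habitat_degradation(m, default_threats(m))
            return habitat_quality(m, D, bio).mean()
        assert hq_mean(urbanized) < hq_mean(lu)
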