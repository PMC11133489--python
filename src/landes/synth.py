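"""Synthetic study areas for an endorheic arid basin.

Every downstream stage (climate correction, the land-use cellular automaton,
the ecosystem-service models, the trade-off analysis) is exercised on fully
synthetic landscapes generated here.  The generator emulates the *structure*
of the real inputs — an east-high / west-low terrain, precipitation rising
and temperature falling with elevation, a strongly evaporative (arid)
climate with a domain-mean annual precipitation of 236 mm, soil surfaces,
driver layers (population, distance to roads and water) and a spatially
autocorrelated six-class land-use map — not a calibrated Central-Asian
climatology.

The map at a later date ``t1`` is produced by :func:`evolve_landuse`, a
*known* transition process (logistic suitability in the drivers plus ranked
allocation) so that the cellular automaton's ability to recover the
transition can be scored against a fixed truth.  Its class counts match the
returned demand table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (CLASS_CODES, CLASS_NAMES, N_CLASSES, Grid, LandUseMap,
                    assert_aligned, class_census, distance_surface)

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "LandscapeBundle",
    "generate_dem",
    "generate_climate",
    "generate_drivers",
    "generate_landuse_t0",
    "evolve_landuse",
    "generate_bundle",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Per-scenario demand changes and climate deltas over the horizon.

    ``demand_change`` maps class name -> relative change of its cell count
    over the full horizon (e.g. +0.79 means +79 %).  ``precip_multiplier``
    and ``temp_offset`` give one climate delta per future period, in order.
    """

    name: str
    demand_change: dict[str, float]
    precip_multiplier: tuple[float, ...] = (1.0,)
    temp_offset: tuple[float, ...] = (0.0,)

    def demand_targets(self, census: dict[str, int],
                       fraction: float = 1.0) -> dict[str, int]:
        """Target census after applying ``fraction`` of the full change.

        The residual from rounding is absorbed by the largest class so the
        targets always sum to the input total.
        """
        total = sum(census.values())
        targets = {}
        for name in CLASS_NAMES:
            change = self.demand_change.get(name, 0.0) * fraction
            targets[name] = max(0, int(round(census[name] * (1.0 + change))))
        # absorb rounding residual into the most populous class
        resid = total - sum(targets.values())
        sink = max(census, key=lambda n: census[n])
        targets[sink] += resid
        if targets[sink] < 0:
            raise ValueError("demanded change exceeds available cells")
        return targets


#: Scenario presets. Demand changes sit inside the reported scenario
#: envelopes (urban +27.09..+134.95 %, cropland −0.63..−16.73 %, grassland
#: −0.18..−15.48 %, barren +0.45..+14.52 %); water declines most under the
#: high-forcing pathway.  Climate deltas span the four future periods.
PRESETS: dict[str, ScenarioPreset] = {
    "SSP126": ScenarioPreset(
        "SSP126",
        {"urban": 1.20, "cropland": -0.02, "grassland": -0.03,
         "barren": 0.01, "forest": -0.01, "water": -0.05},
        precip_multiplier=(1.02, 1.03, 1.04, 1.04),
        temp_offset=(0.8, 1.1, 1.2, 1.2)),
    "SSP245": ScenarioPreset(
        "SSP245",
        {"urban": 0.79, "cropland": -0.12, "grassland": -0.10,
         "barren": 0.10, "forest": -0.03, "water": -0.15},
        precip_multiplier=(1.02, 1.04, 1.05, 1.06),
        temp_offset=(1.0, 1.6, 2.1, 2.5)),
    "SSP370": ScenarioPreset(
        "SSP370",
        {"urban": 0.65, "cropland": -0.08, "grassland": -0.08,
         "barren": 0.08, "forest": -0.04, "water": -0.25},
        precip_multiplier=(1.01, 1.03, 1.05, 1.07),
        temp_offset=(1.1, 2.0, 3.0, 3.9)),
    "SSP585": ScenarioPreset(
        "SSP585",
        {"urban": 0.55, "cropland": -0.05, "grassland": -0.06,
         "barren": 0.06, "forest": -0.05, "water": -0.40},
        precip_multiplier=(1.02, 1.05, 1.08, 1.10),
        temp_offset=(1.2, 2.3, 3.5, 4.8)),
}


@dataclass
class LandscapeBundle:
    """All aligned layers of one synthetic study area."""

    dem: Grid
    precip_annual: Grid
    precip_monthly: list[Grid]
    temp: Grid
    pet: Grid
    soil_erodibility_K: Grid
    awc: Grid
    root_depth: Grid
    pop_density: Grid
    dist_road: Grid
    dist_water: Grid
    landuse_t0: LandUseMap
    landuse_t1: LandUseMap
    true_demands: dict[str, int]
    annual_precip_series: np.ndarray = field(default_factory=lambda: np.array([]))

    def grids(self) -> list[Grid]:
        return [self.dem, self.precip_annual, *self.precip_monthly, self.temp,
                self.pet, self.soil_erodibility_K, self.awc, self.root_depth,
                self.pop_density, self.dist_road, self.dist_water,
                self.landuse_t0, self.landuse_t1]

    def validate(self) -> None:
        assert_aligned(*self.grids())
        monthly_sum = sum(g.values for g in self.precip_monthly)
        if not np.allclose(monthly_sum, self.precip_annual.values, rtol=1e-6):
            raise ValueError("monthly precipitation does not sum to annual")
        if class_census(self.landuse_t1) != self.true_demands:
            raise ValueError("true_demands does not match the t1 census")

    def driver_stack(self) -> np.ndarray:
        """Driver layers as an (n_cells, n_drivers) array over valid cells."""
        names = self.driver_names()
        arrs = [getattr(self, n).values for n in names]
        valid = ~self.dem.nodata_mask
        return np.column_stack([a[valid] for a in arrs])

    @staticmethod
    def driver_names() -> tuple[str, ...]:
        return ("dem", "precip_annual", "temp", "pop_density", "dist_road",
                "dist_water")


# ---------------------------------------------------------------------------
# terrain and climate
# ---------------------------------------------------------------------------

def _fractal_noise(shape: tuple[int, int], rng: np.random.Generator,
                   beta: float = 2.0) -> np.ndarray:
    """Spatially autocorrelated noise via spectral (1/f^beta) synthesis,
    standardized to zero mean and unit variance."""
    white = rng.standard_normal(shape)
    f = np.fft.fft2(white)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    radius[0, 0] = radius.flat[np.abs(radius.flatten()).argsort()[1]]
    filt = radius ** (-beta / 2.0)
    field = np.real(np.fft.ifft2(f * filt))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_dem(shape: tuple[int, int], seed: int,
                 base: float = 200.0, relief: float = 2600.0,
                 noise_sd: float = 260.0, cell_size: float = 1000.0) -> Grid:
    """East-high / west-low terrain with fractal relief, clamped to [0, 5000] m.

    Deterministic per seed; the eastern half's mean elevation strictly
    exceeds the western half's.
    """
    if shape[0] < 20 or shape[1] < 20:
        raise ValueError("shape must be at least 20x20")
    rng = np.random.default_rng(seed)
    cols = np.linspace(0.0, 1.0, shape[1])[None, :]
    ramp = base + relief * cols**1.3
    noise = _fractal_noise(shape, rng) * noise_sd
    dem = np.clip(ramp + noise, 0.0, 5000.0)
    return Grid(dem, cell_size=cell_size)


def generate_climate(dem: Grid, preset: ScenarioPreset | None = None,
                     seed: int = 0, mean_precip: float = 236.0,
                     period_index: int | None = None,
                     noise_sd: float = 0.15, n_years: int = 20) -> dict:
    """Elevation-coupled precipitation, temperature and PET surfaces.

    Precipitation increases with elevation (orographic) with multiplicative
    lognormal noise, rescaled to the configured domain mean (236 mm/yr by
    default, the arid-basin figure).  Temperature falls with elevation at a
    6.0 °C/km lapse rate with Gaussian noise.  PET is driven by temperature
    and sized so the landscape is arid (PET >= P on at least half of the
    cells).  ``noise_sd = 0`` gives exactly affine precip/temp in the DEM.

    Returns a dict with ``precip_annual``, ``precip_monthly`` (12 grids
    summing to the annual grid), ``temp``, ``pet`` and a 20-year domain-mean
    annual precip series.
    """
    rng = np.random.default_rng(seed)
    z = dem.values
    # orographic gradient: ~40 mm per km of elevation around the target mean
    raw = 1.0 + 0.55 * (z - z.mean()) / 1000.0
    if noise_sd > 0:
        sigma = np.sqrt(np.log(1.0 + noise_sd**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, z.shape))
        noise = ndimage.gaussian_filter(noise, 2.0)
        raw = raw * noise
    raw = np.clip(raw, 0.05, None)
    precip = raw * (mean_precip / raw[~dem.nodata_mask].mean())

    temp = 24.0 - 6.0 * z / 1000.0
    if noise_sd > 0:
        temp = temp + ndimage.gaussian_filter(
            rng.normal(0.0, 8.0 * noise_sd, z.shape), 2.0)

    if preset is not None:
        k = period_index if period_index is not None else -1
        precip = precip * preset.precip_multiplier[k]
        temp = temp + preset.temp_offset[k]

    # Hargreaves-flavoured PET: warm lowlands evaporate far more than they
    # receive; scaled so the hottest cells approach ~1700 mm/yr.
    pet = np.clip(70.0 * np.clip(temp, 0.0, None) ** 1.0, 50.0, None)

    # monthly split: mild winter/spring peak typical of continental aridity
    month_w = np.array([.06, .07, .10, .12, .11, .08,
                        .06, .05, .06, .08, .10, .11])
    month_w = month_w / month_w.sum()
    monthly = [dem.like(precip * w) for w in month_w]

    series = mean_precip * np.exp(
        rng.normal(-0.5 * 0.04, 0.2, n_years))  # interannual variability
    return {
        "precip_annual": dem.like(precip),
        "precip_monthly": monthly,
        "temp": dem.like(temp),
        "pet": dem.like(pet),
        "annual_precip_series": series,
    }


def generate_soils(dem: Grid, seed: int) -> dict:
    """Erodibility K, available water capacity and root-restricting depth."""
    rng = np.random.default_rng(seed)
    n1 = _fractal_noise(dem.shape, rng)
    n2 = _fractal_noise(dem.shape, rng)
    n3 = _fractal_noise(dem.shape, rng)
    k = np.clip(0.28 + 0.07 * n1, 0.05, 0.6)          # t·h/(MJ·mm)-ish
    awc = np.clip(0.12 + 0.04 * n2 - 0.02 * dem.values / 5000.0, 0.02, 0.3)
    root = np.clip(1200.0 + 500.0 * n3 - 0.1 * dem.values, 100.0, 3000.0)
    return {"soil_erodibility_K": dem.like(k), "awc": dem.like(awc),
            "root_depth": dem.like(root)}


def generate_drivers(dem: Grid, seed: int, n_roads: int = 3) -> dict:
    """Road network (a few random polylines), distance-to-road and a
    population surface concentrated in the low, road-served west."""
    rng = np.random.default_rng(seed)
    nr, nc = dem.shape
    road = np.zeros(dem.shape)
    for _ in range(n_roads):
        r0, r1 = rng.integers(0, nr, 2)
        c0, c1 = sorted(rng.integers(0, nc, 2))
        length = max(abs(int(r1) - int(r0)), c1 - c0, 1)
        rows = np.round(np.linspace(r0, r1, length + 1)).astype(int)
        cols = np.round(np.linspace(c0, c1, length + 1)).astype(int)
        road[rows, cols] = 1
    dist_road = distance_surface(dem.like(road))
    pop = np.exp(-dist_road.values / 15000.0) * np.exp(-dem.values / 1500.0)
    pop = 500.0 * pop * np.exp(0.5 * _fractal_noise(dem.shape, rng))
    return {"dist_road": dist_road, "pop_density": dem.like(pop)}


# ---------------------------------------------------------------------------
# land use
# ---------------------------------------------------------------------------

#: Default class shares of the initial map (arid basin: barren-dominated).
DEFAULT_SHARES = {"cropland": 0.20, "forest": 0.08, "grassland": 0.28,
                  "water": 0.08, "urban": 0.04, "barren": 0.32}


def _class_potentials(dem: Grid, precip: Grid, dist_road: Grid,
                      pop: Grid, rng: np.random.Generator,
                      noise_scale: float = 0.8) -> np.ndarray:
    """Per-class affinity fields (standardized drivers + smooth noise)."""
    def z(a):
        a = a.values
        return (a - a.mean()) / (a.std() + 1e-12)

    zd, zp, zr, zpop = z(dem), z(precip), z(dist_road), z(pop)
    pot = np.empty((N_CLASSES,) + dem.shape)
    pot[CLASS_CODES["cropland"]] = -0.6 * zd + 0.5 * zp - 0.4 * zr + 0.3 * zpop
    pot[CLASS_CODES["forest"]] = 0.9 * zd + 0.8 * zp
    pot[CLASS_CODES["grassland"]] = 0.3 * zd + 0.6 * zp
    pot[CLASS_CODES["water"]] = -1.5 * zd
    pot[CLASS_CODES["urban"]] = -0.9 * zr + 0.9 * zpop - 0.3 * zd
    pot[CLASS_CODES["barren"]] = -0.8 * zp - 0.2 * zd + 0.3 * zr
    for k in range(N_CLASSES):
        pot[k] += noise_scale * _fractal_noise(dem.shape, rng, beta=2.5)
    return pot


def _allocate_by_rank(pot: np.ndarray, counts: dict[str, int],
                      mask_valid: np.ndarray) -> np.ndarray:
    """Greedy ranked allocation: repeatedly give the globally best remaining
    (cell, class) affinity its class, respecting per-class quotas."""
    nr, nc = mask_valid.shape
    flat_valid = np.flatnonzero(mask_valid.ravel())
    n = flat_valid.size
    quotas = np.array([counts[name] for name in CLASS_NAMES], dtype=np.int64)
    scores = pot.reshape(N_CLASSES, -1)[:, flat_valid]  # (K, n)
    order = np.argsort(scores, axis=None)[::-1]
    out = np.full(n, -1, dtype=np.int16)
    remaining = n
    for idx in order:
        k, i = divmod(idx, n)
        if out[i] >= 0 or quotas[k] == 0:
            continue
        out[i] = k
        quotas[k] -= 1
        remaining -= 1
        if remaining == 0:
            break
    full = np.zeros(nr * nc, dtype=np.int16)
    full[flat_valid] = out
    return full.reshape(nr, nc)


def generate_landuse_t0(dem: Grid, precip: Grid, dist_road: Grid, pop: Grid,
                        seed: int,
                        shares: dict[str, float] | None = None) -> LandUseMap:
    """Initial six-class map by ranked allocation of class-affinity fields.

    All six classes are present at the configured shares, water sits in the
    low west, and the smooth affinity noise gives spatial autocorrelation
    well above a random labeling.
    """
    assert_aligned(dem, precip, dist_road, pop)
    shares = dict(DEFAULT_SHARES if shares is None else shares)
    rng = np.random.default_rng(seed)
    valid = ~dem.nodata_mask
    n = int(valid.sum())
    counts = {name: int(round(shares[name] * n)) for name in CLASS_NAMES}
    sink = max(counts, key=lambda c: counts[c])
    counts[sink] += n - sum(counts.values())
    pot = _class_potentials(dem, precip, dist_road, pop, rng)
    values = _allocate_by_rank(pot, counts, valid)
    return LandUseMap(values, dem.nodata_mask.copy(), dem.cell_size, dem.origin)


def evolve_landuse(t0: LandUseMap, preset: ScenarioPreset, drivers: dict,
                   seed: int, fraction: float = 1.0,
                   noise_scale: float = 0.35
                   ) -> tuple[LandUseMap, dict[str, int]]:
    """Advance ``t0`` by a *known* transition process; return (t1, demands).

    Suitability for each growing class is a fixed logistic function of the
    drivers — urban growth favours road-near, populous cells; water is lost
    first from its shallow (high-elevation, dry) fringe — plus smooth noise.
    Growing classes claim the best-scoring cells of shrinking classes until
    every class hits its target count, so ``census(t1) == demands`` exactly
    and cells only flip class (no creation).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    census = class_census(t0)
    demands = preset.demand_targets(census, fraction)
    gaps = {n: demands[n] - census[n] for n in CLASS_NAMES}
    growers = [n for n in CLASS_NAMES if gaps[n] > 0]
    surplus = {n: -gaps[n] for n in CLASS_NAMES if gaps[n] < 0}
    if sum(surplus.values()) < sum(gaps[g] for g in growers):
        raise ValueError("demanded change exceeds convertible cells")

    dem, precip = drivers["dem"], drivers["precip_annual"]
    dist_road, pop = drivers["dist_road"], drivers["pop_density"]
    pot = _class_potentials(dem, precip, dist_road, pop, rng,
                            noise_scale=noise_scale)

    values = t0.values.copy()
    valid = ~t0.nodata_mask
    classes_flat = values[valid]
    flat_index = np.flatnonzero(valid.ravel())
    # growers with the largest absolute demand claim first
    for g in sorted(growers, key=lambda n: -gaps[n]):
        need = gaps[g]
        score = pot[CLASS_CODES[g]].ravel()[flat_index]
        order = np.argsort(score)[::-1]
        taken = 0
        for i in order:
            c = CLASS_NAMES[classes_flat[i]]
            if c == g or surplus.get(c, 0) <= 0:
                continue
            classes_flat[i] = CLASS_CODES[g]
            surplus[c] -= 1
            taken += 1
            if taken == need:
                break
        if taken < need:  # pragma: no cover - guarded by the sum check
            raise ValueError(f"could not satisfy demand for {g}")
    out = np.zeros_like(values).ravel()
    out[flat_index] = classes_flat
    t1 = LandUseMap(out.reshape(values.shape), t0.nodata_mask.copy(),
                    t0.cell_size, t0.origin)
    assert class_census(t1) == demands
    return t1, demands


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_bundle(shape: tuple[int, int] = (100, 100), seed: int = 0,
                    preset: str | ScenarioPreset = "SSP245",
                    mean_precip: float = 236.0,
                    cell_size: float = 1000.0,
                    shares: dict[str, float] | None = None) -> LandscapeBundle:
    """Generate a complete, internally consistent synthetic study area.

    A pure function of (configuration, seed).  The ``landuse_t1`` layer is
    the output of :func:`evolve_landuse` under the chosen scenario preset,
    with ``true_demands`` equal to its census.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    s_dem, s_clim, s_soil, s_drv, s_lu, s_ev = rng.integers(0, 2**31 - 1, 6)
    dem = generate_dem(shape, int(s_dem), cell_size=cell_size)
    clim = generate_climate(dem, None, int(s_clim), mean_precip=mean_precip)
    soils = generate_soils(dem, int(s_soil))
    drv = generate_drivers(dem, int(s_drv))
    t0 = generate_landuse_t0(dem, clim["precip_annual"], drv["dist_road"],
                             drv["pop_density"], int(s_lu), shares=shares)
    dist_water = distance_surface(dem.like(
        (t0.values == CLASS_CODES["water"]).astype(float)))
    drivers = {"dem": dem, "precip_annual": clim["precip_annual"],
               "temp": clim["temp"], "pop_density": drv["pop_density"],
               "dist_road": drv["dist_road"], "dist_water": dist_water}
    t1, demands = evolve_landuse(t0, preset, drivers, int(s_ev))
    bundle = LandscapeBundle(
        dem=dem, precip_annual=clim["precip_annual"],
        precip_monthly=clim["precip_monthly"], temp=clim["temp"],
        pet=clim["pet"], soil_erodibility_K=soils["soil_erodibility_K"],
        awc=soils["awc"], root_depth=soils["root_depth"],
        pop_density=drv["pop_density"], dist_road=drv["dist_road"],
        dist_water=dist_water, landuse_t0=t0, landuse_t1=t1,
        true_demands=demands,
        annual_precip_series=clim["annual_precip_series"])
    bundle.validate()
    return bundle
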