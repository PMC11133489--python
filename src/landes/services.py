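"""Ecosystem-service layers: water yield, soil conservation, carbon
storage and habitat quality.

Water yield follows the Budyko framework in the Zhang/Fu form used by
annual water-yield models: the evaporative fraction is

    AET/P = 1 + PET'/P − (1 + (PET'/P)^ω)^(1/ω),   ω = Z·AWC_eff/P + 1.25

with ``PET' = Kc·PET`` (a per-class crop coefficient), ``AWC_eff`` the
plant-available water in the rooting zone, and ``Z`` a seasonality
constant.  Yield is ``Y = (1 − AET/P)·P`` and is bounded by ``0 ≤ Y ≤ P``.

Soil conservation is USLE retention, ``ΔUSLE = R·K·LS·(1 − C·P)``: the
erosion a cell's cover and practice factors avoid relative to bare ground.
The rainfall erosivity R uses a monthly Wischmeier-type formula and LS the
Desmet–Govers slope-length formulation over a D8 flow accumulation.

Carbon storage is stock accounting: four per-class pool densities (above-
and below-ground, soil, dead organic matter, t/ha) times cell area.

Habitat quality degrades a per-class suitability ``H_j`` by distance-
decayed, sensitivity-weighted threat exposure ``D`` through the
half-saturation response ``Q = H_j·(1 − D^z/(k^z + D^z))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import (CLASS_CODES, CLASS_NAMES, N_CLASSES, Grid, LandUseMap,
                    assert_aligned)

__all__ = [
    "BiophysicalTable", "ThreatSpec", "ServiceStack",
    "water_yield", "rainfall_erosivity", "ls_factor", "soil_conservation",
    "carbon_storage", "habitat_degradation", "habitat_quality",
    "compute_service_stack", "default_biophysical_table", "default_threats",
]


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

_BIO_COLUMNS = ("usle_C", "usle_P", "c_above", "c_below", "c_soil", "c_dead",
                "habitat", "Kc", "root_depth_mm")


@dataclass
class BiophysicalTable:
    """Per-class biophysical parameters (USLE C/P, carbon pools t/ha,
    habitat suitability, crop coefficient, rooting-depth cap)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _BIO_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"biophysical table missing columns {missing}")
        absent = [n for n in CLASS_NAMES if n not in self.table.index]
        if absent:
            raise ValueError(f"biophysical table missing classes {absent}")
        for col in ("usle_C", "usle_P", "habitat"):
            v = self.table[col]
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} must lie in [0,1]")
        if ((self.table["usle_C"] * self.table["usle_P"]) > 1).any():
            raise ValueError("C*P exceeds 1 for some class")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiophysicalTable":
        df = pd.read_csv(path).set_index("class")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.rename_axis("class").to_csv(path)

    def per_class(self, column: str) -> np.ndarray:
        """Values of one parameter in class-code order."""
        return np.array([float(self.table.loc[n, column])
                         for n in CLASS_NAMES])

    def lookup(self, column: str, lu: LandUseMap) -> np.ndarray:
        """Rasterize one parameter over a land-use map."""
        lut = self.per_class(column)
        out = np.zeros(lu.shape)
        v = ~lu.nodata_mask
        out[v] = lut[lu.values[v].astype(int)]
        return out


def default_biophysical_table() -> BiophysicalTable:
    """Editable defaults for an arid six-class landscape (t/ha pools)."""
    rows = {
        #            C     P   c_ab c_be c_so c_de  hab   Kc   root
        "cropland": (0.25, 0.40, 5.0, 4.0, 55.0, 1.0, 0.40, 0.95, 900.0),
        "forest":   (0.003, 1.00, 60.0, 15.0, 90.0, 5.0, 1.00, 1.00, 2500.0),
        "grassland": (0.05, 1.00, 3.0, 6.0, 65.0, 1.5, 0.75, 0.65, 1200.0),
        "water":    (0.00, 1.00, 0.0, 0.0, 0.0, 0.0, 0.90, 1.00, 10.0),
        "urban":    (0.01, 1.00, 1.0, 0.5, 20.0, 0.2, 0.00, 0.30, 300.0),
        "barren":   (0.35, 1.00, 0.3, 0.3, 15.0, 0.1, 0.10, 0.20, 200.0),
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_BIO_COLUMNS)
    return BiophysicalTable(df)


@dataclass
class ThreatSpec:
    """One degradation source: binary source map, reach, weight, decay and
    per-class sensitivities."""

    name: str
    source: Grid                     # {0,1}
    max_dist_m: float
    weight: float
    decay: str = "exponential"       # or "linear"
    sensitivity: dict[str, float] = field(default_factory=dict)
    accessibility: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weight:
            raise ValueError("threat weight must be positive")
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")
        for n, s in self.sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity S[{n},{self.name}] outside [0,1]")


def default_threats(lu: LandUseMap, dist_road: Grid | None = None
                    ) -> list[ThreatSpec]:
    """Default threat set for arid basins: urban, cropland and roads."""
    threats = [
        ThreatSpec("urban", lu.like(
            (lu.values == CLASS_CODES["urban"]).astype(float)),
            max_dist_m=10000.0, weight=1.0,
            sensitivity={"cropland": 0.3, "forest": 0.8, "grassland": 0.6,
                         "water": 0.7, "urban": 0.0, "barren": 0.1}),
        ThreatSpec("cropland", lu.like(
            (lu.values == CLASS_CODES["cropland"]).astype(float)),
            max_dist_m=8000.0, weight=0.7,
            sensitivity={"cropland": 0.0, "forest": 0.6, "grassland": 0.5,
                         "water": 0.6, "urban": 0.0, "barren": 0.1}),
    ]
    if dist_road is not None:
        road_src = lu.like((dist_road.values == 0).astype(float))
        threats.append(ThreatSpec(
            "road", road_src, max_dist_m=5000.0, weight=0.5,
            sensitivity={"cropland": 0.1, "forest": 0.5, "grassland": 0.4,
                         "water": 0.3, "urban": 0.0, "barren": 0.05}))
    return threats


@dataclass
class ServiceStack:
    """The four aligned service layers plus the elevation-zone map."""

    wy: Grid            # mm
    sc: Grid            # t/cell/yr
    cs: Grid            # t/cell
    hq: Grid            # [0,1]
    zones: Grid | None = None

    def validate(self) -> None:
        grids = [self.wy, self.sc, self.cs, self.hq]
        if self.zones is not None:
            grids.append(self.zones)
        assert_aligned(*grids)
        for g, name, lo in ((self.wy, "wy", 0), (self.sc, "sc", 0)):
            if np.any(g.valid_values < lo - 1e-9):
                raise ValueError(f"{name} has negative cells")
        hq = self.hq.valid_values
        if np.any((hq < -1e-9) | (hq > 1 + 1e-9)):
            raise ValueError("hq outside [0,1]")

    def layers(self) -> dict[str, Grid]:
        return {"WY": self.wy, "SC": self.sc, "CS": self.cs, "HQ": self.hq}

    def summary(self) -> pd.DataFrame:
        cell_ha = self.wy.cell_area_ha
        rows = {
            "WY_mean_mm": self.wy.mean(),
            "WY_total_m3": float(self.wy.valid_values.sum()
                                 * self.wy.cell_area_m2 / 1000.0),
            "SC_total_t": float(self.sc.valid_values.sum()),
            "CS_total_t": float(self.cs.valid_values.sum()),
            "HQ_mean": self.hq.mean(),
            "cell_area_ha": cell_ha,
        }
        return pd.DataFrame([rows])


# ---------------------------------------------------------------------------
# water yield (Budyko)
# ---------------------------------------------------------------------------

def budyko_aet_fraction(pet_over_p: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Zhang/Fu evaporative fraction AET/P for aridity index PET'/P."""
    phi = np.asarray(pet_over_p, dtype=float)
    return 1.0 + phi - (1.0 + phi**omega) ** (1.0 / omega)


def water_yield(precip: Grid, pet: Grid, awc: Grid, root_depth: Grid,
                lu: LandUseMap, bio: BiophysicalTable,
                Z: float = 5.0) -> Grid:
    """Annual water yield Y = (1 − AET/P)·P (mm) under the Budyko curve.

    ``AWC_eff`` is the water held in the rooting zone: the smaller of the
    soil's root-restricting depth and the class rooting cap, times the
    volumetric available water capacity.  Cells with zero precipitation
    yield zero.
    """
    assert_aligned(precip, pet, awc, root_depth, lu)
    for g, name in ((precip, "precip"), (pet, "pet"), (awc, "awc"),
                    (root_depth, "root_depth")):
        if np.any(g.valid_values < 0):
            raise ValueError(f"negative {name} values")
    P = precip.values
    kc = bio.lookup("Kc", lu)
    root_cap = bio.lookup("root_depth_mm", lu)
    pet_eff = kc * pet.values
    awc_eff = np.minimum(root_depth.values, root_cap) * awc.values
    y = np.zeros(P.shape)
    pos = (P > 0) & ~precip.nodata_mask
    omega = Z * awc_eff[pos] / P[pos] + 1.25
    aet_frac = budyko_aet_fraction(pet_eff[pos] / P[pos], omega)
    aet_frac = np.clip(aet_frac, 0.0, 1.0)
    y[pos] = (1.0 - aet_frac) * P[pos]
    return precip.like(y)


# ---------------------------------------------------------------------------
# soil conservation (USLE)
# ---------------------------------------------------------------------------

def rainfall_erosivity(precip_monthly: list[Grid], a: float = 1.735,
                       b: float = 0.8188) -> Grid:
    """Monthly Wischmeier-type erosivity R = Σ_m a·10^(1.5·log10(p_m²/P) − b).

    Equivalently a·10^(−b)·Σ (p_m²/P)^1.5.  Zero-precipitation cells get
    R = 0; doubling every month strictly increases R.  The coefficients are
    exposed so a locally calibrated formula can be substituted.
    """
    if len(precip_monthly) != 12:
        raise ValueError("twelve monthly grids required")
    assert_aligned(*precip_monthly)
    p = np.stack([g.values for g in precip_monthly])
    annual = p.sum(axis=0)
    r = np.zeros(annual.shape)
    pos = annual > 0
    ratio = np.where(pos[None, :, :], p**2 / np.where(pos, annual, 1.0), 0.0)
    r[pos] = (a * 10.0**(-b) * (ratio ** 1.5).sum(axis=0))[pos]
    return precip_monthly[0].like(r)


def _d8_flow_accumulation(dem: Grid) -> np.ndarray:
    """Upslope contributing area (m²) by single-direction (D8) routing."""
    z = dem.values
    nr, nc = z.shape
    cell = dem.cell_size
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0),
               (1, 1)]
    dists = np.array([np.hypot(dr, dc) for dr, dc in offsets]) * cell
    # steepest-descent receiver per cell
    best_slope = np.full((nr, nc), 0.0)
    rec_r = np.full((nr, nc), -1)
    rec_c = np.full((nr, nc), -1)
    for (dr, dc), d in zip(offsets, dists):
        zn = np.full((nr, nc), np.inf)
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        zn[r0:r1, c0:c1] = z[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        slope = (z - zn) / d
        better = slope > best_slope
        best_slope = np.where(better, slope, best_slope)
        rr, cc = np.indices((nr, nc))
        rec_r = np.where(better, rr + dr, rec_r)
        rec_c = np.where(better, cc + dc, rec_c)
    area = np.full((nr, nc), cell * cell)
    order = np.argsort(z.ravel())[::-1]  # high to low
    flat_rec = np.where(rec_r.ravel() >= 0,
                        rec_r.ravel() * nc + rec_c.ravel(), -1)
    area_flat = area.ravel()
    for idx in order:
        rec = flat_rec[idx]
        if rec >= 0:
            area_flat[rec] += area_flat[idx]
    return area_flat.reshape(nr, nc)


def ls_factor(dem: Grid, slope_floor: float = 0.001,
              m_exponent: str = "dynamic") -> Grid:
    """Desmet–Govers LS factor from the DEM.

    Slope comes from central differences (floored at 0.1 %); the length
    factor uses the D8 upslope contributing area; the slope factor is the
    McCool piecewise form.  Flat terrain takes the documented minimum and
    LS grows monotonically with gradient on uniform ramps.
    """
    z = dem.values
    cell = dem.cell_size
    gy, gx = np.gradient(z, cell)
    grad = np.sqrt(gx**2 + gy**2)
    grad = np.maximum(grad, slope_floor)
    theta = np.arctan(grad)
    sin_t = np.sin(theta)
    # McCool slope factor
    s = np.where(grad < 0.09, 10.8 * sin_t + 0.03, 16.8 * sin_t - 0.5)
    # Desmet–Govers length factor
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)
    area_in = _d8_flow_accumulation(dem) - cell * cell  # inflow area
    area_in = np.maximum(area_in, 0.0)
    x = 1.0  # aspect correction neutralized (documented simplification)
    num = (area_in + cell**2) ** (m + 1.0) - area_in ** (m + 1.0)
    den = cell ** (m + 2.0) * x**m * 22.13**m
    length = num / den
    return dem.like(np.maximum(length * s, 0.0))


def soil_conservation(R: Grid, K: Grid, LS: Grid, lu: LandUseMap,
                      bio: BiophysicalTable) -> Grid:
    """USLE retention ΔUSLE = R·K·LS·(1 − C·P) per cell (t/cell/yr).

    R·K·LS is potential erosion on bare ground; the per-class cover (C) and
    practice (P) factors scale actual loss, and their complement is the
    conserved fraction.  The product is taken per cell exactly as written,
    so absolute units follow the calibration of R and K.
    """
    assert_aligned(R, K, LS, lu)
    c = bio.lookup("usle_C", lu)
    p = bio.lookup("usle_P", lu)
    if np.any(c * p > 1.0 + 1e-12):
        raise ValueError("C*P exceeds 1")
    rkls = R.values * K.values * LS.values
    sc = rkls * (1.0 - c * p)
    return R.like(np.where(lu.nodata_mask, 0.0, sc))


# ---------------------------------------------------------------------------
# carbon storage
# ---------------------------------------------------------------------------

def carbon_storage(lu: LandUseMap, bio: BiophysicalTable) -> Grid:
    """Per-cell carbon stock (t): sum of the four pool densities for the
    cell's class times cell area in hectares."""
    total_density = sum(bio.lookup(c, lu)
                        for c in ("c_above", "c_below", "c_soil", "c_dead"))
    cs = total_density * lu.cell_area_ha
    return lu.like(np.where(lu.nodata_mask, 0.0, cs))


# ---------------------------------------------------------------------------
# habitat quality
# ---------------------------------------------------------------------------

def _decay_weights(dist: np.ndarray, max_dist: float, decay: str) -> np.ndarray:
    if decay == "linear":
        w = 1.0 - dist / max_dist
    else:
        w = np.exp(-2.99 * dist / max_dist)
    return np.where(dist <= max_dist, np.clip(w, 0.0, None), 0.0)


def habitat_degradation(lu: LandUseMap, threats: list[ThreatSpec],
                        chunk: int = 2048) -> Grid:
    """Weighted, distance-decayed threat exposure D per cell.

    For each threat the decay is *averaged over all its source cells*
    (``(1/Y_r)·Σ_y i_rxy``), weighted by the normalized threat weight, the
    cell's accessibility and the sensitivity of the cell's class.  A threat
    with no source cells contributes zero, with a warning.
    """
    if not threats:
        return lu.like(np.zeros(lu.shape))
    assert_aligned(lu, *[t.source for t in threats])
    nr, nc = lu.shape
    cell = lu.cell_size
    rows, cols = np.indices((nr, nc))
    coords = np.column_stack([rows.ravel() * cell, cols.ravel() * cell])
    total_weight = sum(t.weight for t in threats)
    D = np.zeros(nr * nc)
    for t in threats:
        src = np.flatnonzero(((t.source.values == 1)
                              & ~t.source.nodata_mask).ravel())
        if src.size == 0:
            warnings.warn(f"threat {t.name!r} has no source cells")
            continue
        sens = np.zeros(N_CLASSES)
        for name, sv in t.sensitivity.items():
            sens[CLASS_CODES[name]] = sv
        src_xy = coords[src]
        exposure = np.zeros(nr * nc)
        for start in range(0, nr * nc, chunk):
            block = coords[start:start + chunk]
            d = np.sqrt(((block[:, None, :] - src_xy[None, :, :])**2)
                        .sum(axis=2))
            exposure[start:start + chunk] = _decay_weights(
                d, t.max_dist_m, t.decay).mean(axis=1)
        s_map = sens[np.clip(lu.values.ravel(), 0, N_CLASSES - 1)]
        D += (t.weight / total_weight) * exposure * t.accessibility * s_map
    D = np.where(lu.nodata_mask.ravel(), 0.0, D)
    return lu.like(D.reshape(nr, nc))


def habitat_quality(lu: LandUseMap, D: Grid, bio: BiophysicalTable,
                    k_half: float | str = "auto", z: float = 2.5) -> Grid:
    """Habitat quality Q = H_j·(1 − D^z/(k^z + D^z)).

    ``k_half='auto'`` sets the half-saturation constant to half the maximum
    degradation (if degradation is zero everywhere, Q = H_j).  ``z``
    defaults to 2.5 (switchable to 2.0).
    """
    assert_aligned(lu, D)
    h = bio.lookup("habitat", lu)
    d = np.clip(D.values, 0.0, None)
    if k_half == "auto":
        dmax = float(d[~lu.nodata_mask].max()) if lu.n_valid else 0.0
        if dmax == 0.0:
            return lu.like(np.where(lu.nodata_mask, 0.0, h))
        k_half = dmax / 2.0
    k_half = float(k_half)
    if k_half <= 0:
        raise ValueError("k_half must be positive")
    q = h * (1.0 - d**z / (k_half**z + d**z))
    return lu.like(np.where(lu.nodata_mask, 0.0, q))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_service_stack(lu: LandUseMap, precip_annual: Grid,
                          precip_monthly: list[Grid], pet: Grid,
                          dem: Grid, awc: Grid, root_depth: Grid, K: Grid,
                          bio: BiophysicalTable | None = None,
                          threats: list[ThreatSpec] | None = None,
                          dist_road: Grid | None = None,
                          Z: float = 5.0, z_hq: float = 2.5,
                          k_half: float | str = "auto",
                          zones: Grid | None = None) -> ServiceStack:
    """Compute all four service layers for one land-use map and climate."""
    bio = bio if bio is not None else default_biophysical_table()
    threats = threats if threats is not None else default_threats(lu, dist_road)
    wy = water_yield(precip_annual, pet, awc, root_depth, lu, bio, Z=Z)
    R = rainfall_erosivity(precip_monthly)
    LS = ls_factor(dem)
    sc = soil_conservation(R, K, LS, lu, bio)
    cs = carbon_storage(lu, bio)
    D = habitat_degradation(lu, threats)
    hq = habitat_quality(lu, D, bio, k_half=k_half, z=z_hq)
    stack = ServiceStack(wy=wy, sc=sc, cs=cs, hq=hq, zones=zones)
    stack.validate()
    return stack
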