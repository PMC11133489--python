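"""Bias correction and aggregation of model climate series.

Model output is corrected against observations by empirical quantile
mapping: each future value is carried through the modelled historical CDF
onto the observed quantile function.  Weibull plotting positions
``p_i = i/(n+1)`` define the empirical quantiles and values between knots
are linearly interpolated.  Outside the calibrated range the correction is
extrapolated with a constant offset for temperature and a constant ratio
for precipitation (which keeps corrected precipitation non-negative).
Ensembles are combined as cellwise arithmetic means and futures averaged
over four 20-year periods (2030s, 2050s, 2070s, 2090s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, assert_aligned

__all__ = ["ClimateSeries", "PeriodWindow", "PERIOD_WINDOWS",
           "quantile_map", "ensemble_mean", "period_mean"]

MIN_SERIES_LENGTH = 5


@dataclass
class ClimateSeries:
    """Ordered annual (or monthly) scalars for one cell and variable."""

    values: np.ndarray
    variable: str = "precip"  # {precip, temp, pet}
    period: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in climate series")
        if self.variable in ("precip", "pet") and np.any(self.values < 0):
            raise ValueError(f"negative {self.variable} values")


@dataclass(frozen=True)
class PeriodWindow:
    label: str
    start: int
    end: int

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)


#: The four disjoint 20-year future periods.
PERIOD_WINDOWS = {
    "2030s": PeriodWindow("2030s", 2021, 2040),
    "2050s": PeriodWindow("2050s", 2041, 2060),
    "2070s": PeriodWindow("2070s", 2061, 2080),
    "2090s": PeriodWindow("2090s", 2081, 2100),
}


def _as_series(x, variable: str) -> ClimateSeries:
    if isinstance(x, ClimateSeries):
        return x
    return ClimateSeries(np.asarray(x, dtype=float), variable)


def quantile_map(obs_hist, mod_hist, mod_fut,
                 variable: str | None = None) -> ClimateSeries:
    """Empirical quantile-mapping bias correction of a future series.

    Each future value ``v`` is mapped to the observed quantile at the
    modelled-historical empirical CDF of ``v`` (Weibull plotting positions,
    linear interpolation between quantile knots).  Beyond the calibrated
    range: additive offset for temperature, multiplicative ratio for
    precipitation/PET.  Correcting ``mod_hist`` itself reproduces the
    observed quantiles (calibration closure).
    """
    if variable is None:
        variable = obs_hist.variable if isinstance(obs_hist, ClimateSeries) \
            else "temp"
    obs = _as_series(obs_hist, variable)
    mod = _as_series(mod_hist, variable)
    fut = _as_series(mod_fut, variable)
    if obs.variable != mod.variable:
        raise ValueError("observed and modelled series differ in variable")
    n_obs, n_mod = obs.values.size, mod.values.size
    if n_obs < MIN_SERIES_LENGTH or n_mod < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series too short for quantile mapping (need >= {MIN_SERIES_LENGTH})")

    obs_sorted = np.sort(obs.values)
    mod_sorted = np.sort(mod.values)
    p_obs = np.arange(1, n_obs + 1) / (n_obs + 1.0)
    p_mod = np.arange(1, n_mod + 1) / (n_mod + 1.0)

    v = fut.values
    out = np.empty_like(v)
    inside = (v >= mod_sorted[0]) & (v <= mod_sorted[-1])
    # v -> CDF under modelled history -> observed quantile
    p = np.interp(v[inside], mod_sorted, p_mod)
    out[inside] = np.interp(p, p_obs, obs_sorted)

    multiplicative = variable in ("precip", "pet")
    low, high = ~inside & (v < mod_sorted[0]), ~inside & (v > mod_sorted[-1])
    if multiplicative:
        lo_ratio = obs_sorted[0] / mod_sorted[0] if mod_sorted[0] > 0 else 1.0
        hi_ratio = obs_sorted[-1] / mod_sorted[-1] if mod_sorted[-1] > 0 else 1.0
        out[low] = v[low] * lo_ratio
        out[high] = v[high] * hi_ratio
    else:
        out[low] = v[low] + (obs_sorted[0] - mod_sorted[0])
        out[high] = v[high] + (obs_sorted[-1] - mod_sorted[-1])
    if multiplicative:
        out = np.clip(out, 0.0, None)
    return ClimateSeries(out, variable, fut.period)


def ensemble_mean(members: list[Grid]) -> Grid:
    """Cellwise arithmetic mean of aligned ensemble members.

    A cell is nodata in the result only where it is nodata in every member.
    """
    if not members:
        raise ValueError("ensemble_mean: no members")
    assert_aligned(*members)
    stack = np.stack([np.where(m.nodata_mask, np.nan, m.values)
                      for m in members])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    mask = np.all([m.nodata_mask for m in members], axis=0)
    mean = np.where(mask, 0.0, mean)
    return Grid(mean, mask, members[0].cell_size, members[0].origin)


def period_mean(annual: list[tuple[int, Grid]],
                window: PeriodWindow | str) -> Grid:
    """Mean grid over exactly the years of a 20-year period window."""
    if isinstance(window, str):
        window = PERIOD_WINDOWS[window]
    by_year = dict(annual)
    missing = [y for y in window.years if y not in by_year]
    if missing:
        raise ValueError(
            f"period {window.label}: missing years {missing}")
    grids = [by_year[y] for y in window.years]
    assert_aligned(*grids)
    mean = np.mean([g.values for g in grids], axis=0)
    return Grid(mean, grids[0].nodata_mask.copy(), grids[0].cell_size,
                grids[0].origin)
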