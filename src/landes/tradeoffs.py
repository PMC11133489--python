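"""Trade-off / synergy analysis among the four service layers.

Service values are sampled at random points (uniform over valid cells,
without replacement, so coincident points never inflate significance), rank
correlations are computed with the midrank Spearman convention and a
t-approximation p-value on n−2 degrees of freedom, and each service pair is
labelled *synergy* (significantly positive), *trade-off* (significantly
negative) or *none* at a configurable alpha (default 0.01).  The analysis
is stratified into upper / middle / lower basin zones split at the 1000 m
and 100 m elevation contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid, assert_aligned
from .services import ServiceStack

__all__ = [
    "SERVICE_NAMES", "ZONE_NAMES", "RelationMatrix",
    "zone_partition", "sample_points", "extract_values",
    "spearman_matrix", "classify_relations", "tradeoff_report",
]

SERVICE_NAMES = ("WY", "SC", "CS", "HQ")
ZONE_NAMES = ("lower", "middle", "upper")
ZONE_CODES = {name: i for i, name in enumerate(ZONE_NAMES)}


@dataclass
class RelationMatrix:
    """Symmetric Spearman rho and p-value matrices over the four services."""

    rho: pd.DataFrame
    p: pd.DataFrame
    labels: pd.DataFrame | None = None
    n: int = 0

    def validate(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(r)) > 1 + 1e-12:
                raise ValueError("|rho| exceeds 1")
        if not np.allclose(r, r.T, equal_nan=True):
            raise ValueError("rho not symmetric")


def zone_partition(dem: Grid, upper_threshold: float = 1000.0,
                   lower_threshold: float = 100.0) -> Grid:
    """Split the basin at elevation contours: upper (>= 1000 m),
    middle (100–1000 m), lower (< 100 m).  Codes 0/1/2 = lower/middle/upper."""
    if not upper_threshold > lower_threshold:
        raise ValueError("upper threshold must exceed lower threshold")
    z = dem.values
    zones = np.where(z >= upper_threshold, ZONE_CODES["upper"],
                     np.where(z >= lower_threshold, ZONE_CODES["middle"],
                              ZONE_CODES["lower"]))
    return dem.like(zones.astype(np.int16))


def sample_points(valid_mask: Grid, n: int = 10000,
                  seed: int = 0) -> np.ndarray:
    """Uniform sample of valid-cell flat indices, without replacement.

    If fewer than ``n`` valid cells exist, all of them are returned with a
    warning.  Deterministic per seed.
    """
    pool = np.flatnonzero(((valid_mask.values != 0)
                           & ~valid_mask.nodata_mask).ravel())
    if pool.size == 0:
        raise ValueError("sample_points: empty valid mask")
    if n >= pool.size:
        if n > pool.size:
            warnings.warn(f"requested {n} points from {pool.size} cells; "
                          "sampling all")
        return np.sort(pool)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=n, replace=False))


def extract_values(points: np.ndarray, stack: ServiceStack,
                   zones: Grid | None = None) -> pd.DataFrame:
    """Service values (and zone labels) at the sampled cells.

    Rows hitting nodata in any service are dropped; the drop count is
    recorded in ``df.attrs['dropped']``.
    """
    layers = stack.layers()
    grids = list(layers.values())
    if zones is None:
        zones = stack.zones
    if zones is not None:
        assert_aligned(*grids, zones)
    else:
        assert_aligned(*grids)
    data = {"point": points}
    bad = np.zeros(points.size, dtype=bool)
    for name, g in layers.items():
        data[name] = g.values.ravel()[points]
        bad |= g.nodata_mask.ravel()[points]
    if zones is not None:
        data["zone"] = np.asarray(ZONE_NAMES)[
            zones.values.ravel()[points].astype(int)]
    df = pd.DataFrame(data)
    dropped = int(bad.sum())
    if dropped == points.size and points.size:
        warnings.warn("every sampled point hits nodata; empty table")
    df = df.loc[~bad].reset_index(drop=True)
    df.attrs["dropped"] = dropped
    return df


def spearman_matrix(table: pd.DataFrame,
                    services: tuple[str, ...] = SERVICE_NAMES
                    ) -> RelationMatrix:
    """Pairwise Spearman rho (midrank convention) with t-approximation
    p-values on n−2 df.  A constant column yields undefined rho, recorded
    as NaN with a warning.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows for the correlation matrix")
    cols = [s for s in services if s in table.columns]
    X = table[cols].to_numpy(dtype=float)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(X[:, i]) == 0 or np.ptp(X[:, j]) == 0:
                warnings.warn(
                    f"constant column among ({cols[i]}, {cols[j]}); "
                    "rho undefined")
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(X[:, i], X[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    out = RelationMatrix(mk(rho), mk(pval), n=len(table))
    out.validate()
    return out


def classify_relations(matrix: RelationMatrix,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Label each off-diagonal pair: synergy (rho>0, p<alpha), trade-off
    (rho<0, p<alpha), else none; undefined correlations are none."""
    rho = matrix.rho.to_numpy(dtype=float)
    p = matrix.p.to_numpy(dtype=float)
    k = rho.shape[0]
    labels = np.full((k, k), "none", dtype=object)
    for i in range(k):
        labels[i, i] = ""
        for j in range(k):
            if i == j or not np.isfinite(rho[i, j]):
                continue
            if p[i, j] < alpha:
                labels[i, j] = "synergy" if rho[i, j] > 0 else "trade-off"
    out = pd.DataFrame(labels, index=matrix.rho.index,
                       columns=matrix.rho.columns)
    matrix.labels = out
    return out


def tradeoff_report(stacks: dict[str, ServiceStack], dem: Grid,
                    n: int = 10000, alpha: float = 0.01, seed: int = 0,
                    per_zone: bool = True,
                    min_zone_points: int = 10) -> pd.DataFrame:
    """Relation matrices per (stack label, zone) as one tidy table.

    One basin-wide point sample is drawn and stratified by the elevation
    zones; a zone with fewer than ``min_zone_points`` sampled points is
    omitted with a warning.  Columns: run, zone, pair, rho, p, n, label.
    """
    zones = zone_partition(dem)
    rows = []
    for run, stack in stacks.items():
        mask = dem.like(np.ones(dem.shape))
        pts = sample_points(mask, n=n, seed=seed)
        table = extract_values(pts, stack, zones=zones)
        groups = [("all", table)]
        if per_zone:
            groups += [(z, table[table["zone"] == z]) for z in ZONE_NAMES]
        for zone, sub in groups:
            if len(sub) < min_zone_points:
                warnings.warn(f"zone {zone!r} in {run!r}: only {len(sub)} "
                              "points; matrix omitted")
                continue
            mat = spearman_matrix(sub)
            labels = classify_relations(mat, alpha=alpha)
            for i, si in enumerate(SERVICE_NAMES):
                for sj in SERVICE_NAMES[i + 1:]:
                    rows.append({
                        "run": run, "zone": zone, "pair": f"{si}-{sj}",
                        "rho": mat.rho.loc[si, sj], "p": mat.p.loc[si, sj],
                        "n": len(sub), "label": labels.loc[si, sj]})
    return pd.DataFrame(rows)
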