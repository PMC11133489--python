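"""Demand-driven land-use cellular automaton with adaptive inertia.

The simulator follows the FLUS recipe: a feed-forward neural network learns
per-class occurrence probabilities ``P_{p,k}`` from driver layers; demand
for each class is then allocated on the map through a roulette competition
in which the total conversion probability of cell ``p`` from its current
class ``c`` to class ``k`` is

    TP_{p,k} = P_{p,k} * Omega_{p,k} * Inertia_k * (1 - sc_{c->k})

``Omega`` is the neighbourhood effect — the count of class-``k`` cells in
an ``N x N`` window around ``p`` (centre excluded), divided by ``N²−1`` and
weighted by ``w_k``.  ``Inertia_k`` starts at 1 and is adapted from the two
most recent demand gaps ``D_k`` (demanded minus allocated cells): it is
left unchanged when the gap is not growing in magnitude, and scaled by the
gap ratio when a deficit deepens or a surplus grows, which steers the
competition toward under-served classes.  ``sc`` is the conversion-cost
matrix; ``sc = 1`` forbids a transition outright.

Validation uses Cohen's kappa on the cellwise confusion matrix and the
figure of merit ``FoM = B/(A+B+C+D)`` computed on *change* cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import (CLASS_NAMES, N_CLASSES, Grid, LandUseMap, assert_aligned,
                    class_census)

__all__ = [
    "SuitabilityModel", "CAState", "DemandSchedule", "AllocationError",
    "sample_training", "fit_suitability", "neighborhood_effect",
    "update_inertia", "total_probability", "allocate", "simulate",
    "kappa", "figure_of_merit",
]


class AllocationError(RuntimeError):
    """Allocation failed to meet the demand within the iteration budget."""


# ---------------------------------------------------------------------------
# suitability learning
# ---------------------------------------------------------------------------

@dataclass
class SuitabilityModel:
    """Trained network mapping a driver vector to six class probabilities."""

    pipeline: object
    classes_: np.ndarray
    n_samples: int
    seed: int
    architecture: tuple[int, ...]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) probabilities; absent training classes get probability 0."""
        raw = self.pipeline.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((raw.shape[0], N_CLASSES))
        out[:, self.classes_.astype(int)] = raw
        return out


def sample_training(lu: LandUseMap, drivers: list[Grid] | np.ndarray,
                    n: int, seed: int = 0,
                    strategy: str = "uniform") -> tuple[np.ndarray, np.ndarray]:
    """Draw (driver-vector, class) training rows from the map.

    ``strategy='uniform'`` samples valid cells without replacement;
    ``'stratified'`` splits ``n`` evenly over the classes present so every
    present class is sampled at least once (absent classes are skipped with
    a warning).
    """
    if isinstance(drivers, np.ndarray):
        X_all = drivers
    else:
        assert_aligned(lu, *drivers)
        valid = ~lu.nodata_mask
        X_all = np.column_stack([g.values[valid] for g in drivers])
    y_all = lu.values[~lu.nodata_mask].astype(int)
    n_valid = y_all.size
    if n > n_valid:
        raise ValueError(f"requested {n} samples from {n_valid} valid cells")
    rng = np.random.default_rng(seed)
    if strategy == "uniform":
        idx = rng.choice(n_valid, size=n, replace=False)
    elif strategy == "stratified":
        present = np.unique(y_all)
        if present.size < N_CLASSES:
            missing = sorted(set(range(N_CLASSES)) - set(present.tolist()))
            warnings.warn(f"classes absent from map, strata skipped: {missing}")
        per = max(1, n // present.size)
        parts = []
        for k in present:
            pool = np.flatnonzero(y_all == k)
            take = min(per, pool.size)
            parts.append(rng.choice(pool, size=take, replace=False))
        idx = np.concatenate(parts)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return X_all[idx], y_all[idx]


def fit_suitability(X: np.ndarray, y: np.ndarray,
                    architecture: tuple[int, ...] = (12,),
                    seed: int = 0, max_iter: int = 600) -> SuitabilityModel:
    """Train the suitability network (one hidden layer of 12 logistic units
    by default, standardized inputs).  Deterministic per seed."""
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training sample contains a single class")
    pipe = make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=architecture, activation="logistic",
                      solver="adam", max_iter=max_iter, random_state=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny demos
        pipe.fit(np.asarray(X, dtype=float), y)
    return SuitabilityModel(pipe, classes, len(y), seed, architecture)


def suitability_surfaces(model: SuitabilityModel, lu: LandUseMap,
                         drivers: list[Grid]) -> np.ndarray:
    """(n_valid, 6) probability surface over the map's valid cells."""
    valid = ~lu.nodata_mask
    X = np.column_stack([g.values[valid] for g in drivers])
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# CA state and kernel operations
# ---------------------------------------------------------------------------

def _default_costs() -> np.ndarray:
    """Conversion-cost matrix: zero diagonal, water<->urban near-forbidden."""
    sc = np.full((N_CLASSES, N_CLASSES), 0.1)
    np.fill_diagonal(sc, 0.0)
    w, u = CLASS_NAMES.index("water"), CLASS_NAMES.index("urban")
    sc[w, u] = sc[u, w] = 0.95
    return sc


@dataclass
class CAState:
    """Mutable allocation state: suitability, inertia, gaps, costs, window."""

    suitability: np.ndarray                       # (n_valid, 6) = P_{p,k}
    inertia: np.ndarray = field(
        default_factory=lambda: np.ones(N_CLASSES))
    gap_prev: np.ndarray | None = None            # D_k^{t-1}
    gap_prev2: np.ndarray | None = None           # D_k^{t-2}
    costs: np.ndarray = field(default_factory=_default_costs)
    weights: np.ndarray = field(
        default_factory=lambda: np.ones(N_CLASSES))
    window: int = 3
    restricted: frozenset[int] = frozenset()
    omega_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window size N must be odd and >= 3")
        if np.any(np.diag(self.costs) != 0):
            raise ValueError("conversion cost sc[c,c] must be 0")
        if np.any((self.costs < 0) | (self.costs > 1)):
            raise ValueError("conversion costs must lie in [0,1]")
        if np.any(self.inertia <= 0):
            raise ValueError("inertia coefficients must be positive")


def neighborhood_effect(map_prev: LandUseMap, k: int, N: int = 3,
                        w_k: float = 1.0) -> Grid:
    """Windowed class density Omega: class-``k`` count in the ``N x N``
    window excluding the centre, over ``N²−1``, times ``w_k``.

    Edge windows are truncated but keep the same divisor, so the effect
    shrinks toward borders (configurable at the state level by renormalizing
    externally if desired).
    """
    if N % 2 == 0 or N < 3:
        raise ValueError("window size N must be odd and >= 3")
    isk = ((map_prev.values == k) & ~map_prev.nodata_mask).astype(float)
    total = ndimage.uniform_filter(isk, size=N, mode="constant", cval=0.0) \
        * (N * N)
    count = total - isk  # exclude the centre cell
    omega = np.clip(count, 0.0, None) / (N * N - 1) * w_k
    return map_prev.like(omega)


def update_inertia(inertia_k: float, d_prev: float, d_prev2: float) -> float:
    """Adaptive-inertia update from the two most recent demand gaps.

    Unchanged when ``|D^{t-1}| <= |D^{t-2}|``; scaled by ``D^{t-2}/D^{t-1}``
    when a deficit deepens (``D^{t-1} < D^{t-2} < 0``); scaled by
    ``D^{t-1}/D^{t-2}`` when a surplus grows (``0 < D^{t-2} < D^{t-1}``).
    Sign-crossing and other unlisted gap patterns leave the coefficient
    unchanged (the conservative reading of the three-branch rule).
    """
    if abs(d_prev) <= abs(d_prev2):
        return inertia_k
    if d_prev < d_prev2 < 0:
        return inertia_k * (d_prev2 / d_prev)
    if 0 < d_prev2 < d_prev:
        return inertia_k * (d_prev / d_prev2)
    return inertia_k


def total_probability(p_pk: float, omega: float, inertia_k: float,
                      sc_ck: float) -> float:
    """TP = P * Omega * Inertia * (1 − sc); zero when the transition is
    forbidden (sc = 1)."""
    return p_pk * omega * inertia_k * (1.0 - sc_ck)


# ---------------------------------------------------------------------------
# allocation
# ---------------------------------------------------------------------------

def _census_vector(values_flat: np.ndarray) -> np.ndarray:
    return np.bincount(values_flat, minlength=N_CLASSES).astype(np.int64)


def allocate(state: CAState, map_prev: LandUseMap, demands: dict[str, int],
             seed: int = 0, max_iters: int = 200,
             tolerance: float | None = None,
             log: list | None = None) -> LandUseMap:
    """Allocate one period's demand on the map by roulette competition.

    Each iteration recomputes the neighbourhood effect from the current map
    and the adaptive inertia from the demand-gap history, then lets every
    cell of an over-allocated class draw a candidate under-demand class with
    probability proportional to TP; flips are accepted in a random order
    while they shrink both classes' absolute gaps.  Valid-cell count is
    conserved exactly.  Raises :class:`AllocationError` with the residual
    gaps if the demand is not met within ``max_iters``.
    """
    demand_vec = np.array([int(demands[n]) for n in CLASS_NAMES])
    valid = ~map_prev.nodata_mask
    flat_index = np.flatnonzero(valid.ravel())
    n_valid = flat_index.size
    if demand_vec.sum() != n_valid:
        raise ValueError(
            f"demands sum to {demand_vec.sum()} but map has {n_valid} valid cells")
    if state.suitability.shape != (n_valid, N_CLASSES):
        raise ValueError("suitability surface does not match the map")
    if tolerance is None:
        tol_vec = np.maximum(5, np.ceil(0.005 * demand_vec)).astype(int)
    else:
        tol_vec = np.full(N_CLASSES, int(tolerance))

    rng = np.random.default_rng(seed)
    current = map_prev.values.ravel()[flat_index].astype(np.int64)
    census = _census_vector(current)
    gap = demand_vec - census            # >0: under-served, <0: over-served
    inertia = state.inertia.copy()
    gap_prev = state.gap_prev.copy() if state.gap_prev is not None else gap.astype(float)
    gap_prev2 = state.gap_prev2.copy() if state.gap_prev2 is not None else gap.astype(float)
    restricted = np.zeros(N_CLASSES, dtype=bool)
    for r in state.restricted:
        restricted[r] = True

    work = LandUseMap(map_prev.values.copy(), map_prev.nodata_mask.copy(),
                      map_prev.cell_size, map_prev.origin)

    for iteration in range(max_iters):
        if np.all(gap == 0) or np.all(np.abs(gap) <= tol_vec) and iteration > 0:
            break
        # adaptive inertia from the two most recent gap records
        if iteration > 0:
            for k in range(N_CLASSES):
                inertia[k] = update_inertia(inertia[k], gap_prev[k],
                                            gap_prev2[k])
        omega = np.column_stack([
            neighborhood_effect(work, k, state.window,
                                state.weights[k]).values.ravel()[flat_index]
            for k in range(N_CLASSES)])
        omega = np.maximum(omega, state.omega_floor)

        under = (gap > 0) & ~restricted
        over = (gap < 0) & ~restricted
        if not under.any() or not over.any():
            break
        donors = np.flatnonzero(over[current])
        if donors.size == 0:
            break
        # roulette draw of a candidate class per donor cell via Gumbel-max
        weights = (state.suitability[donors] * omega[donors] * inertia
                   * (1.0 - state.costs[current[donors]]))
        weights[:, ~under] = 0.0
        with np.errstate(divide="ignore"):
            logw = np.log(weights)
        gumbel = rng.gumbel(size=weights.shape)
        choice = np.argmax(logw + gumbel, axis=1)
        tp = weights[np.arange(donors.size), choice]
        feasible = tp > 0
        # competition: a cell wins its drawn class with probability
        # proportional to its total conversion probability, so high-TP
        # cells claim the demand first
        tp_max = np.zeros(N_CLASSES)
        np.maximum.at(tp_max, choice[feasible], tp[feasible])
        win = rng.random(donors.size) * tp_max[choice] <= tp

        order = rng.permutation(donors.size)
        flips = 0
        for i in order:
            if not feasible[i] or not win[i]:
                continue
            cell = donors[i]
            c, k = current[cell], choice[i]
            if gap[k] <= 0 or gap[c] >= 0:
                continue
            current[cell] = k
            gap[k] -= 1
            gap[c] += 1
            flips += 1
        work.values.ravel()[...] = work.values.ravel()
        flat_vals = work.values.ravel()
        flat_vals[flat_index] = current
        work.values = flat_vals.reshape(work.shape).astype(np.int16)
        gap_prev2, gap_prev = gap_prev, gap.astype(float)
        if log is not None:
            log.append({"iteration": iteration, "flips": flips,
                        **{f"gap_{n}": int(gap[j])
                           for j, n in enumerate(CLASS_NAMES)}})
        if flips == 0 and np.any(np.abs(gap) > tol_vec):
            residual = {n: int(gap[j]) for j, n in enumerate(CLASS_NAMES)}
            raise AllocationError(
                f"no feasible flips remain; residual gaps {residual}")
    else:
        residual = {n: int(gap[j]) for j, n in enumerate(CLASS_NAMES)}
        if np.any(np.abs(gap) > tol_vec):
            raise AllocationError(
                f"demand not met after {max_iters} iterations; residual {residual}")

    state.inertia = inertia
    state.gap_prev = gap.astype(float)
    state.gap_prev2 = gap_prev.astype(float)
    assert _census_vector(current).sum() == n_valid
    return work


def simulate(t0: LandUseMap, drivers: list[Grid],
             schedule: dict[str, dict[str, int]],
             model: SuitabilityModel | None = None,
             state: CAState | None = None, seed: int = 0,
             n_train: int = 2000, window: int = 3,
             costs: np.ndarray | None = None,
             weights: np.ndarray | None = None,
             log: list | None = None) -> dict[str, LandUseMap]:
    """Run the CA over successive demand periods from ``t0``.

    Fits the suitability network on ``t0`` (unless a model or full state is
    supplied), then chains :func:`allocate` across the schedule's periods,
    carrying the adaptive inertia and demand-gap history forward.  Returns
    one map per period label.
    """
    assert_aligned(t0, *drivers)
    rng = np.random.default_rng(seed)
    if state is None:
        if model is None:
            X, y = sample_training(t0, drivers, n=min(n_train, t0.n_valid),
                                   seed=int(rng.integers(2**31 - 1)),
                                   strategy="stratified")
            model = fit_suitability(X, y, seed=int(rng.integers(2**31 - 1)))
        suit = suitability_surfaces(model, t0, drivers)
        state = CAState(suitability=suit, window=window,
                        costs=costs if costs is not None else _default_costs(),
                        weights=weights if weights is not None
                        else np.ones(N_CLASSES))
    maps: dict[str, LandUseMap] = {}
    current = t0
    for period, demands in schedule.items():
        period_log: list = []
        current = allocate(state, current, demands,
                           seed=int(rng.integers(2**31 - 1)), log=period_log)
        if log is not None:
            for row in period_log:
                log.append({"period": period, **row})
        maps[period] = current
    return maps


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------

def kappa(observed: LandUseMap, simulated: LandUseMap) -> float:
    """Cohen's kappa between two aligned categorical maps.

    ``p0`` is the agreeing fraction of valid cells, ``pc`` the chance
    agreement from the class marginals; kappa = (p0 − pc)/(1 − pc).  If both
    maps are the same single class (pc = 1) the agreement is perfect and 1.0
    is returned.
    """
    assert_aligned(observed, simulated)
    valid = ~(observed.nodata_mask | simulated.nodata_mask)
    a = observed.values[valid].astype(int)
    b = simulated.values[valid].astype(int)
    n = a.size
    if n == 0:
        raise ValueError("no jointly valid cells")
    p0 = float(np.mean(a == b))
    pa = np.bincount(a, minlength=N_CLASSES) / n
    pb = np.bincount(b, minlength=N_CLASSES) / n
    pc = float(pa @ pb)
    if pc >= 1.0 - 1e-15:
        warnings.warn("both maps constant and equal; kappa 1 by convention")
        return 1.0
    return (p0 - pc) / (1.0 - pc)


def figure_of_merit(initial: LandUseMap, observed_final: LandUseMap,
                    simulated_final: LandUseMap) -> float:
    """Figure of merit B/(A+B+C+D) on change cells.

    A: observed change simulated as persistence; B: observed change
    simulated as the same new class; C: observed change simulated as a
    different new class; D: observed persistence simulated as change.
    Returns 0 (with a note) when no cell changes in either map.
    """
    assert_aligned(initial, observed_final, simulated_final)
    valid = ~(initial.nodata_mask | observed_final.nodata_mask
              | simulated_final.nodata_mask)
    ini = initial.values[valid].astype(int)
    obs = observed_final.values[valid].astype(int)
    sim = simulated_final.values[valid].astype(int)
    obs_changed = obs != ini
    sim_changed = sim != ini
    A = int(np.sum(obs_changed & ~sim_changed))
    B = int(np.sum(obs_changed & sim_changed & (sim == obs)))
    C = int(np.sum(obs_changed & sim_changed & (sim != obs)))
    D = int(np.sum(~obs_changed & sim_changed))
    denom = A + B + C + D
    if denom == 0:
        warnings.warn("no observed or simulated change; FoM 0 by convention")
        return 0.0
    return B / denom


def random_allocation_baseline(initial: LandUseMap,
                               demands: dict[str, int],
                               seed: int = 0) -> LandUseMap:
    """Demand-respecting but driver-blind allocation: change cells are
    drawn uniformly.  The null model against which the CA's figure of merit
    is judged."""
    rng = np.random.default_rng(seed)
    valid = ~initial.nodata_mask
    flat_index = np.flatnonzero(valid.ravel())
    current = initial.values.ravel()[flat_index].astype(np.int64)
    census = _census_vector(current)
    demand_vec = np.array([int(demands[n]) for n in CLASS_NAMES])
    gap = demand_vec - census
    donors_pool = np.flatnonzero((gap < 0)[current])
    rng.shuffle(donors_pool)
    pos = 0
    for k in np.flatnonzero(gap > 0):
        need = gap[k]
        while need > 0 and pos < donors_pool.size:
            cell = donors_pool[pos]
            pos += 1
            c = current[cell]
            if gap[c] >= 0:
                continue
            current[cell] = k
            gap[c] += 1
            need -= 1
    out = initial.values.copy().ravel()
    out[flat_index] = current
    return LandUseMap(out.reshape(initial.shape).astype(np.int16),
                      initial.nodata_mask.copy(), initial.cell_size,
                      initial.origin)
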