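"""Calibration of the chip model against pooled GTT measurements.

The pipeline is: SEM preprocessing (a floor for unrealistically small
standard errors plus a medium-exchange offset contribution), a weighted
least-squares cost

    V(p) = sum_i sum_t (y_i(t) - yhat_i(t, p))^2 / SEM_i(t)^2,

a chi-square acceptance test of V at the optimum (significance 0.05,
degrees of freedom defaulting to the number of residuals), and a seeded
simulated-annealing search that records *every* evaluated parameter
vector passing the chi-square threshold -- the acceptable set, from which
prediction uncertainty envelopes are built by simulating the members
attaining each free parameter's extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelParameters
from .protocol import FAST_SOLVER, Protocol, SimulationResult, SolverConfig, simulate

__all__ = [
    "GTTDataset",
    "ParameterEnsemble",
    "PredictionEnvelope",
    "FitConfig",
    "preprocess_sem",
    "cost",
    "chi2_threshold",
    "fit",
    "predict_envelope",
]

DATA_COLUMNS = ("signal", "time_h", "mean", "sem", "n", "gtt_window")
SIGNALS = ("glucose", "insulin")


@dataclass(frozen=True)
class GTTDataset:
    """Pooled GTT means and SEMs for one culture condition.

    ``table`` has one row per (signal, time) with columns
    signal / time_h / mean / sem / n / gtt_window.  ``nominal`` maps
    (gtt_window, signal) to the concentration dosed at the window start
    (glucose load, spiked insulin), used by the offset preprocessing rule.
    """

    condition: str
    table: pd.DataFrame
    nominal: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(DATA_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns {sorted(missing)}")
        bad = self.table[self.table["sem"] < 0]
        if len(bad):
            raise ValueError(f"negative SEM at rows {list(bad.index)}")
        dup = self.table.duplicated(subset=["signal", "time_h", "gtt_window"])
        if dup.any():
            raise ValueError(f"duplicate (signal, time, window) rows at {list(self.table.index[dup])}")

    @property
    def n_points(self) -> int:
        return len(self.table)

    def subset_windows(self, windows: Iterable[str]) -> "GTTDataset":
        """Restrict to the given GTT windows (e.g. calibration vs
        validation splits)."""
        keep = set(windows)
        tab = self.table[self.table["gtt_window"].isin(keep)].reset_index(drop=True)
        nom = {k: v for k, v in self.nominal.items() if k[0] in keep}
        return GTTDataset(self.condition, tab, nom)


def preprocess_sem(
    dataset: GTTDataset,
    floor_frac: float = 0.05,
    scope: str = "signal",
) -> GTTDataset:
    """Apply the two SEM corrections used before fitting.

    1.  SEM floor: with only 2-6 replicate circuits the measured SEM can
        be unrealistically small; any SEM below ``floor_frac`` of the
        corresponding |mean| is replaced by the largest SEM in scope
        (``"signal"``: largest SEM of the same signal; ``"dataset"``:
        largest SEM across all points).
    2.  Exchange-offset contribution: for every GTT window and signal the
        magnitude of the measured t=0 deviation from the nominal dosed
        concentration is added to the SEM of all points of that window.
    """
    tab = dataset.table.copy()
    if scope not in ("signal", "dataset"):
        raise ValueError(f"unknown scope {scope!r}")
    groups = tab.groupby("signal").groups if scope == "signal" else {"all": tab.index}
    for _, idx in groups.items():
        sems = tab.loc[idx, "sem"]
        ceiling = sems.max()
        if not ceiling > 0:
            raise ValueError("SEM floor undefined: all SEMs in scope are zero")
        small = ((sems < floor_frac * tab.loc[idx, "mean"].abs()) | (sems == 0)).to_numpy()
        tab.loc[np.asarray(idx)[small], "sem"] = ceiling

    for (window, signal), nominal in dataset.nominal.items():
        sel = (tab["gtt_window"] == window) & (tab["signal"] == signal)
        if not sel.any():
            continue
        win = tab[sel]
        t0 = win["time_h"].min()
        at0 = win[win["time_h"] == t0]
        offset = float(abs(at0["mean"].iloc[0] - nominal))
        tab.loc[sel, "sem"] = tab.loc[sel, "sem"] + offset
    return GTTDataset(dataset.condition, tab, dict(dataset.nominal))


def _sim_lookup(result: SimulationResult) -> dict[tuple[str, float, str], float]:
    table = {}
    for t, w, g, i in zip(result.times, result.windows, result.pooled_glucose, result.pooled_insulin):
        table[("glucose", round(float(t), 6), w)] = g
        table[("insulin", round(float(t), 6), w)] = i
    return table


def cost(
    params: ModelParameters,
    datasets: Sequence[GTTDataset],
    protocols: Sequence[Protocol],
    solver_cfg: SolverConfig | None = None,
) -> float:
    """Weighted sum of squared residuals over all datasets, signals and
    time points, weights 1/SEM^2.  One protocol per dataset."""
    if len(datasets) != len(protocols):
        raise ValueError("need exactly one protocol per dataset")
    total = 0.0
    for ds, proto in zip(datasets, protocols):
        sim = simulate(params, proto, solver_cfg)
        lookup = _sim_lookup(sim)
        for row in ds.table.itertuples(index=False):
            key = (row.signal, round(float(row.time_h), 6), row.gtt_window)
            if key not in lookup:
                raise ValueError(f"no simulated value for data point {key} in condition {ds.condition!r}")
            r = (row.mean - lookup[key]) / row.sem
            total += r * r
    return total


def total_residuals(datasets: Sequence[GTTDataset]) -> int:
    return sum(ds.n_points for ds in datasets)


def chi2_threshold(df: int, alpha: float = 0.05) -> float:
    """(1 - alpha) quantile of the chi-square distribution: the cost at
    the optimum must stay below this for the model to be accepted."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


# ---------------------------------------------------------------------------
# simulated annealing over the free-parameter box


@dataclass(frozen=True)
class FitConfig:
    """Search settings for :func:`fit`.

    ``free`` maps dotted parameter paths (e.g. ``"fast.S_I0"``) to
    (lower, upper) bounds.  Positive-bounded parameters are searched in
    log10 space, sign-free ones (offsets) linearly.  Cooling is geometric,
    T_k = T0 * cooling^k; the proposal step scale shrinks with the square
    root of the temperature ratio.
    """

    free: Mapping[str, tuple[float, float]]
    n_restarts: int = 5
    n_iter: int = 2000
    cooling: float = 0.95
    T0: float | None = None  # default: initial cost of each restart
    step0: float = 0.25  # initial proposal sd, fraction of box width
    min_step: float = 0.02
    alpha: float = 0.05
    df: int | None = None  # default: number of residuals
    seed: int = 0
    solver_cfg: SolverConfig = FAST_SOLVER
    start: Mapping[str, float] | None = None  # optional start guess
    polish: bool = True  # Nelder-Mead refinement from the annealing optimum
    polish_maxfev: int = 150

    def __post_init__(self):
        for name, (lo, hi) in self.free.items():
            if not lo < hi:
                raise ValueError(f"empty bounds for {name}: ({lo}, {hi})")


class _Transform:
    """Per-parameter search-space transform: log10 where bounds are
    strictly positive, identity otherwise."""

    def __init__(self, free: Mapping[str, tuple[float, float]]):
        self.names = list(free.keys())
        self.log = np.array([lo > 0 for lo, _ in free.values()])
        lo = np.array([b[0] for b in free.values()], dtype=float)
        hi = np.array([b[1] for b in free.values()], dtype=float)
        self.lo = np.where(self.log, np.log10(np.where(self.log, lo, 1.0)), lo)
        self.hi = np.where(self.log, np.log10(np.where(self.log, hi, 1.0)), hi)
        self.width = self.hi - self.lo

    def to_params(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.log, 10.0**x, x)

    def from_params(self, v: np.ndarray) -> np.ndarray:
        return np.where(self.log, np.log10(np.where(self.log, v, 1.0)), v)

    def reflect(self, x: np.ndarray) -> np.ndarray:
        """Fold a proposal back into the box."""
        span = self.width
        y = np.mod(x - self.lo, 2 * span)
        y = np.where(y > span, 2 * span - y, y)
        return self.lo + y


@dataclass
class ParameterEnsemble:
    """The acceptable parameter set collected during the search.

    ``vectors`` holds every evaluated parameter vector with cost at or
    below ``threshold`` (rows ordered by evaluation); ``best_vector`` /
    ``best_cost`` always hold the global optimum even when nothing passed
    (then ``vectors`` is empty and the ensemble is flagged unacceptable).
    """

    names: list[str]
    vectors: np.ndarray  # n_acceptable x n_free
    costs: np.ndarray
    threshold: float
    base_params: ModelParameters
    best_vector: np.ndarray
    best_cost: float
    seed: int
    n_evaluations: int

    @property
    def acceptable(self) -> bool:
        return len(self.costs) > 0

    @property
    def optimum_index(self) -> int:
        if not self.acceptable:
            raise ValueError("empty acceptable set")
        return int(np.argmin(self.costs))

    def member_params(self, i: int) -> ModelParameters:
        return self.base_params.set(dict(zip(self.names, self.vectors[i])))

    @property
    def optimum_params(self) -> ModelParameters:
        return self.base_params.set(dict(zip(self.names, self.best_vector)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=self.names)
        df["cost"] = self.costs
        return df


def fit(
    datasets: Sequence[GTTDataset],
    protocols: Sequence[Protocol],
    base_params: ModelParameters,
    config: FitConfig,
) -> ParameterEnsemble:
    """Seeded simulated-annealing search for the acceptable parameter set.

    Minimizes :func:`cost` over the free-parameter box; every evaluated
    vector (accepted move or not) whose cost passes the chi-square
    threshold joins the ensemble.  Deterministic given config and seed.
    """
    tr = _Transform(config.free)
    df = config.df if config.df is not None else total_residuals(datasets)
    threshold = chi2_threshold(df, config.alpha)
    rng = np.random.default_rng(config.seed)

    def evaluate(x: np.ndarray) -> float:
        values = tr.to_params(x)
        p = base_params.set(dict(zip(tr.names, values)))
        try:
            return cost(p, datasets, protocols, config.solver_cfg)
        except Exception:
            return math.inf

    kept_x: list[np.ndarray] = []
    kept_c: list[float] = []
    best_x, best_c = None, math.inf
    n_eval = 0

    def consider(x: np.ndarray, c: float):
        nonlocal best_x, best_c
        if c <= threshold:
            kept_x.append(tr.to_params(x))
            kept_c.append(c)
        if c < best_c:
            best_x, best_c = x.copy(), c

    for restart in range(config.n_restarts):
        if restart == 0 and config.start is not None:
            x = tr.from_params(np.array([config.start[n] for n in tr.names], dtype=float))
        else:
            x = tr.lo + rng.random(len(tr.names)) * tr.width
        c = evaluate(x)
        n_eval += 1
        consider(x, c)
        T0 = config.T0 if config.T0 is not None else max(c, 1.0)
        T = T0
        for k in range(config.n_iter):
            scale = max(config.step0 * math.sqrt(T / T0), config.min_step)
            x_new = tr.reflect(x + rng.normal(0.0, scale * tr.width))
            c_new = evaluate(x_new)
            n_eval += 1
            consider(x_new, c_new)
            if c_new <= c or rng.random() < math.exp(-(c_new - c) / max(T, 1e-12)):
                x, c = x_new, c_new
            T *= config.cooling

    if config.polish and best_x is not None and math.isfinite(best_c):
        # derivative-free local refinement of the annealing optimum; its
        # evaluations join the acceptable set like any others
        from scipy.optimize import minimize

        def obj(x):
            nonlocal n_eval
            xr = np.clip(x, tr.lo, tr.hi)
            c = evaluate(xr)
            n_eval += 1
            consider(xr, c)
            return c

        minimize(
            obj,
            best_x,
            method="Nelder-Mead",
            bounds=list(zip(tr.lo, tr.hi)),
            options={"maxfev": config.polish_maxfev, "xatol": 1e-6, "fatol": 1e-9},
        )

    vectors = np.array(kept_x) if kept_x else np.empty((0, len(tr.names)))
    return ParameterEnsemble(
        names=list(tr.names),
        vectors=vectors,
        costs=np.array(kept_c),
        threshold=threshold,
        base_params=base_params,
        best_vector=tr.to_params(best_x),
        best_cost=best_c,
        seed=config.seed,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# uncertainty envelopes


@dataclass
class PredictionEnvelope:
    """Pointwise min/max band across the simulated ensemble members,
    with the optimal-parameter trajectory as the central curve."""

    times: np.ndarray
    windows: list[str]
    glucose_lower: np.ndarray
    glucose_central: np.ndarray
    glucose_upper: np.ndarray
    insulin_lower: np.ndarray
    insulin_central: np.ndarray
    insulin_upper: np.ndarray

    def contains_glucose(self, values: np.ndarray, rtol: float = 0.0) -> np.ndarray:
        pad = rtol * np.abs(self.glucose_central)
        return (values >= self.glucose_lower - pad) & (values <= self.glucose_upper + pad)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "gtt_window": self.windows,
                "glucose_lower": self.glucose_lower,
                "glucose_central": self.glucose_central,
                "glucose_upper": self.glucose_upper,
                "insulin_lower": self.insulin_lower,
                "insulin_central": self.insulin_central,
                "insulin_upper": self.insulin_upper,
            }
        )


def envelope_member_indices(ensemble: ParameterEnsemble, full: bool = False) -> list[int]:
    """Members to simulate: the optimum plus, for each free parameter,
    the members attaining its minimum and maximum over the acceptable
    set (``full=True`` simulates every member instead)."""
    if not ensemble.acceptable:
        raise ValueError("empty acceptable set")
    if full:
        return list(range(len(ensemble.costs)))
    idx = {ensemble.optimum_index}
    for j in range(ensemble.vectors.shape[1]):
        idx.add(int(np.argmin(ensemble.vectors[:, j])))
        idx.add(int(np.argmax(ensemble.vectors[:, j])))
    return sorted(idx)


def predict_envelope(
    ensemble: ParameterEnsemble,
    protocol: Protocol,
    solver_cfg: SolverConfig | None = None,
    full: bool = False,
) -> PredictionEnvelope:
    """Simulate the per-parameter-extreme members (plus the optimum) and
    return pointwise min/max bands for pooled glucose and insulin."""
    indices = envelope_member_indices(ensemble, full=full)
    sims = [simulate(ensemble.member_params(i), protocol, solver_cfg) for i in indices]
    central = simulate(ensemble.optimum_params, protocol, solver_cfg)
    G = np.stack([s.pooled_glucose for s in sims] + [central.pooled_glucose])
    I = np.stack([s.pooled_insulin for s in sims] + [central.pooled_insulin])
    return PredictionEnvelope(
        times=central.times,
        windows=central.windows,
        glucose_lower=G.min(axis=0),
        glucose_central=central.pooled_glucose,
        glucose_upper=G.max(axis=0),
        insulin_lower=I.min(axis=0),
        insulin_central=central.pooled_insulin,
        insulin_upper=I.max(axis=0),
    )
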