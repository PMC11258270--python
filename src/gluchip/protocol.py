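"""Chip culture protocols as discrete events, and piecewise ODE integration.

A protocol is an ordered list of instantaneous events (complete medium
exchanges, insulin spikes) plus a sampling schedule.  Between events the
model ODEs are integrated with an adaptive solver; at each event the fast
medium states are reset (exchange) or incremented (spike) while the slow
states (exposure integral, glucose average, beta-cell volume, elapsed
time) carry over untouched.

The factories reproduce the study design: model time 0 is the day-1
medium exchange starting the first glucose tolerance test (GTT); medium
is exchanged every 48 h thereafter; GTT windows (11 mM load, pooled
samples at +0, +8, +24, +48 h) start on days 1, optionally 7, and 13; an
insulin spike may accompany the day-13 exchange.  A window's +48 h sample
coincides with the next exchange and reads the pre-exchange medium; all
other samples at event times read the post-event state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_NAMES,
    ModelParameters,
    initial_state,
    nM_to_mIU_per_L,
    ode_rhs,
    pooled_observables,
)

__all__ = [
    "EventKind",
    "OffsetTag",
    "ProtocolEvent",
    "SamplePoint",
    "Protocol",
    "SolverConfig",
    "SimulationResult",
    "apply_event",
    "simulate",
    "gtt_study_protocol",
    "HOURS_PER_DAY",
]

HOURS_PER_DAY = 24.0
GTT_SAMPLE_OFFSETS = (0.0, 8.0, 24.0, 48.0)
GTT_LOAD_MM = 11.0

EventKind = Literal["MEDIUM_EXCHANGE", "INSULIN_SPIKE"]
OffsetTag = Literal["none", "d1", "d13"]


@dataclass(frozen=True)
class ProtocolEvent:
    time: float  # h since co-culture model time 0
    kind: EventKind
    glucose_conc: float = 0.0  # mmol/L dosed with fresh medium (exchanges)
    insulin_conc: float = 0.0  # mIU/L dosed (exchange medium or spike)
    applies_offsets: OffsetTag = "none"

    def __post_init__(self):
        if self.kind not in ("MEDIUM_EXCHANGE", "INSULIN_SPIKE"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.glucose_conc < 0 or self.insulin_conc < 0:
            raise ValueError("dosed concentrations must be nonnegative")
        if self.applies_offsets not in ("none", "d1", "d13"):
            raise ValueError(f"unknown offset tag {self.applies_offsets!r}")


@dataclass(frozen=True)
class SamplePoint:
    """One pooled medium draw.  ``phase`` resolves coincidence with an
    event: 'post' (default; fresh medium at a GTT start) or 'pre' (the
    +48 h draw made just before the next exchange)."""

    time: float
    phase: Literal["post", "pre"] = "post"
    window: str = ""  # GTT window label, '' outside any window


@dataclass(frozen=True)
class Protocol:
    events: tuple[ProtocolEvent, ...]
    samples: tuple[SamplePoint, ...]
    duration: float  # h
    initial_glucose: float = GTT_LOAD_MM  # mmol/L loaded at model time 0
    label: str = ""

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            # allow exchange+spike at the same instant, applied in order
            for t1, t2 in zip(times, times[1:]):
                if t2 < t1:
                    raise ValueError("events must be time-ordered")
        for sp in self.samples:
            if not 0.0 <= sp.time <= self.duration:
                raise ValueError(f"sample time {sp.time} outside [0, {self.duration}]")

    @property
    def sampling_times(self) -> np.ndarray:
        return np.array([sp.time for sp in self.samples])


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive integration settings; hard restart at every event.

    The default absolute tolerances are scaled per state (amounts ~1e-3
    mmol/mIU, concentrations ~10, beta-cell volume ~1e-8 L) so the tiny
    beta-cell state is not drowned by a scalar atol.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: tuple[float, ...] = (1e-12, 1e-12, 1e-12, 1e-12, 1e-8, 1e-8, 1e-17, 1e-6)

    def scaled(self, factor: float) -> "SolverConfig":
        """Loosen (factor > 1) or tighten (factor < 1) all tolerances."""
        return replace(self, rtol=self.rtol * factor, atol=tuple(a * factor for a in self.atol))


FAST_SOLVER = SolverConfig(rtol=1e-6, atol=(1e-10,) * 4 + (1e-6, 1e-6, 1e-15, 1e-4))
"""Looser tolerances used inside iterative calibration loops."""


@dataclass
class SimulationResult:
    times: np.ndarray  # sampling times (h)
    pooled_glucose: np.ndarray  # mmol/L
    pooled_insulin: np.ndarray  # mIU/L
    states: np.ndarray  # n_samples x 8 state trajectory at sampling times
    windows: list[str]
    event_log: list[ProtocolEvent]
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per sampling time with pooled observables
        and the full state."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df.insert(1, "pooled_glucose", self.pooled_glucose)
        df.insert(2, "pooled_insulin", self.pooled_insulin)
        df.insert(3, "gtt_window", self.windows)
        return df

    def to_long(self) -> pd.DataFrame:
        """Long form: one row per (time, state variable)."""
        wide = self.to_frame()
        return wide.melt(id_vars=["time_h", "gtt_window"],
                         value_vars=list(STATE_NAMES) + ["pooled_glucose", "pooled_insulin"],
                         var_name="variable", value_name="value")


def _offset_values(tag: OffsetTag, params: ModelParameters) -> tuple[float, float]:
    o = params.offsets
    if tag == "d1":
        return o.dG_d1, o.dI_d1
    if tag == "d13":
        return o.dG_d13, o.dI_d13
    return 0.0, 0.0


def apply_event(state: np.ndarray, event: ProtocolEvent, params: ModelParameters) -> np.ndarray:
    """Instantaneous state update at an event.

    MEDIUM_EXCHANGE replaces the full medium in both compartments:
    glucose and insulin amounts are reset to (dosed concentration +
    applicable offset) * compartment volume.  INSULIN_SPIKE adds insulin
    at the dosed concentration to both compartments.  Slow states are
    untouched.
    """
    g = params.geometry
    y = np.array(state, dtype=float)
    if event.kind == "MEDIUM_EXCHANGE":
        dG, dI = _offset_values(event.applies_offsets, params)
        y[0] = (event.glucose_conc + dG) * g.V_m_liver
        y[1] = (event.glucose_conc + dG) * g.V_m_pancreas
        y[2] = (event.insulin_conc + dI) * g.V_m_liver
        y[3] = (event.insulin_conc + dI) * g.V_m_pancreas
    elif event.kind == "INSULIN_SPIKE":
        y[2] += event.insulin_conc * g.V_m_liver
        y[3] += event.insulin_conc * g.V_m_pancreas
    else:  # pragma: no cover - guarded in ProtocolEvent
        raise ValueError(f"unknown event kind {event.kind!r}")
    return y


class SolverError(RuntimeError):
    def __init__(self, message: str, segment: tuple[float, float], state: np.ndarray):
        super().__init__(f"{message} in segment {segment}")
        self.segment = segment
        self.state = state


def simulate(
    params: ModelParameters,
    protocol: Protocol,
    solver_cfg: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate a protocol segment-by-segment between events.

    Deterministic given ``params`` and ``solver_cfg``.  Pooled observables
    are evaluated at every sample point, honouring its pre/post phase at
    event times.
    """
    cfg = solver_cfg or SolverConfig()
    state = initial_state(params, protocol.initial_glucose)

    # resolve each sample to (time, phase) and collect values as reached
    samples = sorted(protocol.samples, key=lambda s: (s.time, 0 if s.phase == "pre" else 1))
    out_states: dict[int, np.ndarray] = {}

    boundaries = sorted({e.time for e in protocol.events} | {protocol.duration})
    events_at: dict[float, list[ProtocolEvent]] = {}
    for e in protocol.events:
        events_at.setdefault(e.time, []).append(e)
    # events exactly at t=0 apply to the initial state
    t_now = 0.0
    for e in events_at.pop(0.0, []):
        state = apply_event(state, e, params)

    def record(idx: int, y: np.ndarray):
        out_states[idx] = np.array(y)

    def record_at_time(t: float, y: np.ndarray, phase: str):
        for i, sp in enumerate(samples):
            if sp.time == t and sp.phase == phase and i not in out_states:
                record(i, y)

    record_at_time(0.0, state, "post")
    # also serve 'pre' samples at t=0 from the initial state
    record_at_time(0.0, state, "pre")

    atol = np.asarray(cfg.atol, dtype=float) if np.ndim(cfg.atol) else cfg.atol
    for t_end in boundaries:
        if t_end <= t_now:
            continue
        interior = [
            (i, sp) for i, sp in enumerate(samples) if t_now < sp.time < t_end and i not in out_states
        ]
        t_eval = sorted({sp.time for _, sp in interior} | {t_end})
        sol = solve_ivp(
            lambda t, y: ode_rhs(y, params),
            (t_now, t_end),
            state,
            method=cfg.method,
            t_eval=t_eval,
            rtol=cfg.rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(sol.message, (t_now, t_end), state)
        for k, t in enumerate(sol.t):
            for i, sp in interior:
                if sp.time == t:
                    record(i, sol.y[:, k])
        state = sol.y[:, -1]
        t_now = t_end
        # pre-event samples at this boundary read the old medium
        record_at_time(t_now, state, "pre")
        for e in events_at.pop(t_now, []):
            state = apply_event(state, e, params)
        record_at_time(t_now, state, "post")

    missing = [samples[i].time for i in range(len(samples)) if i not in out_states]
    if missing:
        raise SolverError(f"samples not reached: {missing}", (t_now, protocol.duration), state)

    order = np.argsort([sp.time for sp in samples], kind="stable")
    arr = np.stack([out_states[i] for i in order])
    times = np.array([samples[i].time for i in order])
    windows = [samples[i].window for i in order]
    G, I = zip(*(pooled_observables(y, params.geometry) for y in arr))
    return SimulationResult(
        times=times,
        pooled_glucose=np.array(G),
        pooled_insulin=np.array(I),
        states=arr,
        windows=windows,
        event_log=list(protocol.events),
        label=protocol.label,
    )


def gtt_study_protocol(
    culture_glucose: float = GTT_LOAD_MM,
    gtt_days: Iterable[int] = (1, 7, 13),
    gtt_load: float = GTT_LOAD_MM,
    insulin_spike_nM: float | None = None,
    duration_days: float = 15.0,
    exchange_cadence_h: float = 48.0,
    label: str = "",
    spike_offsets: bool = True,
) -> Protocol:
    """The 15-day chip study as a protocol.

    ``culture_glucose`` is the condition's maintenance glucose (5.5 normo-
    / 11 mmol/L hyperglycemic); GTT windows always load ``gtt_load``.
    Day numbers are culture days; model time 0 is the day-1 exchange, so
    day d maps to t = (d - 1) * 24 h.  ``insulin_spike_nM`` adds an
    insulin spike with the day-13 exchange (converted at 6 pmol/L per
    mIU/L).  Day-1/day-13 offset parameters apply at the corresponding
    GTT exchanges.
    """
    duration = (duration_days - 1.0) * HOURS_PER_DAY
    gtt_starts = {(d - 1) * HOURS_PER_DAY: f"day{d}" for d in gtt_days}
    events: list[ProtocolEvent] = []
    t = 0.0
    while t < duration:
        if t in gtt_starts:
            conc = gtt_load
            tag: OffsetTag = "none"
            if t == 0.0:
                tag = "d1"
            elif t == 12 * HOURS_PER_DAY and spike_offsets:
                tag = "d13"
            events.append(ProtocolEvent(t, "MEDIUM_EXCHANGE", glucose_conc=conc, applies_offsets=tag))
        else:
            events.append(ProtocolEvent(t, "MEDIUM_EXCHANGE", glucose_conc=culture_glucose))
        if t == 12 * HOURS_PER_DAY and insulin_spike_nM is not None:
            events.append(
                ProtocolEvent(t, "INSULIN_SPIKE", insulin_conc=nM_to_mIU_per_L(insulin_spike_nM))
            )
        t += exchange_cadence_h

    samples: list[SamplePoint] = []
    for t0, win in sorted(gtt_starts.items()):
        for dt in GTT_SAMPLE_OFFSETS:
            ts = t0 + dt
            if ts > duration:
                continue
            phase = "pre" if (dt == exchange_cadence_h and ts < duration) else "post"
            samples.append(SamplePoint(ts, phase=phase, window=win))
    return Protocol(
        events=tuple(events),
        samples=tuple(samples),
        duration=duration,
        initial_glucose=gtt_load if 0.0 in gtt_starts else culture_glucose,
        label=label,
    )
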