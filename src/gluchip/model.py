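"""Core glucose-insulin model of the two-compartment pancreas-liver chip.

The chip couples a liver compartment (HepaRG spheroids, insulin-dependent
glucose uptake and insulin clearance) and a pancreas compartment (islets,
glucose-stimulated insulin secretion) through a closed medium loop with flow
rate ``Q``.  The dynamics split into a fast component (hours: glucose and
insulin amounts in the medium between exchanges) and a slow component
(weeks: accumulated hyperglycemic exposure, a running average of pancreatic
glucose, and Topp-type beta-cell volume dynamics).

State vector layout (amounts in mmol / mIU, volumes in litres, time in
hours) -- see :data:`STATE_NAMES`:

    0  NG_m_liver      glucose amount, liver medium        (mmol)
    1  NG_m_pancreas   glucose amount, pancreas medium     (mmol)
    2  NI_m_liver      insulin amount, liver medium        (mIU)
    3  NI_m_pancreas   insulin amount, pancreas medium     (mIU)
    4  G_int           integral of excess liver glucose    (mmol*h/L)
    5  G_slow          long-term average pancreas glucose  (mmol/L)
    6  V_beta          beta-cell volume in the islets      (L)
    7  t_state         elapsed co-culture time             (h)

``t_state`` is carried as a state so the time-dependent declines in insulin
sensitivity and secretion capacity survive event-driven solver restarts.
All unit conversions happen at I/O boundaries, never inside the RHS.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "STATE_NAMES",
    "Hypothesis",
    "MPSGeometry",
    "FastParameters",
    "SlowParameters",
    "H2Parameters",
    "OffsetParameters",
    "ModelParameters",
    "insulin_sensitivity",
    "secretion_capacity",
    "ode_rhs",
    "pooled_observables",
    "initial_state",
]

STATE_NAMES = (
    "NG_m_liver",
    "NG_m_pancreas",
    "NI_m_liver",
    "NI_m_pancreas",
    "G_int",
    "G_slow_pancreas",
    "V_beta_islets",
    "t_state",
)

#: 1 mIU/L of insulin expressed in pmol/L (configurable at call sites).
MIU_PER_L_IN_PMOL = 6.00


def nM_to_mIU_per_L(conc_nM: float, pmol_per_mIU: float = MIU_PER_L_IN_PMOL) -> float:
    """Convert an insulin concentration from nmol/L to mIU/L."""
    return conc_nM * 1000.0 / pmol_per_mIU


class Hypothesis(str, enum.Enum):
    """Mechanistic variants of the insulin-sensitivity / secretion equations.

    H1        insulin resistance from hyperglycemic exposure only.
    H2        H1 plus an additional time-driven diabetogenic factor
              (the high-hydrocortisone effect).
    LOW_HCT   physiological hydrocortisone: the time-driven declines in
              S_I(t) and sigma(t) are omitted; the hyperglycemia term
              in S_I is retained.
    """

    H1 = "H1"
    H2 = "H2"
    LOW_HCT = "LOW_HCT"


def _require_positive(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive, got {v!r}")


def _require_nonnegative(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (v >= 0 and math.isfinite(v)):
            raise ValueError(f"{type(obj).__name__}.{name} must be nonnegative, got {v!r}")


@dataclass(frozen=True)
class MPSGeometry:
    """Chip geometry and operation: 300 ul medium per compartment, 15 ul
    GTT draws, inter-compartment flow equivalent to 4.94 ul/min."""

    V_m_liver: float = 300e-6  # L
    V_m_pancreas: float = 300e-6  # L
    V_HepaRG_spheroids: float = 3.0e-6  # L, total HepaRG cell volume (assumed)
    Q: float = 4.94e-6 * 60.0  # L/h  (4.94 ul/min)
    V_sample_liver: float = 15e-6  # L per GTT draw
    V_sample_pancreas: float = 15e-6  # L per GTT draw

    def __post_init__(self):
        _require_positive(
            self,
            [f.name for f in fields(self)],
        )


@dataclass(frozen=True)
class FastParameters:
    """Kinetics of the fast (hours) glucose-insulin subsystem.

    Defaults are documented assumptions chosen to yield realistic 15-day
    chip dynamics; every value is overridable (see data/default_params.yaml).
    """

    E_G0: float = 1.0  # 1/h, insulin-independent glucose disposal
    S_I0: float = 0.033  # L/mIU/h, initial insulin sensitivity
    I_max_Si: float = 0.85  # max fractional S_I reduction by hyperglycemia
    EC50_Si: float = 150.0  # mmol*h/L, half-max excess-glucose integral
    EGP: float = 0.0  # mmol/L/h, endogenous glucose production (fixed 0)
    sigma_max: float = 2.0e6  # mIU/L/h per unit beta-cell volume
    alpha: float = 150.0**2  # h^2, time scale of secretion-capacity decline
    EC50_I: float = 7.0  # mmol/L, half-max glucose for insulin secretion
    k_elimination_I_spheroids: float = 5.0  # 1/h, hepatic insulin elimination
    G_normo: float = 5.5  # mmol/L, normoglycemic reference

    def __post_init__(self):
        _require_nonnegative(self, [f.name for f in fields(self)])
        if self.I_max_Si > 1:
            raise ValueError("I_max_Si must lie in [0, 1]")


@dataclass(frozen=True)
class SlowParameters:
    """Slow (weeks) beta-cell volume dynamics, Topp-type net growth
    -d_0 + r1*G - r2*G^2 with net replication between ~3.8 and ~7.3 mM."""

    k_v: float = 1.0  # dimensionless scaling
    d_0: float = 2.5e-3  # 1/h, death rate at zero glucose
    r1: float = 1.0e-3  # L/mmol/h, composite linear coefficient
    r2: float = 9.0e-5  # L^2/mmol^2/h, composite quadratic coefficient
    tau_slow: float = 24.0  # h, averaging time scale of G_slow
    V_beta_0: float = 8.8e-9  # L, initial beta-cell volume

    def __post_init__(self):
        _require_nonnegative(self, [f.name for f in fields(self)])


@dataclass(frozen=True)
class H2Parameters:
    """Additional time-driven diabetogenic factor on insulin sensitivity
    (the high-hydrocortisone effect under hypothesis H2)."""

    I_max_additional: float = 0.95  # max fractional reduction, in [0, 1]
    EC50_additional: float = 150.0  # h, time at half-max reduction

    def __post_init__(self):
        _require_nonnegative(self, [f.name for f in fields(self)])
        if self.I_max_additional > 1:
            raise ValueError("I_max_additional must lie in [0, 1]")


@dataclass(frozen=True)
class OffsetParameters:
    """Concentration offsets absorbing experimental error at the day-1 and
    day-13 medium exchanges (mmol/L for glucose, mIU/L for insulin)."""

    dG_d1: float = 0.0
    dG_d13: float = 0.0
    dI_d1: float = 0.0
    dI_d13: float = 0.0

    def __post_init__(self):
        for name in ("dG_d1", "dG_d13", "dI_d1", "dI_d13"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"offset {name} must be finite")
        _require_nonnegative(self, ["dI_d1", "dI_d13"])


@dataclass(frozen=True)
class ModelParameters:
    """Single home of every model constant, grouped by subsystem."""

    geometry: MPSGeometry = field(default_factory=MPSGeometry)
    fast: FastParameters = field(default_factory=FastParameters)
    slow: SlowParameters = field(default_factory=SlowParameters)
    h2: H2Parameters | None = None
    offsets: OffsetParameters = field(default_factory=OffsetParameters)
    hypothesis: Hypothesis = Hypothesis.H1

    def __post_init__(self):
        hyp = Hypothesis(self.hypothesis)
        object.__setattr__(self, "hypothesis", hyp)
        if hyp is Hypothesis.H2 and self.h2 is None:
            object.__setattr__(self, "h2", H2Parameters())
        if hyp is not Hypothesis.H2 and self.h2 is not None:
            raise ValueError("h2 parameters are only meaningful under hypothesis H2")

    # -- flat parameter access (used by calibration and serialization) ----
    def get(self, path: str) -> float:
        """Read a parameter by dotted path, e.g. ``'fast.S_I0'``."""
        group, name = path.split(".")
        block = getattr(self, group)
        if block is None:
            raise KeyError(f"parameter block {group!r} absent for hypothesis {self.hypothesis}")
        return getattr(block, name)

    def set(self, updates: dict[str, float]) -> "ModelParameters":
        """Return a copy with dotted-path parameters replaced."""
        grouped: dict[str, dict[str, float]] = {}
        for path, value in updates.items():
            group, name = path.split(".")
            grouped.setdefault(group, {})[name] = float(value)
        changes = {}
        for group, kv in grouped.items():
            block = getattr(self, group)
            if block is None:
                raise KeyError(f"parameter block {group!r} absent for hypothesis {self.hypothesis}")
            changes[group] = replace(block, **kv)
        return replace(self, **changes)

    def with_hypothesis(self, hypothesis: Hypothesis | str) -> "ModelParameters":
        hyp = Hypothesis(hypothesis)
        h2 = self.h2
        if hyp is Hypothesis.H2 and h2 is None:
            h2 = H2Parameters()
        if hyp is not Hypothesis.H2:
            h2 = None
        return replace(self, hypothesis=hyp, h2=h2)


# ---------------------------------------------------------------------------
# closed-form subexpressions


def insulin_sensitivity(t: float, G_int: float, params: ModelParameters) -> float:
    """Insulin sensitivity S_I(t) of the liver spheroids (L/mIU/h).

    Declines from S_I0 with accumulated hyperglycemic exposure
    (saturating in the excess-glucose integral ``G_int``), and -- under
    H2 -- additionally with a sigmoidal function of co-culture time.
    Under LOW_HCT only the hyperglycemia term is retained.
    """
    if t < 0 or G_int < 0:
        raise ValueError(f"insulin_sensitivity requires t >= 0 and G_int >= 0, got t={t}, G_int={G_int}")
    f = params.fast
    s = f.S_I0 * (1.0 - f.I_max_Si * G_int / (f.EC50_Si + G_int))
    if params.hypothesis is Hypothesis.H2:
        h2 = params.h2
        s *= 1.0 - h2.I_max_additional * t * t / (h2.EC50_additional**2 + t * t)
    return s


def secretion_capacity(t: float, params: ModelParameters) -> float:
    """Insulin secretion capacity sigma(t) per unit beta-cell volume
    (mIU/L/h): sigma_max * (1 - t^2/(alpha + t^2)) under H1/H2, constant
    sigma_max under LOW_HCT."""
    if t < 0:
        raise ValueError(f"secretion_capacity requires t >= 0, got {t}")
    f = params.fast
    if params.hypothesis is Hypothesis.LOW_HCT:
        return f.sigma_max
    return f.sigma_max * (1.0 - t * t / (f.alpha + t * t))


def ode_rhs(state: Sequence[float], params: ModelParameters, G_d: float = 0.0) -> np.ndarray:
    """Time derivatives of all eight states (see module docstring).

    ``G_d`` is a continuous glucose dosing rate (mmol/h) applied to both
    compartments; shipped protocols realize dosing as instantaneous
    exchange events and keep it at 0.
    """
    if len(state) != 8:
        raise ValueError("state must be 8 finite values")
    NG_l, NG_p, NI_l, NI_p, G_int, G_slow, V_beta, t = (float(v) for v in state)
    if not math.isfinite(NG_l + NG_p + NI_l + NI_p + G_int + G_slow + V_beta + t):
        raise ValueError("state must be 8 finite values")
    if G_d < 0:
        raise ValueError("G_d must be nonnegative")
    g = params.geometry
    f = params.fast
    s = params.slow

    G_liver = NG_l / g.V_m_liver
    G_panc = NG_p / g.V_m_pancreas
    I_liver = NI_l / g.V_m_liver
    I_panc = NI_p / g.V_m_pancreas

    # closed forms inlined for speed; definitions in insulin_sensitivity
    # and secretion_capacity
    Gi = G_int if G_int > 0 else 0.0
    S_I = f.S_I0 * (1.0 - f.I_max_Si * Gi / (f.EC50_Si + Gi))
    if params.hypothesis is Hypothesis.H2:
        h2 = params.h2
        S_I *= 1.0 - h2.I_max_additional * t * t / (h2.EC50_additional**2 + t * t)
    if params.hypothesis is Hypothesis.LOW_HCT:
        sigma = f.sigma_max
    else:
        sigma = f.sigma_max * (1.0 - t * t / (f.alpha + t * t))

    dNG_l = (
        G_d
        + g.V_HepaRG_spheroids * f.EGP
        - g.V_HepaRG_spheroids * (f.E_G0 + S_I * I_liver) * G_liver
        + g.Q * G_panc
        - g.Q * G_liver
    )
    dNG_p = G_d + g.Q * G_liver - g.Q * G_panc
    secretion = V_beta * sigma * G_panc**2 / (f.EC50_I**2 + G_panc**2)
    dNI_p = secretion + g.Q * I_liver - g.Q * I_panc
    dNI_l = g.Q * I_panc - g.Q * I_liver - g.V_HepaRG_spheroids * f.k_elimination_I_spheroids * I_liver
    dG_int = max(G_liver - f.G_normo, 0.0)
    dG_slow = (G_panc - G_slow) / s.tau_slow
    dV_beta = s.k_v * (-s.d_0 + s.r1 * G_slow - s.r2 * G_slow**2) * V_beta
    return np.array([dNG_l, dNG_p, dNI_l, dNI_p, dG_int, dG_slow, dV_beta, 1.0])


def pooled_observables(state: Sequence[float], geometry: MPSGeometry) -> tuple[float, float]:
    """Pooled (glucose mmol/L, insulin mIU/L) as the sample-volume-weighted
    mean of the two compartment concentrations -- the quantity the pooled
    15 ul + 15 ul GTT draws measure."""
    y = np.asarray(state, dtype=float)
    vl, vp = geometry.V_sample_liver, geometry.V_sample_pancreas
    total = vl + vp
    if total <= 0:
        raise ValueError("total sample volume must be positive")
    G = (y[0] / geometry.V_m_liver * vl + y[1] / geometry.V_m_pancreas * vp) / total
    I = (y[2] / geometry.V_m_liver * vl + y[3] / geometry.V_m_pancreas * vp) / total
    return G, I


def initial_state(params: ModelParameters, G_dose: float) -> np.ndarray:
    """State at the day-1 medium exchange that starts the first GTT:
    glucose load plus day-1 offsets in both compartments, day-1 insulin
    offset, zero exposure integral, normoglycemic G_slow, nominal
    beta-cell volume."""
    if G_dose < 0:
        raise ValueError("G_dose must be nonnegative")
    g, o = params.geometry, params.offsets
    return np.array(
        [
            (G_dose + o.dG_d1) * g.V_m_liver,
            (G_dose + o.dG_d1) * g.V_m_pancreas,
            o.dI_d1 * g.V_m_liver,
            o.dI_d1 * g.V_m_pancreas,
            0.0,
            params.fast.G_normo,
            params.slow.V_beta_0,
            0.0,
        ]
    )
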