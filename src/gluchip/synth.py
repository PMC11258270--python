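"""Synthetic GTT studies and endpoint matrices.

The generator emulates the statistical structure of the chip studies so
calibration, hypothesis testing and reproducibility statistics can be
exercised end-to-end without measured data: pooled glucose/insulin GTT
curves sampled at +0/+8/+24/+48 h of each window over a 15-day protocol,
with 2-6 replicate circuits, multiplicative (CV-style) measurement noise
and SEM summaries, plus nested lab/study/circuit endpoint matrices for
the reproducibility metrics.  Ground truth is sealed in a separate
record so pipeline code cannot accidentally read it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import GTTDataset
from .model import Hypothesis, ModelParameters, nM_to_mIU_per_L
from .protocol import Protocol, SolverConfig, gtt_study_protocol, simulate
from .repro import EndpointMatrix

__all__ = [
    "Condition",
    "StudyDesign",
    "GroundTruth",
    "GTTStudy",
    "generate_gtt_study",
    "EndpointDesign",
    "generate_endpoint_matrix",
]


@dataclass(frozen=True)
class Condition:
    """One culture arm: maintenance glucose (5.5 normo- or 11 mmol/L
    hyperglycemic) and hydrocortisone regime (high 50 uM / low 10 nM)."""

    glucose: float = 11.0
    hct: str = "high"

    def __post_init__(self):
        if self.hct not in ("high", "low"):
            raise ValueError("hct regime must be 'high' or 'low'")

    @property
    def label(self) -> str:
        glyc = "hyper" if self.glucose > 8.0 else "normo"
        return f"{glyc}-{self.hct}HCT"


@dataclass(frozen=True)
class StudyDesign:
    """Layout and noise model of one synthetic chip study."""

    conditions: tuple[Condition, ...] = (Condition(11.0, "high"), Condition(5.5, "high"))
    n_circuits: int = 4
    gtt_days: tuple[int, ...] = (1, 7, 13)
    spike_nM: float | None = None  # insulin spiked with the day-13 exchange
    noise_cv: float = 0.10  # multiplicative Gaussian noise, CV per sample
    noise_abs: float | None = None  # absolute-noise mode (same units as signal)
    donor_si_mult: float = 1.0  # donor effect on initial insulin sensitivity
    donor_sigma_mult: float = 1.0  # donor effect on secretion capacity
    seed: int = 0

    def __post_init__(self):
        if self.n_circuits < 2:
            raise ValueError("need at least 2 replicate circuits")
        if self.noise_cv < 0 or (self.noise_abs is not None and self.noise_abs < 0):
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Sealed record of what generated the study (for recovery scoring
    only -- pipeline code must not read it)."""

    params_by_condition: dict[str, ModelParameters]
    truth_curves: dict[str, pd.DataFrame]
    design: StudyDesign
    n_truncated: int  # noisy draws clipped at zero concentration


@dataclass(frozen=True)
class GTTStudy:
    datasets: list[GTTDataset]
    protocols: list[Protocol]
    truth: GroundTruth


def condition_params(true_params: ModelParameters, cond: Condition, design: StudyDesign) -> ModelParameters:
    """Parameters governing one condition: donor multipliers applied,
    low-HCT arms switched to the LOW_HCT equations."""
    p = true_params.set(
        {
            "fast.S_I0": true_params.fast.S_I0 * design.donor_si_mult,
            "fast.sigma_max": true_params.fast.sigma_max * design.donor_sigma_mult,
        }
    )
    if cond.hct == "low":
        p = p.with_hypothesis(Hypothesis.LOW_HCT)
    return p


def condition_protocol(cond: Condition, design: StudyDesign, label: str | None = None) -> Protocol:
    return gtt_study_protocol(
        culture_glucose=cond.glucose,
        gtt_days=design.gtt_days,
        insulin_spike_nM=design.spike_nM if 13 in design.gtt_days else None,
        label=label or cond.label,
    )


def generate_gtt_study(
    true_params: ModelParameters,
    design: StudyDesign,
    solver_cfg: SolverConfig | None = None,
) -> GTTStudy:
    """Simulate each condition, draw noisy replicate circuits, and emit
    mean/SEM datasets in the calibration input format.  Fully
    reproducible from ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    datasets, protocols = [], []
    params_by_condition, truth_curves = {}, {}
    n_truncated = 0
    for cond in design.conditions:
        params = condition_params(true_params, cond, design)
        proto = condition_protocol(cond, design)
        sim = simulate(params, proto, solver_cfg)
        params_by_condition[cond.label] = params
        truth_curves[cond.label] = sim.to_frame()[["time_h", "gtt_window", "pooled_glucose", "pooled_insulin"]]

        rows = []
        nominal: dict[tuple[str, str], float] = {}
        spike_mIU = nM_to_mIU_per_L(design.spike_nM) if design.spike_nM is not None else 0.0
        for signal, curve in (("glucose", sim.pooled_glucose), ("insulin", sim.pooled_insulin)):
            for t, win, truth in zip(sim.times, sim.windows, curve):
                if design.noise_abs is not None:
                    reps = truth + design.noise_abs * rng.standard_normal(design.n_circuits)
                else:
                    reps = truth * (1.0 + design.noise_cv * rng.standard_normal(design.n_circuits))
                n_truncated += int(np.sum(reps < 0))
                reps = np.maximum(reps, 0.0)
                rows.append(
                    {
                        "signal": signal,
                        "time_h": float(t),
                        "mean": float(reps.mean()),
                        "sem": float(reps.std(ddof=1) / np.sqrt(design.n_circuits)),
                        "n": design.n_circuits,
                        "gtt_window": win,
                    }
                )
        for win in sorted(set(sim.windows)):
            nominal[(win, "glucose")] = 11.0
            nominal[(win, "insulin")] = spike_mIU if win == "day13" else 0.0
        datasets.append(GTTDataset(cond.label, pd.DataFrame(rows), nominal))
        protocols.append(proto)
    truth = GroundTruth(params_by_condition, truth_curves, design, n_truncated)
    return GTTStudy(datasets, protocols, truth)


# ---------------------------------------------------------------------------
# nested-variance endpoint matrices


@dataclass(frozen=True)
class EndpointDesign:
    n_labs: int = 2
    n_studies_per_lab: int = 2
    n_circuits: int = 4
    n_timepoints: int = 7
    baseline: float = 10.0
    trend_amplitude: float = 0.0  # deterministic timepoint trend (between-target signal)
    condition: str = "healthy"
    seed: int = 0


def generate_endpoint_matrix(
    variance_components: dict[str, float],
    design: EndpointDesign,
) -> list[EndpointMatrix]:
    """Draw circuit x timepoint matrices with nested lab -> study ->
    circuit random effects plus residual noise around a time trend.

    ``variance_components`` holds variances for keys ``lab``, ``study``,
    ``circuit`` and ``residual`` (missing keys default to 0).  Returns
    one matrix per (lab, study)."""
    vc = {k: float(variance_components.get(k, 0.0)) for k in ("lab", "study", "circuit", "residual")}
    if any(v < 0 for v in vc.values()):
        raise ValueError("variance components must be nonnegative")
    rng = np.random.default_rng(design.seed)
    t = np.arange(design.n_timepoints)
    trend = design.baseline + design.trend_amplitude * np.sin(2 * np.pi * t / max(design.n_timepoints, 2))
    out = []
    for lab in range(design.n_labs):
        b_lab = rng.normal(0.0, np.sqrt(vc["lab"]))
        for study in range(design.n_studies_per_lab):
            b_study = rng.normal(0.0, np.sqrt(vc["study"]))
            b_circ = rng.normal(0.0, np.sqrt(vc["circuit"]), size=design.n_circuits)
            eps = rng.normal(0.0, np.sqrt(vc["residual"]), size=(design.n_circuits, design.n_timepoints))
            values = trend[None, :] + b_lab + b_study + b_circ[:, None] + eps
            out.append(
                EndpointMatrix(
                    values=values,
                    condition=design.condition,
                    study=f"lab{lab+1}-study{study+1}",
                    lab=f"lab{lab+1}",
                )
            )
    return out
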