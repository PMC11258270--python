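"""Decision workflows built on the calibrated model.

Three procedures: (1) chi-square validation of a calibrated hypothesis
against held-out GTT data, (2) selection of an insulin dose whose spiked
GTT separates the glucose predictions of two competing hypotheses by more
than the measurement noise, and (3) prediction of the low-hydrocortisone
response by re-baselining insulin sensitivity and secretion capacity on
an early GTT and switching off the time-driven decline terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .calibration import (
    FitConfig,
    GTTDataset,
    ParameterEnsemble,
    PredictionEnvelope,
    chi2_threshold,
    cost,
    envelope_member_indices,
    fit,
    predict_envelope,
)
from .model import Hypothesis
from .protocol import Protocol, SolverConfig

__all__ = [
    "HypothesisVerdict",
    "DoseDesignResult",
    "LowHCTPrediction",
    "test_hypothesis",
    "design_discriminating_dose",
    "predict_low_hct",
]


@dataclass(frozen=True)
class HypothesisVerdict:
    accepted: bool
    min_cost: float
    threshold: float
    df: int
    n_members_evaluated: int


def test_hypothesis(
    ensemble: ParameterEnsemble,
    validation: GTTDataset,
    protocol: Protocol,
    alpha: float = 0.05,
    df: int | None = None,
    max_members: int = 50,
    solver_cfg: SolverConfig | None = None,
) -> HypothesisVerdict:
    """Chi-square validation of a calibrated hypothesis.

    Simulates the validation protocol for a representative subset of the
    acceptable set (the optimum, the per-parameter extremes, and the
    lowest-calibration-cost members up to ``max_members``) and accepts
    the hypothesis if any member's validation cost passes the chi-square
    threshold -- the ensemble is the model's uncertainty, so one member
    explaining the held-out data suffices.  The subset is selected by
    cost and parameter value, so the verdict does not depend on the
    storage order of the ensemble.
    """
    if not ensemble.acceptable:
        raise ValueError("cannot validate an empty acceptable set")
    n_df = df if df is not None else validation.n_points
    threshold = chi2_threshold(n_df, alpha)
    chosen = set(envelope_member_indices(ensemble))
    for i in np.argsort(ensemble.costs, kind="stable"):
        if len(chosen) >= max_members:
            break
        chosen.add(int(i))
    indices = sorted(chosen)
    best = np.inf
    for i in indices:
        c = cost(ensemble.member_params(i), [validation], [protocol], solver_cfg)
        best = min(best, c)
    return HypothesisVerdict(
        accepted=bool(best <= threshold),
        min_cost=float(best),
        threshold=threshold,
        df=n_df,
        n_members_evaluated=len(indices),
    )


@dataclass(frozen=True)
class DoseDesignResult:
    chosen_dose: float | None  # smallest discriminating dose, None if none found
    separation_by_dose: dict[float, float]  # dose -> maximal envelope gap (mmol/L)
    required_separation: float  # the average-SEM criterion


def _envelope_gap(a: PredictionEnvelope, b: PredictionEnvelope) -> np.ndarray:
    """Pointwise gap between two glucose envelopes (0 where they overlap)."""
    if not np.array_equal(a.times, b.times):
        raise ValueError("envelopes must share a time grid")
    return np.maximum(0.0, np.maximum(a.glucose_lower - b.glucose_upper, b.glucose_lower - a.glucose_upper))


def design_discriminating_dose(
    ens_h1: ParameterEnsemble,
    ens_h2: ParameterEnsemble,
    candidate_doses_nM: Sequence[float],
    protocol_for_dose: Callable[[float], Protocol],
    average_sem: float,
    solver_cfg: SolverConfig | None = None,
) -> DoseDesignResult:
    """Pick the smallest insulin dose whose spiked-GTT glucose envelopes
    for the two hypotheses separate by more than ``average_sem`` (the
    mean glucose SEM of the calibration data) at one or more sampling
    times.  Candidate doses must be sorted ascending."""
    doses = list(candidate_doses_nM)
    if doses != sorted(doses):
        raise ValueError("candidate doses must be sorted ascending")
    separation: dict[float, float] = {}
    chosen = None
    for dose in doses:
        proto = protocol_for_dose(dose)
        env1 = predict_envelope(ens_h1, proto, solver_cfg)
        env2 = predict_envelope(ens_h2, proto, solver_cfg)
        gap = float(_envelope_gap(env1, env2).max())
        separation[dose] = gap
        if chosen is None and gap > average_sem:
            chosen = dose
    return DoseDesignResult(chosen, separation, average_sem)


@dataclass
class LowHCTPrediction:
    envelope: PredictionEnvelope
    baseline_ensemble: ParameterEnsemble
    baseline_cost: float
    baseline_threshold: float
    reliable: bool  # False if the baseline re-fit failed its chi-square test


def predict_low_hct(
    ens_high_hct: ParameterEnsemble,
    baseline_gtt: GTTDataset,
    baseline_protocol: Protocol,
    prediction_protocol: Protocol,
    fit_cfg: FitConfig | None = None,
    bounds_factor: float = 10.0,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
) -> LowHCTPrediction:
    """Out-of-sample prediction of the physiological-hydrocortisone GTT.

    Starting from the high-HCT optimum, re-optimizes only the initial
    insulin sensitivity (fast.S_I0) and the maximal secretion capacity
    (fast.sigma_max) against the early baseline GTT under the LOW_HCT
    equations (time-driven declines removed), all other parameters
    frozen; the resulting acceptable set yields the prediction envelope
    for the full protocol.
    """
    opt = ens_high_hct.optimum_params.with_hypothesis(Hypothesis.LOW_HCT)
    start = {"fast.S_I0": opt.fast.S_I0, "fast.sigma_max": opt.fast.sigma_max}
    if fit_cfg is None:
        free = {k: (v / bounds_factor, v * bounds_factor) for k, v in start.items()}
        fit_cfg = FitConfig(free=free, n_restarts=2, n_iter=150, seed=seed, start=start)
    else:
        fit_cfg = replace(fit_cfg, start=dict(fit_cfg.start or start))
    ens = fit([baseline_gtt], [baseline_protocol], opt, fit_cfg)
    reliable = ens.acceptable
    if not reliable:
        # prediction still emitted from the best-found baseline, flagged
        ens = replace_ensemble_with_best(ens)
    env = predict_envelope(ens, prediction_protocol, solver_cfg)
    return LowHCTPrediction(
        envelope=env,
        baseline_ensemble=ens,
        baseline_cost=ens.best_cost,
        baseline_threshold=ens.threshold,
        reliable=reliable,
    )


def replace_ensemble_with_best(ens: ParameterEnsemble) -> ParameterEnsemble:
    """Degenerate one-member ensemble holding only the best-found vector
    (used when nothing passed the chi-square gate)."""
    return ParameterEnsemble(
        names=ens.names,
        vectors=ens.best_vector[None, :],
        costs=np.array([ens.best_cost]),
        threshold=ens.threshold,
        base_params=ens.base_params,
        best_vector=ens.best_vector,
        best_cost=ens.best_cost,
        seed=ens.seed,
        n_evaluations=ens.n_evaluations,
    )
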