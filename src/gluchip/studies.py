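"""Desk-scale in-silico studies exercising the full pipeline.

Each study generates synthetic chip data with the statistical structure
of the wet-lab experiments (pooled GTT means with SEM over replicate
circuits, 10% multiplicative assay noise, 4 circuits by default),
runs the corresponding analysis workflow, and scores it against the
sealed ground truth.  They are the workhorses of the analysis scripts,
the test suite and the acceptance script; sizes (annealing budget,
replicate counts) are deliberately modest so a full battery runs on a
laptop in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import (
    FitConfig,
    GTTDataset,
    ParameterEnsemble,
    chi2_threshold,
    cost,
    envelope_member_indices,
    fit,
    preprocess_sem,
    total_residuals,
)
from .model import Hypothesis, ModelParameters
from .protocol import Protocol, SolverConfig, gtt_study_protocol
from .repro import icc2
from .synth import (
    Condition,
    EndpointDesign,
    StudyDesign,
    condition_protocol,
    generate_endpoint_matrix,
    generate_gtt_study,
)
from .workflows import design_discriminating_dose, predict_low_hct

__all__ = [
    "STUDY_SOLVER",
    "RecoveryResult",
    "recovery_study",
    "DiscriminationResult",
    "discrimination_study",
    "CoverageResult",
    "lowhct_coverage_study",
    "residual_icc_study",
]

#: Solver tolerances for iterative study fits: measurement noise (10% CV)
#: dominates integration error by >3 orders of magnitude at this setting.
STUDY_SOLVER = SolverConfig(rtol=1e-5, atol=(1e-9,) * 4 + (1e-5, 1e-5, 1e-14, 1e-3))

RECOVERY_FREE = {"fast.S_I0": (1e-3, 1.0), "fast.sigma_max": (1e5, 4e7)}


def _donor_multipliers(rng: np.random.Generator, spread: float = 0.25) -> tuple[float, float]:
    """Lognormal donor effects on initial insulin sensitivity and
    secretion capacity (the two axes donors differ on)."""
    return tuple(np.exp(rng.normal(0.0, spread, size=2)))


@dataclass
class RecoveryResult:
    seeds: list[int]
    rel_errors: dict[str, list[float]]  # parameter -> per-seed |rel. error|
    noiseless_rel_errors: dict[str, float]

    def median_abs_rel_error(self, name: str) -> float:
        return float(np.median(self.rel_errors[name]))


def _single_condition_design(seed: int, noise_cv: float, n_circuits: int,
                             si_mult: float, sigma_mult: float) -> StudyDesign:
    return StudyDesign(
        conditions=(Condition(11.0, "high"),),
        n_circuits=n_circuits,
        gtt_days=(1, 7),
        noise_cv=noise_cv,
        donor_si_mult=si_mult,
        donor_sigma_mult=sigma_mult,
        seed=seed,
    )


def recovery_study(
    base_params: ModelParameters,
    seeds: Sequence[int] = tuple(range(10)),
    noise_cv: float = 0.10,
    n_circuits: int = 4,
    n_iter: int = 150,
    n_restarts: int = 2,
) -> RecoveryResult:
    """Can calibration recover donor-scaled S_I0 and sigma_max?

    Per seed: a hyperglycemic 9-day study (GTT windows on days 1 and 7)
    is generated with lognormally drawn donor multipliers on the two
    target parameters; annealing with those two parameters free (started
    from the unscaled nominal values) is scored by absolute relative
    error against the sealed truth.  A noiseless run checks the
    estimator's consistency.
    """
    names = list(RECOVERY_FREE)
    rel_errors: dict[str, list[float]] = {n: [] for n in names}

    def run_one(seed: int, cv: float) -> dict[str, float]:
        rng = np.random.default_rng(seed + 1)
        si_mult, sig_mult = _donor_multipliers(rng)
        design = _single_condition_design(seed, cv, n_circuits, si_mult, sig_mult)
        study = generate_gtt_study(base_params, design, STUDY_SOLVER)
        if cv == 0:
            # noiseless data: SEMs are identically zero, so weighted least
            # squares degenerates; use unit weights instead of the floor rule
            datasets = []
            for ds in study.datasets:
                tab = ds.table.copy()
                tab["sem"] = 1.0
                datasets.append(GTTDataset(ds.condition, tab, dict(ds.nominal)))
        else:
            datasets = [preprocess_sem(ds) for ds in study.datasets]
        cfg = FitConfig(
            free=RECOVERY_FREE,
            n_restarts=n_restarts,
            n_iter=n_iter,
            seed=seed,
            solver_cfg=STUDY_SOLVER,
            start={n: base_params.get(n) for n in names},
        )
        ens = fit(datasets, study.protocols, base_params, cfg)
        truth = study.truth.params_by_condition[design.conditions[0].label]
        est = ens.optimum_params
        return {n: abs(est.get(n) - truth.get(n)) / truth.get(n) for n in names}

    for seed in seeds:
        errs = run_one(seed, noise_cv)
        for n, e in errs.items():
            rel_errors[n].append(e)
    noiseless = run_one(seeds[0], 0.0)
    return RecoveryResult(list(seeds), rel_errors, noiseless)


# ---------------------------------------------------------------------------
# hypothesis discrimination (scaled-down replica of the two-hypothesis study)

# Calibration mirrors the decision workflow: donor-dependent parameters
# (initial insulin sensitivity, secretion capacity) are re-estimated per
# study, the shared hyperglycemia kinetics stay at their nominal values,
# and the additional diabetogenic factor -- the substance of H2 -- is
# estimated only under H2.
DISCRIMINATION_FREE_H1 = {
    "fast.S_I0": (1e-3, 1.0),
    "fast.sigma_max": (1e5, 4e7),
}
DISCRIMINATION_FREE_H2 = DISCRIMINATION_FREE_H1 | {
    "h2.I_max_additional": (1e-3, 1.0),
    "h2.EC50_additional": (20.0, 2000.0),
}


@dataclass
class DiscriminationResult:
    replicates: int
    h1_rejected: list[bool]
    h2_accepted: list[bool]
    h1_validation_costs: list[float]
    h2_validation_costs: list[float]
    validation_threshold: float
    chosen_doses_nM: list[float]

    @property
    def h1_rejection_rate(self) -> float:
        return float(np.mean(self.h1_rejected))

    @property
    def h2_acceptance_rate(self) -> float:
        return float(np.mean(self.h2_accepted))

    @property
    def discrimination_rate(self) -> float:
        both = [r and a for r, a in zip(self.h1_rejected, self.h2_accepted)]
        return float(np.mean(both))


def _validation_glucose(ds: GTTDataset) -> GTTDataset:
    """Glucose rows excluding each window's start sample."""
    tab = ds.table
    keep = tab["signal"] == "glucose"
    for win, sub in tab[keep].groupby("gtt_window"):
        t0 = sub["time_h"].min()
        keep &= ~((tab["gtt_window"] == win) & (tab["time_h"] == t0))
    return GTTDataset(ds.condition, tab[keep].reset_index(drop=True), dict(ds.nominal))


def _min_validation_cost(
    ens: ParameterEnsemble,
    valid: list[GTTDataset],
    protocols: list[Protocol],
    max_members: int,
    solver_cfg: SolverConfig,
) -> float:
    """Minimal pooled validation cost over a cost-ranked member subset
    (optimum + per-parameter extremes + best calibration members)."""
    chosen = set(envelope_member_indices(ens))
    for i in np.argsort(ens.costs, kind="stable"):
        if len(chosen) >= max_members:
            break
        chosen.add(int(i))
    best = np.inf
    for i in sorted(chosen):
        best = min(best, cost(ens.member_params(i), valid, protocols, solver_cfg))
    return best


DOSE_GRID_NM = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 32.0)


def discrimination_study(
    true_params: ModelParameters,
    n_replicates: int = 20,
    seed0: int = 0,
    n_iter: int = 150,
    max_members: int = 25,
    dose_grid_nM: Sequence[float] = DOSE_GRID_NM,
) -> DiscriminationResult:
    """Replica of the two-hypothesis decision workflow.

    Per replicate: data are generated under H2 (strong additional
    diabetogenic factor) for a hyperglycemic and a normoglycemic arm;
    H1 and H2 are calibrated on the day-1 and day-7 GTT windows; the
    insulin dose for the day-13 spike is selected so the two calibrated
    models' glucose envelopes separate by more than the average glucose
    SEM of the calibration data (falling back to the largest-gap dose if
    none formally discriminates); the day-13 spiked GTT is then
    "performed" (generated at the chosen dose) and each hypothesis is
    validated against it.  A hypothesis is accepted when any
    acceptable-set member's pooled validation cost passes the chi-square
    threshold; H1 counts as rejected when its calibration finds no
    acceptable set or its validation fails.
    """
    truth = true_params.with_hypothesis(Hypothesis.H2)
    h1_rej, h2_acc, c1, c2, doses = [], [], [], [], []
    threshold = None
    conditions = (Condition(11.0, "high"), Condition(5.5, "high"))
    for r in range(n_replicates):
        seed = seed0 + 1000 * (r + 1)
        rng = np.random.default_rng(seed)
        si_mult, sig_mult = _donor_multipliers(rng, spread=0.15)

        def make_design(spike: float | None) -> StudyDesign:
            return StudyDesign(
                conditions=conditions,
                n_circuits=4,
                gtt_days=(1, 7, 13),
                spike_nM=spike,
                noise_cv=0.10,
                donor_si_mult=si_mult,
                donor_sigma_mult=sig_mult,
                seed=seed,
            )

        # phase 1: days 1-9 exist, the day-13 dose is not yet decided
        study = generate_gtt_study(truth, make_design(None), STUDY_SOLVER)
        datasets = [preprocess_sem(ds) for ds in study.datasets]
        calib = [ds.subset_windows(["day1", "day7"]) for ds in datasets]

        ensembles = {}
        for hyp, free in (("H1", DISCRIMINATION_FREE_H1), ("H2", DISCRIMINATION_FREE_H2)):
            base = true_params.with_hypothesis(hyp)
            cfg = FitConfig(
                free=free,
                n_restarts=2,
                n_iter=n_iter,
                seed=seed,
                solver_cfg=STUDY_SOLVER,
                start={n: base.get(n) for n in free},
            )
            ensembles[hyp] = fit(calib, study.protocols, base, cfg)

        if not ensembles["H1"].acceptable:
            # H1 already fails in calibration; validate H2 at the nominal dose
            chosen = DOSE_GRID_NM[-2]
        else:
            glu = [ds.table[ds.table["signal"] == "glucose"] for ds in calib]
            avg_sem = float(np.mean(np.concatenate([g["sem"].to_numpy() for g in glu])))
            gaps: dict[float, float] = {d: 0.0 for d in dose_grid_nM}
            for cond in conditions:
                res = design_discriminating_dose(
                    ensembles["H1"],
                    ensembles["H2"],
                    list(dose_grid_nM),
                    lambda d, c=cond: condition_protocol(c, make_design(d)),
                    avg_sem,
                    STUDY_SOLVER,
                )
                for d, g in res.separation_by_dose.items():
                    gaps[d] = max(gaps[d], g)
            passing = [d for d in dose_grid_nM if gaps[d] > avg_sem]
            if passing:
                chosen = passing[0]
            else:
                # no formal discriminator: largest-gap dose, ties to the
                # largest dose (more insulin probes sensitivity harder)
                best_gap = max(gaps.values())
                chosen = max(d for d in gaps if gaps[d] == best_gap)
        doses.append(float(chosen))

        # phase 2: the day-13 spiked GTT is performed at the chosen dose
        # (same seed: donor effects and day-1/-7 measurements are unchanged)
        study2 = generate_gtt_study(truth, make_design(float(chosen)), STUDY_SOLVER)
        datasets2 = [preprocess_sem(ds) for ds in study2.datasets]
        # the hypotheses are discriminated on the glucose tolerance curves;
        # the window-start sample is fixed by the exchange itself and carries
        # no information, so validation uses the three post-load glucose
        # samples per arm (six residuals in this two-arm design)
        valid = [_validation_glucose(ds.subset_windows(["day13"])) for ds in datasets2]
        threshold = chi2_threshold(total_residuals(valid))

        verdicts = {}
        for hyp in ("H1", "H2"):
            ens = ensembles[hyp]
            if not ens.acceptable:
                verdicts[hyp] = (False, np.inf)
                continue
            v = _min_validation_cost(ens, valid, study2.protocols, max_members, STUDY_SOLVER)
            verdicts[hyp] = (v <= threshold, v)
        h1_rej.append(not verdicts["H1"][0])
        h2_acc.append(verdicts["H2"][0])
        c1.append(float(verdicts["H1"][1]))
        c2.append(float(verdicts["H2"][1]))
    return DiscriminationResult(n_replicates, h1_rej, h2_acc, c1, c2, float(threshold), doses)


# ---------------------------------------------------------------------------
# low-hydrocortisone prediction coverage


@dataclass
class CoverageResult:
    seeds: list[int]
    covered: list[bool]
    reliable: list[bool]

    @property
    def coverage_rate(self) -> float:
        return float(np.mean(self.covered))


def lowhct_coverage_study(
    base_params: ModelParameters,
    seeds: Sequence[int] = tuple(range(20)),
    n_iter: int = 150,
) -> CoverageResult:
    """Does the low-hydrocortisone prediction envelope contain the true
    late-culture glucose response?

    Per seed a hyperglycemic low-HCT study (no decline terms) is
    generated with donor-scaled S_I0 / sigma_max; the predictor starts
    from a deliberately donor-naive high-HCT optimum, re-baselines the
    two parameters on the day-1 GTT only, and must bracket the sealed
    day-13 window glucose truth with its envelope.
    """
    covered, reliable = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed + 1)
        si_mult, sig_mult = _donor_multipliers(rng)
        design = StudyDesign(
            conditions=(Condition(11.0, "low"),),
            n_circuits=4,
            gtt_days=(1, 13),
            noise_cv=0.10,
            donor_si_mult=si_mult,
            donor_sigma_mult=sig_mult,
            seed=seed + 500,
        )
        study = generate_gtt_study(base_params, design, STUDY_SOLVER)
        ds = preprocess_sem(study.datasets[0])
        full_proto = study.protocols[0]
        baseline = ds.subset_windows(["day1"])
        baseline_proto = gtt_study_protocol(11.0, gtt_days=(1,), duration_days=3,
                                            label="baseline-day1")
        # donor-naive start: the high-HCT optimum knows nothing of this donor
        high_opt = base_params.with_hypothesis(Hypothesis.H2)
        ens_high = _singleton_ensemble(high_opt)
        cfg = FitConfig(
            free={k: (v / 30.0, v * 30.0) for k, v in
                  (("fast.S_I0", high_opt.fast.S_I0), ("fast.sigma_max", high_opt.fast.sigma_max))},
            n_restarts=2,
            n_iter=n_iter,
            seed=seed,
            solver_cfg=STUDY_SOLVER,
        )
        pred = predict_low_hct(ens_high, baseline, baseline_proto, full_proto,
                               fit_cfg=cfg, solver_cfg=STUDY_SOLVER)
        truth_curve = study.truth.truth_curves[design.conditions[0].label]
        day13 = truth_curve[truth_curve["gtt_window"] == "day13"]
        env = pred.envelope.to_frame()
        env13 = env[env["gtt_window"] == "day13"].set_index("time_h")
        ok = True
        for row in day13.itertuples(index=False):
            lo = env13.loc[row.time_h, "glucose_lower"]
            hi = env13.loc[row.time_h, "glucose_upper"]
            if not (lo - 1e-9 <= row.pooled_glucose <= hi + 1e-9):
                ok = False
        covered.append(ok)
        reliable.append(pred.reliable)
    return CoverageResult(list(seeds), covered, reliable)


def _singleton_ensemble(params: ModelParameters) -> ParameterEnsemble:
    names = ["fast.S_I0", "fast.sigma_max"]
    vec = np.array([params.get(n) for n in names])
    return ParameterEnsemble(
        names=names,
        vectors=vec[None, :],
        costs=np.array([0.0]),
        threshold=np.inf,
        base_params=params,
        best_vector=vec,
        best_cost=0.0,
        seed=0,
        n_evaluations=1,
    )


# ---------------------------------------------------------------------------
# reproducibility statistics under known variance structure


def residual_icc_study(n_seeds: int = 100, seed0: int = 0,
                       components: dict[str, float] | None = None,
                       trend_amplitude: float = 0.0) -> np.ndarray:
    """ICC(2,1) of synthetic endpoint matrices with known variance
    structure; returns one ICC per seed (first matrix of each draw)."""
    comps = components if components is not None else {"residual": 1.0}
    out = []
    for s in range(n_seeds):
        mats = generate_endpoint_matrix(
            comps,
            EndpointDesign(n_labs=1, n_studies_per_lab=1, n_circuits=4,
                           n_timepoints=7, trend_amplitude=trend_amplitude,
                           seed=seed0 + s),
        )
        out.append(icc2(mats[0]))
    return np.array(out)
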