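"""Plain-text readers/writers and the pipeline driver.

Interchange formats (MPS data has no community standard, so the schema
below is the contract and is versioned in the file header):

* GTT tables: CSV with a ``# gluchip-gtt v1 ...`` header comment and
  columns condition, signal, time_h, mean, sem, n, gtt_window plus an
  optional ``nominal`` column (dosed concentration at the window start).
  Units: time_h in h, glucose in mmol/L, insulin in mIU/L.
* Parameters and protocols: YAML with flat dotted keys mirroring the
  model symbol names.
* Ensembles: one CSV of member vectors + costs plus a JSON metadata
  sidecar (threshold, seed, evaluation count).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    DATA_COLUMNS,
    FitConfig,
    GTTDataset,
    ParameterEnsemble,
    fit,
    preprocess_sem,
    total_residuals,
)
from .model import (
    FastParameters,
    H2Parameters,
    Hypothesis,
    ModelParameters,
    MPSGeometry,
    OffsetParameters,
    SlowParameters,
)
from .protocol import Protocol, ProtocolEvent, SamplePoint, gtt_study_protocol
from .synth import Condition
from .workflows import test_hypothesis

log = logging.getLogger("gluchip")

GTT_HEADER = "# gluchip-gtt v1; units: time_h=h glucose=mmol/L insulin=mIU/L"


# ---------------------------------------------------------------------------
# GTT tables


def write_gtt_table(datasets: Sequence[GTTDataset], path: str | Path) -> None:
    frames = []
    for ds in datasets:
        tab = ds.table.copy()
        tab.insert(0, "condition", ds.condition)
        tab["nominal"] = [
            ds.nominal.get((row.gtt_window, row.signal), np.nan) for row in tab.itertuples(index=False)
        ]
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(GTT_HEADER + "\n")
        out.to_csv(fh, index=False)


def read_gtt_table(path: str | Path) -> list[GTTDataset]:
    """Read and validate a GTT table; one dataset per condition.

    Errors name the offending row (1-based data rows, excluding header
    lines)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# gluchip-gtt"):
            raise ValueError(f"{path}: missing 'gluchip-gtt' schema header line")
        if "time_h=h" not in first or "mmol/L" not in first or "mIU/L" not in first:
            raise ValueError(f"{path}: header does not declare the expected units (h, mmol/L, mIU/L)")
        df = pd.read_csv(fh)
    required = ("condition",) + DATA_COLUMNS
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = df.index[df["sem"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative SEM at data row {bad[0] + 1}")
    dup = df.duplicated(subset=["condition", "signal", "time_h", "gtt_window"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (condition, signal, time) at data row {df.index[dup][0] + 1}")
    df["gtt_window"] = df["gtt_window"].fillna("")
    datasets = []
    for cond, sub in df.groupby("condition", sort=False):
        nominal = {}
        if "nominal" in sub.columns:
            for row in sub.itertuples(index=False):
                if np.isfinite(getattr(row, "nominal", np.nan)):
                    nominal[(row.gtt_window, row.signal)] = float(row.nominal)
        tab = sub[list(DATA_COLUMNS)].reset_index(drop=True)
        datasets.append(GTTDataset(str(cond), tab, nominal))
    return datasets


# ---------------------------------------------------------------------------
# parameters and protocols (YAML, flat dotted keys)


def params_to_dict(params: ModelParameters) -> dict:
    out: dict[str, object] = {"hypothesis": params.hypothesis.value}
    for group in ("geometry", "fast", "slow", "h2", "offsets"):
        block = getattr(params, group)
        if block is None:
            continue
        for f in fields(block):
            out[f"{group}.{f.name}"] = float(getattr(block, f.name))
    return out


def params_from_dict(data: dict) -> ModelParameters:
    hyp = Hypothesis(data.get("hypothesis", "H1"))
    groups: dict[str, dict[str, float]] = {}
    for key, value in data.items():
        if key == "hypothesis":
            continue
        group, name = key.split(".")
        groups.setdefault(group, {})[name] = float(value)
    kw = dict(
        geometry=MPSGeometry(**groups.get("geometry", {})),
        fast=FastParameters(**groups.get("fast", {})),
        slow=SlowParameters(**groups.get("slow", {})),
        offsets=OffsetParameters(**groups.get("offsets", {})),
        hypothesis=hyp,
    )
    if hyp is Hypothesis.H2:
        kw["h2"] = H2Parameters(**groups.get("h2", {}))
    return ModelParameters(**kw)


def write_params(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gluchip model parameters (SI-style units: h, L, mmol, mIU)\n")
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)


def read_params(path: str | Path) -> ModelParameters:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def default_params(hypothesis: Hypothesis | str = Hypothesis.H1) -> ModelParameters:
    """The documented default parameter set shipped with the package
    (kinetic values are stated assumptions, not measurements)."""
    path = Path(__file__).parent / "data" / "default_params.yaml"
    return read_params(path).with_hypothesis(hypothesis)


def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "label": protocol.label,
        "duration": float(protocol.duration),
        "initial_glucose": float(protocol.initial_glucose),
        "events": [
            {
                "time": float(e.time),
                "kind": e.kind,
                "glucose_conc": float(e.glucose_conc),
                "insulin_conc": float(e.insulin_conc),
                "applies_offsets": e.applies_offsets,
            }
            for e in protocol.events
        ],
        "samples": [
            {"time": float(s.time), "phase": s.phase, "window": s.window} for s in protocol.samples
        ],
    }


def protocol_from_dict(data: dict) -> Protocol:
    return Protocol(
        events=tuple(ProtocolEvent(**e) for e in data.get("events", [])),
        samples=tuple(SamplePoint(**s) for s in data.get("samples", [])),
        duration=float(data["duration"]),
        initial_glucose=float(data.get("initial_glucose", 11.0)),
        label=data.get("label", ""),
    )


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)


def read_protocol(path: str | Path) -> Protocol:
    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ensembles


def write_ensemble(ensemble: ParameterEnsemble, path: str | Path) -> None:
    """Portable bundle: <path> is a JSON file with metadata and the
    member table inlined as CSV text."""
    buf = _io.StringIO()
    ensemble.to_frame().to_csv(buf, index=False)
    payload = {
        "schema": "gluchip-ensemble v1",
        "names": ensemble.names,
        "threshold": ensemble.threshold,
        "seed": ensemble.seed,
        "n_evaluations": ensemble.n_evaluations,
        "best_vector": [float(v) for v in ensemble.best_vector],
        "best_cost": float(ensemble.best_cost),
        "base_params": params_to_dict(ensemble.base_params),
        "members_csv": buf.getvalue(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ensemble(path: str | Path) -> ParameterEnsemble:
    payload = json.loads(Path(path).read_text())
    df = pd.read_csv(_io.StringIO(payload["members_csv"])) if payload["members_csv"].strip() else None
    names = payload["names"]
    if df is not None and len(df):
        vectors = df[names].to_numpy(dtype=float)
        costs = df["cost"].to_numpy(dtype=float)
    else:
        vectors, costs = np.empty((0, len(names))), np.array([])
    return ParameterEnsemble(
        names=names,
        vectors=vectors,
        costs=costs,
        threshold=payload["threshold"],
        base_params=params_from_dict(payload["base_params"]),
        best_vector=np.array(payload["best_vector"]),
        best_cost=payload["best_cost"],
        seed=payload["seed"],
        n_evaluations=payload["n_evaluations"],
    )


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end run: preprocess -> fit (H1 and/or H2) -> validate."""

    data_path: str
    out_dir: str
    hypotheses: tuple[str, ...] = ("H1", "H2")
    calibration_windows: tuple[str, ...] = ("day1", "day7")
    validation_window: str = "day13"
    spike_nM: float | None = 23.0
    free: dict[str, tuple[float, float]] | None = None
    n_restarts: int = 3
    n_iter: int = 300
    seed: int = 0

    def digest(self) -> str:
        raw = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:12]


DEFAULT_FREE_H1 = {
    "fast.S_I0": (1e-2, 2.0),
    "fast.I_max_Si": (1e-3, 1.0),
    "fast.EC50_Si": (10.0, 2000.0),
    "fast.sigma_max": (1e4, 4e6),
    "fast.alpha": (1e3, 1e6),
    "offsets.dG_d1": (-2.0, 2.0),
    "offsets.dG_d13": (-2.0, 2.0),
    "offsets.dI_d1": (0.0, 5.0),
    "offsets.dI_d13": (0.0, 5.0),
}
DEFAULT_FREE_H2 = DEFAULT_FREE_H1 | {
    "h2.I_max_additional": (1e-3, 1.0),
    "h2.EC50_additional": (20.0, 2000.0),
}


def condition_from_label(label: str) -> Condition:
    glucose = 11.0 if label.startswith("hyper") else 5.5
    hct = "low" if "lowHCT" in label else "high"
    return Condition(glucose, hct)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the calibration/validation pipeline and write artifacts.

    Returns a result bundle (dict) with per-hypothesis fit summaries and
    validation verdicts; every artifact is stamped with the config hash,
    seed and package version."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed, "version": __version__}
    t_start = time.time()

    datasets = read_gtt_table(config.data_path)
    datasets = [preprocess_sem(ds) for ds in datasets]
    gtt_days = tuple(sorted(int(w.removeprefix("day")) for w in
                            set(config.calibration_windows) | {config.validation_window}))
    protocols = [
        gtt_study_protocol(
            culture_glucose=condition_from_label(ds.condition).glucose,
            gtt_days=gtt_days,
            insulin_spike_nM=config.spike_nM,
            label=ds.condition,
        )
        for ds in datasets
    ]
    calib = [ds.subset_windows(config.calibration_windows) for ds in datasets]
    valid = [ds.subset_windows([config.validation_window]) for ds in datasets]
    log.info("pipeline: %d conditions, %d calibration points", len(datasets), total_residuals(calib))

    results: dict = {"stamp": stamp, "hypotheses": {}}
    for hyp in config.hypotheses:
        free = dict(config.free) if config.free else (DEFAULT_FREE_H2 if hyp == "H2" else DEFAULT_FREE_H1)
        base = default_params(hyp)
        cfg = FitConfig(free=free, n_restarts=config.n_restarts, n_iter=config.n_iter, seed=config.seed)
        t0 = time.time()
        ens = fit(calib, protocols, base, cfg)
        log.info("fit %s: cost %.2f vs threshold %.2f (%.1f s)", hyp, ens.best_cost, ens.threshold,
                 time.time() - t0)
        write_ensemble(ens, out / f"ensemble_{hyp}.json")
        entry = {
            "calibration_cost": float(ens.best_cost),
            "calibration_threshold": float(ens.threshold),
            "acceptable_members": int(len(ens.costs)),
        }
        if ens.acceptable:
            verdicts = []
            for ds, proto in zip(valid, protocols):
                if not ds.n_points:
                    continue
                v = test_hypothesis(ens, ds, proto)
                verdicts.append(v.accepted)
                entry.setdefault("validation", {})[ds.condition] = {
                    "accepted": v.accepted,
                    "min_cost": v.min_cost,
                    "threshold": v.threshold,
                }
            entry["accepted"] = bool(verdicts) and all(verdicts)
        else:
            entry["accepted"] = False
            entry["flag"] = "no acceptable calibration found"
        results["hypotheses"][hyp] = entry

    results["wall_time_s"] = round(time.time() - t_start, 2)
    (out / "pipeline_result.json").write_text(json.dumps(results, indent=1))
    return results
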