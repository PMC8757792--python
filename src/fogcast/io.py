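"""Trace/label/dataset file formats and the end-to-end experiment runner.

All on-disk formats are plain text: traces and labels are CSV with an
integer centisecond time column, results are long-format CSV plus a
JSON summary.  Every output bundle carries a provenance record (config
hash, seeds, package version) sufficient to regenerate it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import EnsembleConfig
from .evaluation import (
    class_weight_sweep,
    compare_classifiers,
    gl_correlation,
    sweep,
)
from .labeling import LabelerConfig, label_trace
from .stepsim import ForceTrace, SimConfig, simulate_cohort
from .windowing import WindowedDataset, WindowingParams

__all__ = [
    "read_trace",
    "write_trace",
    "read_labels",
    "write_labels",
    "write_dataset",
    "read_dataset",
    "save_ensemble",
    "load_ensemble",
    "RunConfig",
    "run_experiment",
    "config_hash",
]


class TraceParseError(ValueError):
    """A trace file failed validation; the message names file and line."""


def write_trace(trace: ForceTrace, path) -> None:
    """Write a trace as CSV: ``t_cs,force[,label]`` with full float precision."""
    path = Path(path)
    cols = {"t_cs": np.arange(len(trace)), "force": trace.force}
    if trace.truth_labels is not None:
        cols["label"] = trace.truth_labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trace(path, *, subject_id: str | None = None,
               sampling_rate: float = 100.0) -> ForceTrace:
    """Read a trace CSV written by :func:`write_trace`.

    The header must contain ``t_cs`` and ``force``; an optional
    ``label`` column is loaded as truth labels.  Malformed headers,
    non-monotone time indices and non-finite forces raise
    :class:`TraceParseError` naming the offending column or line.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_cs", "force"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing required column {col!r}")
    t = df["t_cs"].to_numpy()
    if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
        bad = int(np.flatnonzero(np.diff(t) != 1)[0]) + 3  # header is line 1
        raise TraceParseError(f"{path}: non-contiguous t_cs at line {bad}")
    force = df["force"].to_numpy(float)
    if not np.all(np.isfinite(force)):
        bad = int(np.flatnonzero(~np.isfinite(force))[0]) + 2
        raise TraceParseError(f"{path}: non-finite force at line {bad}")
    labels = df["label"].to_numpy(int) if "label" in df.columns else None
    return ForceTrace(
        subject_id=subject_id or path.stem,
        sampling_rate=sampling_rate,
        force=force,
        truth_labels=labels,
    )


def write_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame({"t_cs": np.arange(len(labels)),
                  "label": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise TraceParseError(f"{path}: missing required column 'label'")
    return df["label"].to_numpy(int)


def write_dataset(dataset: WindowedDataset, path) -> None:
    """Write windows as CSV ``subject,start_cs,label,f_0..f_{IL-1}`` plus a
    params sidecar JSON next to it."""
    path = Path(path)
    feat = pd.DataFrame(dataset.inputs,
                        columns=[f"f_{i}" for i in range(dataset.params.IL)])
    meta = pd.DataFrame({"subject": dataset.subjects,
                         "start_cs": dataset.starts,
                         "label": dataset.labels})
    pd.concat([meta, feat], axis=1).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".params.json")
    sidecar.write_text(json.dumps(dataclasses.asdict(dataset.params)))


def read_dataset(path) -> WindowedDataset:
    """Read a windows CSV plus its params sidecar back into memory."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    params = WindowingParams(**json.loads(sidecar.read_text()))
    df = pd.read_csv(path, float_precision="round_trip")
    feat_cols = [f"f_{i}" for i in range(params.IL)]
    return WindowedDataset(
        inputs=df[feat_cols].to_numpy(float),
        labels=df["label"].to_numpy(int),
        subjects=df["subject"].to_numpy(object),
        starts=df["start_cs"].to_numpy(int),
        params=params,
    )


def save_ensemble(results, path) -> None:
    """Persist a fitted ensemble: NB parameters as JSON, RF/NN via joblib,
    full config and provenance embedded."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nb = results.members.get("nb")
    payload = {
        "version": __version__,
        "config": results.config.to_dict(),
        "il": results.il,
        "n_train": results.n_train,
        "train_subjects": list(results.train_subjects),
        "members": list(results.members),
    }
    if nb is not None:
        payload["nb"] = {
            "priors": nb.priors.tolist(),
            "means": nb.means.tolist(),
            "variances": nb.variances.tolist(),
            "variance_floor": nb.variance_floor,
        }
    (path / "ensemble.json").write_text(json.dumps(payload))
    for name in ("rf", "nn"):
        if name in results.members:
            joblib.dump(results.members[name], path / f"{name}.joblib")


def load_ensemble(path):
    """Load an ensemble archive written by :func:`save_ensemble`."""
    import joblib

    from .classifiers import (
        EnsembleForecaster,
        EnsembleForecasterResults,
        GaussianNBModel,
    )
    from .windowing import WindowedDataset as _WD

    path = Path(path)
    payload = json.loads((path / "ensemble.json").read_text())
    cfg = EnsembleConfig(**payload["config"])
    members = {}
    if "nb" in payload:
        nb = payload["nb"]
        members["nb"] = GaussianNBModel(
            priors=np.asarray(nb["priors"]),
            means=np.asarray(nb["means"]),
            variances=np.asarray(nb["variances"]),
            variance_floor=nb["variance_floor"],
        )
    for name in ("rf", "nn"):
        f = path / f"{name}.joblib"
        if f.exists():
            members[name] = joblib.load(f)

    # reconstruct a minimal model shell carrying params and config
    params = WindowingParams(IL=payload["il"])
    shell = object.__new__(EnsembleForecaster)
    shell.config = cfg
    shell.dataset = _WD(
        inputs=np.empty((0, payload["il"])),
        labels=np.empty(0, dtype=int),
        subjects=np.empty(0, dtype=object),
        starts=np.empty(0, dtype=int),
        params=params,
    )
    return EnsembleForecasterResults(
        model=shell,
        members=members,
        n_train=payload["n_train"],
        train_subjects=tuple(payload["train_subjects"]),
    )


def config_hash(obj) -> str:
    """Stable short hash of any dataclass/dict config for provenance."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulate -> label -> sweep experiment."""

    sim: SimConfig = SimConfig()
    labeler: LabelerConfig = LabelerConfig()
    ensemble: EnsembleConfig = EnsembleConfig()
    il_grid: tuple = (28, 57, 113, 226, 339)
    gl_grid: tuple = (0, 28, 57, 113)
    il_fixed: int = 226
    gl_fixed: int = 0
    ol: int = 28
    classifiers: tuple = ("nb", "rf", "nn")
    use_truth_labels: bool = False  # skip the labeller, use simulator truth
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.il_grid or not self.gl_grid:
            raise ValueError("IL and GL grids must be non-empty")
        if not self.classifiers:
            raise ValueError("at least one classifier required")


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline: simulate, label, sweep, summarise.

    Returns a bundle with the simulated traces, automatic labels, the
    :class:`~fogcast.evaluation.SweepResult` and a JSON-serialisable
    summary (median F1 per grid cell, Spearman GL correlation per
    classifier, Kruskal-Wallis comparison across classifiers, and a
    provenance record).  If ``out_dir`` is given, traces, scores and
    the summary are written there.
    """
    sim = dataclasses.replace(config.sim, seed=config.seed)
    ens = dataclasses.replace(config.ensemble, seed=config.seed)
    traces = simulate_cohort(sim)
    if config.use_truth_labels:
        labels = {t.subject_id: t.truth_labels for t in traces}
    else:
        labels = {t.subject_id: label_trace(t, config.labeler) for t in traces}

    result = sweep(
        traces,
        il_grid=config.il_grid,
        gl_grid=config.gl_grid,
        il_fixed=config.il_fixed,
        gl_fixed=config.gl_fixed,
        ol=config.ol,
        labels=labels,
        classifiers=config.classifiers,
        config=ens,
    )

    summary: dict = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
        "median_f1": {},
        "gl_spearman": {},
    }
    med = result.scores.groupby(["classifier", "IL", "GL"])["F1"].median()
    for (clf, il, gl), v in med.items():
        summary["median_f1"][f"{clf}/IL={il}/GL={gl}"] = round(float(v), 6)
    for clf in config.classifiers:
        try:
            rho, p = gl_correlation(result, clf, il_fixed=config.il_fixed)
            summary["gl_spearman"][clf] = {"rho": rho, "p": p}
        except ValueError:
            summary["gl_spearman"][clf] = None
    if len(config.classifiers) >= 2:
        il0, gl0 = config.il_grid[0], config.gl_fixed
        sc = result.scores
        cell = sc[(sc["IL"] == il0) & (sc["GL"] == gl0)]
        groups = [cell[cell["classifier"] == c]["F1"].to_numpy()
                  for c in config.classifiers]
        try:
            h, p = compare_classifiers(*groups)
            summary["kruskal_wallis"] = {"H": h, "p": p,
                                         "at": f"IL={il0},GL={gl0}"}
        except ValueError:
            summary["kruskal_wallis"] = None

    bundle = {"traces": traces, "labels": labels, "sweep": result,
              "summary": summary}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t in traces:
            write_trace(t, out / f"{t.subject_id}.csv")
        result.scores.to_csv(out / "scores.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    return bundle
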