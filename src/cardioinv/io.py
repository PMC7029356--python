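"""Readers/writers for traces, datasets, configs and inversion results.

Conventions: CSV for traces and tables (with a ``# units:`` comment line),
JSON for structured artifacts (datasets, inversion results), YAML or JSON
for run configuration.  Every structured artifact embeds the seed and a
configuration hash so a run can be reproduced bit-compatibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import __version__
from .drug_study import DoseEscalationDataset
from .inversion import InversionConfig, InversionResult
from .model import Trace
from .parameters import CURRENT_NAMES
from .scaling import AdjustmentFactors

PathLike = Union[str, Path]


class TraceParseError(ValueError):
    """Malformed trace file; message carries the offending line number."""


# -- traces ------------------------------------------------------------------

def write_trace(trace: Trace, path: PathLike,
                include_currents: bool = False) -> None:
    """Write t/v/ca columns (optionally plus per-current columns) as CSV
    with a units comment line."""
    path = Path(path)
    units = trace.units
    extra: list[str] = []
    if include_currents:
        if trace.currents is None:
            raise ValueError("trace was recorded without current columns")
        extra = [f"I_{n}" for n in CURRENT_NAMES]
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# units: t={units.get('t', 'ms')},v={units.get('v', 'mV')},"
                 f"ca={units.get('ca', 'mM')}"
                 + "".join(f",{c}=A/F" for c in extra) + "\n")
        fh.write(",".join(["t", "v", "ca"] + extra) + "\n")
        for k, (t, v, ca) in enumerate(zip(trace.t, trace.v, trace.ca)):
            row = [repr(float(t)), repr(float(v)), repr(float(ca))]
            if extra:
                row += [repr(float(x)) for x in trace.currents[k, :13]]
            fh.write(",".join(row) + "\n")


def read_trace(path: PathLike) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (LF or CRLF)."""
    path = Path(path)
    units = None
    rows = []
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()
    header: list[str] = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.lstrip("#").strip().startswith("units:"):
                spec = line.split("units:", 1)[1].strip()
                units = dict(item.split("=", 1) for item in spec.split(","))
            continue
        if not header:
            header = [c.strip() for c in line.split(",")]
            if header[:3] != ["t", "v", "ca"]:
                raise TraceParseError(
                    f"{path}:{ln}: expected header 't,v,ca[,...]', got {line!r}")
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise TraceParseError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}")
        try:
            rows.append(tuple(float(p) for p in parts))
        except ValueError as err:
            raise TraceParseError(f"{path}:{ln}: {err}") from None
    if units is None:
        raise TraceParseError(f"{path}: missing '# units:' header line")
    if not rows:
        raise TraceParseError(f"{path}: no data rows")
    arr = np.asarray(rows)
    currents = None
    if len(header) == 3 + len(CURRENT_NAMES):
        currents = np.column_stack([arr[:, 3:], np.zeros(len(arr))])
    return Trace(t=arr[:, 0], v=arr[:, 1], ca=arr[:, 2], units=units,
                 currents=currents)


# -- datasets ----------------------------------------------------------------

def _trace_to_json(trace: Trace) -> dict:
    return {"t": trace.t.tolist(), "v": trace.v.tolist(),
            "ca": trace.ca.tolist(), "units": dict(trace.units),
            "meta": _plain(trace.meta)}


def _trace_from_json(obj: dict) -> Trace:
    return Trace(t=np.asarray(obj["t"]), v=np.asarray(obj["v"]),
                 ca=np.asarray(obj["ca"]), units=dict(obj.get("units", {})),
                 meta=dict(obj.get("meta", {})))


def write_dataset(dataset: DoseEscalationDataset, path: PathLike) -> None:
    payload = {
        "format": "cardioinv.dose_escalation/1",
        "version": __version__,
        "dose_unit": dataset.dose_unit,
        "relative_units": dataset.relative_units,
        "provenance": _plain(dataset.provenance),
        "traces": {repr(d): _trace_to_json(tr) for d, tr in dataset.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_dataset(path: PathLike) -> DoseEscalationDataset:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "cardioinv.dose_escalation/1":
        raise ValueError(f"{path}: not a dose-escalation dataset envelope")
    traces = {float(d): _trace_from_json(tr) for d, tr in obj["traces"].items()}
    return DoseEscalationDataset(
        traces=traces, dose_unit=obj.get("dose_unit", ""),
        relative_units=bool(obj.get("relative_units", False)),
        provenance=dict(obj.get("provenance", {})))


# -- inversion results -------------------------------------------------------

def result_to_dict(result: InversionResult) -> dict:
    cfg = dataclasses.asdict(result.config)
    return {
        "format": "cardioinv.inversion_result/1",
        "version": __version__,
        "seed": result.seed,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "lambda": result.lam.to_dict(),
        "epsilon": dict(result.eps),
        "ic50": {t: (None if not np.isfinite(v) else v)
                 for t, v in result.ic50.items()},
        "dose_unit": result.dose_unit,
        "cost": result.cost,
        "path": _plain(result.path),
        "fitted_biomarkers": {repr(d): bm.values
                              for d, bm in result.fitted_biomarkers.items()},
    }


def write_result(result: InversionResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=1))


def read_result(path: PathLike) -> dict:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "cardioinv.inversion_result/1":
        raise ValueError(f"{path}: not an inversion result file")
    return obj


# -- configuration -----------------------------------------------------------

_RUN_CONFIG_KEYS = {
    "preset", "protocol", "cost", "inversion", "seed", "out", "log_level",
}


def read_config(path: PathLike) -> dict:
    """Read a YAML/JSON run configuration; unknown top-level keys rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return cfg


def inversion_config_from_dict(d: dict) -> InversionConfig:
    fields = {f.name for f in dataclasses.fields(InversionConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown inversion config keys {sorted(unknown)}")
    d = dict(d)
    for k in ("free_lambda", "free_epsilon"):
        if k in d:
            d[k] = tuple(d[k])
    if "lambda_bounds" in d:
        d["lambda_bounds"] = tuple(d["lambda_bounds"])
    return InversionConfig(**d)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, AdjustmentFactors):
        return obj.to_dict()
    return obj
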