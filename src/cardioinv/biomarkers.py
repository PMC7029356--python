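"""AP/Ca2+ biomarker extraction and the weighted multi-dose cost function.

A model fit is scored by comparing waveform characteristics R_j (AP durations,
Ca2+ transient durations, upstroke velocities, amplitudes, areas and optional
per-current peaks) between a simulated beat and a target beat.  Each term is a
relative absolute difference; the total cost is the weighted sum of squared
terms over all doses of a dose-escalation study, the control included.  The
continuation variant blends the target characteristics between the default
model (θ = 0) and the data (θ = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math
from typing import Callable, Mapping, Optional

import numpy as np

from .model import SolverError, Trace
from .parameters import CURRENT_NAMES

log = logging.getLogger(__name__)

#: waveform-characteristic names always extracted
WAVEFORM_BIOMARKERS: tuple[str, ...] = (
    "APD30", "APD50", "APD80",
    "CaD20", "CaD30", "CaD40", "CaD50", "CaD60", "CaD70", "CaD80",
    "dvdt_max", "dcadt_max", "ca_amp", "ca_base", "int30",
)

#: default cost terms for waveform-only (optical-style) data
DEFAULT_COST_TERMS: tuple[str, ...] = WAVEFORM_BIOMARKERS

#: minimum AP amplitude (mV) for a beat to count as captured
_MIN_AP_AMPLITUDE = 10.0


@dataclass
class BiomarkerSet:
    """Named biomarker values; ``valid`` is False when no AP was detected."""

    values: dict[str, float] = field(default_factory=dict)
    valid: bool = True

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = math.nan) -> float:
        return self.values.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.values


def _crossing_duration(t: np.ndarray, x: np.ndarray, level: float) -> float:
    """Time between the first upward and last downward crossing of ``level``,
    with linear interpolation at both crossings."""
    above = x >= level
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return math.nan
    i0, i1 = idx[0], idx[-1]
    t_up = t[i0]
    if i0 > 0 and x[i0] != x[i0 - 1]:
        frac = (level - x[i0 - 1]) / (x[i0] - x[i0 - 1])
        t_up = t[i0 - 1] + frac * (t[i0] - t[i0 - 1])
    t_down = t[i1]
    if i1 < len(x) - 1 and x[i1] != x[i1 + 1]:
        frac = (level - x[i1]) / (x[i1 + 1] - x[i1])
        t_down = t[i1] + frac * (t[i1 + 1] - t[i1])
    return float(t_down - t_up)


def _durations(t: np.ndarray, x: np.ndarray, percents, prefix: str,
               out: dict[str, float]) -> None:
    x_rest = float(np.min(x))
    x_peak = float(np.max(x))
    for p in percents:
        level = x_peak - p / 100.0 * (x_peak - x_rest)
        out[f"{prefix}{p}"] = _crossing_duration(t, x, level)


def extract_biomarkers(trace: Trace,
                       beat_window: Optional[tuple[float, float]] = None
                       ) -> BiomarkerSet:
    """Extract AP and Ca2+ transient biomarkers from one beat.

    ``beat_window`` restricts the trace to [t0, t1]; by default the full
    trace is used (callers typically pass :meth:`Trace.final_beat` output).
    Durations are measured at amplitude-relative repolarization/decay levels
    with linear interpolation at the crossings, so they are invariant to
    shifting and positive scaling of the signals.  If no AP upstroke is
    detected the set is flagged invalid (which drives the penalty cost).
    """
    if beat_window is not None:
        trace = trace.window(*beat_window)
    t, v, ca = trace.t, trace.v, trace.ca
    if len(t) < 3:
        return BiomarkerSet(valid=False)

    amplitude = float(np.max(v) - np.min(v))
    dv = np.diff(v) / np.diff(t)
    if amplitude < _MIN_AP_AMPLITUDE or not np.isfinite(v).all():
        return BiomarkerSet(valid=False)

    out: dict[str, float] = {}
    _durations(t, v, (30, 50, 80), "APD", out)
    _durations(t, ca, (20, 30, 40, 50, 60, 70, 80), "CaD", out)
    out["dvdt_max"] = float(np.max(dv))
    out["dcadt_max"] = float(np.max(np.diff(ca) / np.diff(t)))
    out["ca_amp"] = float(np.max(ca) - np.min(ca))
    out["ca_base"] = float(np.min(ca))
    # area between v and rest where v exceeds the 30%-repolarization level
    v_rest, v_peak = float(np.min(v)), float(np.max(v))
    level30 = v_peak - 0.30 * (v_peak - v_rest)
    mask = v >= level30
    out["int30"] = float(np.trapezoid(np.where(mask, v - v_rest, 0.0), t))

    if trace.currents is not None:
        for i, name in enumerate(CURRENT_NAMES):
            out[f"I_{name}_max"] = float(np.max(np.abs(trace.currents[:, i])))
    if trace.fluxes is not None:
        out["J_RyR_max"] = float(np.max(trace.flux("J_RyR")))
        out["J_SERCA_max"] = float(np.max(trace.flux("J_SERCA")))
    return BiomarkerSet(out)


def cost_term(r_model: float, r_target: float) -> Optional[float]:
    """Relative absolute difference |R_model - R_target| / |R_target|.

    Returns None (term skipped, with a warning) when the target is zero.
    """
    if r_target == 0.0 or not math.isfinite(r_target):
        log.warning("cost term skipped: target characteristic is %s", r_target)
        return None
    return abs(r_model - r_target) / abs(r_target)


def continuation_targets(r0: BiomarkerSet, r1: BiomarkerSet,
                         theta: float) -> BiomarkerSet:
    """Blended targets R^θ = (1-θ)·R0 + θ·R1, element-wise."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    common = set(r0.values) & set(r1.values)
    return BiomarkerSet(
        {k: (1.0 - theta) * r0.values[k] + theta * r1.values[k] for k in common},
        valid=r0.valid and r1.valid,
    )


@dataclass
class CostSpec:
    """Enabled cost terms, per-term weights and the failed-simulation penalty.

    ``weights`` maps a term to its weight (default 1.0 for enabled terms not
    listed); ``dose_weights`` optionally overrides weights for individual
    doses (keyed by dose value).  The penalty replaces every enabled term of
    a dose whose simulation failed or produced no AP; it must dominate any
    realistic relative difference.
    """

    terms: tuple[str, ...] = DEFAULT_COST_TERMS
    weights: Mapping[str, float] = field(default_factory=dict)
    dose_weights: Mapping[float, Mapping[str, float]] = field(default_factory=dict)
    penalty: float = 10.0
    lambda_l2: float = 0.0      # optional L2 penalty on the free λ factors

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("at least one cost term must be enabled")
        if self.lambda_l2 < 0 or not math.isfinite(self.lambda_l2):
            raise ValueError("lambda_l2 must be finite and >= 0")
        for w in self.weights.values():
            if w < 0 or not math.isfinite(w):
                raise ValueError("weights must be finite and >= 0")

    def weight(self, term: str, dose: Optional[float] = None) -> float:
        if dose is not None and dose in self.dose_weights:
            override = self.dose_weights[dose]
            if term in override:
                return float(override[term])
        return float(self.weights.get(term, 1.0))


def hipsc_fit_cost_spec() -> CostSpec:
    """Weight preset used when fitting the hiPSC model to waveform data:
    CaD20-CaD70 get weight 0.5, APD80 and CaD80 weight 5, the rest 1."""
    weights = {f"CaD{p}": 0.5 for p in (20, 30, 40, 50, 60, 70)}
    weights.update({"APD80": 5.0, "CaD80": 5.0})
    return CostSpec(terms=DEFAULT_COST_TERMS, weights=weights)


def dose_cost(model_bm: BiomarkerSet, target_bm: BiomarkerSet, spec: CostSpec,
              dose: Optional[float] = None) -> float:
    """Weighted sum of squared cost terms for one dose."""
    total = 0.0
    for term in spec.terms:
        w = spec.weight(term, dose)
        if w == 0.0:
            continue
        if not model_bm.valid or term not in model_bm:
            total += w * spec.penalty ** 2
            continue
        h = cost_term(model_bm[term], target_bm.get(term))
        if h is None:
            continue
        total += w * h * h
    return total


def total_cost(lam, eps, dataset, spec: CostSpec,
               simulate_fn: Callable) -> float:
    """Total cost H(λ, ε) = Σ_d Σ_j w_dj · H_j(λ, ε, D_d)² over all doses.

    ``simulate_fn(lam, eps, dose) -> Trace`` produces the measurement beat
    for one dose; a :class:`SolverError` (or an invalid beat) contributes the
    penalty for every enabled term of that dose.
    """
    targets = {d: extract_biomarkers(tr) for d, tr in dataset.items()}
    total = 0.0
    for dose, target_bm in targets.items():
        try:
            model_bm = extract_biomarkers(simulate_fn(lam, eps, dose))
        except SolverError:
            model_bm = BiomarkerSet(valid=False)
        total += dose_cost(model_bm, target_bm, spec, dose)
    return total + _l2_penalty(lam, spec)


def continuation_cost(theta: float, lam, eps, reference: BiomarkerSet,
                      data_targets: Mapping[float, BiomarkerSet],
                      spec: CostSpec, simulate_fn: Callable) -> float:
    """Continuation cost H̄(θ, λ, ε) with per-dose blended targets.

    ``reference`` holds the characteristics of the default model (λ = ε = 0);
    at θ = 0 every dose targets the reference, so H̄(0, 0, 0) = 0; at θ = 1
    the cost equals :func:`total_cost` on the data.
    """
    total = 0.0
    for dose, r1 in data_targets.items():
        blended = continuation_targets(reference, r1, theta)
        try:
            model_bm = extract_biomarkers(simulate_fn(lam, eps, dose))
        except SolverError:
            model_bm = BiomarkerSet(valid=False)
        total += dose_cost(model_bm, blended, spec, dose)
    return total + _l2_penalty(lam, spec)


def _l2_penalty(lam, spec: CostSpec) -> float:
    if spec.lambda_l2 == 0.0 or lam is None:
        return 0.0
    return spec.lambda_l2 * float(sum(v * v for v in dict(lam).values()))


def rescale_to_reference(trace: Trace, reference: Trace) -> Trace:
    """Min/max-map relative-unit (optical) signals onto a model trace.

    Each channel of ``trace`` is affinely rescaled so its minimum and
    maximum match those of ``reference``.  Duration biomarkers are unchanged
    by this map; amplitude/baseline terms become uninformative and should be
    given zero weight for optical data.
    """
    def _map(x, ref):
        span = np.max(x) - np.min(x)
        if span == 0:
            return np.full_like(x, np.min(ref))
        return (np.min(ref)
                + (x - np.min(x)) * (np.max(ref) - np.min(ref)) / span)

    return Trace(t=trace.t.copy(), v=_map(trace.v, reference.v),
                 ca=_map(trace.ca, reference.ca),
                 units=dict(reference.units),
                 meta={**trace.meta, "rescaled": "min/max to reference"})
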