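"""Synthetic dose-escalation studies, the graded-release clamp experiment,
optical-trace preprocessing and the hiPSC-to-adult prediction step.

The synthetic study emulates the simulated drug experiments used to validate
the inversion: the default hiPSC preset is perturbed by a background
adjustment (λ_CaL = λ_NaL = λ_Kr = 0.1), a known IC50-based block is applied
per dose, and the sixth paced AP after each parameter change is recorded as
the measurement beat.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .model import ModelState, Protocol, SolverError, Trace, integrate
from .parameters import ModelParameters
from .presets import get_preset, initial_state
from .scaling import AdjustmentFactors, DrugEffect, apply_adjustments, apply_drug

#: protocol used both to generate study data and inside the inversion:
#: 1 Hz pacing, measurement on beat six after each parameter change.
STUDY_PROTOCOL = Protocol(mode="paced", hz=1.0, beats=6, dt=0.05, sample_dt=1.0)


@dataclass
class DoseEscalationDataset:
    """Control trace plus per-dose traces of one dose-escalation study."""

    traces: dict[float, Trace]
    dose_unit: str = "nM"
    relative_units: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        doses = sorted(self.traces)
        if not doses or doses[0] != 0.0:
            raise ValueError("dataset must contain a control (dose 0) trace")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be >= 0")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted(self.traces))

    @property
    def control(self) -> Trace:
        return self.traces[0.0]

    @property
    def max_dose(self) -> float:
        return self.doses[-1]

    def items(self) -> Iterator[tuple[float, Trace]]:
        return iter(sorted(self.traces.items()))

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class SimulatedDrugSpec:
    """Ground truth of one synthetic drug study."""

    name: str
    ic50: Mapping[str, float]              # per-target IC50, in dose_unit
    doses: tuple[float, ...]               # non-zero dose ladder
    dose_unit: str = "nM"
    background_lambda: Mapping[str, float] = field(
        default_factory=lambda: {"CaL": 0.1, "NaL": 0.1, "Kr": 0.1})
    measure_beat: int = 6
    preset: str = "hipsc"

    def __post_init__(self) -> None:
        for tgt, v in self.ic50.items():
            if v <= 0:
                raise ValueError(f"IC50 for {tgt} must be > 0")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])) or \
                (self.doses and self.doses[0] <= 0):
            raise ValueError("dose ladder must be positive and increasing")

    def drug_effect(self) -> DrugEffect:
        return DrugEffect(eps={t: 1.0 / v for t, v in self.ic50.items()},
                          doses=(0.0,) + tuple(self.doses),
                          dose_unit=self.dose_unit)


def _log_ladder(lo: float, hi: float, n: int = 4) -> tuple[float, ...]:
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


def shipped_drug_specs() -> dict[str, SimulatedDrugSpec]:
    """The five reference drug parameterizations of the simulated study.

    Nifedipine uses the experimentally applied ladder (3-3000 nM); the other
    ladders are 4-point log ladders bracketing the smallest and largest IC50
    (IC50/10 ... 10·IC50).
    """
    return {
        "nifedipine": SimulatedDrugSpec(
            name="nifedipine", ic50={"CaL": 10.0},
            doses=(3.0, 30.0, 300.0, 3000.0), dose_unit="nM"),
        "lidocaine": SimulatedDrugSpec(
            name="lidocaine", ic50={"NaL": 10.0},
            doses=_log_ladder(1.0, 100.0), dose_unit="uM"),
        "cisapride": SimulatedDrugSpec(
            name="cisapride", ic50={"Kr": 10.0},
            doses=_log_ladder(1.0, 100.0), dose_unit="nM"),
        "flecainide": SimulatedDrugSpec(
            name="flecainide", ic50={"CaL": 25.0, "NaL": 20.0, "Kr": 10.0},
            doses=_log_ladder(1.0, 250.0), dose_unit="uM"),
        "verapamil": SimulatedDrugSpec(
            name="verapamil", ic50={"CaL": 200.0, "Kr": 500.0},
            doses=_log_ladder(20.0, 5000.0), dose_unit="nM"),
    }


def make_study_simulator(base: ModelParameters, initial: ModelState,
                         protocol: Protocol = STUDY_PROTOCOL):
    """Forward model used in generation and inversion.

    Returns ``simulate(lam, eps, dose) -> Trace`` producing the measurement
    (final) beat: parameters are adjusted by λ, blocked by Eq-style IC50
    scaling at the given dose, and paced for ``protocol.beats`` cycles from
    ``initial``.
    """
    def simulate(lam, eps: Mapping[str, float], dose: float) -> Trace:
        params = base
        if lam is not None:
            params = apply_adjustments(params, lam)
        if dose > 0.0 and eps:
            drug = DrugEffect(eps=dict(eps), doses=(0.0, dose))
            params = apply_drug(params, drug, dose)
        trace = integrate(params, protocol, initial)
        return trace.final_beat()

    return simulate


def generate_dose_escalation(spec: SimulatedDrugSpec,
                             base: Optional[ModelParameters] = None,
                             protocol: Optional[Protocol] = None
                             ) -> DoseEscalationDataset:
    """Generate the synthetic dataset for one drug spec (deterministic)."""
    if base is None:
        base = get_preset(spec.preset)
    if protocol is None:
        protocol = dataclasses.replace(STUDY_PROTOCOL, beats=spec.measure_beat)
    init = initial_state(spec.preset)
    lam = AdjustmentFactors(dict(spec.background_lambda))
    eps = {t: 1.0 / v for t, v in spec.ic50.items()}
    simulate = make_study_simulator(base, init, protocol)
    traces: dict[float, Trace] = {}
    for dose in (0.0,) + tuple(spec.doses):
        try:
            traces[dose] = simulate(lam, eps, dose)
        except SolverError as err:
            raise SolverError(
                f"simulation failed for {spec.name} at dose "
                f"{dose:g} {spec.dose_unit}: {err}", err.last_valid_time)
    return DoseEscalationDataset(
        traces=traces, dose_unit=spec.dose_unit,
        provenance={"kind": "synthetic", "drug": spec.name,
                    "ic50": dict(spec.ic50), "dose_unit": spec.dose_unit,
                    "background_lambda": dict(spec.background_lambda),
                    "preset": spec.preset, "measure_beat": spec.measure_beat})


def graded_release_experiment(preset: str = "hipsc",
                              clamp_grid: Optional[np.ndarray] = None,
                              duration: float = 100.0,
                              dt: float = 0.02) -> pd.DataFrame:
    """Voltage-clamp scan of SR release gain.

    From the resting state, the membrane potential is clamped at each grid
    value and the L-type trigger flux J_CaL and RyR release flux J_RyR are
    recorded; the table reports their peaks and time integrals over
    [0, duration] per clamp potential.
    """
    if clamp_grid is None:
        clamp_grid = np.arange(-50.0, 80.0 + 1e-9, 5.0)
    clamp_grid = np.asarray(clamp_grid, dtype=float)
    if clamp_grid.min() < -50.0 - 1e-9 or clamp_grid.max() > 80.0 + 1e-9:
        raise ValueError("clamp grid must lie within [-50, 80] mV")
    params = get_preset(preset)
    rest = initial_state(preset)
    rows = []
    for vc in clamp_grid:
        proto = Protocol(mode="voltage-clamp", clamp_v=float(vc),
                         clamp_duration=duration, sample_dt=0.5, dt=dt)
        tr = integrate(params, proto, rest)
        jcal = tr.flux("J_CaL")
        jryr = tr.flux("J_RyR")
        rows.append({
            "clamp_v": float(vc),
            "peak_J_CaL": float(jcal.max()),
            "peak_J_RyR": float(jryr.max()),
            "int_J_CaL": float(np.trapezoid(jcal, tr.t)),
            "int_J_RyR": float(np.trapezoid(jryr, tr.t)),
        })
    return pd.DataFrame(rows)


def preprocess_optical(beats: list[Trace], frame_rate: float = 200.0) -> Trace:
    """Condense repeated optical beats into one representative beat.

    Each channel is smoothed with a 3-point median filter; beats are aligned
    at the sample of maximum first difference of the voltage channel
    (integer-sample shifts), trimmed to common support and averaged.  The
    output is in the input's (relative) units.
    """
    if len(beats) < 2:
        raise ValueError("need at least two beats to average")
    dt = float(np.median(np.diff(beats[0].t)))
    filtered = []
    for b in beats:
        v = medfilt(b.v, 3)
        ca = medfilt(b.ca, 3)
        filtered.append((v, ca))
    # align at max dV/dt sample
    anchors = [int(np.argmax(np.diff(v))) for v, _ in filtered]
    lead = min(anchors)
    tail = min(len(v) - a for (v, _), a in zip(filtered, anchors))
    n = lead + tail
    vs = np.stack([v[a - lead:a + tail] for (v, _), a in zip(filtered, anchors)])
    cas = np.stack([c[a - lead:a + tail] for (_, c), a in zip(filtered, anchors)])
    t = np.arange(n) * dt
    return Trace(t=t, v=vs.mean(axis=0), ca=cas.mean(axis=0),
                 units={"t": "ms", "v": "relative", "ca": "relative"},
                 meta={"n_beats": len(beats), "frame_rate": frame_rate,
                       "aligned_at": "max dV/dt"})


def predict_adult_response(fit, doses, dose_unit: str = "nM",
                           adult_base: Optional[ModelParameters] = None,
                           protocol: Protocol = STUDY_PROTOCOL
                           ) -> dict[float, Trace]:
    """Predicted adult drug response from an hiPSC fit.

    The fitted ε values are applied unchanged to the adult base model
    (single-channel drug effects are maturity-invariant) and the adult model
    is paced at each dose; returns the measurement beat per dose.
    """
    eps = dict(getattr(fit, "eps", fit))
    if adult_base is None:
        adult_base = get_preset("adult")
    init = initial_state("adult")
    simulate = make_study_simulator(adult_base, init, protocol)
    return {float(d): simulate(None, eps, float(d)) for d in doses}
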