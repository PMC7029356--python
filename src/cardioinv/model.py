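"""Simulation layer of the base model: states, protocols, traces, integration.

The heavy numerics live in :mod:`cardioinv._engine`; this module provides the
typed public surface: :class:`ModelState`, :class:`Protocol`, :class:`Trace`,
current/flux evaluation and the :func:`integrate` driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Optional

import numpy as np

from . import _engine
from .parameters import (
    CURRENT_NAMES, FLUX_NAMES, ModelParameters, N_STATES, STATE_INDEX, STATE_NAMES,
)

_CONC_NAMES = ("c_d", "b_d", "c_sl", "b_sl", "c_c", "b_c", "c_s", "b_s", "c_n")


class SolverError(RuntimeError):
    """Integration failure; carries the last valid time reached."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class ModelState:
    """State vector of the base model with named access.

    Holds the membrane potential (mV), thirteen gating variables, free and
    buffered Ca2+ per compartment (mM) and the RyR availability ``r``.
    """

    __slots__ = ("values",)

    def __init__(self, values: Optional[np.ndarray] = None, **kw: float):
        if values is None:
            values = np.zeros(N_STATES)
        values = np.asarray(values, dtype=np.float64).copy()
        if values.shape != (N_STATES,):
            raise ValueError(f"state must have {N_STATES} entries")
        object.__setattr__(self, "values", values)
        for name, val in kw.items():
            if name not in STATE_INDEX:
                raise ValueError(f"unknown state variable {name!r}")
            values[STATE_INDEX[name]] = float(val)

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[STATE_INDEX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name: str, val) -> None:
        if name in STATE_INDEX:
            self.values[STATE_INDEX[name]] = float(val)
        else:
            raise AttributeError(f"unknown state variable {name!r}")

    def copy(self) -> "ModelState":
        return ModelState(self.values)

    def validate(self) -> None:
        for name, idx in STATE_INDEX.items():
            val = self.values[idx]
            if not math.isfinite(val):
                raise ValueError(f"state variable {name!r} is not finite: {val}")
        for name in _CONC_NAMES:
            if self.values[STATE_INDEX[name]] < 0.0:
                raise ValueError(f"concentration {name!r} is negative")
        for idx in list(range(1, 14)) + [STATE_INDEX["r"]]:
            val = self.values[idx]
            if not 0.0 <= val <= 1.0:
                raise ValueError(
                    f"gating variable {STATE_NAMES[idx]!r} outside [0, 1]: {val}")

    def __repr__(self) -> str:
        parts = ", ".join(f"{n}={getattr(self, n):.4g}" for n in ("v", "c_c", "c_s", "r"))
        return f"ModelState({parts}, ...)"


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol.

    Exactly one mode is active: ``paced`` (square stimulus at ``hz``),
    ``voltage-clamp`` (membrane potential held at ``clamp_v``) or
    ``free-running`` (no stimulus).
    """

    mode: str = "paced"
    hz: float = 1.0
    beats: int = 1
    stim_amplitude: float = -40.0   # A/F (negative = depolarizing)
    stim_duration: float = 2.0      # ms
    clamp_v: float = -50.0          # mV
    clamp_duration: float = 100.0   # ms
    sample_dt: float = 1.0          # ms
    dt: float = 0.02                # ms, integrator step

    def __post_init__(self) -> None:
        if self.mode not in ("paced", "voltage-clamp", "free-running"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.sample_dt <= 0.0 or self.dt <= 0.0:
            raise ValueError("sampling interval and dt must be > 0")
        if self.mode == "paced" and self.hz <= 0.0:
            raise ValueError("pacing frequency must be > 0")

    @property
    def period(self) -> float:
        """Pacing cycle length in ms."""
        return 1000.0 / self.hz

    @property
    def duration(self) -> float:
        if self.mode == "voltage-clamp":
            return self.clamp_duration
        return self.beats * self.period

    def stimulus(self, t: float) -> float:
        """Stimulus current I_stim(t) in A/F (0 outside the pulse window)."""
        if self.mode != "paced":
            return 0.0
        tmod = t - self.period * math.floor(t / self.period)
        return self.stim_amplitude if tmod < self.stim_duration else 0.0


@dataclass
class CurrentSet:
    """Membrane currents in A/F, stimulus included."""
    values: dict[str, float]

    def __getattr__(self, name: str) -> float:
        key = name[2:] if name.startswith("I_") else name
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(name) from None

    def total(self) -> float:
        """Sum over the thirteen ionic currents (stimulus excluded)."""
        return float(sum(self.values[n] for n in CURRENT_NAMES))


@dataclass
class FluxSet:
    """Intracellular Ca2+ fluxes in mmol/ms."""
    values: dict[str, float]

    def __getattr__(self, name: str) -> float:
        key = name if name.startswith("J_") else f"J_{name}"
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(name) from None


@dataclass
class Trace:
    """Sampled model output: time (ms), membrane potential (mV), Ca2+ (mM).

    ``ca`` is the bulk cytosolic free Ca2+ concentration, the quantity the
    optical measurements report (up to scaling).  Optional per-current and
    per-flux columns are attached when the integrator records them.
    """

    t: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    states: Optional[np.ndarray] = None          # (n, N_STATES)
    currents: Optional[np.ndarray] = None        # (n, 14)
    fluxes: Optional[np.ndarray] = None          # (n, 14)
    units: dict = field(default_factory=lambda: {"t": "ms", "v": "mV", "ca": "mM"})
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.ca = np.asarray(self.ca, dtype=np.float64)
        if not (len(self.t) == len(self.v) == len(self.ca)):
            raise ValueError("t, v, ca must have equal length")
        if np.any(~np.isfinite(self.t)):
            raise ValueError("time axis contains non-finite values")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def current(self, name: str) -> np.ndarray:
        if self.currents is None:
            raise ValueError("trace was recorded without current columns")
        return self.currents[:, CURRENT_NAMES.index(name)]

    def flux(self, name: str) -> np.ndarray:
        if self.fluxes is None:
            raise ValueError("trace was recorded without flux columns")
        return self.fluxes[:, FLUX_NAMES.index(name)]

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace on [t0, t1], time re-zeroed at t0."""
        mask = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        return Trace(
            t=self.t[mask] - t0, v=self.v[mask], ca=self.ca[mask],
            states=self.states[mask] if self.states is not None else None,
            currents=self.currents[mask] if self.currents is not None else None,
            fluxes=self.fluxes[mask] if self.fluxes is not None else None,
            units=dict(self.units), meta=dict(self.meta),
        )

    def final_beat(self) -> "Trace":
        """The last pacing cycle of a paced trace."""
        period = self.meta.get("period")
        beats = self.meta.get("beats")
        if period is None or beats is None or beats < 1:
            raise ValueError("not a paced trace with recorded beats")
        return self.window((beats - 1) * period, beats * period)

    def final_state(self) -> ModelState:
        if self.states is None:
            raise ValueError("trace was recorded without state columns")
        return ModelState(self.states[-1])


def default_initial_state(params: ModelParameters, v: float = -86.0) -> ModelState:
    """A generic resting initial condition: gates at steady state for ``v``,
    low cytosolic Ca2+, loaded SR, full RyR availability."""
    y = np.zeros(N_STATES)
    y[STATE_INDEX["v"]] = v
    ginf = np.empty(13)
    gtau = np.empty(13)
    _engine.gate_rates(v, ginf, gtau)
    y[1:14] = ginf
    for conc, val in (("c_d", 1e-4), ("c_sl", 1e-4), ("c_c", 1e-4),
                      ("c_s", 0.5), ("c_n", 0.5)):
        y[STATE_INDEX[conc]] = val
    # buffers at binding equilibrium with their compartment
    for comp, conc in (("d", "c_d"), ("sl", "c_sl"), ("c", "c_c"), ("s", "c_s")):
        c = y[STATE_INDEX[conc]]
        b_tot = getattr(params, f"B_tot_{comp}")
        kd = getattr(params, f"k_off_{comp}") / getattr(params, f"k_on_{comp}")
        y[STATE_INDEX[f"b_{comp}"]] = b_tot * c / (c + kd)
    y[STATE_INDEX["r"]] = 1.0
    return ModelState(y)


def compute_currents(state: ModelState, params: ModelParameters,
                     i_stim: float = 0.0) -> CurrentSet:
    """Evaluate all membrane currents (A/F) at a given state."""
    if not isinstance(state, ModelState):
        state = ModelState(np.asarray(state))
    for name, idx in STATE_INDEX.items():
        if not math.isfinite(state.values[idx]):
            raise ValueError(f"state variable {name!r} is not finite")
    cur = np.empty(_engine.N_CUR)
    cur[13] = i_stim
    _engine.calc_currents(state.values, params.to_vector(), cur)
    values = {n: float(cur[i]) for i, n in enumerate(CURRENT_NAMES)}
    values["stim"] = float(i_stim)
    return CurrentSet(values)


def ryr_fluxes(state: ModelState, params: ModelParameters) -> tuple[float, float, float]:
    """RyR release flux, leak flux (mmol/ms) and open probability ``p``.

    Release through available RyRs is graded by the dyadic Ca2+ via a cubic
    Hill open probability; the always-open fraction gives a leak with the
    same driving gradient.
    """
    if params.kappa_RyR <= 0:
        raise ValueError("kappa_RyR must be > 0")
    p_o = float(_engine.ryr_open_probability(state.c_d, params.kappa_RyR))
    grad = state.c_s - state.c_sl
    j_ryr = p_o * state.r * params.alpha_RyR * grad
    j_leak = params.gamma_RyR * params.alpha_RyR * grad
    return j_ryr, j_leak, p_o


def compute_fluxes(state: ModelState, params: ModelParameters) -> FluxSet:
    """Evaluate all intracellular Ca2+ fluxes (mmol/ms) at a given state."""
    cur = np.empty(_engine.N_CUR)
    cur[13] = 0.0
    p = params.to_vector()
    _engine.calc_currents(state.values, p, cur)
    flx = np.empty(_engine.N_FLX)
    _engine.calc_fluxes(state.values, p, cur[2], cur[8], cur[9], cur[10], flx)
    return FluxSet({n: float(flx[i]) for i, n in enumerate(FLUX_NAMES)})


def rhs(t: float, state: ModelState, params: ModelParameters,
        protocol: Protocol) -> np.ndarray:
    """Time-derivative of the full state vector at time ``t``.

    The membrane potential obeys dv/dt = -(sum of currents); each Ca2+
    compartment obeys its flux balance divided by the compartment volume; in
    voltage-clamp mode dv/dt is forced to zero.
    """
    if isinstance(state, np.ndarray):
        state = ModelState(state)
    if min(params.frac_d, params.frac_sl, params.frac_c,
           params.frac_s, params.frac_n) <= 0:
        raise ValueError("compartment volumes must be positive")
    i_stim = protocol.stimulus(t)
    cur = compute_currents(state, params, i_stim=i_stim)
    flx = compute_fluxes(state, params)
    dy = np.zeros(N_STATES)
    if protocol.mode != "voltage-clamp":
        dy[STATE_INDEX["v"]] = -(cur.total() + i_stim)
    ginf = np.empty(13)
    gtau = np.empty(13)
    _engine.gate_rates(state.v, ginf, gtau)
    dy[1:14] = (ginf - state.values[1:14]) / gtau
    v_cell = params.V_cell
    v_d = params.frac_d * v_cell
    v_sl = params.frac_sl * v_cell
    v_c = params.frac_c * v_cell
    v_s = params.frac_s * v_cell
    v_n = params.frac_n * v_cell
    si = STATE_INDEX
    dy[si["c_d"]] = (flx.J_CaL - flx.J_db - flx.J_dc) / v_d
    dy[si["b_d"]] = flx.J_db / v_d
    dy[si["c_sl"]] = (flx.J_esl - flx.J_slc - flx.J_slb + flx.J_ssl) / v_sl
    dy[si["b_sl"]] = flx.J_slb / v_sl
    dy[si["c_c"]] = (flx.J_slc + flx.J_dc - flx.J_cn - flx.J_cb) / v_c
    dy[si["b_c"]] = flx.J_cb / v_c
    dy[si["c_s"]] = (flx.J_ns - flx.J_ssl - flx.J_sb) / v_s
    dy[si["b_s"]] = flx.J_sb / v_s
    dy[si["c_n"]] = (flx.J_cn - flx.J_ns) / v_n
    p_o = float(_engine.ryr_open_probability(state.c_d, params.kappa_RyR))
    dy[si["r"]] = (-flx.J_RyR / (v_cell * params.beta_RyR)
                   + params.eta_RyR * p_o * (1.0 - state.r))
    return dy


def integrate(params: ModelParameters, protocol: Protocol,
              initial: Optional[ModelState] = None) -> Trace:
    """Deterministically integrate the model under a protocol.

    Returns a :class:`Trace` sampled every ``protocol.sample_dt`` ms with
    state, current and flux columns recorded.  For paced mode the trace
    covers all beats; the final (measurement) beat is accessible through
    :meth:`Trace.final_beat`.

    Raises :class:`SolverError` if the state becomes non-finite.
    """
    if initial is None:
        initial = default_initial_state(params)
    y0 = np.asarray(initial.values if isinstance(initial, ModelState) else initial,
                    dtype=np.float64)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")
    p = params.to_vector()

    duration = protocol.duration
    if duration <= 0.0:  # zero beats: the initial state sampled once
        cur = np.empty((1, _engine.N_CUR))
        cur[0, 13] = 0.0
        _engine.calc_currents(y0, p, cur[0])
        flx = np.empty((1, _engine.N_FLX))
        _engine.calc_fluxes(y0, p, cur[0, 2], cur[0, 8], cur[0, 9], cur[0, 10], flx[0])
        return Trace(t=np.zeros(1), v=y0[0:1].copy(),
                     ca=y0[STATE_INDEX["c_c"]:STATE_INDEX["c_c"] + 1].copy(),
                     states=y0[None, :].copy(), currents=cur, fluxes=flx,
                     meta={"protocol": protocol.mode, "beats": 0})

    n_sub = max(1, round(protocol.sample_dt / protocol.dt))
    dt = protocol.sample_dt / n_sub
    n_samples = int(round(duration / protocol.sample_dt)) + 1

    t_out = np.empty(n_samples)
    y_out = np.empty((n_samples, N_STATES))
    cur_out = np.empty((n_samples, _engine.N_CUR))
    flx_out = np.empty((n_samples, _engine.N_FLX))

    clamp = protocol.mode == "voltage-clamp"
    period = protocol.period if protocol.mode == "paced" else 0.0
    status = _engine.integrate_kernel(
        p, y0, n_samples, n_sub, dt, period,
        protocol.stim_amplitude, protocol.stim_duration,
        clamp, protocol.clamp_v, t_out, y_out, cur_out, flx_out,
    )
    if status != 0:
        bad = int(np.argmax(~np.isfinite(y_out[:, 0])))
        raise SolverError(
            f"integration diverged near t = {t_out[bad]:.1f} ms",
            last_valid_time=float(t_out[max(bad - 1, 0)]))

    meta = {"protocol": protocol.mode, "dt": dt}
    if protocol.mode == "paced":
        meta.update(beats=protocol.beats, period=protocol.period,
                    final_beat_start=(protocol.beats - 1) * protocol.period)
    return Trace(t=t_out, v=y_out[:, 0], ca=y_out[:, STATE_INDEX["c_c"]],
                 states=y_out, currents=cur_out, fluxes=flx_out, meta=meta)
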