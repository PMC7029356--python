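"""Shipped parameterizations of the base model.

The adult ventricular preset is the *default base model*: every other
parameterization is expressed relative to it through adjustment factors.
The hiPSC-CM preset is derived from the adult preset by inverting the
shipped maturation factors (p_adult = (1+λ)·p_hiPSC), so the two presets
are linked exactly by the published maturation map.

Initial conditions shipped per preset are the resting state after 100 paced
beats at 1 Hz of the default parameterization, computed once and frozen in
:mod:`cardioinv._initial_states`.
"""

from __future__ import annotations

import numpy as np

from .model import ModelState, Protocol, default_initial_state, integrate
from .parameters import ModelParameters
from .scaling import MATURATION_LAMBDA, apply_adjustments

#: Adult (default base model) parameter values.  Conductance magnitudes are
#: in the range of published adult ventricular models; RyR/SERCA/buffer and
#: geometry values are tuned so that both this preset and the derived hiPSC
#: preset produce stable 1 Hz paced action potentials and Ca2+ transients
#: with graded, high-gain SR release.
_ADULT_VALUES: dict[str, float] = {
    # membrane conductances / densities (A/F scale)
    "g_Na": 23.0,
    "g_NaL": 0.1,
    "g_CaL": 1.75e-4,
    "g_to": 0.294,
    "g_Kr": 0.3,
    "g_Ks": 0.4,
    "g_K1": 5.405,
    "g_NaK": 1.362,
    "g_NaCa": 100.0,
    "g_pCa": 0.05,
    "g_bCa": 2.0e-3,
    "g_bCl": 0.009,
    "g_f": 3.0e-4,
    # RyR release
    "alpha_RyR": 6.0e-13,   # L/ms
    "beta_RyR": 0.04,       # mM
    "gamma_RyR": 0.0035,
    "eta_RyR": 0.5,         # 1/ms
    "kappa_RyR": 0.01,      # mM
    # SERCA
    "g_SERCA": 2.5e-15,     # mmol/ms
    "K_SERCA": 1.5e-4,      # mM
    # buffers (totals density-scaled; on/off kinetics fixed)
    "B_tot_d": 1.5, "k_on_d": 100.0, "k_off_d": 1.0,
    "B_tot_sl": 0.3, "k_on_sl": 100.0, "k_off_sl": 1.3,
    "B_tot_c": 0.07, "k_on_c": 32.7, "k_off_c": 0.0196,
    "B_tot_s": 25.0, "k_on_s": 1.0, "k_off_s": 0.65,
    # inter-compartment diffusion (L/ms)
    "k_dc": 1.0e-13,
    "k_slc": 1.5e-13,
    "k_ns": 4.0e-15,
    # geometry
    "V_cell": 2.0e-11,      # L
    "frac_d": 0.001, "frac_sl": 0.02, "frac_c": 0.65,
    "frac_s": 0.004, "frac_n": 0.03,
    "chi": 0.6,             # 1/um (t-tubules roughly double the membrane area)
    "C_m": 0.01,            # pF/um^2
    # fixed ionic conditions
    "Na_i": 10.0, "Na_o": 140.0,
    "K_i": 140.0, "K_o": 5.4,
    "Ca_o": 1.8,
    "E_Cl": -50.0,
    "E_f": -17.0,
}


def adult_parameters() -> ModelParameters:
    """The default base model (generic adult ventricular cardiomyocyte)."""
    return ModelParameters.from_dict(_ADULT_VALUES)


def hipsc_parameters() -> ModelParameters:
    """The default hiPSC-CM preset: adult preset divided by (1+λ_maturation)."""
    return apply_adjustments(adult_parameters(), MATURATION_LAMBDA.inverse())


_PRESETS = {"adult": adult_parameters, "hipsc": hipsc_parameters}


def get_preset(name: str) -> ModelParameters:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None


def compute_resting_state(params: ModelParameters, beats: int = 100,
                          hz: float = 1.0, dt: float = 0.02) -> ModelState:
    """Quasi-steady paced state: final state after ``beats`` cycles at ``hz``."""
    proto = Protocol(mode="paced", hz=hz, beats=beats, dt=dt, sample_dt=5.0)
    trace = integrate(params, proto, default_initial_state(params))
    return trace.final_state()


def initial_state(preset: str) -> ModelState:
    """Shipped initial condition for a preset (frozen post-pacing rest state)."""
    from ._initial_states import INITIAL_STATES
    if preset in INITIAL_STATES:
        return ModelState(np.asarray(INITIAL_STATES[preset]))
    return compute_resting_state(get_preset(preset))
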