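"""Parameter and state containers for the cardiomyocyte base model.

The base model describes a single paced cardiomyocyte with twelve membrane
currents plus the funny current, five intracellular Ca2+ compartments (dyad,
subsarcolemmal space, bulk cytosol, junctional SR, network SR) with first-order
buffers, SERCA uptake and an availability-limited ryanodine-receptor release
model.  A single parameter set (:class:`ModelParameters`) describes one
maturity stage; density-like parameters are scaled between stages by
adjustment factors while single-channel kinetics stay fixed.

Units used package-wide: ms, mV, mM, A/F, L; fluxes in mmol/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
import math

import numpy as np

#: Canonical ordering of membrane currents (matches the λ ordering used in
#: adjustment factors and in the identifiability current matrix).
CURRENT_NAMES: tuple[str, ...] = (
    "Na", "NaL", "CaL", "to", "Kr", "Ks", "K1",
    "NaK", "NaCa", "pCa", "bCa", "bCl", "f",
)

#: Names of model fluxes recorded by the integrator, in column order.
FLUX_NAMES: tuple[str, ...] = (
    "J_CaL", "J_db", "J_dc", "J_esl", "J_slc", "J_slb", "J_ssl",
    "J_RyR", "J_leak", "J_cn", "J_cb", "J_ns", "J_sb", "J_SERCA",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the base model for one maturity stage.

    Density-like parameters (lumped conductances ``g_x`` in A/F per unit
    driving term, RyR ``alpha_RyR``/``beta_RyR``, SERCA scale, buffer totals,
    diffusion rates and the surface-to-volume ratio ``chi``) are the targets
    of adjustment factors; everything else describes single-channel function
    or fixed experimental conditions and is identical across maturity stages.
    """

    # lumped membrane conductances / densities (current in A/F)
    g_Na: float
    g_NaL: float
    g_CaL: float
    g_to: float
    g_Kr: float
    g_Ks: float
    g_K1: float
    g_NaK: float
    g_NaCa: float
    g_pCa: float
    g_bCa: float
    g_bCl: float
    g_f: float
    # RyR release model
    alpha_RyR: float   # L/ms, lumped release rate (density-scaled)
    beta_RyR: float    # mM, availability depletion scale (density-scaled)
    gamma_RyR: float   # dimensionless always-open (leak) fraction
    eta_RyR: float     # 1/ms, availability recovery rate
    kappa_RyR: float   # mM, half-activation of the RyR open probability
    # SERCA
    g_SERCA: float     # mmol/ms, maximal uptake rate (density-scaled)
    K_SERCA: float     # mM, pump half-saturation
    # buffers: totals (density-scaled) and on/off rates (fixed kinetics)
    B_tot_d: float
    k_on_d: float      # 1/(mM*ms)
    k_off_d: float     # 1/ms
    B_tot_sl: float
    k_on_sl: float
    k_off_sl: float
    B_tot_c: float
    k_on_c: float
    k_off_c: float
    B_tot_s: float
    k_on_s: float
    k_off_s: float
    # inter-compartment diffusion (lumped, L/ms; density-scaled)
    k_dc: float
    k_slc: float
    k_ns: float
    # geometry
    V_cell: float      # L
    frac_d: float
    frac_sl: float
    frac_c: float
    frac_s: float
    frac_n: float
    chi: float         # 1/um, surface-to-volume ratio (density-scaled)
    C_m: float         # pF/um^2, specific membrane capacitance
    # fixed ionic conditions
    Na_i: float        # mM
    Na_o: float
    K_i: float
    K_o: float
    Ca_o: float
    E_Cl: float        # mV, chloride reversal potential
    E_f: float         # mV, funny-current reversal potential

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"parameter {f.name!r} is not finite: {val}")
        nonneg = [f.name for f in fields(self) if f.name not in ("E_Cl", "E_f")]
        for name in nonneg:
            if getattr(self, name) < 0.0:
                raise ValueError(f"parameter {name!r} must be >= 0")
        if self.kappa_RyR <= 0.0:
            raise ValueError("kappa_RyR must be > 0")
        vol = self.frac_d + self.frac_sl + self.frac_c + self.frac_s + self.frac_n
        if vol > 1.0 + 1e-12:
            raise ValueError(f"compartment volume fractions sum to {vol} > 1")
        if self.V_cell <= 0.0:
            raise ValueError("V_cell must be > 0")

    # -- array conversion (fixed field order) ---------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        names = [f.name for f in fields(cls)]
        if len(vec) != len(names):
            raise ValueError(f"expected {len(names)} parameters, got {len(vec)}")
        return cls(**{n: float(v) for n, v in zip(names, vec)})

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kw: float) -> "ModelParameters":
        return replace(self, **kw)

    # -- derived geometry ----------------------------------------------
    @property
    def total_capacitance(self) -> float:
        """Total membrane capacitance in Farads (C_m * chi * V_cell)."""
        # A [um^2] = chi [1/um] * V_cell [L] * 1e15 [um^3/L];  pF -> F: 1e-12
        return self.C_m * self.chi * self.V_cell * 1e3

    def compartment_volume(self, comp: str) -> float:
        return getattr(self, f"frac_{comp}") * self.V_cell


#: Index of each parameter in the flat vector used by the compiled kernels.
PARAM_INDEX: dict[str, int] = {f.name: i for i, f in enumerate(fields(ModelParameters))}
N_PARAMS: int = len(PARAM_INDEX)

#: State vector layout used by the integrator.
STATE_NAMES: tuple[str, ...] = (
    "v",
    "m", "h", "j", "mL", "hL", "d", "f_gate",
    "r_to", "s_to", "xr1", "xr2", "xs", "xf",
    "c_d", "b_d", "c_sl", "b_sl", "c_c", "b_c", "c_s", "b_s", "c_n",
    "r",
)
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}
N_STATES: int = len(STATE_NAMES)

#: names of gating variables constrained to [0, 1]
GATE_NAMES: tuple[str, ...] = STATE_NAMES[1:14] + ("r",)
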