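"""Adjustment factors, IC50 drug block and the hiPSC-to-adult maturation map.

A cell at one maturity stage differs from the default base model only in
channel/pump/buffer densities and geometry; single-channel function is
invariant.  Each density-like parameter ``p`` is scaled as ``(1+λ)·p``.
Drug block scales the targeted conductances by ``1/(1+D·ε)`` with
``ε = 1/IC50``; the ε of a drug is assumed identical across maturity stages
(single-channel invariance), which is what allows drug effects identified in
hiPSC-CMs to be transferred to the adult model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
import math
from typing import Mapping, Optional

from .parameters import CURRENT_NAMES, ModelParameters

#: canonical adjustment-factor names, in the order used throughout
LAMBDA_NAMES: tuple[str, ...] = CURRENT_NAMES + (
    "RyR", "SERCA", "Bd", "Bsl", "Bc", "Bs", "dc", "slc", "ns", "chi",
)

#: map from λ name to the ModelParameters fields it scales
_LAMBDA_TARGETS: dict[str, tuple[str, ...]] = {
    **{name: (f"g_{name}",) for name in CURRENT_NAMES},
    "RyR": ("alpha_RyR", "beta_RyR"),
    "SERCA": ("g_SERCA",),
    "Bd": ("B_tot_d",), "Bsl": ("B_tot_sl",), "Bc": ("B_tot_c",), "Bs": ("B_tot_s",),
    "dc": ("k_dc",), "slc": ("k_slc",), "ns": ("k_ns",),
    "chi": ("chi",),
}


class AdjustmentFactors(Mapping):
    """The λ vector mapping the default base model to a fitted cell model.

    Stored per-name; the shared-buffer (λ_B) and shared-diffusion (λ_α)
    constraints used during inversion are expressed by constructing the
    factors through :meth:`shared`, which sets all buffer (resp. diffusion)
    entries from a single value.  The shipped maturation factors keep the
    per-compartment values of the published map.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Optional[Mapping[str, float]] = None, **kw: float):
        merged: dict[str, float] = {n: 0.0 for n in LAMBDA_NAMES}
        for src in (values or {}), kw:
            for name, lam in src.items():
                if name not in merged:
                    raise ValueError(f"unknown adjustment factor {name!r}")
                merged[name] = float(lam)
        for name, lam in merged.items():
            if not math.isfinite(lam) or 1.0 + lam <= 0.0:
                raise ValueError(f"1 + lambda_{name} must be positive, got {lam}")
        self._values = merged

    @classmethod
    def shared(cls, lambda_B: float = 0.0, lambda_alpha: float = 0.0,
               **kw: float) -> "AdjustmentFactors":
        """Build factors with a single shared buffer and diffusion factor."""
        vals = dict(kw)
        vals.update({n: lambda_B for n in ("Bd", "Bsl", "Bc", "Bs")})
        vals.update({n: lambda_alpha for n in ("dc", "slc", "ns")})
        return cls(vals)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self):
        return iter(LAMBDA_NAMES)

    def __len__(self) -> int:
        return len(LAMBDA_NAMES)

    def inverse(self) -> "AdjustmentFactors":
        """Element-wise inverse: composing with it is the identity."""
        return AdjustmentFactors({n: 1.0 / (1.0 + lam) - 1.0
                                  for n, lam in self._values.items()})

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def __repr__(self) -> str:
        nz = {n: round(v, 4) for n, v in self._values.items() if v != 0.0}
        return f"AdjustmentFactors({nz})"


#: Maturation factors between the shipped hiPSC-CM and adult presets:
#: p_adult = (1 + λ) · p_hiPSC for every density-like parameter.  χ maps
#: 0.9 μm⁻¹ (hiPSC) to 0.6 μm⁻¹ (adult), i.e. λ_χ = −1/3.
MATURATION_LAMBDA = AdjustmentFactors({
    "Na": 2.00, "NaL": -0.08, "Kr": -0.54, "Ks": 0.68, "K1": 2.23,
    "to": 8.45, "f": -0.99, "bCl": 42.43, "NaK": -0.16, "CaL": -0.53,
    "bCa": 3.90, "pCa": -0.85, "NaCa": -0.69, "RyR": -0.20, "SERCA": -0.53,
    "chi": -1.0 / 3.0,
    "slc": -0.14, "ns": -0.10, "dc": -0.61,
    "Bc": -0.56, "Bd": -0.72, "Bsl": -0.60, "Bs": -0.58,
})


def apply_adjustments(base: ModelParameters, lam: AdjustmentFactors) -> ModelParameters:
    """Scale every density-like parameter of ``base`` by its (1+λ).

    α_RyR and β_RyR share λ_RyR; buffer totals and diffusion rates use their
    per-compartment entries; χ scales with λ_chi; single-channel kinetics
    (on/off rates, pump affinities, κ_RyR, γ_RyR, η_RyR) are untouched.
    """
    if not isinstance(lam, AdjustmentFactors):
        lam = AdjustmentFactors(lam)
    updates: dict[str, float] = {}
    for name, targets in _LAMBDA_TARGETS.items():
        factor = 1.0 + lam[name]
        for tgt in targets:
            updates[tgt] = getattr(base, tgt) * factor
    return base.replace(**updates)


@dataclass(frozen=True)
class DrugEffect:
    """Inverse-IC50 drug parameters ε per targeted current plus a dose ladder.

    ``eps`` entries are in inverse concentration units (1/``dose_unit``);
    currents not listed are unaffected.  The first dose is the control
    (D = 0).
    """

    eps: Mapping[str, float] = field(default_factory=dict)
    doses: tuple[float, ...] = (0.0,)
    dose_unit: str = "nM"

    #: currents a drug is allowed to target
    TARGETS = ("CaL", "NaL", "Kr")

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps", dict(self.eps))
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        for name, e in self.eps.items():
            if name not in self.TARGETS:
                raise ValueError(f"unsupported drug target {name!r}")
            if e < 0.0 or not math.isfinite(e):
                raise ValueError(f"epsilon for {name} must be finite and >= 0")
        if self.doses[0] != 0.0:
            raise ValueError("dose ladder must start with the control D = 0")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")

    def epsilon(self, target: str) -> float:
        return float(self.eps.get(target, 0.0))

    def block_factor(self, target: str, dose: float) -> float:
        """Conductance scaling 1/(1 + D·ε) at the given dose."""
        return 1.0 / (1.0 + dose * self.epsilon(target))


def apply_drug(control: ModelParameters, drug: DrugEffect,
               dose: float) -> ModelParameters:
    """Scale the drug-targeted conductances of ``control`` at one dose.

    g_CaL, g_NaL and g_Kr are each multiplied by 1/(1 + D·ε); every other
    parameter is unchanged.  D = 0 returns the control unchanged.
    """
    if dose < 0.0:
        raise ValueError("dose must be >= 0")
    if dose == 0.0:
        return control
    updates = {f"g_{t}": getattr(control, f"g_{t}") * drug.block_factor(t, dose)
               for t in DrugEffect.TARGETS}
    return control.replace(**updates)


def epsilon_to_ic50(eps: float) -> float:
    """IC50 = 1/ε (same concentration unit as 1/ε)."""
    if eps <= 0.0:
        raise ValueError(
            "epsilon = 0 means no detectable block; IC50 is above the tested "
            "range and has no finite value")
    return 1.0 / eps


def ic50_to_epsilon(ic50: float) -> float:
    if ic50 <= 0.0:
        raise ValueError("IC50 must be > 0")
    return 1.0 / ic50


@dataclass(frozen=True)
class MaturationMap:
    """Per-parameter multiplicative map Q with Q·p_hiPSC = p_adult."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", dict(self.factors))
        for name, q in self.factors.items():
            if q <= 0.0 or not math.isfinite(q):
                raise ValueError(f"maturation factor for {name!r} must be > 0")

    def apply(self, params: ModelParameters) -> ModelParameters:
        return ModelParameters.from_dict(
            {name: getattr(params, name) * self.factors.get(name, 1.0)
             for name in self.factors})

    def inverse(self) -> "MaturationMap":
        return MaturationMap({n: 1.0 / q for n, q in self.factors.items()})


def build_maturation_map(hipsc: ModelParameters,
                         adult: ModelParameters) -> MaturationMap:
    """Element-wise ratio map: Q = p_adult / p_hiPSC per parameter."""
    factors: dict[str, float] = {}
    for f in dc_fields(ModelParameters):
        h = getattr(hipsc, f.name)
        a = getattr(adult, f.name)
        if h == 0.0:
            if a != 0.0:
                raise ValueError(
                    f"undefined maturation ratio for {f.name!r}: "
                    f"hiPSC value is 0 but adult value is {a}")
            factors[f.name] = 1.0
        else:
            factors[f.name] = a / h
    return MaturationMap(factors)


# -- text reports ------------------------------------------------------------

def format_maturation_table(lam: AdjustmentFactors) -> str:
    """Maturation-map summary table (λ per parameter group)."""
    lines = ["parameter  lambda", "-" * 18]
    for name in LAMBDA_NAMES:
        lines.append(f"{name:<10} {lam[name]:+7.2f}")
    return "\n".join(lines)


def format_ic50_report(eps: Mapping[str, float], dose_unit: str,
                       max_dose: Optional[float] = None) -> str:
    """Inversion-result IC50 table (one row per targeted current)."""
    lines = [f"current  Inversion IC50 ({dose_unit})", "-" * 34]
    for target in DrugEffect.TARGETS:
        e = float(eps.get(target, 0.0))
        if e <= 0.0:
            entry = "no detectable block"
            if max_dose is not None:
                entry += f" (IC50 > {max_dose:g} {dose_unit} tested)"
        else:
            entry = f"{1.0 / e:,.4g}"
        lines.append(f"{target:<8} {entry}")
    return "\n".join(lines)
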