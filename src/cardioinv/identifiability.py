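"""SVD-based identifiability analysis of the membrane currents.

The model currents sampled over one paced beat form a matrix A (time x
currents).  Right singular vectors of A associated with large singular
values are conductance-perturbation directions expected to change the AP
strongly; directions with small singular values barely change it.  Each
direction is scored by perturbing the conductances with λ = ω·v_i over a
grid of amplitudes ω and measuring the cost against the unperturbed model.
Directions whose maximal cost stays below a threshold span the
*unidentifiable space* N; the identifiability index of current j is
k(e_j) = ||e_j − P_N e_j||₂ (1 = identifiable, 0 = unidentifiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .biomarkers import BiomarkerSet, CostSpec, dose_cost, extract_biomarkers
from .model import ModelState, Protocol, SolverError, Trace, integrate
from .parameters import CURRENT_NAMES, ModelParameters
from .presets import get_preset, initial_state
from .scaling import AdjustmentFactors

#: cost used for perturbation scans: AP durations and the 30%-level area,
#: APD80 up-weighted.
IDENT_COST_SPEC = CostSpec(terms=("APD30", "APD50", "APD80", "int30"),
                           weights={"APD80": 5.0})

#: protocol for the scan: measurement on the third paced beat
IDENT_PROTOCOL = Protocol(mode="paced", hz=1.0, beats=3, dt=0.05, sample_dt=1.0)


@dataclass
class CurrentMatrix:
    """Sampled model currents: rows are times t_n = n·Δt, columns currents."""

    A: np.ndarray
    dt: float
    current_names: tuple[str, ...] = CURRENT_NAMES

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if not np.all(np.isfinite(self.A)):
            raise ValueError("current matrix contains non-finite entries")
        if self.A.shape[1] != len(self.current_names):
            raise ValueError("column count does not match current names")


@dataclass
class IdentifiabilityResult:
    singular_values: np.ndarray          # descending
    singular_vectors: np.ndarray         # columns v_i, sign-normalized
    max_costs: np.ndarray                # max_ω H(ω·v_i) per vector
    basis: np.ndarray                    # (Nc, k) unidentifiable-space basis
    indices: dict[str, float]            # k(e_j) per current
    threshold: float
    current_names: tuple[str, ...] = CURRENT_NAMES


def build_current_matrix(params: ModelParameters,
                         protocol: Protocol = IDENT_PROTOCOL,
                         dt: float = 1.0,
                         initial: Optional[ModelState] = None) -> CurrentMatrix:
    """Simulate the measurement beat and sample each membrane current.

    The stimulus current is not a model current and is excluded.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    import dataclasses
    proto = dataclasses.replace(protocol, sample_dt=dt)
    trace = integrate(params, proto, initial)
    beat = trace.final_beat() if proto.mode == "paced" else trace
    return CurrentMatrix(A=beat.currents[1:, :13], dt=dt)


def _scan_costs(params: ModelParameters, direction: np.ndarray,
                omega_grid: Sequence[float], costspec: CostSpec,
                protocol: Protocol, initial: Optional[ModelState],
                reference: BiomarkerSet) -> np.ndarray:
    costs = np.empty(len(omega_grid))
    for k, omega in enumerate(omega_grid):
        lam_vals = {name: float(omega * direction[i])
                    for i, name in enumerate(CURRENT_NAMES)}
        try:
            lam = AdjustmentFactors(lam_vals)
            trace = integrate(params if omega == 0 else
                              _apply_current_lambdas(params, lam),
                              protocol, initial)
            bm = extract_biomarkers(trace.final_beat())
        except (ValueError, SolverError):
            # an infeasible or diverging perturbation takes the penalty
            bm = BiomarkerSet(valid=False)
        costs[k] = dose_cost(bm, reference, costspec)
    return costs


def _apply_current_lambdas(params: ModelParameters,
                           lam: AdjustmentFactors) -> ModelParameters:
    updates = {f"g_{n}": getattr(params, f"g_{n}") * (1.0 + lam[n])
               for n in CURRENT_NAMES}
    return params.replace(**updates)


def perturbation_scan(params: ModelParameters, v_i: np.ndarray,
                      omega_grid: Optional[Sequence[float]] = None,
                      costspec: CostSpec = IDENT_COST_SPEC,
                      protocol: Protocol = IDENT_PROTOCOL,
                      initial: Optional[ModelState] = None,
                      reference: Optional[BiomarkerSet] = None) -> float:
    """Maximum cost of conductance perturbations λ = ω·v_i over the ω grid."""
    v_i = np.asarray(v_i, dtype=float)
    if abs(np.linalg.norm(v_i) - 1.0) > 1e-8:
        raise ValueError("singular vector must have unit norm")
    if omega_grid is None:
        omega_grid = np.linspace(0.0, 1.0, 11)
    if reference is None:
        ref_trace = integrate(params, protocol, initial)
        reference = extract_biomarkers(ref_trace.final_beat())
    costs = _scan_costs(params, v_i, omega_grid, costspec, protocol,
                        initial, reference)
    return float(np.max(costs))


def unidentifiable_space(singular_vectors: np.ndarray, max_costs: np.ndarray,
                         threshold: float = 0.05) -> np.ndarray:
    """Orthonormal basis of the directions with max cost below threshold."""
    sel = np.asarray(max_costs) < threshold
    return np.asarray(singular_vectors)[:, sel]


def identifiability_index(j, basis: np.ndarray) -> float:
    """k(e_j) = ||e_j − P_N e_j||₂ for current j (name or column index)."""
    if isinstance(j, str):
        j = CURRENT_NAMES.index(j)
    e = np.zeros(basis.shape[0] if basis.size else len(CURRENT_NAMES))
    e[j] = 1.0
    if basis.size == 0:
        return 1.0
    proj = basis @ (basis.T @ e)
    return float(np.linalg.norm(e - proj))


def run_identifiability(preset_or_params, dt: float = 1.0,
                        omega_grid: Optional[Sequence[float]] = None,
                        threshold: float = 0.05,
                        costspec: CostSpec = IDENT_COST_SPEC,
                        protocol: Protocol = IDENT_PROTOCOL
                        ) -> IdentifiabilityResult:
    """Full analysis: current matrix, SVD, perturbation scans, k indices."""
    if isinstance(preset_or_params, str):
        params = get_preset(preset_or_params)
        initial = initial_state(preset_or_params)
    else:
        params = preset_or_params
        initial = None
    if omega_grid is None:
        omega_grid = np.linspace(0.0, 1.0, 11)

    cm = build_current_matrix(params, protocol, dt=dt, initial=initial)
    _, sigma, vt = np.linalg.svd(cm.A, full_matrices=False)
    v = vt.T
    # SVD sign convention: largest-magnitude component of each vector positive
    for i in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, i])), i] < 0:
            v[:, i] = -v[:, i]

    ref_trace = integrate(params, protocol, initial)
    reference = extract_biomarkers(ref_trace.final_beat())
    max_costs = np.array([
        np.max(_scan_costs(params, v[:, i], omega_grid, costspec, protocol,
                           initial, reference))
        for i in range(v.shape[1])])
    basis = unidentifiable_space(v, max_costs, threshold)
    indices = {name: identifiability_index(i, basis)
               for i, name in enumerate(CURRENT_NAMES)}
    return IdentifiabilityResult(
        singular_values=sigma, singular_vectors=v, max_costs=max_costs,
        basis=basis, indices=indices, threshold=threshold)


def format_identifiability_report(res: IdentifiabilityResult) -> str:
    lines = ["i   sigma_i      max cost", "-" * 28]
    for i, (s, c) in enumerate(zip(res.singular_values, res.max_costs)):
        lines.append(f"{i:<3d} {s:12.4g} {c:9.4g}")
    lines.append("")
    lines.append("current  k (1 = identifiable)")
    lines.append("-" * 29)
    for name in res.current_names:
        lines.append(f"{name:<8} {res.indices[name]:.3f}")
    return "\n".join(lines)
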