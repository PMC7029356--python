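"""Continuation-based multi-start Nelder-Mead inversion.

The inversion jointly fits control adjustment factors λ and drug parameters
ε = 1/IC50 to a dose-escalation dataset.  Directly minimizing the full cost
is fragile, so the target characteristics are blended: at θ = 0 they are the
default model's own characteristics (optimum λ = ε = 0, known); θ is stepped
to 1 in M increments, and at each step a limited-budget Nelder-Mead search
is run from the incumbent plus a cloud of random starts drawn around it.
ε is searched in log space (its natural, scale-free parameterization).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
import logging
import math
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

from .biomarkers import (
    BiomarkerSet, CostSpec, continuation_cost, extract_biomarkers,
)
from .scaling import LAMBDA_NAMES, AdjustmentFactors

log = logging.getLogger(__name__)

#: special shared-factor names allowed in free_lambda
_SHARED = {"B": ("Bd", "Bsl", "Bc", "Bs"), "alpha": ("dc", "slc", "ns")}


@dataclass(frozen=True)
class InversionConfig:
    """Knobs of the continuation search.

    Defaults follow the full-scale schedule (M = 20 continuation steps,
    63 random starts per step, 5 simplex iterations per start for the first
    three quarters of the steps and 25 for the last quarter, λ starts drawn
    within ±0.2 of the incumbent and ε starts within a factor 5).
    Scaled-down configurations shrink M, the start count and the iteration
    budget, not the sampling ranges.
    """

    free_lambda: tuple[str, ...] = ("CaL", "NaL", "Kr")
    free_epsilon: tuple[str, ...] = ("CaL", "NaL", "Kr")
    n_steps: int = 20
    n_starts: int = 63
    iters_early: int = 5
    iters_late: int = 25
    late_fraction: float = 0.75
    lambda_halfwidth: float = 0.2
    epsilon_factor: float = 5.0
    epsilon_floor: Optional[float] = None   # default: 0.01 / smallest dose
    lambda_bounds: tuple[float, float] = (-0.95, 20.0)
    final_polish: int = 0     # extra simplex iterations at theta = 1
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_starts < 1:
            raise ValueError("n_steps and n_starts must be >= 1")
        if self.lambda_halfwidth < 0 or self.epsilon_factor < 1.0:
            raise ValueError("invalid sampling ranges")
        for name in self.free_lambda:
            if name not in LAMBDA_NAMES and name not in _SHARED:
                raise ValueError(f"unknown free lambda {name!r}")
        if not (self.free_lambda or self.free_epsilon):
            raise ValueError("free-parameter lists are empty")

    def iters_for_step(self, m: int) -> int:
        return self.iters_late if m > self.late_fraction * self.n_steps \
            else self.iters_early


@dataclass
class InversionResult:
    """Fitted λ and ε with the full continuation path."""

    lam: AdjustmentFactors
    eps: dict[str, float]
    path: list[dict]          # M+1 entries, theta = 0 ... 1
    seed: int
    config: InversionConfig
    cost: float
    dose_unit: str = "nM"
    fitted_biomarkers: dict[float, BiomarkerSet] = field(default_factory=dict)

    @property
    def ic50(self) -> dict[str, float]:
        """IC50 per fitted target (inf where ε = 0)."""
        return {t: (1.0 / e if e > 0 else math.inf) for t, e in self.eps.items()}


def sample_starts(lam0: np.ndarray, eps0: np.ndarray, config: InversionConfig,
                  rng: np.random.Generator, floor: float) -> np.ndarray:
    """Random start vectors around the incumbent.

    λ components are uniform in [λ−hw, λ+hw] clipped to the λ bounds; ε
    components are log-uniform in [ε/k, k·ε] (with ``floor`` replacing a
    zero incumbent).  Returns shape (n_starts, n_lam + n_eps) where the ε
    block is in log space.
    """
    n_lam, n_eps = len(lam0), len(eps0)
    out = np.empty((config.n_starts, n_lam + n_eps))
    lo, hi = config.lambda_bounds
    for i in range(config.n_starts):
        lam = lam0 + rng.uniform(-config.lambda_halfwidth,
                                 config.lambda_halfwidth, n_lam)
        out[i, :n_lam] = np.clip(lam, lo, hi)
        u0 = np.log(np.maximum(eps0, floor))
        width = math.log(config.epsilon_factor)
        out[i, n_lam:] = u0 + rng.uniform(-width, width, n_eps)
    return out


def local_minimize(f: Callable[[np.ndarray], float], start: np.ndarray,
                   iterations: int) -> tuple[np.ndarray, float]:
    """Budget-limited Nelder-Mead descent; never worse than the start."""
    start = np.asarray(start, dtype=float)
    if iterations <= 0:
        return start, f(start)
    res = minimize(f, start, method="Nelder-Mead",
                   options={"maxiter": iterations, "xatol": 1e-12,
                            "fatol": 1e-12})
    f_start = f(start)
    if res.fun <= f_start:
        return np.asarray(res.x), float(res.fun)
    return start, float(f_start)


def _decode(x: np.ndarray, config: InversionConfig
            ) -> tuple[AdjustmentFactors, dict[str, float]]:
    """Internal vector -> (λ factors, ε dict).  ε block is in log space."""
    n_lam = len(config.free_lambda)
    lo, hi = config.lambda_bounds
    lam_vals = np.clip(x[:n_lam], lo, hi)
    individual: dict[str, float] = {}
    shared_b = shared_a = 0.0
    for name, val in zip(config.free_lambda, lam_vals):
        if name == "B":
            shared_b = float(val)
        elif name == "alpha":
            shared_a = float(val)
        else:
            individual[name] = float(val)
    lam = AdjustmentFactors.shared(lambda_B=shared_b, lambda_alpha=shared_a,
                                   **individual)
    eps = {t: float(np.exp(u)) for t, u in zip(config.free_epsilon, x[n_lam:])}
    return lam, eps


def invert(dataset, config: InversionConfig, costspec: CostSpec,
           simulate_fn: Callable) -> InversionResult:
    """Continuation inversion of a dose-escalation dataset.

    ``simulate_fn(lam, eps, dose) -> Trace`` is the forward model (see
    :func:`cardioinv.drug_study.make_study_simulator`).  Deterministic for a
    fixed ``config.seed``.
    """
    doses = dataset.doses
    if len(doses) < 2:
        raise ValueError("dataset must contain a control and at least one dose")
    data_targets = {d: extract_biomarkers(tr) for d, tr in dataset.items()}
    reference = extract_biomarkers(simulate_fn(AdjustmentFactors(), {}, 0.0))
    if not reference.valid:
        raise RuntimeError("default model produced no AP; cannot invert")

    floor = config.epsilon_floor
    if floor is None:
        # block of <= 1% at the smallest tested dose: undetectable anywhere
        # in the ladder, yet within reach of the multiplicative start range
        # of any block expressible inside the dose range
        d_min = min(d for d in doses if d > 0)
        floor = 0.01 / d_min

    rng = np.random.default_rng(config.seed)
    n_lam, n_eps = len(config.free_lambda), len(config.free_epsilon)
    x_inc = np.concatenate([np.zeros(n_lam), np.full(n_eps, np.log(floor))])

    def objective_at(theta: float) -> Callable[[np.ndarray], float]:
        def f(x: np.ndarray) -> float:
            lam, eps = _decode(x, config)
            return continuation_cost(theta, lam, eps, reference, data_targets,
                                     costspec, simulate_fn)
        return f

    # the path starts at the known theta = 0 optimum (lambda = epsilon = 0,
    # where the blended targets equal the reference by construction)
    path: list[dict] = [{
        "theta": 0.0,
        "lambda": {n: 0.0 for n in config.free_lambda if n in LAMBDA_NAMES},
        "epsilon": {t: 0.0 for t in config.free_epsilon},
        "cost": 0.0,
        "best_start": None,
    }]
    best_cost = math.inf
    for m in range(1, config.n_steps + 1):
        theta = m / config.n_steps
        f = objective_at(theta)
        lam_inc = x_inc[:n_lam]
        eps_inc = np.exp(x_inc[n_lam:])
        starts = [x_inc.copy()]
        starts.extend(sample_starts(lam_inc, eps_inc, config, rng, floor))
        iters = config.iters_for_step(m)
        if config.workers > 1:
            with ThreadPoolExecutor(max_workers=config.workers) as pool:
                results = list(pool.map(lambda s: local_minimize(f, s, iters),
                                        starts))
        else:
            results = [local_minimize(f, s, iters) for s in starts]
        # lowest cost wins; ties broken by start index (incumbent first)
        best_idx = min(range(len(results)), key=lambda i: results[i][1])
        x_inc, best_cost = results[best_idx]
        lam_m, eps_m = _decode(x_inc, config)
        path.append({"theta": theta,
                     "lambda": {n: lam_m[n] for n in config.free_lambda
                                if n in LAMBDA_NAMES},
                     "epsilon": dict(eps_m),
                     "cost": float(best_cost),
                     "best_start": int(best_idx)})
        log.info("continuation step %d/%d: theta=%.3f best cost %.4g "
                 "(start %d)", m, config.n_steps, theta, best_cost, best_idx)

    if config.final_polish > 0:
        x_inc, best_cost = local_minimize(objective_at(1.0), x_inc,
                                          config.final_polish)
        lam_p, eps_p = _decode(x_inc, config)
        path.append({"theta": 1.0,
                     "lambda": {n: lam_p[n] for n in config.free_lambda
                                if n in LAMBDA_NAMES},
                     "epsilon": dict(eps_p),
                     "cost": float(best_cost),
                     "best_start": None})

    lam_fit, eps_fit = _decode(x_inc, config)
    # ε below the sampling floor means no detectable block
    eps_fit = {t: (0.0 if e <= floor * 1.0000001 else e)
               for t, e in eps_fit.items()}
    fitted_bm: dict[float, BiomarkerSet] = {}
    for d in doses:
        try:
            fitted_bm[d] = extract_biomarkers(simulate_fn(lam_fit, eps_fit, d))
        except Exception:   # a failed fit simulation is reported, not fatal
            fitted_bm[d] = BiomarkerSet(valid=False)
    return InversionResult(
        lam=lam_fit, eps=eps_fit, path=path, seed=config.seed, config=config,
        cost=float(best_cost), dose_unit=getattr(dataset, "dose_unit", ""),
        fitted_biomarkers=fitted_bm)
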