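"""Nutrient-intake inference.

The intake of candidate nutrients to the gut is not measured, so it is
inferred per individual: find the non-negative intake vector whose cascade-
predicted relative abundances best match the measured ones, with the misfit
taken on the log10 scale (order-of-magnitude resolution).  Because the
predicted relative profile is invariant to the overall intake scale, the
fit runs over free non-negative amounts and the result is renormalized to
the simplex afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .flow import CommunitySample, FlowParameters, IntakeProfile, cascade_operators
from .network import CrossFeedingNetwork

DEFAULT_FLOOR = 1e-6


def abundance_log_error(
    predicted: dict[str, float] | "np.ndarray",
    observed: dict[str, float] | "np.ndarray",
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Mean |log10 p - log10 m| over species, flooring both sides.

    The floor keeps species the cascade cannot reach (predicted 0) finite.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if isinstance(predicted, dict):
        keys = sorted(predicted)
        if set(keys) != set(observed):
            raise ValueError("predicted and observed species sets differ")
        p = np.array([predicted[k] for k in keys], dtype=float)
        m = np.array([observed[k] for k in keys], dtype=float)
    else:
        p = np.asarray(predicted, dtype=float)
        m = np.asarray(observed, dtype=float)
        if p.shape != m.shape:
            raise ValueError("shape mismatch")
    if p.size == 0:
        raise ValueError("empty species set")
    return float(np.mean(np.abs(np.log10(np.maximum(p, floor)) - np.log10(np.maximum(m, floor)))))


@dataclass
class FitResult:
    """Outcome of one per-sample intake fit."""

    intake: IntakeProfile  # normalized to the simplex
    objective: float  # mean |log10 p - log10 m| at the optimum
    restart_objectives: list[float]
    seed: int
    converged: bool
    n_species: int
    raw_amounts: np.ndarray = field(repr=False, default=None)
    intake_metabolites: list[str] = field(default_factory=list, repr=False)

    @property
    def amounts(self) -> np.ndarray:
        a = np.array([self.intake.amounts[m] for m in self.intake_metabolites])
        return a


def fit_intake(
    net: CrossFeedingNetwork,
    sample: CommunitySample,
    intake_metabolites: Sequence[str],
    params: FlowParameters,
    n_restarts: int = 10,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the intake vector minimizing the log-scale abundance misfit.

    Bounded (non-negative) least squares on the per-species residuals
    ``log10(max(p, floor)) - log10(max(m, floor))``; each restart starts
    from amounts drawn uniform(0, 1) and normalized to sum 1; the best
    restart is kept and its intake renormalized to the simplex.
    """
    intake_metabolites = list(intake_metabolites)
    K = len(intake_metabolites)
    species_overlap = [s for s in sample.abundances if s in net.species_index]
    if not species_overlap:
        raise ValueError("no species overlap between sample and network")
    sub = sample.restrict_to(set(net.species))

    if K == 1:
        return FitResult(
            intake=IntakeProfile({intake_metabolites[0]: 1.0}),
            objective=_objective_for(net, sub, intake_metabolites, np.ones(1), params, floor),
            restart_objectives=[],
            seed=seed,
            converged=True,
            n_species=len(species_overlap),
            raw_amounts=np.ones(1),
            intake_metabolites=intake_metabolites,
        )

    # biomass is linear in the intake: precompute the operator once
    L_b, _, species, _ = cascade_operators(net, sub, params)
    met_idx = []
    for m in intake_metabolites:
        if m not in net.metabolite_index:
            raise KeyError(f"intake metabolite {m!r} not in network")
        met_idx.append(net.metabolite_index[m])
    L = L_b[:, met_idx]  # species x intake

    obs_species = [k for k, s in enumerate(species) if sub.abundances.get(s, 0.0) > 0]
    m_obs = np.array([sub.abundances[species[k]] for k in obs_species])
    Lo = L[obs_species, :]
    log_m = np.log10(np.maximum(m_obs, floor))

    LN10 = np.log(10.0)
    colsum = Lo.sum(axis=0)

    def residuals(x: np.ndarray) -> np.ndarray:
        b = Lo @ x
        total = b.sum()
        p = b / total if total > 0 else b
        return np.log10(np.maximum(p, floor)) - log_m

    def jacobian(x: np.ndarray) -> np.ndarray:
        # d/dx log10(p) with p = Lx / sum(Lx); rows of floored species vanish
        b = Lo @ x
        total = b.sum()
        p = b / total if total > 0 else b
        J = Lo / total - np.outer(b / total**2, colsum)
        active = p > floor
        with np.errstate(divide="ignore"):
            scale = np.where(active, 1.0 / (LN10 * np.maximum(p, floor)), 0.0)
        return J * scale[:, None]

    rng = np.random.default_rng(seed)
    best = None
    restart_objs = []
    any_success = False
    for _ in range(max(1, n_restarts)):
        x0 = rng.uniform(0.0, 1.0, size=K)
        x0 /= x0.sum()
        res = least_squares(
            residuals, x0, jac=jacobian, bounds=(0.0, np.inf),
            xtol=tol, ftol=tol, gtol=tol, method="trf",
        )
        obj = float(np.mean(np.abs(residuals(res.x))))
        restart_objs.append(obj)
        any_success = any_success or res.success
        if best is None or obj < best[0]:
            best = (obj, res.x, res.success)

    obj, x, success = best
    total = x.sum()
    if total <= 0:
        x = np.full(K, 1.0 / K)
        total = 1.0
    amounts = {m: float(v / total) for m, v in zip(intake_metabolites, x)}
    return FitResult(
        intake=IntakeProfile(amounts),
        objective=obj,
        restart_objectives=restart_objs,
        seed=seed,
        converged=bool(success),
        n_species=len(obs_species),
        raw_amounts=x,
        intake_metabolites=intake_metabolites,
    )


def _objective_for(net, sample, intake_metabolites, x, params, floor) -> float:
    L_b, _, species, _ = cascade_operators(net, sample, params)
    idx = [net.metabolite_index[m] for m in intake_metabolites]
    b = L_b[:, idx] @ x
    obs = [k for k, s in enumerate(species) if sample.abundances.get(s, 0.0) > 0]
    p = b[obs] / b[obs].sum() if b[obs].sum() > 0 else b[obs]
    m = np.array([sample.abundances[species[k]] for k in obs])
    return abundance_log_error(p, m, floor)
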