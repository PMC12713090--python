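"""Linear-programming engine: FBA, pinned-constraint optimization, pFBA,
production envelopes.

All computations solve over the steady-state polytope {v : S·v = 0,
lb ≤ v ≤ ub} with scipy's HiGHS interface. Determinism: variable ordering
follows the model's stable reaction ordering, the solver method is fixed
("highs"), and feasibility/optimality tolerances are pinned at 1e-9, so
identical inputs give identical flux distributions.

Equality pins (:class:`FixedConstraint`) are implemented as the interval
``value ± 1e-9·max(1, |value|)`` intersected with the reaction's bounds —
strict equality is numerically brittle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel, stoichiometric_matrix

#: mass-balance tolerance asserted on every optimal solution
MASS_BALANCE_TOL = 1e-6

#: relative half-width of an equality pin
PIN_TOL = 1e-9

_SOLVER_METHOD = "highs"
_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class FixedConstraint:
    """Pin one reaction's flux to a value (within the pin tolerance)."""

    reaction_id: str
    value: float


@dataclass
class FluxDistribution:
    """One LP solution: reaction fluxes, objective value, solver status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


def _pinned_bounds(
    model: MetabolicModel, constraints: Sequence[FixedConstraint]
) -> Optional[List[Tuple[float, float]]]:
    """Per-reaction bounds after intersecting equality pins.

    Returns None when some intersection is empty (constraint set infeasible
    against the bounds)."""
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    for c in constraints:
        j = model.reaction_index(c.reaction_id)
        half = PIN_TOL * max(1.0, abs(c.value))
        lo = max(bounds[j][0], c.value - half)
        hi = min(bounds[j][1], c.value + half)
        if lo > hi:
            return None
        bounds[j] = (lo, hi)
    return bounds


def _solve(
    model: MetabolicModel,
    c: np.ndarray,
    bounds: List[Tuple[float, float]],
) -> Tuple[str, Optional[np.ndarray], float]:
    S = stoichiometric_matrix(model)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method=_SOLVER_METHOD,
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS_MAP.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return status, None, float("nan")
    return status, res.x, float(res.fun)


def maximize_flux(
    model: MetabolicModel,
    objective_reaction_id: str,
    constraints: Sequence[FixedConstraint] = (),
) -> FluxDistribution:
    """Maximize one reaction's flux subject to S·v = 0, bounds, and pins.

    Infeasibility and unboundedness are reported in ``status``, never raised.
    """
    bounds = _pinned_bounds(model, constraints)
    if bounds is None:
        return FluxDistribution({}, float("nan"), INFEASIBLE)
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(objective_reaction_id)] = -1.0
    status, x, fun = _solve(model, c, bounds)
    if status != OPTIMAL:
        return FluxDistribution({}, float("nan"), status)
    fluxes = {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    return FluxDistribution(fluxes, -fun, OPTIMAL)


def pfba(
    model: MetabolicModel,
    constraints: Sequence[FixedConstraint] = (),
) -> FluxDistribution:
    """Parsimonious FBA: minimize total absolute flux Σ|v| subject to
    S·v = 0, bounds, and pins.

    Implemented by splitting every reaction into non-negative forward and
    backward halves (v = v⁺ − v⁻) and minimizing Σ(v⁺ + v⁻); the halves are
    re-merged in the returned distribution. ``objective_value`` is the
    achieved Σ|v|.
    """
    bounds = _pinned_bounds(model, constraints)
    if bounds is None:
        return FluxDistribution({}, float("nan"), INFEASIBLE)

    n = len(model.reactions)
    S = stoichiometric_matrix(model)
    # columns [v+ | v-], S v+ - S v- = 0
    S_split = sparse.hstack([S, -S], format="csr")
    split_bounds: List[Tuple[float, float]] = []
    for lb, ub in bounds:  # v+ half
        split_bounds.append((max(0.0, lb), max(0.0, ub)))
    for lb, ub in bounds:  # v- half
        split_bounds.append((max(0.0, -ub), max(0.0, -lb)))
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=S_split,
        b_eq=np.zeros(S.shape[0]),
        bounds=split_bounds,
        method=_SOLVER_METHOD,
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS_MAP.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxDistribution({}, float("nan"), status)
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxDistribution(fluxes, float(res.fun), OPTIMAL)


@dataclass
class EnvelopePoint:
    fraction: float
    biomass_flux: float
    max_target_flux: float
    status: str = OPTIMAL


def production_envelope(
    model: MetabolicModel,
    biomass_reaction_id: str,
    target_reaction_id: str,
    fractions: Sequence[float],
) -> List[EnvelopePoint]:
    """Upper boundary of the attainable (growth, product) region.

    For each fraction f of the maximum biomass flux, biomass is pinned at
    f·max and the target maximized. Points are returned in input order;
    an infeasible point carries its status instead of a value.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    base = maximize_flux(model, biomass_reaction_id)
    if not base.ok:
        return [EnvelopePoint(f, float("nan"), float("nan"), base.status) for f in fractions]
    mu_max = base.objective_value
    points = []
    for f in fractions:
        sol = maximize_flux(
            model,
            target_reaction_id,
            [FixedConstraint(biomass_reaction_id, f * mu_max)],
        )
        if sol.ok:
            points.append(EnvelopePoint(f, f * mu_max, sol.objective_value))
        else:
            points.append(EnvelopePoint(f, f * mu_max, float("nan"), sol.status))
    return points


def check_solution(
    model: MetabolicModel,
    solution: FluxDistribution,
    tol: float = MASS_BALANCE_TOL,
) -> bool:
    """True iff an optimal solution is mass-balanced (‖S·v‖∞ ≤ tol) and
    within bounds ± tol. Used by the test suite on every solution."""
    if not solution.ok:
        return False
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    S = stoichiometric_matrix(model)
    if np.max(np.abs(S @ v)) > tol:
        return False
    for r, vj in zip(model.reactions, v):
        if vj < r.lower_bound - tol or vj > r.upper_bound + tol:
            return False
    return True
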