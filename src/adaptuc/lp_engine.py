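"""Linear-programming primitives: FBA, variability, knockouts, references.

All solves go through scipy's HiGHS interface.  The contract of every
operation is the *objective value*; flux vectors at degenerate optima
are solver-dependent, so operations that report a full distribution can
request the parsimonious (total-flux-minimising) secondary objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import ConfigurationError, SolverError
from .model_core import MetabolicModel, set_medium

#: Absolute tolerance for reported-equality comparisons (steady-state
#: residuals, requirement thresholds).
TOLERANCE = 1e-6


@dataclass
class FluxState:
    """An LP solution: flux vector, objective and solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ReferenceState:
    """Pre-deletion maximal growth rates on each substrate alone (1/h)."""

    v0bio_uc: float
    v0bio_cosub: float

    def __post_init__(self) -> None:
        # clamp tiny solver negatives
        self.v0bio_uc = max(0.0, self.v0bio_uc)
        self.v0bio_cosub = max(0.0, self.v0bio_cosub)


@dataclass
class _Arrays:
    """Matrix view of a model for the solver layer."""

    S: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    index: dict[str, int] = field(repr=False)
    reaction_ids: list[str] = field(repr=False)


def model_arrays(model: MetabolicModel) -> _Arrays:
    """Build the stoichiometric matrix S (metabolites × reactions) and bounds."""
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    n = len(model.reactions)
    lb = np.empty(n)
    ub = np.empty(n)
    index = {}
    for j, rxn in enumerate(model.reactions):
        index[rxn.id] = j
        lb[j], ub[j] = rxn.lb, rxn.ub
        for met, coef in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), n)
    )
    return _Arrays(S=S, lb=lb, ub=ub, index=index, reaction_ids=model.reaction_ids)


_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded"}


def _linprog(c, arrays, lb=None, ub=None, extra_ub=None):
    """Solve min c·v s.t. S v = 0, lb <= v <= ub (+ optional A_ub rows)."""
    lb = arrays.lb if lb is None else lb
    ub = arrays.ub if ub is None else ub
    kwargs = {}
    if extra_ub is not None:
        kwargs["A_ub"], kwargs["b_ub"] = extra_ub
    res = linprog(
        c,
        A_eq=arrays.S,
        b_eq=np.zeros(arrays.S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        **kwargs,
    )
    status = _STATUS.get(res.status)
    if status is None or status == "limit":
        raise SolverError(f"LP solver failure: {res.message}", status=res.status)
    return res, status


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
    parsimonious: bool = False,
) -> FluxState:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    With ``parsimonious=True`` a second LP minimises the total absolute
    flux at the fixed optimum, making reported distributions reproducible
    across solvers.
    """
    objective_id = objective_id or model.biomass_id
    arrays = model_arrays(model)
    if objective_id not in arrays.index:
        raise ConfigurationError(f"unknown objective reaction {objective_id!r}")
    if sense not in ("max", "min"):
        raise ConfigurationError(f"sense must be 'max' or 'min', got {sense!r}")
    j = arrays.index[objective_id]
    n = len(arrays.lb)
    c = np.zeros(n)
    c[j] = -1.0 if sense == "max" else 1.0
    res, status = _linprog(c, arrays)
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=float("nan"), status=status)
    objective = res.x[j]
    x = res.x
    if parsimonious:
        x = _pfba_vector(arrays, j, objective, sense)
    fluxes = dict(zip(arrays.reaction_ids, map(float, x)))
    return FluxState(
        fluxes=fluxes,
        objective_value=float(objective),
        status="optimal",
        parsimonious=parsimonious,
    )


def _pfba_vector(arrays, j, objective, sense):
    """Minimise sum |v| with the objective flux pinned at its optimum."""
    n = len(arrays.lb)
    lb = arrays.lb.copy()
    ub = arrays.ub.copy()
    eps = 1e-9
    lo = objective - eps if sense == "max" else lb[j]
    hi = ub[j] if sense == "max" else objective + eps
    lb[j], ub[j] = max(lb[j], lo), min(ub[j], hi)
    # variables [v, w]; w_i >= |v_i|
    S = sp.hstack([arrays.S, sp.csr_matrix((arrays.S.shape[0], n))]).tocsr()
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]).tocsr()
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    wmax = np.maximum(np.abs(lb), np.abs(ub))
    bounds = np.column_stack(
        [np.concatenate([lb, np.zeros(n)]), np.concatenate([ub, wmax])]
    )
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError("parsimonious refinement failed", status=res.status)
    return res.x[:n]


def apply_knockouts(model: MetabolicModel, knockouts: set[str]) -> MetabolicModel:
    """Copy of ``model`` with each listed reaction's bounds forced to zero."""
    out = model.copy()
    index = out._index()
    for rid in knockouts:
        if rid not in index:
            raise ConfigurationError(f"unknown knockout target {rid!r}")
        index[rid].lb = 0.0
        index[rid].ub = 0.0
    return out


def reference_growth(
    model: MetabolicModel, substrate_exchange: str, uptake: float
) -> float:
    """Maximal growth with only the given carbon exchange open at ``uptake``."""
    if substrate_exchange not in model.exchange_ids:
        raise ConfigurationError(f"{substrate_exchange!r} is not an exchange reaction")
    medium = set_medium(model, {substrate_exchange: uptake})
    state = solve_fba(medium, sense="max")
    if not state.optimal:
        raise SolverError(f"reference FBA not optimal ({state.status})")
    return max(0.0, state.objective_value)


def flux_variability(
    model: MetabolicModel, reaction_ids: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Tight per-reaction flux ranges under the model's current bounds.

    No growth requirement is imposed; a (0, 0) range therefore means the
    reaction is structurally blocked in the current medium.
    """
    arrays = model_arrays(model)
    targets = reaction_ids if reaction_ids is not None else list(arrays.reaction_ids)
    n = len(arrays.lb)
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        if rid not in arrays.index:
            raise ConfigurationError(f"unknown reaction id {rid!r}")
        j = arrays.index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_res, lo_status = _linprog(c, arrays)
        c[j] = -1.0
        hi_res, hi_status = _linprog(c, arrays)
        if lo_status != "optimal" or hi_status != "optimal":
            raise SolverError(f"FVA failed for {rid!r} ({lo_status}/{hi_status})")
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        if abs(lo) < TOLERANCE:
            lo = 0.0
        if abs(hi) < TOLERANCE:
            hi = 0.0
        out[rid] = (lo, hi)
    return out


def flux_state_tsv(state: FluxState, model: MetabolicModel) -> str:
    """Serialise a flux state as TSV (reaction id, flux, lb, ub)."""
    lines = ["reaction\tflux\tlb\tub"]
    for rxn in model.reactions:
        flux = state.fluxes.get(rxn.id, float("nan"))
        lines.append(f"{rxn.id}\t{flux:.10g}\t{rxn.lb:.10g}\t{rxn.ub:.10g}")
    return "\n".join(lines) + "\n"
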