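"""Single-level MILP reformulation of the bilevel strain-design problem.

The bilevel program — an outer search over reaction knockouts ``y``
maximising the substrate assimilation driving force, with four inner
FBA problems describing the knockout strain — is collapsed into one
mixed-integer linear program:

* inner problem 1 (growth on the UC alone) is certified by *weak
  duality* for variant A (a dual-feasible point whose objective is
  already below the allowed ceiling bounds the inner maximum) and by a
  *primal witness* for variant B (any feasible flux vector reaching the
  required growth floor proves the maximum does too);
* inner problem 2 (growth on the cosubstrate alone) carries a *strong
  duality* certificate — primal witness + dual-feasible point + primal
  objective ≥ dual objective — because its *value* ``v2bio`` enters both
  the requirement-2 ceiling and the design objective and must therefore
  be the true optimum, not just a feasible guess;
* inner problem 3 (growth on both substrates) needs only a primal
  witness reaching the reference growth;
* inner problem 4 (minimal UC uptake restoring reference growth) also
  carries a strong-duality certificate so ``vUC`` is the true minimum.

Knockout terms ``bound·(1−y)`` are linear in the binaries; the only
bilinear products are (a) duals × binaries in the certificate
objectives, linearised with big-M envelopes, and (b) the
Charnes–Cooper scalar ``t = 1/vUC`` × binaries, linearised exactly via
the bounds on ``t``.  The fractional objective
``(v0bio_cosub − v2bio)/vUC`` becomes the linear ``v0bio_cosub·t − c·w2``
after scaling blocks 2 and 4 by ``t`` (``w = t·v``), so the MILP
objective value *is* the SADF.

Alternative solutions are enumerated with integer cuts; every incumbent
is re-verified by direct FBA through :mod:`adaptuc.metrics` before
being reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from . import metrics
from .config import DesignConfig
from .errors import ConfigurationError, SolverError
from .lp_engine import ReferenceState, model_arrays, TOLERANCE
from .model_core import MetabolicModel, set_medium

logger = logging.getLogger(__name__)

_INF = np.inf


@dataclass
class MilpOptions:
    """Numerical knobs of the reformulation.

    ``bigm_dual`` bounds every dual multiplier; ``eps_uc`` is the
    smallest representable minimal UC uptake (it caps the
    Charnes–Cooper scalar at ``1/eps_uc``).  ``strict_cut`` switches the
    integer cut from the standard no-good form (excludes a found set and
    its supersets) to a stricter variant that also excludes sets sharing
    all but one member with it.
    """

    bigm_dual: float = 1000.0
    eps_uc: float = 1e-4
    mip_gap: float = 1e-4
    strict_cut: bool = False
    bigm_slack: float = 1e-3  # proximity that triggers big-M escalation
    max_bigm_escalations: int = 2


class _Builder:
    """Incremental variable/constraint store finalised into scipy arrays."""

    def __init__(self) -> None:
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.names: list[str] = []
        self.rows: list[tuple[dict[int, float], float, float]] = []

    def var(self, name: str, lo: float, hi: float, integer: bool = False) -> int:
        self.names.append(name)
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        return len(self.names) - 1

    def con(self, coeffs: dict[int, float], lo: float, hi: float) -> None:
        self.rows.append((coeffs, lo, hi))

    @property
    def n(self) -> int:
        return len(self.names)

    def finalize(self):
        n = self.n
        rows_i, cols, vals = [], [], []
        cl, cu = [], []
        for i, (coeffs, lo, hi) in enumerate(self.rows):
            cl.append(lo)
            cu.append(hi)
            for j, v in coeffs.items():
                rows_i.append(i)
                cols.append(j)
                vals.append(v)
        A = sp.csr_matrix((vals, (rows_i, cols)), shape=(len(self.rows), n))
        return A, np.array(cl), np.array(cu), np.array(self.lb), np.array(self.ub), np.array(self.integrality)


@dataclass
class MilpFormulation:
    """A built single-level design MILP plus its bookkeeping."""

    model: MetabolicModel
    config: DesignConfig
    candidates: list[str]
    options: MilpOptions
    reference: ReferenceState
    builder: _Builder
    y_index: dict[str, int]
    t_index: int | None
    objective: np.ndarray  # minimisation vector
    flux_blocks: dict[str, np.ndarray] = field(default_factory=dict)
    bigm_watch: list[tuple[int, float]] = field(default_factory=list)
    cuts: list[set[str]] = field(default_factory=list)
    ratio_objective: bool = True

    @property
    def num_binaries(self) -> int:
        return len(self.y_index)

    def add_integer_cut(self, knockouts: set[str], strict: bool | None = None) -> None:
        """Exclude a found knockout set from subsequent solves.

        The default no-good cut ``sum_{j in S} y_j <= |S| - 1`` removes
        the set and all of its supersets; ``strict=True`` uses
        ``<= |S| - 2``, additionally removing every set that keeps all
        but one member of S.
        """
        strict = self.options.strict_cut if strict is None else strict
        coeffs = {self.y_index[r]: 1.0 for r in knockouts}
        if not coeffs:
            raise ConfigurationError("cannot cut the empty knockout set")
        limit = len(knockouts) - (2 if strict else 1)
        self.builder.con(coeffs, -_INF, float(limit))
        self.cuts.append(set(knockouts))

    def to_lp(self) -> str:
        """Export the formulation in CPLEX-LP text format."""
        b = self.builder
        names = [f"x{i}_{n}".replace(" ", "_") for i, n in enumerate(b.names)]

        def expr(coeffs):
            parts = []
            for j, v in sorted(coeffs.items()):
                parts.append(f"{'+' if v >= 0 else '-'} {abs(v):.12g} {names[j]}")
            return " ".join(parts) or "0 " + names[0]

        lines = ["Minimize", " obj: " + expr({j: c for j, c in enumerate(self.objective) if c})]
        lines.append("Subject To")
        for i, (coeffs, lo, hi) in enumerate(b.rows):
            if lo == hi:
                lines.append(f" c{i}: {expr(coeffs)} = {lo:.12g}")
            else:
                if hi < _INF:
                    lines.append(f" c{i}u: {expr(coeffs)} <= {hi:.12g}")
                if lo > -_INF:
                    lines.append(f" c{i}l: {expr(coeffs)} >= {lo:.12g}")
        lines.append("Bounds")
        for j, (lo, hi) in enumerate(zip(b.lb, b.ub)):
            lines.append(f" {lo:.12g} <= {names[j]} <= {hi:.12g}")
        binaries = [names[j] for j, f in enumerate(b.integrality) if f]
        if binaries:
            lines.append("Binary")
            lines.extend(" " + n for n in binaries)
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class DesignSolution:
    """A solved design: knockout set, objective, status, verification."""

    knockouts: set[str]
    objective_sadf: float | None
    milp_status: str  # optimal | feasible | infeasible | limit
    verified: bool = False
    sadf: float | None = None            # re-scored by direct LP
    ucco: float | None = None
    requirements: metrics.RequirementReport | None = None
    bigm_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "knockouts": sorted(self.knockouts),
            "objective_sadf": self.objective_sadf,
            "milp_status": self.milp_status,
            "verified": self.verified,
            "sadf": self.sadf,
            "ucco": self.ucco,
            "requirements": self.requirements.to_dict() if self.requirements else None,
        }


# ---------------------------------------------------------------------------
# formulation construction


def _medium_bounds(model, arrays, uptakes, config):
    """Per-reaction bounds of a medium variant, as arrays aligned to ``arrays``."""
    medium = set_medium(model, uptakes)
    lb = arrays.lb.copy()
    ub = arrays.ub.copy()
    index = arrays.index
    for rxn in medium.reactions:
        j = index[rxn.id]
        lb[j], ub[j] = rxn.lb, rxn.ub
    return lb, ub


def _add_primal_block(b, fm, name, lb, ub, cand_idx, t=None, z=None):
    """Flux block with knockout-switchable bounds; scaled by ``t`` if given.

    Unscaled candidate j:      l(1−y) ≤ v ≤ u(1−y)  (linear in y).
    Scaled (w = t·v, z = t·y): l(t−z) ≤ w ≤ u(t−z).
    """
    arrays = fm["arrays"]
    n = len(lb)
    t_max = fm["t_max"]
    cand = set(cand_idx)
    v = np.empty(n, dtype=int)
    for j in range(n):
        lo, hi = lb[j], ub[j]
        if t is None:
            if j in cand:
                box = (min(lo, 0.0), max(hi, 0.0))
            else:
                box = (lo, hi)
            v[j] = b.var(f"{name}_{j}", *box)
            if j in cand:
                yj = fm["y_vars"][j]
                if hi != 0:
                    b.con({v[j]: 1.0, yj: hi}, -_INF, hi)     # v ≤ u(1−y)
                else:
                    b.con({v[j]: 1.0}, -_INF, 0.0)
                if lo != 0:
                    b.con({v[j]: 1.0, yj: lo}, lo, _INF)      # v ≥ l(1−y)
                else:
                    b.con({v[j]: 1.0}, 0.0, _INF)
        else:
            box_lo = min(lo * t_max, lo * fm["t_min"], 0.0)
            box_hi = max(hi * t_max, hi * fm["t_min"], 0.0)
            v[j] = b.var(f"{name}_{j}", box_lo, box_hi)
            if j in cand:
                zj = z[j]
                b.con({v[j]: 1.0, t: -hi, zj: hi}, -_INF, 0.0)  # w ≤ u(t−z)
                b.con({v[j]: 1.0, t: -lo, zj: lo}, 0.0, _INF)   # w ≥ l(t−z)
            else:
                if hi < _INF:
                    b.con({v[j]: 1.0, t: -hi}, -_INF, 0.0)      # w ≤ u·t
                if lo > -_INF:
                    b.con({v[j]: 1.0, t: -lo}, 0.0, _INF)       # w ≥ l·t
    # steady state S v = 0
    S = arrays.S.tocoo()
    rows: dict[int, dict[int, float]] = {}
    for i, j, val in zip(S.row, S.col, S.data):
        rows.setdefault(i, {})[int(v[j])] = float(val)
    for coeffs in rows.values():
        b.con(coeffs, 0.0, 0.0)
    return v


def _add_dual_block(b, fm, name, lb, ub, cost, sense, cand_idx, t=None):
    """Dual-feasibility block for one inner LP; returns the dual-objective expr.

    For an inner maximisation (``sense='max'``) of ``cost·v`` over
    ``S v = 0, l ≤ v ≤ u`` the dual is ``min u·α − l·β`` subject to
    ``Sᵀλ + α − β = cost``; any feasible point bounds the inner max from
    above.  For an inner minimisation the dual is ``max l·β − u·α``
    subject to ``Sᵀλ + β − α = cost`` and bounds the inner min from
    below.  Candidate bounds carry the (1−y) factor, so their objective
    terms use big-M-linearised products ``(1−y)·α``.
    """
    arrays = fm["arrays"]
    m, n = arrays.S.shape
    Mdual = fm["options"].bigm_dual
    Mcap = Mdual * (fm["t_max"] if t is not None else 1.0)
    cand = set(cand_idx)
    lam = [b.var(f"{name}_lam_{i}", -_INF, _INF) for i in range(m)]
    alpha = [b.var(f"{name}_al_{j}", 0.0, Mcap) for j in range(n)]
    beta = [b.var(f"{name}_be_{j}", 0.0, Mcap) for j in range(n)]
    # Sᵀλ ± (α − β) = cost (·t when scaled)
    ST = arrays.S.tocoo()
    cols: dict[int, dict[int, float]] = {j: {} for j in range(n)}
    for i, j, val in zip(ST.row, ST.col, ST.data):
        cols[int(j)][lam[i]] = float(val)
    sign = 1.0 if sense == "max" else -1.0
    for j in range(n):
        coeffs = dict(cols[j])
        coeffs[alpha[j]] = sign
        coeffs[beta[j]] = -sign
        rhs = cost.get(j, 0.0)
        if t is not None and rhs:
            coeffs[t] = coeffs.get(t, 0.0) - rhs
            rhs = 0.0
        b.con(coeffs, rhs, rhs)
    # products (1−y)·α, (1−y)·β for candidate bounds
    pa, pb = {}, {}
    for j in cand:
        yj = fm["y_vars"][j]
        pa[j] = b.var(f"{name}_pal_{j}", 0.0, Mcap)
        pb[j] = b.var(f"{name}_pbe_{j}", 0.0, Mcap)
        for p, d in ((pa[j], alpha[j]), (pb[j], beta[j])):
            b.con({p: 1.0, d: -1.0}, -_INF, 0.0)        # p ≤ α
            b.con({p: 1.0, yj: Mcap}, -_INF, Mcap)      # p ≤ M(1−y)
            b.con({p: 1.0, d: -1.0, yj: Mcap}, 0.0, _INF)  # p ≥ α − M·y
    # dual objective expression
    obj: dict[int, float] = {}

    def _acc(idx, coef):
        if coef:
            obj[idx] = obj.get(idx, 0.0) + coef

    for j in range(n):
        a_var = pa[j] if j in cand else alpha[j]
        b_var = pb[j] if j in cand else beta[j]
        if sense == "max":
            _acc(a_var, ub[j])
            _acc(b_var, -lb[j])
        else:
            _acc(b_var, lb[j])
            _acc(a_var, -ub[j])
    # only duals that actually enter a certificate objective can be
    # distorted by their big-M cap; watch those for escalation
    for idx in obj:
        fm["watch"].append((idx, Mcap))
    return obj


def build_milp(
    model: MetabolicModel,
    config: DesignConfig,
    candidates: list[str],
    options: MilpOptions | None = None,
    ratio_objective: bool = True,
) -> MilpFormulation:
    """Assemble the single-level design MILP.

    With ``ratio_objective=True`` the objective is the SADF itself
    (Charnes–Cooper scaled); with ``False`` a feasibility formulation is
    built (requirements + budget only, minimising the number of
    knockouts) for the enumerate-then-score workflow.
    """
    options = options or MilpOptions()
    arrays = model_arrays(model)
    cand_set = set(candidates)
    if len(cand_set) != len(candidates):
        raise ConfigurationError("duplicate candidate ids")
    unknown = cand_set - set(arrays.index)
    if unknown:
        raise ConfigurationError(f"unknown candidate reactions: {sorted(unknown)}")
    forbidden = {model.biomass_id, config.uc_exchange, config.cosub_exchange}
    bad = cand_set & forbidden
    if bad:
        raise ConfigurationError(
            f"candidates must exclude biomass and substrate exchanges: {sorted(bad)}"
        )
    if not candidates and config.max_knockouts > 0:
        raise ConfigurationError("empty candidate list with a positive knockout budget")

    ref = metrics.reference_state(model, config)
    if ref.v0bio_cosub <= TOLERANCE:
        raise ConfigurationError("reference strain does not grow on the cosubstrate")

    ub_rate = config.uptake_bound
    lb1, ub1 = _medium_bounds(model, arrays, {config.uc_exchange: ub_rate}, config)
    lb2, ub2 = _medium_bounds(model, arrays, {config.cosub_exchange: ub_rate}, config)
    lb3, ub3 = _medium_bounds(
        model, arrays, {config.uc_exchange: ub_rate, config.cosub_exchange: ub_rate}, config
    )
    lb4, ub4 = _medium_bounds(
        model, arrays,
        {config.uc_exchange: config.uc_recovery_bound, config.cosub_exchange: ub_rate},
        config,
    )
    bio = arrays.index[model.biomass_id]
    lb4[bio] = ref.v0bio_cosub  # growth-recovery floor of inner problem 4
    uc_j = arrays.index[config.uc_exchange]

    b = _Builder()
    cand_idx = sorted(arrays.index[r] for r in candidates)
    y_vars = {j: b.var(f"y_{j}", 0.0, 1.0, integer=True) for j in cand_idx}
    y_index = {model.reactions[j].id: y_vars[j] for j in cand_idx}

    t_min = 1.0 / config.uc_recovery_bound
    t_max = 1.0 / options.eps_uc
    fm = {
        "arrays": arrays, "y_vars": y_vars, "options": options,
        "t_min": t_min, "t_max": t_max, "watch": [],
    }
    c_bio = {bio: 1.0}
    f_uc = {uc_j: -1.0}  # uptake magnitude of the UC exchange
    blocks: dict[str, np.ndarray] = {}

    t = z = None
    if ratio_objective:
        t = b.var("t", t_min, t_max)
        fm["watch"].append((t, t_max))
        z = {}
        for j in cand_idx:
            zj = b.var(f"z_{j}", 0.0, t_max)
            z[j] = zj
            yj = y_vars[j]
            b.con({zj: 1.0, yj: -t_max}, -_INF, 0.0)            # z ≤ t_max·y
            b.con({zj: 1.0, yj: -t_min}, 0.0, _INF)             # z ≥ t_min·y
            b.con({zj: 1.0, t: -1.0, yj: -t_min}, -_INF, -t_min)  # z ≤ t − t_min(1−y)
            b.con({zj: 1.0, t: -1.0, yj: -t_max}, -t_max, _INF)   # z ≥ t − t_max(1−y)

    # -- requirement 1: growth on the UC alone
    f1 = config.effective_req1_fraction
    if config.variant == "A":
        dual1 = _add_dual_block(b, fm, "d1", lb1, ub1, c_bio, "max", cand_idx)
        b.con(dual1, -_INF, f1 * ref.v0bio_uc)  # inner max ≤ ceiling (weak duality)
    else:
        v1 = _add_primal_block(b, fm, "v1", lb1, ub1, cand_idx)
        blocks["v1"] = v1
        b.con({int(v1[bio]): 1.0}, f1 * ref.v0bio_uc, _INF)  # primal witness

    # -- requirement 2: collapse on the cosubstrate alone (strong duality)
    v2 = _add_primal_block(b, fm, "v2", lb2, ub2, cand_idx, t=t, z=z)
    blocks["v2"] = v2
    dual2 = _add_dual_block(b, fm, "d2", lb2, ub2, c_bio, "max", cand_idx, t=t)
    sd2 = {int(v2[bio]): 1.0}
    for idx, coef in dual2.items():
        sd2[idx] = sd2.get(idx, 0.0) - coef
    b.con(sd2, 0.0, _INF)  # primal ≥ dual ⇒ v2bio is the true maximum
    ceiling = config.req2_fraction * ref.v0bio_cosub
    if t is not None:
        b.con({int(v2[bio]): 1.0, t: -ceiling}, -_INF, 0.0)
    else:
        b.con({int(v2[bio]): 1.0}, -_INF, ceiling)

    # -- requirement 3: recovery with both substrates (primal witness)
    v3 = _add_primal_block(b, fm, "v3", lb3, ub3, cand_idx)
    blocks["v3"] = v3
    b.con({int(v3[bio]): 1.0}, ref.v0bio_cosub, _INF)

    if ratio_objective:
        # -- inner problem 4: minimal UC uptake at reference growth
        v4 = _add_primal_block(b, fm, "v4", lb4, ub4, cand_idx, t=t, z=z)
        blocks["v4"] = v4
        b.con({int(v4[uc_j]): -1.0}, 1.0, 1.0)  # vUC·t = 1 (Charnes–Cooper)
        dual4 = _add_dual_block(b, fm, "d4", lb4, ub4, f_uc, "min", cand_idx, t=t)
        b.con(dual4, 1.0, _INF)  # dual ≥ primal min (=1 scaled) ⇒ vUC is the true min
        objective = np.zeros(b.n)
        objective[v2[bio]] = 1.0          # minimise  c·w2 − v0·t  = −SADF
        objective[t] = -ref.v0bio_cosub
    else:
        objective = np.zeros(b.n)
        for yj in y_vars.values():
            objective[yj] = 1.0           # parsimony among feasible designs

    # -- knockout budget
    b.con({yj: 1.0 for yj in y_vars.values()}, -_INF, float(config.max_knockouts))

    return MilpFormulation(
        model=model,
        config=config,
        candidates=list(candidates),
        options=options,
        reference=ref,
        builder=b,
        y_index=y_index,
        t_index=t,
        objective=objective,
        flux_blocks=blocks,
        bigm_watch=fm["watch"],
        ratio_objective=ratio_objective,
    )


# ---------------------------------------------------------------------------
# solving


_MILP_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "limit"}


def _solve_raw(formulation: MilpFormulation, time_limit: float | None):
    b = formulation.builder
    A, cl, cu, lb, ub, integrality = b.finalize()
    n = len(lb)
    obj = np.zeros(n)
    obj[: len(formulation.objective)] = formulation.objective
    options = {"mip_rel_gap": formulation.options.mip_gap, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=obj,
        constraints=[LinearConstraint(A, cl, cu)],
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options=options,
    )
    status = _MILP_STATUS.get(res.status, "limit")
    if status == "optimal" and res.x is None:
        status = "limit"
    return res, status


def _extract_knockouts(formulation: MilpFormulation, x: np.ndarray) -> set[str]:
    return {rid for rid, j in formulation.y_index.items() if x[j] > 0.5}


def _bigm_flagged(formulation: MilpFormulation, x: np.ndarray) -> bool:
    slack = formulation.options.bigm_slack
    for idx, cap in formulation.bigm_watch:
        if idx < len(x) and x[idx] >= cap * (1.0 - slack):
            return True
    return False


def _minimal_support(formulation: MilpFormulation, knockouts: set[str]) -> set[str]:
    """Greedily drop knockouts that change neither feasibility nor SADF."""
    model, config = formulation.model, formulation.config
    base_sadf = metrics.sadf(model, knockouts, config)
    if base_sadf is None:
        return knockouts
    current = set(knockouts)
    for rid in sorted(knockouts):
        if len(current) == 1:
            break
        trial = current - {rid}
        report = metrics.check_requirements(model, trial, config)
        if not report.passed:
            continue
        trial_sadf = metrics.sadf(model, trial, config)
        if trial_sadf is not None and abs(trial_sadf - base_sadf) <= 1e-6 * max(1.0, abs(base_sadf)):
            current = trial
    return current


def solve_design(
    formulation: MilpFormulation,
    time_limit: float | None = None,
    minimal_support: bool = True,
) -> DesignSolution:
    """Solve the design MILP and post-verify the incumbent by direct FBA.

    When any big-M-bounded variable lands within the escalation slack of
    its bound, the formulation is rebuilt with a tenfold larger constant
    (existing integer cuts preserved) and re-solved, up to
    ``max_bigm_escalations`` times.
    """
    fm = formulation
    for attempt in range(fm.options.max_bigm_escalations + 1):
        res, status = _solve_raw(fm, time_limit)
        if status in ("infeasible", "unbounded"):
            return DesignSolution(set(), None, "infeasible")
        if res.x is None:
            return DesignSolution(set(), None, "limit")
        if not _bigm_flagged(fm, res.x):
            break
        logger.warning("big-M proximity detected; escalating constants (x10)")
        opts = replace(fm.options, bigm_dual=fm.options.bigm_dual * 10.0)
        rebuilt = build_milp(fm.model, fm.config, fm.candidates, opts, fm.ratio_objective)
        for cut in fm.cuts:
            rebuilt.add_integer_cut(cut)
        fm = rebuilt
    formulation.options = fm.options  # keep escalated constants for later cuts
    formulation.builder = fm.builder
    formulation.y_index = fm.y_index
    formulation.bigm_watch = fm.bigm_watch
    formulation.objective = fm.objective
    formulation.t_index = fm.t_index
    formulation.flux_blocks = fm.flux_blocks

    knockouts = _extract_knockouts(fm, res.x)
    objective_sadf = -float(res.fun) if fm.ratio_objective else None
    if minimal_support and knockouts:
        knockouts = _minimal_support(fm, knockouts)
    model, config = fm.model, fm.config
    report = metrics.check_requirements(model, knockouts, config)
    scored_sadf = metrics.sadf(model, knockouts, config)
    scored_ucco = metrics.ucco_ratio(model, knockouts, config)
    verified = report.passed and scored_sadf is not None
    if verified and fm.ratio_objective and objective_sadf is not None:
        rel = abs(objective_sadf - scored_sadf) / max(1.0, abs(scored_sadf))
        verified = rel <= 1e-3
    return DesignSolution(
        knockouts=knockouts,
        objective_sadf=objective_sadf,
        milp_status=status if status == "optimal" else "feasible",
        verified=verified,
        sadf=scored_sadf,
        ucco=scored_ucco,
        requirements=report,
        bigm_flagged=_bigm_flagged(fm, res.x),
    )


def enumerate_designs(
    formulation: MilpFormulation,
    max_solutions: int,
    time_limit: float | None = None,
) -> list[DesignSolution]:
    """Iteratively solve, cutting each found knockout set, until exhaustion.

    Returned sets are pairwise distinct; objectives are *not* guaranteed
    non-increasing, since near-optimal alternatives are admitted.
    """
    solutions: list[DesignSolution] = []
    for _ in range(max_solutions):
        sol = solve_design(formulation, time_limit=time_limit)
        if sol.milp_status in ("infeasible", "limit") or not sol.knockouts:
            break
        solutions.append(sol)
        formulation.add_integer_cut(sol.knockouts)
    return solutions


def enumerate_then_score(
    model: MetabolicModel,
    config: DesignConfig,
    candidates: list[str],
    max_solutions: int,
    options: MilpOptions | None = None,
    time_limit: float | None = None,
) -> list[DesignSolution]:
    """Fallback workflow: enumerate feasible designs, score each by direct LP.

    Robust against fractional-objective numerics: the MILP only encodes
    the three requirements and the budget, and every enumerated set is
    scored exactly by :func:`adaptuc.metrics.sadf` / ``ucco_ratio``.
    Results are sorted by SADF descending.
    """
    formulation = build_milp(model, config, candidates, options, ratio_objective=False)
    solutions = enumerate_designs(formulation, max_solutions, time_limit)
    solutions.sort(
        key=lambda s: (-(s.sadf if s.sadf is not None else -np.inf), len(s.knockouts))
    )
    return solutions
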