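"""Evaluation layer: starting-strain requirements, SADF, UC/Co, curves,
and biomass-precursor producibility.

Scores are always recomputed by direct LP on the knockout strain —
never read off a MILP certificate — so they are independent of how the
design problem was reformulated.

Definitions
-----------
SADF (substrate assimilation driving force, gDW/mmol)
    ``(v0bio_cosub − v2bio) / vUC`` — the growth regained per unit
    uptake of the unadapted carbon source (UC), where ``v2bio`` is the
    knockout strain's maximal growth on the cosubstrate alone and
    ``vUC`` the minimal UC uptake that restores the reference growth.

UC/Co (dimensionless)
    Parsimonious uptake ratio at a fixed growth floor: first minimise
    the UC uptake subject to growth ≥ 0.1 1/h, then fix that uptake and
    minimise the cosubstrate uptake; report their ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .config import DesignConfig
from .errors import ConfigurationError
from .lp_engine import (
    TOLERANCE,
    ReferenceState,
    apply_knockouts,
    reference_growth,
    solve_fba,
)
from .model_core import DEFAULT_BOUND, MetabolicModel, Reaction, molar_mass, set_medium

logger = logging.getLogger(__name__)

#: Demand flux above which a biomass precursor counts as producible.
PRODUCIBILITY_THRESHOLD = 1e-4

#: Coupling fraction at or below which a strategy is classed "minimal".
MINIMAL_COUPLING_FRACTION = 0.10

#: Sentinel ratio when the cosubstrate is not needed at all (step-2
#: denominator of UC/Co is zero).
INFINITE_COUPLING = math.inf


@dataclass
class RequirementReport:
    """Growth rates and pass flags for the three starting-strain requirements."""

    v1bio: float
    v2bio: float
    v3bio: float
    req1_pass: bool
    req2_pass: bool
    req3_pass: bool
    reference: ReferenceState
    variant: str

    @property
    def passed(self) -> bool:
        return self.req1_pass and self.req2_pass and self.req3_pass

    def to_dict(self) -> dict:
        return {
            "v1bio": self.v1bio,
            "v2bio": self.v2bio,
            "v3bio": self.v3bio,
            "req1_pass": self.req1_pass,
            "req2_pass": self.req2_pass,
            "req3_pass": self.req3_pass,
            "v0bio_uc": self.reference.v0bio_uc,
            "v0bio_cosub": self.reference.v0bio_cosub,
            "variant": self.variant,
        }


@dataclass
class ProducibilityReport:
    """Per-precursor producibility from the cosubstrate alone."""

    producible: dict[str, bool]
    mass_fractions: dict[str, float]
    coupling_fraction: float
    coupling_class: str  # minimal | intermediate | full
    mass_basis: str      # molar_mass | coefficient

    def to_dict(self) -> dict:
        return {
            "producible": self.producible,
            "mass_fractions": self.mass_fractions,
            "coupling_fraction": self.coupling_fraction,
            "coupling_class": self.coupling_class,
            "mass_basis": self.mass_basis,
        }


@dataclass
class StrategyScore:
    """A knockout set with its evaluation metrics."""

    knockouts: set[str]
    sadf: float | None
    ucco: float | None
    v_uc_min: float
    coupling_fraction: float = float("nan")
    coupling_class: str = ""
    requirements: RequirementReport | None = None

    def to_dict(self) -> dict:
        return {
            "knockouts": sorted(self.knockouts),
            "sadf": self.sadf,
            "ucco": self.ucco,
            "v_uc_min": self.v_uc_min,
            "coupling_fraction": self.coupling_fraction,
            "coupling_class": self.coupling_class,
            "requirements": self.requirements.to_dict() if self.requirements else None,
        }


def reference_state(model: MetabolicModel, config: DesignConfig) -> ReferenceState:
    """Pre-deletion growth on each substrate alone at the uptake bound."""
    return ReferenceState(
        v0bio_uc=reference_growth(model, config.uc_exchange, config.uptake_bound),
        v0bio_cosub=reference_growth(model, config.cosub_exchange, config.uptake_bound),
    )


def check_requirements(
    model: MetabolicModel,
    knockouts: set[str],
    config: DesignConfig,
    reference: ReferenceState | None = None,
) -> RequirementReport:
    """Evaluate the three requirements of an ALE starting strain by direct FBA.

    v1bio: UC-only medium; v2bio: cosubstrate-only; v3bio: both substrates
    open at the uptake bound — all on the knockout strain.  Variant A
    requires v1bio ≤ f1·v0bio_uc, variant B requires v1bio ≥ f1·v0bio_uc.
    """
    ref = reference or reference_state(model, config)
    if ref.v0bio_cosub <= TOLERANCE:
        raise ConfigurationError(
            "reference strain does not grow on the cosubstrate; "
            "check the exchange id and medium"
        )
    ko = apply_knockouts(model, knockouts)
    ub = config.uptake_bound

    def growth(uptakes: dict[str, float]) -> float:
        state = solve_fba(set_medium(ko, uptakes), sense="max")
        return max(0.0, state.objective_value) if state.optimal else 0.0

    v1 = growth({config.uc_exchange: ub})
    v2 = growth({config.cosub_exchange: ub})
    v3 = growth({config.uc_exchange: ub, config.cosub_exchange: ub})
    f1 = config.effective_req1_fraction
    if config.variant == "A":
        req1 = v1 <= f1 * ref.v0bio_uc + TOLERANCE
    else:
        req1 = v1 >= f1 * ref.v0bio_uc - TOLERANCE
    req2 = v2 <= config.req2_fraction * ref.v0bio_cosub + TOLERANCE
    req3 = v3 >= ref.v0bio_cosub - TOLERANCE
    return RequirementReport(
        v1bio=v1, v2bio=v2, v3bio=v3,
        req1_pass=req1, req2_pass=req2, req3_pass=req3,
        reference=ref, variant=config.variant,
    )


def _min_uc_uptake(
    ko: MetabolicModel,
    config: DesignConfig,
    growth_target: float,
    cosub_uptake: float | None = None,
) -> float:
    """Minimal UC uptake magnitude achieving ``growth_target``; inf if unreachable."""
    cosub = config.uptake_bound if cosub_uptake is None else cosub_uptake
    medium = set_medium(
        ko, {config.cosub_exchange: cosub, config.uc_exchange: config.uc_recovery_bound}
    )
    medium.reaction(medium.biomass_id).lb = growth_target
    # minimising uptake magnitude = maximising the (negative) exchange flux
    state = solve_fba(medium, objective_id=config.uc_exchange, sense="max")
    if not state.optimal:
        return math.inf
    return max(0.0, -state.objective_value)


def minimal_uc_uptake(
    model: MetabolicModel,
    knockouts: set[str],
    growth_target: float,
    config: DesignConfig,
) -> float:
    """Minimal UC uptake so that growth ≥ ``growth_target`` with both
    substrates available (cosubstrate at the uptake bound, UC effectively
    unlimited).  Returns 0 when the target needs no UC and ``math.inf``
    when it is unreachable even with UC.
    """
    ko = apply_knockouts(model, knockouts)
    return _min_uc_uptake(ko, config, growth_target)


def sadf(
    model: MetabolicModel,
    knockouts: set[str],
    config: DesignConfig,
    reference: ReferenceState | None = None,
) -> float | None:
    """Average substrate assimilation driving force (gDW/mmol).

    ``(v0bio_cosub − v2bio) / vUC`` with ``v2bio`` recomputed by direct
    FBA on the cosubstrate-only medium and ``vUC`` the minimal UC uptake
    at the reference-growth target.  Returns ``None`` when undefined
    (no coupling, ``vUC = 0``) or when the reference growth cannot be
    restored at all.
    """
    ref = reference or reference_state(model, config)
    ko = apply_knockouts(model, knockouts)
    state = solve_fba(set_medium(ko, {config.cosub_exchange: config.uptake_bound}))
    v2 = max(0.0, state.objective_value) if state.optimal else 0.0
    v_uc = _min_uc_uptake(ko, config, ref.v0bio_cosub)
    if not math.isfinite(v_uc):
        logger.warning("SADF undefined: reference growth unreachable for %s", sorted(knockouts))
        return None
    if v_uc <= TOLERANCE:
        logger.warning("SADF undefined: no UC coupling for %s", sorted(knockouts))
        return None
    return (ref.v0bio_cosub - v2) / v_uc


def ucco_ratio(
    model: MetabolicModel,
    knockouts: set[str],
    config: DesignConfig,
) -> float | None:
    """Parsimonious UC-to-cosubstrate uptake ratio at the growth floor.

    Step 1 minimises the UC uptake subject to growth ≥ ``ucco_growth``;
    step 2 fixes that uptake and minimises the cosubstrate uptake.
    Returns ``math.inf`` (flagged in logs) when the cosubstrate is not
    needed at all, and ``None`` when the growth floor is unreachable.
    """
    ko = apply_knockouts(model, knockouts)
    uc_min = _min_uc_uptake(ko, config, config.ucco_growth)
    if not math.isfinite(uc_min):
        logger.warning("UC/Co undefined: growth floor unreachable for %s", sorted(knockouts))
        return None
    medium = set_medium(
        ko,
        {config.cosub_exchange: config.uptake_bound,
         config.uc_exchange: config.uc_recovery_bound},
    )
    medium.reaction(medium.biomass_id).lb = config.ucco_growth
    uc_rxn = medium.reaction(config.uc_exchange)
    uc_rxn.lb = -uc_min
    uc_rxn.ub = -uc_min
    state = solve_fba(medium, objective_id=config.cosub_exchange, sense="max")
    if not state.optimal:
        logger.warning("UC/Co step 2 infeasible for %s", sorted(knockouts))
        return None
    co_min = max(0.0, -state.objective_value)
    if co_min <= TOLERANCE:
        logger.warning("UC/Co: cosubstrate not needed (infinite coupling) for %s",
                       sorted(knockouts))
        return INFINITE_COUPLING
    return uc_min / co_min


def growth_uc_curve(
    model: MetabolicModel,
    knockouts: set[str],
    cosub_uptakes: list[float],
    growth_grid: list[float],
    config: DesignConfig,
) -> pd.DataFrame:
    """Minimal UC uptake over a (cosubstrate level × growth rate) grid.

    Each fixed-cosubstrate column of the returned table is a
    non-decreasing, piecewise-linear function of growth; unreachable
    growth rates carry ``inf``.
    """
    if any(u < 0 for u in cosub_uptakes) or any(g < 0 for g in growth_grid):
        raise ConfigurationError("grids must be non-negative")
    ko = apply_knockouts(model, knockouts)
    rows = []
    for cosub in cosub_uptakes:
        for g in growth_grid:
            if g == 0:
                uc = 0.0
            else:
                uc = _min_uc_uptake(ko, config, g, cosub_uptake=cosub)
            rows.append({"cosub_uptake": cosub, "growth": g, "min_uc_uptake": uc})
    return pd.DataFrame(rows)


def precursor_producibility(
    model: MetabolicModel,
    knockouts: set[str],
    config: DesignConfig,
) -> ProducibilityReport:
    """Which biomass precursors can be made from the cosubstrate alone.

    For every substrate-side metabolite of the biomass reaction, a unit
    demand sink is added on the cosubstrate-only medium and its maximal
    flux solved; the precursor is producible when that flux exceeds
    :data:`PRODUCIBILITY_THRESHOLD`.  Mass fractions use formula-derived
    molar masses when available, else fall back (with a warning) to a
    coefficient-weight basis.  The coupling fraction is the summed mass
    fraction of non-producible precursors; a strategy is classed
    ``full`` when nothing is producible, ``minimal`` at ≤ 10% coupling,
    else ``intermediate``.
    """
    biomass = model.reaction(model.biomass_id)
    precursors = sorted(m for m, c in biomass.stoichiometry.items() if c < 0)
    if not precursors:
        raise ConfigurationError("biomass reaction has no substrate-side precursors")
    ko = apply_knockouts(model, knockouts)
    medium = set_medium(ko, {config.cosub_exchange: config.uptake_bound})

    masses: dict[str, float] = {}
    basis = "molar_mass"
    for met in precursors:
        mass = molar_mass(model.metabolite_formula(met))
        if mass is None:
            basis = "coefficient"
            break
        masses[met] = mass
    if basis == "coefficient":
        logger.warning(
            "missing/unparseable formula among biomass precursors; "
            "mass fractions reported on a coefficient-weight basis"
        )
        masses = {met: 1.0 for met in precursors}

    weights = {m: -biomass.stoichiometry[m] * masses[m] for m in precursors}
    total = sum(weights.values())
    mass_fractions = {m: w / total for m, w in weights.items()}

    producible: dict[str, bool] = {}
    for met in precursors:
        probe = medium.copy()
        demand_id = f"DM__{met}"
        probe.reactions.append(
            Reaction(demand_id, {met: -1.0}, lb=0.0, ub=DEFAULT_BOUND, has_gene=False)
        )
        probe.validate()
        state = solve_fba(probe, objective_id=demand_id, sense="max")
        producible[met] = bool(
            state.optimal and state.objective_value >= PRODUCIBILITY_THRESHOLD
        )
    coupling_fraction = sum(mass_fractions[m] for m in precursors if not producible[m])
    if not any(producible.values()):
        coupling_class = "full"
    elif coupling_fraction <= MINIMAL_COUPLING_FRACTION:
        coupling_class = "minimal"
    else:
        coupling_class = "intermediate"
    return ProducibilityReport(
        producible=producible,
        mass_fractions=mass_fractions,
        coupling_fraction=coupling_fraction,
        coupling_class=coupling_class,
        mass_basis=basis,
    )


def score_strategy(
    model: MetabolicModel,
    knockouts: set[str],
    config: DesignConfig,
    with_producibility: bool = True,
) -> StrategyScore:
    """Assemble the full evaluation record for one knockout set."""
    ref = reference_state(model, config)
    report = check_requirements(model, knockouts, config, reference=ref)
    score = StrategyScore(
        knockouts=set(knockouts),
        sadf=sadf(model, knockouts, config, reference=ref),
        ucco=ucco_ratio(model, knockouts, config),
        v_uc_min=minimal_uc_uptake(model, knockouts, ref.v0bio_cosub, config),
        requirements=report,
    )
    if with_producibility:
        prod = precursor_producibility(model, knockouts, config)
        score.coupling_fraction = prod.coupling_fraction
        score.coupling_class = prod.coupling_class
    return score
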