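"""Candidate-knockout reduction applied before MILP construction.

Genome-scale models carry thousands of reactions; only a small fraction
are sensible deletion targets.  Filters are applied in a fixed order and
every removal is recorded, so the reduction is reproducible and
auditable:

1. ``category`` — exchanges and the biomass reaction;
2. ``substrate`` — the two substrates' exchange and transport steps
   (deleting the substrate's own entry route trivially decouples it);
3. ``gene`` — gene-unassociated reactions (not deletable in the lab);
4. ``blocked`` — reactions that can carry no flux with both substrates
   open (flux variability range (0, 0));
5. ``peripheral`` — a user-supplied subsystem/reaction exclusion list;
6. ``essential`` (optional) — reactions whose single deletion already
   makes growth recovery (requirement 3) impossible; since growth only
   decreases under further knockouts, no passing design can contain
   them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import DesignConfig
from .lp_engine import TOLERANCE, apply_knockouts, flux_variability, reference_growth, solve_fba
from .model_core import MetabolicModel, set_medium


@dataclass
class FilterTrace:
    """Reproducible record of a prefilter run."""

    initial_count: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    final_candidates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "initial_count": self.initial_count,
            "removed": self.removed,
            "removed_counts": {k: len(v) for k, v in self.removed.items()},
            "final_candidates": self.final_candidates,
        }


DEFAULT_FILTERS = ("category", "substrate", "gene", "blocked", "peripheral")


def _compartment_free(met: str) -> str:
    if "_" in met:
        base, comp = met.rsplit("_", 1)
        if len(comp) <= 2 and comp.isalpha():
            return base
    return met


def _substrate_reactions(model: MetabolicModel, exchange_id: str) -> set[str]:
    """The exchange plus transport steps moving its metabolite between compartments."""
    met = model.exchange_metabolite(exchange_id)
    base = _compartment_free(met)
    hits = {exchange_id}
    for rxn in model.reactions:
        if rxn.id in model.exchange_ids:
            continue
        involved = [m for m in rxn.stoichiometry if _compartment_free(m) == base]
        # a transporter touches the substrate species in >= 2 compartments
        if met in rxn.stoichiometry and len(involved) >= 2:
            hits.add(rxn.id)
    return hits


def candidate_knockouts(
    model: MetabolicModel,
    config: DesignConfig,
    filters: tuple[str, ...] = DEFAULT_FILTERS,
    peripheral: set[str] | None = None,
) -> FilterTrace:
    """Apply the declared filters in order and return the audit trace.

    ``peripheral`` may contain reaction ids or subsystem names (matched
    case-insensitively against each reaction's subsystem annotation).
    """
    peripheral = peripheral or set()
    peripheral_lower = {p.lower() for p in peripheral}
    remaining = list(model.reaction_ids)
    trace = FilterTrace(initial_count=len(remaining))

    def drop(name: str, hit: set[str]) -> None:
        nonlocal remaining
        removed = sorted(r for r in remaining if r in hit)
        trace.removed[name] = removed
        remaining = [r for r in remaining if r not in hit]

    for name in filters:
        if name == "category":
            drop(name, set(model.exchange_ids) | {model.biomass_id})
        elif name == "substrate":
            hit = _substrate_reactions(model, config.uc_exchange)
            hit |= _substrate_reactions(model, config.cosub_exchange)
            drop(name, hit)
        elif name == "gene":
            drop(name, {r.id for r in model.reactions if not r.has_gene})
        elif name == "blocked":
            open_both = set_medium(
                model,
                {config.uc_exchange: config.uptake_bound,
                 config.cosub_exchange: config.uptake_bound},
            )
            ranges = flux_variability(open_both, remaining)
            drop(name, {rid for rid, (lo, hi) in ranges.items() if lo == 0.0 and hi == 0.0})
        elif name == "peripheral":
            hit = set()
            for rid in remaining:
                rxn = model.reaction(rid)
                if rid.lower() in peripheral_lower or (
                    rxn.subsystem and rxn.subsystem.lower() in peripheral_lower
                ):
                    hit.add(rid)
            drop(name, hit)
        elif name == "essential":
            v0_cosub = reference_growth(model, config.cosub_exchange, config.uptake_bound)
            both = {config.uc_exchange: config.uptake_bound,
                    config.cosub_exchange: config.uptake_bound}
            hit = set()
            for rid in remaining:
                ko = set_medium(apply_knockouts(model, {rid}), both)
                state = solve_fba(ko, sense="max")
                growth = state.objective_value if state.optimal else 0.0
                if growth < v0_cosub - TOLERANCE:
                    hit.add(rid)
            drop(name, hit)
        else:
            raise ValueError(f"unknown filter {name!r}")
    trace.final_candidates = remaining
    return trace
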