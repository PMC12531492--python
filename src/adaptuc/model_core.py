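"""Metabolic-model data structures, pathway augmentation and media handling.

The in-memory representation is deliberately small: a stoichiometric
network is a list of metabolite ids, a list of :class:`Reaction` objects
(each carrying its own stoichiometry and flux bounds) and a designated
biomass reaction.  Exchange reactions — single-metabolite boundary
reactions — follow the standard sign convention: a *negative* flux is
uptake, so opening a substrate at 10 mmol/gDW/h means setting the
exchange lower bound to −10.

Standard-format I/O (SBML Level 3 + FBC, BiGG-style JSON) lives in
:mod:`adaptuc.io`; this module owns the structures and the in-place
model surgery (heterologous pathway insertion, organism preprocessing
profiles, medium composition).
"""

from __future__ import annotations

import copy
import logging
import math
import re
from dataclasses import dataclass, field

from .errors import AugmentationError, ConfigurationError, ModelError

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

#: Atomic weights for molar-mass computation from formula annotations.
_ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938, "Cl": 35.45,
    "Co": 58.933, "Mo": 95.95, "Ni": 58.693, "Se": 78.971, "W": 183.84,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def molar_mass(formula: str) -> float | None:
    """Molar mass (g/mmol·1000 = g/mol) of a chemical formula string.

    Returns ``None`` when the formula is empty, contains unknown element
    symbols (e.g. polymer placeholders ``R``/``X``) or does not parse.
    """
    if not formula:
        return None
    consumed = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        element, count = match.groups()
        if element not in _ATOMIC_WEIGHTS:
            return None
        total += _ATOMIC_WEIGHTS[element] * (float(count) if count else 1.0)
        consumed += len(match.group(0))
    if consumed != len(formula) or total <= 0:
        return None
    return total


@dataclass
class Reaction:
    """A single reaction: signed stoichiometry plus flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``has_gene`` records whether any gene
    association is present in the source model; gene-unassociated
    reactions are excluded from knockout candidacy by the prefilter.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    has_gene: bool = True
    name: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id!r} has lb > ub")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelError(
                    f"reaction {self.id!r}: coefficient of {met!r} must be "
                    f"finite and nonzero, got {coef}"
                )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lb=self.lb,
            ub=self.ub,
            has_gene=self.has_gene,
            name=self.name,
            subsystem=self.subsystem,
        )


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds and a biomass objective.

    ``annotations`` is free-form; recognised keys include
    ``"metabolite_formulas"`` (mapping metabolite id → formula string,
    used for biomass mass fractions) and ``"base_medium"`` (exchange ids
    held open regardless of medium changes, e.g. O2 and mineral ions).
    """

    metabolites: list[str]
    reactions: list[Reaction]
    biomass_id: str
    exchange_ids: set[str] = field(default_factory=set)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        if self.biomass_id not in set(ids):
            raise ModelError(f"biomass reaction {self.biomass_id!r} not in model")
        known = set(self.metabolites)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )
        for ex in self.exchange_ids:
            rxn = self.reaction(ex)
            if len(rxn.stoichiometry) != 1:
                raise ModelError(
                    f"exchange {ex!r} must touch exactly one metabolite"
                )

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._index()[rid]
        except KeyError:
            raise ConfigurationError(f"unknown reaction id {rid!r}") from None

    def _index(self) -> dict[str, Reaction]:
        # rebuilt on demand; the model is small relative to LP solve cost
        return {r.id: r for r in self.reactions}

    def has_reaction(self, rid: str) -> bool:
        return rid in self._index()

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            exchange_ids=set(self.exchange_ids),
            annotations=copy.deepcopy(self.annotations),
        )

    def exchange_metabolite(self, exchange_id: str) -> str:
        """The single metabolite touched by an exchange reaction."""
        rxn = self.reaction(exchange_id)
        if exchange_id not in self.exchange_ids or len(rxn.stoichiometry) != 1:
            raise ConfigurationError(f"{exchange_id!r} is not an exchange reaction")
        return next(iter(rxn.stoichiometry))

    def metabolite_formula(self, met: str) -> str:
        return self.annotations.get("metabolite_formulas", {}).get(met, "")

    def carbon_exchanges(self) -> list[str]:
        """Exchanges whose metabolite contains carbon.

        When no formula annotation is available for a metabolite the
        exchange is conservatively treated as a carbon source unless it
        appears in the model's ``base_medium`` annotation.
        """
        base = set(self.annotations.get("base_medium", ()))
        result = []
        for ex in sorted(self.exchange_ids):
            met = self.exchange_metabolite(ex)
            formula = self.metabolite_formula(met)
            if formula:
                if re.search(r"C[A-Z0-9]|C$|C\d", formula) or formula == "C":
                    result.append(ex)
            elif ex not in base:
                result.append(ex)
        return result


@dataclass
class PathwaySpec:
    """Reactions to graft onto a model, plus exchanges they require."""

    reactions: list[Reaction] = field(default_factory=list)
    required_exchanges: list[Reaction] = field(default_factory=list)
    new_metabolite_formulas: dict[str, str] = field(default_factory=dict)


def detect_exchanges(reactions: list[Reaction]) -> set[str]:
    """Exchange reactions by the single-metabolite boundary pattern."""
    return {r.id for r in reactions if len(r.stoichiometry) == 1}


# -- model surgery ---------------------------------------------------------


def add_pathway(model: MetabolicModel, spec: PathwaySpec) -> MetabolicModel:
    """Return a copy of ``model`` augmented with a heterologous pathway.

    ``spec.required_exchanges`` are only added when an exchange of the
    same id is not already present.  New metabolites referenced by the
    added reactions are appended to the metabolite list.
    """
    out = model.copy()
    existing = set(out.reaction_ids)
    collisions = {r.id for r in spec.reactions} & existing
    if collisions:
        raise AugmentationError(f"pathway reaction ids already present: {sorted(collisions)}")
    to_add = [r.copy() for r in spec.reactions]
    for ex in spec.required_exchanges:
        if ex.id not in existing:
            to_add.append(ex.copy())
            out.exchange_ids.add(ex.id)
    known = set(out.metabolites)
    for rxn in to_add:
        for met in rxn.stoichiometry:
            if met not in known:
                out.metabolites.append(met)
                known.add(met)
        out.reactions.append(rxn)
    if spec.new_metabolite_formulas:
        out.annotations.setdefault("metabolite_formulas", {}).update(
            spec.new_metabolite_formulas
        )
    out.validate()
    return out


def rump_pathway(
    cofactor: str = "nad",
    methanol_met: str = "meoh_c",
    exchange_met: str = "meoh_e",
) -> PathwaySpec:
    """The three-reaction ribulose-monophosphate methanol pathway.

    MEDH oxidises methanol to formaldehyde (NAD-dependent by default;
    ``cofactor="none"`` omits the redox pair for models lacking the NAD
    ids), HPS condenses formaldehyde with ribulose 5-phosphate into
    hexulose 6-phosphate and PHI isomerises it to fructose 6-phosphate.
    A methanol exchange and transport step are declared as required.
    """
    if cofactor == "nad":
        medh_stoich = {
            methanol_met: -1.0, "nad_c": -1.0,
            "fald_c": 1.0, "nadh_c": 1.0, "h_c": 1.0,
        }
    elif cofactor == "none":
        medh_stoich = {methanol_met: -1.0, "fald_c": 1.0}
    else:
        raise ConfigurationError(f"unknown MEDH cofactor {cofactor!r}")
    reactions = [
        Reaction("MEDH", medh_stoich, lb=0.0, ub=DEFAULT_BOUND,
                 name="methanol dehydrogenase"),
        Reaction("HPS", {"fald_c": -1.0, "ru5p__D_c": -1.0, "h6p__D_c": 1.0},
                 lb=0.0, ub=DEFAULT_BOUND, name="3-hexulose-6-phosphate synthase"),
        Reaction("PHI", {"h6p__D_c": -1.0, "f6p_c": 1.0},
                 lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND,
                 name="6-phospho-3-hexuloisomerase"),
        Reaction("MEOHt", {exchange_met: -1.0, methanol_met: 1.0},
                 lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND, name="methanol transport"),
    ]
    exchanges = [
        Reaction("EX_meoh_e", {exchange_met: -1.0}, lb=0.0, ub=DEFAULT_BOUND,
                 name="methanol exchange"),
    ]
    return PathwaySpec(
        reactions=reactions,
        required_exchanges=exchanges,
        new_metabolite_formulas={"h6p__D_c": "C6H11O9P"},
    )


#: Carbon-fixation reactions kept active by the preprocessing profiles
#: (phosphoenolpyruvate carboxylase, carbamate kinase, isocitrate
#: dehydrogenase, carbamoyl-phosphate synthase, pyruvate carboxylase,
#: acetyl-CoA carboxylase, methylmalonate-semialdehyde dehydrogenase).
CARBON_FIXATION_WHITELIST = frozenset({
    "PPC", "PPCr", "CBMK", "CBMKr", "ICDHyr", "ICDHy", "ICDHx",
    "CBPS", "PC", "PYC", "ACCOAC", "MMSAD", "MMSAD3", "MSAD",
})

_CO2_IDS = ("co2_c", "co2_p", "co2_e", "hco3_c", "hco3_p", "hco3_e")


def _deactivate(model: MetabolicModel, rid: str) -> None:
    if model.has_reaction(rid):
        rxn = model.reaction(rid)
        rxn.lb = 0.0
        rxn.ub = 0.0
    else:
        logger.warning("preprocessing target %r not in model; skipped", rid)


def _block_carbon_fixation(model: MetabolicModel, whitelist: frozenset[str]) -> None:
    """Close the CO2/bicarbonate-consuming direction of non-whitelisted reactions.

    Only the fixing direction is blocked so that ordinary decarboxylations
    keep running; the biomass and exchange reactions are never touched.
    """
    for rxn in model.reactions:
        if rxn.id in whitelist or rxn.id == model.biomass_id:
            continue
        if rxn.id in model.exchange_ids:
            continue
        net = sum(rxn.stoichiometry.get(m, 0.0) for m in _CO2_IDS)
        if net < 0 and rxn.ub > 0:   # forward flux consumes CO2
            rxn.ub = 0.0
        elif net > 0 and rxn.lb < 0:  # reverse flux consumes CO2
            rxn.lb = 0.0


def apply_preprocessing(
    model: MetabolicModel,
    profile: str,
    carbon_fixation_whitelist: frozenset[str] = CARBON_FIXATION_WHITELIST,
) -> MetabolicModel:
    """Organism-specific cleanup applied before design.

    ``"ecoli"`` deactivates the anaerobic formate lyases (PFL, OBTFL) and
    two reactions reported unrealistic (DRPA, PAI2T); ``"cglutamicum"``
    adds a xylose transport reaction when absent.  Both profiles block
    the carbon-fixing direction of reactions outside the whitelist.
    ``"none"`` returns an unchanged copy.  Missing targets are logged,
    never fatal, so one profile works across model versions.
    """
    out = model.copy()
    if profile == "none":
        return out
    if profile == "ecoli":
        for rid in ("PFL", "OBTFL", "DRPA", "PAI2T"):
            _deactivate(out, rid)
    elif profile == "cglutamicum":
        if not out.has_reaction("XYLt"):
            spec = PathwaySpec(
                reactions=[
                    Reaction("XYLt", {"xyl__D_e": -1.0, "xyl__D_c": 1.0},
                             lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND,
                             name="xylose transport"),
                ],
                required_exchanges=[
                    Reaction("EX_xyl__D_e", {"xyl__D_e": -1.0},
                             lb=0.0, ub=DEFAULT_BOUND, name="xylose exchange"),
                ],
            )
            out = add_pathway(out, spec)
    else:
        raise ConfigurationError(f"unknown preprocessing profile {profile!r}")
    _block_carbon_fixation(out, carbon_fixation_whitelist)
    out.validate()
    return out


def set_medium(
    model: MetabolicModel,
    uptakes: dict[str, float],
    base_medium: tuple[str, ...] | list[str] | None = None,
) -> MetabolicModel:
    """Return a copy with the given carbon sources open and all others closed.

    Each exchange listed in ``uptakes`` gets ``lb = -rate``; every other
    *carbon* exchange is closed (``lb = 0``).  Non-carbon medium
    components (O2, ions — identified by formula annotation or by the
    ``base_medium`` list) keep their current bounds, as do secretion
    upper bounds.  Idempotent for a fixed mapping.
    """
    out = model.copy()
    if base_medium is not None:
        out.annotations["base_medium"] = tuple(base_medium)
    index = out._index()
    for ex in uptakes:
        if ex not in out.exchange_ids:
            raise ConfigurationError(f"{ex!r} is not an exchange reaction")
    carbon = set(out.carbon_exchanges())
    for ex in carbon:
        if ex not in uptakes:
            index[ex].lb = 0.0
    for ex, rate in uptakes.items():
        if rate < 0:
            raise ConfigurationError("uptake rates are magnitudes; got a negative value")
        index[ex].lb = -float(rate)
    out.validate()
    return out
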