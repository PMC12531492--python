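"""Standard-format model I/O (SBML Level 3 + FBC, BiGG-style JSON).

Parsing and serialisation are delegated to COBRApy; this module only
converts between :class:`cobra.Model` and the package's lightweight
:class:`~adaptuc.model_core.MetabolicModel`.  The biomass reaction is
taken from the source model's objective, falling back to an id match on
``biomass``.
"""

from __future__ import annotations

import logging
import os

import cobra
import cobra.io

from .errors import ModelError, ModelFormatError
from .model_core import DEFAULT_BOUND, MetabolicModel, Reaction, detect_exchanges

logger = logging.getLogger(__name__)

_DIALECTS = ("bigg-json", "sbml-fbc")


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".json":
        return "bigg-json"
    if ext in (".xml", ".sbml"):
        return "sbml-fbc"
    raise ModelFormatError(f"cannot infer model dialect from {path!r}")


def _biomass_id(cm: cobra.Model) -> str:
    from cobra.util.solver import linear_reaction_coefficients

    for rxn, coef in linear_reaction_coefficients(cm).items():
        if coef:
            return rxn.id
    candidates = [r.id for r in cm.reactions if "biomass" in r.id.lower()]
    if candidates:
        # prefer a "core" biomass over wild-type duplicates, else shortest id
        core = [c for c in candidates if "core" in c.lower()]
        return (core or sorted(candidates, key=len))[0]
    raise ModelError("no biomass reaction identifiable in model")


def from_cobra(cm: cobra.Model) -> MetabolicModel:
    """Convert a COBRApy model, preserving ids, stoichiometry and bounds."""
    reactions = []
    for rxn in cm.reactions:
        stoich = {m.id: float(c) for m, c in rxn.metabolites.items()}
        if not stoich:
            logger.warning("dropping empty reaction %r", rxn.id)
            continue
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry=stoich,
                lb=float(rxn.lower_bound),
                ub=float(rxn.upper_bound),
                has_gene=bool(rxn.genes),
                name=rxn.name or "",
                subsystem=rxn.subsystem or "",
            )
        )
    formulas = {m.id: m.formula for m in cm.metabolites if m.formula}
    model = MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        biomass_id=_biomass_id(cm),
        exchange_ids=detect_exchanges(reactions),
        annotations={"metabolite_formulas": formulas, "source_id": cm.id or ""},
    )
    return model


def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert to a COBRApy model (placeholder genes keep ``has_gene``)."""
    cm = cobra.Model(model.annotations.get("source_id") or "adaptuc_model")
    formulas = model.annotations.get("metabolite_formulas", {})
    mets = {}
    for mid in model.metabolites:
        compartment = mid.rsplit("_", 1)[1] if "_" in mid else "c"
        if not (len(compartment) <= 2 and compartment.isalpha()):
            compartment = "c"
        met = cobra.Metabolite(mid, formula=formulas.get(mid) or None,
                               compartment=compartment)
        mets[mid] = met
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name,
                            lower_bound=rxn.lb, upper_bound=rxn.ub)
        cr.subsystem = rxn.subsystem
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.has_gene and rxn.id != model.biomass_id:
            cr.gene_reaction_rule = f"g_{rxn.id}"
    cm.objective = model.biomass_id
    return cm


def load_model(path: str, dialect: str | None = None) -> MetabolicModel:
    """Read a genome-scale model from SBML-FBC or BiGG-style JSON.

    The dialect is inferred from the file extension when not given.
    Exchange reactions are auto-detected by the single-metabolite
    boundary pattern.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ModelFormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not os.path.exists(path):
        raise ModelFormatError(f"model file not found: {path}")
    try:
        if dialect == "bigg-json":
            cm = cobra.io.load_json_model(path)
        else:
            cm = cobra.io.read_sbml_model(path)
    except ModelError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface any parser failure uniformly
        raise ModelFormatError(f"could not parse {path} as {dialect}: {exc}") from exc
    return from_cobra(cm)


def write_model(model: MetabolicModel, path: str, dialect: str | None = None) -> None:
    """Write a model as BiGG-style JSON or SBML-FBC (by extension)."""
    dialect = dialect or _infer_dialect(path)
    cm = to_cobra(model)
    if dialect == "bigg-json":
        cobra.io.save_json_model(cm, path)
    elif dialect == "sbml-fbc":
        cobra.io.write_sbml_model(cm, path)
    else:
        raise ModelFormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
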