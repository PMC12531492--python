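import math

import pytest

from adaptuc import (
    AugmentationError,
    ConfigurationError,
    ModelError,
    load_model,
    write_model,
)
from adaptuc.model_core import (
    MetabolicModel,
    PathwaySpec,
    Reaction,
    add_pathway,
    apply_preprocessing,
    molar_mass,
    rump_pathway,
    set_medium,
)
from adaptuc.synth_models import ToySpec, make_toy


def small_model():
    reactions = [
        Reaction("EX_a", {"a": -1.0}, lb=-10, ub=1000),
        Reaction("r1", {"a": -1.0, "b": 1.0}, lb=0, ub=1000),
        Reaction("grow", {"b": -1.0}, lb=0, ub=1000),
    ]
    return MetabolicModel(
        metabolites=["a", "b"],
        reactions=reactions,
        biomass_id="grow",
        exchange_ids={"EX_a"},
    )


class TestReactionInvariants:
    def test_bounds_order_enforced(self):
        with pytest.raises(ModelError):
            Reaction("r", {"a": 1.0}, lb=1.0, ub=0.0)

    @pytest.mark.parametrize("coef", [0.0, float("nan"), float("inf")])
    def test_coefficients_finite_nonzero(self, coef):
        with pytest.raises(ModelError):
            Reaction("r", {"a": coef})

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelError):
            Reaction("r", {})


class TestModelStructure:
    def test_biomass_must_exist(self):
        with pytest.raises(ModelError):
            MetabolicModel(metabolites=["a"],
                           reactions=[Reaction("r", {"a": 1.0})],
                           biomass_id="missing")

    def test_dangling_metabolite_rejected(self):
        with pytest.raises(ModelError):
            MetabolicModel(metabolites=["a"],
                           reactions=[Reaction("r", {"a": -1.0, "ghost": 1.0})],
                           biomass_id="r")

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ModelError):
            MetabolicModel(metabolites=["a", "b"],
                           reactions=[Reaction("r", {"a": -1.0, "b": 1.0})],
                           biomass_id="r", exchange_ids={"r"})

    def test_stoichiometric_dimensions(self):
        from adaptuc.lp_engine import model_arrays
        arrays = model_arrays(small_model())
        assert arrays.S.shape == (2, 3)


class TestIO:
    def test_round_trip_json_preserves_everything(self, tmp_path):
        model, _ = make_toy(ToySpec(phi=0.3, decoys=2, seed=7))
        path = tmp_path / "toy.json"
        write_model(model, str(path))
        loaded = load_model(str(path))
        assert loaded.biomass_id == model.biomass_id
        assert loaded.exchange_ids == model.exchange_ids
        assert set(loaded.reaction_ids) == set(model.reaction_ids)
        for rxn in model.reactions:
            other = loaded.reaction(rxn.id)
            assert other.stoichiometry == rxn.stoichiometry
            assert (other.lb, other.ub) == (rxn.lb, rxn.ub)
            assert other.has_gene == rxn.has_gene

    def test_round_trip_sbml(self, tmp_path):
        model, _ = make_toy(ToySpec(phi=0.5))
        path = tmp_path / "toy.xml"
        write_model(model, str(path))
        loaded = load_model(str(path))
        for rxn in model.reactions:
            other = loaded.reaction(rxn.id)
            assert other.stoichiometry == rxn.stoichiometry
            assert (other.lb, other.ub) == (rxn.lb, rxn.ub)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        from adaptuc import ModelFormatError
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(str(bad))


class TestAddPathway:
    def test_empty_spec_is_identity(self):
        model = small_model()
        out = add_pathway(model, PathwaySpec())
        assert out.reaction_ids == model.reaction_ids

    def test_id_collision_rejected(self):
        model = small_model()
        spec = PathwaySpec(reactions=[Reaction("r1", {"a": 1.0})])
        with pytest.raises(AugmentationError):
            add_pathway(model, spec)

    def test_rump_pathway_adds_reactions_and_exchange(self):
        base = MetabolicModel(
            metabolites=["ru5p__D_c", "f6p_c", "nad_c", "nadh_c", "h_c", "b"],
            reactions=[
                Reaction("src", {"ru5p__D_c": 1.0, "nad_c": 1.0}, lb=0),
                Reaction("use", {"f6p_c": -1.0, "nadh_c": -1.0, "h_c": -1.0,
                                 "b": 1.0}, lb=0),
                Reaction("grow", {"b": -1.0}, lb=0),
            ],
            biomass_id="grow",
        )
        out = add_pathway(base, rump_pathway())
        # MEDH + HPS + PHI + transport + exchange
        assert len(out.reactions) == len(base.reactions) + 5
        assert "EX_meoh_e" in out.exchange_ids
        assert out.reaction("HPS").stoichiometry == {
            "fald_c": -1.0, "ru5p__D_c": -1.0, "h6p__D_c": 1.0}

    def test_original_model_untouched(self):
        model = small_model()
        add_pathway(model, PathwaySpec(reactions=[Reaction("new", {"a": -1.0, "b": 1.0})]))
        assert not model.has_reaction("new")


class TestPreprocessing:
    def ecoli_like(self):
        reactions = [
            Reaction("EX_a", {"a": -1.0}, lb=-10),
            Reaction("PFL", {"a": -1.0, "b": 1.0}, lb=0),
            Reaction("OBTFL", {"a": -1.0, "b": 1.0}, lb=0),
            Reaction("FIX", {"co2_c": -1.0, "b": 1.0}, lb=-1000),
            Reaction("PPC", {"co2_c": -1.0, "b": 1.0}, lb=0),
            Reaction("DECARB", {"b": -1.0, "co2_c": 1.0}, lb=0),
            Reaction("grow", {"b": -1.0}, lb=0),
        ]
        return MetabolicModel(metabolites=["a", "b", "co2_c"], reactions=reactions,
                              biomass_id="grow", exchange_ids={"EX_a"})

    def test_ecoli_profile_deactivates_anaerobic_lyases(self):
        out = apply_preprocessing(self.ecoli_like(), "ecoli")
        for rid in ("PFL", "OBTFL"):
            rxn = out.reaction(rid)
            assert rxn.lb == 0 and rxn.ub == 0

    def test_carbon_fixation_blocked_except_whitelist(self):
        out = apply_preprocessing(self.ecoli_like(), "ecoli")
        assert out.reaction("FIX").ub == 0          # fixing direction closed
        assert out.reaction("FIX").lb == -1000      # reverse (producing) kept
        assert out.reaction("PPC").ub > 0           # whitelisted
        assert out.reaction("DECARB").ub > 0        # pure decarboxylation kept

    def test_missing_targets_logged_not_fatal(self, caplog):
        model = small_model()
        with caplog.at_level("WARNING"):
            out = apply_preprocessing(model, "ecoli")
        assert "PFL" in caplog.text
        assert set(out.reaction_ids) == set(model.reaction_ids)

    def test_profile_none_is_identity(self):
        model = small_model()
        out = apply_preprocessing(model, "none")
        for rxn in model.reactions:
            other = out.reaction(rxn.id)
            assert (other.lb, other.ub) == (rxn.lb, rxn.ub)

    def test_cglutamicum_adds_xylose_transport(self):
        out = apply_preprocessing(small_model(), "cglutamicum")
        assert out.has_reaction("XYLt")
        assert "EX_xyl__D_e" in out.exchange_ids


class TestSetMedium:
    def test_opens_listed_and_closes_other_carbon(self):
        model, _ = make_toy(ToySpec(phi=0.1))
        out = set_medium(model, {"EX_M": 10})
        assert out.reaction("EX_M").lb == -10
        assert out.reaction("EX_A").lb == 0

    def test_empty_mapping_closes_all_carbon(self):
        from adaptuc import solve_fba
        model, _ = make_toy(ToySpec(phi=0.1))
        out = set_medium(model, {})
        state = solve_fba(out)
        assert state.optimal and state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        model, _ = make_toy(ToySpec(phi=0.1))
        once = set_medium(model, {"EX_M": 5})
        twice = set_medium(once, {"EX_M": 5})
        for rxn in once.reactions:
            assert twice.reaction(rxn.id).lb == rxn.lb

    def test_unknown_exchange_rejected(self):
        model, _ = make_toy(ToySpec(phi=0.1))
        with pytest.raises(ConfigurationError):
            set_medium(model, {"EX_nope": 10})

    def test_non_carbon_base_medium_untouched(self):
        model, _ = make_toy(ToySpec(phi=0.1))
        model.annotations["base_medium"] = ("EX_M",)  # declare M non-carbon-like
        out = set_medium(model, {"EX_A": 10})
        assert out.reaction("EX_M").lb == model.reaction("EX_M").lb


class TestMolarMass:
    @pytest.mark.parametrize("formula,expected", [
        ("C6H12O6", 180.156),
        ("H2O", 18.015),
        ("C", 12.011),
    ])
    def test_known_masses(self, formula, expected):
        assert molar_mass(formula) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("formula", ["", "R2X", "C6H12O6R"])
    def test_unparseable_returns_none(self, formula):
        assert molar_mass(formula) is None
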