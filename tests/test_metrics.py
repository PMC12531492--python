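import math

import pytest
from hypothesis import given, settings, strategies as st

from adaptuc import (
    ConfigurationError,
    check_requirements,
    growth_uc_curve,
    minimal_uc_uptake,
    precursor_producibility,
    sadf,
    score_strategy,
    ucco_ratio,
)
from adaptuc.synth_models import ToySpec, default_config, make_toy

PHI_GRID = (1.0, 0.5, 0.25, 0.1, 0.05)


class TestRequirements:
    def test_coupling_deletion_passes_all(self, toy):
        model, _, cfg = toy
        report = check_requirements(model, {"rQ1"}, cfg)
        assert report.v1bio == pytest.approx(0.0, abs=1e-8)
        assert report.v2bio == pytest.approx(0.0, abs=1e-8)
        assert report.v3bio >= 10.0 - 1e-8
        assert report.passed

    def test_reference_strain_fails_dependence(self, toy):
        model, _, cfg = toy
        report = check_requirements(model, set(), cfg)
        assert not report.req2_pass
        assert report.v2bio == pytest.approx(cfg.uptake_bound, abs=1e-8)

    def test_blocking_bulk_precursor_fails_recovery(self, toy):
        model, _, cfg = toy
        report = check_requirements(model, {"rP"}, cfg)
        assert not report.req3_pass

    def test_variant_b_requires_uc_growth(self, toy_factory):
        model, _, cfg = toy_factory(phi=0.5, variant="B", include_uc_only_route=True)
        report = check_requirements(model, {"rQ1"}, cfg)
        assert report.passed
        assert report.v1bio >= 0.5 * report.reference.v0bio_uc - 1e-8

    def test_variant_b_floor_trivial_without_uc_route(self, toy_factory):
        # with no UC-only route the reference UC growth is 0, so the
        # variant-B floor (>= 0.5 * 0) is trivially met; dependence
        # (requirement 2) still decides the design
        model, _, cfg = toy_factory(phi=0.5, variant="B")
        report = check_requirements(model, {"rQ1"}, cfg)
        assert report.reference.v0bio_uc == pytest.approx(0.0, abs=1e-9)
        assert report.req1_pass

    def test_no_cosubstrate_growth_raises(self, toy):
        model, _, cfg = toy
        from dataclasses import replace
        bad = replace(cfg, cosub_exchange="EX_M", uc_exchange="EX_A")
        with pytest.raises(ConfigurationError):
            check_requirements(model, set(), bad)

    def test_leak_route_defeats_single_deletion(self, toy_factory):
        model, key, cfg = toy_factory(phi=0.1, include_leak_route=True)
        assert key.leak_violates_req2
        assert not check_requirements(model, {"rQ1"}, cfg).req2_pass
        assert check_requirements(model, {"rQ1", "rLeak"}, cfg).passed


class TestMinimalUptake:
    def test_closed_form(self, toy):
        model, _, cfg = toy
        assert minimal_uc_uptake(model, {"rQ1"}, 10.0, cfg) == pytest.approx(0.5, abs=1e-8)

    def test_no_knockouts_need_no_uc(self, toy):
        model, _, cfg = toy
        assert minimal_uc_uptake(model, set(), 10.0, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_unreachable_target_is_infinite(self, toy):
        model, _, cfg = toy
        assert math.isinf(minimal_uc_uptake(model, {"rQ1"}, 100.0, cfg))


class TestScores:
    @pytest.mark.parametrize("phi", PHI_GRID)
    def test_sadf_matches_closed_form(self, toy_factory, phi):
        model, key, cfg = toy_factory(phi=phi)
        assert sadf(model, {"rQ1"}, cfg) == pytest.approx(key.expected_sadf, abs=1e-6)

    @pytest.mark.parametrize("phi", PHI_GRID)
    def test_ucco_matches_closed_form(self, toy_factory, phi):
        model, key, cfg = toy_factory(phi=phi)
        assert ucco_ratio(model, {"rQ1"}, cfg) == pytest.approx(key.expected_ucco, abs=1e-6)

    def test_sadf_undefined_without_coupling(self, toy):
        model, _, cfg = toy
        assert sadf(model, set(), cfg) is None

    def test_full_coupling_sentinel(self, toy_factory):
        # phi=1 biomass is pure Q; deleting rP is harmless, deleting rQ1
        # leaves rQ2 needing A and M in 1:1, so the cosubstrate is still
        # required and the ratio stays finite
        model, _, cfg = toy_factory(phi=1.0)
        ratio = ucco_ratio(model, {"rQ1"}, cfg)
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_score_strategy_assembles_everything(self, toy):
        model, key, cfg = toy
        score = score_strategy(model, {"rQ1"}, cfg)
        assert score.sadf == pytest.approx(key.expected_sadf, abs=1e-6)
        assert score.coupling_fraction == pytest.approx(key.expected_coupling_fraction, abs=1e-9)
        assert score.coupling_class == "minimal"
        assert score.requirements.passed

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.02, max_value=1.0))
    def test_closed_forms_hold_across_phi(self, phi):
        model, _ = make_toy(ToySpec(phi=phi))
        cfg = default_config(ToySpec(phi=phi))
        assert sadf(model, {"rQ1"}, cfg) == pytest.approx(2.0 / phi, rel=1e-9, abs=1e-6)
        assert ucco_ratio(model, {"rQ1"}, cfg) == pytest.approx(phi / (2 - phi), rel=1e-9, abs=1e-6)


class TestCurve:
    def test_slope_matches_closed_form(self, toy_factory):
        phi = 0.2
        model, _, cfg = toy_factory(phi=phi)
        grid = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        table = growth_uc_curve(model, {"rQ1"}, [10.0], grid, cfg)
        uc = list(table["min_uc_uptake"])
        for g, v in zip(grid, uc):
            assert v == pytest.approx(phi * g / 2, abs=1e-7)

    def test_zero_growth_needs_nothing(self, toy):
        model, _, cfg = toy
        table = growth_uc_curve(model, {"rQ1"}, [10.0], [0.0], cfg)
        assert table["min_uc_uptake"].iloc[0] == 0.0

    def test_monotone_non_decreasing_per_level(self, toy):
        model, _, cfg = toy
        grid = [0.0, 1.0, 3.0, 5.0, 9.0, 10.0]
        table = growth_uc_curve(model, {"rQ1"}, [5.0, 10.0], grid, cfg)
        for _, sub in table.groupby("cosub_uptake"):
            uc = list(sub.sort_values("growth")["min_uc_uptake"])
            assert all(b >= a - 1e-9 for a, b in zip(uc, uc[1:]))

    def test_uc_only_curve_positive_without_cosubstrate(self, toy_factory):
        model, _, cfg = toy_factory(phi=0.5, variant="B", include_uc_only_route=True)
        table = growth_uc_curve(model, {"rQ1"}, [0.0], [1.0, 2.0], cfg)
        assert (table["min_uc_uptake"] > 0).all()
        assert (table["min_uc_uptake"] < math.inf).all()

    def test_curve_agrees_with_minimal_uptake_at_reference(self, toy):
        model, _, cfg = toy
        table = growth_uc_curve(model, {"rQ1"}, [10.0], [10.0], cfg)
        direct = minimal_uc_uptake(model, {"rQ1"}, 10.0, cfg)
        assert table["min_uc_uptake"].iloc[0] == pytest.approx(direct, abs=1e-8)


class TestProducibility:
    def test_coupled_precursor_detected(self, toy):
        model, key, cfg = toy
        report = precursor_producibility(model, {"rQ1"}, cfg)
        assert report.producible == {"P": True, "Q": False}
        assert report.coupling_fraction == pytest.approx(key.expected_coupling_fraction)
        assert report.coupling_class == "minimal"
        assert report.mass_basis == "coefficient"

    def test_full_coupling_class(self, toy_factory):
        model, _, cfg = toy_factory(phi=1.0)
        report = precursor_producibility(model, {"rQ1"}, cfg)
        assert report.coupling_class == "full"
        assert report.coupling_fraction == pytest.approx(1.0)

    def test_intermediate_class(self, toy_factory):
        model, _, cfg = toy_factory(phi=0.5)
        report = precursor_producibility(model, {"rQ1"}, cfg)
        assert report.coupling_class == "intermediate"

    def test_reference_strain_everything_producible(self, toy):
        model, _, cfg = toy
        report = precursor_producibility(model, set(), cfg)
        assert all(report.producible.values())
        assert report.coupling_fraction == 0.0

    def test_molar_mass_basis_with_formulas(self, toy):
        model, _, cfg = toy
        model.annotations["metabolite_formulas"] = {
            "P": "C3H6O3", "Q": "C6H12O6", "A": "C6H12O6", "M": "CH4O"}
        report = precursor_producibility(model, {"rQ1"}, cfg)
        assert report.mass_basis == "molar_mass"
        w_p = 0.9 * 90.078
        w_q = 0.1 * 180.156
        assert report.mass_fractions["Q"] == pytest.approx(w_q / (w_p + w_q), rel=1e-6)
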