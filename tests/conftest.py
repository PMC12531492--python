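import pytest

from adaptuc.synth_models import ToySpec, default_config, make_toy


@pytest.fixture
def toy():
    """Default variant-A toy at phi=0.1 with its answer key and config."""
    spec = ToySpec(phi=0.1)
    model, key = make_toy(spec)
    return model, key, default_config(spec)


@pytest.fixture
def toy_factory():
    def build(phi=0.1, variant="A", max_knockouts=2, **kwargs):
        spec = ToySpec(phi=phi, **kwargs)
        model, key = make_toy(spec)
        return model, key, default_config(spec, variant=variant,
                                          max_knockouts=max_knockouts)
    return build


def internal_candidates(model):
    """All non-exchange, non-biomass reactions of a toy."""
    return [r.id for r in model.reactions
            if r.id not in model.exchange_ids and r.id != model.biomass_id]
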