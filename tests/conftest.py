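import pytest

from ureascape import curation, synthetic


@pytest.fixture(scope="session")
def noiseless_library():
    """Mid-size noiseless synthetic library with planted cliffs."""
    cfg = synthetic.SyntheticConfig(n_compounds=150, noise_sd=0.0, seed=3)
    records, truth = synthetic.generate_library(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def noiseless_curated(noiseless_library):
    _, records, _ = noiseless_library
    curated, normalized, rejects = curation.curate(records)
    return curated, normalized, rejects


def make_record(**kwargs):
    """A RawActivityRecord with sensible defaults, overridable per test."""
    defaults = dict(
        record_id="r1",
        smiles="CCO",
        activity_value=10.0,
        activity_type="IC50",
        control_value=20.0,
        species="Canavalia ensiformis",
        year=2015,
        reference_id="ref1",
    )
    defaults.update(kwargs)
    return curation.RawActivityRecord(**defaults)
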