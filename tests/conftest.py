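import pytest

from venomine import est, synthetic


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic EST dataset shared across the suite."""
    return synthetic.generate_dataset(synthetic.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def psm_bundle():
    """Full synthetic bundle: dataset, variant DB, PSM table and its truth."""
    return synthetic.generate_psm_dataset(synthetic.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def frames_by_read(dataset):
    return {r.id: est.six_frame_translate(r) for r in dataset.records}
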