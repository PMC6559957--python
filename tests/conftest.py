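import pytest

from folliscan.identify import filter_candidates
from folliscan.simulate import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (seed 1), shared across the suite."""
    return generate_bundle(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def cascade(bundle):
    return filter_candidates(
        bundle.assembled, bundle.reference, bundle.transcript_seqs, bundle.known
    )
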