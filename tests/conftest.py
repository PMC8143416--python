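import pytest

from ptmimpact import synthetic


@pytest.fixture(scope="session")
def config():
    return synthetic.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(
        synthetic.GeneratorConfig(seed=7, n_complexes=6, n_snapshots=40)
    )
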