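import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vhh_typology import (  # noqa: E402
    RepertoireConfig,
    generate_germline_db,
    generate_repertoire,
)


@pytest.fixture(scope="session")
def germline_db():
    return generate_germline_db()


@pytest.fixture(scope="session")
def small_repertoire():
    """300-record labeled repertoire at 3% per-base hypermutation."""
    cfg = RepertoireConfig(n_sequences=300, shm_rate=0.03, seed=11)
    records, annotations, truth = generate_repertoire(cfg)
    return records, annotations, truth
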