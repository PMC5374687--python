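import numpy as np
import pytest

from vintect.align import AlignParams, ReferenceIndex


@pytest.fixture(scope="session")
def seeded_refs():
    """Small random host/virus references shared across alignment tests."""
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(bases[rng.integers(0, 4, n)])

    host = {"chr1": seq(4000), "chr2": seq(2500)}
    virus = {"virusA": seq(1000)}
    params = AlignParams()
    return {
        "host": host,
        "virus": virus,
        "host_index": ReferenceIndex(host, params.word),
        "virus_index": ReferenceIndex(virus, params.word),
        "params": params,
    }
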