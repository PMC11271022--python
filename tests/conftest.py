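import numpy as np
import pytest

import habrange as hr


@pytest.fixture(scope="session")
def corsica_records():
    return hr.corsica_occurrences()


@pytest.fixture(scope="session")
def island():
    """Small deterministic island shared by raster-stage tests."""
    return hr.generate_island(seed=7, n_rows=200, n_cols=200, n_classes=6, sea_fraction=0.45)


@pytest.fixture(scope="session")
def truth():
    return hr.SyntheticTruth(
        suitable_classes=frozenset({2, 3}),
        elev_min=50.0,
        elev_max=1200.0,
        p_in_habitat=1.0,
        seed=7,
    )


@pytest.fixture()
def rng(request):
    # Per-test stream keyed on the test name: deterministic regardless of
    # which subset of the suite runs.
    import zlib

    seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng([20240725, seed])
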