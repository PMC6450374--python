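import numpy as np
import pytest

from bsamap import SegregationTable

# Published six-cell segregation tables for gene-based markers scored on two
# F2 mapping populations (counts: dominant AA/Aa/aa, recessive AA/Aa/aa),
# with the reference RF, LOD (None where undefined at RF 0.5) and joint
# chi-square each table reproduces.
TABLE3 = {
    # F2(NGB1238 x N24), markers linked to the causal gene
    "ZFP": ((30, 47, 0, 0, 1, 30), 0.0092, 25.815, 124.3951),
    "Upl": ((32, 43, 2, 0, 5, 26), 0.0660, 17.655, 90.4198),
    "RibL13l": ((31, 46, 0, 0, 1, 30), 0.0093, 25.819, 125.1111),
    "AUXfp": ((33, 43, 1, 0, 4, 27), 0.0475, 19.835, 100.6667),
    "PrOx": ((35, 40, 2, 1, 6, 24), 0.0970, 14.582, 80.3457),
    "sdhFP": ((33, 42, 2, 1, 8, 22), 0.1159, 12.656, 66.1235),
    "IPD3:c319del": ((30, 47, 0, 0, 0, 31), 0.0, 28.284, 133.3580),
    # F2(NGB1238 x N24), unlinked markers (other linkage group)
    "PsC908p622": ((23, 42, 12, 12, 16, 3), 0.5, None, 10.4198),
    "PsC8268p528": ((26, 39, 12, 9, 19, 2), 0.5, None, 11.4798),
    # F2(SGE x N24)
    "RibL13l/SGE": ((7, 11, 0, 0, 0, 9), 0.0, 7.667, 42.6296),
    "AUXfp/SGE": ((4, 13, 1, 0, 1, 8), 0.0640, 4.723, 31.2716),
    "IPD3:c319del/SGE": ((7, 11, 0, 0, 0, 9), 0.0, 7.667, 42.6296),
}


@pytest.fixture(scope="session")
def table3():
    return {name: (SegregationTable(*row[0]), *row[1:])
            for name, row in TABLE3.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
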