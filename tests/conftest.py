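import io

import numpy as np
import pytest
from hypothesis import settings

from popassign.data import MISSING, GenotypeDataset, Marker, Sample

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


TOY_MAP = """\
1 m1 0 100
1 m2 0 200
2 m3 0 300
"""

# Sample B is missing at marker m2 ("0 0"); everything else called.
TOY_PED = """\
FAM1 A 0 0 1 -9 A A A G G G
FAM2 B 0 0 2 -9 A G 0 0 G G
"""


@pytest.fixture
def toy_ped_map():
    return io.StringIO(TOY_PED), io.StringIO(TOY_MAP)


def make_dataset(dosages, populations=None, alleles=("A", "G"),
                 chromosomes=None, positions=None):
    """Build a small dataset from a dosage matrix (rows = samples)."""
    g = np.asarray(dosages, dtype=np.int8)
    n, m = g.shape
    populations = populations or ["POP1"] * n
    samples = [Sample(f"s{i + 1}", populations[i]) for i in range(n)]
    markers = [
        Marker(
            f"m{j + 1}",
            chromosomes[j] if chromosomes else "1",
            positions[j] if positions else j + 1,
            alleles,
        )
        for j in range(m)
    ]
    return GenotypeDataset(samples, markers, g)


@pytest.fixture
def callrate_dataset():
    """4 samples x 4 markers with missing calls at (s2,m1), (s2,m2),
    (s4,m1), (s4,m2), (s4,m3).

    Hand-enumerated call rates: individuals s1=1, s2=0.5, s3=1, s4=0.25;
    markers (over all 4 samples) m1=0.5, m2=0.5, m3=0.75, m4=1.
    """
    g = np.array([
        [2, 1, 1, 2],
        [MISSING, MISSING, 1, 0],
        [1, 2, 0, 1],
        [MISSING, MISSING, MISSING, 1],
    ])
    return make_dataset(g)
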