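import numpy as np
import pandas as pd
import pytest

from karma.io import FRAGMENT_COLUMNS
from karma.simulate import SimDesign, simulate_karma_dataset


@pytest.fixture(scope="session")
def noiseless_design():
    return SimDesign(noise_sigma=0.0, missingness=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_design):
    return simulate_karma_dataset(noiseless_design, seed=11)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_karma_dataset(SimDesign(), seed=12)


def random_fragment_table(rng, n_proteins=3, n_precursors=4, n_fragments=3,
                          replicates=3, times=(0.0, 30.0, 60.0, 90.0),
                          p_zero=0.25, integer_intensities=True):
    """Random small fragment report exercising every filter path.

    Integer intensities keep aggregation order-independent so pipeline and
    brute-force oracle agree bitwise.
    """
    rows = []
    for ip in range(n_proteins):
        prot = f"P{ip}"
        for jp in range(n_precursors):
            pid = f"P{ip}_pep{jp}/2"
            proteo = rng.random() > 0.15
            lys = int(rng.integers(1, 3)) if rng.random() < 0.3 else 1
            for jf in range(n_fragments):
                series = "b" if rng.random() < 0.2 else "y"
                excl = rng.random() < 0.1
                for rep in range(1, replicates + 1):
                    for t in times:
                        for chan in ("light", "heavy"):
                            if rng.random() < p_zero:
                                inten = 0.0
                            else:
                                inten = float(rng.integers(1, 1000))
                            rows.append((
                                "B1", "none", rep, t, prot, proteo, pid,
                                series, 3 + jf, 1, chan, inten, excl, lys, 0))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
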