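import numpy as np
import pandas as pd
import pytest

from symnet.observations import ObservationTable


def make_table(rows: list[dict]) -> ObservationTable:
    """Build a validated observation table from a list of row dicts."""
    defaults = dict(
        year=2021,
        location="site01",
        plant_species=None,
        parasitoid_species=None,
        strain_id=None,
        source="mummy",
    )
    full = []
    for k, row in enumerate(rows):
        r = {**defaults, "sample_id": f"S{k + 1:04d}", **row}
        full.append(r)
    df = pd.DataFrame(full)
    return ObservationTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sym(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric matrix with zero diagonal (distance-like)."""
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A
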