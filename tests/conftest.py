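import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pronorm.benchmark import run_benchmark
from pronorm.matrix import IntensityMatrix, read_wide_matrix

DATA = Path(__file__).parent / "data"

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def bench():
    """The benchmark cohort analysed end to end (shared across tests)."""
    return run_benchmark(seed=1)


@pytest.fixture(scope="session")
def toy():
    """The printed 6-run / 20-peptide fixture with hand-countable filters."""
    x = read_wide_matrix(DATA / "toy_matrix.csv", scale="natural")
    meta = pd.read_csv(DATA / "toy_metadata.tsv", sep="\t")
    pmeta = pd.read_csv(DATA / "toy_peptides.tsv", sep="\t")
    return x, meta, pmeta


def make_matrix(values, run_ids=None, peptide_ids=None) -> IntensityMatrix:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    runs = run_ids or [f"r{i}" for i in range(m)]
    peps = peptide_ids or [f"p{j}" for j in range(n)]
    return IntensityMatrix(pd.DataFrame(values, index=runs, columns=peps))


def simple_meta(run_ids, sample_types, instruments=None, days=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": run_ids,
            "instrument": instruments or ["MS1"] * len(run_ids),
            "day": days or [1] * len(run_ids),
            "sample_type": sample_types,
        }
    )
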