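"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ldsem.studies import simulate_gc


@pytest.fixture(scope="session")
def factor_gc():
    """One (S, V) replicate simulated under the default factor model."""
    return simulate_gc("factor", 20_000, seed=1234)


@pytest.fixture(scope="session")
def simplex_gc():
    """One (S, V) replicate simulated under the default simplex model."""
    return simulate_gc("simplex", 20_000, seed=4321, run_munge=False,
                       n_blocks=100)


def toy_sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a small sumstats table with sensible defaults per row."""
    defaults = dict(CHR="1", BP=0, A1="G", A2="T", Z=1.0, N=10_000,
                    INFO=0.99, FRQ=0.30)
    full = []
    for i, row in enumerate(rows):
        rec = {**defaults, "BP": 1000 * (i + 1)}
        rec.update(row)
        full.append(rec)
    tab = pd.DataFrame(full)
    cols = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "INFO", "FRQ"]
    return tab[cols]
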