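import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enforcement_lens import (
    LandscapeConfig,
    generate_enforcement,
    generate_landscape,
)


def binom99(n: int, p: float) -> tuple[float, float]:
    """Exact binomial central 99% interval for a realized fraction."""
    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)


@pytest.fixture(scope="session")
def small_landscape():
    cfg = LandscapeConfig(seed=42, years=(2012, 2014), patches_per_year=30)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_landscape):
    return generate_enforcement(small_landscape, small_landscape.config)


def make_records(rows):
    """Build an enforcement-record table from (id, pid, date, state, theme, type, fine, x, y)."""
    return pd.DataFrame(
        rows,
        columns=["record_id", "process_id", "date", "state", "theme",
                 "sanction_type", "fine_value_brl", "x", "y"],
    )


@pytest.fixture
def ingest_fixture():
    """10 raw rows: 2 exact duplicates and 1 record outside the Legal Amazon."""
    base = [
        (f"R{i}", f"P{i}", f"2010-0{1 + i % 9}-15", "PA", "flora",
         "infraction_notice", 1000.0 * (i + 1), np.nan, np.nan)
        for i in range(7)
    ]
    rows = base + [base[0], base[1]]  # exact duplicates
    rows.append(("R9", "P9", "2010-05-01", "SP", "flora", "infraction_notice", 500.0, np.nan, np.nan))
    return make_records(rows)
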