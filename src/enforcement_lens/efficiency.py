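"""Currency-adjusted expenditure and the operational-efficiency metric.

Operational efficiency of enforcement is the unit cost of a sanction:
OE_{i,y} = E_y / I_{i,y}, where E_y is the inspection expenditure of year y
(deflated to a base year and converted to USD) and I_{i,y} the number of
sanctions of type i issued that year.  Because a single infraction notice
commonly spawns the embargo and the confiscation of the same case, the same
E_y enters every sanction type — unit costs are not additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EfficiencyTable", "deflate_convert", "operational_efficiency", "period_unit_cost"]

SANCTION_COUNT_COLUMNS = {
    "infraction_notice": "notices_count",
    "embargo": "embargoes_count",
    "confiscation_destruction": "confiscations_count",
}


def deflate_convert(
    series: pd.Series,
    index: pd.Series,
    base_year: int,
    exchange_rate_brl_per_usd: float = 5.0,
) -> pd.Series:
    """Deflate a nominal BRL series to base-year prices and convert to USD.

    real_usd(y) = nominal(y) x index(base)/index(y) / rate.  The default
    rate of 5 BRL per USD is the conventional round figure for the study
    period.
    """
    if exchange_rate_brl_per_usd <= 0:
        raise ValueError("exchange rate must be > 0")
    if base_year not in index.index:
        raise ValueError(f"price index does not cover base year {base_year}")
    missing = set(series.index) - set(index.index)
    if missing:
        raise ValueError(f"price index does not cover years {sorted(missing)}")
    if (index <= 0).any():
        raise ValueError("price index must be strictly positive")
    real = series * float(index.loc[base_year]) / index.reindex(series.index)
    return real / exchange_rate_brl_per_usd


@dataclass
class EfficiencyTable:
    """Unit costs with the inputs they came from."""

    expenditure_usd: pd.Series  # year -> E_y
    counts: pd.DataFrame  # year x sanction-count columns (I_{i,y})
    oe: pd.DataFrame  # year x sanction type, NaN where I = 0


def operational_efficiency(expenditure_usd: pd.Series, counts: pd.DataFrame) -> EfficiencyTable:
    """OE_{i,y} = E_y / I_{i,y} per sanction type and year.

    Years present in both inputs are used; cells with zero sanctions are
    reported missing rather than divided.
    """
    years = expenditure_usd.index.intersection(counts.index)
    if len(years) == 0:
        raise ValueError("no overlapping years between expenditure and counts")
    e = expenditure_usd.loc[years]
    oe = pd.DataFrame(index=years)
    for sanction, col in SANCTION_COUNT_COLUMNS.items():
        n = counts.loc[years, col].astype(float)
        oe[sanction] = (e / n.where(n > 0)).astype(float)
    return EfficiencyTable(
        expenditure_usd=e, counts=counts.loc[years, list(SANCTION_COUNT_COLUMNS.values())], oe=oe
    )


def period_unit_cost(
    table: EfficiencyTable, period: tuple[int, int], method: str = "pooled"
) -> pd.Series:
    """Average unit cost per sanction type over a period.

    ``pooled`` (default) divides total expenditure by total sanctions —
    the ratio-of-sums matching multi-year totals; ``mean_of_ratios``
    averages the annual OE values instead.
    """
    if method not in ("pooled", "mean_of_ratios"):
        raise ValueError("method must be 'pooled' or 'mean_of_ratios'")
    y0, y1 = period
    years = table.oe.index[(table.oe.index >= y0) & (table.oe.index <= y1)]
    if len(years) == 0:
        raise ValueError(f"period {period} not covered")
    if method == "mean_of_ratios":
        return table.oe.loc[years].mean(skipna=True)
    e_total = float(table.expenditure_usd.loc[years].sum())
    out = {}
    for sanction, col in SANCTION_COUNT_COLUMNS.items():
        n = float(table.counts.loc[years, col].sum())
        out[sanction] = e_total / n if n > 0 else np.nan
    return pd.Series(out)
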