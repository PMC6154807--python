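"""Packaged reference tables.

The six-province observed/expected mortality table for northern Thailand
(adults diagnosed with lung cancer, deaths 2008-2017) ships with the package
as a small fixture: it is the published provincial aggregate of the study's
district-level registry data, which are themselves not public.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .areal_data import AGE_BANDS, StrataTable, StratumRecord


def load_province_totals() -> pd.DataFrame:
    """Six-province observed/expected death totals, overall and by gender.

    Columns: area_id (province), population (persons over 15), then
    obs_/exp_ pairs for overall, male, female.  Observed and expected column
    sums agree (internal standardization conserves totals).
    """
    with resources.files("bymmap.data").joinpath("province_totals.csv").open() as fh:
        return pd.read_csv(fh)


def province_strata() -> StrataTable:
    """The province table recast as a single-band strata table.

    Age detail below the provincial aggregate is not published, so each
    province x gender cell is collapsed into the open-ended top age band.
    Useful for exercising aggregation and gender filtering on real printed
    numbers; not suitable for computing age-specific rates.
    """
    totals = load_province_totals()
    band = len(AGE_BANDS) - 1  # "85+"
    records = []
    for row in totals.itertuples(index=False):
        records.append(
            StratumRecord(row.area_id, band, "male", int(row.population), int(row.obs_male))
        )
        records.append(
            StratumRecord(row.area_id, band, "female", int(row.population), int(row.obs_female))
        )
    return StrataTable.from_records(records)
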