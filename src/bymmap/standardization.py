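"""Indirect standardization: reference rates, expected counts, SMRs.

Expected counts follow the classic indirect scheme: pool the study window's
deaths and midpoint populations over all areas within each age x gender
stratum to get reference rates, then apply those rates to each area's own
stratum populations.  When rates come from the same table ("internal"
standardization) the expected counts conserve the observed total exactly,
so the population-weighted mean SMR is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .areal_data import (
    AGE_BANDS,
    GENDERS,
    N_AGE_BANDS,
    AreaTable,
    StrataTable,
    ValidationError,
)

_GENDER_INDEX = {g: i for i, g in enumerate(GENDERS)}


@dataclass
class RateTable:
    """Deaths per person over the study period, per (age band, gender).

    ``rates`` has shape (18, 2) with gender axis ordered (male, female).
    A stratum whose pooled population is zero has rate 0 by convention.
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_AGE_BANDS, len(GENDERS)):
            raise ValidationError(
                f"rate table must have shape ({N_AGE_BANDS}, {len(GENDERS)})"
            )
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ValidationError("rates must be finite and nonnegative")

    def rate(self, age_band: int, gender: str) -> float:
        return float(self.rates[age_band, _GENDER_INDEX[gender]])


def reference_rates(strata: StrataTable) -> RateTable:
    """Pooled stratum-specific mortality rates over all areas.

    rate[s] = sum_i deaths[i, s] / sum_i population[i, s], with rate 0 for
    strata whose pooled population is zero (deaths are then necessarily zero
    too, by the per-record invariant).
    """
    if len(strata) == 0:
        raise ValidationError("cannot compute rates from an empty strata table")
    deaths = strata.dense("deaths").sum(axis=0)
    pop = strata.dense("population").sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(pop > 0, deaths / np.where(pop > 0, pop, 1.0), 0.0)
    return RateTable(rates)


def expected_counts(
    strata: StrataTable,
    rates: RateTable | None = None,
    gender: str = "both",
) -> AreaTable:
    """Expected (and observed) counts per area by indirect standardization.

    E[i] = sum_s population[i, s] * rate[s] over the selected gender strata.
    ``rates=None`` computes internal reference rates from *strata* itself,
    in which case sum(E) == sum(Y) to floating-point accuracy.  For a
    gender-specific analysis pass ``gender=`` and the standardization is
    internal to that gender's strata (rates are stratum-specific, so the
    restriction is exact).

    Raises if an area has E == 0 but observed deaths > 0 — the relative risk
    is then undefined and coarser strata (merging) are needed.
    """
    if gender not in ("both", *GENDERS):
        raise ValidationError(f"gender must be 'both', 'male' or 'female', got {gender!r}")
    if rates is None:
        rates = reference_rates(strata)
    pop = strata.dense("population")
    deaths = strata.dense("deaths")
    if gender == "both":
        E = (pop * rates.rates[None, :, :]).sum(axis=(1, 2))
        Y = deaths.sum(axis=(1, 2))
    else:
        g = _GENDER_INDEX[gender]
        E = (pop[:, :, g] * rates.rates[None, :, g]).sum(axis=1)
        Y = deaths[:, :, g].sum(axis=1)
    bad = (E <= 0) & (Y > 0)
    if np.any(bad):
        ids = [strata.area_ids[i] for i in np.flatnonzero(bad)]
        raise ValidationError(
            f"areas {ids} have expected count 0 but observed deaths > 0; "
            "merge strata so every observed death falls in a stratum with "
            "nonzero reference rate"
        )
    return AreaTable(strata.area_ids, Y.astype(int), E)


def smr(areas: AreaTable) -> np.ndarray:
    """Standardized mortality ratio Y/E per area (requires E > 0)."""
    if areas.E is None:
        raise ValidationError("AreaTable has no expected counts")
    if np.any(areas.E <= 0):
        raise ValidationError("SMR undefined: some expected counts are <= 0")
    return areas.Y / areas.E


def write_area_table(areas: AreaTable, path: str | Path, sep: str = ",") -> None:
    """Write area_id, Y, E, SMR as delimited text."""
    areas.to_frame().to_csv(path, sep=sep, index=False)
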