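"""Stratified areal count tables.

Holds registry-style mortality counts cross-classified by area, 18 five-year
age bands (0-4 ... 85+) and gender, plus the per-area observed/expected table
every downstream stage consumes.  Areas are kept in lexicographic order of
their identifier everywhere so that count vectors, expected counts and the
adjacency graph can never silently misalign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

AGE_BANDS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
)
N_AGE_BANDS = len(AGE_BANDS)
GENDERS: tuple[str, str] = ("male", "female")

_COLUMNS = ("area_id", "age_band", "gender", "population", "deaths")

_AGE_INDEX = {label: i for i, label in enumerate(AGE_BANDS)}
_GENDER_INDEX = {g: i for i, g in enumerate(GENDERS)}


class ValidationError(ValueError):
    """A table violates a structural invariant (duplicate key, bad counts...)."""


@dataclass(frozen=True)
class StratumRecord:
    """One area x age-band x gender cell.

    ``age_band`` is the integer band index 0..17; the textual labels exist
    only at I/O boundaries.  ``population`` is persons at the study midpoint,
    ``deaths`` the observed count over the study window.
    """

    area_id: str
    age_band: int
    gender: str
    population: int
    deaths: int

    def __post_init__(self) -> None:
        if not 0 <= self.age_band < N_AGE_BANDS:
            raise ValidationError(
                f"age_band index {self.age_band} outside 0..{N_AGE_BANDS - 1}"
            )
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.population < 0 or self.deaths < 0:
            raise ValidationError(
                f"negative count in stratum ({self.area_id}, {AGE_BANDS[self.age_band]}, "
                f"{self.gender}): population={self.population}, deaths={self.deaths}"
            )
        if self.deaths > self.population:
            raise ValidationError(
                f"deaths={self.deaths} exceeds population={self.population} in stratum "
                f"({self.area_id}, {AGE_BANDS[self.age_band]}, {self.gender})"
            )

    @property
    def age_label(self) -> str:
        return AGE_BANDS[self.age_band]


class StrataTable:
    """A validated collection of :class:`StratumRecord`.

    Missing (area, band, gender) combinations are implicitly population 0,
    deaths 0.  Internally a tidy DataFrame sorted by (area_id, age_band,
    gender); dense (n_areas, 18, 2) arrays are available for standardization.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)
        self._area_ids: tuple[str, ...] = tuple(
            sorted(self._frame["area_id"].unique())
        )

    @classmethod
    def from_records(cls, records: Iterable[StratumRecord]) -> "StrataTable":
        rows = [
            (r.area_id, r.age_band, r.gender, r.population, r.deaths)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(_COLUMNS)))

    @property
    def frame(self) -> pd.DataFrame:
        """Tidy view (age_band as integer index)."""
        return self._frame

    @property
    def area_ids(self) -> tuple[str, ...]:
        return self._area_ids

    @property
    def n_areas(self) -> int:
        return len(self._area_ids)

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[StratumRecord]:
        return self.records()

    def records(self) -> Iterator[StratumRecord]:
        for row in self._frame.itertuples(index=False):
            yield StratumRecord(
                row.area_id, int(row.age_band), row.gender,
                int(row.population), int(row.deaths),
            )

    def dense(self, column: str) -> np.ndarray:
        """Dense ``(n_areas, 18, 2)`` array of *column*, zeros where absent.

        Axis order: areas (lexicographic), age band index, gender
        (male, female).
        """
        out = np.zeros((self.n_areas, N_AGE_BANDS, len(GENDERS)), dtype=float)
        ai = self._frame["area_id"].map({a: i for i, a in enumerate(self._area_ids)})
        gi = self._frame["gender"].map(_GENDER_INDEX)
        out[ai.to_numpy(), self._frame["age_band"].to_numpy(), gi.to_numpy()] = (
            self._frame[column].to_numpy(dtype=float)
        )
        return out

    def write(self, path: str | Path, sep: str = ",") -> None:
        write_strata(self, path, sep=sep)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(
            f"strata table must have columns {list(_COLUMNS)}; missing {sorted(missing)}"
        )
    df = frame.loc[:, list(_COLUMNS)].copy()
    df["area_id"] = df["area_id"].astype(str)
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()

    bad_gender = ~df["gender"].isin(GENDERS)
    if bad_gender.any():
        row = int(np.flatnonzero(bad_gender.to_numpy())[0])
        raise ValidationError(
            f"row {row + 1}: gender {df['gender'].iloc[row]!r} not in {GENDERS}"
        )

    # Age bands arrive either as labels or as already-encoded indices.
    band = df["age_band"]
    if band.dtype == object or pd.api.types.is_string_dtype(band):
        labels = band.astype(str).str.strip()
        unknown = ~labels.isin(_AGE_INDEX)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}: unknown age band {labels.iloc[row]!r}; "
                f"legal labels are {list(AGE_BANDS)}"
            )
        df["age_band"] = labels.map(_AGE_INDEX).astype(int)
    else:
        df["age_band"] = band.astype(int)
        out_of_range = (df["age_band"] < 0) | (df["age_band"] >= N_AGE_BANDS)
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}: age band index {df['age_band'].iloc[row]} "
                f"outside 0..{N_AGE_BANDS - 1}"
            )

    for col in ("population", "deaths"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            row = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise ValidationError(f"row {row + 1}: negative {col} ({vals.iloc[row]})")
        if not np.allclose(vals, np.round(vals)):
            row = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
            raise ValidationError(f"row {row + 1}: non-integer {col} ({vals.iloc[row]})")
        df[col] = vals.astype(int)

    over = df["deaths"] > df["population"]
    if over.any():
        row = int(np.flatnonzero(over.to_numpy())[0])
        raise ValidationError(
            f"row {row + 1}: deaths={df['deaths'].iloc[row]} exceeds "
            f"population={df['population'].iloc[row]} for "
            f"({df['area_id'].iloc[row]}, {AGE_BANDS[df['age_band'].iloc[row]]}, "
            f"{df['gender'].iloc[row]})"
        )

    dup = df.duplicated(subset=["area_id", "age_band", "gender"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = (
            df["area_id"].iloc[row],
            AGE_BANDS[df["age_band"].iloc[row]],
            df["gender"].iloc[row],
        )
        raise ValidationError(f"duplicate stratum key {key}")

    return df.sort_values(["area_id", "age_band", "gender"], kind="stable").reset_index(
        drop=True
    )


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_strata(path: str | Path, sep: str | None = None) -> StrataTable:
    """Read a delimited strata table (comma default, tab accepted).

    The header must name the five fields ``area_id, age_band, gender,
    population, deaths``; age bands use the 18 textual labels.  Raises
    :class:`ValidationError` on duplicate keys, deaths > population, or
    unknown age labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype={"area_id": str})
    return StrataTable(frame)


def write_strata(table: StrataTable, path: str | Path, sep: str = ",") -> None:
    """Write a strata table with textual age-band labels (round-trips)."""
    out = table.frame.copy()
    out["age_band"] = out["age_band"].map(dict(enumerate(AGE_BANDS)))
    out.to_csv(path, sep=sep, index=False)


@dataclass
class AreaTable:
    """Per-area observed count Y and (optionally) expected count E.

    Vectors are aligned to ``area_ids``, which is always lexicographically
    sorted.  ``E`` must be strictly positive for every area admitted to model
    fitting; zero expected counts are tolerated here only alongside zero
    observed counts.
    """

    area_ids: tuple[str, ...]
    Y: np.ndarray
    E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_ids = tuple(str(a) for a in self.area_ids)
        if list(self.area_ids) != sorted(self.area_ids):
            raise ValidationError("AreaTable area_ids must be sorted lexicographically")
        self.Y = np.asarray(self.Y)
        if self.Y.shape != (len(self.area_ids),):
            raise ValidationError("Y length does not match area_ids")
        if np.any(self.Y < 0) or not np.allclose(self.Y, np.round(self.Y)):
            raise ValidationError("Y must be nonnegative integers")
        self.Y = np.round(self.Y).astype(int)
        if self.E is not None:
            self.E = np.asarray(self.E, dtype=float)
            if self.E.shape != self.Y.shape:
                raise ValidationError("E length does not match area_ids")
            if np.any(self.E < 0):
                raise ValidationError("E must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def smr(self) -> np.ndarray:
        """Y/E per area (requires E > 0 everywhere)."""
        from .standardization import smr  # local import: avoid cycle

        return smr(self)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"area_id": list(self.area_ids), "Y": self.Y}
        if self.E is not None:
            data["E"] = self.E
            if np.all(self.E > 0):
                data["SMR"] = self.Y / self.E
        return pd.DataFrame(data)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_area_table(path: str | Path, sep: str = ",") -> AreaTable:
    df = pd.read_csv(path, sep=sep, dtype={"area_id": str})
    df = df.sort_values("area_id", kind="stable")
    E = df["E"].to_numpy(float) if "E" in df.columns else None
    return AreaTable(tuple(df["area_id"]), df["Y"].to_numpy(), E)


def aggregate_to_areas(strata: StrataTable, gender: str = "both") -> AreaTable:
    """Sum observed deaths to the area level for one gender or both.

    Every area present anywhere in the table appears in the output (missing
    strata count as zero), sorted by area id.
    """
    if len(strata) == 0:
        raise ValidationError("cannot aggregate an empty strata table")
    if gender not in ("both", *GENDERS):
        raise ValidationError(f"gender must be 'both', 'male' or 'female', got {gender!r}")
    deaths = strata.dense("deaths")  # (areas, bands, genders)
    if gender == "both":
        Y = deaths.sum(axis=(1, 2))
    else:
        Y = deaths[:, :, _GENDER_INDEX[gender]].sum(axis=1)
    return AreaTable(strata.area_ids, Y.astype(int))
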