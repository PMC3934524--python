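"""Record types and readers for annual effort tables, per-set observer
records, and monthly climate-index files.

The annual effort/bycatch table for the 1999-2012 Western Mediterranean
surface-longline observer programme ships with the package (``load_table1``);
equivalent tables, per-set observer records, and agency-style monthly
climate-index files are read from delimited text.

Conventions: annual effort is stored in thousands of hooks, exactly as the
published table prints it; per-set effort (``SetRecord.hooks``) is a raw hook
count. Conversions between the two are always explicit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

GEARS = ("LLHB", "LLALB", "LLJAP")
"""Spanish surface-longline gear codes: swordfish (LLHB), albacore (LLALB),
and bluefin-tuna (LLJAP) targeting gears."""


class FormatError(ValueError):
    """A delimited file is structurally wrong (missing column, bad field)."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant (negative count, bad month)."""


@dataclass(frozen=True)
class YearRecord:
    """One year of observed effort and turtle bycatch.

    Attributes
    ----------
    year : int
        Calendar year of observation.
    hooks_thousands : float
        Observed hooks divided by 1000 (the effort unit of CPUE).
    loggerhead, leatherback : int
        Observed bycatch counts for each species.
    """

    year: int
    hooks_thousands: float
    loggerhead: int
    leatherback: int

    def __post_init__(self) -> None:
        if self.hooks_thousands < 0:
            raise ValidationError(f"year {self.year}: negative effort")
        if self.loggerhead < 0 or self.leatherback < 0:
            raise ValidationError(f"year {self.year}: negative bycatch count")


@dataclass(frozen=True)
class SetRecord:
    """One longline set from an observer record.

    ``hooks`` is the raw number of hooks in the set; ``south_of_40N`` flags
    the fishing region used to stratify the loggerhead analysis.
    """

    year: int
    gear: str
    south_of_40N: bool
    hooks: int
    loggerhead: int
    leatherback: int

    def __post_init__(self) -> None:
        if self.gear not in GEARS:
            raise ValidationError(f"unknown gear {self.gear!r}")
        if self.hooks <= 0:
            raise ValidationError(f"year {self.year}: hooks must be positive")
        if self.loggerhead < 0 or self.leatherback < 0:
            raise ValidationError(f"year {self.year}: negative bycatch count")


@dataclass(frozen=True)
class MonthlyIndexSeries:
    """Monthly values of a climate index (e.g. the NAO index).

    ``entries`` is a tuple of ``(year, month, value)`` sorted by
    (year, month); duplicates and out-of-range months are rejected.
    """

    entries: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for year, month, _ in self.entries:
            if not 1 <= month <= 12:
                raise ValidationError(f"month {month} out of range in year {year}")
            if (year, month) in seen:
                raise ValidationError(f"duplicate entry for {year}-{month:02d}")
            seen.add((year, month))
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: (e[0], e[1])))
        )

    @property
    def years(self) -> set[int]:
        return {year for year, _, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["year", "month", "value"])


_YEAR_COLUMNS = ["year", "hooks_thousands", "loggerhead", "leatherback"]
_SET_COLUMNS = ["year", "gear", "south_of_40N", "hooks", "loggerhead", "leatherback"]


def load_table1() -> list[YearRecord]:
    """Return the packaged 1999-2012 annual effort/bycatch table.

    The 14 records total 7889.711 thousand hooks, 3940 loggerhead and
    8 leatherback turtles.
    """
    text = resources.files("bycatchclim.data").joinpath("table1.csv").read_text()
    return read_year_records(io.StringIO(text))


def _check_columns(df: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")


def read_year_records(path) -> list[YearRecord]:
    """Read annual records from comma-delimited text with a header row.

    Row order is preserved. Raises :class:`FormatError` for a missing
    column or an unparseable field, :class:`ValidationError` for negative
    counts (with the offending row number) or duplicate years.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _YEAR_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = YearRecord(
                year=int(row.year),
                hooks_thousands=float(row.hooks_thousands),
                loggerhead=int(row.loggerhead),
                leatherback=int(row.leatherback),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise FormatError(f"row {i}: unparseable field ({exc})") from exc
        records.append(rec)
    years = [r.year for r in records]
    if len(set(years)) != len(years):
        raise ValidationError("duplicate years in annual record table")
    return records


def write_year_records(path, records: Iterable[YearRecord]) -> None:
    # repr() is the shortest round-trip representation, so read(write(x)) == x
    pd.DataFrame([vars(r) for r in records], columns=_YEAR_COLUMNS).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def read_set_records(path) -> list[SetRecord]:
    """Read per-set observer records from comma-delimited text."""
    df = pd.read_csv(path)
    _check_columns(df, _SET_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SetRecord(
                year=int(row.year),
                gear=str(row.gear),
                south_of_40N=_parse_bool(row.south_of_40N),
                hooks=int(row.hooks),
                loggerhead=int(row.loggerhead),
                leatherback=int(row.leatherback),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise FormatError(f"row {i}: unparseable field ({exc})") from exc
        records.append(rec)
    return records


def write_set_records(path, records: Iterable[SetRecord]) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_SET_COLUMNS).to_csv(
        path, index=False
    )


def aggregate_annual(records: Iterable[SetRecord]) -> list[YearRecord]:
    """Collapse per-set observer records to one YearRecord per year.

    Effort converts explicitly from raw hooks to thousands of hooks.
    """
    records = list(records)
    if not records:
        raise ValidationError("no set records to aggregate")
    df = pd.DataFrame(
        {
            "year": [r.year for r in records],
            "hooks": [r.hooks for r in records],
            "loggerhead": [r.loggerhead for r in records],
            "leatherback": [r.leatherback for r in records],
        }
    ).groupby("year").sum()
    return [
        YearRecord(
            year=int(year),
            hooks_thousands=row.hooks / 1000.0,
            loggerhead=int(row.loggerhead),
            leatherback=int(row.leatherback),
        )
        for year, row in df.iterrows()
    ]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_monthly_index(path) -> MonthlyIndexSeries:
    """Read a monthly climate-index file (year, month, value per row).

    Accepts either whitespace-delimited agency-style files or CSV, with or
    without a header line. Entries are returned sorted by (year, month).
    """
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError("expected at least three columns: year, month, value")
    df = df.iloc[:, :3]
    df.columns = ["year", "month", "value"]
    # tolerate one header line of column names
    if not str(df.iloc[0, 0]).lstrip("-").replace(".", "").isdigit():
        df = df.iloc[1:]
    if df.empty:
        return MonthlyIndexSeries(entries=())
    try:
        entries = tuple(
            (int(float(y)), int(float(m)), float(v))
            for y, m, v in df.itertuples(index=False)
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"unparseable monthly index row ({exc})") from exc
    return MonthlyIndexSeries(entries=entries)


def write_monthly_index(path, series: MonthlyIndexSeries) -> None:
    with open(path, "w") as fh:
        for year, month, value in series.entries:
            fh.write(f"{year} {month} {value:.3f}\n")
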