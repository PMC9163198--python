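"""Ingestion and reshaping of community abundance records.

The central object is :class:`AbundanceMatrix`, a gap-free monthly grid of
nonnegative abundances (time x unit), built from long-format count records by
taking the maximum count observed within each month and zero-filling months
with no record (an absence of counts is treated as a true absence).  From it
the module derives seasonal yearly series (warm season May-August; cold
season November-February straddling the year boundary), guild-summed
matrices, period splits around a management change, and biomass conversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SeasonalSeries",
    "GroupScheme",
    "BodyMassTable",
    "WARM_MONTHS",
    "COLD_MONTHS",
    "read_counts",
    "read_group_scheme",
    "read_body_masses",
    "build_monthly_matrix",
    "select_frequent",
    "group_sum",
    "seasonal_mean",
    "split_period",
    "to_biomass",
]

#: Months composing the warm season (May through August of one year).
WARM_MONTHS: tuple[int, ...] = (5, 6, 7, 8)
#: Months composing the cold season: November, December of year y and
#: January, February of year y+1; the season is labeled with year y.
COLD_MONTHS: tuple[int, ...] = (11, 12, 1, 2)

SEASONS = ("warm", "cold")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Monthly time x unit grid of nonnegative abundances with no gaps.

    ``data`` is a DataFrame indexed by a contiguous monthly ``PeriodIndex``
    with one float column per unit (species or group).  Absences are exact
    zeros, never missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise ValueError("AbundanceMatrix index must be a monthly PeriodIndex")
        if len(idx) == 0:
            raise ValueError("AbundanceMatrix must span at least one month")
        steps = np.diff(idx.asi8)
        if len(steps) and not np.all(steps == 1):
            raise ValueError("AbundanceMatrix months must be contiguous and increasing")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate unit labels")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("abundances must be finite (no missing cells)")
        if (vals < 0).any():
            raise ValueError("abundances must be nonnegative")

    # -- accessors ---------------------------------------------------------
    @property
    def times(self) -> pd.PeriodIndex:
        return self.data.index

    @property
    def units(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """(n_months, n_units) float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_months(self) -> int:
        return len(self.data.index)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        units: Sequence[str],
        start: str = "1981-01",
    ) -> "AbundanceMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        idx = pd.period_range(start=start, periods=values.shape[0], freq="M")
        return cls(pd.DataFrame(values, index=idx, columns=list(units)))

    # -- I/O ---------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long-format records (year, month, species, count), one per cell."""
        df = self.data.stack().rename("count").reset_index()
        df.columns = ["time", "species", "count"]
        df["year"] = df["time"].dt.year
        df["month"] = df["time"].dt.month
        return df[["year", "month", "species", "count"]]

    def write(self, path: str | Path, sep: str = "\t") -> None:
        out = self.data.copy()
        out.index = out.index.strftime("%Y-%m")
        out.index.name = "time"
        out.to_csv(path, sep=sep)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = pd.PeriodIndex(df.index, freq="M")
        df.index.name = None
        return cls(df)


@dataclass(frozen=True)
class SeasonalSeries:
    """Year x unit grid of seasonal mean abundances for one season.

    ``period`` tags which slice of the study the series covers (``all`` or a
    label such as ``pre2006``/``post2006`` produced by :func:`split_period`).
    """

    data: pd.DataFrame  # index: season-years (int), columns: units
    season: str
    period: str = "all"

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        years = np.asarray(self.data.index)
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("season-years must be strictly increasing")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("seasonal means must be finite and nonnegative")

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=int)

    @property
    def units(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_years(self) -> int:
        return len(self.data.index)

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        units: Sequence[str] | None = None,
        season: str = "warm",
        period: str = "all",
        start_year: int = 1981,
    ) -> "SeasonalSeries":
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if units is None:
            units = [f"u{i+1}" for i in range(values.shape[1])]
        years = np.arange(start_year, start_year + values.shape[0])
        return cls(pd.DataFrame(values, index=years, columns=list(units)), season, period)


@dataclass(frozen=True)
class GroupScheme:
    """Assignment of unit labels to groups (e.g. species to guilds).

    Units absent from ``mapping`` are excluded when the scheme is applied.
    """

    name: str
    mapping: Mapping[str, str]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)


@dataclass(frozen=True)
class BodyMassTable:
    """Species -> mean body mass in grams."""

    masses: Mapping[str, float]

    def __post_init__(self) -> None:
        for sp, m in self.masses.items():
            if not (float(m) > 0):
                raise ValueError(f"body mass for {sp!r} must be positive, got {m}")

    def __getitem__(self, species: str) -> float:
        return float(self.masses[species])

    def __contains__(self, species: str) -> bool:
        return species in self.masses


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read long-format count records (columns year, month, species, count).

    ``sep=None`` sniffs comma vs tab.  Records are validated: integer months
    in 1..12, nonnegative counts.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"year", "month", "species", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return _validate_records(df)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    df["species"] = df["species"].astype(str)
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise ValueError("month outside 1..12 in count records")
    counts = pd.to_numeric(df["count"])
    if (counts < 0).any():
        raise ValueError("negative counts in records")
    df["count"] = counts.astype(float)
    return df


def read_group_scheme(path: str | Path, name: str | None = None, sep: str | None = None) -> GroupScheme:
    """Two-column delimited table (species, group) -> :class:`GroupScheme`."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    sp_col, gr_col = df.columns[:2]
    mapping = dict(zip(df[sp_col].astype(str), df[gr_col].astype(str)))
    return GroupScheme(name or Path(path).stem, mapping)


def read_body_masses(path: str | Path, sep: str | None = None) -> BodyMassTable:
    """Two-column delimited table (species, mass_g) -> :class:`BodyMassTable`."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    sp_col, m_col = df.columns[:2]
    return BodyMassTable(dict(zip(df[sp_col].astype(str), df[m_col].astype(float))))


# ---------------------------------------------------------------------------
# matrix construction and transforms
# ---------------------------------------------------------------------------

def build_monthly_matrix(
    records: pd.DataFrame | Iterable[tuple],
    species_universe: Sequence[str] | None = None,
    time_range: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> AbundanceMatrix:
    """Reduce raw count records to a monthly snapshot matrix.

    Within each (month, species) cell the *maximum* observed count is kept --
    repeated surveys within a month never sum.  The grid is completed over
    ``species_universe`` x ``time_range`` and months without any record for a
    species become exact zeros.

    Parameters
    ----------
    records
        DataFrame with columns year, month, species, count, or an iterable of
        (year, month, species, count) tuples.  May be empty.
    species_universe
        Ordered unit labels of the output; defaults to the sorted species
        observed in ``records``.
    time_range
        ((year, month), (year, month)) inclusive bounds; defaults to the span
        of the records.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=["year", "month", "species", "count"])
    if len(records):
        records = _validate_records(records)

    if time_range is None:
        if not len(records):
            raise ValueError("empty records require an explicit time_range")
        per = pd.PeriodIndex.from_fields(year=records["year"], month=records["month"], freq="M")
        start, stop = per.min(), per.max()
    else:
        (y0, m0), (y1, m1) = time_range
        start = pd.Period(year=y0, month=m0, freq="M")
        stop = pd.Period(year=y1, month=m1, freq="M")
    if stop < start:
        raise ValueError("time_range end precedes start")
    idx = pd.period_range(start, stop, freq="M")

    if species_universe is None:
        if not len(records):
            raise ValueError("empty records require an explicit species_universe")
        species_universe = sorted(records["species"].unique())
    if len(species_universe) == 0:
        raise ValueError("species_universe must be nonempty")

    grid = pd.DataFrame(0.0, index=idx, columns=list(species_universe))
    if len(records):
        records = records[records["species"].isin(species_universe)]
        per = pd.PeriodIndex.from_fields(year=records["year"], month=records["month"], freq="M")
        in_range = (per >= start) & (per <= stop)
        records = records.loc[np.asarray(in_range)]
        per = per[np.asarray(in_range)]
        if len(records):
            cell_max = (
                records.assign(time=per)
                .groupby(["time", "species"], observed=True)["count"]
                .max()
                .unstack(fill_value=0.0)
            )
            grid.loc[cell_max.index, cell_max.columns] = cell_max
    return AbundanceMatrix(grid)


def select_frequent(matrix: AbundanceMatrix, k: int) -> AbundanceMatrix:
    """Keep the ``k`` most frequent units.

    Frequency is the number of months with a nonzero abundance; ties are
    broken by total summed abundance and then by label order, making the
    selection deterministic.
    """
    if k < 1 or k > len(matrix.units):
        raise ValueError(f"k must be in 1..{len(matrix.units)}, got {k}")
    occ = (matrix.data > 0).sum(axis=0)
    tot = matrix.data.sum(axis=0)
    order = sorted(matrix.units, key=lambda u: (-occ[u], -tot[u], u))
    keep = order[:k]
    # preserve the original column order among the retained units
    kept = [u for u in matrix.units if u in set(keep)]
    return AbundanceMatrix(matrix.data[kept])


def group_sum(matrix: AbundanceMatrix, scheme: GroupScheme) -> AbundanceMatrix:
    """Sum member species within each group, month by month.

    Species the scheme does not map are dropped.  Grouping happens on the
    monthly matrix, i.e. *before* any seasonal averaging, so that seasonal
    means of a group equal the mean of the summed monthly series.
    """
    present = [u for u in matrix.units if u in scheme.mapping]
    if not present:
        raise ValueError(f"group scheme {scheme.name!r} maps no unit present in the matrix")
    cols = {}
    for g in scheme.groups():
        members = [u for u in present if scheme.mapping[u] == g]
        if members:
            cols[g] = matrix.data[members].sum(axis=1)
    return AbundanceMatrix(pd.DataFrame(cols, index=matrix.times))


def seasonal_mean(matrix: AbundanceMatrix, season: str) -> SeasonalSeries:
    """Average monthly abundances over one season per year.

    The warm season of year y covers May-August of y; the cold season of
    year y covers November-December of y plus January-February of y+1 (the
    season is labeled with the November year).  Seasons with fewer than four
    months inside the matrix span are dropped so that every seasonal mean
    averages the same number of months.
    """
    if season not in SEASONS:
        raise ValueError(f"season must be one of {SEASONS}")
    months = matrix.times.month
    years = matrix.times.year
    if season == "warm":
        sel = np.isin(months, WARM_MONTHS)
        season_year = years[sel]
    else:
        sel = np.isin(months, COLD_MONTHS)
        # Jan/Feb belong to the cold season labeled with the previous year.
        season_year = np.where(months[sel] <= 2, years[sel] - 1, years[sel])
    sub = matrix.data.loc[np.asarray(sel)]
    if not len(sub):
        raise ValueError(f"matrix contains no {season}-season months")
    grouped = sub.groupby(season_year)
    counts = grouped.size()
    complete = counts.index[counts == 4]
    if len(complete) == 0:
        raise ValueError(f"matrix spans no complete {season} season")
    means = grouped.mean().loc[complete]
    means.index = means.index.astype(int)
    return SeasonalSeries(means, season=season, period="all")


def split_period(
    series: SeasonalSeries, cut_year: int = 2006
) -> tuple[SeasonalSeries, SeasonalSeries]:
    """Split a seasonal series at ``cut_year`` (half-open: the cut year
    belongs to the *post* period)."""
    pre_mask = series.years < cut_year
    pre = SeasonalSeries(series.data.loc[pre_mask], series.season, f"pre{cut_year}")
    post = SeasonalSeries(series.data.loc[~pre_mask], series.season, f"post{cut_year}")
    if pre.n_years == 0 or post.n_years == 0:
        warnings.warn(
            f"split at {cut_year} leaves an empty period "
            f"(pre={pre.n_years} years, post={post.n_years} years)",
            stacklevel=2,
        )
    return pre, post


def to_biomass(matrix: AbundanceMatrix, masses: BodyMassTable | Mapping[str, float]) -> AbundanceMatrix:
    """Convert counts to biomass (grams) by per-species body mass."""
    if not isinstance(masses, BodyMassTable):
        masses = BodyMassTable(dict(masses))
    missing = [u for u in matrix.units if u not in masses]
    if missing:
        raise KeyError(f"no body mass for species: {missing}")
    factors = np.array([masses[u] for u in matrix.units])
    return AbundanceMatrix(matrix.data * factors)
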