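"""Data model and I/O for cross-country life-expectancy panels.

The canonical input is a long CSV with one row per (location, year, sex, age)
holding remaining life expectancy ``ex`` in years, in the style of abridged
life-table extracts from the UN World Population Prospects: columns
``location, iso_code, year, sex, age, ex, population`` (``iso_code`` and
``population`` optional). All downstream analysis consumes a validated
:class:`LifePanel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Ages (exact years) at which remaining life expectancy is analysed.
SUPPORTED_AGES: tuple[int, ...] = (0, 5, 15, 35, 50, 70)

#: Upper bound on plausible remaining life expectancy, in years.
EX_MAX = 110.0

_SEX_ALIASES = {"female": "female", "f": "female", "male": "male", "m": "male"}

REQUIRED_COLUMNS = ("location", "year", "sex", "age", "ex")
OPTIONAL_COLUMNS = ("iso_code", "population")


class PanelFormatError(ValueError):
    """A panel file is structurally unusable (missing column, no valid rows)."""


class RegionConfigError(ValueError):
    """A region-mapping config is empty or self-contradictory."""


def normalize_sex(value: object) -> str:
    """Map a sex label ({female, f, male, m}, any case) to 'female'/'male'.

    Raises ValueError for anything else.
    """
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognized sex label: {value!r}")
    return _SEX_ALIASES[key]


@dataclass(frozen=True)
class LifeExpectancyRecord:
    """One (location, year, sex, age) observation of remaining life expectancy."""

    location: str
    year: int
    sex: str
    age: int
    ex: float
    iso_code: str | None = None
    population: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if self.age not in SUPPORTED_AGES:
            raise ValueError(f"unsupported age {self.age}; expected one of {SUPPORTED_AGES}")
        if not (0.0 < self.ex < EX_MAX):
            raise ValueError(f"life expectancy {self.ex} outside (0, {EX_MAX})")
        if self.population is not None and self.population < 0:
            raise ValueError("population must be non-negative")


@dataclass
class LifePanel:
    """A validated collection of life-expectancy observations.

    Backed by a pandas DataFrame with columns
    ``location, iso_code, year, sex, age, ex, population`` and unique
    (location, year, sex, age) keys. ``rejections`` counts input rows dropped
    at read time, by reason; ``dropped_cells`` counts (location, year, age)
    cells removed by :func:`complete_panel` because one sex was missing.
    """

    data: pd.DataFrame
    rejections: dict[str, int] = field(default_factory=dict)
    dropped_cells: int = 0

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("iso_code", "population"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"panel missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise PanelFormatError("panel contains no valid rows")
        df["year"] = df["year"].astype(int)
        df["age"] = df["age"].astype(int)
        df["ex"] = df["ex"].astype(float)
        df["sex"] = df["sex"].map(normalize_sex)
        dupes = df.duplicated(subset=["location", "year", "sex", "age"])
        if dupes.any():
            raise PanelFormatError(
                f"{int(dupes.sum())} duplicate (location, year, sex, age) key(s)"
            )
        self.data = df[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)].reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def ages(self) -> list[int]:
        return sorted(self.data["age"].unique().tolist())

    @property
    def locations(self) -> list[str]:
        return sorted(self.data["location"].unique().tolist())

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> Iterable[LifeExpectancyRecord]:
        for row in self.data.itertuples(index=False):
            yield LifeExpectancyRecord(
                location=row.location,
                year=row.year,
                sex=row.sex,
                age=row.age,
                ex=row.ex,
                iso_code=None if pd.isna(row.iso_code) else str(row.iso_code),
                population=None if pd.isna(row.population) else float(row.population),
            )

    def population_2019_style(self, year: int) -> pd.Series:
        """Population per location in ``year`` (NaN when unknown)."""
        sub = self.data[self.data["year"] == year]
        return sub.groupby("location")["population"].first()


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating record invariants; count rejections by reason."""
    rejections: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)

    sex_norm = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    bad = sex_norm.isna() & keep
    if bad.any():
        rejections["invalid_sex"] = int(bad.sum())
        keep &= ~bad
    df = df.assign(sex=sex_norm)

    ex = pd.to_numeric(df["ex"], errors="coerce")
    bad = (~((ex > 0) & (ex < EX_MAX)) | ex.isna()) & keep
    if bad.any():
        rejections["ex_out_of_range"] = int(bad.sum())
        keep &= ~bad
    df = df.assign(ex=ex)

    age = pd.to_numeric(df["age"], errors="coerce")
    bad = (~age.isin(SUPPORTED_AGES)) & keep
    if bad.any():
        rejections["unsupported_age"] = int(bad.sum())
        keep &= ~bad

    year = pd.to_numeric(df["year"], errors="coerce")
    bad = year.isna() & keep
    if bad.any():
        rejections["invalid_year"] = int(bad.sum())
        keep &= ~bad

    if "population" in df.columns:
        pop = pd.to_numeric(df["population"], errors="coerce")
        bad = (pop < 0) & keep
        if bad.any():
            rejections["negative_population"] = int(bad.sum())
            keep &= ~bad
        df = df.assign(population=pop)

    return df[keep], rejections


def read_panel(path: str | Path, dialect: str = "long_csv") -> LifePanel:
    """Read a long-CSV life-expectancy panel and validate it.

    Rows violating record invariants (non-positive or implausible ``ex``,
    unknown sex label, unsupported age) are rejected and counted per reason in
    ``panel.rejections``; sex labels are normalized case-insensitively from
    {female, f} / {male, m}.
    """
    if dialect != "long_csv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    valid, rejections = _validate_rows(df)
    if rejections:
        logger.warning("read_panel: rejected rows by reason: %s", rejections)
    if len(valid) == 0:
        raise PanelFormatError(f"{path.name}: no valid rows after validation")
    return LifePanel(valid, rejections=rejections)


def write_panel(panel: LifePanel, path: str | Path, float_format: str = "%.6f") -> None:
    """Write a panel back to the long-CSV dialect."""
    panel.data.to_csv(path, index=False, float_format=float_format)


def complete_panel(panel: LifePanel) -> LifePanel:
    """Restrict to (location, year, age) cells where both sexes are present.

    Ratios need both sexes; incomplete cells are dropped and counted in the
    returned panel's ``dropped_cells`` (idempotent on complete panels).
    """
    df = panel.data
    n_sexes = df.groupby(["location", "year", "age"])["sex"].transform("nunique")
    complete = df[n_sexes == 2]
    n_cells = len(df.groupby(["location", "year", "age"]))
    n_kept = len(complete.groupby(["location", "year", "age"])) if len(complete) else 0
    dropped = n_cells - n_kept
    if dropped:
        logger.info("complete_panel: dropped %d incomplete (location, year, age) cell(s)", dropped)
    return LifePanel(complete.reset_index(drop=True), rejections=dict(panel.rejections),
                     dropped_cells=dropped)


@dataclass(frozen=True)
class RegionMap:
    """Mapping from location label (or ISO code) to region label."""

    mapping: Mapping[str, str]
    scheme: str = "CIH 3.0"

    def region_of(self, location: str) -> str | None:
        return self.mapping.get(location)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def unmapped(self, locations: Iterable[str]) -> list[str]:
        return sorted(loc for loc in set(locations) if loc not in self.mapping)


def read_region_map(path: str | Path, scheme: str = "CIH 3.0") -> RegionMap:
    """Read a location-to-region map from YAML (flat dict) or two-column CSV.

    Duplicate locations mapped to conflicting regions raise
    :class:`RegionConfigError`.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw:
            raise RegionConfigError(f"{path.name}: empty region config")
        if not isinstance(raw, dict):
            raise RegionConfigError(f"{path.name}: expected a flat location: region mapping")
        pairs = [(str(k), str(v)) for k, v in raw.items()]
    else:
        df = pd.read_csv(path)
        if df.empty or df.shape[1] < 2:
            raise RegionConfigError(f"{path.name}: expected two columns (location, region)")
        pairs = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    mapping: dict[str, str] = {}
    for loc, region in pairs:
        if not region or not str(region).strip():
            raise RegionConfigError(f"{path.name}: empty region label for {loc!r}")
        if loc in mapping and mapping[loc] != region:
            raise RegionConfigError(
                f"{path.name}: {loc!r} mapped to both {mapping[loc]!r} and {region!r}"
            )
        mapping[loc] = region
    if not mapping:
        raise RegionConfigError(f"{path.name}: empty region config")
    return RegionMap(mapping=mapping, scheme=scheme)
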