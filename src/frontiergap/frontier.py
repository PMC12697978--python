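"""Frontier estimation: upper-percentile benchmarks of life expectancy by sex.

The frontier for a (year, age) is, per sex, the (1 - p) empirical quantile of
the cross-country distribution of remaining life expectancy — by default the
upper 5th percentile (p = 0.05), computed with linear interpolation between
order statistics (the "type 7" convention). Countries at or above the
sex-specific frontier value are frontier members; the female and male member
sets may differ. The frontier sex ratio R* = Lf*/Lm* is the benchmark against
which country sex ratios are adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import LifePanel

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few locations to estimate a frontier."""


@dataclass(frozen=True)
class FrontierBenchmark:
    """Sex-specific frontier life expectancies and ratio for one (year, age).

    Attributes
    ----------
    lf_star, lm_star : float
        Female and male frontier remaining life expectancies, in years.
    r_star : float
        Frontier sex ratio, ``lf_star / lm_star``.
    percentile : float
        Upper-tail fraction used (0.05 means "top 5%").
    female_members, male_members : tuple of str
        Locations with life expectancy at or above the sex-specific frontier.
    """

    year: int
    age: int
    lf_star: float
    lm_star: float
    percentile: float
    female_members: tuple[str, ...] = field(default_factory=tuple)
    male_members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.lf_star <= 0 or self.lm_star <= 0:
            raise ValueError("frontier life expectancies must be positive")

    @property
    def r_star(self) -> float:
        return self.lf_star / self.lm_star

    @property
    def gap(self) -> float:
        """Frontier female-minus-male gap in years."""
        return self.lf_star - self.lm_star


def _sex_values(panel: LifePanel, year: int, age: int,
                min_population: float | None) -> pd.DataFrame:
    """Wide (location x {female, male}) ex table for one (year, age) cell."""
    sub = panel.data[(panel.data["year"] == year) & (panel.data["age"] == age)]
    wide = sub.pivot(index="location", columns="sex", values="ex").dropna()
    if min_population is not None:
        pop = sub.groupby("location")["population"].first()
        known = pop.reindex(wide.index)
        unknown = known.isna()
        if unknown.any():
            logger.warning(
                "frontier: %d location(s) with unknown population excluded from "
                "population-filtered frontier", int(unknown.sum()))
        wide = wide[(known >= min_population).fillna(False)]
    return wide


def estimate_frontier(panel: LifePanel, year: int, age: int,
                      percentile: float = 0.05,
                      min_population: float | None = None) -> FrontierBenchmark:
    """Estimate the sex-specific frontier benchmark for one (year, age).

    Parameters
    ----------
    percentile : float
        Upper-tail fraction p in (0, 0.5); the frontier is the (1 - p)
        quantile of each sex's cross-country life-expectancy distribution,
        linearly interpolated on the sorted values.
    min_population : float, optional
        When given, locations with population below it (or unknown) are
        excluded from the distribution before the quantile is taken — the
        "population at least 5 million" frontier variant.
    """
    if not (0.0 < percentile < 0.5):
        raise ValueError(f"percentile must be in (0, 0.5), got {percentile}")
    wide = _sex_values(panel, year, age, min_population)
    if len(wide) < 2:
        raise InsufficientDataError(
            f"need >= 2 locations with both sexes at (year={year}, age={age}); "
            f"found {len(wide)}")
    q = 1.0 - percentile
    lf_star = float(np.quantile(wide["female"].to_numpy(), q))
    lm_star = float(np.quantile(wide["male"].to_numpy(), q))
    female_members = tuple(sorted(wide.index[wide["female"] >= lf_star]))
    male_members = tuple(sorted(wide.index[wide["male"] >= lm_star]))
    return FrontierBenchmark(
        year=year, age=age, lf_star=lf_star, lm_star=lm_star,
        percentile=percentile,
        female_members=female_members, male_members=male_members,
    )


def frontier_schedule(panel: LifePanel, year: int, percentile: float = 0.05,
                      min_population: float | None = None,
                      ages: list[int] | None = None) -> list[FrontierBenchmark]:
    """One :class:`FrontierBenchmark` per age present in the panel for ``year``."""
    if ages is None:
        ages = sorted(panel.data.loc[panel.data["year"] == year, "age"].unique())
    return [estimate_frontier(panel, year, age, percentile, min_population)
            for age in ages]


def schedule_frame(benchmarks: list[FrontierBenchmark]) -> pd.DataFrame:
    """Tabulate benchmarks: year, age, lf_star, lm_star, r_star, members."""
    return pd.DataFrame(
        {
            "year": [b.year for b in benchmarks],
            "age": [b.age for b in benchmarks],
            "lf_star": [b.lf_star for b in benchmarks],
            "lm_star": [b.lm_star for b in benchmarks],
            "r_star": [b.r_star for b in benchmarks],
            "percentile": [b.percentile for b in benchmarks],
            "n_female_members": [len(b.female_members) for b in benchmarks],
            "n_male_members": [len(b.male_members) for b in benchmarks],
            "female_members": [";".join(b.female_members) for b in benchmarks],
            "male_members": [";".join(b.male_members) for b in benchmarks],
        }
    )
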