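"""Synthetic life-expectancy panels with known ground truth.

Generates long-format panels that mimic a WPP-style abridged life-table
extract: ~200 locations, remaining life expectancy by sex at ages
0/5/15/35/50/70, a female-male gap whose relative size widens with age, and
optional injected country-level deficits for one sex, so that frontier
estimation, adjustment, and classification can be tested without any
download.

The default age schedule and sex-gap profile are anchored to the 2019
cross-country frontier regime: female life expectancy at birth spread over
roughly 55-87 years, remaining life expectancy decaying to ~22% of e0 by age
70, and a ~4.3-year gap at birth shrinking to ~3.0 years at age 70 — which
puts the frontier sex ratio near 1.05 at birth and near 1.19 at age 70.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import SUPPORTED_AGES, LifePanel

#: Remaining-ex fraction of female e0 by age (2019 frontier-like schedule).
DEFAULT_AGE_DECAY: dict[int, float] = {
    0: 1.0, 5: 0.946, 15: 0.830, 35: 0.599, 50: 0.430, 70: 0.220,
}

#: Per-age multiplier on the female-male gap at birth. The absolute gap
#: shrinks slightly with age while remaining life expectancy shrinks faster,
#: so the *relative* gap (and hence the sex ratio) widens with age.
DEFAULT_GAP_PROFILE: dict[int, float] = {
    0: 1.0, 5: 1.023, 15: 1.023, 35: 0.953, 50: 0.930, 70: 0.698,
}


class GenerationError(ValueError):
    """The configuration would produce a non-positive life expectancy."""


@dataclass(frozen=True)
class Disadvantage:
    """An injected deficit: ``years`` subtracted from one sex's ex at all ages."""

    location_index: int
    sex: str
    years: float


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic panel generator.

    Attributes
    ----------
    n_locations : int
        Number of countries/territories.
    years : sequence of int
        Calendar years to generate (cross-sections are independent draws of
        noise around the same schedules).
    ages : sequence of int
        Exact ages for remaining life expectancy.
    base_e0_range : (float, float)
        Interval (years) over which female life expectancy at birth is spread
        evenly across locations.
    age_decay : mapping age -> fraction
        Expected remaining ex at each age as a fraction of female e0.
    sex_gap_at_birth : float
        Mean female-minus-male gap at birth, years.
    gap_age_profile : mapping age -> multiplier
        Scales the birth gap at each age.
    gap_mode : {"absolute", "proportional"}
        "absolute": the gap in years is the same for every location, so
        lower-longevity countries mechanically carry higher sex ratios (the
        realistic regime). "proportional": the gap scales with each
        location's life expectancy, so every location shares exactly the
        frontier sex ratio — the parity construction used to test that a
        panel with no avoidable inequality classifies as no-disadvantage
        everywhere.
    noise_sd : float
        SD (years) of one Gaussian level shift drawn per (location, sex) and
        applied at every age, keeping the age schedule perfectly correlated
        within a location.
    injected_disadvantage : sequence of Disadvantage
        Deficits subtracted from the designated sex's ex at all ages.
    population_range : (float, float)
        Log10-uniform range of location populations (persons).
    seed : int
        Seed for all randomness; panels are bit-identical per seed.
    """

    n_locations: int = 200
    years: Sequence[int] = (2019,)
    ages: Sequence[int] = SUPPORTED_AGES
    base_e0_range: tuple[float, float] = (55.0, 87.0)
    age_decay: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DECAY))
    sex_gap_at_birth: float = 4.3
    gap_age_profile: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_GAP_PROFILE))
    gap_mode: Literal["absolute", "proportional"] = "absolute"
    noise_sd: float = 0.5
    injected_disadvantage: Sequence[Disadvantage] = ()
    population_range: tuple[float, float] = (1e5, 1.4e9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("need at least 2 locations")
        lo, hi = self.base_e0_range
        if not (0 < lo <= hi):
            raise ValueError("base_e0_range must be positive and ordered")
        missing = [a for a in self.ages if a not in self.age_decay]
        if missing:
            raise ValueError(f"age_decay missing ages: {missing}")
        missing = [a for a in self.ages if a not in self.gap_age_profile]
        if missing:
            raise ValueError(f"gap_age_profile missing ages: {missing}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for d in self.injected_disadvantage:
            if not (0 <= d.location_index < self.n_locations):
                raise ValueError(f"location_index {d.location_index} out of range")
            if d.sex not in ("female", "male"):
                raise ValueError(f"invalid sex in injected disadvantage: {d.sex!r}")


def generate(config: SyntheticConfig) -> LifePanel:
    """Generate a panel from ``config``; deterministic given ``config.seed``.

    Raises :class:`GenerationError` naming the first offending cell if any
    generated life expectancy would be non-positive.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_locations
    locations = [f"Synthland-{i:03d}" for i in range(n)]
    iso_codes = [f"SYN{i:03d}" for i in range(n)]

    lo, hi = config.base_e0_range
    # Evenly spread base levels so the cross-country distribution (and its
    # upper quantile) is stable across n; noise supplies the randomness.
    base_e0 = np.linspace(lo, hi, n)
    rng.shuffle(base_e0)

    log_lo, log_hi = np.log10(config.population_range[0]), np.log10(config.population_range[1])
    population = 10 ** rng.uniform(log_lo, log_hi, size=n)

    deficits = {"female": np.zeros(n), "male": np.zeros(n)}
    for d in config.injected_disadvantage:
        deficits[d.sex][d.location_index] += d.years

    rows: list[dict] = []
    for year in config.years:
        # one level shift per (location, sex): ages stay perfectly correlated
        noise = {
            "female": rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n),
            "male": rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n),
        }
        for age in config.ages:
            decay = config.age_decay[age]
            gap = config.sex_gap_at_birth * config.gap_age_profile[age]
            ex_f_sched = base_e0 * decay
            if config.gap_mode == "proportional":
                # same relative gap everywhere: Lm = Lf / (frontier-like ratio)
                ratio = (hi * decay) / (hi * decay - gap)
                ex_m_sched = ex_f_sched / ratio
            else:
                ex_m_sched = ex_f_sched - gap
            for sex, sched in (("female", ex_f_sched), ("male", ex_m_sched)):
                ex = sched + noise[sex] - deficits[sex]
                bad = np.nonzero(ex <= 0)[0]
                if bad.size:
                    i = int(bad[0])
                    raise GenerationError(
                        f"non-positive ex at (location={locations[i]}, year={year}, "
                        f"sex={sex}, age={age}): {ex[i]:.3f}")
                for i in range(n):
                    rows.append({
                        "location": locations[i],
                        "iso_code": iso_codes[i],
                        "year": year,
                        "sex": sex,
                        "age": age,
                        "ex": float(ex[i]),
                        "population": float(population[i]),
                    })
    return LifePanel(pd.DataFrame(rows))
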