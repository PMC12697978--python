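"""Raw and adjusted sex ratios, buffers, and disadvantage classification.

A country's sex ratio R = Lf/Lm is divided by the frontier ratio R* to give
the adjusted ratio N = R/R*, read as the avoidable component of the sex gap:
N > 1 indicates male disadvantage, N < 1 female disadvantage. Because a
ratio slightly off 1 can reflect negligible absolute differences, a buffer
(L, U) around 1 is constructed — by default from a half-year increase in the
frontier life expectancies — inside which neither sex is labelled
disadvantaged. The difference-space analogs use (Lf - Lm) minus the frontier
gap with a +/-0.5-year buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .frontier import FrontierBenchmark, frontier_schedule
from .panel_io import LifePanel

FEMALE_DISADVANTAGE = "female_disadvantage"
MALE_DISADVANTAGE = "male_disadvantage"
NO_DISADVANTAGE = "none"

LABELS = (FEMALE_DISADVANTAGE, MALE_DISADVANTAGE, NO_DISADVANTAGE)


class BufferMethod(str, Enum):
    """How the no-disadvantage interval around N = 1 is constructed."""

    HALF_YEAR_INCREASE = "half_year_increase"
    ONE_YEAR_DECREASE = "one_year_decrease"
    CENTRAL_30PCT = "central_30pct"
    FIXED_0_99_1_01 = "fixed_0.99_1.01"

    @classmethod
    def coerce(cls, value: "BufferMethod | str") -> "BufferMethod":
        if isinstance(value, cls):
            return value
        aliases = {
            "half_year": cls.HALF_YEAR_INCREASE,
            "one_year": cls.ONE_YEAR_DECREASE,
            "central30": cls.CENTRAL_30PCT,
            "fixed": cls.FIXED_0_99_1_01,
        }
        key = str(value).strip().lower()
        if key in aliases:
            return aliases[key]
        return cls(key)


@dataclass(frozen=True)
class Buffer:
    """Classification boundaries (L, U) around adjusted-ratio parity for one age.

    ``lower < 1 < upper`` always; values in [L, U] (boundaries included)
    classify as no disadvantage.
    """

    year: int
    age: int
    lower: float
    upper: float
    method: BufferMethod

    def __post_init__(self) -> None:
        if not (self.lower < 1.0 < self.upper):
            raise ValueError(
                f"buffer must straddle 1: got L={self.lower}, U={self.upper} "
                f"(year={self.year}, age={self.age}, method={self.method.value})")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def compute_sex_ratio(lf: float, lm: float) -> float:
    """Raw sex ratio R = lf/lm of female over male life expectancy."""
    if lf <= 0 or lm <= 0:
        raise ValueError("life expectancies must be positive")
    return lf / lm


def compute_adjusted_ratio(ratio: float, r_star: float) -> float:
    """Adjusted ratio N = R/R*; >1 male disadvantage, <1 female disadvantage."""
    if ratio <= 0 or r_star <= 0:
        raise ValueError("ratios must be positive")
    return ratio / r_star


def frontier_progress(ex: float, frontier_ex: float) -> float:
    """Fraction of the sex-specific frontier a country has attained (ex / ex*)."""
    if ex <= 0 or frontier_ex <= 0:
        raise ValueError("life expectancies must be positive")
    return ex / frontier_ex


def compute_adjusted_difference(lf: float, lm: float,
                                benchmark: FrontierBenchmark) -> float:
    """Difference-space analog: (lf - lm) minus the frontier gap, in years.

    Positive values indicate male disadvantage, negative female disadvantage.
    """
    return (lf - lm) - benchmark.gap


def compute_buffer(benchmark: FrontierBenchmark,
                   method: BufferMethod | str = BufferMethod.HALF_YEAR_INCREASE,
                   panel: LifePanel | None = None,
                   central_fraction: float = 0.30) -> Buffer:
    """Construct the no-disadvantage buffer for one (year, age) benchmark.

    Methods
    -------
    half_year_increase
        U = ((Lf*+0.5)/Lm*)/R* = (Lf*+0.5)/Lf*; L = (Lf*/(Lm*+0.5))/R*
        = Lm*/(Lm*+0.5). A half-year perturbation is a larger share of the
        smaller remaining life expectancies at older ages, so the buffer
        widens with age.
    one_year_decrease
        U = Lm*/(Lm*-1); L = (Lf*-1)/Lf*.
    fixed_0.99_1.01
        Absolute bounds L = 0.99, U = 1.01 regardless of age.
    central_30pct
        Bounds enclosing the ``central_fraction`` of the panel's adjusted
        ratios nearest 1 (rank by |N-1|, take the smallest 30% rounded to the
        nearest count, use their min/max). Requires ``panel``.
    """
    method = BufferMethod.coerce(method)
    lf, lm = benchmark.lf_star, benchmark.lm_star
    if method is BufferMethod.HALF_YEAR_INCREASE:
        upper = (lf + 0.5) / lf
        lower = lm / (lm + 0.5)
    elif method is BufferMethod.ONE_YEAR_DECREASE:
        if lm <= 1.0 or lf <= 1.0:
            raise ValueError("one_year_decrease needs frontier life expectancies > 1 year")
        upper = lm / (lm - 1.0)
        lower = (lf - 1.0) / lf
    elif method is BufferMethod.FIXED_0_99_1_01:
        lower, upper = 0.99, 1.01
    elif method is BufferMethod.CENTRAL_30PCT:
        if panel is None:
            raise ValueError("central_30pct buffer requires the panel")
        adjusted = _adjusted_ratios_for_cell(panel, benchmark)
        n_take = int(round(central_fraction * len(adjusted)))
        n_take = max(n_take, 1)
        central = adjusted.iloc[(adjusted - 1.0).abs().argsort()[:n_take]]
        lower, upper = float(central.min()), float(central.max())
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown buffer method: {method}")
    return Buffer(year=benchmark.year, age=benchmark.age,
                  lower=lower, upper=upper, method=method)


def _adjusted_ratios_for_cell(panel: LifePanel,
                              benchmark: FrontierBenchmark) -> pd.Series:
    sub = panel.data[(panel.data["year"] == benchmark.year)
                     & (panel.data["age"] == benchmark.age)]
    wide = sub.pivot(index="location", columns="sex", values="ex").dropna()
    return (wide["female"] / wide["male"]) / benchmark.r_star


def classify(adjusted_ratio: float, buffer: Buffer) -> str:
    """Label one adjusted ratio against a buffer (boundary ties -> none)."""
    if adjusted_ratio > buffer.upper:
        return MALE_DISADVANTAGE
    if adjusted_ratio < buffer.lower:
        return FEMALE_DISADVANTAGE
    return NO_DISADVANTAGE


def classify_difference(adjusted_difference: float,
                        halfwidth: float = 0.5) -> str:
    """Difference-space classification with a +/-``halfwidth``-year buffer."""
    if adjusted_difference > halfwidth:
        return MALE_DISADVANTAGE
    if adjusted_difference < -halfwidth:
        return FEMALE_DISADVANTAGE
    return NO_DISADVANTAGE


def evaluate_panel(panel: LifePanel,
                   percentile: float = 0.05,
                   buffer_method: BufferMethod | str = BufferMethod.HALF_YEAR_INCREASE,
                   min_population: float | None = None,
                   difference_halfwidth: float = 0.5,
                   years: list[int] | None = None,
                   ages: list[int] | None = None) -> pd.DataFrame:
    """Run the full four-step pipeline over every (location, year, age).

    The frontier and buffer are computed once per (year, age) and shared by
    all locations. Returns one row per (location, year, age) with columns:
    location, year, age, lf, lm, ratio, adjusted_ratio, difference,
    adjusted_difference, lf_star, lm_star, r_star, buffer_lower,
    buffer_upper, classification, classification_difference.
    """
    buffer_method = BufferMethod.coerce(buffer_method)
    if years is None:
        years = panel.years
    frames: list[pd.DataFrame] = []
    for year in years:
        year_ages = ages
        if year_ages is None:
            year_ages = sorted(
                panel.data.loc[panel.data["year"] == year, "age"].unique())
        for benchmark in frontier_schedule(panel, year, percentile,
                                           min_population, ages=year_ages):
            buf = compute_buffer(benchmark, buffer_method, panel=panel)
            sub = panel.data[(panel.data["year"] == year)
                             & (panel.data["age"] == benchmark.age)]
            wide = sub.pivot(index="location", columns="sex", values="ex").dropna()
            ratio = wide["female"] / wide["male"]
            adjusted = ratio / benchmark.r_star
            diff = wide["female"] - wide["male"]
            adj_diff = diff - benchmark.gap
            frames.append(pd.DataFrame({
                "location": wide.index,
                "year": year,
                "age": benchmark.age,
                "lf": wide["female"].to_numpy(),
                "lm": wide["male"].to_numpy(),
                "ratio": ratio.to_numpy(),
                "adjusted_ratio": adjusted.to_numpy(),
                "difference": diff.to_numpy(),
                "adjusted_difference": adj_diff.to_numpy(),
                "lf_star": benchmark.lf_star,
                "lm_star": benchmark.lm_star,
                "r_star": benchmark.r_star,
                "buffer_lower": buf.lower,
                "buffer_upper": buf.upper,
                "classification": [classify(n, buf) for n in adjusted],
                "classification_difference": [
                    classify_difference(d, difference_halfwidth) for d in adj_diff],
            }))
    if not frames:
        raise ValueError("panel has no (year, age) cells to evaluate")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["year", "age", "location"]).reset_index(drop=True)


def round_for_report(results: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: ratios to 2 decimals, life expectancies to 1.

    Classification always uses the unrounded values; this is presentation
    only.
    """
    out = results.copy()
    for col in ("ratio", "adjusted_ratio", "r_star"):
        if col in out.columns:
            out[col] = out[col].round(2)
    for col in ("lf", "lm", "lf_star", "lm_star",
                "difference", "adjusted_difference"):
        if col in out.columns:
            out[col] = out[col].round(1)
    return out
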