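"""Sensitivity of frontier estimation and classification to parameter choices.

The method has two free parameters: the upper-tail fraction defining the
frontier and the buffer construction. This module re-runs the pipeline over
a grid of both (optionally with a minimum-population filter on frontier
membership) and summarizes, per location, how stable the default
classification is across settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .frontier import estimate_frontier
from .metrics import BufferMethod, evaluate_panel
from .panel_io import LifePanel

DEFAULT_PERCENTILES = (0.01, 0.05, 0.10, 0.15)
DEFAULT_BUFFERS = (
    BufferMethod.HALF_YEAR_INCREASE,
    BufferMethod.ONE_YEAR_DECREASE,
    BufferMethod.FIXED_0_99_1_01,
    BufferMethod.CENTRAL_30PCT,
)


@dataclass
class SensitivityGrid:
    """Grid of settings to sweep.

    ``min_population`` applies only to which locations set the frontier,
    never to which get classified.
    """

    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    buffer_methods: tuple[BufferMethod, ...] = DEFAULT_BUFFERS
    min_population: float | None = None
    default_percentile: float = 0.05
    default_buffer: BufferMethod = BufferMethod.HALF_YEAR_INCREASE

    def __post_init__(self) -> None:
        if not self.percentiles or not self.buffer_methods:
            raise ValueError("percentiles and buffer_methods must be non-empty")
        bad = [p for p in self.percentiles if not (0.0 < p < 0.5)]
        if bad:
            raise ValueError(f"percentiles outside (0, 0.5): {bad}")
        self.buffer_methods = tuple(BufferMethod.coerce(b) for b in self.buffer_methods)
        self.default_buffer = BufferMethod.coerce(self.default_buffer)


@dataclass
class SensitivityResult:
    """Long table of classifications per setting plus a stability summary."""

    table: pd.DataFrame
    stability: pd.DataFrame
    grid: SensitivityGrid = field(repr=False, default=None)


def run_sensitivity(panel: LifePanel, grid: SensitivityGrid | None = None,
                    years: list[int] | None = None,
                    ages: list[int] | None = None) -> SensitivityResult:
    """Classify every location-year-age under every grid setting.

    The returned ``table`` has one row per (percentile, buffer_method,
    location, year, age) with the adjusted ratio and classification under
    that setting. ``stability`` has, per (location, year, age), the fraction
    of settings whose classification agrees with the default setting
    (percentile 0.05, half-year buffer, no population filter).
    """
    grid = grid or SensitivityGrid()
    frames = []
    for p in grid.percentiles:
        for buf in grid.buffer_methods:
            res = evaluate_panel(panel, percentile=p, buffer_method=buf,
                                 min_population=grid.min_population,
                                 years=years, ages=ages)
            res = res[["location", "year", "age", "adjusted_ratio",
                       "classification"]].copy()
            res.insert(0, "buffer_method", buf.value)
            res.insert(0, "percentile", p)
            frames.append(res)
    table = pd.concat(frames, ignore_index=True)

    default = evaluate_panel(panel, percentile=grid.default_percentile,
                             buffer_method=grid.default_buffer,
                             years=years, ages=ages)
    default = default[["location", "year", "age", "classification"]].rename(
        columns={"classification": "default_classification"})
    merged = table.merge(default, on=["location", "year", "age"], how="left")
    merged["agrees"] = merged["classification"] == merged["default_classification"]
    stability = (merged.groupby(["location", "year", "age"])
                 .agg(stability=("agrees", "mean"),
                      default_classification=("default_classification", "first"))
                 .reset_index())
    return SensitivityResult(table=table, stability=stability, grid=grid)


def frontier_percentile_curve(panel: LifePanel, year: int, age: int,
                              percentiles: list[float] | None = None,
                              min_population: float | None = None) -> pd.DataFrame:
    """Frontier values and ratio as a function of the upper-tail fraction.

    One row per percentile with columns percentile, lf_star, lm_star,
    r_star — the table behind the nonlinearity of R* in the tail fraction.
    """
    percentiles = list(percentiles) if percentiles is not None else list(DEFAULT_PERCENTILES)
    rows = []
    for p in percentiles:
        b = estimate_frontier(panel, year, age, percentile=p,
                              min_population=min_population)
        rows.append({"percentile": p, "lf_star": b.lf_star,
                     "lm_star": b.lm_star, "r_star": b.r_star})
    return pd.DataFrame(rows)
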