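"""Model/Results interface over the adjusted-sex-ratio pipeline.

``FrontierSexGapModel`` is built from a life-expectancy panel plus the two
method parameters (frontier percentile, buffer construction); ``fit()``
estimates the frontiers, builds the buffers, and returns a
``FrontierSexGapResults`` carrying the per-country adjusted ratios,
classifications, and summary tables, with sensitivity analysis and plotting
hanging off it.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import reporting
from .frontier import FrontierBenchmark, frontier_schedule, schedule_frame
from .metrics import Buffer, BufferMethod, compute_buffer, evaluate_panel
from .panel_io import LifePanel, RegionMap, complete_panel
from .sensitivity import SensitivityGrid, SensitivityResult, run_sensitivity


class FrontierSexGapModel:
    """Frontier-benchmarked sex-inequality model for a life-expectancy panel.

    Parameters
    ----------
    panel : LifePanel
        Long panel of remaining life expectancy by location, year, sex, age.
        Incomplete (location, year, age) cells are dropped on construction.
    percentile : float
        Upper-tail fraction defining the frontier (default 0.05 = top 5%).
    buffer_method : BufferMethod or str
        No-disadvantage interval construction (default half-year increase).
    min_population : float, optional
        Restrict frontier membership to locations at or above this
        population; classification still covers all locations.
    region_map : RegionMap, optional
        Enables regional breakdowns on the results.

    Examples
    --------
    >>> from frontiergap import FrontierSexGapModel, SyntheticConfig, generate
    >>> panel = generate(SyntheticConfig(seed=1))
    >>> res = FrontierSexGapModel(panel).fit()
    >>> res.results.columns  # doctest: +SKIP
    """

    def __init__(self, panel: LifePanel, percentile: float = 0.05,
                 buffer_method: BufferMethod | str = BufferMethod.HALF_YEAR_INCREASE,
                 min_population: float | None = None,
                 region_map: RegionMap | None = None,
                 difference_halfwidth: float = 0.5):
        self.panel = complete_panel(panel)
        self.percentile = percentile
        self.buffer_method = BufferMethod.coerce(buffer_method)
        self.min_population = min_population
        self.region_map = region_map
        self.difference_halfwidth = difference_halfwidth

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FrontierSexGapModel":
        """Build from a long DataFrame (columns location, year, sex, age, ex)."""
        return cls(LifePanel(df), **kwargs)

    def fit(self) -> "FrontierSexGapResults":
        """Estimate frontiers, construct buffers, and classify every cell."""
        benchmarks: dict[tuple[int, int], FrontierBenchmark] = {}
        buffers: dict[tuple[int, int], Buffer] = {}
        for year in self.panel.years:
            for b in frontier_schedule(self.panel, year, self.percentile,
                                       self.min_population):
                benchmarks[(year, b.age)] = b
                buffers[(year, b.age)] = compute_buffer(
                    b, self.buffer_method, panel=self.panel)
        results = evaluate_panel(
            self.panel, percentile=self.percentile,
            buffer_method=self.buffer_method,
            min_population=self.min_population,
            difference_halfwidth=self.difference_halfwidth)
        return FrontierSexGapResults(self, benchmarks, buffers, results)


class FrontierSexGapResults:
    """Fitted frontiers, buffers, and per-country adjusted results.

    Attributes
    ----------
    results : pandas.DataFrame
        One row per (location, year, age): ratios, adjusted ratios,
        differences, buffer bounds, classifications.
    benchmarks : dict (year, age) -> FrontierBenchmark
    buffers : dict (year, age) -> Buffer
    """

    def __init__(self, model: FrontierSexGapModel,
                 benchmarks: dict[tuple[int, int], FrontierBenchmark],
                 buffers: dict[tuple[int, int], Buffer],
                 results: pd.DataFrame):
        self.model = model
        self.benchmarks = benchmarks
        self.buffers = buffers
        self.results = results

    # -- tables ---------------------------------------------------------------

    @property
    def frontier_table(self) -> pd.DataFrame:
        """Frontier life expectancies, ratios and members per (year, age)."""
        return schedule_frame(list(self.benchmarks.values()))

    def classification_summary(self,
                               weights: Mapping[str, float] | None = None
                               ) -> pd.DataFrame:
        """Counts/percentages per age, raw (vs 1) and adjusted (vs buffer)."""
        return reporting.summarize_classifications(self.results, weights=weights)

    def regional(self) -> dict[str, pd.DataFrame]:
        """Per-region tables sorted by adjusted ratio (needs a region map)."""
        if self.model.region_map is None:
            raise ValueError("model was built without a region_map")
        return reporting.regional_breakdown(self.results, self.model.region_map)

    def compare(self, other: "FrontierSexGapResults | pd.DataFrame",
                age: int) -> pd.DataFrame:
        """Year-on-year comparison of adjusted ratios at one age."""
        other_res = other.results if isinstance(other, FrontierSexGapResults) else other
        return reporting.compare_years(self.results, other_res, age)

    def sensitivity(self, grid: SensitivityGrid | None = None) -> SensitivityResult:
        """Re-run classification across a percentile x buffer grid."""
        return run_sensitivity(self.model.panel, grid)

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary: frontiers per age and classification counts."""
        lines = ["Frontier-adjusted sex ratios of life expectancy",
                 "=" * 48,
                 f"Locations: {len(self.model.panel.locations)}   "
                 f"Years: {', '.join(map(str, self.model.panel.years))}",
                 f"Frontier: top {self.model.percentile:.0%} "
                 f"(quantile, linear interpolation)   "
                 f"Buffer: {self.model.buffer_method.value}",
                 ""]
        ft = self.frontier_table
        lines.append("Frontier benchmarks")
        lines.append(f"{'year':>6} {'age':>4} {'Lf*':>7} {'Lm*':>7} {'R*':>6} "
                     f"{'members (F/M)':>14}")
        for row in ft.itertuples(index=False):
            lines.append(f"{row.year:>6} {row.age:>4} {row.lf_star:>7.1f} "
                         f"{row.lm_star:>7.1f} {row.r_star:>6.2f} "
                         f"{row.n_female_members:>6}/{row.n_male_members}")
        lines.append("")
        cs = self.classification_summary()
        lines.append("Adjusted classification (countries per label)")
        lines.append(f"{'year':>6} {'age':>4} {'female':>8} {'male':>8} {'none':>8}")
        for row in cs.itertuples(index=False):
            lines.append(
                f"{row.year:>6} {row.age:>4} "
                f"{row.adjusted_female_disadvantage_count:>4} "
                f"({row.adjusted_female_disadvantage_pct:>2.0f}%) "
                f"{row.adjusted_male_disadvantage_count:>4} "
                f"({row.adjusted_male_disadvantage_pct:>2.0f}%) "
                f"{row.adjusted_none_count:>4} ({row.adjusted_none_pct:>2.0f}%)")
        return "\n".join(lines)

    def plot_distribution(self, year: int, **kwargs):
        return reporting.plot_adjusted_ratio_dotplot(self.results, year, **kwargs)

    def plot_frontier_progress(self, year: int, age: int, **kwargs):
        return reporting.plot_frontier_progress(self.results, year, age, **kwargs)
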