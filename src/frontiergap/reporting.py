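"""Summary tables and basic plots over classified results.

Produces the standard artifacts of the analysis: classification counts per
age before and after adjustment, regional breakdowns, year-on-year
comparisons of adjusted ratios, and optional population-weighted shares.
Counts are the source of truth; percentages are rounded integers for
presentation.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .metrics import FEMALE_DISADVANTAGE, LABELS, MALE_DISADVANTAGE, NO_DISADVANTAGE
from .panel_io import RegionMap

logger = logging.getLogger(__name__)

UNASSIGNED = "Unassigned"


def raw_label(ratio: float) -> str:
    """Pre-adjustment label: ratio < 1 female disadvantage, > 1 male, == 1 none."""
    if ratio < 1.0:
        return FEMALE_DISADVANTAGE
    if ratio > 1.0:
        return MALE_DISADVANTAGE
    return NO_DISADVANTAGE


def _shares(sub: pd.DataFrame, column: str,
            weights: pd.Series | None) -> dict[str, float]:
    if weights is None:
        return {}
    w = sub["location"].map(weights).fillna(0.0)
    total = float(w.sum())
    if total == 0:
        return {label: float("nan") for label in LABELS}
    return {label: float(w[sub[column] == label].sum()) / total for label in LABELS}


def summarize_classifications(results: pd.DataFrame,
                              weights: Mapping[str, float] | pd.Series | None = None
                              ) -> pd.DataFrame:
    """Classification counts and percentages per (year, age), raw and adjusted.

    Raw classification compares the unadjusted ratio against 1 with no
    buffer; adjusted classification is taken from the ``classification``
    column produced by ``evaluate_panel``. With ``weights`` (population per
    location), population-weighted shares are appended.
    """
    weights = pd.Series(weights) if weights is not None else None
    rows = []
    for (year, age), sub in results.groupby(["year", "age"]):
        n = len(sub)
        raw = sub["ratio"].map(raw_label)
        sub = sub.assign(_raw=raw)
        row: dict[str, object] = {"year": year, "age": age, "n_locations": n}
        for prefix, col in (("raw", "_raw"), ("adjusted", "classification")):
            counts = sub[col].value_counts()
            for label in LABELS:
                c = int(counts.get(label, 0))
                row[f"{prefix}_{label}_count"] = c
                row[f"{prefix}_{label}_pct"] = round(100.0 * c / n)
        for prefix, col in (("raw", "_raw"), ("adjusted", "classification")):
            for label, share in _shares(sub, col, weights).items():
                row[f"{prefix}_{label}_weighted_share"] = share
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["year", "age"]).reset_index(drop=True)


def compare_years(results_a: pd.DataFrame, results_b: pd.DataFrame,
                  age: int) -> pd.DataFrame:
    """Side-by-side adjusted ratios at one age for locations in both result sets.

    One row per common location with the two adjusted ratios, both labels,
    and a ``switched`` flag where the labels differ.
    """
    def _at_age(res: pd.DataFrame) -> pd.DataFrame:
        sub = res[res["age"] == age]
        if sub.empty:
            raise ValueError(f"no results at age {age}")
        return sub.set_index("location")[["year", "adjusted_ratio", "classification"]]

    a, b = _at_age(results_a), _at_age(results_b)
    merged = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    merged["switched"] = merged["classification_a"] != merged["classification_b"]
    return merged.reset_index().sort_values("location").reset_index(drop=True)


def extremes(results: pd.DataFrame, age: int) -> pd.DataFrame:
    """Min and max adjusted ratio per year at one age, with the locations."""
    sub = results[results["age"] == age]
    rows = []
    for year, g in sub.groupby("year"):
        lo, hi = g.loc[g["adjusted_ratio"].idxmin()], g.loc[g["adjusted_ratio"].idxmax()]
        rows.append({"year": year, "age": age,
                     "min_location": lo["location"], "min_adjusted_ratio": lo["adjusted_ratio"],
                     "max_location": hi["location"], "max_adjusted_ratio": hi["adjusted_ratio"]})
    return pd.DataFrame(rows)


def regional_breakdown(results: pd.DataFrame,
                       regions: RegionMap) -> dict[str, pd.DataFrame]:
    """Split results by region; within each, sort by adjusted ratio per age.

    Locations absent from the map go to an "Unassigned" bucket with a
    warning — never silently dropped.
    """
    region = results["location"].map(dict(regions.mapping))
    unmapped = regions.unmapped(results["location"])
    if unmapped:
        logger.warning("regional_breakdown: %d location(s) not in region map "
                       "assigned to %r: %s", len(unmapped), UNASSIGNED,
                       ", ".join(unmapped[:10]))
    tagged = results.assign(region=region.fillna(UNASSIGNED))
    out: dict[str, pd.DataFrame] = {}
    for name, sub in tagged.groupby("region"):
        out[str(name)] = (sub.sort_values(["year", "age", "adjusted_ratio"])
                          .reset_index(drop=True))
    return out


# -- plotting ---------------------------------------------------------------


def plot_adjusted_ratio_dotplot(results: pd.DataFrame, year: int,
                                ax=None, xlim: tuple[float, float] | None = None):
    """Dot plot of adjusted ratios by age (one panel, all locations).

    ``xlim`` clips the axes only; the data are never truncated.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = results[results["year"] == year]
    for i, (age, g) in enumerate(sub.groupby("age")):
        ax.scatter(g["adjusted_ratio"], [i] * len(g), s=8, alpha=0.6)
        lo, up = g["buffer_lower"].iloc[0], g["buffer_upper"].iloc[0]
        ax.plot([lo, lo], [i - 0.3, i + 0.3], color="gray", ls=":")
        ax.plot([up, up], [i - 0.3, i + 0.3], color="gray", ls=":")
    ax.axvline(1.0, color="black", lw=0.8)
    ax.set_yticks(range(sub["age"].nunique()))
    ax.set_yticklabels(sorted(sub["age"].unique()))
    ax.set_xlabel("adjusted sex ratio")
    ax.set_ylabel("age")
    ax.set_title(f"Adjusted sex ratios by age, {year}")
    if xlim:
        ax.set_xlim(*xlim)
    return ax


def plot_frontier_progress(results: pd.DataFrame, year: int, age: int, ax=None):
    """Scatter of female vs male progress toward the sex-specific frontier."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = results[(results["year"] == year) & (results["age"] == age)]
    ax.scatter(sub["lf"] / sub["lf_star"], sub["lm"] / sub["lm_star"], s=10, alpha=0.6)
    lim = (0, 1.1)
    ax.plot(lim, lim, color="black", lw=0.8)
    ax.set_xlim(*lim)
    ax.set_ylim(*lim)
    ax.set_xlabel("female ex / frontier")
    ax.set_ylabel("male ex / frontier")
    ax.set_title(f"Progress toward the frontier, {year}, age {age}")
    return ax
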