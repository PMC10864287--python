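"""Song and song-year pattern classification.

Songs are labeled SHORT or LONG from their median INI: the two observed
modes sit near 10 s (fall-winter) and 15 s (spring), so the default
threshold is their midpoint, 12.5 s.  A song year is then typed from its
monthly label composition:

- SEASONAL_SHIFT — SHORT predominates in Sep-Dec and LONG in Mar-Apr
  (the recurring New York Bight / Gulf of Maine pattern);
- CONSTANT_LONG / CONSTANT_SHORT — one label predominates year-round,
  including the months where the other would be expected;
- UNDETERMINED — too few months with data.

Within-month co-occurrence of both labels (as seen in October-November of
the anomalous year, when short-INI "intruder" songs appeared among long-INI
songs) is flagged separately, since overlapping song patterns are the
acoustic signature of overlapping subpopulations.  All thresholds are
configuration, not biology: the field classification is done by eye, and
these defaults merely reproduce it on well-separated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ini_pipeline import SongSummary

__all__ = [
    "SongLabel",
    "YearPattern",
    "classify_song",
    "classify_song_year",
    "detect_cooccurrence",
    "detect_transitions",
    "plot_monthly_medians",
    "SHORT_LONG_THRESHOLD_S",
]

SHORT_LONG_THRESHOLD_S = 12.5
VARIABLE_IQR_S = 2.0
PREDOMINANCE = 0.75
MIN_LABELED_MONTHS = 4
FALL_WINTER_MONTHS = (9, 10, 11, 12)
SPRING_MONTHS = (3, 4)


@dataclass
class SongLabel:
    song_id: str
    label: str                 # "SHORT" | "LONG"
    median_ini: float
    variable: bool             # IQR above the variability threshold


@dataclass
class YearPattern:
    song_year: int
    pattern: str               # SEASONAL_SHIFT | CONSTANT_LONG | CONSTANT_SHORT | UNDETERMINED
    monthly_labels: dict[int, str] = field(default_factory=dict)
    cooccurrence_months: list[int] = field(default_factory=list)
    transition_months: list[int] = field(default_factory=list)


def classify_song(summary: SongSummary,
                  threshold_s: float = SHORT_LONG_THRESHOLD_S,
                  variable_iqr_s: float = VARIABLE_IQR_S) -> SongLabel:
    """SHORT if the median INI is below the threshold, else LONG.

    The boundary itself (median == threshold) is LONG; songs with IQR
    above ``variable_iqr_s`` are flagged variable.
    """
    label = "SHORT" if summary.median < threshold_s else "LONG"
    return SongLabel(summary.song_id, label, summary.median,
                     summary.iqr > variable_iqr_s)


def _predominant(labels: list[str]) -> str | None:
    if not labels:
        return None
    n_short = sum(1 for x in labels if x == "SHORT")
    return "SHORT" if n_short * 2 > len(labels) else (
        "LONG" if n_short * 2 < len(labels) else None)


def classify_song_year(labels: pd.DataFrame,
                       predominance: float = PREDOMINANCE,
                       min_months: int = MIN_LABELED_MONTHS) -> YearPattern:
    """Type one song year from its monthly song labels.

    ``labels`` has columns ``month``, ``label`` (and ``song_year``).  The
    year is SEASONAL_SHIFT when SHORT predominates across Sep-Dec and LONG
    across Mar-Apr; CONSTANT_LONG (resp. CONSTANT_SHORT) when at least
    ``predominance`` of all labeled songs are LONG (SHORT) including the
    months where the opposite would be expected; UNDETERMINED with fewer
    than ``min_months`` labeled months.
    """
    sy = int(labels["song_year"].iloc[0]) if len(labels) else -1
    monthly = {int(m): _predominant(list(g["label"]))
               for m, g in labels.groupby("month")}
    monthly = {m: v for m, v in monthly.items() if v is not None}
    if labels.empty or labels["month"].nunique() < min_months:
        return YearPattern(sy, "UNDETERMINED", monthly)

    fall = _predominant(
        list(labels[labels["month"].isin(FALL_WINTER_MONTHS)]["label"]))
    spring = _predominant(
        list(labels[labels["month"].isin(SPRING_MONTHS)]["label"]))
    if fall == "SHORT" and spring == "LONG":
        return YearPattern(sy, "SEASONAL_SHIFT", monthly)

    frac_long = (labels["label"] == "LONG").mean()
    if frac_long >= predominance and fall == "LONG":
        return YearPattern(sy, "CONSTANT_LONG", monthly)
    if (1.0 - frac_long) >= predominance and spring == "SHORT":
        return YearPattern(sy, "CONSTANT_SHORT", monthly)
    return YearPattern(sy, "UNDETERMINED", monthly)


def detect_cooccurrence(month_labels: pd.DataFrame
                        ) -> tuple[bool, dict[str, int]]:
    """Flag months where SHORT and LONG songs co-occur.

    ``month_labels`` holds the labels of one month x song-year cell.
    Single-song months are not evaluable and never flagged.  Returns
    ``(flagged, counts)`` with per-label song counts.
    """
    counts = {"SHORT": int((month_labels["label"] == "SHORT").sum()),
              "LONG": int((month_labels["label"] == "LONG").sum())}
    if len(month_labels) < 2:
        return False, counts
    return counts["SHORT"] > 0 and counts["LONG"] > 0, counts


def plot_monthly_medians(labels: pd.DataFrame, path=None):
    """Per-song median INI (whiskers = quartiles) by month, colored by year.

    ``labels`` needs columns ``month``, ``song_year``, ``median_ini`` and
    optionally ``q25``/``q75``.  Months run July..June (the song-year
    axis).  Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = [7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6]
    pos = {m: i for i, m in enumerate(order)}
    fig, ax = plt.subplots(figsize=(9, 4))
    years = sorted(labels["song_year"].unique())
    cmap = plt.get_cmap("viridis", max(len(years), 2))
    rng = np.random.default_rng(0)  # fixed jitter for overplotting only
    for ci, sy in enumerate(years):
        g = labels[labels["song_year"] == sy]
        x = g["month"].map(pos) + rng.uniform(-0.22, 0.22, len(g))
        if {"q25", "q75"} <= set(g.columns):
            yerr = np.vstack([g["median_ini"] - g["q25"],
                              g["q75"] - g["median_ini"]])
            ax.errorbar(x, g["median_ini"], yerr=yerr, fmt="o", ms=4,
                        color=cmap(ci), alpha=0.8, lw=1,
                        label=f"song year {sy}")
        else:
            ax.plot(x, g["median_ini"], "o", ms=4, color=cmap(ci),
                    alpha=0.8, label=f"song year {sy}")
    ax.axhline(SHORT_LONG_THRESHOLD_S, ls=":", c="gray", lw=1)
    ax.set_xticks(range(12))
    ax.set_xticklabels(["Jul", "Aug", "Sep", "Oct", "Nov", "Dec", "Jan",
                        "Feb", "Mar", "Apr", "May", "Jun"])
    ax.set_ylabel("median INI (s)")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def detect_transitions(monthly: pd.DataFrame,
                       dispersion_factor: float = 2.0,
                       intermediacy_margin_s: float = 1.0,
                       short_mode_s: float = 10.0,
                       long_mode_s: float = 15.0,
                       min_months: int = 4) -> list[int]:
    """Months with transitional (intermediate or unusually variable) INIs.

    ``monthly`` has columns ``month`` and ``median_ini`` with one row per
    song.  A month is transitional when the spread of its song medians
    (IQR across songs) exceeds ``dispersion_factor`` times the typical
    stable-month spread, or when its monthly median sits strictly between
    the short and long modes by more than ``intermediacy_margin_s`` on
    each side.  The rule measures intermediacy, not change: an abrupt step
    with no intermediate months yields no transitions.
    """
    if monthly["month"].nunique() < min_months:
        return []
    per_month = monthly.groupby("month")["median_ini"]
    med = per_month.median()
    iqr = per_month.apply(lambda s: float(np.subtract(*np.percentile(s, [75, 25])))
                          if len(s) > 1 else 0.0)
    stable = [m for m in med.index
              if med[m] < short_mode_s + intermediacy_margin_s
              or med[m] > long_mode_s - intermediacy_margin_s]
    baseline = float(np.median([iqr[m] for m in stable])) if stable else 0.0
    out = []
    for m in med.index:
        intermediate = (short_mode_s + intermediacy_margin_s < med[m]
                        < long_mode_s - intermediacy_margin_s)
        dispersed = baseline > 0 and iqr[m] > dispersion_factor * baseline
        if intermediate or dispersed:
            out.append(int(m))
    return sorted(out)
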