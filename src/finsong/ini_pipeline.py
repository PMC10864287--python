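"""Song construction, inclusion filters, INI computation and summaries.

A "song" is one singer-day's ordered set of measured 20 Hz notes.  Songs
enter analysis only if they span at least two minutes and have a mean SNR
of at least 10 dB (filters applied in that order).  The inter-note
interval (INI) is the difference between the center times of consecutive
notes; INIs below 4.5 s or above 30 s are removed (surfacing gaps, missed
or overlapped notes, multipath).  Summaries mirror the field analysis:
per-song median and quartiles, per-period pooled means with standard
errors (short-INI period = Sep-Dec, long-INI period = Mar-May), the
pooled-75th-percentile high-SNR note subset, and month x song-year effort
tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Song",
    "INISeries",
    "SongSummary",
    "PeriodMean",
    "build_songs",
    "compute_inis",
    "assign_song_year",
    "summarize_song",
    "period_means",
    "select_high_snr_notes",
    "effort_summary",
    "load_observed_song_counts",
    "load_ini_literature",
    "INI_MIN_S",
    "INI_MAX_S",
    "MIN_SONG_DURATION_S",
    "MIN_MEAN_SNR_DB",
    "SHORT_PERIOD_MONTHS",
    "LONG_PERIOD_MONTHS",
]

INI_MIN_S = 4.5
INI_MAX_S = 30.0
MIN_SONG_DURATION_S = 120.0
MIN_MEAN_SNR_DB = 10.0
MIN_HIGH_SNR_NOTES_PER_DAY = 10
SHORT_PERIOD_MONTHS = (9, 10, 11, 12)
LONG_PERIOD_MONTHS = (3, 4, 5)

#: First song year ("song year 1") starts July 1 of this calendar year.
SONG_YEAR_EPOCH = 2016
SONG_YEAR_RANGE = (1, 5)

SNR_COL = "SNR NIST Quick (dB)"
CT_COL = "Center Time (s)"


@dataclass
class Song:
    """One singer-day's ordered note set with inclusion status."""

    song_id: str
    singer_id: str
    recording_id: str
    notes: pd.DataFrame            # NoteMeasurement rows, center-time sorted
    date: dt.date
    included: bool = True
    exclusion_reasons: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        """Last note end minus first note begin, seconds."""
        return float(self.notes["End Time (s)"].iloc[-1]
                     - self.notes["Begin Time (s)"].iloc[0])

    @property
    def mean_snr(self) -> float:
        """Mean SNR over notes with a defined SNR, dB."""
        s = self.notes[SNR_COL].dropna()
        return float(s.mean()) if len(s) else np.nan

    @property
    def month(self) -> int:
        return self.date.month

    @property
    def song_year(self) -> int:
        return assign_song_year(self.date)


@dataclass
class INISeries:
    """Raw and range-filtered INIs of one song."""

    song_id: str
    raw: np.ndarray
    kept: np.ndarray
    removed: list[tuple[float, str]]


@dataclass
class SongSummary:
    song_id: str
    median: float
    q25: float
    q75: float
    n_inis: int

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


@dataclass
class PeriodMean:
    """Pooled INI mean (+/- s.e.m.) over one period of one song year."""

    song_year: int
    period: str                    # "short" or "long"
    mean: float | None
    sem: float | None
    n_songs: int
    n_inis: int

    @property
    def no_data(self) -> bool:
        return self.n_songs == 0


def assign_song_year(date: dt.date, epoch: int = SONG_YEAR_EPOCH,
                     valid_range: tuple[int, int] = SONG_YEAR_RANGE) -> int:
    """Map a date to its song year (song years run July 1 - June 30).

    Song year 1 spans July 1 of ``epoch`` through June 30 of the next
    calendar year; dates outside ``valid_range`` raise.
    """
    sy = date.year - epoch + (1 if date.month >= 7 else 0)
    lo, hi = valid_range
    if not lo <= sy <= hi:
        raise ValueError(f"date {date} falls in song year {sy}, outside the "
                         f"study range {lo}..{hi}")
    return sy


def build_songs(measurements: pd.DataFrame,
                min_duration_s: float = MIN_SONG_DURATION_S,
                min_mean_snr_db: float = MIN_MEAN_SNR_DB) -> list[Song]:
    """Group note measurements into songs and apply the inclusion filters.

    ``measurements`` must carry ``Singer`` (ISO date) and ``SongID``
    columns along with the standard measurement columns.  Filters are
    applied in order: minimum duration (two minutes), then mean SNR
    (>= 10 dB, strict boundary).  Excluded songs are returned too, with
    machine-readable reasons.
    """
    songs: list[Song] = []
    if measurements.empty:
        return songs
    for song_id, grp in measurements.groupby("SongID", sort=True):
        grp = grp.sort_values(CT_COL).reset_index(drop=True)
        singer = str(grp["Singer"].iloc[0])
        date = dt.date.fromisoformat(singer)
        song = Song(song_id=str(song_id), singer_id=singer,
                    recording_id=str(grp["Begin File"].iloc[0]),
                    notes=grp, date=date)
        if song.duration < min_duration_s:
            song.included = False
            song.exclusion_reasons.append("duration")
        elif not (song.mean_snr >= min_mean_snr_db):
            song.included = False
            song.exclusion_reasons.append("snr")
        songs.append(song)
    return songs


def compute_inis(song: Song, ini_min: float = INI_MIN_S,
                 ini_max: float = INI_MAX_S) -> INISeries:
    """Successive center-time differences, range-filtered to [4.5, 30] s."""
    ct = song.notes[CT_COL].to_numpy(float)
    if ct.size < 2:
        return INISeries(song.song_id, np.array([]), np.array([]), [])
    raw = np.diff(ct)
    keep = (raw >= ini_min) & (raw <= ini_max)
    removed = [(float(v), "lt_4.5" if v < ini_min else "gt_30")
               for v in raw[~keep]]
    return INISeries(song.song_id, raw, raw[keep], removed)


def summarize_song(series: INISeries,
                   interpolation: str = "linear") -> SongSummary | None:
    """Median and quartiles of the kept INIs (linear-interpolated).

    Returns None when no INIs survive the range filter (the song then
    contributes nothing to per-song summary figures).
    """
    if series.kept.size == 0:
        return None
    q25, med, q75 = np.percentile(series.kept, [25, 50, 75],
                                  method=interpolation)
    return SongSummary(series.song_id, float(med), float(q25), float(q75),
                       int(series.kept.size))


def period_means(songs: list[Song], series_by_id: dict[str, INISeries],
                 period: str, song_year: int | None = None) -> list[PeriodMean]:
    """Pooled mean +/- s.e.m. of kept INIs over a period's months.

    ``period`` is "short" (Sep-Dec) or "long" (Mar-May).  INIs from all of
    the period's included songs are pooled; the s.e.m. treats them as
    independent.  Returns one record per song year present (or the
    requested one, possibly as a no-data record).
    """
    months = {"short": SHORT_PERIOD_MONTHS, "long": LONG_PERIOD_MONTHS}[period]
    years = ([song_year] if song_year is not None
             else sorted({s.song_year for s in songs if s.included}))
    out = []
    for sy in years:
        pool, n_songs = [], 0
        for s in songs:
            if not s.included or s.song_year != sy or s.month not in months:
                continue
            kept = series_by_id[s.song_id].kept
            if kept.size:
                pool.append(kept)
                n_songs += 1
        if not pool:
            out.append(PeriodMean(sy, period, None, None, 0, 0))
            continue
        inis = np.concatenate(pool)
        sem = float(inis.std(ddof=1) / np.sqrt(inis.size)) if inis.size > 1 else 0.0
        out.append(PeriodMean(sy, period, float(inis.mean()), sem,
                              n_songs, int(inis.size)))
    return out


def select_high_snr_notes(measurements: pd.DataFrame,
                          quantile: float = 0.75,
                          min_notes_per_day: int = MIN_HIGH_SNR_NOTES_PER_DAY
                          ) -> tuple[float, pd.DataFrame, pd.Series]:
    """High-SNR note subset for spectral-characteristic analysis.

    The threshold is the pooled ``quantile`` (default 75th percentile,
    linear interpolation) of SNR across all notes from included songs; the
    subset keeps notes at or above it, on days with at least
    ``min_notes_per_day`` such notes.  Returns
    ``(threshold_db, subset, per_day_counts)``.
    """
    snr = measurements[SNR_COL].dropna()
    if snr.size < 4:
        raise ValueError(f"need >= 4 notes with defined SNR, got {snr.size}")
    threshold = float(np.percentile(snr, 100 * quantile, method="linear"))
    qualifying = measurements[measurements[SNR_COL] >= threshold]
    per_day = qualifying.groupby("Singer").size()
    good_days = per_day[per_day >= min_notes_per_day].index
    subset = qualifying[qualifying["Singer"].isin(good_days)]
    return threshold, subset.copy(), per_day


MONTH_ORDER = [7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6]
MONTH_NAMES = {1: "January", 2: "February", 3: "March", 4: "April",
               5: "May", 6: "June", 7: "July", 8: "August", 9: "September",
               10: "October", 11: "November", 12: "December"}


def effort_summary(songs: list[Song], series_by_id: dict[str, INISeries],
                   effort_days_by_year: dict[int, int] | None = None
                   ) -> pd.DataFrame:
    """Month x song-year counts of songs and kept INIs, with totals.

    Rows are months in song-year order (July..June) plus a Totals row;
    columns one per song year plus Totals.  Each cell holds
    ``(n songs, n INIs)``; when ``effort_days_by_year`` is given a final
    row reports days (and 3 h/day review hours) per year.
    """
    years = sorted({s.song_year for s in songs if s.included}) or [1]
    counts = {(m, sy): [0, 0] for m in MONTH_ORDER for sy in years}
    for s in songs:
        if not s.included:
            continue
        kept = series_by_id[s.song_id].kept
        c = counts[(s.month, s.song_year)]
        c[0] += 1
        c[1] += int(kept.size)
    records = []
    for m in MONTH_ORDER:
        row = {"Month": MONTH_NAMES[m]}
        tot_s = tot_i = 0
        for sy in years:
            ns, ni = counts[(m, sy)]
            row[f"SY{sy} songs"], row[f"SY{sy} INIs"] = ns, ni
            tot_s += ns
            tot_i += ni
        row["Total songs"], row["Total INIs"] = tot_s, tot_i
        records.append(row)
    total_row = {"Month": "Totals"}
    for sy in years:
        total_row[f"SY{sy} songs"] = sum(counts[(m, sy)][0] for m in MONTH_ORDER)
        total_row[f"SY{sy} INIs"] = sum(counts[(m, sy)][1] for m in MONTH_ORDER)
    total_row["Total songs"] = sum(r["Total songs"] for r in records)
    total_row["Total INIs"] = sum(r["Total INIs"] for r in records)
    records.append(total_row)
    df = pd.DataFrame(records)
    if effort_days_by_year:
        row = {"Month": "Days reviewed"}
        for sy in years:
            d = effort_days_by_year.get(sy, 0)
            row[f"SY{sy} songs"] = d
            row[f"SY{sy} INIs"] = d * 3  # 6 recordings x 30 min = 3 h/day
        row["Total songs"] = sum(effort_days_by_year.values())
        row["Total INIs"] = row["Total songs"] * 3
        df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df


def load_observed_song_counts() -> pd.DataFrame:
    """Packaged transcription of the observed New York Bight month x
    song-year song and INI counts (2017-2020).

    Columns: Month, then per song year ``SY<k> songs`` / ``SY<k> INIs``
    (NaN where the buoy was out of the water), plus review effort rows.
    """
    with resources.files("finsong.data").joinpath(
            "nyb_song_counts_2017_2020.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_ini_literature() -> pd.DataFrame:
    """Reference compilation of INI patterns reported across the Atlantic
    (static literature table; not used by any computation)."""
    with resources.files("finsong.data").joinpath(
            "atlantic_ini_literature.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
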