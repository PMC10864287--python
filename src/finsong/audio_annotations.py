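"""Recording and annotation I/O, review-effort subsampling, and the
daily-song / singer-attribution rules.

The field protocol this mirrors: a duty-cycled buoy records 30 min of
every hour; every other calendar day (starting with the first full day of
each deployment leg) is reviewed, six recordings per reviewed day (hours
00, 04, 08, 12, 16, 20), first 30 min of each.  At most one recording with
song is annotated per day — the clearest song — and the recording date
serves as the singer identifier, since the every-other-day design exceeds
the longest documented song-sequence duration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Selection",
    "EffortPlan",
    "read_wav",
    "write_wav",
    "read_selection_table",
    "write_selection_table",
    "subsample_effort",
    "pick_daily_song",
    "assign_singer_ids",
    "split_singers_by_amplitude",
    "REVIEW_HOURS",
    "MANDATORY_COLUMNS",
]

REVIEW_HOURS = (0, 4, 8, 12, 16, 20)
REVIEW_MINUTES_PER_RECORDING = 30

MANDATORY_COLUMNS = ("Begin Time (s)", "End Time (s)",
                     "Low Freq (Hz)", "High Freq (Hz)")

_PCM16_SCALE = 32768.0


@dataclass
class Recording:
    """A timestamped, duty-cycle-aware mono audio segment.

    ``samples`` are float64 in [-1, 1]; quantization to 16-bit PCM happens
    only at WAV write time.
    """

    id: str
    start: dt.datetime
    fs: int
    samples: np.ndarray
    duty_phase: tuple[int, int] = (30, 60)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Selection:
    """One time-frequency annotation box (a Raven selection-table row)."""

    selection_id: int
    recording_id: str
    begin: float
    end: float
    low: float
    high: float
    annotations: dict = field(default_factory=dict)

    def validate(self, recording: Recording | None = None) -> None:
        if not 0 <= self.begin < self.end:
            raise ValueError(f"invalid begin/end: [{self.begin}, {self.end})")
        if not 0 <= self.low < self.high:
            raise ValueError(f"invalid low/high: [{self.low}, {self.high}]")
        if recording is not None:
            if self.end > recording.duration + 1e-9:
                raise ValueError("selection extends past end of recording")
            if self.high > recording.fs / 2:
                raise ValueError("selection extends above Nyquist")


# ---------------------------------------------------------------------------
# WAV I/O (PCM_16 mono)
# ---------------------------------------------------------------------------

def write_wav(recording: Recording, path) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    x = np.asarray(recording.samples, dtype=np.float64)
    q = np.clip(np.round(x * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(path, recording.fs, q)


def read_wav(path, id: str | None = None,
             start: dt.datetime | None = None,
             duty_phase: tuple[int, int] = (30, 60)) -> Recording:
    """Read a mono PCM WAV into a :class:`Recording` (floats in [-1, 1]).

    A write -> read round trip is bit-exact at 16-bit resolution.  The
    recording start time is parsed from a ``NYB_%Y%m%d_%H%M%S`` style
    filename when not given explicitly.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.ndim} channels")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    samples = data.astype(np.float64) / _PCM16_SCALE
    stem = _stem(path)
    if start is None:
        start = _parse_start(stem)
    return Recording(id=id or stem, start=start, fs=int(fs),
                     samples=samples, duty_phase=duty_phase)


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def _parse_start(stem: str) -> dt.datetime:
    parts = stem.split("_")
    if len(parts) >= 3:
        try:
            return dt.datetime.strptime("_".join(parts[-2:]), "%Y%m%d_%H%M%S")
        except ValueError:
            pass
    return dt.datetime(1970, 1, 1)


# ---------------------------------------------------------------------------
# Raven-dialect selection tables (tab-separated, "." decimal)
# ---------------------------------------------------------------------------

def read_selection_table(path) -> pd.DataFrame:
    """Read a tab-separated Raven-dialect selection table.

    Unknown columns are preserved verbatim; missing mandatory columns
    raise a parse error naming the first absent one.
    """
    df = pd.read_csv(path, sep="\t")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"selection table {path}: missing mandatory "
                             f"column {col!r}")
    return df


def write_selection_table(df: pd.DataFrame, path) -> None:
    """Write a selection table; read -> write -> read is lossless."""
    df.to_csv(path, sep="\t", index=False)


def selections_from_table(df: pd.DataFrame,
                          recording_id_col: str = "Begin File"
                          ) -> list[Selection]:
    """Convert table rows into :class:`Selection` objects."""
    known = set(MANDATORY_COLUMNS) | {"Selection", recording_id_col}
    out = []
    for _, row in df.iterrows():
        extras = {c: row[c] for c in df.columns if c not in known}
        out.append(Selection(
            selection_id=int(row.get("Selection", 0)),
            recording_id=str(row.get(recording_id_col, "")),
            begin=float(row["Begin Time (s)"]),
            end=float(row["End Time (s)"]),
            low=float(row["Low Freq (Hz)"]),
            high=float(row["High Freq (Hz)"]),
            annotations=extras,
        ))
    return out


# ---------------------------------------------------------------------------
# effort subsampling
# ---------------------------------------------------------------------------

@dataclass
class EffortPlan:
    """Which recordings are reviewed: dates x hours, 30 min each."""

    reviewed_dates: list[dt.date]
    reviewed_hours: tuple[int, ...] = REVIEW_HOURS
    minutes_per_recording: int = REVIEW_MINUTES_PER_RECORDING

    @property
    def n_days(self) -> int:
        return len(self.reviewed_dates)

    @property
    def review_hours_total(self) -> float:
        """Total review effort in hours: days x 6 recordings x 30 min."""
        return (self.n_days * len(self.reviewed_hours)
                * self.minutes_per_recording / 60.0)

    def covers(self, start: dt.datetime) -> bool:
        return (start.date() in set(self.reviewed_dates)
                and start.hour in self.reviewed_hours
                and start.minute == 0)


def subsample_effort(index: pd.DataFrame,
                     hours: tuple[int, ...] = REVIEW_HOURS,
                     leg_gap_days: int = 2) -> EffortPlan:
    """Build the every-other-day review plan from a recording index.

    ``index`` needs a ``start`` column of timestamps.  Within each
    deployment leg (legs are split wherever consecutive recording dates are
    more than ``leg_gap_days`` apart), reviewing starts on the first full
    calendar day — the day after the leg's first recording, unless that
    recording begins at midnight — and proceeds every second day.
    """
    if index.empty:
        return EffortPlan(reviewed_dates=[])
    starts = pd.to_datetime(index["start"]).sort_values()
    dates = sorted({s.date() for s in starts})
    first_start = {d: min(s for s in starts if s.date() == d) for d in dates}

    reviewed: list[dt.date] = []
    prev = dates[0]
    legs: list[list[dt.date]] = [[dates[0]]]
    for d in dates[1:]:
        if (d - prev).days > leg_gap_days:
            legs.append([])
        legs[-1].append(d)
        prev = d
    for leg in legs:
        d0 = leg[0]
        t0 = first_start[d0]
        anchor = d0 if t0.time() == dt.time(0) else d0 + dt.timedelta(days=1)
        for d in leg:
            if d >= anchor and (d - anchor).days % 2 == 0:
                reviewed.append(d)
    return EffortPlan(reviewed_dates=reviewed, reviewed_hours=hours)


# ---------------------------------------------------------------------------
# daily-song selection and singer attribution
# ---------------------------------------------------------------------------

def pick_daily_song(candidates: pd.DataFrame) -> str | None:
    """Choose the one recording per day whose song is annotated.

    ``candidates`` has one row per recording with song on a single
    reviewed day, with columns ``recording_id``, ``n_notes`` and
    optionally ``mean_snr``.  The "clearest, most distinct song" rule is
    operationalized as: most annotated notes, tie-break by highest mean
    SNR, then earliest recording (lexicographic id = earliest hour).
    """
    if candidates.empty:
        return None
    df = candidates.copy()
    if "mean_snr" not in df.columns:
        df["mean_snr"] = 0.0
    df = df.sort_values(["n_notes", "mean_snr", "recording_id"],
                        ascending=[False, False, True],
                        kind="mergesort")
    return str(df.iloc[0]["recording_id"])


def assign_singer_ids(songs: pd.DataFrame,
                      date_col: str = "date") -> pd.Series:
    """Assign singer identifiers: the ISO recording date.

    One analyzed song per day implies date is injective over songs; two
    songs on the same date violate the design and raise.
    """
    dates = pd.to_datetime(songs[date_col]).dt.date
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"two songs assigned to the same day: {dup}")
    return dates.map(lambda d: d.isoformat())


def split_singers_by_amplitude(notes: pd.DataFrame,
                               tolerance_db: float = 3.0,
                               min_separation_db: float = 6.0
                               ) -> tuple[pd.Series | None, bool]:
    """Attribute notes in a multi-singer recording by received level.

    ``notes`` has columns ``begin``, ``end`` and ``inband_power`` (dB),
    time-sorted.  Notes are assigned to the singer (louder/softer) whose
    running median inband power they fall within ``tolerance_db`` of.
    Returns ``(labels, ambiguous)``: labels are "A" (louder) / "B";
    ``ambiguous`` is True — and labels None — when any note overlaps
    another in time, falls within tolerance of both singers, or the two
    amplitude clusters are separated by less than ``min_separation_db``
    (the whole song is then excluded from analysis, mirroring the
    exclude-on-uncertainty rule).
    """
    df = notes.sort_values("begin").reset_index(drop=True)
    # temporal overlap between consecutive notes -> ambiguous outright
    if (df["begin"].values[1:] < df["end"].values[:-1]).any():
        return None, True
    p = df["inband_power"].to_numpy(float)
    lo, hi = p.min(), p.max()
    if hi - lo < min_separation_db:
        # single apparent level: one singer, nothing to split
        if hi - lo <= tolerance_db:
            return pd.Series(["A"] * len(df)), False
        return None, True
    # two-level split seeded at the extremes, refined by running medians
    labels = np.where(np.abs(p - hi) <= np.abs(p - lo), "A", "B")
    med_a, med_b = np.median(p[labels == "A"]), np.median(p[labels == "B"])
    if med_a - med_b < min_separation_db:
        return None, True
    near_a = np.abs(p - med_a) <= tolerance_db
    near_b = np.abs(p - med_b) <= tolerance_db
    if (near_a & near_b).any() or (~near_a & ~near_b).any():
        return None, True
    return pd.Series(np.where(near_a, "A", "B")), False
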