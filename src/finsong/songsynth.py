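"""Synthetic fin whale song deployments with ground-truth annotations.

Fin whale song consists of long sequences of short (~1 s) 20 Hz downsweep
notes separated by a stereotyped inter-note interval (INI).  This module
synthesizes single-channel hydrophone deployments — colored ambient noise,
duty-cycled 30-minute recordings, and mixed-in song sequences — together
with Raven-style truth selection tables, so that the entire measurement and
analysis chain can be exercised and validated without any field recordings.

The seasonal presets encode the New York Bight song phenology: short INIs
(~10 s) from September through December, long INIs (~15 s) from March
through May, and transitional months with variable INIs in between.  A
"constant long" preset emulates a year in which the short-INI period never
appears, apart from a small number of short-INI intruder songs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.signal import get_window

__all__ = [
    "NoteSpec",
    "SongSpec",
    "NoiseSpec",
    "DeploymentSpec",
    "CANONICAL_NOTE",
    "TABLE3_PRESET_MEANS",
    "make_note",
    "make_song",
    "make_noise",
    "make_deployment",
    "seasonal_month_means",
    "constant_long_mean_for_pooled_target",
]

#: Months comprising the short-INI period (fall through winter).
SHORT_MONTHS = (9, 10, 11, 12)
#: Months comprising the long-INI period (spring).
LONG_MONTHS = (3, 4, 5)
#: Transition months with variable INIs.
TRANSITION_MONTHS = (1, 2, 7, 8)

#: Observed period-mean INIs (s) per song year used to parameterize presets.
#: ``None`` marks periods with no data.
TABLE3_PRESET_MEANS: dict[int, dict[str, float | None]] = {
    1: {"short": None, "long": 15.68},
    2: {"short": 9.92, "long": 15.38},
    3: {"short": 9.75, "long": 15.67},
    4: {"short": 14.78, "long": 15.90},
    5: {"short": 9.84, "long": None},
}

_FALLBACK_SHORT = 10.0
_FALLBACK_LONG = 15.5


def _fail(field_name: str, msg: str) -> None:
    raise ValueError(f"invalid {field_name}: {msg}")


@dataclass(frozen=True)
class NoteSpec:
    """One 20 Hz note: a linear downsweep with a shaped amplitude envelope.

    Parameters
    ----------
    f_start, f_end
        Sweep endpoints in Hz; ``f_start > f_end`` (downsweep), both in
        the open interval (10, 40) Hz.
    duration
        Note length in seconds (0, 3].
    amplitude
        Peak sample magnitude as a fraction of digital full scale (0, 1].
    envelope
        Window name understood by :func:`scipy.signal.get_window`; a tuple
        ``(name, param)`` selects a parameterized window such as
        ``("tukey", 0.5)``.
    """

    f_start: float = 22.5
    f_end: float = 17.5
    duration: float = 0.9
    amplitude: float = 0.5
    envelope: str | tuple = "hann"

    def validate(self) -> None:
        if not self.f_start > self.f_end:
            _fail("f_start", f"must exceed f_end for a downsweep "
                  f"(got {self.f_start} <= {self.f_end})")
        for name, f in (("f_start", self.f_start), ("f_end", self.f_end)):
            if not 10.0 < f < 40.0:
                _fail(name, f"must lie in (10, 40) Hz, got {f}")
        if not 0.0 < self.duration <= 3.0:
            _fail("duration", f"must lie in (0, 3] s, got {self.duration}")
        if not 0.0 < self.amplitude <= 1.0:
            _fail("amplitude", f"must lie in (0, 1], got {self.amplitude}")


#: The frozen canonical note behind the spectral measurement checks: a
#: noiseless 22.5 -> 17.5 Hz linear downsweep of 0.9 s with a Hann envelope.
#: Measured with the standard spectrogram (Hann, 1024 FFT, 90% overlap,
#: fs = 2000) it yields a peak frequency of 19.53 Hz and a 90% bandwidth of
#: 3.91 Hz, matching the medians observed for high-SNR notes in the field.
CANONICAL_NOTE = NoteSpec(f_start=22.5, f_end=17.5, duration=0.9,
                          amplitude=0.5, envelope="hann")


@dataclass(frozen=True)
class SongSpec:
    """Timing structure of one song sequence.

    ``ini_mean`` is the target inter-note interval (onset-to-onset, equal to
    center-to-center for constant-duration notes).  Every
    ``breath_gap_every``-th interval is replaced by a surfacing gap drawn
    uniformly from ``breath_gap_range`` (whose minimum must exceed 30 s so
    the downstream INI range filter removes those intervals).
    ``doublet_offset`` alternates intervals around the mean for doublet
    patterning; the default 0 gives singlet (constant-INI) songs.
    """

    ini_mean: float = 10.0
    ini_jitter_sd: float = 0.3
    doublet_offset: float = 0.0
    n_notes: int = 41
    breath_gap_every: int | None = 15
    breath_gap_range: tuple[float, float] = (35.0, 90.0)
    note: NoteSpec = field(default_factory=NoteSpec)

    def validate(self) -> None:
        if not 4.5 <= self.ini_mean <= 30.0:
            _fail("ini_mean", f"must lie in [4.5, 30] s, got {self.ini_mean}")
        if self.ini_jitter_sd < 0:
            _fail("ini_jitter_sd", "must be non-negative")
        if self.n_notes < 2:
            _fail("n_notes", f"need at least 2 notes, got {self.n_notes}")
        if self.breath_gap_every is not None:
            lo, hi = self.breath_gap_range
            if not 30.0 < lo <= hi:
                _fail("breath_gap_range",
                      f"minimum must exceed 30 s, got {self.breath_gap_range}")
            if self.breath_gap_every < 2:
                _fail("breath_gap_every", "must be >= 2")
        self.note.validate()


@dataclass(frozen=True)
class NoiseSpec:
    """Colored ambient noise: Gaussian, with a power-law spectral slope.

    ``level`` is the broadband RMS in dB re digital full scale (must be
    negative); ``spectral_slope`` in dB/octave (negative = red noise,
    typical of low-frequency ocean ambient).
    """

    level: float = -40.0
    spectral_slope: float = -3.0

    def validate(self) -> None:
        if not self.level < 0:
            _fail("level", f"must be < 0 dB re full scale, got {self.level}")


@dataclass(frozen=True)
class DeploymentSpec:
    """A synthetic buoy deployment.

    The recorder runs on a duty cycle of ``duty_cycle = (minutes on,
    cycle minutes)`` — the default (30, 60) records 30 minutes of every
    hour.  On each calendar day a Bernoulli draw with that month's
    ``monthly_song_prob`` decides whether a song is present (at most one
    analyzed song per day, mirroring the one-song-per-day selection rule);
    ``song_days`` instead forces songs on an explicit set of dates.
    ``pattern_preset`` controls the month-to-INI-mean mapping:

    - ``("SEASONAL", year_tag)``: short-INI mean in Sep-Dec, long-INI mean
      in Mar-May, linear interpolation with inflated jitter in the
      transition months (Jan-Feb, Jul-Aug), with period means taken from
      the preset table for ``year_tag``;
    - ``("CONSTANT_LONG", long_mean)``: the same long mean in every month,
      with ``intruder_days`` songs generated at ``intruder_mean`` instead;
    - ``("CUSTOM", {month: mean})``: explicit mapping.

    ``singer_levels`` are per-singer received levels as peak amplitudes in
    dB re full scale; one singer is drawn per song day.
    """

    date_range: tuple[dt.date, dt.date] = (dt.date(2017, 9, 1),
                                           dt.date(2017, 9, 7))
    duty_cycle: tuple[int, int] = (30, 60)
    fs: int = 2000
    monthly_song_prob: dict[int, float] = field(
        default_factory=lambda: {m: 0.5 for m in range(1, 13)})
    song_days: tuple[dt.date, ...] | None = None
    pattern_preset: tuple = ("SEASONAL", 2)
    singer_levels: tuple[float, ...] = (-20.0, -26.0)
    intruder_days: tuple[dt.date, ...] = ()
    intruder_mean: float = 9.9
    ini_jitter_sd: float = 0.3
    transition_jitter_factor: float = 4.0
    n_notes: int = 41
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    song_offset_s: float = 60.0

    def validate(self) -> None:
        d0, d1 = self.date_range
        if d1 < d0:
            _fail("date_range", f"empty range {d0}..{d1}")
        on, cycle = self.duty_cycle
        if not 0 < on <= cycle:
            _fail("duty_cycle", f"on-time must be in (0, cycle], got {self.duty_cycle}")
        if self.fs <= 0:
            _fail("fs", "must be positive")
        for m, p in self.monthly_song_prob.items():
            if not 0.0 <= p <= 1.0:
                _fail("monthly_song_prob", f"month {m}: {p} not in [0, 1]")
        if not self.singer_levels:
            _fail("singer_levels", "need at least one singer level")
        self.noise.validate()


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def make_note(spec: NoteSpec, fs: float) -> np.ndarray:
    """Synthesize one 20 Hz note as a float waveform in [-1, 1].

    The instantaneous frequency sweeps linearly from ``f_start`` to
    ``f_end`` over ``duration``; the amplitude envelope is the named
    window, rescaled so the peak sample magnitude equals ``amplitude``.
    """
    spec.validate()
    if fs < 4 * spec.f_start:
        _fail("fs", f"must be >= 4*f_start = {4 * spec.f_start}, got {fs}")
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    sweep_rate = (spec.f_end - spec.f_start) / spec.duration
    phase = 2.0 * np.pi * (spec.f_start * t + 0.5 * sweep_rate * t * t)
    env = get_window(spec.envelope, n, fftbins=False)
    x = np.sin(phase) * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= spec.amplitude / peak
    return x


def make_noise(n: int, spec: NoiseSpec, fs: float,
               rng: np.random.Generator) -> np.ndarray:
    """Colored Gaussian noise of length ``n`` at the requested RMS level.

    White noise is shaped in the frequency domain with gain
    ``(f / f_ref) ** (slope_dB / 6.02)`` (f_ref = 100 Hz, clamped below
    1 Hz to avoid the DC singularity), then rescaled exactly to
    ``10**(level/20)`` RMS, so the broadband level invariant holds by
    construction.
    """
    spec.validate()
    white = rng.standard_normal(n, dtype=np.float32)
    if spec.spectral_slope != 0.0:
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        f = np.maximum(freqs, 1.0)
        gain = ((f / 100.0) ** (spec.spectral_slope / 6.0206)).astype(np.float32)
        spec_w = sfft.rfft(white) * gain
        x = sfft.irfft(spec_w, n)
    else:
        x = white
    x = x.astype(np.float64)
    rms = np.sqrt(np.mean(x * x))
    target = 10.0 ** (spec.level / 20.0)
    return x * (target / rms)


# ---------------------------------------------------------------------------
# song timing
# ---------------------------------------------------------------------------

def make_song(spec: SongSpec, start: dt.datetime,
              rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the note onset times of one song.

    Returns ``(onsets, truth)`` where ``onsets`` are note start times in
    seconds relative to ``start`` and ``truth`` is a table with one row per
    note: onset, duration, and the true INI to the following note
    (NaN on the last note).  Inter-onset intervals are
    ``Normal(ini_mean +/- doublet_offset, ini_jitter_sd)`` clipped to
    [4.5, 30] s, with every ``breath_gap_every``-th interval replaced by a
    uniform draw from ``breath_gap_range``.
    """
    spec.validate()
    k = spec.n_notes - 1
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    means = spec.ini_mean + signs * spec.doublet_offset
    intervals = rng.normal(means, spec.ini_jitter_sd)
    intervals = np.clip(intervals, 4.5, 30.0)
    if spec.breath_gap_every is not None:
        gap_idx = np.arange(spec.breath_gap_every - 1, k, spec.breath_gap_every)
        intervals[gap_idx] = rng.uniform(*spec.breath_gap_range, size=gap_idx.size)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    truth = pd.DataFrame({
        "note_index": np.arange(spec.n_notes),
        "onset_s": onsets,
        "duration_s": spec.note.duration,
        "true_ini_s": np.concatenate([intervals, [np.nan]]),
        "start_time": start,
    })
    return onsets, truth


def seasonal_month_means(year_tag: int,
                         fallback_short: float = _FALLBACK_SHORT,
                         fallback_long: float = _FALLBACK_LONG
                         ) -> dict[int, float]:
    """Per-month true INI means (s) for a SEASONAL preset year.

    Short-INI months get the year's short-period mean, long-INI months the
    long-period mean, and the transition months interpolate linearly
    between the flanking periods (Dec->Mar through Jan-Feb; May->Sep
    through Jul-Aug).
    """
    entry = TABLE3_PRESET_MEANS.get(year_tag, {})
    short = entry.get("short") or fallback_short
    long_ = entry.get("long") or fallback_long
    means = {m: short for m in SHORT_MONTHS}
    means.update({m: long_ for m in LONG_MONTHS})
    means[6] = long_
    # Dec (short) -> Mar (long): Jan, Feb at 1/3 and 2/3 of the way.
    means[1] = short + (long_ - short) / 3.0
    means[2] = short + 2.0 * (long_ - short) / 3.0
    # Jun (long) -> Sep (short): Jul, Aug.
    means[7] = long_ + (short - long_) / 3.0
    means[8] = long_ + 2.0 * (short - long_) / 3.0
    return means


def constant_long_mean_for_pooled_target(pooled_target: float, n_songs: int,
                                         n_intruders: int,
                                         intruder_mean: float = 9.9) -> float:
    """Long-song INI mean that makes the pooled period mean hit a target.

    With equal INI counts per song, the pooled mean over a period with
    ``n_intruders`` short-INI intruder songs satisfies
    ``pooled = ((n-k)*L + k*intruder_mean) / n``; solve for ``L``.
    """
    n_long = n_songs - n_intruders
    if n_long <= 0:
        raise ValueError("need at least one non-intruder song")
    return (pooled_target * n_songs - n_intruders * intruder_mean) / n_long


def _month_mean(preset: tuple, month: int) -> tuple[float, float]:
    """(ini_mean, jitter_factor) for a month under a pattern preset."""
    kind = preset[0]
    if kind == "SEASONAL":
        means = seasonal_month_means(preset[1])
        factor = 1.0 if month not in TRANSITION_MONTHS else None
        return means[month], factor or 1.0
    if kind == "CONSTANT_LONG":
        return float(preset[1]), 1.0
    if kind == "CUSTOM":
        return float(preset[1][month]), 1.0
    raise ValueError(f"invalid pattern_preset: unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# deployment assembly
# ---------------------------------------------------------------------------

RAVEN_COLUMNS = ["Selection", "View", "Channel", "Begin Time (s)",
                 "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]

#: Frequency bounds used for truth selection boxes around 20 Hz notes.
NOTE_BOX_LOW_HZ = 15.0
NOTE_BOX_HIGH_HZ = 25.0


def _day_rng(seed: int, day: dt.date) -> np.random.Generator:
    # Child stream keyed by calendar date: adding days never perturbs others.
    ss = np.random.SeedSequence(seed, spawn_key=(day.toordinal(),))
    return np.random.default_rng(ss)


def _recording_id(start: dt.datetime) -> str:
    return start.strftime("NYB_%Y%m%d_%H%M%S")


def deployment_index(spec: DeploymentSpec) -> pd.DataFrame:
    """Metadata index of every duty-cycle-on window of a deployment.

    One row per scheduled recording (id, start), independent of whether
    its waveform is rendered — the basis for review-effort planning.
    """
    spec.validate()
    d0, d1 = spec.date_range
    _, cycle_min = spec.duty_cycle
    rows = []
    for i in range((d1 - d0).days + 1):
        day = d0 + dt.timedelta(days=i)
        for start_min in range(0, 24 * 60, cycle_min):
            start = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(
                minutes=start_min)
            rows.append({"id": _recording_id(start), "start": start})
    return pd.DataFrame(rows)


def make_deployment(spec: DeploymentSpec, render: str = "all"):
    """Generate a deployment: recordings plus a ground-truth table.

    Returns ``(recordings, truth)``.  ``recordings`` is a list of
    :class:`finsong.audio_annotations.Recording`; ``truth`` is a
    Raven-dialect selection table (one row per note) with extra ``Begin
    File``, ``Singer``, ``SongID`` and ``TrueINI_s`` columns.

    ``render='all'`` synthesizes every duty-cycle-on window;
    ``render='song_only'`` synthesizes waveforms only for recordings that
    contain song (the truth table is identical either way), which keeps
    large simulated deployments tractable.
    """
    from .audio_annotations import Recording  # local import, avoids cycle

    spec.validate()
    if render not in ("all", "song_only"):
        raise ValueError(f"render must be 'all' or 'song_only', got {render!r}")

    d0, d1 = spec.date_range
    on_min, cycle_min = spec.duty_cycle
    n_on = on_min * 60 * spec.fs
    days = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
    # Hours at which song is placed: the subsampled review hours, so the
    # generated songs are always within review effort.
    song_hours = (0, 4, 8, 12, 16, 20)

    recordings: list[Recording] = []
    truth_rows: list[pd.DataFrame] = []
    sel_counter = 0

    for day in days:
        rng = _day_rng(spec.seed, day)
        month = day.month
        if spec.song_days is not None:
            has_song = day in spec.song_days
        else:
            has_song = rng.random() < spec.monthly_song_prob.get(month, 0.0)
        song_hour = int(rng.choice(song_hours))
        singer_level = float(rng.choice(spec.singer_levels))

        song_truth = None
        if has_song:
            if day in spec.intruder_days:
                mean = spec.intruder_mean
                jitter = spec.ini_jitter_sd
            else:
                mean, factor = _month_mean(spec.pattern_preset, month)
                jitter = spec.ini_jitter_sd * (
                    spec.transition_jitter_factor
                    if (spec.pattern_preset[0] == "SEASONAL"
                        and month in TRANSITION_MONTHS) else 1.0)
            note = replace(CANONICAL_NOTE,
                           amplitude=10.0 ** (singer_level / 20.0))
            song_spec = SongSpec(ini_mean=mean, ini_jitter_sd=jitter,
                                 n_notes=spec.n_notes, note=note)
            song_start = dt.datetime.combine(
                day, dt.time(song_hour)) + dt.timedelta(
                    seconds=spec.song_offset_s)
            onsets, song_truth = make_song(song_spec, song_start, rng)
            song_truth["_note_amp"] = note.amplitude
            song_truth["_note_spec"] = [note] * len(song_truth)

        for hour_start_min in range(0, 24 * 60, cycle_min):
            rec_start = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(
                minutes=hour_start_min)
            rec_id = _recording_id(rec_start)
            rec_has_song = (song_truth is not None
                            and hour_start_min == song_hour * 60)
            if render == "song_only" and not rec_has_song:
                continue
            x = make_noise(n_on, spec.noise, spec.fs, rng)
            if rec_has_song:
                note_wave = make_note(song_truth["_note_spec"].iloc[0], spec.fs)
                dur = song_truth["duration_s"].iloc[0]
                rows = []
                for _, r in song_truth.iterrows():
                    begin = spec.song_offset_s + r["onset_s"]
                    i0 = int(round(begin * spec.fs))
                    if i0 + note_wave.size > x.size:
                        break  # song truncated by end of duty window
                    x[i0:i0 + note_wave.size] += note_wave
                    sel_counter += 1
                    rows.append({
                        "Selection": sel_counter,
                        "View": "Spectrogram 1",
                        "Channel": 1,
                        "Begin Time (s)": begin,
                        "End Time (s)": begin + dur,
                        "Low Freq (Hz)": NOTE_BOX_LOW_HZ,
                        "High Freq (Hz)": NOTE_BOX_HIGH_HZ,
                        "Begin File": rec_id,
                        "Singer": day.isoformat(),
                        "SongID": f"{rec_id}_song",
                        "TrueINI_s": r["true_ini_s"],
                    })
                if rows:
                    rows[-1]["TrueINI_s"] = np.nan  # truncated tail has no next
                    truth_rows.append(pd.DataFrame(rows))
            np.clip(x, -1.0, 1.0, out=x)
            recordings.append(Recording(id=rec_id, start=rec_start,
                                        fs=spec.fs, samples=x,
                                        duty_phase=spec.duty_cycle))

    if truth_rows:
        truth = pd.concat(truth_rows, ignore_index=True)
    else:
        truth = pd.DataFrame(columns=RAVEN_COLUMNS
                             + ["Begin File", "Singer", "SongID", "TrueINI_s"])
    return recordings, truth
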