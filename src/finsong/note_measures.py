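"""Spectrogram computation and per-selection acoustic measurements.

All measurements follow the Raven Pro conventions used for 20 Hz note
analysis: a Hann-window spectrogram (1024-point FFT, 90% overlap, which at
fs = 2000 Hz gives 1.95 Hz frequency and ~0.05 s temporal resolution),
inband power summed over the selection box, peak frequency at the maximum
bin, center frequency and 90% bandwidth from discrete cumulative-energy
quantiles (the "first bin reaching the threshold" rule, so every reported
frequency is a multiple of fs/nfft), and SNR against an auto-generated
noise window of equal duration and frequency bounds ending five seconds
before the note.

The spectrogram grid is energy-normalized: the sum of the grid over all
frames and bins approximates the time-domain energy ``sum(x**2)`` (exact
up to window edge effects), so Parseval-style checks and inband power in
dB re full-scale energy are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio_annotations import Recording, Selection

__all__ = [
    "SpectrogramGrid",
    "spectrogram",
    "inband_power",
    "peak_frequency",
    "center_frequency",
    "bandwidth90",
    "center_time",
    "note_snr",
    "measure_notes",
    "MEASUREMENT_COLUMNS",
]

NOISE_GAP_S = 5.0  #: noise window ends this many seconds before note begin
_EPS = 1e-300


@dataclass
class SpectrogramGrid:
    """Time-frequency energy grid (frames x one-sided frequency bins)."""

    psd: np.ndarray          # energy per (frame, bin); sums to signal energy
    frame_times: np.ndarray  # frame-center times, s
    bin_freqs: np.ndarray    # k * fs / nfft, Hz
    fs: float
    nfft: int
    hop: int
    window: str = "hann"

    @property
    def bin_width(self) -> float:
        return self.fs / self.nfft

    @property
    def hop_seconds(self) -> float:
        return self.hop / self.fs


def spectrogram(recording: Recording, nfft: int = 1024,
                overlap: float = 0.9, window: str = "hann",
                t_start: float = 0.0,
                t_stop: float | None = None) -> SpectrogramGrid:
    """Hann spectrogram with 90% overlap (hop = floor(nfft/10) samples).

    ``t_start``/``t_stop`` restrict the analysis to a time span of the
    recording (frame times stay recording-relative); the default covers
    the whole recording.  Raises when the analyzed span is shorter than
    one analysis window.
    """
    fs = float(recording.fs)
    i0 = max(int(t_start * fs), 0)
    i1 = (recording.samples.size if t_stop is None
          else min(int(np.ceil(t_stop * fs)), recording.samples.size))
    x = np.asarray(recording.samples[i0:i1], dtype=np.float32)
    if x.size < nfft:
        raise ValueError(f"recording {recording.id}: analyzed span of "
                         f"{x.size} samples is shorter than one "
                         f"{nfft}-sample window")
    hop = int(nfft * (1.0 - overlap))
    win = sps.get_window(window, nfft)
    freqs, times, sxx = sps.spectrogram(
        x, fs=fs, window=win.astype(np.float32), nperseg=nfft,
        noverlap=nfft - hop, detrend=False, scaling="density", mode="psd")
    # scipy's density PSD -> per-frame energy contribution such that the
    # grid total matches sum(x**2) (interior coverage; window-gain exact).
    energy = sxx.T.astype(np.float64) * (fs * hop / nfft)
    return SpectrogramGrid(psd=energy, frame_times=times + i0 / fs,
                           bin_freqs=freqs, fs=fs, nfft=nfft, hop=hop,
                           window=window)


def _box(grid: SpectrogramGrid, begin: float, end: float,
         low: float, high: float) -> np.ndarray:
    """Sub-grid (view) of frames/bins intersecting a selection box.

    Frame times and bin frequencies are sorted, so the box reduces to two
    ``searchsorted`` slices.
    """
    t0 = int(np.searchsorted(grid.frame_times, begin, side="left"))
    t1 = int(np.searchsorted(grid.frame_times, end, side="right"))
    f0 = int(np.searchsorted(grid.bin_freqs, low, side="left"))
    f1 = int(np.searchsorted(grid.bin_freqs, high, side="right"))
    if t1 <= t0 or f1 <= f0:
        raise ValueError(
            f"selection box [{begin}, {end}] s x [{low}, {high}] Hz does not "
            "intersect the spectrogram grid")
    return grid.psd[t0:t1, f0:f1]


def inband_power(grid: SpectrogramGrid, sel: Selection) -> float:
    """Total energy in the selection box, dB re unit full-scale energy."""
    e = _box(grid, sel.begin, sel.end, sel.low, sel.high).sum()
    return 10.0 * np.log10(max(e, _EPS))


def _band_energy(grid: SpectrogramGrid, sel: Selection) -> tuple[np.ndarray,
                                                                 np.ndarray]:
    """(per-bin energy summed over frames, bin frequencies) inside the box."""
    fi = (grid.bin_freqs >= sel.low) & (grid.bin_freqs <= sel.high)
    box = _box(grid, sel.begin, sel.end, sel.low, sel.high)
    return box.sum(axis=0), grid.bin_freqs[fi]


def peak_frequency(grid: SpectrogramGrid, sel: Selection) -> float:
    """Frequency of the maximum-energy bin (ties -> lowest bin)."""
    per_bin, freqs = _band_energy(grid, sel)
    return float(freqs[int(np.argmax(per_bin))])


def _cum_quantile_freq(per_bin: np.ndarray, freqs: np.ndarray,
                       q: float) -> float:
    """Lowest bin frequency at which ascending cumulative energy >= q."""
    c = np.cumsum(per_bin)
    total = c[-1]
    if total <= 0:
        raise ValueError("selection contains no energy")
    idx = int(np.searchsorted(c, q * total))
    return float(freqs[min(idx, freqs.size - 1)])


def center_frequency(grid: SpectrogramGrid, sel: Selection) -> float:
    """Energy-median frequency (discrete 50% cumulative-energy bin)."""
    per_bin, freqs = _band_energy(grid, sel)
    return _cum_quantile_freq(per_bin, freqs, 0.50)


def bandwidth90(grid: SpectrogramGrid, sel: Selection) -> float:
    """90% bandwidth: f95 - f5 from the discrete cumulative-energy rule."""
    per_bin, freqs = _band_energy(grid, sel)
    f5 = _cum_quantile_freq(per_bin, freqs, 0.05)
    f95 = _cum_quantile_freq(per_bin, freqs, 0.95)
    return f95 - f5


def center_time(sel: Selection) -> float:
    """Selection midpoint in recording-relative seconds."""
    return 0.5 * (sel.begin + sel.end)


def note_snr(grid: SpectrogramGrid, sel: Selection,
             other_selections: list[Selection] | None = None
             ) -> tuple[float, tuple[float, float], list[str]]:
    """SNR of a note against its auto-generated noise window.

    The noise window has the same duration and frequency bounds as the
    note and ends exactly ``NOISE_GAP_S`` seconds before the note begins.
    With S the linear inband power of the note box (signal + noise) and N
    that of the noise box, ``snr = 10*log10((S - N)/N)``.

    Returns ``(snr_db, (noise_begin, noise_end), flags)``.  ``snr_db`` is
    NaN — with an explanatory flag — when the noise window falls outside
    the recording or when S <= N; a ``noise_overlaps_note`` flag (the
    measurement still proceeds) marks noise windows that intersect another
    provided selection.
    """
    dur = sel.end - sel.begin
    nz_begin = sel.begin - NOISE_GAP_S - dur
    nz_end = sel.begin - NOISE_GAP_S
    flags: list[str] = []
    if nz_begin < grid.frame_times[0] - grid.hop_seconds:
        return np.nan, (nz_begin, nz_end), ["noise_window_out_of_bounds"]
    if other_selections:
        for o in other_selections:
            if o is not sel and o.begin < nz_end and o.end > nz_begin:
                flags.append("noise_overlaps_note")
                break
    s_db = inband_power(grid, sel)
    noise_sel = Selection(selection_id=-1, recording_id=sel.recording_id,
                          begin=max(nz_begin, 0.0), end=nz_end,
                          low=sel.low, high=sel.high)
    n_db = inband_power(grid, noise_sel)
    s_lin = 10.0 ** (s_db / 10.0)
    n_lin = 10.0 ** (n_db / 10.0)
    if s_lin <= n_lin:
        flags.append("snr_undefined")
        return np.nan, (nz_begin, nz_end), flags
    return 10.0 * np.log10((s_lin - n_lin) / n_lin), (nz_begin, nz_end), flags


MEASUREMENT_COLUMNS = ["Selection", "Begin File", "Begin Time (s)",
                       "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)",
                       "Center Time (s)", "Inband Power (dB)",
                       "Peak Freq (Hz)", "Center Freq (Hz)", "BW 90% (Hz)",
                       "SNR NIST Quick (dB)", "Noise Begin (s)",
                       "Noise End (s)", "Flags"]


def measure_notes(recording: Recording, selections: list[Selection],
                  grid: SpectrogramGrid | None = None) -> pd.DataFrame:
    """Measure every selection of a recording; one row per selection.

    Deterministic: repeated runs on the same inputs give identical tables.
    """
    if grid is None and selections:
        # analyze only the span the selections (and their auto noise
        # windows, NOISE_GAP_S + duration before each note) require
        durs = [s.end - s.begin for s in selections]
        t0 = min(s.begin for s in selections) - NOISE_GAP_S - max(durs) - 1.0
        t1 = max(s.end for s in selections) + 1.0
        grid = spectrogram(recording, t_start=max(t0, 0.0), t_stop=t1)
    rows = []
    for sel in selections:
        sel.validate(recording)
        snr, (nz0, nz1), flags = note_snr(grid, sel, selections)
        rows.append({
            "Selection": sel.selection_id,
            "Begin File": sel.recording_id or recording.id,
            "Begin Time (s)": sel.begin,
            "End Time (s)": sel.end,
            "Low Freq (Hz)": sel.low,
            "High Freq (Hz)": sel.high,
            "Center Time (s)": center_time(sel),
            "Inband Power (dB)": inband_power(grid, sel),
            "Peak Freq (Hz)": peak_frequency(grid, sel),
            "Center Freq (Hz)": center_frequency(grid, sel),
            "BW 90% (Hz)": bandwidth90(grid, sel),
            "SNR NIST Quick (dB)": snr,
            "Noise Begin (s)": nz0,
            "Noise End (s)": nz1,
            "Flags": ";".join(flags),
            **sel.annotations,
        })
    return pd.DataFrame(rows, columns=None if rows else MEASUREMENT_COLUMNS)
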