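import datetime as dt

import numpy as np
import pytest

from finsong.audio_annotations import Recording, Selection
from finsong.note_measures import spectrogram
from finsong.songsynth import CANONICAL_NOTE, make_note

FS = 2000


@pytest.fixture(scope="session")
def canonical_recording() -> Recording:
    """The canonical 20 Hz note embedded in a silent 10 s recording at t=4 s."""
    note = make_note(CANONICAL_NOTE, FS)
    x = np.zeros(FS * 10)
    x[FS * 4:FS * 4 + note.size] += note
    return Recording(id="canon", start=dt.datetime(2017, 9, 5, 4), fs=FS,
                     samples=x)


@pytest.fixture(scope="session")
def canonical_grid(canonical_recording):
    return spectrogram(canonical_recording)


@pytest.fixture(scope="session")
def canonical_selection() -> Selection:
    return Selection(selection_id=1, recording_id="canon",
                     begin=4.0, end=4.0 + CANONICAL_NOTE.duration,
                     low=15.0, high=25.0)


def tone_recording(freq: float, duration: float = 60.0,
                   amplitude: float = 0.5, fs: int = FS) -> Recording:
    t = np.arange(int(duration * fs)) / fs
    return Recording(id=f"tone{freq}", start=dt.datetime(2017, 9, 5), fs=fs,
                     samples=amplitude * np.sin(2 * np.pi * freq * t))


@pytest.fixture(scope="session")
def tone20_grid():
    rec = tone_recording(20.0)
    return rec, spectrogram(rec)
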