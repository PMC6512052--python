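import numpy as np
import pytest

from ecgbeats.io import AnnotatedRecord, BeatAnnotation


def make_record(peak_samples, symbols, n_samples=None, fs=360.0, record_id="rec"):
    """A flat-signal record with unit spikes at the given peak samples."""
    n = n_samples or (max(peak_samples) + 200 if peak_samples else 100)
    signal = np.zeros(n)
    for p in peak_samples:
        signal[p] = 1.0
    anns = [BeatAnnotation(p, s) for p, s in zip(peak_samples, symbols)]
    return AnnotatedRecord(record_id=record_id, signal=signal, fs=fs, annotations=anns)


@pytest.fixture
def uniform_record():
    """10 evenly spaced normal beats, one every 360 samples."""
    peaks = [360 * i for i in range(1, 11)]
    return make_record(peaks, ["N"] * 10, n_samples=360 * 12)
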