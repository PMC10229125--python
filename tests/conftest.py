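import numpy as np
import pytest

from alquant.spikes import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def match_rate(detected: SpikeTrain, truth: SpikeTrain, tol_s: float = 0.0005):
    """(recall, precision) of detected spike times against ground truth."""
    det = detected.spike_times_s
    tru = truth.spike_times_s
    if tru.size == 0:
        return 1.0, (1.0 if det.size == 0 else 0.0)
    if det.size == 0:
        return 0.0, 1.0
    recall = np.mean([np.min(np.abs(det - t)) <= tol_s for t in tru])
    precision = np.mean([np.min(np.abs(tru - t)) <= tol_s for t in det])
    return float(recall), float(precision)
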