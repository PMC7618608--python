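import numpy as np
import pytest

from rhythm_ioi.sequence_model import AnnotationSet, ElementRecord


def make_annotations(onsets, durations=0.05, classes="C", recording="rec",
                     individual="bird"):
    """Annotation set from onset times (single recording/individual)."""
    n = len(onsets)
    if np.isscalar(durations):
        durations = [durations] * n
    if isinstance(classes, str):
        classes = [classes] * n
    records = [
        ElementRecord(recording=recording, individual=individual,
                      onset=float(o), offset=float(o) + float(d),
                      element_class=c)
        for o, d, c in zip(onsets, durations, classes)
    ]
    return AnnotationSet(records)


def annotations_from_iois(iois, classes=None, individual="bird",
                          recording="rec", duration=None):
    """One bout whose inter-onset intervals are exactly ``iois``."""
    iois = np.asarray(iois, dtype=float)
    onsets = np.concatenate([[0.0], np.cumsum(iois)])
    gap = min(float(iois.min()) / 2, 0.02)
    durations = [float(i) - gap for i in iois] + [0.05]
    cls = classes if classes is not None else "C"
    return make_annotations(onsets, durations, cls, recording, individual)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_annotations():
    return make_annotations([0.0, 0.2, 0.5, 0.9], durations=0.05)
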