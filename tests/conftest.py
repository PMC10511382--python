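import numpy as np
import pytest

from tva_arousal.tva_model import (
    LETTER_ALPHABET,
    WholeReportDataset,
    WholeReportTrial,
)


def make_whole_report_trials(scores, exposure_ms=100.0, masked=True):
    """Build trials whose report scores equal the given integers (0..6)."""
    trials = []
    for s in scores:
        displayed = LETTER_ALPHABET[:6]
        trials.append(
            WholeReportTrial(
                exposure_ms=exposure_ms,
                masked=masked,
                displayed=displayed,
                reported=displayed[:s],
            )
        )
    return trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    return WholeReportDataset(
        subject_id="toy", trials=make_whole_report_trials([0, 2, 4])
    )
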