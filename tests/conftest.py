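"""Shared fixtures: the default eye model, a fast pupil grid, and the
published TCA condition medians used as a worked example throughout."""

import numpy as np
import pytest

from chromasim import ChromaticEyeModel, PupilSpec, TCAMeasurement


@pytest.fixture(scope="session")
def eye_model():
    return ChromaticEyeModel()


@pytest.fixture(scope="session")
def fast_pupil():
    """128 samples across a 4-mm pupil: fast but still well resolved."""
    return PupilSpec(samples_across=128, padding=4)


#: Median horizontal TCA (arcmin) per (eye, pair, lca_state) condition.
TCA_CONDITION_MEDIANS = {
    ("left", "blue-vs-red", "corrected"): -1.04,
    ("left", "blue-vs-red", "uncorrected"): -0.30,
    ("right", "blue-vs-red", "corrected"): 2.25,
    ("right", "blue-vs-red", "uncorrected"): -0.65,
    ("left", "green-vs-red", "corrected"): -0.54,
    ("left", "green-vs-red", "uncorrected"): -0.19,
    ("right", "green-vs-red", "corrected"): 1.30,
    ("right", "green-vs-red", "uncorrected"): -0.41,
}


@pytest.fixture(scope="session")
def printed_tca_medians():
    return [
        TCAMeasurement(eye=e, pair=p, lca_state=s, horizontal=h, vertical=0.0)
        for (e, p, s), h in TCA_CONDITION_MEDIANS.items()
    ]
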