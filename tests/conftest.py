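"""Shared fixtures: small ground-truth videos rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cellspin import SelfRotationModel, render, single_cell_scene


@pytest.fixture(scope="session")
def study_video():
    """Short video under the reference study conditions (54.76 rpm, 15 fps)."""
    spec = single_cell_scene(rpm=54.76, n_frames=80, seed=1)
    seq, manifest = render(spec)
    return seq, manifest


@pytest.fixture(scope="session")
def study_fit(study_video):
    seq, manifest = study_video
    res = SelfRotationModel(seq, roi=(64, 64, 16, 16), lbound="auto").fit()
    return res, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
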