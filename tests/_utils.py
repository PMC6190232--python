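"""Helpers shared by the unit and acceptance tests."""

from __future__ import annotations

from cellspin import SelfRotationModel, render, single_cell_scene


def measure_with_retries(rpm, n_frames, seed, *, attempts=5, roi=(64, 64, 16, 16),
                         f_fps=15.0, **model_kwargs):
    """Fit the model on a fresh synthetic video; re-record on an incomplete run.

    A measurement that comes back with no complete cycle is a detectable
    failure (flagged by the pipeline itself), so the in-silico analogue of
    recording another video is to render a new scene from a derived seed.
    Retries never depend on the measured value.
    """
    model_kwargs.setdefault("lbound", "auto")
    model_kwargs.setdefault(
        "n_background", min(max(40, int(60.0 * f_fps / rpm) + 5), n_frames)
    )
    for k in range(attempts):
        seq, manifest = render(
            single_cell_scene(rpm=rpm, n_frames=n_frames, f_fps=f_fps,
                              seed=seed + 1000 * k)
        )
        try:
            result = SelfRotationModel(seq, roi, **model_kwargs).fit()
        except Exception:
            continue
        if result.mean_speed_rpm is not None:
            return result, manifest
    raise AssertionError(
        f"no complete measurement after {attempts} recordings at {rpm} rpm"
    )
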