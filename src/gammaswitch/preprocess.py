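"""Referencing, channel exclusion, and epoching around cue onsets.

Gameplay epochs span a 2400 ms window centered on each cue onset
(response detection); because the task is self-paced with a ~1.36 s
mean inter-response interval, neighboring epochs overlap by design.
Reference epochs of the same length are sampled from a non-gameplay
rest recording, one per trial, without overlap whenever the rest
recording is long enough.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .datatypes import ElectrodeSite, EpochSet, Recording, TrialRecord, trials_to_frame

logger = logging.getLogger(__name__)

EPOCH_MS = 2400.0  # full epoch length, centered on the cue


def common_average_reference(
    recording: Recording, montage: Sequence[ElectrodeSite]
) -> Recording:
    """Re-reference to the common average of *included* channels.

    Excluded sites (seizure onset zone, lesion, artifact) contribute
    nothing to the average and are dropped from the output.  After CAR,
    the mean across retained channels is zero at every sample.
    """
    by_label = {s.label: s for s in montage}
    keep = [
        i
        for i, name in enumerate(recording.ch_names)
        if name in by_label and by_label[name].included
    ]
    if len(keep) < 2:
        raise ValueError("common average reference needs >= 2 included channels")
    data = recording.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(
        data=data,
        sfreq=recording.sfreq,
        ch_names=[recording.ch_names[i] for i in keep],
        events=recording.events.copy(),
        session_bounds=list(recording.session_bounds),
        kind=recording.kind,
    )


def _epoch_half_samples(sfreq: float) -> int:
    return int(round(EPOCH_MS / 2 / 1000.0 * sfreq))


def extract_epochs(
    recording: Recording, trials: Sequence[TrialRecord]
) -> EpochSet:
    """One 2400-ms epoch per trial, centered on its cue onset.

    A trial is retained only if its full window fits inside the
    recording and inside its own session (windows crossing a session
    boundary would splice unrelated signal); dropped trials are counted
    and logged.
    """
    half = _epoch_half_samples(recording.sfreq)
    n_len = 2 * half  # 2400 samples at 1000 Hz
    kept_rows = []
    segments = []
    for trial in trials:
        cue = trial.cue_onset
        if cue is None:
            raise ValueError("trial lacks cue_onset")
        a, b = cue - half, cue + half
        if a < 0 or b > recording.n_samples:
            continue
        if recording.session_bounds:
            sess = recording.session_of_sample(cue)
            if sess is None:
                continue
            s0, s1 = recording.session_bounds[sess]
            if a < s0 or b > s1:
                continue
        segments.append(recording.data[:, a:b])
        kept_rows.append(trial)
    n_dropped = len(trials) - len(kept_rows)
    if n_dropped:
        logger.info(
            "extract_epochs: dropped %d/%d trials without a full in-session window",
            n_dropped,
            len(trials),
        )
    data = (
        np.stack(segments)
        if segments
        else np.empty((0, recording.n_channels, n_len))
    )
    return EpochSet(
        data=data,
        sfreq=recording.sfreq,
        ch_names=list(recording.ch_names),
        alignment=half,
        kind="gameplay",
        trial_rows=trials_to_frame(kept_rows) if kept_rows else None,
        n_dropped=n_dropped,
    )


def sample_reference_epochs(
    rest: Recording, n: int, rng: np.random.Generator
) -> EpochSet:
    """Sample ``n`` 2400-ms reference epochs from a rest recording.

    Epochs are pairwise non-overlapping when the recording is long
    enough (starts drawn by the uniform spacing construction); otherwise
    overlapping starts are drawn uniformly and a warning is logged.
    """
    half = _epoch_half_samples(rest.sfreq)
    n_len = 2 * half
    if rest.n_samples < n_len:
        raise ValueError("rest recording shorter than one 2400 ms epoch")
    slack = rest.n_samples - n * n_len
    if slack >= 0:
        # Non-overlapping uniform placement: sort n uniform draws over the
        # slack, then lay epochs end-to-end after each offset.
        gaps = np.sort(rng.integers(0, slack + 1, size=n))
        starts = gaps + np.arange(n) * n_len
    else:
        logger.warning(
            "rest recording too short for %d non-overlapping epochs; sampling with overlap",
            n,
        )
        starts = rng.integers(0, rest.n_samples - n_len + 1, size=n)
    data = np.stack([rest.data[:, s : s + n_len] for s in starts])
    return EpochSet(
        data=data,
        sfreq=rest.sfreq,
        ch_names=list(rest.ch_names),
        alignment=half,
        kind="reference",
    )
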