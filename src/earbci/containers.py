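"""Core in-memory containers for continuous recordings, events and epoched trials.

Conventions used throughout the package:

* sample indices are 0-based and time 0 is the first sample;
* epoch windows are half-open ``[start, stop)`` in samples;
* signal values are in microvolts (µV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: montage group tags recognised by the package
MONTAGE_GROUPS = ("in_ear_left", "in_ear_right", "mastoid", "occipital", "other")


def default_montage_tags(channel_labels) -> dict:
    """Infer montage groups from conventional labels (L1-L5, R1-R5, M1/M2, OZ)."""
    tags = {}
    for lab in channel_labels:
        u = lab.upper()
        if u.startswith("L") and u[1:].isdigit():
            tags[lab] = "in_ear_left"
        elif u.startswith("R") and u[1:].isdigit():
            tags[lab] = "in_ear_right"
        elif u in ("M1", "M2"):
            tags[lab] = "mastoid"
        elif u in ("OZ", "O1", "O2"):
            tags[lab] = "occipital"
        else:
            tags[lab] = "other"
    return tags


@dataclass
class Recording:
    """Continuous multi-channel EEG, ``data`` is channel x sample in µV."""

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    montage_tags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channel x sample)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.montage_tags:
            self.montage_tags = default_montage_tags(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channels_in_group(self, *groups: str) -> list[int]:
        """Indices of channels whose montage tag is in ``groups``."""
        return [
            i
            for i, lab in enumerate(self.channel_labels)
            if self.montage_tags.get(lab, "other") in groups
        ]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.rate, list(self.channel_labels), dict(self.montage_tags)
        )


@dataclass
class StimulusSpec:
    """One stimulation class: flicker frequency, initial phase and duration."""

    frequency_hz: float
    phase_rad: float = 0.0
    duration_s: float = 1.0

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be positive, got {self.frequency_hz}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")


@dataclass
class EventTable:
    """Stimulus schedule: onset (s from recording start), class, frequency, phase."""

    onset_s: np.ndarray
    class_index: np.ndarray
    frequency_hz: np.ndarray
    phase_rad: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.class_index = np.asarray(self.class_index, dtype=int)
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        n = len(self.onset_s)
        for name in ("class_index", "frequency_hz", "phase_rad", "duration_s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"EventTable column {name} has wrong length")
        if np.any(np.diff(self.onset_s) < 0):
            raise ValueError("event onsets must be non-decreasing")
        if np.any(self.class_index < 0):
            raise ValueError("class_index must be >= 0")

    def __len__(self) -> int:
        return len(self.onset_s)


@dataclass
class TrialSet:
    """Epoched trials: ``data`` is trial x channel x sample.

    ``labels`` holds the class index per trial, ``blocks`` (optional) the
    repetition-block index used by leave-one-block-out cross-validation, and
    ``stimuli`` the per-class stimulus specification.
    """

    data: np.ndarray
    rate: float
    labels: np.ndarray
    stimuli: list[StimulusSpec]
    channel_labels: list[str]
    blocks: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("TrialSet data must be 3-D (trial x channel x sample)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.n_trials and self.labels.size and self.labels.max() >= len(self.stimuli):
            raise ValueError("every label must index a stimulus")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one channel label per channel required")
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks, dtype=int)
            if len(self.blocks) != self.n_trials:
                raise ValueError("one block index per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.stimuli)

    def select(self, mask) -> "TrialSet":
        """Subset of trials selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        return TrialSet(
            self.data[mask],
            self.rate,
            self.labels[mask],
            self.stimuli,
            list(self.channel_labels),
            None if self.blocks is None else self.blocks[mask],
        )


def slice_epochs(rec: Recording, events: EventTable, window_s: float) -> TrialSet:
    """Cut fixed-length epochs out of a continuous recording.

    Trial *i* covers samples ``[round(onset_i * rate), round(onset_i * rate) +
    round(window_s * rate))``; onsets are rounded to the nearest sample.
    """
    n_win = int(round(window_s * rec.rate))
    starts = np.round(events.onset_s * rec.rate).astype(int)
    bad = [
        i
        for i, s in enumerate(starts)
        if s < 0 or s + n_win > rec.n_samples
    ]
    if bad:
        raise ValueError(
            f"epoch window ({window_s} s) exceeds recording bounds for events {bad}"
        )
    if len(events) == 0:
        data = np.empty((0, rec.n_channels, n_win))
        stimuli: list[StimulusSpec] = []
    else:
        data = np.stack([rec.data[:, s : s + n_win] for s in starts])
        n_classes = int(events.class_index.max()) + 1
        stimuli = [StimulusSpec(1.0, 0.0, window_s)] * n_classes
        for i in range(len(events)):
            c = int(events.class_index[i])
            stimuli[c] = StimulusSpec(
                float(events.frequency_hz[i]),
                float(events.phase_rad[i]),
                float(events.duration_s[i]),
            )
    logger.info(
        "slice_epochs: %d events, window %.3f s -> trials %s", len(events), window_s, data.shape
    )
    return TrialSet(data, rec.rate, events.class_index, stimuli, list(rec.channel_labels))
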