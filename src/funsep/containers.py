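"""Core in-memory containers for continuous and epoched EEG.

A :class:`Recording` holds a continuous multichannel potential matrix in
microvolts together with its sampling rate, a simple 2-D electrode layout and
an event table.  An :class:`EpochSet` holds trials cut around a named trigger
with an explicit time axis.  Both round-trip to an ``.npz`` array container
with a JSON metadata sidecar; events are stored as a two-column tab-separated
file (sample, label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Event", "Recording", "EpochSet", "read_events_tsv", "write_events_tsv"]


@dataclass(frozen=True)
class Event:
    sample: int
    label: str


@dataclass
class Recording:
    """Continuous channels x samples EEG in microvolts."""

    data: np.ndarray            # (n_channels, n_samples), uV
    fs: float                   # Hz
    channel_labels: list[str]
    channel_pos: np.ndarray     # (n_channels, 2), unit-disc layout coordinates
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def event_samples(self, label: str) -> np.ndarray:
        """Samples of all events carrying ``label``, in temporal order."""
        return np.array([e.sample for e in self.events if e.label == label], dtype=int)

    def copy(self, data: np.ndarray | None = None, fs: float | None = None,
             events: list[Event] | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            channel_pos=self.channel_pos.copy(),
            events=list(self.events) if events is None else events,
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write to ``<path>.npz`` plus ``<path>.json`` and ``<path>.events.tsv``."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data,
                            channel_pos=self.channel_pos)
        meta = {"fs": self.fs, "channel_labels": self.channel_labels}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        write_events_tsv(path.with_suffix(".events.tsv"), self.events)

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        events_path = path.with_suffix(".events.tsv")
        events = read_events_tsv(events_path) if events_path.exists() else []
        return cls(data=arrays["data"], fs=meta["fs"],
                   channel_labels=meta["channel_labels"],
                   channel_pos=arrays["channel_pos"], events=events)


@dataclass
class EpochSet:
    """Trials x channels x samples cut around a named trigger."""

    data: np.ndarray            # (n_trials, n_channels, n_samples), uV
    fs: float
    t0_offset: float            # time of first sample relative to the trigger, s
    trigger_label: str
    trial_ids: np.ndarray       # original event indices, unique and sorted

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if self.trial_ids.shape[0] != self.data.shape[0]:
            raise ValueError("one trial id per trial required")
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise ValueError("trial ids must be unique")
        if np.any(np.diff(self.trial_ids) < 0):
            raise ValueError("trial ids must be sorted")

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
    def times(self) -> np.ndarray:
        """Time axis in seconds: ``t0_offset + k / fs``."""
        return self.t0_offset + np.arange(self.n_samples) / self.fs

    def channel(self, idx: int) -> np.ndarray:
        """Trials x samples view of a single channel."""
        return self.data[:, idx, :]

    def subset(self, keep: np.ndarray) -> "EpochSet":
        keep = np.asarray(keep)
        return EpochSet(data=self.data[keep], fs=self.fs, t0_offset=self.t0_offset,
                        trigger_label=self.trigger_label, trial_ids=self.trial_ids[keep])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data,
                            trial_ids=self.trial_ids)
        meta = {"fs": self.fs, "t0_offset": self.t0_offset,
                "trigger_label": self.trigger_label}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data=arrays["data"], fs=meta["fs"], t0_offset=meta["t0_offset"],
                   trigger_label=meta["trigger_label"], trial_ids=arrays["trial_ids"])


def write_events_tsv(path: str | Path, events: list[Event]) -> None:
    lines = ["sample\tlabel"] + [f"{e.sample}\t{e.label}" for e in events]
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_tsv(path: str | Path) -> list[Event]:
    lines = Path(path).read_text().strip().splitlines()
    out = []
    for line in lines[1:]:
        sample, label = line.split("\t")
        out.append(Event(sample=int(sample), label=label))
    return out
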