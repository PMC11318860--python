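"""Button-press event trains and emotion-duration targets.

During each song, listeners hold one of four buttons reporting their
ongoing emotional state: neutral, pleasure, chill (goosebumps/shivers) or
tear (weeping/lump in the throat); chill and tear may co-occur.  The
behavioral targets are per-trial total durations of each state, cleaned by
two rules applied in this order:

1. presses shorter than a minimum duration (default 1 s) are discarded as
   accidental, then
2. consecutive presses of the same label are merged into one sustained
   event whose duration is the *sum* of the merged press durations
   (repeat presses of the same button are read as one sustained report).

Because dropping precedes merging, a sub-threshold press sandwiched
between two same-label presses bridges them into a single event.

Events are exchanged as BIDS-style ``events.tsv`` tables (columns
``onset``, ``duration``, ``trial_type``; seconds; time origin at music
onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EMOTION_LABELS = ("neutral", "pleasure", "chill", "tear")
_COOCCUR_OK = frozenset({frozenset({"chill", "tear"})})


@dataclass(frozen=True)
class EventTrain:
    """Ordered button events for one trial.

    ``events`` is a DataFrame with columns onset, duration, trial_type
    (seconds, labels from :data:`EMOTION_LABELS`); rows are sorted by
    onset on construction. Every event must fit inside
    ``trial_duration``.
    """

    events: pd.DataFrame
    trial_duration: float

    def __post_init__(self):
        df = pd.DataFrame(self.events, columns=["onset", "duration", "trial_type"])
        df = df.astype({"onset": float, "duration": float, "trial_type": str})
        df = df.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "events", df)
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if len(df):
            if (df["duration"] <= 0).any():
                raise ValueError("event durations must be positive")
            if (df["onset"] < -1e-9).any():
                raise ValueError("event onsets must be non-negative")
            if (df["onset"] + df["duration"] > self.trial_duration + 1e-6).any():
                raise ValueError("event extends beyond trial_duration")
            bad = ~df["trial_type"].isin(EMOTION_LABELS)
            if bad.any():
                raise ValueError(
                    f"unknown labels: {sorted(df.loc[bad, 'trial_type'].unique())}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def from_records(cls, records: Sequence[tuple], trial_duration: float) -> "EventTrain":
        df = pd.DataFrame(records, columns=["onset", "duration", "trial_type"])
        return cls(events=df, trial_duration=trial_duration)


@dataclass(frozen=True)
class EmotionSummary:
    """Per-trial totals and counts for each emotion label."""

    durations: Mapping[str, float]
    counts: Mapping[str, int]
    trial_duration: float

    def __post_init__(self):
        object.__setattr__(self, "durations",
                           {l: float(self.durations.get(l, 0.0)) for l in EMOTION_LABELS})
        object.__setattr__(self, "counts",
                           {l: int(self.counts.get(l, 0)) for l in EMOTION_LABELS})


def _check_overlaps(df: pd.DataFrame) -> None:
    ends = (df["onset"] + df["duration"]).to_numpy()
    onsets = df["onset"].to_numpy()
    labels = df["trial_type"].to_numpy()
    for i in range(len(df) - 1):
        for j in range(i + 1, len(df)):
            if onsets[j] >= ends[i] - 1e-9:
                break
            pair = frozenset({labels[i], labels[j]})
            if len(pair) == 2 and pair not in _COOCCUR_OK:
                warnings.warn(
                    f"overlapping events {labels[i]!r}/{labels[j]!r} at "
                    f"{onsets[j]:.2f}s kept as-is",
                    stacklevel=3,
                )


def clean_presses(raw: EventTrain, min_duration: float = 1.0) -> EventTrain:
    """Drop sub-threshold presses, then merge consecutive same-label runs.

    Merged events keep the first onset and carry the *sum* of merged
    durations (inter-press gaps are not counted).  Overlaps between
    different labels other than the permitted chill+tear co-occurrence
    trigger a validation warning but are kept.
    """
    df = raw.events
    df = df[df["duration"] >= min_duration].reset_index(drop=True)
    merged: list[list] = []
    for row in df.itertuples(index=False):
        if merged and merged[-1][2] == row.trial_type:
            merged[-1][1] += row.duration
        else:
            merged.append([row.onset, row.duration, row.trial_type])
    out = pd.DataFrame(merged, columns=["onset", "duration", "trial_type"])
    if len(out):
        _check_overlaps(out)
    return EventTrain(events=out, trial_duration=raw.trial_duration)


def emotion_durations(clean: EventTrain) -> EmotionSummary:
    """Total duration and event count per label (absent labels are 0)."""
    if len(clean):
        g = clean.events.groupby("trial_type")["duration"]
        durations = g.sum().to_dict()
        counts = g.size().to_dict()
    else:
        durations, counts = {}, {}
    return EmotionSummary(durations=durations, counts=counts,
                          trial_duration=clean.trial_duration)


def participant_means(summaries: Sequence[EmotionSummary]) -> dict:
    """Arithmetic mean of per-trial totals across a participant's trials."""
    if not summaries:
        raise ValueError("need at least one trial summary")
    return {
        label: float(np.mean([s.durations[label] for s in summaries]))
        for label in EMOTION_LABELS
    }


def read_events(path: str | Path, trial_duration: float) -> EventTrain:
    """Read a BIDS-style ``events.tsv`` (onset, duration, trial_type)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return EventTrain(events=df[["onset", "duration", "trial_type"]],
                      trial_duration=trial_duration)


def write_events(train: EventTrain, path: str | Path) -> None:
    train.events.to_csv(path, sep="\t", index=False, float_format="%.10g")
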