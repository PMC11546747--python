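"""Time-stamped behavioral event streams.

Every peri-event analysis in this package (photometry PSTHs, spike PSTHs,
trial tensors) is aligned against a :class:`TrialEvents` stream: a flat,
time-sorted table of cue onsets, lever presses, reward/infusion deliveries
and trial boundaries sharing one session clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_KINDS = (
    "trial_start",
    "cue_on",
    "cue_off",
    "active_press",
    "inactive_press",
    "reward",
    "infusion",
    "trial_end",
)


@dataclass
class TrialEvents:
    """Session event stream: (time_s, event, trial_index) records.

    Parameters
    ----------
    table
        DataFrame with columns ``time_s`` (seconds from session start,
        non-decreasing), ``event`` (one of :data:`EVENT_KINDS`) and
        ``trial_index`` (1-based, contiguous).
    session_length
        Nominal session duration in seconds (end of the recording clock).
    """

    table: pd.DataFrame
    session_length: float = field(default=np.nan)

    def __post_init__(self) -> None:
        required = {"time_s", "event", "trial_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"TrialEvents table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table["time_s"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) < 0):
            raise ValueError("event times must be non-decreasing")
        bad = set(self.table["event"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        idx = self.table["trial_index"].to_numpy()
        if len(idx):
            if idx.min() < 1:
                raise ValueError("trial indices must be >= 1")
            uniq = np.unique(idx)
            if not np.array_equal(uniq, np.arange(1, uniq.max() + 1)):
                raise ValueError("trial indices must be contiguous from 1")
            starts = set(self.table.loc[self.table.event == "trial_start", "trial_index"])
            ends = set(self.table.loc[self.table.event == "trial_end", "trial_index"])
            if not ends <= starts:
                raise ValueError("every trial_end needs a matching trial_start")

    # -- accessors ---------------------------------------------------------

    def times_of(self, kind: str) -> np.ndarray:
        """Times (s) of all events of one kind, in session order."""
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        return self.table.loc[self.table.event == kind, "time_s"].to_numpy(dtype=float)

    @property
    def n_trials(self) -> int:
        return 0 if self.table.empty else int(self.table["trial_index"].max())

    @property
    def duration(self) -> float:
        if np.isfinite(self.session_length):
            return float(self.session_length)
        return float(self.table["time_s"].max()) if len(self.table) else 0.0

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["time_s"] = out["time_s"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, session_length: float = np.nan) -> "TrialEvents":
        table = pd.read_csv(path)
        return cls(table=table, session_length=session_length)

    @classmethod
    def from_records(cls, records, session_length: float = np.nan) -> "TrialEvents":
        """Build from an iterable of (time_s, event, trial_index) tuples."""
        table = pd.DataFrame(records, columns=["time_s", "event", "trial_index"])
        return cls(table=table, session_length=session_length)
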