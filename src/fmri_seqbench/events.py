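"""Event paradigms for the fast event-related functional localizer.

The localizer interleaves ten task types probing sensorimotor and
associative functions: sentence reading / listening, mental computation
cued visually or auditorily, button presses with the left or right hand
cued in either modality, and two flashing-checkerboard variants.  The
generator reproduces the statistical structure of that paradigm
(condition set, pseudo-random order, event density within a ~5:20 min
run), not any literal stimulus schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "EventTable",
    "SchedulingError",
    "generate_paradigm",
    "read_events",
    "write_events",
]

#: The ten task types of the localizer.
CONDITIONS: tuple[str, ...] = (
    "visual_sentence",
    "auditory_sentence",
    "visual_computation",
    "auditory_computation",
    "visual_left_press",
    "visual_right_press",
    "auditory_left_press",
    "auditory_right_press",
    "horizontal_checkerboard",
    "vertical_checkerboard",
)

_COLUMNS = ("onset", "duration", "condition")


class SchedulingError(ValueError):
    """Requested events cannot be packed into the run."""


@dataclass(frozen=True)
class EventTable:
    """Stimulus onsets, durations and condition labels for one run.

    Onsets and durations are in seconds from run start.  Within each
    condition onsets are strictly increasing; labels come from a fixed
    catalogue (:data:`CONDITIONS` unless overridden at construction).
    """

    frame: pd.DataFrame
    catalogue: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        object.__setattr__(
            self, "frame", df.loc[:, list(_COLUMNS)].reset_index(drop=True)
        )
        df = self.frame
        if len(df) == 0:
            return
        if not np.issubdtype(df["onset"].dtype, np.number) or not np.issubdtype(
            df["duration"].dtype, np.number
        ):
            raise ValueError("onset and duration must be numeric")
        if (df["onset"] < 0).any():
            raise ValueError("negative onsets")
        if (df["duration"] <= 0).any():
            raise ValueError("durations must be positive")
        unknown = set(df["condition"]) - set(self.catalogue)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        for cond, grp in df.groupby("condition"):
            on = grp["onset"].to_numpy()
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"onsets not strictly increasing for {cond!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> list[str]:
        """Catalogue conditions present in the table, catalogue order."""
        present = set(self.frame["condition"])
        return [c for c in self.catalogue if c in present]

    @property
    def end_time(self) -> float:
        if len(self.frame) == 0:
            return 0.0
        return float((self.frame["onset"] + self.frame["duration"]).max())

    def onsets(self, condition: str) -> np.ndarray:
        sel = self.frame["condition"] == condition
        return self.frame.loc[sel, "onset"].to_numpy(dtype=float)

    def durations(self, condition: str) -> np.ndarray:
        sel = self.frame["condition"] == condition
        return self.frame.loc[sel, "duration"].to_numpy(dtype=float)


def generate_paradigm(
    run_duration: float,
    events_per_condition: int,
    min_gap: float = 1.0,
    seed: int = 0,
    *,
    event_duration: float = 2.5,
    catalogue: tuple[str, ...] | None = None,
) -> EventTable:
    """Generate a pseudo-randomized fast event-related paradigm.

    All catalogue conditions occur exactly ``events_per_condition`` times in
    a shuffled order; inter-onset gaps are at least ``min_gap`` seconds,
    with the residual run time spread randomly across gaps.  The same seed
    always yields the same table.

    Raises
    ------
    SchedulingError
        If the requested events plus gaps do not fit in ``run_duration``.
    ValueError
        If a catalogue override is empty or contains duplicates.
    """
    if run_duration <= 0:
        raise ValueError("run_duration must be positive")
    if events_per_condition < 0:
        raise ValueError("events_per_condition must be >= 0")
    if catalogue is None:
        catalogue = CONDITIONS
    else:
        catalogue = tuple(catalogue)
        if len(catalogue) == 0 or len(set(catalogue)) != len(catalogue):
            raise ValueError("condition catalogue must be non-empty and unique")

    n_events = events_per_condition * len(catalogue)
    if n_events == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                              zip(_COLUMNS, (float, float, str))})
        return EventTable(empty, catalogue=catalogue)

    occupied = n_events * (event_duration + min_gap)
    if occupied > run_duration:
        raise SchedulingError(
            f"{n_events} events of {event_duration}s with {min_gap}s gaps "
            f"need {occupied:.1f}s but the run lasts {run_duration}s"
        )

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.asarray(catalogue, dtype=object), events_per_condition)
    rng.shuffle(labels)

    # Distribute the slack over the n_events leading gaps (Dirichlet-flat),
    # so onset spacing is irregular but reproducible.
    slack = run_duration - occupied
    extra = rng.dirichlet(np.ones(n_events)) * slack
    steps = event_duration + min_gap + extra[1:]
    onsets = extra[0] + np.concatenate([[0.0], np.cumsum(steps)])

    frame = pd.DataFrame(
        {
            "onset": np.round(onsets, 3),
            "duration": np.full(n_events, float(event_duration)),
            "condition": labels,
        }
    )
    return EventTable(frame, catalogue=catalogue)


def write_events(table: EventTable, path: str | Path) -> None:
    """Write a tab-separated ``onset  duration  condition`` file."""
    table.frame.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path, catalogue: tuple[str, ...] = CONDITIONS) -> EventTable:
    """Read and validate a tab-separated events file.

    Raises a ``ValueError`` naming the offending line when a row has a
    negative onset, a non-positive duration, a non-numeric field, or a
    condition outside the catalogue.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: non-numeric onset/duration") from exc
        if onset < 0:
            raise ValueError(f"{path}:{line}: negative onset {onset}")
        if duration <= 0:
            raise ValueError(f"{path}:{line}: non-positive duration {duration}")
        if row["condition"] not in catalogue:
            raise ValueError(f"{path}:{line}: unknown condition {row['condition']!r}")
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    return EventTable(df, catalogue=catalogue)
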