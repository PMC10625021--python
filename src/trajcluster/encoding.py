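"""Daily categorical state sequences from long-format event calendars.

Each patient's pre-index year is rendered as a length-``T`` integer vector:
position ``t`` is day ``t - T`` relative to the index (so the last position
is day -1 and day 0 itself is excluded).  Day intervals are half-open
``[start, end)``; when stays overlap, the highest alphabet code wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import (CARDIO_RESP, COPD_MARKER, EXACERBATION, ICU,
                       INDEX_EVENT, OXYGEN_START, POINT_EVENT_TYPES)

__all__ = ["StateAlphabet", "DEFAULT_ALPHABET", "DEFAULT_IGNORE",
           "UnknownEventTypeError", "encode", "encode_cohort",
           "write_sequences", "read_sequences"]


class UnknownEventTypeError(ValueError):
    """An event type is neither in the alphabet nor in the ignore list."""


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered state names; the list index is the integer code.

    Code 0 is reserved for "no event"; higher codes take priority when
    events overlap on a day.
    """

    states: tuple[str, ...] = ("none", EXACERBATION, CARDIO_RESP, ICU)

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("alphabet needs at least one non-none state")
        if self.states[0] != "none":
            raise ValueError("code 0 must be the 'none' state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def code(self, name: str) -> int:
        return self.states.index(name)


DEFAULT_ALPHABET = StateAlphabet()

# Point events and administrative markers are not part of the clustered
# sequence; they feed profiling only.
DEFAULT_IGNORE = frozenset(POINT_EVENT_TYPES) | {
    INDEX_EVENT, OXYGEN_START, COPD_MARKER,
    "cystic_fibrosis_diagnosis", "neuromuscular_diagnosis",
}


def encode(events: pd.DataFrame, alphabet: StateAlphabet = DEFAULT_ALPHABET,
           window_days: int = 365,
           ignore: frozenset = DEFAULT_IGNORE) -> np.ndarray:
    """Encode one patient's events into a daily state vector of length T.

    Events outside ``[-T, 0)`` are clipped; events of unknown type raise
    :class:`UnknownEventTypeError` unless listed in ``ignore``.
    """
    T = int(window_days)
    seq = np.zeros(T, dtype=np.int16)
    for ev_type, start, end in zip(events["event_type"], events["start_day"],
                                   events["end_day"]):
        if ev_type in ignore:
            continue
        if ev_type not in alphabet.states:
            raise UnknownEventTypeError(
                f"event type {ev_type!r} is not in the alphabet and not ignored")
        if start > end:
            raise ValueError(f"event with start_day {start} > end_day {end}")
        code = alphabet.code(ev_type)
        lo = max(int(start), -T) + T
        hi = min(int(end), 0) + T
        if hi > lo:
            np.maximum(seq[lo:hi], code, out=seq[lo:hi])
    return seq


def encode_cohort(events: pd.DataFrame, patient_ids: Iterable,
                  alphabet: StateAlphabet = DEFAULT_ALPHABET,
                  window_days: int = 365,
                  ignore: frozenset = DEFAULT_IGNORE) -> tuple[np.ndarray, np.ndarray]:
    """Encode every listed patient; patients without events get all-zero rows.

    Returns ``(ids, matrix)`` with ``matrix`` of shape ``(n, T)`` in the
    order of ``patient_ids``.
    """
    ids = np.asarray(list(patient_ids))
    groups = {pid: g for pid, g in events.groupby("patient_id", sort=False)}
    empty = events.iloc[0:0]
    mat = np.zeros((len(ids), int(window_days)), dtype=np.int16)
    for row, pid in enumerate(ids):
        mat[row] = encode(groups.get(pid, empty), alphabet, window_days, ignore)
    return ids, mat


def write_sequences(path: str | Path, ids: np.ndarray, matrix: np.ndarray,
                    alphabet: StateAlphabet = DEFAULT_ALPHABET) -> None:
    """Persist sequences as a delimited matrix plus a JSON alphabet sidecar."""
    path = Path(path)
    T = matrix.shape[1]
    df = pd.DataFrame(matrix, columns=[f"d{t - T}" for t in range(T)])
    df.insert(0, "patient_id", ids)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".alphabet.json")
    sidecar.write_text(json.dumps(
        {"states": list(alphabet.states), "window_days": T}, indent=2))


def read_sequences(path: str | Path) -> tuple[np.ndarray, np.ndarray, StateAlphabet]:
    """Inverse of :func:`write_sequences`; round-trips losslessly."""
    path = Path(path)
    df = pd.read_csv(path)
    ids = df["patient_id"].to_numpy()
    mat = df.drop(columns="patient_id").to_numpy(dtype=np.int16)
    sidecar = path.with_suffix(path.suffix + ".alphabet.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        alphabet = StateAlphabet(tuple(meta["states"]))
    else:
        alphabet = DEFAULT_ALPHABET
    return ids, mat, alphabet
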