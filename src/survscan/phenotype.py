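"""Survival phenotype container for the counting-process formulation.

Each individual contributes an interval ``(entry, exit]`` plus an event
indicator: ``entry`` is the left-truncation age (first contact with the
healthcare system — the individual is unobservable, and not known to be at
risk, before it), ``exit`` is the age at event or right censoring.  Risk sets
are formed as ``{i : entry_i < t <= exit_i}``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SurvivalPhenotype:
    """Per-individual (entry, exit, status] triples.

    Parameters
    ----------
    entry : array of float
        Left-truncation times. Zero means observed from time origin.
    exit : array of float
        Event or censoring times; must be strictly greater than ``entry``.
    status : array of {0, 1}
        1 if the event was observed at ``exit``, 0 if right censored.
    ids : array, optional
        Individual identifiers; defaults to 0..n-1.
    """

    entry: np.ndarray
    exit: np.ndarray
    status: np.ndarray
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)
        self.status = np.asarray(self.status)
        if self.entry.shape != self.exit.shape or self.entry.shape != self.status.shape:
            raise ValueError("entry, exit and status must have equal length")
        if not np.all(np.isfinite(self.entry)) or not np.all(np.isfinite(self.exit)):
            raise ValueError("entry and exit times must be finite")
        if np.any(self.exit <= self.entry):
            bad = int(np.sum(self.exit <= self.entry))
            raise ValueError(f"{bad} individuals have exit <= entry")
        uniq = np.unique(self.status)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("status must be coded 0/1")
        self.status = self.status.astype(np.int8)
        if self.ids is None:
            self.ids = np.arange(len(self.entry))
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.entry):
                raise ValueError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.entry)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, mask_or_index) -> "SurvivalPhenotype":
        return SurvivalPhenotype(
            self.entry[mask_or_index],
            self.exit[mask_or_index],
            self.status[mask_or_index],
            self.ids[mask_or_index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "entry_age": self.entry,
                "exit_age": self.exit,
                "event": self.status,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalPhenotype":
        return cls(
            df["entry_age"].to_numpy(float),
            df["exit_age"].to_numpy(float),
            df["event"].to_numpy(),
            df["id"].to_numpy(),
        )
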