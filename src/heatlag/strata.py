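"""Time-stratified case-crossover strata.

Each calendar day is assigned to the stratum (year, month, weekday): its
control days are the other days sharing weekday, month and year.  Stratum
sizes are therefore 4 or 5.  Conditioning on these strata removes weekly
patterns, seasonality and long-term trends by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StratumIndex", "build_strata", "informative_strata"]

logger = logging.getLogger(__name__)

_WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass
class StratumIndex:
    """Mapping from calendar date to (year, month, weekday) stratum.

    ``codes[i]`` is the integer stratum code of ``dates[i]``; ``labels[c]``
    is the (year, month, weekday) tuple of code ``c`` with weekday encoded
    Monday=0..Sunday=6.
    """

    dates: pd.DatetimeIndex
    codes: np.ndarray
    labels: list[tuple[int, int, int]]

    @property
    def n_strata(self) -> int:
        return len(self.labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_strata)

    def members(self, label: tuple[int, int, int]) -> pd.DatetimeIndex:
        code = self.labels.index(label)
        return self.dates[self.codes == code]

    def to_frame(self) -> pd.DataFrame:
        lab = [self.labels[c] for c in self.codes]
        return pd.DataFrame(
            {
                "date": self.dates,
                "stratum_label": [f"{y}-{m:02d}-{_WEEKDAYS[w]}" for y, m, w in lab],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def subset(self, keep_codes: np.ndarray) -> "StratumIndex":
        """Restrict to the given stratum codes, recoding compactly."""
        keep_codes = np.asarray(sorted(set(int(c) for c in keep_codes)))
        mask = np.isin(self.codes, keep_codes)
        old_to_new = {old: new for new, old in enumerate(keep_codes)}
        new_codes = np.array([old_to_new[c] for c in self.codes[mask]], dtype=int)
        return StratumIndex(
            dates=self.dates[mask],
            codes=new_codes,
            labels=[self.labels[c] for c in keep_codes],
        )


def build_strata(dates: pd.DatetimeIndex) -> StratumIndex:
    """Assign every day of a consecutive calendar range to its stratum."""
    dates = pd.DatetimeIndex(dates)
    if dates.has_duplicates:
        raise ValueError("duplicate dates in calendar range")
    if len(dates) > 1 and not (np.diff(dates.values) == np.timedelta64(1, "D")).all():
        raise ValueError("dates must be consecutive calendar days")
    keys = list(zip(dates.year.to_numpy(), dates.month.to_numpy(), dates.weekday.to_numpy()))
    labels: list[tuple[int, int, int]] = []
    seen: dict[tuple[int, int, int], int] = {}
    codes = np.empty(len(dates), dtype=int)
    for i, k in enumerate(keys):
        k = (int(k[0]), int(k[1]), int(k[2]))
        if k not in seen:
            seen[k] = len(labels)
            labels.append(k)
        codes[i] = seen[k]
    return StratumIndex(dates=dates, codes=codes, labels=labels)


def informative_strata(counts: np.ndarray | pd.Series, strata: StratumIndex) -> StratumIndex:
    """Drop strata with no events.

    Days in all-zero strata contribute a constant to the conditional
    likelihood, so removing them leaves the fit unchanged; dropping them
    up front is bookkeeping, and the dropped-stratum count is logged.
    """
    y = np.asarray(counts, dtype=float)
    if y.size != len(strata.dates):
        raise ValueError(f"counts length {y.size} does not match strata dates {len(strata.dates)}")
    totals = np.bincount(strata.codes, weights=y, minlength=strata.n_strata)
    keep = np.flatnonzero(totals > 0)
    dropped = strata.n_strata - keep.size
    if dropped:
        logger.info("dropping %d uninformative (all-zero) strata of %d", dropped, strata.n_strata)
    return strata.subset(keep)
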