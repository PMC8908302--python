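"""Epoch-by-dyad contact matrix construction.

Detections are binned into fixed wall-clock epochs (default 30 minutes,
48 per day) aligned to midnight of the study start date; epoch intervals
are half-open ``[t, t + epoch_minutes)`` so a detection exactly on a
boundary belongs to the later epoch.  Columns index unordered participant
pairs (dyads) in row-major upper-triangle order over the sorted
participant ids.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from proxnet.io import DetectionRecord

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 24 * 60


@dataclass(frozen=True)
class EpochGrid:
    """Uniform epoch grid covering [start_date, end_date] inclusive."""

    start_date: date
    end_date: date
    epoch_minutes: int = 30

    @property
    def epochs_per_day(self) -> int:
        return MINUTES_PER_DAY // self.epoch_minutes

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def n_epochs(self) -> int:
        """Total epoch count I."""
        return self.n_days * self.epochs_per_day

    def epoch_of(self, ts: datetime) -> int:
        """Index of the half-open epoch containing ``ts``; raises if outside."""
        day_offset = (ts.date() - self.start_date).days
        if not 0 <= day_offset < self.n_days:
            raise ValueError(f"timestamp {ts} outside grid "
                             f"[{self.start_date}, {self.end_date}]")
        minute = ts.hour * 60 + ts.minute
        return day_offset * self.epochs_per_day + minute // self.epoch_minutes

    def epoch_start(self, i: int) -> datetime:
        if not 0 <= i < self.n_epochs:
            raise IndexError(f"epoch index {i} out of range [0, {self.n_epochs})")
        day, slot = divmod(i, self.epochs_per_day)
        return (datetime.combine(self.start_date, datetime.min.time())
                + timedelta(days=day, minutes=slot * self.epoch_minutes))

    def epoch_starts(self) -> list[datetime]:
        return [self.epoch_start(i) for i in range(self.n_epochs)]


def build_epoch_grid(start: date, end: date, epoch_minutes: int = 30) -> EpochGrid:
    """Validated EpochGrid constructor.

    ``epoch_minutes`` must divide 1440 so that days split into whole
    epochs; ``start`` must not be after ``end``.
    """
    if start > end:
        raise ValueError(f"start date {start} is after end date {end}")
    if epoch_minutes <= 0 or MINUTES_PER_DAY % epoch_minutes != 0:
        raise ValueError(f"epoch_minutes={epoch_minutes} must be a positive "
                         f"divisor of {MINUTES_PER_DAY}")
    return EpochGrid(start, end, epoch_minutes)


@dataclass(frozen=True)
class DyadIndex:
    """Bijection between unordered participant pairs and matrix columns."""

    participants: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    _col_of: dict[tuple[str, str], int] = field(repr=False, hash=False, compare=False,
                                                default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_dyads(self) -> int:
        """Column count J = N(N-1)/2."""
        return len(self.pairs)

    def column(self, a: str, b: str) -> int:
        """Column index of the unordered pair {a, b}."""
        key = (a, b) if a < b else (b, a)
        try:
            return self._col_of[key]
        except KeyError:
            raise KeyError(f"unknown dyad ({a}, {b})") from None

    def pair(self, j: int) -> tuple[str, str]:
        return self.pairs[j]

    def columns_of(self, participant: str) -> list[int]:
        """All columns whose dyad contains ``participant``."""
        return [j for j, (a, b) in enumerate(self.pairs)
                if participant in (a, b)]


def build_dyad_index(participant_ids: list[str]) -> DyadIndex:
    """Deterministic dyad ordering: sorted ids, upper-triangle row-major."""
    if len(set(participant_ids)) != len(participant_ids):
        raise ValueError("duplicate participant ids")
    if len(participant_ids) < 2:
        raise ValueError("need at least 2 participants to form dyads")
    ids = tuple(sorted(participant_ids))
    pairs = tuple((ids[a], ids[b])
                  for a in range(len(ids)) for b in range(a + 1, len(ids)))
    col_of = {p: j for j, p in enumerate(pairs)}
    return DyadIndex(ids, pairs, col_of)


@dataclass
class ContactMatrix:
    """I x J nonnegative count matrix with its grid and dyad labels."""

    Y: np.ndarray
    grid: EpochGrid
    dyads: DyadIndex

    def __post_init__(self) -> None:
        expected = (self.grid.n_epochs, self.dyads.n_dyads)
        if self.Y.shape != expected:
            raise ValueError(f"Y shape {self.Y.shape} != grid/dyad shape {expected}")
        if np.any(self.Y < 0):
            raise ValueError("contact matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape


def build_contact_matrix(records: list[DetectionRecord], grid: EpochGrid,
                         dyads: DyadIndex, direction_rule: str = "sum",
                         cap: int | None = None) -> ContactMatrix:
    """Bin detections into per-epoch dyad counts.

    ``direction_rule="sum"`` adds A->B and B->A detections within an
    epoch; ``"max"`` keeps the larger directional count.  ``cap``, when
    given, truncates each cell (a physical bound of
    ``directions * epoch_minutes / scan_interval`` detections per epoch).

    Records must already be windowed to the grid and carry participant
    ids present in the dyad index; violations raise.
    """
    if direction_rule not in ("sum", "max"):
        raise ValueError(f"unknown direction_rule {direction_rule!r}")
    if cap is not None and cap < 0:
        raise ValueError("cap must be nonnegative")
    known = set(dyads.participants)
    # directional counts keyed by (epoch, column, direction)
    counts: dict[tuple[int, int, int], int] = {}
    for r in records:
        if r.observer_id not in known or r.observed_id not in known:
            raise ValueError(f"record involves unknown participant: "
                             f"{r.observer_id!r} -> {r.observed_id!r}")
        i = grid.epoch_of(r.timestamp)  # raises if outside grid
        j = dyads.column(r.observer_id, r.observed_id)
        d = 0 if r.observer_id < r.observed_id else 1
        counts[(i, j, d)] = counts.get((i, j, d), 0) + 1

    Y = np.zeros((grid.n_epochs, dyads.n_dyads), dtype=np.int64)
    if direction_rule == "sum":
        for (i, j, _), c in counts.items():
            Y[i, j] += c
    else:
        for (i, j, _), c in counts.items():
            Y[i, j] = max(Y[i, j], c)
    if cap is not None:
        np.minimum(Y, cap, out=Y)
    return ContactMatrix(Y, grid, dyads)


def matrix_summary(cm: ContactMatrix) -> dict:
    """Per-participant mean detections/day, nonzero fraction, column sums.

    A participant's detections/day is the total count over all of their
    dyads divided by the grid's day count.
    """
    col_sums = cm.Y.sum(axis=0)
    per_participant = {}
    for p in cm.dyads.participants:
        total = sum(col_sums[j] for j in cm.dyads.columns_of(p))
        per_participant[p] = float(total) / cm.grid.n_days
    return {
        "detections_per_day": per_participant,
        "mean_detections_per_day": float(np.mean(list(per_participant.values()))),
        "nonzero_fraction": float(np.count_nonzero(cm.Y)) / cm.Y.size,
        "column_sums": col_sums,
    }


# ---------------------------------------------------------------------------
# persistence: Matrix Market + label sidecars

def save_contact_matrix(cm: ContactMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus epoch/dyad label sidecar files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")),
                     scipy.sparse.coo_matrix(cm.Y))
    with open(prefix.parent / (prefix.name + ".epochs.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "start"])
        for i, t in enumerate(cm.grid.epoch_starts()):
            w.writerow([i, t.isoformat()])
    with open(prefix.parent / (prefix.name + ".dyads.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "participant_a", "participant_b"])
        for j, (a, b) in enumerate(cm.dyads.pairs):
            w.writerow([j, a, b])


def load_contact_matrix(prefix: str | Path, grid: EpochGrid,
                        dyads: DyadIndex) -> ContactMatrix:
    prefix = Path(prefix)
    Y = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    return ContactMatrix(np.asarray(Y), grid, dyads)
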