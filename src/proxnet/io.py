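"""Reading, validation and windowing of raw detection logs and rosters.

File formats (all delimited text, comma by default):

* detection log -- header ``timestamp,observer_id,observed_id``,
  ISO-8601 timestamps;
* roster -- header ``participant_id,device_id``;
* carry record -- header ``participant_id,date`` with one row per
  participant-day on which any data was uploaded.

Timestamps are wall-clock in a single fixed study timezone; the
``timezone`` argument is recorded as a label and no DST conversion is
applied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionRecord:
    """One device-sees-device event at one timestamp."""

    timestamp: datetime
    observer_id: str
    observed_id: str

    def __post_init__(self) -> None:
        if self.observer_id == self.observed_id:
            raise ValueError(
                f"self-detection: observer == observed == {self.observer_id!r}"
            )


@dataclass
class Roster:
    """Participant/device mapping plus per-participant carry calendar.

    ``participants`` is a list of ``(participant_id, device_id)`` pairs;
    the device -> participant mapping must be injective.  ``carry_record``
    maps each participant to the set of calendar days with any uploaded
    data.
    """

    participants: list[tuple[str, str]]
    carry_record: dict[str, set[date]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        devices = [d for _, d in self.participants]
        if len(devices) != len(set(devices)):
            raise ValueError("device_id -> participant_id mapping is not injective")
        pids = [p for p, _ in self.participants]
        if len(pids) != len(set(pids)):
            raise ValueError("duplicate participant ids in roster")

    @property
    def device_to_participant(self) -> dict[str, str]:
        return {d: p for p, d in self.participants}

    @property
    def participant_ids(self) -> list[str]:
        return [p for p, _ in self.participants]


def read_detections(path: str | Path, timezone: str | None = None) -> list[DetectionRecord]:
    """Read a detection log, skipping (and counting) malformed rows.

    Parameters
    ----------
    path
        Delimited text file with header ``timestamp,observer_id,observed_id``.
    timezone
        Informational label for the study timezone; timestamps are kept
        as naive wall-clock datetimes.

    Returns
    -------
    list of DetectionRecord in file order.  The number of skipped rows is
    reported via logging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"detection log not found: {path}")
    records: list[DetectionRecord] = []
    n_skipped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row_no, row in enumerate(reader):
            if row_no == 0 and row and row[0].strip().lower() == "timestamp":
                continue  # header
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                n_skipped += 1
                continue
            try:
                ts = datetime.fromisoformat(row[0].strip())
                rec = DetectionRecord(ts, row[1].strip(), row[2].strip())
            except ValueError:
                n_skipped += 1
                continue
            records.append(rec)
    if n_skipped:
        logger.warning("read_detections: skipped %d malformed row(s) in %s",
                       n_skipped, path)
    logger.info("read_detections: %d record(s) from %s (timezone=%s)",
                len(records), path, timezone)
    return records


def write_detections(records: list[DetectionRecord], path: str | Path) -> None:
    """Write records in the canonical detection-log format (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "observer_id", "observed_id"])
        for r in records:
            writer.writerow([r.timestamp.isoformat(), r.observer_id, r.observed_id])


def window_records(records: list[DetectionRecord], start: date, end: date) -> list[DetectionRecord]:
    """Keep records whose timestamp date lies in [start, end], order preserved."""
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    return [r for r in records if start <= r.timestamp.date() <= end]


def map_to_participants(records: list[DetectionRecord], roster: Roster) -> list[DetectionRecord]:
    """Translate device ids to participant ids, dropping non-roster devices.

    Devices also hear non-study Bluetooth hardware; records whose observer
    or observed device is not in the roster are dropped and counted in the
    log.
    """
    mapping = roster.device_to_participant
    out: list[DetectionRecord] = []
    n_dropped = 0
    for r in records:
        a = mapping.get(r.observer_id)
        b = mapping.get(r.observed_id)
        if a is None or b is None:
            n_dropped += 1
            continue
        out.append(DetectionRecord(r.timestamp, a, b))
    if n_dropped:
        logger.info("map_to_participants: dropped %d record(s) with non-roster devices",
                    n_dropped)
    return out


def _longest_consecutive_run(days: set[date]) -> int:
    """Length of the longest run of consecutive calendar days in ``days``."""
    if not days:
        return 0
    best = 0
    one = timedelta(days=1)
    for d in days:
        if d - one in days:
            continue  # not a run start
        length = 1
        cur = d
        while cur + one in days:
            cur += one
            length += 1
        best = max(best, length)
    return best


def apply_inclusion_rule(roster: Roster, min_days: int = 61,
                         mode: str = "consecutive") -> set[str]:
    """Participants whose carry calendar satisfies the inclusion rule.

    ``mode="consecutive"`` (default) requires the longest run of
    consecutive carry-days to reach ``min_days``; ``mode="total"`` counts
    cumulative carry-days instead.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    if mode not in ("consecutive", "total"):
        raise ValueError(f"unknown inclusion mode {mode!r}")
    included: set[str] = set()
    for pid, _ in roster.participants:
        days = roster.carry_record.get(pid, set())
        n = _longest_consecutive_run(days) if mode == "consecutive" else len(days)
        if n >= min_days:
            included.add(pid)
    return included


def read_roster(path: str | Path, carry_path: str | Path | None = None) -> Roster:
    """Read a roster file and (optionally) a carry-record file."""
    path = Path(path)
    participants: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row_no, row in enumerate(reader):
            if row_no == 0 and row and row[0].strip().lower() == "participant_id":
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"roster row {row_no + 1} has fewer than 2 fields")
            participants.append((row[0].strip(), row[1].strip()))
    carry: dict[str, set[date]] = {}
    if carry_path is not None:
        with open(carry_path, newline="") as fh:
            reader = csv.reader(fh)
            for row_no, row in enumerate(reader):
                if row_no == 0 and row and row[0].strip().lower() == "participant_id":
                    continue
                if not row or all(not c.strip() for c in row):
                    continue
                pid = row[0].strip()
                carry.setdefault(pid, set()).add(date.fromisoformat(row[1].strip()))
    return Roster(participants, carry)


def write_roster(roster: Roster, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "device_id"])
        for pid, did in roster.participants:
            writer.writerow([pid, did])
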