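"""Camera-trap capture records: ingest, independence filtering, effort tables.

A *detection* is one photo-capture row (species, station, timestamp).  An
*event* is a detection that survived the independence filter: within each
(species, station) stream, a capture counts as a new event only when it falls
strictly more than a fixed window (30 min by convention) after the most
recently retained event of that stream.  Events divided by per-station
trap-nights give the relative abundance index (RAI); events aggregated by the
station's habitat class give the habitat-use profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four habitat classes of the dry-teak-forest study design.
HABITAT_CLASSES = ("MoistMixed", "TeakAcaciaZizyphus", "Mixed", "Thorn")


class SchemaError(ValueError):
    """A required column is missing or mis-mapped in an input table."""


class RowParseError(ValueError):
    """A data row could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True, order=True)
class Detection:
    """One raw photo-capture."""

    species: str
    station_id: str
    timestamp: datetime

    def __post_init__(self):
        if not self.species:
            raise ValueError("species must be non-empty")
        if not self.station_id:
            raise ValueError("station_id must be non-empty")
        if not isinstance(self.timestamp, datetime):
            raise TypeError("timestamp must be a datetime")


#: An independent event has the same fields as a raw detection; the
#: distinction is which list it lives in.
Event = Detection


@dataclass(frozen=True)
class StationDeployment:
    """A camera-trap station with habitat class and accumulated effort.

    ``trap_nights`` is the effort denominator for the RAI: one trap-night is
    one station active for one 24-h period.
    """

    station_id: str
    habitat: str
    trap_nights: float

    def __post_init__(self):
        if self.habitat not in HABITAT_CLASSES:
            raise ValueError(
                f"habitat {self.habitat!r} not one of {HABITAT_CLASSES}"
            )
        if not self.trap_nights > 0:
            raise ValueError("trap_nights must be > 0")


@dataclass(frozen=True)
class RAIMatrix:
    """Species x station grid of events per trap-night."""

    values: pd.DataFrame  # index: species, columns: station ids

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("RAI cells must be non-negative")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def stations(self) -> list[str]:
        return list(self.values.columns)

    def row(self, species: str) -> np.ndarray:
        return self.values.loc[species].to_numpy(dtype=float)


@dataclass(frozen=True)
class HabitatProfile:
    """Species x habitat event counts and their row percentages."""

    counts: pd.DataFrame   # index: species, columns: HABITAT_CLASSES
    percents: pd.DataFrame

    def __post_init__(self):
        sums = self.percents.sum(axis=1)
        if len(sums) and not np.allclose(sums, 100.0, atol=0.5):
            raise ValueError("each percent row must sum to 100 (±0.5)")


_DEFAULT_SCHEMA = {"species": "species", "station": "station", "timestamp": "timestamp"}


def read_detections(
    path,
    schema: Mapping[str, str] | None = None,
    timestamp_format: str | None = None,
) -> list[Detection]:
    """Read a detections CSV into a sorted list of :class:`Detection`.

    Parameters
    ----------
    path
        CSV file with one row per photo-capture.
    schema
        Maps the logical names ``species``, ``station``, ``timestamp`` to the
        file's column names.  Defaults to those literal names.
    timestamp_format
        Optional ``strftime`` format; when omitted, ISO-8601 is assumed.

    Rows are returned sorted by (species, station, timestamp); the row count
    is preserved.  A missing column raises :class:`SchemaError` naming the
    column; an unparseable timestamp raises :class:`RowParseError` with the
    1-based data-row number.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str)
    for logical, column in colmap.items():
        if column not in df.columns:
            raise SchemaError(
                f"required column {column!r} (for {logical!r}) not found; "
                f"file has {list(df.columns)}"
            )
    out: list[Detection] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        raw = getattr(rec, "_asdict")()
        ts_text = raw[colmap["timestamp"]]
        try:
            if timestamp_format is not None:
                ts = datetime.strptime(ts_text, timestamp_format)
            else:
                ts = datetime.fromisoformat(str(ts_text))
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"unparseable timestamp {ts_text!r}: {exc}", i)
        out.append(
            Detection(
                species=str(raw[colmap["species"]]),
                station_id=str(raw[colmap["station"]]),
                timestamp=ts,
            )
        )
    out.sort(key=lambda d: (d.species, d.station_id, d.timestamp))
    return out


def read_stations(path, schema: Mapping[str, str] | None = None) -> list[StationDeployment]:
    """Read station metadata CSV (columns station, habitat, trap_nights)."""
    colmap = {"station": "station", "habitat": "habitat", "trap_nights": "trap_nights"}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    for logical, column in colmap.items():
        if column not in df.columns:
            raise SchemaError(f"required column {column!r} (for {logical!r}) not found")
    return [
        StationDeployment(
            station_id=str(r[colmap["station"]]),
            habitat=str(r[colmap["habitat"]]),
            trap_nights=float(r[colmap["trap_nights"]]),
        )
        for _, r in df.iterrows()
    ]


def _dedupe_same_minute(stream: list[Detection]) -> list[Detection]:
    # Paired left/right cameras fire together; collapse same-minute duplicates
    # of one species/station before the independence scan.
    seen: set[tuple] = set()
    out = []
    for d in stream:
        key = d.timestamp.replace(second=0, microsecond=0)
        if key not in seen:
            seen.add(key)
            out.append(d)
    return out


def filter_independent(
    detections: Iterable[Detection],
    window_minutes: float = 30.0,
    anchor: str = "retained",
    collapse_same_minute: bool = True,
) -> list[Event]:
    """Reduce raw detections to independent events.

    Greedy scan per (species, station) stream in time order: the first
    detection is always retained; a later one is retained iff its gap to the
    anchor exceeds ``window_minutes`` *strictly*.  With the default
    ``anchor="retained"`` the gap is measured to the most recently retained
    event (idempotent); ``anchor="previous"`` measures to the immediately
    preceding raw photo instead.

    Returns the union of retained detections across streams, sorted by
    (species, station, timestamp).
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    if anchor not in ("retained", "previous"):
        raise ValueError("anchor must be 'retained' or 'previous'")
    streams: dict[tuple[str, str], list[Detection]] = {}
    for d in detections:
        streams.setdefault((d.species, d.station_id), []).append(d)
    window_s = window_minutes * 60.0
    events: list[Event] = []
    for key in sorted(streams):
        stream = sorted(streams[key], key=lambda d: d.timestamp)
        if collapse_same_minute:
            stream = _dedupe_same_minute(stream)
        last_anchor = None
        for d in stream:
            if last_anchor is None:
                events.append(d)
                last_anchor = d.timestamp
            else:
                gap = (d.timestamp - last_anchor).total_seconds()
                if gap > window_s:
                    events.append(d)
                    last_anchor = d.timestamp
                elif anchor == "previous":
                    last_anchor = d.timestamp
    events.sort(key=lambda d: (d.species, d.station_id, d.timestamp))
    return events


def rai_matrix(
    events: Sequence[Event], stations: Sequence[StationDeployment]
) -> RAIMatrix:
    """Relative abundance index: events per trap-night, species x station.

    Every event's station must appear in ``stations``; cells with no events
    are 0.  Station column order follows the metadata order.
    """
    station_ids = [s.station_id for s in stations]
    effort = {s.station_id: s.trap_nights for s in stations}
    if len(effort) != len(station_ids):
        raise ValueError("duplicate station_id in station metadata")
    species = sorted({e.species for e in events})
    counts = pd.DataFrame(0.0, index=species, columns=station_ids)
    for e in events:
        if e.station_id not in effort:
            raise KeyError(
                f"event at unknown station {e.station_id!r}: not in metadata"
            )
        counts.loc[e.species, e.station_id] += 1
    rai = counts.div(pd.Series(effort), axis=1)
    return RAIMatrix(values=rai)


def habitat_use(
    events: Sequence[Event], stations: Sequence[StationDeployment]
) -> HabitatProfile:
    """Species x habitat event counts with row percentages.

    Species with zero events are omitted (their percent row is undefined)
    with a logged warning.
    """
    habitat_of = {s.station_id: s.habitat for s in stations}
    species = sorted({e.species for e in events})
    counts = pd.DataFrame(0, index=species, columns=list(HABITAT_CLASSES))
    for e in events:
        if e.station_id not in habitat_of:
            raise KeyError(
                f"event at unknown station {e.station_id!r}: not in metadata"
            )
        counts.loc[e.species, habitat_of[e.station_id]] += 1
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index
    for sp in empty:
        logger.warning("species %r has zero events; habitat row omitted", sp)
    counts = counts.drop(index=empty)
    totals = counts.sum(axis=1)
    percents = counts.div(totals, axis=0) * 100.0
    return HabitatProfile(counts=counts, percents=percents)
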