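"""Trajectory containers and delimited-text track-table I/O.

A *track* is the frame-indexed 2D path of one molecule, as produced by a
single-particle localization/linking package (SLIMfast, TrackMate, u-track,
...) after export to a delimited table with one localization per row.
Coordinates are micrometres throughout; inputs recorded in pixels can be
rescaled on read with ``coord_scale``.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Localization",
    "Track",
    "TrackSet",
    "TrackTableError",
    "TrackFormatError",
    "TrackParseError",
    "TrackIntegrityError",
    "DEFAULT_DIALECT",
    "read_track_table",
    "write_track_table",
]


class TrackTableError(ValueError):
    """Base class for track-table format problems."""


class TrackFormatError(TrackTableError):
    """A required column is missing or the header is unusable."""


class TrackParseError(TrackTableError):
    """A cell could not be parsed; the message names the 1-based row."""


class TrackIntegrityError(TrackTableError):
    """Duplicate (track, frame) pair or other structural violation."""


#: Column-name mapping from logical field to the column header in the file.
DEFAULT_DIALECT: Mapping[str, str] = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x_um",
    "y": "y_um",
}


@dataclass(frozen=True)
class Localization:
    """One fitted molecule position: frame index plus (x, y) in micrometres."""

    frame: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate ({self.x}, {self.y})")


@dataclass(frozen=True)
class Track:
    """Ordered localizations of one molecule.

    Frames are strictly increasing but need not be contiguous (the linker may
    bridge gaps); ``duration`` counts localizations, not frame span.
    """

    track_id: str
    localizations: tuple[Localization, ...]

    def __post_init__(self) -> None:
        frames = [loc.frame for loc in self.localizations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(
                f"track {self.track_id!r}: frames must be strictly increasing"
            )

    @property
    def duration(self) -> int:
        return len(self.localizations)

    @property
    def frames(self) -> tuple[int, ...]:
        return tuple(loc.frame for loc in self.localizations)

    def positions(self):
        """(n, 2) float array of coordinates in micrometres."""
        import numpy as np

        return np.array([(l.x, l.y) for l in self.localizations], dtype=float)


@dataclass(frozen=True)
class TrackSet:
    """A collection of tracks acquired under one imaging condition.

    ``frame_interval_s`` defaults to 0.01 s (100 Hz stroboscopic imaging).
    """

    tracks: tuple[Track, ...]
    frame_interval_s: float = 0.01
    condition: str = ""
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError("track_id values must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def with_tracks(self, tracks: Iterable[Track]) -> "TrackSet":
        return replace(self, tracks=tuple(tracks))


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_track_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    frame_interval_s: float = 0.01,
    condition: str = "",
    cell_id: str | None = None,
    coord_scale: float = 1.0,
) -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    Parameters
    ----------
    path : path to a comma- or tab-delimited file with a header row.
        Lines starting with ``#`` are treated as comments.
    dialect : mapping from the logical fields ``track_id, frame, x, y`` to
        the column names actually present; defaults to
        ``track_id, frame, x_um, y_um``.
    coord_scale : multiplicative factor applied to x and y on read, e.g. a
        pixel size in micrometres for pixel-unit tables.

    Rows may appear in any order; localizations are sorted by frame within
    each track and tracks by first appearance.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return TrackSet(
            tracks=(),
            frame_interval_s=frame_interval_s,
            condition=condition,
            cell_id=cell_id,
        )
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter=delim)
    header = reader.fieldnames or []
    for logical in ("track_id", "frame", "x", "y"):
        col = dialect.get(logical)
        if col is None or col not in header:
            raise TrackFormatError(
                f"required column {col or logical!r} (field {logical!r}) "
                f"not found in header {header}"
            )

    per_track: dict[str, dict[int, Localization]] = {}
    order: list[str] = []
    for rownum, row in enumerate(reader, start=2):
        tid = str(row[dialect["track_id"]]).strip()
        try:
            frame = int(float(row[dialect["frame"]]))
            x = float(row[dialect["x"]]) * coord_scale
            y = float(row[dialect["y"]]) * coord_scale
        except (TypeError, ValueError) as exc:
            raise TrackParseError(
                f"row {rownum}: could not parse numeric cell ({exc})"
            ) from None
        locs = per_track.setdefault(tid, {})
        if not locs:
            order.append(tid)
        if frame in locs:
            raise TrackIntegrityError(
                f"duplicate localization for track {tid!r} at frame {frame} "
                f"(row {rownum})"
            )
        locs[frame] = Localization(frame=frame, x=x, y=y)

    tracks = tuple(
        Track(track_id=tid, localizations=tuple(per_track[tid][f] for f in sorted(per_track[tid])))
        for tid in order
    )
    return TrackSet(
        tracks=tracks,
        frame_interval_s=frame_interval_s,
        condition=condition,
        cell_id=cell_id,
    )


def write_track_table(
    trackset: TrackSet,
    path: str | Path,
    *,
    provenance: Sequence[str] = (),
) -> Path:
    """Write a TrackSet as a comma-delimited table (round-trip safe).

    Coordinates are written with :func:`repr` precision so
    ``read_track_table(write_track_table(S))`` reproduces ``S`` exactly.
    Extra ``provenance`` strings are emitted as leading ``#`` comment lines.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write(f"# frame_interval_s={trackset.frame_interval_s!r}\n")
        if trackset.condition:
            fh.write(f"# condition={trackset.condition}\n")
        writer = csv.writer(fh)
        writer.writerow(["track_id", "frame", "x_um", "y_um"])
        for track in trackset:
            for loc in track.localizations:
                writer.writerow([track.track_id, loc.frame, repr(loc.x), repr(loc.y)])
    return path
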