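"""Physical placement of markers and neighboring-marker distances in Kb."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import round_half_up

__all__ = ["MapEntry", "build_map", "map_summary", "map_to_frame"]


@dataclass(frozen=True)
class MapEntry:
    marker: str
    seq_id: str
    position: int  # 1-based bp, SSR tract start
    gap_kb: float | None  # None for the first marker on a sequence


def build_map(
    markers: Sequence[tuple[str, str, int]],
) -> tuple[list[MapEntry], pd.Series, float | None, list[str]]:
    """Order markers along each sequence and compute neighbor gaps.

    ``markers`` is (marker_id, seq_id, position) in any order; the map is a
    pure function of those pairs.  The mean gap averages all adjacent pairs
    within sequences (never across sequence boundaries) and is reported in
    Kb rounded half-up to one decimal.  Duplicate (seq, position) markers
    are kept with gap 0 and a warning.

    Returns (entries, per-sequence counts with Total, mean gap Kb or None,
    warnings).
    """
    ordered = sorted(markers, key=lambda m: (m[1], m[2], m[0]))
    entries: list[MapEntry] = []
    warnings: list[str] = []
    gaps: list[float] = []
    prev: tuple[str, int] | None = None
    for marker_id, seq_id, position in ordered:
        if position < 1:
            raise ValueError(f"marker {marker_id!r} has non-positive position {position}")
        if prev is not None and prev[0] == seq_id:
            gap = (position - prev[1]) / 1000.0
            if gap == 0.0:
                warnings.append(f"duplicate position {seq_id}:{position} ({marker_id})")
            gaps.append(gap)
            entries.append(MapEntry(marker_id, seq_id, position, gap))
        else:
            entries.append(MapEntry(marker_id, seq_id, position, None))
        prev = (seq_id, position)
    counts = map_summary(entries)
    mean_gap = round_half_up(sum(gaps) / len(gaps), 1) if gaps else None
    return entries, counts, mean_gap, warnings


def map_summary(entries: Sequence[MapEntry]) -> pd.Series:
    """Per-sequence marker counts plus a ``Total`` cell."""
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.seq_id] = counts.get(e.seq_id, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    series.loc["Total"] = int(series.sum())
    return series


def map_to_frame(entries: Sequence[MapEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.seq_id, e.position, e.marker, "" if e.gap_kb is None else e.gap_kb) for e in entries],
        columns=["seq_id", "position", "marker", "gap_kb"],
    )
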