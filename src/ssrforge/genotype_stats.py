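"""Marker informativeness and transferability from amplicon-size matrices.

The genotype matrix is marker x accession; each cell is one allele size
(bp), two sizes ``a/b`` for a heterozygote, or the missing sentinel ``-``.
PIC follows Botstein's definition:

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import percent_half_up
from .errors import FrequencySumError, NoDataError, UnknownGroupError

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "allele_freqs",
    "pic",
    "allele_count_distribution",
    "transferability",
    "per_marker_stats",
]

MISSING = "-"

Call = tuple[int, ...] | None  # 1 or 2 allele sizes, or None for missing


@dataclass
class GenotypeMatrix:
    """Marker x accession table of amplicon-size calls."""

    markers: list[str]
    accessions: list[str]
    groups: dict[str, str] = field(default_factory=dict)  # accession -> group label
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc in self.accessions:
            self.groups.setdefault(acc, "default")
        for call in self.calls.values():
            if call is not None and any(a <= 0 for a in call):
                raise ValueError("allele sizes must be positive integers")

    def call(self, marker: str, accession: str) -> Call:
        return self.calls.get((marker, accession))

    def group_members(self, group: str) -> list[str]:
        members = [a for a in self.accessions if self.groups[a] == group]
        if not members:
            raise UnknownGroupError(f"no accessions in group {group!r}")
        return members

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for a in self.accessions:
            g = self.groups[a]
            if g not in seen:
                seen.append(g)
        return seen

    # ---- CSV round trip ------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, groups_row: bool | None = None) -> "GenotypeMatrix":
        """Read the genotype CSV.

        Row 1: header of accession ids (first cell is the marker-id column
        name).  Row 2 optionally carries group labels, detected by a first
        cell equal to ``group`` (case-insensitive) unless ``groups_row``
        forces either reading.  Remaining rows: marker id then calls.
        """
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r]
        if not rows:
            return cls(markers=[], accessions=[])
        header = rows[0]
        accessions = header[1:]
        body = rows[1:]
        groups: dict[str, str] = {}
        has_groups = groups_row
        if has_groups is None:
            has_groups = bool(body) and body[0][0].strip().lower() == "group"
        if has_groups:
            labels = body[0][1:]
            groups = dict(zip(accessions, labels))
            body = body[1:]
        markers: list[str] = []
        calls: dict[tuple[str, str], Call] = {}
        for row in body:
            marker = row[0]
            markers.append(marker)
            for acc, cell in zip(accessions, row[1:]):
                calls[(marker, acc)] = parse_call(cell)
        return cls(markers=markers, accessions=accessions, groups=groups, calls=calls)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["marker"] + self.accessions)
            if any(g != "default" for g in self.groups.values()):
                writer.writerow(["group"] + [self.groups[a] for a in self.accessions])
            for m in self.markers:
                writer.writerow([m] + [format_call(self.call(m, a)) for a in self.accessions])


def parse_call(cell: str) -> Call:
    cell = cell.strip()
    if cell in ("", MISSING):
        return None
    parts = cell.split("/")
    if len(parts) not in (1, 2):
        raise ValueError(f"malformed call {cell!r}")
    return tuple(int(p) for p in parts)


def format_call(call: Call) -> str:
    if call is None:
        return MISSING
    return "/".join(str(a) for a in call)


def allele_freqs(matrix: GenotypeMatrix, marker: str) -> dict[int, float]:
    """Allele frequencies from the non-missing calls of one marker.

    A homozygous call contributes weight 1 to its allele, a heterozygous
    call weight 1/2 to each of its two alleles.
    """
    weights: dict[int, float] = {}
    total = 0.0
    for acc in matrix.accessions:
        call = matrix.call(marker, acc)
        if call is None:
            continue
        w = 1.0 / len(call)
        for allele in call:
            weights[allele] = weights.get(allele, 0.0) + w
        total += 1.0
    if total == 0:
        raise NoDataError(f"marker {marker!r} has no non-missing calls")
    return {a: w / total for a, w in sorted(weights.items())}


def pic(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Botstein polymorphism information content of one marker."""
    p = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    if any(x <= 0 for x in p):
        raise ValueError("frequencies must be positive")
    if abs(sum(p) - 1.0) > 1e-6:
        raise FrequencySumError(f"frequencies sum to {sum(p)}, expected 1")
    homo = sum(x * x for x in p)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] * p[i] * p[j] * p[j]
    return 1.0 - homo - cross


def allele_count_distribution(matrix: GenotypeMatrix) -> tuple[dict[int, int], int | None, tuple[int, int] | None]:
    """Histogram over markers of the number of distinct non-missing alleles,
    plus the lower median and (min, max) range.  Markers with no calls are
    skipped; an empty matrix yields ({}, None, None)."""
    counts: list[int] = []
    for m in matrix.markers:
        alleles = set()
        for acc in matrix.accessions:
            call = matrix.call(m, acc)
            if call is not None:
                alleles.update(call)
        if alleles:
            counts.append(len(alleles))
    if not counts:
        return {}, None, None
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    ordered = sorted(counts)
    median = ordered[(len(ordered) - 1) // 2]  # lower median for even n
    return dict(sorted(hist.items())), median, (ordered[0], ordered[-1])


def transferability(matrix: GenotypeMatrix, group: str) -> float:
    """Percentage of markers with >= 1 non-missing call in ``group``,
    rounded half-up to one decimal."""
    members = matrix.group_members(group)
    if not matrix.markers:
        raise NoDataError("matrix has no markers")
    amplified = 0
    for m in matrix.markers:
        if any(matrix.call(m, acc) is not None for acc in members):
            amplified += 1
    return percent_half_up(amplified, len(matrix.markers))


def per_marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker table: number of distinct alleles and PIC."""
    rows = []
    for m in matrix.markers:
        try:
            freqs = allele_freqs(matrix, m)
        except NoDataError:
            rows.append((m, 0, float("nan")))
            continue
        rows.append((m, len(freqs), pic(freqs)))
    return pd.DataFrame(rows, columns=["marker", "n_alleles", "PIC"])
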