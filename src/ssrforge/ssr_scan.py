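"""Detection of perfect microsatellite tracts in genomic sequence.

The scanner reports every maximal perfect tandem run of a primitive 1-6 bp
unit whose repeat count meets the per-class threshold.  Motifs are grouped
into families by cyclic rotation on the same strand (``GA`` -> ``AG``);
reverse complements are *not* merged, so ``AG``/``GA`` and ``CT``/``TC`` are
distinct families.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidAlphabetError, InvalidMotifError, MissingSequenceError

__all__ = [
    "MOTIF_CLASSES",
    "CLASS_BY_UNIT_LENGTH",
    "DEFAULT_MIN_REPEATS",
    "ScanConfig",
    "SSRLocus",
    "Fragment",
    "canonical_family",
    "is_primitive",
    "scan_sequence",
    "scan_genome",
    "extract_flanks",
    "classify_genomic_context",
    "summarize_context",
    "summarize_by_class_and_chrom",
]

#: Motif class name -> repeat unit length in bases.
MOTIF_CLASSES: dict[str, int] = {
    "Mono": 1,
    "Di": 2,
    "Tri": 3,
    "Tetra": 4,
    "Penta": 5,
    "Hexa": 6,
}

CLASS_BY_UNIT_LENGTH: dict[int, str] = {v: k for k, v in MOTIF_CLASSES.items()}

#: Default minimum repeat counts per motif class.
DEFAULT_MIN_REPEATS: dict[str, int] = {
    "Mono": 20,
    "Di": 8,
    "Tri": 8,
    "Tetra": 8,
    "Penta": 6,
    "Hexa": 6,
}

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


@dataclass(frozen=True)
class ScanConfig:
    """Scan thresholds plus optional per-sequence overrides.

    ``per_sequence_overrides`` maps ``(seq_id, class_name)`` to a replacement
    minimum repeat count; this is how a per-chromosome exception (e.g. a
    relaxed dinucleotide threshold on one chromosome) is expressed without
    hard-coding it.
    """

    thresholds: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    per_sequence_overrides: Mapping[tuple[str, str], int] = field(default_factory=dict)
    flank_length: int = 200

    def __post_init__(self) -> None:
        for cls in MOTIF_CLASSES:
            if cls not in self.thresholds:
                raise ValueError(f"missing threshold for class {cls!r}")
        for cls, t in self.thresholds.items():
            if cls not in MOTIF_CLASSES:
                raise ValueError(f"unknown motif class {cls!r}")
            if t < 2:
                raise ValueError(f"threshold for {cls} must be >= 2, got {t}")
        for (seq_id, cls), t in self.per_sequence_overrides.items():
            if cls not in MOTIF_CLASSES:
                raise ValueError(f"unknown motif class {cls!r} in override for {seq_id!r}")
            if t < 2:
                raise ValueError(f"override for ({seq_id}, {cls}) must be >= 2, got {t}")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")

    def min_repeats(self, seq_id: str, class_name: str) -> int:
        """Effective threshold for ``class_name`` on ``seq_id``."""
        return self.per_sequence_overrides.get((seq_id, class_name), self.thresholds[class_name])


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect microsatellite tract (forward strand, 1-based)."""

    locus_id: str
    seq_id: str
    start: int
    end: int
    motif: str
    family: str
    motif_class: str
    repeat_count: int
    tract_length: int

    def __post_init__(self) -> None:
        unit = MOTIF_CLASSES[self.motif_class]
        if len(self.motif) != unit:
            raise ValueError("motif length does not match motif class")
        if self.tract_length != self.end - self.start + 1:
            raise ValueError("tract_length inconsistent with coordinates")
        if self.tract_length != unit * self.repeat_count:
            raise ValueError("tract_length must equal unit_length * repeat_count")


@dataclass(frozen=True)
class Fragment:
    """An SSR tract plus flanking sequence, with absolute coordinates."""

    locus_id: str
    seq_id: str
    start: int
    end: int
    sequence: str
    left_clip: int
    right_clip: int
    tract_start: int  # 1-based within fragment
    tract_end: int


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_family(motif: str) -> str:
    """Canonical family of a primitive motif: its smallest cyclic rotation.

    Rotations on the same strand are merged (``GA`` and ``AG`` are one
    family); reverse complements are not.

    Raises
    ------
    InvalidAlphabetError
        If the motif contains a character outside ACGT or is empty.
    InvalidMotifError
        If the motif is itself a repetition of a shorter unit.
    """
    if not motif or any(c not in _DNA for c in motif):
        raise InvalidAlphabetError(f"motif must be non-empty uppercase ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise InvalidMotifError(f"motif {motif!r} is not primitive")
    doubled = motif + motif
    return min(doubled[i : i + len(motif)] for i in range(len(motif)))


def _scan_segment(seg: str, offset: int) -> Iterable[tuple[int, int, int]]:
    """Yield (start0, unit_length, repeat_count) for every maximal perfect
    tandem run of a primitive unit with repeat_count >= 2 in ``seg``.

    ``start0`` is 0-based within the parent sequence (``offset`` applied).
    A run is the leading whole-unit part of a maximal periodic stretch; the
    stretch start defines the motif phase.
    """
    m = len(seg)
    for k in range(1, 7):
        pos = 0
        limit = m - 2 * k
        while pos <= limit:
            if seg[pos] != seg[pos + k]:
                pos += 1
                continue
            # maximal periodic stretch of period k starting at pos
            j = pos
            while j + k < m and seg[j] == seg[j + k]:
                j += 1
            run_len = j - pos + k
            reps = run_len // k
            if reps >= 2 and is_primitive(seg[pos : pos + k]):
                yield offset + pos, k, reps
            pos = j + 1


def scan_sequence(seq_id: str, sequence: str, config: ScanConfig | None = None) -> list[SSRLocus]:
    """Detect all qualifying perfect SSR tracts on the forward strand.

    Runs containing ``N`` are broken at the ``N``; each run is assigned to
    the smallest unit length that generates it (a poly-A tract is Mono,
    never Di ``AA``).  Output is sorted by start coordinate, then unit
    length.  Case-insensitive input; only ``ACGTN`` allowed.
    """
    if config is None:
        config = ScanConfig()
    seq = sequence.upper()
    bad = set(seq) - _DNA_N
    if bad:
        raise InvalidAlphabetError(f"invalid characters in sequence {seq_id!r}: {sorted(bad)}")

    loci: list[SSRLocus] = []
    # split on N: tracts never span an N
    seg_start = 0
    segments: list[tuple[str, int]] = []
    for part in seq.split("N"):
        if part:
            segments.append((part, seg_start))
        seg_start += len(part) + 1

    for seg, offset in segments:
        for start0, k, reps in _scan_segment(seg, offset):
            cls = CLASS_BY_UNIT_LENGTH[k]
            if reps < config.min_repeats(seq_id, cls):
                continue
            motif = seq[start0 : start0 + k]
            start = start0 + 1
            end = start0 + reps * k
            loci.append(
                SSRLocus(
                    locus_id=f"{seq_id}:{start}:{cls}",
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    family=canonical_family(motif),
                    motif_class=cls,
                    repeat_count=reps,
                    tract_length=reps * k,
                )
            )
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def scan_genome(genome: Mapping[str, str], config: ScanConfig | None = None) -> list[SSRLocus]:
    """Scan every sequence of a genome, in the mapping's order."""
    out: list[SSRLocus] = []
    for seq_id, seq in genome.items():
        out.extend(scan_sequence(seq_id, seq, config))
    return out


def extract_flanks(locus: SSRLocus, genome: Mapping[str, str], flank_length: int = 200) -> Fragment:
    """Cut the tract plus up to ``flank_length`` bases on each side.

    Clipping at sequence edges is recorded so downstream anchoring can tell
    how much flank is actually available.
    """
    if locus.seq_id not in genome:
        raise MissingSequenceError(f"sequence {locus.seq_id!r} not in genome")
    seq = genome[locus.seq_id].upper()
    n = len(seq)
    frag_start = max(1, locus.start - flank_length)
    frag_end = min(n, locus.end + flank_length)
    left_clip = flank_length - (locus.start - frag_start)
    right_clip = flank_length - (frag_end - locus.end)
    return Fragment(
        locus_id=locus.locus_id,
        seq_id=locus.seq_id,
        start=frag_start,
        end=frag_end,
        sequence=seq[frag_start - 1 : frag_end],
        left_clip=left_clip,
        right_clip=right_clip,
        tract_start=locus.start - frag_start + 1,
        tract_end=locus.end - frag_start + 1,
    )


def classify_genomic_context(
    loci: Sequence[SSRLocus],
    coding_intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> dict[str, str]:
    """Label each locus ``coding`` iff it overlaps a coding interval by >= 1 bp.

    Intervals are 1-based inclusive.  An empty interval set labels every
    locus ``non-coding``.
    """
    labels: dict[str, str] = {}
    for locus in loci:
        ivs = coding_intervals.get(locus.seq_id, ())
        coding = any(s <= locus.end and e >= locus.start for s, e in ivs)
        labels[locus.locus_id] = "coding" if coding else "non-coding"
    return labels


def summarize_context(loci: Sequence[SSRLocus], labels: Mapping[str, str]) -> pd.DataFrame:
    """Count loci by (seq_id, motif class, coding/non-coding label)."""
    classes = list(MOTIF_CLASSES)
    rows = [
        {"seq_id": l.seq_id, "motif_class": l.motif_class, "label": labels[l.locus_id]}
        for l in loci
    ]
    if not rows:
        cols = pd.MultiIndex.from_product([classes, ["coding", "non-coding"]])
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="seq_id", columns=["motif_class", "label"], aggfunc="size", fill_value=0
    )
    return table.sort_index()


def summarize_by_class_and_chrom(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Count table: rows = seq_id (sorted) plus ``Total`` row, columns =
    motif classes plus ``Total`` column.  Totals are sums of the counts."""
    classes = list(MOTIF_CLASSES)
    counts: dict[str, dict[str, int]] = {}
    for locus in loci:
        counts.setdefault(locus.seq_id, {c: 0 for c in classes})
        counts[locus.seq_id][locus.motif_class] += 1
    table = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=classes, fill_value=0)
    table = table.sort_index()
    table["Total"] = table.sum(axis=1)
    total_row = table.sum(axis=0)
    table.loc["Total"] = total_row
    return table.astype(int)
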