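"""Deterministic primer-pair selection for SSR fragments.

One locus-specific pair is chosen per fragment by exhaustively enumerating
candidate windows on both flanks, filtering on explicit constraints and
minimizing a fixed penalty.  Melting temperatures use the Wallace rule
(2*(A+T) + 4*(G+C)) so every number is exactly reproducible; this is a
documented deviation from thermodynamic Tm models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import revcomp
from .errors import InvalidAlphabetError

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "DesignResult",
    "wallace_tm",
    "gc_fraction",
    "max_homopolymer",
    "design_pair",
    "batch_design",
    "in_silico_pcr",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerConstraints:
    """All design constraints; every bound is overridable."""

    min_len: int = 18
    max_len: int = 24
    min_tm: float = 55.0
    max_tm: float = 62.0
    min_gc: float = 0.40
    max_gc: float = 0.60
    max_tm_diff: float = 3.0
    min_product: int = 100
    max_product: int = 300
    max_homopolymer: int = 4

    def __post_init__(self) -> None:
        if self.min_len > self.max_len or self.min_tm > self.max_tm:
            raise ValueError("min must not exceed max")
        if self.min_gc > self.max_gc or self.min_product > self.max_product:
            raise ValueError("min must not exceed max")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair.  Coordinates are 1-based on the fragment; the
    reverse primer sequence is given 5'->3' on the minus strand."""

    fwd_seq: str
    rev_seq: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int
    penalty: float


@dataclass(frozen=True)
class DesignResult:
    pair: PrimerPair | None
    reasons: tuple[str, ...] = ()


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C); '' -> 0."""
    bad = set(seq) - _DNA
    if bad:
        raise InvalidAlphabetError(f"invalid bases for Tm: {sorted(bad)}")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return float(2 * at + 4 * gc)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = 0
    run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def _valid_windows(
    region: str,
    region_offset: int,
    constraints: PrimerConstraints,
    reverse: bool,
) -> list[tuple[int, int, str, float, float]]:
    """Enumerate valid primer windows inside ``region``.

    Returns (start, end, primer_seq, tm, gc) with 1-based fragment
    coordinates (``region_offset`` = fragment coordinate of region[0]).
    For reverse primers the primer sequence is the reverse complement of
    the window.
    """
    out = []
    n = len(region)
    for length in range(constraints.min_len, constraints.max_len + 1):
        for i in range(0, n - length + 1):
            window = region[i : i + length]
            primer = revcomp(window) if reverse else window
            gc = gc_fraction(primer)
            if not (constraints.min_gc <= gc <= constraints.max_gc):
                continue
            tm = wallace_tm(primer)
            if not (constraints.min_tm <= tm <= constraints.max_tm):
                continue
            if max_homopolymer(primer) > constraints.max_homopolymer:
                continue
            out.append((region_offset + i, region_offset + i + length - 1, primer, tm, gc))
    return out


def design_pair(
    fragment: str,
    tract_start: int,
    tract_end: int,
    constraints: PrimerConstraints | None = None,
) -> DesignResult:
    """Select the minimum-penalty primer pair flanking the tract.

    ``tract_start``/``tract_end`` are 1-based inclusive on ``fragment``.
    Neither primer may overlap the tract, so every amplicon contains the
    whole tract.  penalty = |tm_f - 60| + |tm_r - 60| + |tm_f - tm_r| +
    0.01 * |product_size - 200|; ties broken by smaller forward start, then
    smaller product size, then shorter primers.  Returns a result with
    ``pair=None`` plus reason codes when no pair satisfies every
    constraint.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    fragment = fragment.upper()
    n = len(fragment)
    reasons: list[str] = []
    if n < constraints.min_product:
        return DesignResult(None, ("product-range",))
    left_len = tract_start - 1
    right_len = n - tract_end
    if left_len < constraints.min_len or right_len < constraints.min_len:
        return DesignResult(None, ("flank-too-short",))

    fwd = _valid_windows(fragment[: tract_start - 1], 1, constraints, reverse=False)
    rev = _valid_windows(fragment[tract_end:], tract_end + 1, constraints, reverse=True)
    if not fwd:
        reasons.append("no-valid-forward-primer")
    if not rev:
        reasons.append("no-valid-reverse-primer")
    if reasons:
        return DesignResult(None, tuple(reasons))

    best: tuple | None = None
    best_pair: PrimerPair | None = None
    for f_start, f_end, f_seq, f_tm, f_gc in fwd:
        for r_start, r_end, r_seq, r_tm, r_gc in rev:
            product = r_end - f_start + 1
            if not (constraints.min_product <= product <= constraints.max_product):
                continue
            if abs(f_tm - r_tm) > constraints.max_tm_diff:
                continue
            penalty = (
                abs(f_tm - 60.0)
                + abs(r_tm - 60.0)
                + abs(f_tm - r_tm)
                + 0.01 * abs(product - 200)
            )
            key = (penalty, f_start, product, len(f_seq), len(r_seq))
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(
                    fwd_seq=f_seq,
                    rev_seq=r_seq,
                    fwd_start=f_start,
                    fwd_end=f_end,
                    rev_start=r_start,
                    rev_end=r_end,
                    tm_f=f_tm,
                    tm_r=r_tm,
                    gc_f=f_gc,
                    gc_r=r_gc,
                    product_size=product,
                    penalty=penalty,
                )
    if best_pair is None:
        return DesignResult(None, ("no-compatible-pair",))
    return DesignResult(best_pair)


def in_silico_pcr(template: str, fwd_seq: str, rev_seq: str) -> list[tuple[int, int]]:
    """Exact-match PCR: every (start, end) 1-based amplicon on ``template``
    bounded by a forward-primer site and a downstream reverse-primer site."""
    template = template.upper()
    rev_site = revcomp(rev_seq)
    fwd_positions = []
    pos = template.find(fwd_seq)
    while pos != -1:
        fwd_positions.append(pos)
        pos = template.find(fwd_seq, pos + 1)
    rev_positions = []
    pos = template.find(rev_site)
    while pos != -1:
        rev_positions.append(pos)
        pos = template.find(rev_site, pos + 1)
    products = []
    for f in fwd_positions:
        for r in rev_positions:
            end = r + len(rev_site)
            if end > f + len(fwd_seq):
                products.append((f + 1, end))
    return products


def batch_design(
    fragments: Iterable[tuple[str, str, str, int, int]],
    constraints: PrimerConstraints | None = None,
) -> tuple[dict[str, DesignResult], pd.Series]:
    """Design a pair per fragment; tally designed pairs per sequence.

    ``fragments`` yields (locus_id, seq_id, fragment, tract_start,
    tract_end).  Returns ({locus_id: result}, per-seq_id designed counts
    with a ``Total`` entry).
    """
    results: dict[str, DesignResult] = {}
    counts: dict[str, int] = {}
    for locus_id, seq_id, fragment, tract_start, tract_end in fragments:
        res = design_pair(fragment, tract_start, tract_end, constraints)
        results[locus_id] = res
        if res.pair is not None:
            counts[seq_id] = counts.get(seq_id, 0) + 1
    series = count_by_sequence(counts)
    return results, series


def count_by_sequence(counts: dict[str, int]) -> pd.Series:
    """Per-sequence counts plus a ``Total`` cell equal to their sum."""
    series = pd.Series(counts, dtype=int).sort_index()
    series.loc["Total"] = int(series.sum())
    return series


def pairs_to_frame(results: dict[str, DesignResult]) -> pd.DataFrame:
    rows = []
    for locus_id, res in results.items():
        if res.pair is None:
            continue
        p = res.pair
        rows.append(
            (locus_id, p.fwd_seq, p.rev_seq, p.fwd_start, p.rev_start,
             p.tm_f, p.tm_r, p.product_size, round(p.penalty, 4))
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "fwd_seq", "rev_seq", "fwd_start", "rev_start",
                 "tm_f", "tm_r", "product_size", "penalty"],
    )
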