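"""Single-copy filtering of SSR-containing fragments.

A fragment is kept iff its best genome alignment scores at least ``fold``
times (default five-fold) higher than the second best.  Hits come either
from an external 12-column tabular alignment file or from the built-in
desk-scale seed-and-extend search (:func:`naive_search`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FragmentTooShortError, HitTableParseError, NoHitError
from .ssr_scan import SSRLocus

__all__ = [
    "AlignmentHit",
    "read_hit_table",
    "naive_search",
    "single_copy_test",
    "filter_single_copy",
    "DecisionRecord",
]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_start: int  # 1-based
    subject_end: int
    score: float
    identity: float  # fraction in [0, 1]


@dataclass(frozen=True)
class DecisionRecord:
    locus_id: str
    top_score: float | None
    second_score: float | None
    verdict: str  # single-copy | multi-copy | no-hit


def _sort_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    return sorted(hits, key=lambda h: (-h.score, h.subject_id, h.subject_start))


def read_hit_table(path: str | Path) -> dict[str, list[AlignmentHit]]:
    """Parse standard 12-column tabular alignment output.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore.  The bitscore column is
    the score; %identity is converted to a fraction.  Rows are grouped by
    query and sorted by descending score (ties: subject id, subject start).
    """
    table: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitTableParseError(
                    f"line {lineno}: expected >= 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    score=float(fields[11]),
                    identity=float(fields[2]) / 100.0,
                )
            except ValueError as exc:
                raise HitTableParseError(f"line {lineno}: {exc}") from exc
            table.setdefault(hit.query_id, []).append(hit)
    return {q: _sort_hits(hits) for q, hits in table.items()}


def _max_segment(scores: Sequence[int]) -> tuple[int, int, int]:
    """Best-scoring contiguous segment of a +1/-1 vector (Kadane).

    Returns (score, start, end) with ``end`` exclusive; ties broken by
    smaller start, then smaller end (shortest earliest segment).
    """
    best = (0, 0, 0)
    cur = 0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    return best


def naive_search(
    query_id: str,
    fragment: str,
    genome: Mapping[str, str],
    k: int = 15,
    min_score: int = 30,
) -> list[AlignmentHit]:
    """Desk-scale seed-and-extend search of ``fragment`` against ``genome``.

    Exact ``k``-mer seeds define candidate diagonals; on each diagonal the
    best-scoring ungapped segment (match +1 / mismatch -1) is computed and
    reported when its score reaches ``min_score``.  The self-hit of a
    fragment copied from the genome scores exactly the fragment length.
    Alignments sharing no exact k-mer with the genome are not found (this
    stands in for a full aligner at test scale).
    """
    fragment = fragment.upper()
    if len(fragment) < k:
        raise FragmentTooShortError(f"fragment length {len(fragment)} < k={k}")

    frag_kmers: dict[str, list[int]] = {}
    for qi in range(len(fragment) - k + 1):
        frag_kmers.setdefault(fragment[qi : qi + k], []).append(qi)

    hits: list[AlignmentHit] = []
    for subject_id, seq in genome.items():
        seq = seq.upper()
        diagonals: set[int] = set()
        for gj in range(len(seq) - k + 1):
            positions = frag_kmers.get(seq[gj : gj + k])
            if positions:
                for qi in positions:
                    diagonals.add(gj - qi)
        for d in sorted(diagonals):
            q_lo = max(0, -d)
            q_hi = min(len(fragment), len(seq) - d)
            if q_hi - q_lo < k:
                continue
            vec = [1 if fragment[q] == seq[q + d] else -1 for q in range(q_lo, q_hi)]
            score, s, e = _max_segment(vec)
            if score >= min_score:
                matches = sum(1 for v in vec[s:e] if v == 1)
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=subject_id,
                        subject_start=d + q_lo + s + 1,
                        subject_end=d + q_lo + e,
                        score=float(score),
                        identity=matches / (e - s),
                    )
                )
    return _sort_hits(hits)


def single_copy_test(scores: Sequence[float], fold: float = 5.0) -> bool:
    """Five-fold top-score rule: single copy iff the top score is at least
    ``fold`` times the second one (boundary inclusive), or there is no
    second hit.  The score list must be sorted descending."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if len(scores) == 0:
        raise NoHitError("empty score list")
    if len(scores) == 1:
        return True
    return scores[0] >= fold * scores[1]


def filter_single_copy(
    loci: Sequence[SSRLocus],
    hit_table: Mapping[str, Sequence[AlignmentHit]],
    fold: float = 5.0,
) -> tuple[list[SSRLocus], list[DecisionRecord]]:
    """Keep loci passing :func:`single_copy_test`; log every decision.

    Loci with zero hits cannot be confirmed single-copy and are removed
    (verdict ``no-hit``).
    """
    retained: list[SSRLocus] = []
    log: list[DecisionRecord] = []
    for locus in loci:
        hits = hit_table.get(locus.locus_id, ())
        if not hits:
            log.append(DecisionRecord(locus.locus_id, None, None, "no-hit"))
            continue
        scores = [h.score for h in hits]
        ok = single_copy_test(scores, fold)
        second = scores[1] if len(scores) > 1 else None
        log.append(
            DecisionRecord(locus.locus_id, scores[0], second, "single-copy" if ok else "multi-copy")
        )
        if ok:
            retained.append(locus)
    return retained, log


def decision_log_frame(log: Sequence[DecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.locus_id, r.top_score, r.second_score, r.verdict) for r in log],
        columns=["locus_id", "top_score", "second_score", "verdict"],
    )
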