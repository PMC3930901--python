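"""Independent brute-force oracles.

These deliberately share no code with the package implementations they
check: the scanner oracle tests every primitive motif at every position,
the aligner oracle scans every diagonal, and the primer oracle enumerates
every window pair with its own arithmetic.
"""

from __future__ import annotations


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def oracle_scan(seq: str, thresholds: dict[int, int]) -> list[tuple[int, int, int]]:
    """All maximal perfect tandem runs meeting per-unit-length thresholds.

    ``thresholds`` maps unit length (1-6) -> min repeat count.  Returns
    (start 1-based, unit_length, repeat_count) triples sorted by
    (start, unit_length).  Tests every primitive motif of length 1-6 at
    every position; a run is reported at a position iff it is
    left-maximal (the same motif does not also occur immediately before).
    Shifted phases of one periodic stretch are same-family duplicates
    (e.g. ACGCTA inside an AACGCT stretch with a partial trailing unit);
    overlapping same-family runs are deduplicated keeping the earliest.
    Runs never span an N.
    """
    seq = seq.upper()
    out: list[tuple[int, int, int]] = []
    offset = 0
    for segment in seq.split("N"):
        m = len(segment)
        candidates: list[tuple[int, int, int, str]] = []
        for i in range(m):
            for k in range(1, 7):
                if i + 2 * k > m:
                    break
                unit = segment[i : i + k]
                if segment[i + k : i + 2 * k] != unit:
                    continue
                if not _primitive(unit):
                    continue
                if i >= k and segment[i - k : i] == unit:
                    continue  # not left-maximal
                reps = 2
                while segment[i + reps * k : i + (reps + 1) * k] == unit:
                    reps += 1
                if reps >= thresholds[k]:
                    family = min(unit[r:] + unit[:r] for r in range(k))
                    candidates.append((i, k, reps, family))
        kept: list[tuple[int, int, int, str]] = []
        for cand in sorted(candidates):
            i, k, reps, family = cand
            end = i + reps * k - 1
            if any(
                f == family and i <= pe and end >= p
                for p, kk, r, f in kept
                for pe in (p + r * kk - 1,)
            ):
                continue
            kept.append(cand)
        out.extend((offset + i + 1, k, reps) for i, k, reps, _ in kept)
        offset += m + 1
    out.sort()
    return out


def oracle_local_hits(fragment: str, genome: dict[str, str], min_score: int):
    """Best ungapped +1/-1 segment on every diagonal of every sequence."""
    hits = []
    for subject_id, seq in genome.items():
        for d in range(-len(fragment) + 1, len(seq)):
            q_lo = max(0, -d)
            q_hi = min(len(fragment), len(seq) - d)
            if q_hi <= q_lo:
                continue
            best = cur = 0
            best_span = (0, 0)
            cur_start = q_lo
            for q in range(q_lo, q_hi):
                s = 1 if fragment[q] == seq[q + d] else -1
                if cur <= 0:
                    cur = s
                    cur_start = q
                else:
                    cur += s
                if cur > best:
                    best = cur
                    best_span = (cur_start, q + 1)
            if best >= min_score:
                hits.append((float(best), subject_id, d + best_span[0] + 1, d + best_span[1]))
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    return hits


def _tm(seq: str) -> float:
    return 2.0 * sum(c in "AT" for c in seq) + 4.0 * sum(c in "GC" for c in seq)


def _gc(seq: str) -> float:
    return sum(c in "GC" for c in seq) / len(seq)


def _homopolymer(seq: str) -> int:
    best, run = 1, 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def oracle_design(fragment: str, tract_start: int, tract_end: int, c) -> tuple | None:
    """Exhaustive enumeration of every (forward, reverse) primer window.

    ``c`` is any object exposing the same constraint attributes as the
    implementation's constraint record.  Returns the winning tuple
    (penalty, fwd_start, product, fwd_len, rev_len, fwd_seq, rev_seq) or
    None.  1-based coordinates on ``fragment``.
    """
    n = len(fragment)
    best = None
    for f_len in range(c.min_len, c.max_len + 1):
        for f_start in range(1, tract_start - f_len + 1):  # fwd fully left of tract
            f_seq = fragment[f_start - 1 : f_start - 1 + f_len]
            if not (c.min_gc <= _gc(f_seq) <= c.max_gc):
                continue
            f_tm = _tm(f_seq)
            if not (c.min_tm <= f_tm <= c.max_tm):
                continue
            if _homopolymer(f_seq) > c.max_homopolymer:
                continue
            for r_len in range(c.min_len, c.max_len + 1):
                for r_start in range(tract_end + 1, n - r_len + 2):
                    r_end = r_start + r_len - 1
                    r_seq = _revcomp(fragment[r_start - 1 : r_end])
                    if not (c.min_gc <= _gc(r_seq) <= c.max_gc):
                        continue
                    r_tm = _tm(r_seq)
                    if not (c.min_tm <= r_tm <= c.max_tm):
                        continue
                    if _homopolymer(r_seq) > c.max_homopolymer:
                        continue
                    if abs(f_tm - r_tm) > c.max_tm_diff:
                        continue
                    product = r_end - f_start + 1
                    if not (c.min_product <= product <= c.max_product):
                        continue
                    penalty = (
                        abs(f_tm - 60.0) + abs(r_tm - 60.0) + abs(f_tm - r_tm)
                        + 0.01 * abs(product - 200)
                    )
                    key = (penalty, f_start, product, f_len, r_len, f_seq, r_seq)
                    if best is None or key < best:
                        best = key
    return best
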