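"""Cross-assembly SSR length-polymorphism calling.

For each reference locus, the 50 bp of flank immediately adjacent to the
tract on each side is located in an alternate assembly (exact match first,
then best match with a small mismatch budget, both required unique).  The
inter-anchor interval is re-measured for the locus' motif family and the
length difference against the reference tract is the polymorphism call.
This replaces whole-fragment alignment with a fully specified, testable
procedure; anchor uniqueness guards against paralogy artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._util import percent_half_up
from .ssr_scan import Fragment, SSRLocus, extract_flanks

__all__ = [
    "Anchored",
    "LocusComparison",
    "anchor_flanks",
    "measure_alt_tract",
    "call_polymorphism",
    "compare_loci",
    "summarize_rates",
    "comparisons_to_frame",
]

POLYMORPHIC = "polymorphic"
MONOMORPHIC = "monomorphic"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Anchored:
    """Inter-anchor interval located in an alternate assembly (1-based)."""

    seq_id: str
    start: int
    end: int  # end < start for an empty interval
    sequence: str


@dataclass(frozen=True)
class LocusComparison:
    locus_id: str
    seq_id: str
    family: str
    motif_class: str
    ref_len: int
    alt_lens: Mapping[str, int | None] = field(default_factory=dict)
    deltas: Mapping[str, int | None] = field(default_factory=dict)
    status: str = UNRESOLVED
    reasons: Mapping[str, str] = field(default_factory=dict)


def _find_unique(assembly: Mapping[str, str], pattern: str, max_mismatches: int) -> tuple[str, int] | None:
    """Locate ``pattern`` in the assembly (forward strand).

    Exact occurrences are counted first; a single exact hit wins.  With no
    exact hit, every position is scanned and the hit with the fewest
    mismatches (<= ``max_mismatches``) wins if it is unique.  Multiple
    equally good hits -> None (ambiguous).  Returns (seq_id, 0-based pos).
    """
    exact: list[tuple[str, int]] = []
    for seq_id, seq in assembly.items():
        pos = seq.find(pattern)
        while pos != -1:
            exact.append((seq_id, pos))
            if len(exact) > 1:
                return None
            pos = seq.find(pattern, pos + 1)
    if len(exact) == 1:
        return exact[0]

    m = len(pattern)
    best_mm = max_mismatches + 1
    best: tuple[str, int] | None = None
    tied = False
    for seq_id, seq in assembly.items():
        for pos in range(len(seq) - m + 1):
            window = seq[pos : pos + m]
            mm = 0
            aborted = False
            for a, b in zip(pattern, window):
                if a != b:
                    mm += 1
                    if mm > best_mm:  # cannot beat nor tie the best
                        aborted = True
                        break
            if aborted:
                continue
            if mm < best_mm:
                best_mm = mm
                best = (seq_id, pos)
                tied = False
            elif mm == best_mm and mm <= max_mismatches:
                tied = True
    if best is None or tied or best_mm > max_mismatches:
        return None
    return best


def anchor_flanks(
    left_flank: str,
    right_flank: str,
    alt_assembly: Mapping[str, str],
    max_mismatches: int = 2,
    anchor_length: int = 50,
) -> tuple[Anchored | None, str]:
    """Locate both flank anchors in an alternate assembly.

    The anchors are the ``anchor_length`` bases of flank adjacent to the
    tract.  Both must be found uniquely, on the same assembly sequence, in
    order.  Returns (interval, reason); interval is None when unresolved.
    """
    if len(left_flank) < anchor_length or len(right_flank) < anchor_length:
        return None, "flank-too-short"
    left_anchor = left_flank[-anchor_length:]
    right_anchor = right_flank[:anchor_length]
    left_hit = _find_unique(alt_assembly, left_anchor, max_mismatches)
    if left_hit is None:
        return None, "left-anchor-not-unique"
    right_hit = _find_unique(alt_assembly, right_anchor, max_mismatches)
    if right_hit is None:
        return None, "right-anchor-not-unique"
    if left_hit[0] != right_hit[0]:
        return None, "anchors-on-different-sequences"
    seq_id = left_hit[0]
    inter_start0 = left_hit[1] + anchor_length  # 0-based, first base after left anchor
    inter_end0 = right_hit[1]  # 0-based, first base of right anchor
    if inter_end0 < inter_start0:
        return None, "anchors-out-of-order"
    seq = alt_assembly[seq_id]
    return (
        Anchored(
            seq_id=seq_id,
            start=inter_start0 + 1,
            end=inter_end0,
            sequence=seq[inter_start0:inter_end0],
        ),
        "ok",
    )


def measure_alt_tract(interval_sequence: str, family: str) -> int:
    """Length in bases of the longest maximal run in the interval whose
    repeat unit is a cyclic rotation of ``family``.

    Partial trailing units extend the run length; an interval holding no
    complete unit of the family measures 0.
    """
    k = len(family)
    rotations = {family[i:] + family[:i] for i in range(k)}
    s = interval_sequence
    m = len(s)
    best = 0
    pos = 0
    while pos + k <= m:
        if s[pos : pos + k] in rotations:
            end = pos + k
            while end < m and s[end] == s[end - k]:
                end += 1
            best = max(best, end - pos)
            pos = max(pos + 1, end - k + 1)
        else:
            pos += 1
    return best


def call_polymorphism(
    ref_len: int,
    alt_lens: Mapping[str, int | None],
    min_diff: int = 1,
) -> tuple[str, dict[str, int | None]]:
    """Status plus signed per-assembly deltas (alt - ref, bases).

    polymorphic iff any anchored assembly differs by >= ``min_diff`` bases;
    monomorphic iff all anchored assemblies are within < ``min_diff``;
    unresolved iff no assembly anchored.
    """
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    deltas: dict[str, int | None] = {
        name: (alt - ref_len if alt is not None else None) for name, alt in alt_lens.items()
    }
    anchored = [d for d in deltas.values() if d is not None]
    if not anchored:
        return UNRESOLVED, deltas
    if any(abs(d) >= min_diff for d in anchored):
        return POLYMORPHIC, deltas
    return MONOMORPHIC, deltas


def compare_loci(
    loci: Sequence[SSRLocus],
    ref_genome: Mapping[str, str],
    alt_assemblies: Mapping[str, Mapping[str, str]],
    min_diff: int = 1,
    flank_length: int = 200,
    anchor_length: int = 50,
    max_mismatches: int = 2,
) -> list[LocusComparison]:
    """Run flank anchoring and tract re-measurement for every locus against
    every named alternate assembly."""
    out: list[LocusComparison] = []
    for locus in loci:
        frag: Fragment = extract_flanks(locus, ref_genome, flank_length)
        left_flank = frag.sequence[: frag.tract_start - 1]
        right_flank = frag.sequence[frag.tract_end :]
        alt_lens: dict[str, int | None] = {}
        reasons: dict[str, str] = {}
        for name, assembly in alt_assemblies.items():
            anchored, reason = anchor_flanks(
                left_flank, right_flank, assembly, max_mismatches, anchor_length
            )
            reasons[name] = reason
            if anchored is None:
                alt_lens[name] = None
            else:
                alt_lens[name] = measure_alt_tract(anchored.sequence, locus.family)
        status, deltas = call_polymorphism(locus.tract_length, alt_lens, min_diff)
        out.append(
            LocusComparison(
                locus_id=locus.locus_id,
                seq_id=locus.seq_id,
                family=locus.family,
                motif_class=locus.motif_class,
                ref_len=locus.tract_length,
                alt_lens=alt_lens,
                deltas=deltas,
                status=status,
                reasons=reasons,
            )
        )
    return out


def summarize_rates(
    comparisons: Sequence[LocusComparison],
    group_by: str = "seq_id",
    min_diff: int = 1,
) -> pd.DataFrame:
    """Per-group polymorphism counts and percentages for each assembly.

    ``group_by`` is ``seq_id`` or ``motif_class``.  A locus counts as
    polymorphic versus an assembly iff that assembly anchored and
    |delta| >= ``min_diff``.

    Percentage cells are recomputed from the integer counts in the same
    row, rounded half-up to one decimal; 0-of-0 yields a blank (NaN).
    """
    if group_by not in ("seq_id", "motif_class"):
        raise ValueError("group_by must be 'seq_id' or 'motif_class'")
    assemblies: list[str] = []
    for c in comparisons:
        for name in c.alt_lens:
            if name not in assemblies:
                assemblies.append(name)
    groups: dict[str, dict[str, int]] = {}
    for c in comparisons:
        key = getattr(c, group_by)
        row = groups.setdefault(key, {"total": 0, **{f"{a}_poly": 0 for a in assemblies}})
        for a in assemblies:
            row.setdefault(f"{a}_poly", 0)
        row["total"] += 1
        for a in assemblies:
            d = c.deltas.get(a)
            if d is not None and abs(d) >= min_diff:
                row[f"{a}_poly"] += 1
    if not groups:
        cols = ["total"]
        for a in assemblies:
            cols += [f"{a}_poly", f"{a}_pct"]
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame.from_dict(groups, orient="index").sort_index()
    table.loc["Total"] = table.sum(axis=0)
    for a in assemblies:
        table[f"{a}_pct"] = [
            percent_half_up(r[f"{a}_poly"], r["total"]) for _, r in table.iterrows()
        ]
    ordered = ["total"]
    for a in assemblies:
        ordered += [f"{a}_poly", f"{a}_pct"]
    return table[ordered]


def comparisons_to_frame(comparisons: Sequence[LocusComparison]) -> pd.DataFrame:
    assemblies: list[str] = []
    for c in comparisons:
        for name in c.alt_lens:
            if name not in assemblies:
                assemblies.append(name)
    rows = []
    for c in comparisons:
        row: dict[str, object] = {
            "locus_id": c.locus_id,
            "seq_id": c.seq_id,
            "family": c.family,
            "class": c.motif_class,
            "ref_len": c.ref_len,
        }
        for a in assemblies:
            alt = c.alt_lens.get(a)
            delta = c.deltas.get(a)
            row[f"{a}_len"] = "" if alt is None else alt
            row[f"{a}_delta"] = "" if delta is None else delta
        row["status"] = c.status
        rows.append(row)
    return pd.DataFrame(rows)
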