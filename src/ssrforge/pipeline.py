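"""End-to-end orchestration: scan -> unique -> compare -> design -> map.

A run is configured by a flat key=value file (full CLI override), writes
every stage's table before the next stage starts, and ends with a
consolidated summary table whose percentage cells are always recomputed
from the integer count cells in the same row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import fastaio
from ._util import percent_half_up
from .errors import ConfigError
from .physical_map import build_map, map_to_frame
from .polymorphism_compare import POLYMORPHIC, compare_loci, comparisons_to_frame, summarize_rates
from .primer_design import PrimerConstraints, batch_design, pairs_to_frame
from .ssr_scan import DEFAULT_MIN_REPEATS, MOTIF_CLASSES, ScanConfig, extract_flanks, scan_genome
from .uniqueness import decision_log_frame, filter_single_copy, naive_search

__all__ = ["RunConfig", "StageReport", "run_all", "report_table"]

_SCALARS = {
    "reference": str,
    "annotation": str,
    "genotypes": str,
    "output_dir": str,
    "seed": int,
    "flank_length": int,
    "fold": float,
    "min_diff": int,
    "anchor_length": int,
    "max_mismatches": int,
    "min_product": int,
    "max_product": int,
    "select": str,
}


@dataclass
class RunConfig:
    reference: str = ""
    alternates: dict[str, str] = field(default_factory=dict)  # name -> fasta path
    annotation: str = ""
    genotypes: str = ""
    output_dir: str = "ssrforge_out"
    seed: int = 0
    thresholds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    overrides: dict[tuple[str, str], int] = field(default_factory=dict)
    flank_length: int = 200
    fold: float = 5.0
    min_diff: int = 1
    anchor_length: int = 50
    max_mismatches: int = 2
    min_product: int = 100
    max_product: int = 300
    select: str = "either"  # either | both: polymorphism vs how many assemblies

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse the flat key=value config dialect.

        Recognised keys: the scalar fields, ``alt.NAME=path``,
        ``threshold.CLASS=N`` and ``override.SEQ.CLASS=N``.  Unknown keys
        are rejected.
        """
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in _SCALARS:
                try:
                    setattr(cfg, key, _SCALARS[key](value))
                except ValueError as exc:
                    raise ConfigError(f"line {lineno}: bad value for {key}: {exc}") from exc
            elif key.startswith("alt."):
                cfg.alternates[key[4:]] = value
            elif key.startswith("threshold."):
                cls_name = key[len("threshold."):]
                cfg.thresholds[cls_name] = int(value)
            elif key.startswith("override."):
                parts = key[len("override."):].rsplit(".", 1)
                if len(parts) != 2:
                    raise ConfigError(f"line {lineno}: override key must be override.SEQ.CLASS")
                cfg.overrides[(parts[0], parts[1])] = int(value)
            else:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.reference:
            raise ConfigError("reference FASTA path is required")
        if not Path(self.reference).exists():
            raise ConfigError(f"reference FASTA not found: {self.reference}")
        for name, p in self.alternates.items():
            if not Path(p).exists():
                raise ConfigError(f"alternate assembly {name!r} not found: {p}")
        for cls_name in self.thresholds:
            if cls_name not in MOTIF_CLASSES:
                raise ConfigError(f"unknown motif class in thresholds: {cls_name!r}")
        for (_, cls_name) in self.overrides:
            if cls_name not in MOTIF_CLASSES:
                raise ConfigError(f"unknown motif class in overrides: {cls_name!r}")
        if self.select not in ("either", "both"):
            raise ConfigError("select must be 'either' or 'both'")
        if self.fold <= 1:
            raise ConfigError("fold must be > 1")

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            thresholds=dict(self.thresholds),
            per_sequence_overrides=dict(self.overrides),
            flank_length=self.flank_length,
        )

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "alternates":
                lines.extend(f"alt.{k} = {p}" for k, p in v.items())
            elif f.name == "thresholds":
                lines.extend(f"threshold.{k} = {t}" for k, t in v.items())
            elif f.name == "overrides":
                lines.extend(f"override.{s}.{c} = {t}" for (s, c), t in v.items())
            elif v != "":
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class StageReport:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + sum(self.dropped.values()):
            raise ValueError(f"stage {self.stage}: input != output + dropped")


def report_table(
    counts: pd.DataFrame,
    pct_pairs: Sequence[tuple[str, str, str]] = (),
    totals_row: str = "Total",
) -> pd.DataFrame:
    """Append a totals row to integer count columns and recompute every
    percentage cell as 100 * numerator / denominator (half-up, 1 decimal).

    ``pct_pairs`` lists (numerator_col, denominator_col, pct_col); the pct
    columns are (re)computed from the counts in the same row, a 0-of-0 cell
    is blank.  An empty input yields a header-only table.
    """
    table = counts.copy()
    if table.empty:
        for _, _, pct_col in pct_pairs:
            table[pct_col] = pd.Series(dtype=float)
        return table
    table.loc[totals_row] = table.sum(axis=0)
    for num_col, den_col, pct_col in pct_pairs:
        table[pct_col] = [
            percent_half_up(row[num_col], row[den_col]) for _, row in table.iterrows()
        ]
    return table


def _is_selected(comparison, select: str) -> bool:
    deltas = [d for d in comparison.deltas.values() if d is not None]
    if not deltas:
        return False
    hits = [abs(d) >= 1 for d in deltas]
    if select == "both":
        return len(deltas) == len(comparison.deltas) and all(hits)
    return any(hits)


def run_all(config: RunConfig) -> dict[str, object]:
    """Run every stage in order, writing each stage's outputs first.

    Returns the in-memory artifacts: loci, retained loci, comparisons,
    designs, map entries, stage reports and the consolidated summary.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.txt").write_text(config.to_text())

    reference = fastaio.read_fasta(config.reference)
    scan_cfg = config.scan_config()
    reports: list[StageReport] = []

    # stage 1: scan
    loci = scan_genome(reference, scan_cfg)
    fastaio.write_loci(out / "loci.tsv", loci)
    reports.append(StageReport("scan", len(loci), len(loci)))

    # stage 2: single-copy filter (built-in search of each fragment)
    hit_table = {}
    for locus in loci:
        frag = extract_flanks(locus, reference, config.flank_length)
        hit_table[locus.locus_id] = naive_search(locus.locus_id, frag.sequence, reference)
    retained, log = filter_single_copy(loci, hit_table, config.fold)
    decision_log_frame(log).to_csv(out / "single_copy_log.tsv", sep="\t", index=False)
    fastaio.write_loci(out / "single_copy_loci.tsv", retained)
    dropped: dict[str, int] = {}
    for rec in log:
        if rec.verdict != "single-copy":
            dropped[rec.verdict] = dropped.get(rec.verdict, 0) + 1
    reports.append(StageReport("unique", len(loci), len(retained), dropped))

    # stage 3: polymorphism comparison
    alternates = {name: fastaio.read_fasta(p) for name, p in config.alternates.items()}
    comparisons = compare_loci(
        retained,
        reference,
        alternates,
        min_diff=config.min_diff,
        flank_length=config.flank_length,
        anchor_length=config.anchor_length,
        max_mismatches=config.max_mismatches,
    )
    comparisons_to_frame(comparisons).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    if alternates:
        summarize_rates(comparisons, "seq_id", config.min_diff).to_csv(
            out / "polymorphism_rates.tsv", sep="\t"
        )
    selected = [c for c in comparisons if c.status == POLYMORPHIC and _is_selected(c, config.select)]
    n_dropped = len(retained) - len(selected)
    reports.append(
        StageReport("compare", len(retained), len(selected), {"not-polymorphic": n_dropped})
    )

    # stage 4: primer design
    by_id = {l.locus_id: l for l in retained}
    constraints = PrimerConstraints(min_product=config.min_product, max_product=config.max_product)
    frag_iter = []
    for c in selected:
        locus = by_id[c.locus_id]
        frag = extract_flanks(locus, reference, config.flank_length)
        frag_iter.append((locus.locus_id, locus.seq_id, frag.sequence, frag.tract_start, frag.tract_end))
    designs, design_counts = batch_design(frag_iter, constraints)
    pairs_to_frame(designs).to_csv(out / "primers.tsv", sep="\t", index=False)
    n_designed = sum(1 for r in designs.values() if r.pair is not None)
    reports.append(
        StageReport("design", len(selected), n_designed, {"no-pair": len(selected) - n_designed})
    )

    # stage 5: physical map of designed markers
    markers = [
        (lid, by_id[lid].seq_id, by_id[lid].start)
        for lid, res in designs.items()
        if res.pair is not None
    ]
    entries, map_counts, mean_gap, warnings = build_map(markers)
    map_to_frame(entries).to_csv(out / "physical_map.tsv", sep="\t", index=False)

    # consolidated Table-1-shaped summary
    seq_ids = sorted(reference)
    rows = {}
    for sid in seq_ids:
        row = {"n_ssr": sum(1 for l in loci if l.seq_id == sid)}
        for name in alternates:
            row[f"{name}_poly"] = sum(
                1
                for c in comparisons
                if c.seq_id == sid
                and c.deltas.get(name) is not None
                and abs(c.deltas[name]) >= config.min_diff
            )
        row["designed"] = sum(
            1 for lid, r in designs.items() if r.pair is not None and by_id[lid].seq_id == sid
        )
        rows[sid] = row
    summary_counts = pd.DataFrame.from_dict(rows, orient="index")
    pct_pairs = [(f"{name}_poly", "n_ssr", f"{name}_pct") for name in alternates]
    summary = report_table(summary_counts, pct_pairs)
    summary.to_csv(out / "summary.tsv", sep="\t")

    stage_frame = pd.DataFrame(
        [(r.stage, r.n_in, r.n_out, ";".join(f"{k}={v}" for k, v in r.dropped.items()))
         for r in reports],
        columns=["stage", "n_in", "n_out", "dropped"],
    )
    stage_frame.to_csv(out / "stage_reports.tsv", sep="\t", index=False)

    return {
        "loci": loci,
        "retained": retained,
        "comparisons": comparisons,
        "selected": selected,
        "designs": designs,
        "map_entries": entries,
        "mean_gap_kb": mean_gap,
        "map_warnings": warnings,
        "reports": reports,
        "summary": summary,
    }
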