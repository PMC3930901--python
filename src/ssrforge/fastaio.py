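"""FASTA and tabular I/O shared across pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ssr_scan import SSRLocus

LOCI_COLUMNS = [
    "locus_id",
    "seq_id",
    "start",
    "end",
    "motif",
    "family",
    "class",
    "repeat_count",
    "tract_length",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, genome: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def loci_to_frame(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    rows = [
        (l.locus_id, l.seq_id, l.start, l.end, l.motif, l.family, l.motif_class,
         l.repeat_count, l.tract_length)
        for l in loci
    ]
    return pd.DataFrame(rows, columns=LOCI_COLUMNS)


def write_loci(path: str | Path, loci: Sequence[SSRLocus]) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_loci(path: str | Path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "seq_id": str})
    return [
        SSRLocus(
            locus_id=row.locus_id,
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            motif=row.motif,
            family=row.family,
            motif_class=row[6],
            repeat_count=int(row.repeat_count),
            tract_length=int(row.tract_length),
        )
        for row in df.itertuples(index=False)
    ]


def write_gff3(path: str | Path, loci: Sequence[SSRLocus]) -> None:
    """Write loci as GFF3 ``microsatellite`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            attrs = f"ID={l.locus_id};motif={l.motif};family={l.family};repeat_count={l.repeat_count}"
            fh.write(
                f"{l.seq_id}\tssrforge\tmicrosatellite\t{l.start}\t{l.end}\t.\t+\t.\t{attrs}\n"
            )
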