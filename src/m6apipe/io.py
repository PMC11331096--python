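"""Readers and writers for the package's on-disk formats.

Window tables, truth tables and all reports are plain TSV; transcript
models are written as single-exon GFF3 (1-based inclusive, per the GFF3
convention — internal coordinates are 0-based half-open); sequences go
through FASTA (Biopython); peak calls are additionally emitted as BED6
with the transcript id in the chrom column and 0-based half-open
coordinates.
"""
from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import TranscriptModel

__all__ = [
    "write_gff3",
    "write_fasta",
    "read_fasta",
    "write_tsv",
    "read_window_table",
    "write_bed6",
]


def write_gff3(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as a minimal gene/mRNA/exon/CDS GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene = m.gene_id or m.transcript_id.rsplit(".", 1)[0]

            def line(ftype, start0, end0, attrs):
                # convert 0-based half-open to 1-based inclusive
                return "\t".join(
                    [
                        m.transcript_id,
                        "m6apipe",
                        ftype,
                        str(start0 + 1),
                        str(end0),
                        ".",
                        "+",
                        "0" if ftype == "CDS" else ".",
                        attrs,
                    ]
                )

            fh.write(line("gene", 0, m.spliced_length, f"ID={gene}") + "\n")
            fh.write(
                line("mRNA", 0, m.spliced_length, f"ID={m.transcript_id};Parent={gene}")
                + "\n"
            )
            fh.write(
                line(
                    "exon",
                    0,
                    m.spliced_length,
                    f"ID={m.transcript_id}.exon1;Parent={m.transcript_id}",
                )
                + "\n"
            )
            fh.write(
                line(
                    "CDS",
                    m.cds_start,
                    m.cds_end,
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}",
                )
                + "\n"
            )


def write_fasta(sequences: dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_tsv(frame: pd.DataFrame, path: str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_window_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "window_start", "window_end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return table.sort_values(["transcript_id", "window_start"], kind="stable").reset_index(
        drop=True
    )


def write_bed6(peaks: pd.DataFrame, path: str, score_cols: Iterable[str] = ()) -> None:
    """BED6: chrom = transcript id, score = min supporting POI x 100.

    For m6A peak tables the score is the minimum per-replicate POI
    among supporting replicates, x100 and rounded (capped at 1000);
    tables without POI columns get score 0.
    """
    score_cols = [c for c in (score_cols or peaks.columns) if str(c).startswith("poi_rep")]
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            if score_cols:
                pois = [getattr(row, c) for c in score_cols]
                supporting = [p for p in pois if p > 3.0] or pois
                score = int(min(round(min(supporting) * 100), 1000))
            else:
                score = 0
            name = f"peak_{i + 1}"
            fh.write(
                "\t".join(
                    [
                        str(row.transcript_id),
                        str(int(row.start)),
                        str(int(row.end)),
                        name,
                        str(score),
                        "+",
                    ]
                )
                + "\n"
            )
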