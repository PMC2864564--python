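"""GFF3 reading/writing and FASTA helpers.

Annotations are held as a plain DataFrame with columns
(id, chrom, type, start, end, strand); coordinates are GFF3-style 1-based
inclusive throughout the package except where a BED/bedGraph export states
otherwise.
"""

from __future__ import annotations

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_COLUMNS = ["id", "chrom", "type", "start", "end", "strand"]

# record types that describe sequence extent, not transcription
NON_TRANSCRIBED_TYPES = {"chromosome", "region", "contig", "telomere"}


def read_gff3(path) -> pd.DataFrame:
    """Parse a GFF3 file into a feature DataFrame (in-memory gffutils db)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        rows.append(
            {
                "id": feat.id,
                "chrom": feat.seqid,
                "type": feat.featuretype,
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand,
            }
        )
    frame = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return frame.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def require_strands(features: pd.DataFrame) -> None:
    if not features["strand"].isin(["+", "-"]).all():
        bad = features.loc[~features["strand"].isin(["+", "-"]), "id"].iloc[0]
        raise ValueError(f"annotation feature {bad!r} lacks a strand")


def write_gff3(features: pd.DataFrame, path, chrom_sizes: dict | None = None,
               source: str = "tilecycle") -> str:
    lines = ["##gff-version 3"]
    for chrom, size in sorted((chrom_sizes or {}).items()):
        lines.append(f"##sequence-region {chrom} 1 {size}")
    for row in features.itertuples(index=False):
        attrs = f"ID={row.id}"
        if hasattr(row, "category"):
            attrs += f";category={row.category}"
        lines.append(
            "\t".join(
                [row.chrom, source, row.type, str(int(row.start)), str(int(row.end)),
                 ".", row.strand, ".", attrs]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_fasta(genome: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
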