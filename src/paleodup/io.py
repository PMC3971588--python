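"""Readers and writers for the pipeline's plain-text interchange formats.

Counts are TSV with a leading ``gene_id`` column and one integer column per
sample; sample sheets, pair lists, anchor tables and truth tables are plain
TSV.  Gene models come from GFF3 (1-based inclusive) or BED (0-based
half-open, converted on read).  Aligned CDS pairs are FASTA with two
records per pair sharing an id prefix (``<pair>_g1`` / ``<pair>_g2``).
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .dnds import CodonAlignment
from .expression import CountsMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "read_annotation",
    "read_alignments",
    "write_alignments",
    "sha256_file",
]


def read_counts(
    path, lengths: pd.Series | None = None, totals: pd.Series | None = None
) -> CountsMatrix | pd.DataFrame:
    """Read a counts TSV; returns a CountsMatrix when lengths are given."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if lengths is None:
        return df
    return CountsMatrix(df, lengths, totals)


def write_counts(counts: CountsMatrix | pd.DataFrame, path) -> None:
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_annotation(path) -> pd.DataFrame:
    """Gene models as a frame with gene_id, chrom, start, end, length_bp.

    GFF3 coordinates are kept 1-based inclusive; BED intervals are
    converted from 0-based half-open.  A TSV with those columns is passed
    through.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                m = _GFF_ATTR_ID.search(fields[8])
                if not m:
                    raise ValueError(f"gene feature without ID attribute: {line!r}")
                rows.append(
                    {
                        "gene_id": m.group(1),
                        "chrom": fields[0],
                        "start": int(fields[3]),
                        "end": int(fields[4]),
                    }
                )
        ann = pd.DataFrame(rows)
    elif suffix == ".bed":
        ann = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
        )
        ann["start"] = ann["start"] + 1  # 0-based half-open -> 1-based inclusive
        ann = ann[["gene_id", "chrom", "start", "end"]]
    else:
        ann = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "start", "end"}
        if not required <= set(ann.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
    ann["length_bp"] = ann["end"] - ann["start"] + 1
    return ann.reset_index(drop=True)


_PAIR_SUFFIX = re.compile(r"_g[12]$")


def read_alignments(path) -> list[CodonAlignment]:
    """Read aligned CDS pairs from FASTA (two records per pair)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of records, expected pairs")
    alignments = []
    for r1, r2 in zip(records[::2], records[1::2]):
        p1 = _PAIR_SUFFIX.sub("", r1.id)
        p2 = _PAIR_SUFFIX.sub("", r2.id)
        pair_id = p1 if p1 == p2 else f"{r1.id}|{r2.id}"
        alignments.append(CodonAlignment.from_records(pair_id, r1, r2))
    return alignments


def write_alignments(alignments: list[CodonAlignment], path) -> None:
    records = []
    for aln in alignments:
        records.extend(aln.to_records())
    SeqIO.write(records, str(path), "fasta")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
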