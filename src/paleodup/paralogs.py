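"""Strict-duplicate paralog calling from collinearity anchor tables.

A "strictly duplicated" pair consists of two G. raimondii (Gr) genes that
(i) anchor a Gr–Gr collinear block spanning the two duplicated regions,
(ii) both trace to one and the same syntenic region in T. cacao (Tc), and
(iii) both trace to one and the same syntenic region in V. vinifera (Vv).
Region identity is block-ID equality.  Genes with more than two Gr copies
(anchored to more than one partner), and pairs whose Tc or Vv ortholog
occupies more than one outgroup region, are excluded; tandem anchors within
a single Gr block are not pairs.  Collinear-block detection itself is
upstream tooling: this module consumes precomputed anchor tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ParalogPair",
    "call_strict_duplicates",
    "pairs_to_frame",
    "write_links_file",
    "read_links_file",
]

ANCHOR_COLUMNS = ["geneA", "genomeA", "blockA", "geneB", "genomeB", "blockB"]


@dataclass(frozen=True)
class ParalogPair:
    """A strictly duplicated Gr gene pair with genomic context.

    Coordinates are 1-based inclusive; gene1_id < gene2_id lexicographically.
    """

    pair_id: str
    gene1_id: str
    gene2_id: str
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    tc_region_id: str
    vv_region_id: str

    def __post_init__(self) -> None:
        if self.gene1_id >= self.gene2_id:
            raise ValueError("gene1_id must sort before gene2_id")


def _check_anchor_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(ANCHOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name} anchor table is missing columns {sorted(missing)}")
    return df


def _outgroup_blocks(anchors: pd.DataFrame) -> dict[str, set[str]]:
    """Map each Gr gene to the set of outgroup block IDs it anchors to."""
    blocks: dict[str, set[str]] = defaultdict(set)
    for row in anchors.itertuples():
        if row.genomeA == "Gr":
            blocks[row.geneA].add(row.blockB)
        if row.genomeB == "Gr":
            blocks[row.geneB].add(row.blockA)
    return blocks


def call_strict_duplicates(
    gr_gr: pd.DataFrame,
    gr_tc: pd.DataFrame,
    gr_vv: pd.DataFrame,
    annotation: pd.DataFrame,
) -> list[ParalogPair]:
    """Call strictly duplicated pairs from the three anchor tables.

    ``annotation`` must have columns gene_id, chrom, start, end for the Gr
    genes.  Returns canonically ordered, unique pairs; deterministic (no
    randomness).  Raises if an anchored Gr gene is absent from the
    annotation.
    """
    gr_gr = _check_anchor_table(gr_gr, "Gr-Gr")
    gr_tc = _check_anchor_table(gr_tc, "Gr-Tc")
    gr_vv = _check_anchor_table(gr_vv, "Gr-Vv")

    ann = annotation.set_index("gene_id")
    gr_genes = set()
    for df in (gr_gr, gr_tc, gr_vv):
        gr_genes |= set(df.loc[df["genomeA"] == "Gr", "geneA"])
        gr_genes |= set(df.loc[df["genomeB"] == "Gr", "geneB"])
    absent = sorted(g for g in gr_genes if g not in ann.index)
    if absent:
        raise ValueError(
            f"{len(absent)} gene(s) referenced in anchors are absent from the "
            f"annotation: {absent[:10]}"
        )

    # cross-block candidates only: tandem anchors within one block are not pairs
    cand = gr_gr[gr_gr["blockA"] != gr_gr["blockB"]]

    # one-to-one correspondence: a gene anchored to >1 distinct partner has
    # >2 Gr copies (or is ambiguous) and is dropped together with its pairs
    partners: dict[str, set[str]] = defaultdict(set)
    for row in cand.itertuples():
        partners[row.geneA].add(row.geneB)
        partners[row.geneB].add(row.geneA)
    ambiguous = {g for g, ps in partners.items() if len(ps) > 1}

    tc_blocks = _outgroup_blocks(gr_tc)
    vv_blocks = _outgroup_blocks(gr_vv)

    seen: set[tuple[str, str]] = set()
    accepted: list[tuple[str, str, str, str]] = []
    for row in cand.itertuples():
        g1, g2 = sorted((row.geneA, row.geneB))
        if (g1, g2) in seen:
            continue
        seen.add((g1, g2))
        if g1 in ambiguous or g2 in ambiguous:
            continue
        tc1, tc2 = tc_blocks.get(g1, set()), tc_blocks.get(g2, set())
        if len(tc1) != 1 or tc1 != tc2:
            continue
        vv1, vv2 = vv_blocks.get(g1, set()), vv_blocks.get(g2, set())
        if len(vv1) != 1 or vv1 != vv2:
            continue
        accepted.append((g1, g2, next(iter(tc1)), next(iter(vv1))))

    accepted.sort()
    pairs = []
    for i, (g1, g2, tc_region, vv_region) in enumerate(accepted):
        a1, a2 = ann.loc[g1], ann.loc[g2]
        pairs.append(
            ParalogPair(
                pair_id=f"pair{i:05d}",
                gene1_id=g1,
                gene2_id=g2,
                chrom1=str(a1["chrom"]),
                start1=int(a1["start"]),
                end1=int(a1["end"]),
                chrom2=str(a2["chrom"]),
                start2=int(a2["start"]),
                end2=int(a2["end"]),
                tc_region_id=tc_region,
                vv_region_id=vv_region,
            )
        )
    return pairs


def pairs_to_frame(pairs: list[ParalogPair]) -> pd.DataFrame:
    cols = [
        "pair_id", "gene1_id", "gene2_id", "chrom1", "start1", "end1",
        "chrom2", "start2", "end2", "tc_region_id", "vv_region_id",
    ]
    return pd.DataFrame([vars(p) for p in pairs], columns=cols)


LINKS_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "pair_id"]


def write_links_file(pairs: list[ParalogPair], path) -> None:
    """Write a Circos-style links TSV (1-based inclusive coordinates)."""
    pairs_to_frame(pairs)[LINKS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_links_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LINKS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"links file missing columns {sorted(missing)}")
    return df[LINKS_COLUMNS]
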