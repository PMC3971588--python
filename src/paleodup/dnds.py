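"""Pairwise dN/dS for aligned paralog coding sequences.

Site and difference counting follows the Nei–Gojobori (1986) scheme:
synonymous/nonsynonymous *sites* are fractional counts per codon obtained by
enumerating the three single-nucleotide mutations at each position, and
*differences* between two codons are averaged over all minimal mutational
pathways.  Observed proportions are corrected for multiple hits with the
Jukes–Cantor formula ``d = -(3/4) ln(1 - 4p/3)``.

Mutations to stop codons are excluded from the site denominator (the
remaining mutations at that position are renormalized so every codon still
contributes three sites), and pathways passing through a stop codon are
dropped with renormalization over the surviving pathways.  Codons containing
gaps or ``N`` in either sequence, and stop codons, are excluded pairwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "count_sites",
    "count_diffs",
    "jukes_cantor",
    "dnds",
]

_BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: frozenset[str] = frozenset(CODON_TO_AA)


@dataclass
class CodonAlignment:
    """A pair of aligned coding sequences for one paralog pair.

    Sequences must be equal length, a multiple of 3, over {A,C,G,T,-,N}.
    """

    pair_id: str
    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        self.seq1 = str(self.seq1).upper()
        self.seq2 = str(self.seq2).upper()
        if len(self.seq1) != len(self.seq2):
            raise ValueError(
                f"{self.pair_id}: aligned sequences differ in length "
                f"({len(self.seq1)} vs {len(self.seq2)})"
            )
        if len(self.seq1) % 3 != 0:
            raise ValueError(f"{self.pair_id}: alignment length not a multiple of 3")
        alphabet = set("ACGTN-")
        bad = (set(self.seq1) | set(self.seq2)) - alphabet
        if bad:
            raise ValueError(f"{self.pair_id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq1)

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codons(self):
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i : i + 3], self.seq2[i : i + 3]

    @classmethod
    def from_records(cls, pair_id: str, rec1: SeqRecord, rec2: SeqRecord) -> "CodonAlignment":
        return cls(pair_id, str(rec1.seq), str(rec2.seq))

    def to_records(self) -> tuple[SeqRecord, SeqRecord]:
        return (
            SeqRecord(Seq(self.seq1), id=f"{self.pair_id}_g1", description=""),
            SeqRecord(Seq(self.seq2), id=f"{self.pair_id}_g2", description=""),
        )


@dataclass
class DnDsResult:
    pair_id: str
    n_codons_compared: int
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    pn: float
    ps: float
    dn: float  # nan when saturated
    ds: float  # nan when saturated
    omega: float  # nan when undefined (ds == 0 or saturated)
    identical: bool = False
    saturated_dn: bool = False
    saturated_ds: bool = False
    undefined_omega: bool = False
    n_codons_skipped: int = 0
    flags: list[str] = field(default_factory=list)


def _is_comparable(c1: str, c2: str) -> bool:
    return c1 in SENSE_CODONS and c2 in SENSE_CODONS


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one sense codon.

    At each of the three positions the fraction of synonymous sites is the
    number of single-nucleotide mutations that preserve the amino acid,
    divided by the number of mutations that do not create a stop codon.
    The two fractions at every position sum to 1, so S + N = 3.
    """
    codon = codon.upper()
    if codon not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if CODON_TO_AA[mut] == aa:
                n_syn += 1
        if n_valid:
            s += n_syn / n_valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are enumerated (1, 2, or 6
    pathways); each single-nucleotide step is classified by whether it
    preserves the amino acid.  Pathways whose intermediate codons are stops
    are excluded and the average renormalized over the rest.  Returns (0, 0)
    for identical codons; raises if every pathway is blocked (callers should
    skip such codon pairs).
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    for c in (codon1, codon2):
        if c not in SENSE_CODONS:
            raise ValueError(f"{c!r} is not a sense codon")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon1
        path_syn = 0
        path_nonsyn = 0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
                break
            if nxt in STOP_CODONS:  # endpoint is codon2, already checked sense
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if not blocked:
            syn_total += path_syn
            nonsyn_total += path_nonsyn
            n_paths += 1
    if n_paths == 0:
        raise ValueError(
            f"all mutational pathways between {codon1} and {codon2} pass through stop codons"
        )
    return syn_total / n_paths, nonsyn_total / n_paths


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance ``d = -(3/4) ln(1 - 4p/3)``.

    Returns ``nan`` for p >= 0.75 (saturation: the formula's domain
    boundary); raises for p outside [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds(alignment: CodonAlignment) -> DnDsResult:
    """NG86 dN/dS with Jukes–Cantor correction for one aligned pair.

    Site counts are averaged over the two sequences; omega is dN/dS when
    dS > 0 and both distances are defined, otherwise flagged undefined.
    """
    s_sites1 = s_sites2 = 0.0
    s_diffs = n_diffs = 0.0
    n_compared = 0
    n_skipped = 0
    flags: list[str] = []
    for c1, c2 in alignment.codons():
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            n_skipped += 1
            continue
        if not _is_comparable(c1, c2):
            n_skipped += 1
            flags.append(f"stop_codon_skipped:{c1}/{c2}")
            continue
        try:
            sd, nd = count_diffs(c1, c2)
        except ValueError:
            n_skipped += 1
            flags.append(f"blocked_pathways_skipped:{c1}/{c2}")
            continue
        s1, _ = count_sites(c1)
        s2, _ = count_sites(c2)
        s_sites1 += s1
        s_sites2 += s2
        s_diffs += sd
        n_diffs += nd
        n_compared += 1
    if n_compared == 0:
        raise ValueError(f"{alignment.pair_id}: no comparable codons after filtering")
    if n_skipped:
        warnings.warn(
            f"{alignment.pair_id}: skipped {n_skipped} codon(s) with gaps/N/stops",
            stacklevel=2,
        )
    s_sites = (s_sites1 + s_sites2) / 2.0
    n_sites = 3.0 * n_compared - s_sites
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    saturated_ds = math.isnan(ds)
    saturated_dn = math.isnan(dn)
    identical = s_diffs == 0 and n_diffs == 0
    if saturated_ds or saturated_dn or not ds or math.isnan(ds):
        omega = math.nan
        undefined = True
    else:
        omega = dn / ds
        undefined = False
    return DnDsResult(
        pair_id=alignment.pair_id,
        n_codons_compared=n_compared,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=n_diffs,
        s_diffs=s_diffs,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        omega=omega,
        identical=identical,
        saturated_dn=saturated_dn,
        saturated_ds=saturated_ds,
        undefined_omega=undefined,
        n_codons_skipped=n_skipped,
        flags=flags,
    )
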