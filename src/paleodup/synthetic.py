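"""Synthetic data with planted truth for every pipeline stage.

Three generators:

* :func:`simulate_counts` — negative-binomial RNA-seq counts for paralog
  pairs across tissues with replicates, with planted gene (G), tissue (T)
  and gene-by-tissue (G×T) effects, reciprocal-silencing and complementary
  expression scenarios, and a truth table recording the planted category.
* :func:`simulate_codon_pair` — an aligned CDS pair carrying an exact,
  known number of synonymous and nonsynonymous single-nucleotide codon
  changes (built from fourfold-degenerate-rich codons so the planted
  classes are achievable exactly).
* :func:`simulate_synteny_fixture` — toy three-genome (Gr/Tc/Vv) gene-order
  and collinearity anchor tables in which a known fraction of Gr genes are
  strictly duplicated (two Gr copies tracing to a single Tc and a single Vv
  region), plus triplicate / outgroup-duplicated / tandem decoys.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnds import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from .expression import CountsMatrix

__all__ = [
    "SCENARIOS",
    "SimulationDesign",
    "SyntenyFixture",
    "simulate_counts",
    "simulate_codon_pair",
    "simulate_synteny_fixture",
]

SCENARIOS = (
    "null",
    "G_only",
    "GxT",
    "G_T_GxT",
    "reciprocal_silencing",
    "complementary",
)

# proportions used by the special scenarios: silencing plants a 99%/1%
# paralog split (safely beyond the 95% rule), complementary a 65%/35%
# dominance reversal without silencing
_SILENCING_PROP = 0.99
_COMPLEMENTARY_PROP = 0.65


@dataclass
class SimulationDesign:
    """Parameters of a simulated paralog-pair expression experiment.

    The negative binomial is parameterized by mean and dispersion phi with
    variance = mu + phi * mu**2.  Library size acts multiplicatively on the
    NB mean (the simulation analogue of a model offset); gene length is
    shared by both paralogs of a pair so expression effects are not
    confounded with length effects.  Default library sizes emulate
    20–40 M-read libraries scaled down 100x for desk-scale runs.
    """

    n_pairs: int = 500
    tissues: tuple[str, ...] = ("petal", "leaf", "seed")
    n_reps: int = 3
    scenario_mix: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.08,
            "G_only": 0.22,
            "GxT": 0.25,
            "G_T_GxT": 0.25,
            "reciprocal_silencing": 0.05,
            "complementary": 0.15,
        }
    )
    effect_log2fc: float = 2.0
    interaction_log2fc: float = 2.0
    tissue_log2fc: float = 1.0
    dispersion: float = 0.05
    lib_size_range: tuple[int, int] = (200_000, 400_000)
    length_range: tuple[int, int] = (500, 3000)
    expr_log10_range: tuple[float, float] = (1.7, 3.0)
    species: str = "Gr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, rng in (("lib_size_range", self.lib_size_range),
                          ("length_range", self.length_range)):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"{name} must be positive and ordered")
        bad = set(self.scenario_mix) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}; valid: {SCENARIOS}")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario_mix must sum to 1, got {total}")


def _planted_effects(
    scenario: str, design: SimulationDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, str, tuple[str, str] | None, tuple[str, str] | None]:
    """Per-tissue gene log2 fold change, tissue effects, and truth labels.

    Returns (gene_lfc_per_tissue, tissue_effect, category, silenced, complementary).
    The gene lfc is log2(mean_gene1 / mean_gene2) in each tissue.  The
    tissue ramp is shuffled per pair and the interaction sign randomized so
    planted effects are gene-specific and cannot be absorbed by the global
    per-sample normalization (a tissue shift shared by every gene is
    indistinguishable from sequencing depth); the gene main effect keeps a
    fixed positive sign so planted log2 ratios average to the design value.
    """
    T = len(design.tissues)
    lfc = np.zeros(T)
    teff = np.zeros(T)
    silenced = complementary = None
    e, i, tl = design.effect_log2fc, design.interaction_log2fc, design.tissue_log2fc
    # zero-sum interaction pattern over the first two tissues, random sign
    pattern = np.zeros(T)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    pattern[0], pattern[1] = sign, -sign
    if scenario == "null":
        category = "none"
    elif scenario == "G_only":
        lfc += e
        category = "G"
    elif scenario == "GxT":
        lfc = i * pattern
        category = "GxT"
    elif scenario == "G_T_GxT":
        lfc = e + i * pattern
        ramp = np.arange(T) - (T - 1) / 2.0
        teff = tl * rng.permutation(ramp)
        category = "G+T+GxT"
    elif scenario == "reciprocal_silencing":
        L = np.log2(_SILENCING_PROP / (1 - _SILENCING_PROP))
        lfc = L * pattern
        category = "GxT"
        silenced = (design.tissues[0], design.tissues[1])
    elif scenario == "complementary":
        C = np.log2(_COMPLEMENTARY_PROP / (1 - _COMPLEMENTARY_PROP))
        lfc = C * pattern
        category = "GxT"
        complementary = (design.tissues[0], design.tissues[1])
    else:  # pragma: no cover - guarded by SimulationDesign validation
        raise ValueError(scenario)
    return lfc, teff, category, silenced, complementary


def simulate_counts(
    design: SimulationDesign,
) -> tuple[CountsMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate NB counts for paralog pairs under the planted design.

    Returns ``(counts, samples, truth)``.  ``samples`` has columns
    sample_id, species, tissue, timepoint, replicate.  ``truth`` has one
    row per pair: gene ids, scenario, true_category (one of the eight
    G/T/G×T combinations), silenced/complementary tissue pairs, and the
    planted per-tissue log2 fold change (gene1 over gene2).
    """
    rng = np.random.default_rng(design.seed)
    T = len(design.tissues)
    n = design.n_pairs

    scen_names = [s for s in SCENARIOS if design.scenario_mix.get(s, 0) > 0]
    probs = np.array([design.scenario_mix[s] for s in scen_names], dtype=float)
    scenarios = rng.choice(scen_names, size=n, p=probs / probs.sum())

    samples = pd.DataFrame(
        [
            {
                "sample_id": f"{design.species}_{tissue}_r{r + 1}",
                "species": design.species,
                "tissue": tissue,
                "timepoint": 0,
                "replicate": r + 1,
            }
            for tissue in design.tissues
            for r in range(design.n_reps)
        ]
    )
    lib_sizes = rng.integers(
        design.lib_size_range[0], design.lib_size_range[1] + 1, size=len(samples)
    ).astype(float)

    lengths_arr = rng.integers(
        design.length_range[0], design.length_range[1] + 1, size=n
    ).astype(float)
    base_expr = 10.0 ** rng.uniform(*design.expr_log10_range, size=n)

    width = max(4, len(str(n)))
    pair_ids = [f"P{k:0{width}d}" for k in range(n)]
    gene_ids: list[str] = []
    truth_rows = []
    mu = np.empty((2 * n, len(samples)))
    tissue_of_sample = samples["tissue"].to_numpy()
    for k in range(n):
        lfc, teff, category, silenced, compl = _planted_effects(
            scenarios[k], design, rng
        )
        t_idx = np.array([design.tissues.index(t) for t in tissue_of_sample])
        base = (
            base_expr[k]
            * (lengths_arr[k] / 1e3)
            * (lib_sizes / 1e6)
            * 2.0 ** teff[t_idx]
        )
        mu[2 * k] = base * 2.0 ** (lfc[t_idx] / 2.0)
        mu[2 * k + 1] = base * 2.0 ** (-lfc[t_idx] / 2.0)
        g1, g2 = f"{pair_ids[k]}a", f"{pair_ids[k]}b"
        gene_ids.extend([g1, g2])
        truth_rows.append(
            {
                "pair_id": pair_ids[k],
                "gene1_id": g1,
                "gene2_id": g2,
                "scenario": scenarios[k],
                "true_category": category,
                "true_silenced_tissues": "|".join(silenced) if silenced else "",
                "true_complementary_tissues": "|".join(compl) if compl else "",
                "planted_log2fc_per_tissue": ";".join(
                    f"{t}:{v:.4f}" for t, v in zip(design.tissues, lfc)
                ),
                "length_bp": int(lengths_arr[k]),
            }
        )

    if design.dispersion > 0:
        r_shape = 1.0 / design.dispersion
        p = r_shape / (r_shape + mu)
        counts = rng.negative_binomial(r_shape, p)
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples["sample_id"]
    )
    lengths = pd.Series(
        np.repeat(lengths_arr, 2), index=counts_df.index, name="length_bp"
    )
    totals = pd.Series(lib_sizes, index=samples["sample_id"], name="total_mapped")
    cm = CountsMatrix(counts_df, lengths, totals)
    truth = pd.DataFrame(truth_rows)
    return cm, samples, truth


# --- codon-pair fixture --------------------------------------------------

# first two bases of the eight fourfold-degenerate codon families of the
# standard code; any third base keeps the amino acid
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "CG", "CT", "GT", "TC", "AC")
_BASES = "ACGT"


def simulate_codon_pair(
    n_codons: int, syn_subs: int, nonsyn_subs: int, seed: int = 0,
    pair_id: str = "pair0",
) -> tuple[SeqRecord, SeqRecord]:
    """Aligned CDS pair differing by exact planted substitution counts.

    Each substitution is a single-nucleotide change in its own codon:
    synonymous changes use the third position of a fourfold-degenerate
    codon, nonsynonymous changes a first/second-position mutation to a
    sense codon with a different amino acid.  No codon carries more than
    one substitution, so NG86 counting recovers the planted (Sd, Nd)
    exactly.
    """
    if syn_subs < 0 or nonsyn_subs < 0:
        raise ValueError("substitution counts must be non-negative")
    if syn_subs + nonsyn_subs > n_codons:
        raise ValueError(
            f"requested {syn_subs}+{nonsyn_subs} substitutions but only "
            f"{n_codons} codons are available (one substitution per codon)"
        )
    rng = np.random.default_rng(seed)
    codons = [
        _FOURFOLD_PREFIXES[rng.integers(len(_FOURFOLD_PREFIXES))]
        + _BASES[rng.integers(4)]
        for _ in range(n_codons)
    ]
    seq1 = list(codons)
    seq2 = list(codons)
    targets = rng.permutation(n_codons)[: syn_subs + nonsyn_subs]
    for j, idx in enumerate(targets):
        codon = seq2[idx]
        if j < syn_subs:
            # third-position change inside a fourfold family: synonymous
            choices = [b for b in _BASES if b != codon[2]]
            seq2[idx] = codon[:2] + choices[rng.integers(3)]
        else:
            cands = []
            for pos in range(2):
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    if mut in SENSE_CODONS and CODON_TO_AA[mut] != CODON_TO_AA[codon]:
                        cands.append(mut)
            if not cands:  # pragma: no cover - fourfold pool always has candidates
                raise ValueError(f"no nonsynonymous sense mutation for {codon}")
            seq2[idx] = cands[rng.integers(len(cands))]
    rec1 = SeqRecord(Seq("".join(seq1)), id=f"{pair_id}_g1", description="")
    rec2 = SeqRecord(Seq("".join(seq2)), id=f"{pair_id}_g2", description="")
    assert not any(c in STOP_CODONS for c in seq2)
    return rec1, rec2


# --- synteny fixture -----------------------------------------------------


@dataclass
class SyntenyFixture:
    """Toy Gr/Tc/Vv gene orders and anchor tables with planted strict pairs."""

    gene_orders: dict[str, pd.DataFrame]  # genome -> gene_id, chrom, start, end, block
    anchors: dict[str, pd.DataFrame]  # "gr_gr", "gr_tc", "gr_vv"
    planted_pairs: pd.DataFrame  # pair_id, gene1_id, gene2_id
    gr_annotation: pd.DataFrame  # gene_id, chrom, start, end


def _anchor_row(gene_a, genome_a, block_a, gene_b, genome_b, block_b):
    return {
        "geneA": gene_a, "genomeA": genome_a, "blockA": block_a,
        "geneB": gene_b, "genomeB": genome_b, "blockB": block_b,
    }


def simulate_synteny_fixture(
    n_blocks: int = 5,
    genes_per_block: int = 10,
    fraction_strict: float = 0.6,
    seed: int = 0,
    n_triplicate_decoys: int = 2,
    n_tc_dup_decoys: int = 2,
    n_vv_dup_decoys: int = 2,
    n_tandem_decoys: int = 2,
) -> SyntenyFixture:
    """Construct a three-genome synteny fixture with a known answer.

    Each ancestral region k yields two Gr blocks, one Tc block and one Vv
    block.  The first ``round(fraction_strict * genes_per_block)`` genes of
    each region are retained in both Gr blocks (planted strict pairs); the
    rest are single-copy.  Decoys are appended: Gr triplicates (three Gr
    copies), pairs whose Tc or Vv ortholog occupies two outgroup regions,
    and tandem duplicates inside one Gr block.  A correct strict-duplicate
    caller must return exactly the planted pairs.
    """
    if not 0.0 <= fraction_strict <= 1.0:
        raise ValueError("fraction_strict must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_strict = round(fraction_strict * genes_per_block)
    gene_rows: dict[str, list[dict]] = {"Gr": [], "Tc": [], "Vv": []}
    gr_gr, gr_tc, gr_vv = [], [], []
    planted = []

    def add_gene(genome: str, gene_id: str, block: str) -> None:
        gene_rows[genome].append({"gene_id": gene_id, "block": block})

    for k in range(n_blocks):
        gr_a, gr_b = f"GrB{2 * k}", f"GrB{2 * k + 1}"
        tc_b, vv_b = f"TcB{k}", f"VvB{k}"
        for j in range(genes_per_block):
            g1 = f"Gr{k:02d}_{j:02d}a"
            tc_gene, vv_gene = f"Tc{k:02d}_{j:02d}", f"Vv{k:02d}_{j:02d}"
            add_gene("Gr", g1, gr_a)
            add_gene("Tc", tc_gene, tc_b)
            add_gene("Vv", vv_gene, vv_b)
            gr_tc.append(_anchor_row(g1, "Gr", gr_a, tc_gene, "Tc", tc_b))
            gr_vv.append(_anchor_row(g1, "Gr", gr_a, vv_gene, "Vv", vv_b))
            if j < n_strict:
                g2 = f"Gr{k:02d}_{j:02d}b"
                add_gene("Gr", g2, gr_b)
                gr_gr.append(_anchor_row(g1, "Gr", gr_a, g2, "Gr", gr_b))
                gr_tc.append(_anchor_row(g2, "Gr", gr_b, tc_gene, "Tc", tc_b))
                gr_vv.append(_anchor_row(g2, "Gr", gr_b, vv_gene, "Vv", vv_b))
                a, b = sorted((g1, g2))
                planted.append(
                    {"pair_id": f"SP{len(planted):04d}", "gene1_id": a, "gene2_id": b}
                )

    # --- decoys ---------------------------------------------------------
    extra_gr_block = f"GrB{2 * n_blocks}"  # a third duplicated Gr region
    extra_tc_block = f"TcB{n_blocks}"
    extra_vv_block = f"VvB{n_blocks}"
    for d in range(n_triplicate_decoys):
        # three Gr copies in three blocks: excluded (not *strictly* duplicated)
        c1, c2, c3 = (f"GrTRI{d}_{i}" for i in range(3))
        blocks = ("GrB0", "GrB1", extra_gr_block)
        for c, b in zip((c1, c2, c3), blocks):
            add_gene("Gr", c, b)
        gr_gr.append(_anchor_row(c1, "Gr", blocks[0], c2, "Gr", blocks[1]))
        gr_gr.append(_anchor_row(c1, "Gr", blocks[0], c3, "Gr", blocks[2]))
        gr_gr.append(_anchor_row(c2, "Gr", blocks[1], c3, "Gr", blocks[2]))
        tc_gene = f"TcTRI{d}"
        add_gene("Tc", tc_gene, "TcB0")
        for c, b in zip((c1, c2, c3), blocks):
            gr_tc.append(_anchor_row(c, "Gr", b, tc_gene, "Tc", "TcB0"))
        vv_gene = f"VvTRI{d}"
        add_gene("Vv", vv_gene, "VvB0")
        for c, b in zip((c1, c2, c3), blocks):
            gr_vv.append(_anchor_row(c, "Gr", b, vv_gene, "Vv", "VvB0"))
    for d in range(n_tc_dup_decoys):
        # proper Gr pair, but the Tc ortholog is itself duplicated -> excluded
        g1, g2 = f"GrTCD{d}a", f"GrTCD{d}b"
        add_gene("Gr", g1, "GrB0")
        add_gene("Gr", g2, "GrB1")
        gr_gr.append(_anchor_row(g1, "Gr", "GrB0", g2, "Gr", "GrB1"))
        tc1, tc2 = f"TcDUP{d}_1", f"TcDUP{d}_2"
        add_gene("Tc", tc1, "TcB0")
        add_gene("Tc", tc2, extra_tc_block)
        for g, b in ((g1, "GrB0"), (g2, "GrB1")):
            gr_tc.append(_anchor_row(g, "Gr", b, tc1, "Tc", "TcB0"))
            gr_tc.append(_anchor_row(g, "Gr", b, tc2, "Tc", extra_tc_block))
        vv_gene = f"VvTCD{d}"
        add_gene("Vv", vv_gene, "VvB0")
        for g, b in ((g1, "GrB0"), (g2, "GrB1")):
            gr_vv.append(_anchor_row(g, "Gr", b, vv_gene, "Vv", "VvB0"))
    for d in range(n_vv_dup_decoys):
        g1, g2 = f"GrVVD{d}a", f"GrVVD{d}b"
        add_gene("Gr", g1, "GrB0")
        add_gene("Gr", g2, "GrB1")
        gr_gr.append(_anchor_row(g1, "Gr", "GrB0", g2, "Gr", "GrB1"))
        tc_gene = f"TcVVD{d}"
        add_gene("Tc", tc_gene, "TcB0")
        for g, b in ((g1, "GrB0"), (g2, "GrB1")):
            gr_tc.append(_anchor_row(g, "Gr", b, tc_gene, "Tc", "TcB0"))
        vv1, vv2 = f"VvDUP{d}_1", f"VvDUP{d}_2"
        add_gene("Vv", vv1, "VvB0")
        add_gene("Vv", vv2, extra_vv_block)
        for g, b in ((g1, "GrB0"), (g2, "GrB1")):
            gr_vv.append(_anchor_row(g, "Gr", b, vv1, "Vv", "VvB0"))
            gr_vv.append(_anchor_row(g, "Gr", b, vv2, "Vv", extra_vv_block))
    for d in range(n_tandem_decoys):
        # tandem duplicates inside a single Gr block: not a WGD pair
        g1, g2 = f"GrTAN{d}a", f"GrTAN{d}b"
        add_gene("Gr", g1, "GrB0")
        add_gene("Gr", g2, "GrB0")
        gr_gr.append(_anchor_row(g1, "Gr", "GrB0", g2, "Gr", "GrB0"))

    gene_orders = {}
    for genome, rows in gene_rows.items():
        df = pd.DataFrame(rows)
        blocks = sorted(df["block"].unique())
        out = []
        for bi, block in enumerate(blocks):
            sub = df[df["block"] == block].reset_index(drop=True)
            chrom = f"{genome}_chr{bi % 13 + 1}"
            for gi, rec in enumerate(sub.itertuples()):
                length = int(rng.integers(1000, 3001))
                start = 1 + (bi // 13) * 10_000_000 + gi * 5000
                out.append(
                    {
                        "genome": genome,
                        "gene_id": rec.gene_id,
                        "chrom": chrom,
                        "start": start,
                        "end": start + length - 1,
                        "block": block,
                    }
                )
        gene_orders[genome] = pd.DataFrame(out)

    planted_df = pd.DataFrame(planted, columns=["pair_id", "gene1_id", "gene2_id"])
    gr_ann = gene_orders["Gr"][["gene_id", "chrom", "start", "end"]].copy()
    anchors = {
        "gr_gr": pd.DataFrame(gr_gr),
        "gr_tc": pd.DataFrame(gr_tc),
        "gr_vv": pd.DataFrame(gr_vv),
    }
    for key, df in anchors.items():
        if df.empty:
            anchors[key] = pd.DataFrame(
                columns=["geneA", "genomeA", "blockA", "geneB", "genomeB", "blockB"]
            )
    return SyntenyFixture(gene_orders, anchors, planted_df, gr_ann)
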