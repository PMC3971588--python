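"""Full-pipeline orchestration from a single configuration.

Stages run in order: paralog calling (when anchor tables are given),
normalization, per-pair log-ratio DE, reciprocal-silencing detection,
fold-change and overlap summaries, the per-pair NB GLM with categories and
complementary calls, pooled ANOVA, dN/dS (when alignments are given), and
downstream group statistics.  All outputs are TSV; a JSON run manifest
records the config, input/output checksums and per-stage row counts.
Identical inputs and seed reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .dnds import dnds
from .expression import (
    de_pairwise,
    detect_reciprocal_silencing,
    fold_change_table,
    overlap_summary,
    rpkm,
    upper_quartile,
)
from .glm import detect_complementary, glm_pairwise, pooled_anova
from .paralogs import call_strict_duplicates, pairs_to_frame, write_links_file
from .stats import category_wilcoxon, positional_bias_test

__all__ = ["PipelineConfig", "run_pipeline", "render_summary"]

logger = logging.getLogger("paleodup")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Provide either ``pairs`` or the three anchor tables (plus annotation)
    from which pairs are called.  ``alignments`` is optional; without it
    the dN/dS and omega-group stages are skipped with a logged notice.
    """

    counts: str
    samples: str
    outdir: str
    pairs: str | None = None
    anchors_gr_gr: str | None = None
    anchors_gr_tc: str | None = None
    anchors_gr_vv: str | None = None
    annotation: str | None = None
    lengths: str | None = None
    alignments: str | None = None
    normalization: str = "rpkm"
    fdr: float = 0.05
    pseudocount: float = 0.5
    min_expr: float = 1.0
    silencing_threshold: float = 0.95
    fold_thresholds: tuple[float, ...] = (1.5, 2.0, 5.0)
    window_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0.5 < self.silencing_threshold <= 1.0:
            raise ValueError("silencing threshold must lie in (0.5, 1]")
        if any(t <= 1.0 for t in self.fold_thresholds):
            raise ValueError("fold thresholds must exceed 1")
        if self.normalization not in {"rpkm", "uq"}:
            raise ValueError("normalization must be 'rpkm' or 'uq'")
        if self.pairs is None and self.anchors_gr_gr is None:
            raise ValueError("provide a pair list or anchor tables")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fold_thresholds" in raw:
            raw["fold_thresholds"] = tuple(raw["fold_thresholds"])
        return cls(**raw)


def _load_lengths(config: PipelineConfig) -> pd.Series | None:
    if config.lengths:
        df = pio.read_table(config.lengths)
        return df.set_index("gene_id")["length_bp"]
    if config.annotation:
        ann = pio.read_annotation(config.annotation)
        return ann.set_index("gene_id")["length_bp"]
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "paleodup",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
        "outputs": {},
        "warnings": 0,
        "notices": [],
    }
    input_paths = {
        k: getattr(config, k)
        for k in ("counts", "samples", "pairs", "anchors_gr_gr", "anchors_gr_tc",
                  "anchors_gr_vv", "annotation", "lengths", "alignments")
        if getattr(config, k)
    }
    for name, path in input_paths.items():
        manifest["inputs"][name] = {"path": str(path), "sha256": pio.sha256_file(path)}

    caught: list = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        pio.write_table(df, path)
        manifest["outputs"][name] = {"sha256": pio.sha256_file(path), "rows": len(df)}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- pairs -------------------------------------------------------
        if config.pairs:
            pairs = pio.read_table(config.pairs)
        else:
            annotation = pio.read_annotation(config.annotation)
            called = call_strict_duplicates(
                pio.read_table(config.anchors_gr_gr),
                pio.read_table(config.anchors_gr_tc),
                pio.read_table(config.anchors_gr_vv),
                annotation,
            )
            pairs = pairs_to_frame(called)
            emit("pairs.tsv", pairs)
            write_links_file(called, outdir / "links.tsv")
            manifest["outputs"]["links.tsv"] = {
                "sha256": pio.sha256_file(outdir / "links.tsv"), "rows": len(called),
            }
        manifest["stages"]["pairs"] = {"n_pairs": len(pairs)}

        # --- counts & normalization ---------------------------------------
        samples = pio.read_table(config.samples)
        lengths = _load_lengths(config)
        cm = pio.read_counts(config.counts, lengths=lengths) if lengths is not None \
            else pio.read_counts(config.counts)
        if not hasattr(cm, "counts"):
            from .expression import CountsMatrix

            cm = CountsMatrix(cm)
        norm = rpkm(cm) if config.normalization == "rpkm" else upper_quartile(cm)
        manifest["stages"]["normalization"] = {
            "method": norm.method, "n_genes": norm.values.shape[0],
            "n_samples": norm.values.shape[1],
        }

        # --- differential expression --------------------------------------
        de = de_pairwise(
            norm, pairs, samples,
            pseudocount=config.pseudocount, min_expr=config.min_expr, fdr=config.fdr,
        )
        emit("pair_de.tsv", de)

        sil = detect_reciprocal_silencing(
            norm, pairs, samples, de, threshold=config.silencing_threshold
        )
        emit("silencing.tsv", sil)

        fct = fold_change_table(de, config.fold_thresholds).reset_index()
        emit("fold_change_table.tsv", fct)

        ovl = overlap_summary(de)
        emit("overlap_summary.tsv", ovl)

        # --- GLM ----------------------------------------------------------
        glm_res = glm_pairwise(cm, samples, pairs, fdr=config.fdr)
        emit("glm_results.tsv", glm_res)
        compl = detect_complementary(glm_res, fdr=config.fdr)
        emit("complementary.tsv", compl)
        uq = upper_quartile(cm)
        log_vals = np.log2(uq.values + config.pseudocount)
        anova = pooled_anova(log_vals, samples, pairs)
        emit("anova_table.tsv", anova)

        # --- dN/dS + downstream ------------------------------------------
        if config.alignments:
            alns = pio.read_alignments(config.alignments)
            dnds_rows = []
            for aln in alns:
                r = dnds(aln)
                d = vars(r).copy()
                d["flags"] = ";".join(d["flags"])
                dnds_rows.append(d)
            dnds_df = pd.DataFrame(dnds_rows)
            emit("dnds.tsv", dnds_df)
            cw = category_wilcoxon(glm_res, dnds_df)
            emit("category_wilcoxon.tsv", cw)
        else:
            manifest["notices"].append("no alignments given: dN/dS stages skipped")
            logger.info("no alignments given: dN/dS stages skipped")

        if {"chrom1", "start1", "chrom2", "start2"} <= set(pairs.columns):
            bias = positional_bias_test(
                de, pairs, window_size=config.window_size, fdr=config.fdr
            )
            emit("positional_bias.tsv", bias)
        else:
            manifest["notices"].append(
                "pair list has no coordinates: positional bias skipped"
            )

        # --- summary ------------------------------------------------------
        summary = render_summary(
            {"pair_de": de, "silencing": sil, "glm_results": glm_res,
             "complementary": compl, "overlap": ovl}
        )
        emit("summary.tsv", summary)

    manifest["warnings"] = len(caught)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def render_summary(results: dict) -> pd.DataFrame:
    """Figure-ready counts: DE per tissue, overlaps, silencing, categories.

    ``results`` maps stage names (pair_de, silencing, glm_results,
    complementary, overlap) to their frames; missing stages are skipped.
    """
    rows: list[tuple[str, str, float]] = []
    de = results.get("pair_de")
    if de is not None:
        n_pairs = de["pair_id"].nunique()
        for tissue, sub in de.groupby("tissue"):
            n = int(sub["reject"].sum())
            rows.append(("de_count", tissue, n))
            rows.append(("de_pct", tissue, round(100.0 * n / max(n_pairs, 1), 2)))
        any_de = de.loc[de["reject"], "pair_id"].nunique()
        rows.append(("de_any_tissue_count", "any", any_de))
        rows.append(("de_any_tissue_pct", "any",
                     round(100.0 * any_de / max(n_pairs, 1), 2)))
    ovl = results.get("overlap")
    if ovl is not None:
        for r in ovl.itertuples():
            if r.statistic in {"intersection", "same_direction"}:
                rows.append((r.statistic, r.tissues, r.count))
    sil = results.get("silencing")
    if sil is not None:
        if len(sil):
            for (a, b), sub in sil.groupby(["condition_a", "condition_b"]):
                rows.append(("silencing_count", f"{a}&{b}", len(sub)))
        rows.append(("silencing_total", "all", len(sil)))
    glm_res = results.get("glm_results")
    if glm_res is not None:
        n_pairs = len(glm_res)
        counts = glm_res["category"].value_counts()
        for cat in ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii"]:
            n = int(counts.get(cat, 0))
            rows.append(("category_count", cat, n))
            rows.append(("category_pct", cat, round(100.0 * n / max(n_pairs, 1), 2)))
    compl = results.get("complementary")
    if compl is not None:
        if len(compl):
            for (a, b), sub in compl.groupby(["tissue_a", "tissue_b"]):
                rows.append(("complementary_count", f"{a}&{b}", len(sub)))
        rows.append(("complementary_pairs", "all",
                     compl["pair_id"].nunique() if len(compl) else 0))
    return pd.DataFrame(rows, columns=["statistic", "key", "value"])
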