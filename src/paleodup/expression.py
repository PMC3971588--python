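"""Count normalization and per-pair log-ratio differential expression.

Paralogs of a pair are measured in the same libraries, so per-replicate
log2 expression ratios cancel library effects and a one-sample Student
t-test of the ratios against zero is the natural per-pair, per-tissue test
(3 replicates -> 2 degrees of freedom).  P-values are adjusted per tissue
with Benjamini–Hochberg step-up FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountsMatrix",
    "NormalizedMatrix",
    "rpkm",
    "upper_quartile",
    "pair_log_ratios",
    "pair_ttest",
    "bh_adjust",
    "de_pairwise",
    "fold_change_table",
    "overlap_summary",
    "detect_reciprocal_silencing",
]


@dataclass
class CountsMatrix:
    """Raw read counts (genes x samples) with gene lengths and library totals.

    ``totals`` defaults to the column sums; supply it when the per-sample
    total mapped reads differ from the in-matrix sum (e.g. genome-wide
    totals for a gene subset).
    """

    counts: pd.DataFrame
    lengths: pd.Series | None = None
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
                raise ValueError(f"missing gene lengths, e.g. {missing}")
            if (self.lengths <= 0).any():
                raise ValueError("gene lengths must be positive")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)
        else:
            self.totals = self.totals.reindex(self.counts.columns).astype(float)
            if self.totals.isna().any():
                raise ValueError("totals missing for some samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class NormalizedMatrix:
    """Normalized expression values with the method tag and scale factors."""

    values: pd.DataFrame
    method: str  # "RPKM" or "UQ"
    scale_factors: pd.Series


def rpkm(counts: CountsMatrix) -> NormalizedMatrix:
    """Reads per kilobase of gene model per million mapped reads.

    value = count * 1e9 / (length_bp * total_mapped_reads).
    """
    if counts.lengths is None:
        raise ValueError("RPKM requires gene lengths")
    if (counts.totals <= 0).any():
        bad = counts.totals.index[counts.totals <= 0].tolist()
        raise ValueError(f"zero/negative library totals for samples {bad}")
    vals = counts.counts.astype(float).mul(1e9)
    vals = vals.div(counts.lengths, axis=0).div(counts.totals, axis=1)
    return NormalizedMatrix(vals, "RPKM", counts.totals / 1e6)


def upper_quartile(counts: CountsMatrix) -> NormalizedMatrix:
    """Upper-quartile normalization (Bullard et al. style).

    The per-sample scale factor is the 75th percentile of that sample's
    nonzero gene counts; values are divided by the factor and multiplied by
    the geometric mean of all factors so the output stays on a count-like
    scale regardless of which samples are present.
    """
    factors = {}
    for s in counts.sample_ids:
        col = counts.counts[s].values
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {s!r} has no nonzero counts")
        factors[s] = float(np.percentile(nz, 75))
    factors = pd.Series(factors, name="uq_factor")
    ref = float(np.exp(np.mean(np.log(factors.values))))
    vals = counts.counts.astype(float).div(factors, axis=1) * ref
    return NormalizedMatrix(vals, "UQ", factors)


def pair_log_ratios(
    norm: NormalizedMatrix,
    gene1: str,
    gene2: str,
    sample_ids: list[str],
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-replicate log2((x1 + c)/(x2 + c)) ratios; antisymmetric in the pair."""
    for g in (gene1, gene2):
        if g not in norm.values.index:
            raise KeyError(f"gene {g!r} not in normalized matrix")
    x1 = norm.values.loc[gene1, sample_ids].to_numpy(dtype=float)
    x2 = norm.values.loc[gene2, sample_ids].to_numpy(dtype=float)
    return np.log2(x1 + pseudocount) - np.log2(x2 + pseudocount)


def pair_ttest(log_ratios: np.ndarray) -> tuple[float, int, float, bool]:
    """One-sample two-sided t-test of the mean log ratio against zero.

    Returns (t, df, p, degenerate) where ``degenerate`` marks zero
    replicate variance: with nonzero mean the p-value is reported as 0,
    with zero mean as (t=0, p=1).
    """
    r = np.asarray(log_ratios, dtype=float)
    r = r[np.isfinite(r)]
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 finite log ratios")
    mean = r.mean()
    sd = r.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, True
        return math_inf_sign(mean), df, 0.0, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p), False


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (q_values, reject_flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def _tissue_samples(samples: pd.DataFrame, tissue: str) -> list[str]:
    sub = samples.loc[samples["tissue"] == tissue]
    return sub.sort_values("replicate")["sample_id"].tolist()


def de_pairwise(
    norm: NormalizedMatrix,
    pairs: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 0.5,
    min_expr: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-pair, per-tissue log-ratio t-tests with BH correction per tissue.

    ``pairs`` needs columns pair_id, gene1_id, gene2_id; ``samples`` needs
    sample_id, tissue, replicate.  Pairs where both paralogs fall below the
    minimum-expression floor (mean normalized value < ``min_expr`` in that
    tissue) are excluded from testing (``tested`` False, p/q NaN).

    Returns a tidy frame: one row per pair x tissue with the ratio summary,
    t, df, p, q, reject, fold_change (linear, >= 1), direction.
    """
    tissues = sorted(samples["tissue"].unique())
    v = norm.values
    rows = []
    for tissue in tissues:
        cols = _tissue_samples(samples, tissue)
        if len(cols) < 2:
            raise ValueError(f"tissue {tissue!r} has fewer than 2 replicates")
        x1 = v.loc[pairs["gene1_id"], cols].to_numpy(dtype=float)
        x2 = v.loc[pairs["gene2_id"], cols].to_numpy(dtype=float)
        tested = (x1.mean(axis=1) >= min_expr) | (x2.mean(axis=1) >= min_expr)
        ratios = np.log2(x1 + pseudocount) - np.log2(x2 + pseudocount)
        n = ratios.shape[1]
        mean = ratios.mean(axis=1)
        sd = ratios.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        degenerate = sd == 0.0
        p = 2.0 * sps.t.sf(np.abs(t), n - 1)
        p[degenerate & (mean != 0)] = 0.0
        t[degenerate & (mean == 0)] = 0.0
        p[degenerate & (mean == 0)] = 1.0
        p[~tested] = np.nan
        q = np.full_like(p, np.nan)
        reject = np.zeros(p.shape, dtype=bool)
        if tested.any():
            q[tested], reject[tested] = bh_adjust(p[tested], fdr)
        fold = 2.0 ** np.abs(mean)
        direction = np.where(
            mean > 0, "gene1_higher", np.where(mean < 0, "gene2_higher", "none")
        )
        frame = pd.DataFrame(
            {
                "pair_id": pairs["pair_id"].values,
                "tissue": tissue,
                "n_reps": n,
                "mean_log2_ratio": mean,
                "t": t,
                "df": n - 1,
                "p": p,
                "q": q,
                "reject": reject,
                "fold_change": fold,
                "direction": direction,
                "tested": tested,
                "degenerate_variance": degenerate,
            }
        )
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["norm_method"] = norm.method
    out.attrs["fdr"] = fdr
    return out


def fold_change_table(
    results: pd.DataFrame, thresholds: tuple[float, ...] = (1.5, 2.0, 5.0)
) -> pd.DataFrame:
    """Counts of BH-significant pairs meeting each fold-change threshold.

    One row per tissue plus a ``max_any_tissue`` row counting pairs meeting
    the threshold (with significance) in at least one tissue.  Cells are
    nested: count(5x) <= count(2x) <= count(1.5x).
    """
    tissues = sorted(results["tissue"].unique())
    table = {}
    for tissue in tissues:
        sub = results[results["tissue"] == tissue]
        hit = sub["reject"].to_numpy()
        fold = sub["fold_change"].to_numpy()
        table[tissue] = {
            f"fold_{thr:g}": int((hit & (fold >= thr)).sum()) for thr in thresholds
        }
    any_row = {}
    for thr in thresholds:
        winners = results.loc[
            results["reject"] & (results["fold_change"] >= thr), "pair_id"
        ]
        any_row[f"fold_{thr:g}"] = int(winners.nunique())
    table["max_any_tissue"] = any_row
    return pd.DataFrame(table).T.rename_axis("tissue")


def _de_sets(results: pd.DataFrame) -> dict[str, set]:
    return {
        tissue: set(sub.loc[sub["reject"], "pair_id"])
        for tissue, sub in results.groupby("tissue")
    }


def overlap_summary(
    results: pd.DataFrame, results_other: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Set-algebra summary of per-tissue DE calls.

    Rows: per-tissue counts, every pairwise intersection (with the count of
    pairs whose ratio direction agrees in both tissues), the all-tissue
    intersection, and — when a second species' result frame is supplied on
    the same pair universe — per-tissue cross-species intersections.
    """
    sets = _de_sets(results)
    tissues = sorted(sets)
    universe = set(results["pair_id"])
    rows = []
    for t in tissues:
        rows.append(("de_count", t, len(sets[t])))
    dirmap = {
        (r.pair_id, r.tissue): r.direction
        for r in results.itertuples()
        if r.reject
    }
    for a, b in combinations(tissues, 2):
        inter = sets[a] & sets[b]
        same = sum(1 for p in inter if dirmap[(p, a)] == dirmap[(p, b)])
        rows.append(("intersection", f"{a}&{b}", len(inter)))
        rows.append(("same_direction", f"{a}&{b}", same))
    if len(tissues) >= 3:
        allset = set.intersection(*sets.values())
        rows.append(("intersection", "&".join(tissues), len(allset)))
    anyset = set.union(*sets.values()) if sets else set()
    rows.append(("de_any_tissue", "any", len(anyset)))
    rows.append(("pair_universe", "all", len(universe)))
    if results_other is not None:
        if set(results_other["pair_id"]) != universe:
            raise ValueError("pair universes differ between result sets")
        other = _de_sets(results_other)
        for t in tissues:
            if t in other:
                rows.append(("cross_species_intersection", t, len(sets[t] & other[t])))
    return pd.DataFrame(rows, columns=["statistic", "tissues", "count"])


def detect_reciprocal_silencing(
    norm: NormalizedMatrix,
    pairs: pd.DataFrame,
    samples: pd.DataFrame,
    de_results: pd.DataFrame,
    conditions: list[tuple[str, str]] | None = None,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Tissue-specific reciprocal silencing calls among DE paralog pairs.

    A pair is called for a condition pair (A, B) when it is BH-significant
    in both conditions and the mean share of the pair total contributed by
    one paralog is >= ``threshold`` in one condition and <= 1 - threshold in
    the other (boundaries inclusive).  Replicates with zero pair total are
    ignored; pairs with no expressed replicate in a condition are excluded
    with a warning.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    tissues = sorted(samples["tissue"].unique())
    if conditions is None:
        conditions = list(combinations(tissues, 2))
    sig = {
        (r.pair_id, r.tissue) for r in de_results.itertuples() if r.reject
    }
    v = norm.values
    calls = []
    for cond_a, cond_b in conditions:
        cols_a = _tissue_samples(samples, cond_a)
        cols_b = _tissue_samples(samples, cond_b)
        for rec in pairs.itertuples():
            if (rec.pair_id, cond_a) not in sig or (rec.pair_id, cond_b) not in sig:
                continue
            props = []
            skip = False
            for cols, cond in ((cols_a, cond_a), (cols_b, cond_b)):
                x1 = v.loc[rec.gene1_id, cols].to_numpy(dtype=float)
                x2 = v.loc[rec.gene2_id, cols].to_numpy(dtype=float)
                tot = x1 + x2
                ok = tot > 0
                if not ok.any():
                    warnings.warn(
                        f"pair {rec.pair_id} has zero total expression in "
                        f"{cond}; excluded from silencing detection",
                        stacklevel=2,
                    )
                    skip = True
                    break
                props.append(float(np.mean(x1[ok] / tot[ok])))
            if skip:
                continue
            pa, pb = props
            lo = 1.0 - threshold
            if (pa >= threshold and pb <= lo) or (pa <= lo and pb >= threshold):
                calls.append(
                    {
                        "pair_id": rec.pair_id,
                        "condition_a": cond_a,
                        "condition_b": cond_b,
                        "dominant_gene_in_a": rec.gene1_id if pa >= 0.5 else rec.gene2_id,
                        "dominant_gene_in_b": rec.gene1_id if pb >= 0.5 else rec.gene2_id,
                        "proportion_a": pa,
                        "proportion_b": pb,
                    }
                )
    return pd.DataFrame(
        calls,
        columns=[
            "pair_id",
            "condition_a",
            "condition_b",
            "dominant_gene_in_a",
            "dominant_gene_in_b",
            "proportion_a",
            "proportion_b",
        ],
    )
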