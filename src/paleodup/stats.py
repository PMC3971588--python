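"""Downstream group comparisons: dN/dS by GLM category, positional bias.

Category comparisons use the two-sample Wilcoxon rank-sum test (the groups
are independent sets of pairs, so the paired signed-rank form does not
apply); W is reported on the rank-sum scale.  Positional bias is an exact
two-sided binomial test of over- vs underexpression in sliding windows of
consecutive pair-anchoring genes along each chromosome, BH-corrected per
tissue across windows.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import bh_adjust

__all__ = [
    "wilcoxon_compare",
    "category_wilcoxon",
    "positional_bias_test",
]


def wilcoxon_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank-sum of group A.  The exact null distribution is used for
    min(nA, nB) <= 10 without ties; otherwise the normal approximation with
    tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(res.pvalue)


def category_wilcoxon(
    glm_results: pd.DataFrame,
    dnds_results: pd.DataFrame,
    min_group: int = 2,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of omega (dN/dS) between categories.

    Pairs with undefined omega (e.g. dS = 0) are excluded; the excluded
    count is recorded in the frame attrs.  Categories with fewer than
    ``min_group`` finite members are skipped.
    """
    merged = glm_results[["pair_id", "category"]].merge(
        dnds_results[["pair_id", "omega"]], on="pair_id", how="inner"
    )
    finite = merged[np.isfinite(merged["omega"])]
    n_excluded = len(merged) - len(finite)
    groups = {
        cat: sub["omega"].to_numpy()
        for cat, sub in finite.groupby("category")
        if len(sub) >= min_group
    }
    rows = []
    for ca, cb in combinations(sorted(groups), 2):
        w, p = wilcoxon_compare(groups[ca], groups[cb])
        rows.append(
            {
                "category_a": ca, "category_b": cb,
                "n_a": len(groups[ca]), "n_b": len(groups[cb]),
                "mean_omega_a": float(np.mean(groups[ca])),
                "mean_omega_b": float(np.mean(groups[cb])),
                "W": w, "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["category_a", "category_b", "n_a", "n_b",
                 "mean_omega_a", "mean_omega_b", "W", "p"],
    )
    out.attrs["n_omega_excluded"] = n_excluded
    return out


def positional_bias_test(
    de_results: pd.DataFrame,
    pairs: pd.DataFrame,
    window_size: int = 20,
    step: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Windowed binomial test for regional over/under-expression bias.

    Every DE pair contributes its two gene locations; at each location the
    local gene either is or is not the higher-expressed member of its pair.
    Per chromosome and tissue, sliding windows of ``window_size``
    consecutive locations (default 50% overlap) are tested against a fair
    coin with an exact two-sided binomial test, then BH-corrected across
    windows within the tissue.
    """
    if step is None:
        step = max(1, window_size // 2)
    pair_info = pairs.set_index("pair_id")
    out_rows = []
    for tissue, sub in de_results.groupby("tissue"):
        hits = sub[sub["reject"] & (sub["direction"] != "none")]
        members = []
        for row in hits.itertuples():
            info = pair_info.loc[row.pair_id]
            members.append(
                {
                    "chrom": info["chrom1"], "start": info["start1"],
                    "higher": row.direction == "gene1_higher",
                }
            )
            members.append(
                {
                    "chrom": info["chrom2"], "start": info["start2"],
                    "higher": row.direction == "gene2_higher",
                }
            )
        if not members:
            continue
        mdf = pd.DataFrame(members).sort_values(["chrom", "start"])
        tissue_rows = []
        for chrom, cdf in mdf.groupby("chrom"):
            cdf = cdf.reset_index(drop=True)
            i = 0
            while i < len(cdf):
                win = cdf.iloc[i : i + window_size]
                if len(win) > 0:
                    n = int(len(win))
                    k = int(win["higher"].sum())
                    p = sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue
                    tissue_rows.append(
                        {
                            "tissue": tissue, "chrom": chrom,
                            "start": int(win["start"].iloc[0]),
                            "end": int(win["start"].iloc[-1]),
                            "n_in_window": n, "n_higher": k, "p": float(p),
                        }
                    )
                if i + window_size >= len(cdf):
                    break
                i += step
        tdf = pd.DataFrame(tissue_rows)
        q, reject = bh_adjust(tdf["p"].to_numpy(), fdr)
        tdf["q"] = q
        tdf["reject"] = reject
        out_rows.append(tdf)
    if not out_rows:
        return pd.DataFrame(
            columns=["tissue", "chrom", "start", "end", "n_in_window",
                     "n_higher", "p", "q", "reject"]
        )
    return pd.concat(out_rows, ignore_index=True)
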