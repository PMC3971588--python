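"""Per-pair negative-binomial GLM with gene/tissue/interaction contrasts.

For each paralog pair the model is

    log mu = intercept + gene + tissue + gene:tissue + offset

fit to the raw counts of the two paralogs across tissues and replicates
(NB2 variance mu + phi mu^2; reference coding with gene1 and the
alphabetically first tissue as references; offsets carry the normalization
scale, e.g. log upper-quartile factors).  Wald contrasts give

* G     — the gene difference averaged over tissues (1 df),
* T     — joint test that pooled-paralog means differ between tissues (T-1 df),
* G×T   — joint test of all interaction terms (T-1 df),
* G|T_t — the gene difference within each tissue t (1 df each).

P-values are BH-adjusted across pairs separately within each effect family
and every pair is assigned to exactly one of the eight significance
categories i (none) … viii (G+T+G×T).  A classical balanced two-way ANOVA
on log-scale normalized values (gene with 2·n_pairs levels × tissue) is
provided for the pooled view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy import stats as sps

from .expression import CountsMatrix, bh_adjust, upper_quartile

__all__ = [
    "PairGlmFit",
    "fit_pair_glm",
    "contrast_tests",
    "assign_categories",
    "glm_pairwise",
    "detect_complementary",
    "pooled_anova",
]

_ALPHA_MIN = 1e-8
_ALPHA_MAX = 50.0

CATEGORY_OF = {
    (False, False, False): "i",
    (True, False, False): "ii",
    (False, True, False): "iii",
    (False, False, True): "iv",
    (True, True, False): "v",
    (True, False, True): "vi",
    (False, True, True): "vii",
    (True, True, True): "viii",
}
CATEGORY_LABELS = {
    "i": "none", "ii": "G", "iii": "T", "iv": "GxT",
    "v": "G+T", "vi": "G+GxT", "vii": "T+GxT", "viii": "G+T+GxT",
}


@dataclass
class PairGlmFit:
    pair_id: str
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float  # NB2 phi; 0 means Poisson fallback
    genes: tuple[str, str]
    tissues: list[str]
    offsets: np.ndarray
    converged: bool
    llf: float
    n_obs: int
    flags: list[str] = field(default_factory=list)


def _nb2_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood at fixed means (used to profile the dispersion)."""
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - r * np.log1p(alpha * mu)
        )
    )


def _design(gene_idx, tissue_idx, tissues):
    """Reference-coded design matrix; column names for contrasts."""
    T = len(tissues)
    n = len(gene_idx)
    cols = {"const": np.ones(n), "gene": (gene_idx == 1).astype(float)}
    for t in range(1, T):
        cols[f"tissue[{tissues[t]}]"] = (tissue_idx == t).astype(float)
    for t in range(1, T):
        cols[f"gene:tissue[{tissues[t]}]"] = cols["gene"] * cols[f"tissue[{tissues[t]}]"]
    return pd.DataFrame(cols)


def fit_pair_glm(
    data: pd.DataFrame,
    pair_id: str = "pair",
    dispersion: str | float = "mle",
) -> PairGlmFit:
    """Fit the per-pair NB GLM.

    ``data`` is a tidy frame with columns ``count`` (non-negative integers),
    ``gene`` (two levels), ``tissue`` (>= 2 levels) and optionally
    ``offset`` (log scale).  ``dispersion`` is ``"mle"`` for the per-pair
    profile maximum-likelihood estimate (boundary values fall back to
    Poisson with a flag) or a fixed non-negative phi.
    """
    y = np.asarray(data["count"], dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    genes = sorted(data["gene"].unique())
    tissues = sorted(data["tissue"].unique())
    if len(genes) != 2:
        raise ValueError(f"expected exactly 2 genes, got {genes}")
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    gene_idx = data["gene"].map({genes[0]: 0, genes[1]: 1}).to_numpy()
    tissue_idx = data["tissue"].map({t: i for i, t in enumerate(tissues)}).to_numpy()
    for g in range(2):
        for t in range(len(tissues)):
            if ((gene_idx == g) & (tissue_idx == t)).sum() < 2:
                raise ValueError("need >= 2 replicates in every gene x tissue cell")
    offset = (
        np.asarray(data["offset"], dtype=float)
        if "offset" in data.columns
        else np.zeros_like(y)
    )
    X = _design(gene_idx, tissue_idx, tissues)
    flags: list[str] = []

    def fit_at(alpha: float):
        fam = (
            sm.families.NegativeBinomial(alpha=alpha)
            if alpha > 0
            else sm.families.Poisson()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)

    if isinstance(dispersion, (int, float)):
        alpha = float(dispersion)
        if alpha < 0:
            raise ValueError("dispersion must be >= 0")
        res = fit_at(alpha)
    elif dispersion == "mle":
        alpha = 0.1
        res = fit_at(alpha)
        for _ in range(4):
            mu = np.maximum(res.mu, 1e-10)
            opt = optimize.minimize_scalar(
                lambda la: -_nb2_loglik(y, mu, np.exp(la)),
                bounds=(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            new_alpha = float(np.exp(opt.x))
            done = abs(np.log(new_alpha) - np.log(alpha)) < 1e-3
            alpha = new_alpha
            res = fit_at(alpha)
            if done:
                break
        if alpha <= 2 * _ALPHA_MIN:
            alpha = 0.0
            res = fit_at(0.0)
            flags.append("poisson_fallback")
    else:
        raise ValueError(f"unknown dispersion method {dispersion!r}")

    params = pd.Series(np.asarray(res.params), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params()), index=X.columns, columns=X.columns
    )
    converged = bool(getattr(res, "converged", True))
    if np.any(res.mu < 1e-6) or np.any(np.abs(params.values) > 15):
        flags.append("near_boundary")
    return PairGlmFit(
        pair_id=pair_id,
        params=params,
        cov=cov,
        dispersion=alpha,
        genes=(genes[0], genes[1]),
        tissues=tissues,
        offsets=offset,
        converged=converged,
        llf=float(res.llf),
        n_obs=len(y),
        flags=flags,
    )


def _wald(
    params: np.ndarray, cov: np.ndarray, L: np.ndarray, df_resid: int
) -> tuple[float, int, float]:
    """Joint Wald test of L @ beta = 0 referred to F(df, df_resid).

    The F reference (Wald statistic divided by its rank, with the per-pair
    residual degrees of freedom in the denominator) keeps small-sample
    type-I error near nominal where the chi-square reference is
    anti-conservative with few replicates and an estimated dispersion.
    """
    L = np.atleast_2d(L)
    est = L @ params
    vc = L @ cov @ L.T
    try:
        stat = float(est @ np.linalg.solve(vc, est))
    except np.linalg.LinAlgError:
        return np.nan, L.shape[0], np.nan
    if not np.isfinite(stat) or stat < 0:
        return np.nan, L.shape[0], np.nan
    df = L.shape[0]
    return stat, df, float(sps.f.sf(stat / df, df, df_resid))


def contrast_tests(fit: PairGlmFit) -> dict:
    """Wald contrasts for G, T, G×T and per-tissue G|T effects."""
    names = list(fit.params.index)
    p = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    T = len(fit.tissues)
    idx = {name: i for i, name in enumerate(names)}
    k = len(names)

    def vec(entries: dict[str, float]) -> np.ndarray:
        v = np.zeros(k)
        for name, val in entries.items():
            v[idx[name]] = val
        return v

    df_resid = fit.n_obs - k
    int_names = [f"gene:tissue[{t}]" for t in fit.tissues[1:]]
    # G: gene difference averaged over tissues
    g_vec = vec({"gene": 1.0, **{n: 1.0 / T for n in int_names}})
    _, _, p_g = _wald(p, V, g_vec, df_resid)
    # T: pooled-paralog mean differences between tissues (T-1 rows)
    t_rows = [
        vec({f"tissue[{t}]": 1.0, f"gene:tissue[{t}]": 0.5}) for t in fit.tissues[1:]
    ]
    _, _, p_t = _wald(p, V, np.array(t_rows), df_resid)
    # GxT: all interaction terms jointly
    gxt_rows = [vec({n: 1.0}) for n in int_names]
    _, _, p_gxt = _wald(p, V, np.array(gxt_rows), df_resid)
    # G|T per tissue
    p_g_by_t = {}
    for t in fit.tissues:
        entries = {"gene": 1.0}
        if t != fit.tissues[0]:
            entries[f"gene:tissue[{t}]"] = 1.0
        _, _, pv = _wald(p, V, vec(entries), df_resid)
        p_g_by_t[t] = pv
    missing = any(
        np.isnan(v) for v in (p_g, p_t, p_gxt, *p_g_by_t.values())
    )
    return {
        "p_G": p_g,
        "p_T": p_t,
        "p_GxT": p_gxt,
        "p_G_by_T": p_g_by_t,
        "singular": missing,
    }


def gene1_proportion(fit: PairGlmFit, tissue: str) -> float:
    """Model-based share of the pair total contributed by gene1 in a tissue."""
    delta = fit.params["gene"]
    if tissue != fit.tissues[0]:
        delta += fit.params[f"gene:tissue[{tissue}]"]
    # gene2 mean / gene1 mean = exp(delta)
    return float(1.0 / (1.0 + np.exp(delta)))


def assign_categories(results: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Assign each pair to one of the eight exclusive G/T/G×T categories.

    Categories: i=none, ii=G, iii=T, iv=G×T, v=G+T, vi=G+G×T, vii=T+G×T,
    viii=G+T+G×T, from the BH-adjusted q-value indicators at ``fdr``.
    Missing q-values withhold the category (NaN).
    """
    cats = []
    for row in results.itertuples():
        qs = (row.q_G, row.q_T, row.q_GxT)
        if any(pd.isna(q) for q in qs):
            cats.append(np.nan)
            continue
        cats.append(CATEGORY_OF[tuple(q <= fdr for q in qs)])
    return pd.Series(cats, index=results.index, name="category")


def glm_pairwise(
    counts: CountsMatrix,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr: float = 0.05,
    dispersion: str | float = "mle",
) -> pd.DataFrame:
    """Fit the NB GLM for every pair and run all contrasts.

    Offsets are log upper-quartile scale factors, so normalization happens
    inside the count model.  BH correction is applied across pairs
    separately within each effect family (G, T, G×T, and each tissue's
    G|T).  Returns one row per pair with p/q per effect, the per-tissue
    gene1 proportion (model-based), the exclusive category, dispersion and
    convergence diagnostics.
    """
    uq = upper_quartile(counts)
    log_factors = np.log(uq.scale_factors)
    tissues = sorted(samples["tissue"].unique())
    sample_tissue = samples.set_index("sample_id")["tissue"]
    sample_ids = list(samples["sample_id"])

    rows = []
    for rec in pairs.itertuples():
        data = pd.DataFrame(
            {
                "count": np.concatenate(
                    [
                        counts.counts.loc[rec.gene1_id, sample_ids].to_numpy(float),
                        counts.counts.loc[rec.gene2_id, sample_ids].to_numpy(float),
                    ]
                ),
                "gene": ["g1"] * len(sample_ids) + ["g2"] * len(sample_ids),
                "tissue": list(sample_tissue.loc[sample_ids]) * 2,
                "offset": np.tile(log_factors.loc[sample_ids].to_numpy(), 2),
            }
        )
        fit = fit_pair_glm(data, pair_id=rec.pair_id, dispersion=dispersion)
        tests = contrast_tests(fit)
        row = {
            "pair_id": rec.pair_id,
            "p_G": tests["p_G"],
            "p_T": tests["p_T"],
            "p_GxT": tests["p_GxT"],
            "dispersion": fit.dispersion,
            "converged": fit.converged,
            "flags": ";".join(fit.flags + (["singular"] if tests["singular"] else [])),
        }
        for t in tissues:
            row[f"p_GbyT_{t}"] = tests["p_G_by_T"][t]
            row[f"prop_gene1_{t}"] = gene1_proportion(fit, t)
        rows.append(row)
    out = pd.DataFrame(rows)

    for fam in ["p_G", "p_T", "p_GxT"] + [f"p_GbyT_{t}" for t in tissues]:
        qcol = fam.replace("p_", "q_", 1)
        p = out[fam].to_numpy()
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok], _ = bh_adjust(p[ok], fdr)
        out[qcol] = q
    out["category"] = assign_categories(out, fdr)
    out["category_label"] = out["category"].map(CATEGORY_LABELS)
    out.attrs["fdr"] = fdr
    out.attrs["tissues"] = tissues
    return out


def detect_complementary(
    glm_results: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Complementary expression: reversed paralog dominance in two tissues.

    For every unordered tissue pair (A, B) a pair is complementary when its
    per-tissue gene contrast is significant in both tissues (q_G|T <= fdr)
    and the dominant paralog (model-based proportion > 0.5) differs between
    A and B.  Silencing is not required; an exact 0.5 proportion yields no
    dominant paralog and no call.
    """
    tissues = glm_results.attrs.get("tissues")
    if tissues is None:
        tissues = sorted(
            c.replace("q_GbyT_", "")
            for c in glm_results.columns
            if c.startswith("q_GbyT_")
        )
    calls = []
    from itertools import combinations

    for row in glm_results.itertuples():
        for a, b in combinations(tissues, 2):
            qa = getattr(row, f"q_GbyT_{a}")
            qb = getattr(row, f"q_GbyT_{b}")
            if pd.isna(qa) or pd.isna(qb) or qa > fdr or qb > fdr:
                continue
            pa = getattr(row, f"prop_gene1_{a}")
            pb = getattr(row, f"prop_gene1_{b}")
            if pa == 0.5 or pb == 0.5:
                continue
            dom_a, dom_b = pa > 0.5, pb > 0.5
            if dom_a != dom_b:
                calls.append(
                    {
                        "pair_id": row.pair_id,
                        "tissue_a": a,
                        "tissue_b": b,
                        "dominant_in_a": "gene1" if dom_a else "gene2",
                        "dominant_in_b": "gene1" if dom_b else "gene2",
                        "prop_gene1_a": pa,
                        "prop_gene1_b": pb,
                    }
                )
    return pd.DataFrame(
        calls,
        columns=[
            "pair_id", "tissue_a", "tissue_b", "dominant_in_a",
            "dominant_in_b", "prop_gene1_a", "prop_gene1_b",
        ],
    )


def pooled_anova(
    values: pd.DataFrame, samples: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Classical balanced two-way ANOVA pooled over all pairs.

    ``values`` are log-scale normalized expression values (genes x
    samples).  Factors: gene (2·n_pairs levels) and tissue, with
    interaction; replicates within tissue supply the residual.  Computed by
    direct mean decomposition (the design matrix at full scale would have
    thousands of columns); exact for balanced data, which is enforced.
    """
    tissues = sorted(samples["tissue"].unique())
    reps_per_tissue = samples.groupby("tissue")["sample_id"].count()
    if reps_per_tissue.nunique() != 1:
        raise ValueError(
            f"unbalanced design: replicates per tissue {dict(reps_per_tissue)}"
        )
    n = int(reps_per_tissue.iloc[0])
    genes = pd.unique(pairs[["gene1_id", "gene2_id"]].to_numpy().ravel())
    G, T = len(genes), len(tissues)
    Y = np.empty((G, T, n))
    for t_i, tissue in enumerate(tissues):
        cols = samples.loc[samples["tissue"] == tissue].sort_values("replicate")[
            "sample_id"
        ]
        block = values.loc[genes, cols].to_numpy(dtype=float)
        if np.isnan(block).any():
            bad = [g for g, row in zip(genes, block) if np.isnan(row).any()]
            raise ValueError(f"missing cells for genes {bad[:5]} in {tissue}")
        Y[:, t_i, :] = block
    grand = Y.mean()
    gene_means = Y.mean(axis=(1, 2))
    tissue_means = Y.mean(axis=(0, 2))
    cell_means = Y.mean(axis=2)
    ss_gene = T * n * float(np.sum((gene_means - grand) ** 2))
    ss_tissue = G * n * float(np.sum((tissue_means - grand) ** 2))
    ss_int = n * float(
        np.sum(
            (cell_means - gene_means[:, None] - tissue_means[None, :] + grand) ** 2
        )
    )
    ss_res = float(np.sum((Y - cell_means[:, :, None]) ** 2))
    df_gene, df_tissue = G - 1, T - 1
    df_int, df_res = df_gene * df_tissue, G * T * (n - 1)
    rows = []
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for name, ss, df in (
        ("Gene(G)", ss_gene, df_gene),
        ("Tissue(T)", ss_tissue, df_tissue),
        ("Gene:tissue(GxT)", ss_int, df_int),
    ):
        ms = ss / df if df > 0 else np.nan
        if ms_res and np.isfinite(ms_res) and ms_res > 0:
            F = ms / ms_res
            pv = float(sps.f.sf(F, df, df_res))
        else:
            F, pv = np.nan, np.nan
        rows.append({"term": name, "df": df, "sum_sq": ss, "mean_sq": ms, "F": F, "p": pv})
    rows.append(
        {"term": "Residuals", "df": df_res, "sum_sq": ss_res, "mean_sq": ms_res,
         "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)
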