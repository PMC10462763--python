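"""Per-dataset differential expression and DerSimonian-Laird meta-analysis.

Each dataset contributes, per gene, a log2 fold change (stimulated minus
control) with a standard error from an ordinary least squares fit of log2
expression on the condition indicator (plus optional covariates).  Effects
are then pooled across datasets with the DerSimonian-Laird random-effects
moment estimator:

    w_i   = 1 / SE_i^2                      (fixed-effect weights)
    ybar  = sum(w_i y_i) / sum(w_i)
    Q     = sum(w_i (y_i - ybar)^2)         (Cochran heterogeneity)
    tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i))
    w*_i  = 1 / (SE_i^2 + tau^2)            (random-effects weights)

with the pooled estimate sum(w* y)/sum(w*), SE (sum w*)^(-1/2), a 1.96-SE
95% interval, I^2 = max(0, (Q - (k-1))/Q) and a normal-approximation
meta p-value.  BH adjustment across genes is applied by the caller via
:func:`bh_adjust`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import PromdivergeError

__all__ = [
    "DatasetExpression",
    "EffectEstimate",
    "MetaResult",
    "log2_cpm",
    "per_dataset_de",
    "dl_meta",
    "meta_analyse",
    "bh_adjust",
    "forest_table",
]

SE_FLOOR = 1e-8


@dataclass
class DatasetExpression:
    """One expression dataset: genes x samples plus a two-level condition."""

    dataset_id: str
    matrix: pd.DataFrame  # genes x samples; log2 scale unless platform == "counts"
    condition: pd.Series  # per sample: "control" | "stimulated"
    platform: str = "log2-array"  # or "counts"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.matrix.columns)
        if self.condition.isna().any():
            raise PromdivergeError(f"{self.dataset_id}: missing condition labels")
        counts = self.condition.value_counts()
        if len(counts) != 2 or (counts < 3).any():
            raise PromdivergeError(
                f"{self.dataset_id}: need two conditions with >= 3 samples each"
            )
        if self.platform not in ("log2-array", "counts"):
            raise PromdivergeError(f"{self.dataset_id}: unknown platform {self.platform!r}")


@dataclass(frozen=True)
class EffectEstimate:
    dataset_id: str
    gene: str
    logfc: float
    se: float
    p: float
    q: float
    df: int
    reason: str = ""


@dataclass(frozen=True)
class MetaResult:
    gene: str
    k: int
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    i2: float
    p: float
    q: float = float("nan")


def log2_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2(CPM + prior).

    The prior count sits on the counts-per-million scale, which keeps the
    transform exactly invariant to rescaling any one sample's library.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise PromdivergeError("library sizes must be positive")
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + prior)


def _ols_groups(y: np.ndarray, x: np.ndarray, covar: np.ndarray | None):
    """Vectorised OLS of each row of y on [1, x] (+ covariates).

    Returns (beta_x, se, p, df) arrays. With no covariates this is the
    two-sample pooled-variance t-test in regression form.
    """
    n = x.size
    design = [np.ones(n), x]
    if covar is not None:
        design.extend(np.asarray(covar, dtype=float).T)
    X = np.column_stack(design)
    p_params = X.shape[1]
    df = n - p_params
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T  # params x n
    betas = y @ H.T  # genes x params
    resid = y - betas @ X.T
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / max(df, 1)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    se = np.maximum(se, SE_FLOOR)
    beta = betas[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df) if df > 0 else np.ones_like(t)
    return beta, se, pvals, df


def per_dataset_de(
    ds: DatasetExpression, genes: Sequence[str] | None = None
) -> list[EffectEstimate]:
    """Per-gene logFC/SE/p for stimulated vs control in one dataset.

    Counts-platform matrices are transformed to log2 CPM (prior count 0.5)
    before the per-gene OLS fit; BH adjustment is applied within the dataset.
    """
    mat = ds.matrix if genes is None else ds.matrix.loc[list(genes)]
    if ds.platform == "counts":
        mat = log2_cpm(mat)
    x = (ds.condition.to_numpy() == "stimulated").astype(float)
    covar = ds.covariates.to_numpy() if ds.covariates is not None else None
    beta, se, pvals, df = _ols_groups(mat.to_numpy(dtype=float), x, covar)
    qvals = bh_adjust(pvals)
    return [
        EffectEstimate(ds.dataset_id, g, float(b), float(s), float(p), float(q), int(df))
        for g, b, s, p, q in zip(mat.index, beta, se, pvals, qvals)
    ]


def dl_meta(effects: Sequence[EffectEstimate],
            hartung_knapp: bool = False) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of one gene's effects.

    By default the meta p-value uses the normal approximation
    z = pooled/SE.  With ``hartung_knapp=True`` the variance is rescaled by
    the weighted residual heterogeneity and the reference distribution is
    t with k-1 degrees of freedom, which holds the type-I error near
    nominal when the number of studies is small; the normal approximation
    is anticonservative there.
    """
    if len(effects) == 0:
        raise PromdivergeError("dl_meta needs at least one effect estimate")
    gene = effects[0].gene
    if any(e.gene != gene for e in effects):
        raise PromdivergeError("dl_meta called with mixed genes")
    y = np.array([e.logfc for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if (se <= 0).any():
        raise PromdivergeError("all standard errors must be positive")
    k = y.size
    w = 1.0 / se**2
    ybar = float((w * y).sum() / w.sum())
    q_stat = float((w * (y - ybar) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q_stat - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q_stat - (k - 1)) / q_stat) if q_stat > 0 else 0.0
    else:
        tau2, i2 = 0.0, 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    pooled_se = float(w_star.sum() ** -0.5)
    if hartung_knapp and k > 1:
        scale = float((w_star * (y - pooled) ** 2).sum() / ((k - 1) * w_star.sum()))
        hk_se = max(np.sqrt(scale), SE_FLOOR)
        p = float(2.0 * stats.t.sf(abs(pooled / hk_se), k - 1))
        pooled_se = hk_se
    else:
        z = pooled / pooled_se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene=gene, k=k, pooled=pooled, se=pooled_se,
        ci_low=pooled - 1.96 * pooled_se, ci_high=pooled + 1.96 * pooled_se,
        tau2=tau2, q_stat=q_stat, i2=i2, p=p,
    )


def meta_analyse(per_gene_effects: dict[str, Sequence[EffectEstimate]]) -> list[MetaResult]:
    """Pool every gene and BH-adjust the meta p-values across genes."""
    results = [dl_meta(effs) for effs in per_gene_effects.values()]
    qs = bh_adjust([r.p for r in results])
    return [
        MetaResult(r.gene, r.k, r.pooled, r.se, r.ci_low, r.ci_high,
                   r.tau2, r.q_stat, r.i2, r.p, q=float(q))
        for r, q in zip(results, qs)
    ]


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise PromdivergeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def forest_table(
    results: Sequence[MetaResult],
    per_gene_effects: dict[str, Sequence[EffectEstimate]],
) -> pd.DataFrame:
    """Long-format forest-plot table: one row per (gene, dataset) + pooled row."""
    rows = []
    for r in results:
        for e in per_gene_effects[r.gene]:
            rows.append({
                "gene": r.gene, "row": e.dataset_id, "kind": "dataset",
                "logfc": e.logfc, "ci_low": e.logfc - 1.96 * e.se,
                "ci_high": e.logfc + 1.96 * e.se,
                "tau2": np.nan, "i2": np.nan, "p": e.p, "q": e.q,
            })
        rows.append({
            "gene": r.gene, "row": "pooled", "kind": "pooled",
            "logfc": r.pooled, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "tau2": r.tau2, "i2": r.i2, "p": r.p, "q": r.q,
        })
    return pd.DataFrame(rows)
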