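"""Single-cell scoring, pseudobulking, pseudobulk DE and cell-type specificity.

Per-cell gene-set activity is scored AUCell-style: genes are ranked by
decreasing count within each cell (ties broken by a seeded permutation) and
the score is the area under the recovery curve of set members within the top
``top_fraction`` of ranks, normalised by the maximum achievable area, so it
lies in [0, 1].  Microglial subclusters are labelled by the marker set whose
scores dominate every other set.  Counts are then pseudobulked — summed per
(sample, cell type) — and differential expression between groups or
subclusters runs on log2 counts-per-million of the pseudobulk columns, which
is far better behaved for sparsely detected genes than per-cell tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._util import PromdivergeError, stream_rng
from .meta import DatasetExpression, EffectEstimate, bh_adjust, log2_cpm, per_dataset_de

__all__ = [
    "CellMatrix",
    "PseudobulkMatrix",
    "GeneSetScore",
    "aucell_score",
    "label_subclusters",
    "pseudobulk",
    "pseudobulk_de",
    "cell_specificity",
    "specificity_table",
]

logger = logging.getLogger(__name__)

_REQUIRED_OBS = ("sample", "group", "cell_type", "subcluster")


@dataclass
class CellMatrix:
    """Sparse gene x cell counts with per-cell sample/group/type/subcluster labels."""

    counts: sparse.csr_matrix  # genes x cells
    genes: list[str]
    obs: pd.DataFrame  # one row per cell; columns include _REQUIRED_OBS

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.obs)):
            raise PromdivergeError("counts shape must be (n_genes, n_cells)")
        missing = [c for c in _REQUIRED_OBS if c not in self.obs.columns]
        if missing:
            raise PromdivergeError(f"missing per-cell labels: {missing}")
        if self.obs[list(_REQUIRED_OBS)].isna().any().any():
            raise PromdivergeError("every cell must carry all labels")
        if (self.counts.data < 0).any():
            raise PromdivergeError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class PseudobulkMatrix:
    """Summed counts per (sample, cell type) column."""

    matrix: pd.DataFrame  # genes x columns; column names "sample|cell_type"
    meta: pd.DataFrame  # per column: sample, cell_type, group, n_cells
    dropped: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeneSetScore:
    cell_id: str
    gene_set: str
    score: float


def aucell_score(
    cells: CellMatrix,
    gene_set: Sequence[str],
    set_name: str = "set",
    top_fraction: float = 0.05,
    seed: int = 0,
) -> list[GeneSetScore]:
    """AUCell-style recovery-curve score of one gene set for every cell.

    Per cell, genes are ranked by decreasing count (ties broken by a seeded
    random permutation shared across cells and recorded via ``seed``); with
    k = ceil(top_fraction * n_genes) ranks considered, the recovery curve
    rec(i) counts set members within the top i ranks and the score is
    sum_{i<=k} rec(i) divided by its maximum sum_{i<=k} min(i, |set|).
    """
    members = np.array([g in set(gene_set) for g in cells.genes])
    if not members.any():
        missing = sorted(set(gene_set))
        raise PromdivergeError(f"gene set has no genes in the matrix: {missing}")
    G = cells.n_genes
    k = max(1, math.ceil(top_fraction * G))
    m = int(members.sum())
    rng = stream_rng(seed, "aucell-ties")
    tiebreak = rng.permutation(G)
    dense = np.asarray(cells.counts.todense(), dtype=float)
    max_area = float(np.minimum(np.arange(1, k + 1), m).sum())
    scores: list[GeneSetScore] = []
    cell_ids = (cells.obs["cell_id"] if "cell_id" in cells.obs.columns
                else cells.obs.index.astype(str))
    for j, cid in enumerate(cell_ids):
        order = np.lexsort((tiebreak, -dense[:, j]))
        hits = members[order[:k]]
        rec = np.cumsum(hits)
        scores.append(GeneSetScore(str(cid), set_name, float(rec.sum() / max_area)))
    return scores


def label_subclusters(
    scores_by_set: dict[str, Sequence[GeneSetScore]],
    subcluster_of_cell: pd.Series,
    q_threshold: float = 0.05,
) -> dict[str, str]:
    """Assign each subcluster the marker set that dominates every other set.

    A subcluster gets the set with the highest median per-cell score when
    that set beats every other set by a two-sided rank-sum test at BH
    q <= ``q_threshold`` (and a strictly greater median); otherwise it is
    labelled ``"ambiguous"``.
    """
    sets = sorted(scores_by_set)
    if len(sets) < 2:
        raise PromdivergeError("need at least two gene sets to label subclusters")
    frames = {
        name: pd.Series({s.cell_id: s.score for s in scores}, dtype=float)
        for name, scores in scores_by_set.items()
    }
    subclusters = sorted(subcluster_of_cell.astype(str).unique())
    if len(subclusters) < 2:
        raise PromdivergeError("need at least two subclusters")
    tests = []  # (subcluster, top_set, other_set, p, medians_differ)
    top_of = {}
    for sc in subclusters:
        cell_ids = subcluster_of_cell.index[subcluster_of_cell.astype(str) == sc]
        medians = {name: float(frames[name].reindex(cell_ids).median())
                   for name in sets}
        top = max(sets, key=lambda s: medians[s])
        top_of[sc] = top
        for other in sets:
            if other == top:
                continue
            a = frames[top].reindex(cell_ids).to_numpy()
            b = frames[other].reindex(cell_ids).to_numpy()
            if np.array_equal(a, b):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
            tests.append((sc, top, other, p, medians[top] > medians[other]))
    qs = bh_adjust([t[3] for t in tests])
    ok: dict[str, bool] = {sc: True for sc in subclusters}
    for (sc, _top, _other, _p, median_gt), q in zip(tests, qs):
        if not (median_gt and q <= q_threshold):
            ok[sc] = False
    return {sc: (top_of[sc] if ok[sc] else "ambiguous") for sc in subclusters}


def pseudobulk(cells: CellMatrix, min_cells: int = 10,
               by: str = "cell_type") -> PseudobulkMatrix:
    """Sum counts over cells per (sample, ``by``) column.

    ``by`` is usually ``"cell_type"``; pass ``"subcluster"`` to aggregate
    microglial subclusters for the activated-vs-homeostatic contrast.
    Columns aggregating fewer than ``min_cells`` cells are dropped (and
    logged); sums are exact integer sums, invariant to cell order.
    """
    if by not in cells.obs.columns:
        raise PromdivergeError(f"unknown grouping column {by!r}")
    key = cells.obs["sample"].astype(str) + "|" + cells.obs[by].astype(str)
    columns = sorted(key.unique())
    col_index = {c: i for i, c in enumerate(columns)}
    indicator = sparse.csr_matrix(
        (np.ones(cells.n_cells), (np.arange(cells.n_cells),
                                  key.map(col_index).to_numpy())),
        shape=(cells.n_cells, len(columns)),
    )
    summed = np.asarray((cells.counts @ indicator).todense())
    meta_rows = []
    for c in columns:
        cells_in = cells.obs[key == c]
        meta_rows.append({
            "column": c,
            "sample": cells_in["sample"].iloc[0],
            "cell_type": cells_in[by].iloc[0],
            "group": cells_in["group"].iloc[0],
            "n_cells": int(len(cells_in)),
        })
    meta = pd.DataFrame(meta_rows).set_index("column")
    keep = meta["n_cells"] >= min_cells
    dropped = list(meta.index[~keep])
    for col in dropped:
        logger.info("pseudobulk: dropping column %s (%d cells < floor %d)",
                    col, meta.loc[col, "n_cells"], min_cells)
    matrix = pd.DataFrame(summed, index=cells.genes, columns=columns)
    return PseudobulkMatrix(matrix=matrix.loc[:, keep.to_numpy()],
                            meta=meta.loc[keep], dropped=dropped)


def pseudobulk_de(
    pb: PseudobulkMatrix,
    contrast: str = "group",
    cell_type: str | None = None,
    stimulated_level: str | None = None,
    dataset_id: str = "pseudobulk",
) -> list[EffectEstimate]:
    """Differential expression between two pseudobulk column groups.

    ``contrast`` names a column of the pseudobulk metadata (``group`` or
    ``subcluster``-style labels stored in ``cell_type``); columns are
    restricted to ``cell_type`` when given.  Counts go through log2 CPM
    (prior 0.5), then the per-gene OLS fit used for bulk datasets; BH across
    genes.  ``stimulated_level`` picks which level gets positive logFC
    (default: lexicographically larger level).
    """
    meta = pb.meta
    cols = meta.index
    if cell_type is not None:
        cols = meta.index[meta["cell_type"] == cell_type]
    if contrast not in meta.columns:
        raise PromdivergeError(f"unknown contrast column {contrast!r}")
    labels = meta.loc[cols, contrast].astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise PromdivergeError(
            f"contrast {contrast!r} needs exactly 2 levels, got {levels}")
    if stimulated_level is None:
        stimulated_level = levels[1]
    if (labels == stimulated_level).sum() < 2 or (labels != stimulated_level).sum() < 2:
        raise PromdivergeError("need >= 2 columns per contrast level")
    condition = labels.map(
        lambda v: "stimulated" if v == stimulated_level else "control")
    # reuse the bulk OLS path; DatasetExpression enforces >= 3 per level, so
    # fit directly when a level has only 2 pseudobulk columns
    mat = log2_cpm(pb.matrix.loc[:, cols])
    from .meta import _ols_groups  # shared fitting core

    x = (condition.to_numpy() == "stimulated").astype(float)
    beta, se, pvals, df = _ols_groups(mat.to_numpy(dtype=float), x, None)
    qvals = bh_adjust(pvals)
    return [
        EffectEstimate(dataset_id, g, float(b), float(s), float(p), float(q), int(df))
        for g, b, s, p, q in zip(mat.index, beta, se, pvals, qvals)
    ]


def cell_specificity(
    cells: CellMatrix | PseudobulkMatrix,
    gene: str,
    target_type: str = "microglia",
    fold_threshold: float = 4.0,
    q_threshold: float = 0.05,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Selectivity of one gene for a target cell type vs every other type.

    Pseudobulks per (sample, cell type), converts to log2 CPM, and for each
    non-target type reports the mean log2 ratio target/other (paired by
    sample where both columns exist) with a one-sided rank-sum p.  The gene
    is flagged ``selective`` when the fold ratio is >= ``fold_threshold``
    against every other type at BH q <= ``q_threshold``.
    """
    pb = cells if isinstance(cells, PseudobulkMatrix) else pseudobulk(cells, min_cells)
    if gene not in pb.matrix.index:
        raise PromdivergeError(f"gene {gene!r} absent from the matrix")
    table = specificity_table(pb, [gene], target_type, fold_threshold, q_threshold)
    return table[table["gene"] == gene].reset_index(drop=True)


def specificity_table(
    pb: PseudobulkMatrix,
    genes: Sequence[str],
    target_type: str = "microglia",
    fold_threshold: float = 4.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Vectorised specificity report for many genes at once.

    One row per (gene, other cell type); the per-gene ``selective`` flag
    requires every comparison to pass both the fold and the BH-q gates.
    """
    meta = pb.meta
    types = sorted(meta["cell_type"].unique())
    if target_type not in types:
        raise PromdivergeError(f"target cell type {target_type!r} not present")
    if len(types) < 2:
        raise PromdivergeError("need >= 2 cell types")
    logcpm = log2_cpm(pb.matrix)
    sub = logcpm.loc[list(genes)]
    cols_of = {t: meta.index[meta["cell_type"] == t] for t in types}
    rows = []
    for other in types:
        if other == target_type:
            continue
        a = sub.loc[:, cols_of[target_type]].to_numpy()
        b = sub.loc[:, cols_of[other]].to_numpy()
        ratio = a.mean(axis=1) - b.mean(axis=1)  # log2 scale
        res = stats.mannwhitneyu(a, b, alternative="greater", axis=1)
        pvals = np.atleast_1d(res.pvalue)
        for gi, g in enumerate(genes):
            rows.append({
                "gene": g, "other_type": other,
                "log2_ratio": float(ratio[gi]), "p": float(pvals[gi]),
            })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    log2_fold = math.log2(fold_threshold)
    passed = (table["log2_ratio"] >= log2_fold) & (table["q"] <= q_threshold)
    table["comparison_pass"] = passed
    selective = table.groupby("gene")["comparison_pass"].all()
    table["selective"] = table["gene"].map(selective)
    return table
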