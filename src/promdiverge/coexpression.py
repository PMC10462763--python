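"""Signed-hybrid weighted co-expression networks and TOM module detection.

The network adjacency between genes i and j is cor(i,j)^beta when the
Pearson correlation is positive and 0 otherwise (signed hybrid), with a zero
diagonal.  The soft power beta is the smallest integer in the candidate
range whose connectivity distribution fits a scale-free topology at the
configured R^2.  Topological overlap similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),  TOM_ii = 1

feeds average-linkage hierarchical clustering on 1 - TOM; a static cut at
the configured height plus a minimum module size yields module assignments
(module 0 = unassigned).  Cross-species module correspondence is assessed by
hypergeometric overlap against a size-matched random-module baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import PromdivergeError, stream_rng

__all__ = [
    "CoexpressionConfig",
    "ModuleAssignment",
    "filter_expressed",
    "pick_soft_threshold",
    "adjacency",
    "adjacency_tom",
    "detect_modules",
    "module_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionConfig:
    powers: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.85
    min_module_size: int = 30
    cut_height: float = 0.95
    min_fraction_expressed: float = 0.5  # gene kept if >= 1 count in this sample fraction

    def __post_init__(self) -> None:
        if any(int(b) != b or b < 1 for b in self.powers):
            raise PromdivergeError("powers must be integers >= 1")
        for name in ("rsq_target", "cut_height", "min_fraction_expressed"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise PromdivergeError(f"{name} must lie in (0, 1]")


@dataclass
class ModuleAssignment:
    modules: pd.Series  # gene -> module id (int, 0 = unassigned)
    sizes: dict[int, int] = field(default_factory=dict)
    target_module: int | None = None

    def genes_in(self, module: int) -> list[str]:
        return list(self.modules.index[self.modules == module])


def filter_expressed(expr: pd.DataFrame, min_fraction: float = 0.5,
                     min_value: float = 1.0) -> pd.DataFrame:
    """Keep genes with >= ``min_value`` in at least ``min_fraction`` of samples."""
    keep = (expr >= min_value).mean(axis=1) >= min_fraction
    return expr.loc[keep]


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    const = expr.std(axis=1, ddof=0) == 0
    if const.any():
        logger.info("dropping %d constant genes", int(const.sum()))
    return expr.loc[~const]


def adjacency(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Signed-hybrid adjacency: cor^beta for positive correlations, else 0."""
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    a = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of log10 frequency vs log10 mean connectivity over bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    freq, edges = np.histogram(k, bins=n_bins)
    xs, ys = [], []
    for b in range(n_bins):
        if freq[b] == 0:
            continue
        in_bin = k[(k >= edges[b]) & (k <= edges[b + 1])]
        xs.append(np.log10(in_bin.mean()))
        ys.append(np.log10(freq[b] / k.size))
    if len(xs) < 3 or len(set(ys)) < 2:
        return 0.0, 0.0
    slope, _inter, r, _p, _se = stats.linregress(xs, ys)
    return float(r**2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame, config: CoexpressionConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power: smallest beta whose scale-free fit R^2 meets
    the target (with a negative slope); falls back to argmax R^2 with a
    warning when none qualifies.  Returns (beta, per-beta diagnostics).
    """
    config = config or CoexpressionConfig()
    expr = _drop_constant(expr)
    if expr.shape[0] < 20 or expr.shape[1] < 8:
        raise PromdivergeError("need >= 20 genes and >= 8 samples")
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    pos = np.where(cor > 0, cor, 0.0)
    np.fill_diagonal(pos, 0.0)
    rows = []
    for beta in config.powers:
        k = (pos**beta).sum(axis=1)
        rsq, slope = _scale_free_fit(k)
        rows.append({"beta": int(beta), "rsq": rsq, "slope": slope,
                     "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows)
    ok = diag[(diag["rsq"] >= config.rsq_target) & (diag["slope"] < 0)]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(diag.loc[diag["rsq"].idxmax(), "beta"])
        logger.warning("no power reached R^2 target %.2f; using argmax beta=%d",
                       config.rsq_target, beta)
    return beta, diag


def adjacency_tom(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Topological overlap similarity of the signed-hybrid network."""
    a = adjacency(expr, beta)
    k = a.sum(axis=1)
    numerator = a @ a + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(
    tom: pd.DataFrame,
    config: CoexpressionConfig | None = None,
    target_gene: str | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than the minimum module size become module 0
    (unassigned); surviving modules are renumbered 1.. by decreasing size
    (ties by smallest member gene) so labels are deterministic.
    """
    config = config or CoexpressionConfig()
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")
    genes = list(tom.index)
    labels = pd.Series(raw, index=genes)
    keep = labels.value_counts()
    keep = keep[keep >= config.min_module_size]
    order = sorted(
        keep.index,
        key=lambda c: (-keep[c], min(g for g, l in labels.items() if l == c)),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    modules = labels.map(lambda c: remap.get(c, 0)).astype(int)
    sizes = modules.value_counts().to_dict()
    target_module = None
    if target_gene is not None:
        if target_gene not in modules.index:
            raise PromdivergeError(f"target gene {target_gene!r} not in TOM")
        target_module = int(modules[target_gene])
    return ModuleAssignment(modules=modules, sizes=sizes, target_module=target_module)


def module_overlap(
    module_a: list[str],
    module_b: list[str],
    universe: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Overlap of two gene modules within a shared universe.

    Reports |A ∩ B|, the one-sided hypergeometric tail p-value, and the mean
    overlap of ``n_draws`` size-matched random module pairs (seeded).
    """
    uni = set(universe)
    if not uni:
        raise PromdivergeError("universe must be non-empty")
    a, b = set(module_a), set(module_b)
    if not a <= uni or not b <= uni:
        raise PromdivergeError("modules must be subsets of the universe")
    n, ka, kb = len(uni), len(a), len(b)
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, n, ka, kb))
    rng = stream_rng(seed, "module-overlap-null")
    uni_arr = np.array(sorted(uni))
    null = np.empty(n_draws)
    for i in range(n_draws):
        da = rng.choice(n, size=ka, replace=False)
        db = rng.choice(n, size=kb, replace=False)
        null[i] = np.intersect1d(da, db).size
    return {
        "overlap": overlap, "p": p,
        "n_a": ka, "n_b": kb, "universe": n,
        "null_mean_overlap": float(null.mean()),
        "expected_overlap": ka * kb / n,
        "n_draws": n_draws,
    }
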