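"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study designs the
pipeline consumes: cross-species promoter sequences evolved under an
equal-rates independent-sites substitution model with a binding motif planted
in one clade; multi-dataset stimulated-vs-control myeloid expression with
per-dataset effects drawn around a true mean with between-dataset spread;
sample-labelled sparse single-cell counts with activated and homeostatic
microglial subpopulations and cell-type-specific genes; and a gene
annotation plus TF-binding intervals with known promoter-window occupancy.
Every generator derives an independent random stream from one global seed,
so outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import sparse

from ._util import PromdivergeError, stream_rng
from .meta import DatasetExpression
from .motifs import MotifMatrix, builtin_motifs
from .phylo import AlignedPromoterSet
from .singlecell import CellMatrix

__all__ = [
    "SimulationConfig",
    "ScreenWorldConfig",
    "ScreenWorld",
    "DEFAULT_SPECIES_TREE",
    "gen_promoters",
    "gen_expression_datasets",
    "gen_sc_counts",
    "gen_annotation_intervals",
    "gen_screen_world",
    "write_sc_counts",
    "read_sc_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 15 mammals mirroring a cross-species promoter panel: a Muroidea clade
# (mouse, rat, Chinese hamster), other rodents, primates, ungulates,
# carnivores and rabbit.  Branch lengths in expected substitutions per site.
DEFAULT_SPECIES_TREE = (
    "(((((Mouse:0.06,Rat:0.06):0.04,Chinese_hamster:0.09)Muroidea:0.10,"
    "(Squirrel:0.12,Guinea_pig:0.13):0.03):0.04,Rabbit:0.15):0.02,"
    "(((Human:0.02,Chimp:0.02):0.02,Macaque:0.04):0.04,Marmoset:0.08):0.05,"
    "(((Cow:0.07,Sheep:0.07):0.03,Pig:0.10):0.03,(Dog:0.09,Cat:0.09):0.03):0.02);"
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    # promoters
    species_tree: str = DEFAULT_SPECIES_TREE
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    substitution_rate_scale: float = 1.0
    planted_motif: str = "AP1"
    planted_clade: str = "Muroidea"
    motif_offset: int = -300  # from the TSS; negative = upstream
    # bulk expression datasets
    n_datasets: int = 10
    genes_per_dataset: int = 200
    samples_per_group: int = 5
    n_planted: int = 20
    theta: float = 1.0  # true mean log2 fold change of planted genes
    tau: float = 0.3  # between-dataset SD of the planted effect
    sigma: float = 0.5  # residual SD (log2 scale)
    n_count_datasets: int = 0  # leading datasets emitted as counts
    # single-cell counts
    sc_samples: int = 8
    sc_cells_per_sample: int = 250
    sc_genes: int = 300
    cell_type_proportions: dict = field(default_factory=lambda: {
        "microglia": 0.35, "astrocyte": 0.25, "neuron": 0.25, "oligodendrocyte": 0.15,
    })
    nb_dispersion: float = 2.0  # NB size; var = mu + mu^2/size; inf => Poisson
    sc_library_sigma: float = 0.3  # log-normal SD of per-cell library factors
    activated_fraction: dict = field(default_factory=lambda: {
        "disease": 0.55, "control": 0.25})
    n_activation_genes: int = 10
    n_homeostatic_genes: int = 5
    n_specific_genes: int = 10
    activation_fold: float = 4.0
    specificity_ratio: float = 8.0
    # gene annotation / TF intervals
    n_annotation_genes: int = 1000
    ap1_occupancy: float = 0.3
    interval_length: int = 300

    def __post_init__(self) -> None:
        if self.samples_per_group < 3:
            raise PromdivergeError("samples_per_group must be >= 3")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise PromdivergeError("cell type proportions must sum to 1")
        for name in ("theta", "tau", "sigma", "substitution_rate_scale"):
            if not np.isfinite(getattr(self, name)):
                raise PromdivergeError(f"{name} must be finite")
        if self.sigma < 0 or self.tau < 0 or self.substitution_rate_scale < 0:
            raise PromdivergeError("scale parameters must be non-negative")

    @property
    def promoter_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream


# ---------------------------------------------------------------------------
# Promoters


def _evolve_jc(parent: np.ndarray, branch: float, rate_scale: float,
               rng: np.random.Generator) -> np.ndarray:
    """One branch of equal-rates substitution: each site changes independently
    with the Jukes-Cantor probability 3/4 (1 - exp(-4/3 b))."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch * rate_scale))
    child = parent.copy()
    flip = rng.random(parent.size) < p_change
    if flip.any():
        # new state uniform among the three other bases
        shift = rng.integers(1, 4, size=int(flip.sum()))
        child[flip] = (child[flip] + shift) % 4
    return child


def gen_promoters(
    config: SimulationConfig,
    motif: MotifMatrix | None = None,
) -> tuple[AlignedPromoterSet, pd.DataFrame]:
    """Evolve one promoter per species leaf and plant a motif in one clade.

    Sequences evolve without indels along the species tree, so the ungapped
    output is already a valid alignment.  A binding-site instance is sampled
    from the motif's column probabilities independently for each leaf of the
    designated clade and written over the sequence at the configured offset
    from the TSS (the TSS sits at index ``promoter_upstream``); no other
    leaf receives a planted site.  Returns the aligned set plus a truth
    table of per-leaf clade membership and planted coordinates.
    """
    if motif is None:
        motif = builtin_motifs()[config.planted_motif]
    rng = stream_rng(config.seed, "promoters")
    tree = dendropy.Tree.get(data=config.species_tree, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=False)
    clade_node = None
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label == config.planted_clade:
            clade_node = node
            break
    if clade_node is None:
        raise PromdivergeError(
            f"clade label {config.planted_clade!r} absent from the species tree")
    clade_leaves = {lf.taxon.label for lf in clade_node.leaf_iter()}
    pos = config.promoter_upstream + config.motif_offset
    if pos < 0 or pos + motif.width > config.promoter_length:
        raise PromdivergeError("planted motif would overrun the promoter window")
    L = config.promoter_length
    root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}

    def walk(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            branch = child.edge.length or 0.0
            child_seq = _evolve_jc(seq, branch, config.substitution_rate_scale, rng)
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    taxa = sorted(seqs)
    # one ancestral gain: a functional (high-scoring) site instance sampled
    # once and conserved across the clade
    site = motif.sample_site(rng, min_score_fraction=0.85)
    truth_rows = []
    sequences = []
    for taxon in taxa:
        arr = seqs[taxon]
        in_clade = taxon in clade_leaves
        if in_clade:
            arr = arr.copy()
            arr[pos : pos + motif.width] = [
                "ACGT".index(b) for b in site]
        sequences.append(bytes(_BASES[arr]).decode("ascii"))
        truth_rows.append({
            "taxon": taxon, "in_clade": in_clade,
            "motif_start": pos if in_clade else -1,
            "motif_end": pos + motif.width if in_clade else -1,
            "motif": config.planted_motif if in_clade else "",
        })
    aln = AlignedPromoterSet(taxa=taxa, sequences=sequences)
    return aln, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Bulk expression datasets


def gen_expression_datasets(
    config: SimulationConfig,
) -> tuple[list[DatasetExpression], pd.DataFrame]:
    """Multi-dataset stimulated-vs-control expression with planted effects.

    Gene g's effect in dataset d is delta_{g,d} ~ Normal(theta_g, tau^2)
    (zero mean and spread for null genes); samples are baseline log2
    expression plus Normal(0, sigma^2) noise, with stimulated samples
    shifted by delta.  The leading ``n_count_datasets`` datasets are emitted
    as Poisson counts around 2^log2-expression, flagged ``counts``.
    """
    rng = stream_rng(config.seed, "expression")
    G, n = config.genes_per_dataset, config.samples_per_group
    genes = [f"gene_{i:04d}" for i in range(G)]
    theta = np.zeros(G)
    tau = np.zeros(G)
    theta[: config.n_planted] = config.theta
    tau[: config.n_planted] = config.tau
    baseline = rng.uniform(4.0, 12.0, size=G)
    datasets: list[DatasetExpression] = []
    truth_rows = []
    for d in range(config.n_datasets):
        ds_id = f"dataset_{d:02d}"
        delta = rng.normal(theta, tau)
        noise = rng.normal(0.0, config.sigma, size=(G, 2 * n))
        mat = baseline[:, None] + noise
        mat[:, n:] += delta[:, None]
        samples = [f"{ds_id}_s{i:02d}" for i in range(2 * n)]
        condition = pd.Series(["control"] * n + ["stimulated"] * n, index=samples)
        platform = "counts" if d < config.n_count_datasets else "log2-array"
        frame = pd.DataFrame(mat, index=genes, columns=samples)
        if platform == "counts":
            frame = pd.DataFrame(
                rng.poisson(np.power(2.0, mat)).astype(float),
                index=genes, columns=samples)
        datasets.append(DatasetExpression(
            dataset_id=ds_id, matrix=frame, condition=condition, platform=platform))
        for g, dl in zip(genes, delta):
            truth_rows.append({"dataset": ds_id, "gene": g, "delta": float(dl)})
    truth = pd.DataFrame(truth_rows)
    truth = truth.merge(
        pd.DataFrame({"gene": genes, "theta": theta, "tau": tau,
                      "planted": theta != 0}),
        on="gene")
    return datasets, truth


# ---------------------------------------------------------------------------
# Single-cell counts


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(dispersion):
        return rng.poisson(mu)
    if dispersion <= 0:
        raise PromdivergeError("NB dispersion (size) must be positive")
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def gen_sc_counts(
    config: SimulationConfig,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Sparse cell-typed, sample-labelled counts with planted structure.

    Cells carry sample, group (disease/control), cell type and microglial
    subcluster labels.  Counts are negative binomial around cell-class means
    scaled by a per-cell library factor.  Planted structure: microglia-
    specific genes have class means ``specificity_ratio`` above every other
    type; activation marker genes rise ``activation_fold``-fold in activated
    microglia (baseline elsewhere), homeostatic marker genes are expressed
    ``activation_fold``-fold above baseline in homeostatic microglia and
    fall back to baseline in activated ones — both marker classes are
    therefore highly expressed in the state they mark, as real microglial
    state markers are; one designated null analogue gene is left untouched
    everywhere.
    """
    if config.sc_samples < 4:
        raise PromdivergeError("need >= 2 samples per group")
    if len(config.cell_type_proportions) < 2:
        raise PromdivergeError("need >= 2 cell types")
    rng = stream_rng(config.seed, "sc-counts")
    G = config.sc_genes
    genes = [f"gene_{i:04d}" for i in range(G)]
    # reserved truth roles at fixed positions after the bulk-planted block
    spec_genes = genes[: config.n_specific_genes]
    act_genes = genes[config.n_specific_genes:
                      config.n_specific_genes + config.n_activation_genes]
    hom_genes = genes[config.n_specific_genes + config.n_activation_genes:
                      config.n_specific_genes + config.n_activation_genes
                      + config.n_homeostatic_genes]
    analog_gene = genes[config.n_specific_genes + config.n_activation_genes
                        + config.n_homeostatic_genes]
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=G).clip(0.05, 50.0)
    types = sorted(config.cell_type_proportions)
    probs = np.array([config.cell_type_proportions[t] for t in types])
    spec_idx = np.array([g in set(spec_genes) for g in genes])
    act_idx = np.array([g in set(act_genes) for g in genes])
    hom_idx = np.array([g in set(hom_genes) for g in genes])
    # canonical state/type markers are well-detected genes in real data;
    # floor their baseline at one count per cell
    marker = spec_idx | act_idx | hom_idx
    base_mean[marker] = base_mean[marker].clip(1.0, None)
    n_half = config.sc_samples // 2
    obs_rows = []
    blocks = []
    for s in range(config.sc_samples):
        sample = f"sample_{s:02d}"
        group = "disease" if s < n_half else "control"
        n_cells = config.sc_cells_per_sample
        cell_types = rng.choice(len(types), size=n_cells, p=probs)
        lib = rng.lognormal(0.0, config.sc_library_sigma, size=n_cells)
        act_p = config.activated_fraction[group]
        for j in range(n_cells):
            ctype = types[cell_types[j]]
            if ctype == "microglia":
                sub = "activated" if rng.random() < act_p else "homeostatic"
            else:
                sub = "none"
            mu = base_mean.copy()
            if ctype == "microglia":
                mu[spec_idx] *= config.specificity_ratio
                if sub == "activated":
                    mu[act_idx] *= config.activation_fold
                else:
                    mu[hom_idx] *= config.activation_fold
            counts = _nb_draw(mu * lib[j], config.nb_dispersion, rng)
            blocks.append(counts)
            obs_rows.append({
                "cell_id": f"{sample}_c{j:04d}", "sample": sample,
                "group": group, "cell_type": ctype, "subcluster": sub,
            })
    matrix = sparse.csr_matrix(np.column_stack(blocks))
    obs = pd.DataFrame(obs_rows).set_index("cell_id", drop=False)
    truth = pd.DataFrame({
        "gene": genes,
        "microglia_specific": spec_idx,
        "activation": act_idx,
        "homeostatic": hom_idx,
        "null_analog": [g == analog_gene for g in genes],
    })
    return CellMatrix(counts=matrix, genes=genes, obs=obs), truth


# ---------------------------------------------------------------------------
# Annotation and TF-binding intervals


def gen_annotation_intervals(
    config: SimulationConfig,
    occupied_genes: set[str] | None = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene TSS table + TF-family BED intervals with known window occupancy.

    Genes are laid out on one chromosome with territories wide enough that
    promoter windows never abut, so occupancy is controlled exactly: an
    AP1-family interval is drawn inside the window of every occupied gene,
    background AP1 intervals land only in window-free intergenic space, and
    non-AP1 (SP1-labelled) intervals may fall anywhere.  Returns
    (annotation, intervals, truth) data frames.
    """
    rng = stream_rng(config.seed, "annotation")
    n = config.n_annotation_genes
    if n < 1:
        raise PromdivergeError("need at least one gene")
    genes = [f"gene_{i:04d}" for i in range(n)]
    territory = 20000
    tss = 10000 + territory * np.arange(n) + rng.integers(-1000, 1000, size=n)
    strand = rng.choice(["+", "-"], size=n)
    if (tss < 0).any():
        raise PromdivergeError("negative coordinates generated")
    if occupied_genes is None:
        occupied = rng.random(n) < config.ap1_occupancy
    else:
        occupied = np.array([g in occupied_genes for g in genes])
    ap1_labels = ["JUN", "JUNB", "JUND", "FOS", "FOSL1", "FOSL2"]
    rows = []
    for i in range(n):
        w_lo = (tss[i] - upstream) if strand[i] == "+" else (tss[i] - downstream + 1)
        w_hi = w_lo + upstream + downstream
        if occupied[i]:
            length = config.interval_length
            start = int(rng.integers(w_lo - length + 1, w_hi))
            rows.append({"chrom": "chr1", "start": max(0, start),
                         "end": start + length,
                         "label": ap1_labels[int(rng.integers(6))]})
        # background AP1 interval safely away from any promoter window
        if rng.random() < 0.5:
            bg = int(territory * i + 14000 + rng.integers(0, 2000))
            rows.append({"chrom": "chr1", "start": bg,
                         "end": bg + config.interval_length,
                         "label": ap1_labels[int(rng.integers(6))]})
        # non-AP1 interval anywhere (never affects occupancy truth)
        if rng.random() < 0.5:
            start = int(rng.integers(max(0, w_lo - 500), w_hi + 500))
            rows.append({"chrom": "chr1", "start": start,
                         "end": start + config.interval_length, "label": "SP1"})
    annotation = pd.DataFrame({
        "gene": genes, "chrom": "chr1", "tss": tss.astype(int), "strand": strand})
    intervals = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end"]).reset_index(drop=True)
    truth = pd.DataFrame({"gene": genes, "occupied": occupied})
    return annotation, intervals, truth


# ---------------------------------------------------------------------------
# The composed screen world


@dataclass
class ScreenWorldConfig:
    """Conditions of the end-to-end biomarker-screen simulation."""

    seed: int = 0
    n_genes: int = 2000
    n_biomarkers: int = 5
    n_decoys_per_class: int = 5
    n_meta_datasets: int = 5
    n_cohorts: int = 3
    samples_per_group: int = 5
    cohort_samples_per_group: int = 10
    theta: float = 2.0
    tau: float = 0.3
    sigma: float = 0.5
    cohort_effect: float = 2.0
    background_occupancy: float = 0.3
    sc_samples: int = 8
    sc_cells_per_sample: int = 250
    specificity_ratio: float = 8.0
    nb_dispersion: float = 2.0


@dataclass
class ScreenWorld:
    annotation: pd.DataFrame
    intervals: pd.DataFrame
    meta_datasets: list
    cohorts: list
    cells: CellMatrix
    truth: pd.DataFrame
    config: ScreenWorldConfig


def gen_screen_world(config: ScreenWorldConfig) -> ScreenWorld:
    """Synthetic inputs for the four-stage screen with single-stage decoys.

    Roles: ``biomarker`` genes pass every stage; ``decoy_ap1`` lack the
    promoter AP1 interval but pass everything else; ``decoy_meta`` are AP1-
    occupied but null in the meta-analysis; ``decoy_cohort`` fail (are null
    in) one disease cohort; ``decoy_specificity`` pass stages 1-3 but are
    pan-cellular.  All remaining genes are background with random occupancy
    and null effects.
    """
    rng = stream_rng(config.seed, "screen-world")
    n = config.n_genes
    genes = [f"gene_{i:04d}" for i in range(n)]
    k, m = config.n_biomarkers, config.n_decoys_per_class
    roles = np.array(["background"] * n, dtype=object)
    roles[:k] = "biomarker"
    roles[k : k + m] = "decoy_ap1"
    roles[k + m : k + 2 * m] = "decoy_meta"
    roles[k + 2 * m : k + 3 * m] = "decoy_cohort"
    roles[k + 3 * m : k + 4 * m] = "decoy_specificity"
    role_of = dict(zip(genes, roles))

    # --- stage-1 truth: AP1 window occupancy -------------------------------
    occupied = {
        g for g in genes
        if role_of[g] in ("biomarker", "decoy_meta", "decoy_cohort",
                          "decoy_specificity")
    }
    background = [g for g in genes if role_of[g] == "background"]
    bg_occ = stream_rng(config.seed, "screen-bg-occ").random(len(background))
    occupied |= {g for g, r in zip(background, bg_occ)
                 if r < config.background_occupancy}
    ann_cfg = SimulationConfig(seed=config.seed, n_annotation_genes=n)
    annotation, intervals, occ_truth = gen_annotation_intervals(
        ann_cfg, occupied_genes=occupied)

    # --- stage-2 inputs: meta-analysis datasets ----------------------------
    theta = np.zeros(n)
    up_in_meta = np.isin(roles, ["biomarker", "decoy_ap1", "decoy_cohort",
                                 "decoy_specificity"])
    theta[up_in_meta] = config.theta
    bulk_cfg = SimulationConfig(
        seed=config.seed, n_datasets=config.n_meta_datasets,
        genes_per_dataset=n, samples_per_group=config.samples_per_group,
        n_planted=0, theta=config.theta, tau=config.tau, sigma=config.sigma)
    meta_datasets, _ = gen_expression_datasets(bulk_cfg)
    # re-plant effects per role (the stock generator plants a prefix block)
    erng = stream_rng(config.seed, "screen-meta-effects")
    n_s = config.samples_per_group
    for ds in meta_datasets:
        delta = erng.normal(theta, np.where(theta != 0, config.tau, 0.0))
        ds.matrix.iloc[:, n_s:] = (
            ds.matrix.iloc[:, n_s:].to_numpy() + delta[:, None])

    # --- stage-3 inputs: disease cohorts -----------------------------------
    crng = stream_rng(config.seed, "screen-cohorts")
    up_in_cohorts = np.isin(roles, ["biomarker", "decoy_ap1", "decoy_meta",
                                    "decoy_specificity", "decoy_cohort"])
    cohorts = []
    nc = config.cohort_samples_per_group
    baseline = crng.uniform(4.0, 12.0, size=n)
    for c in range(config.n_cohorts):
        cid = f"cohort_{c}"
        effect = np.where(up_in_cohorts, config.cohort_effect, 0.0)
        if c == 0:  # decoy_cohort genes are null in the first cohort
            effect = np.where(roles == "decoy_cohort", 0.0, effect)
        mat = baseline[:, None] + crng.normal(0, config.sigma, size=(n, 2 * nc))
        mat[:, nc:] += effect[:, None]
        samples = [f"{cid}_s{i:02d}" for i in range(2 * nc)]
        condition = pd.Series(["control"] * nc + ["stimulated"] * nc, index=samples)
        cohorts.append(DatasetExpression(
            dataset_id=cid,
            matrix=pd.DataFrame(mat, index=genes, columns=samples),
            condition=condition))

    # --- stage-4 inputs: single-cell world for specificity -----------------
    selective_roles = ("biomarker", "decoy_ap1", "decoy_meta", "decoy_cohort")
    srng = stream_rng(config.seed, "screen-sc")
    spec_idx = np.isin(roles, selective_roles)
    base_mean = srng.lognormal(0.5, 0.8, size=n).clip(0.2, 50.0)
    types = ["astrocyte", "microglia", "neuron", "oligodendrocyte"]
    probs = np.array([0.25, 0.35, 0.25, 0.15])
    obs_rows, blocks = [], []
    n_half = config.sc_samples // 2
    for s in range(config.sc_samples):
        sample = f"sample_{s:02d}"
        group = "disease" if s < n_half else "control"
        cell_types = srng.choice(4, size=config.sc_cells_per_sample, p=probs)
        lib = srng.lognormal(0.0, 0.3, size=config.sc_cells_per_sample)
        for j in range(config.sc_cells_per_sample):
            ctype = types[cell_types[j]]
            mu = base_mean.copy()
            if ctype == "microglia":
                mu[spec_idx] *= config.specificity_ratio
            counts = _nb_draw(mu * lib[j], config.nb_dispersion, srng)
            blocks.append(counts)
            obs_rows.append({
                "cell_id": f"{sample}_c{j:04d}", "sample": sample,
                "group": group, "cell_type": ctype, "subcluster": "none"})
    cells = CellMatrix(
        counts=sparse.csr_matrix(np.column_stack(blocks)),
        genes=genes,
        obs=pd.DataFrame(obs_rows).set_index("cell_id", drop=False))

    truth = pd.DataFrame({
        "gene": genes, "role": roles,
        "occupied": occ_truth["occupied"].to_numpy(),
        "meta_up": up_in_meta,
        "all_cohorts_up": up_in_cohorts & (roles != "decoy_cohort"),
        "selective": spec_idx,
    })
    return ScreenWorld(annotation=annotation, intervals=intervals,
                       meta_datasets=meta_datasets, cohorts=cohorts,
                       cells=cells, truth=truth, config=config)


# ---------------------------------------------------------------------------
# File round-trips (MTX triplet convention)


def write_sc_counts(cells: CellMatrix, out_dir) -> None:
    """Write counts as MTX + features/barcodes/metadata TSVs."""
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", sparse.coo_matrix(cells.counts))
    pd.Series(cells.genes).to_csv(out / "features.tsv", sep="\t",
                                  index=False, header=False)
    cells.obs["cell_id"].to_csv(out / "barcodes.tsv", sep="\t",
                                index=False, header=False)
    cells.obs.to_csv(out / "metadata.tsv", sep="\t", index=False)


def read_sc_counts(in_dir) -> CellMatrix:
    from scipy.io import mmread

    path = Path(in_dir)
    counts = sparse.csr_matrix(mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.read_csv(path / "metadata.tsv", sep="\t").set_index(
        "cell_id", drop=False)
    return CellMatrix(counts=counts, genes=genes, obs=obs)
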