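"""Multi-stage AP1-promoter biomarker screen.

Stage 1 keeps genes whose promoter window (2 kb upstream to 1 kb downstream
of the TSS, strand-aware) overlaps at least one AP1-family transcription-
factor binding interval.  Stage 2 intersects with genes significantly
upregulated in the cross-dataset random-effects meta-analysis.  Stage 3
requires significant upregulation in every supplied disease cohort.  Stage 4
requires cell-type selectivity for the target cell type (microglia).  The
surviving candidates are ranked by pooled meta-analytic effect size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import PromdivergeError
from .meta import EffectEstimate, MetaResult

__all__ = [
    "GeneAnnotation",
    "IntervalSet",
    "ScreenThresholds",
    "ScreenResult",
    "AP1_FAMILY",
    "map_binding_to_genes",
    "run_screen",
    "screen_report",
]

AP1_FAMILY = ("JUN", "JUNB", "JUND", "FOS", "FOSL1", "FOSL2")


@dataclass
class GeneAnnotation:
    """Gene table: id, chromosome, 0-based TSS coordinate, strand."""

    table: pd.DataFrame  # columns: gene, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "tss", "strand"}
        if not required <= set(self.table.columns):
            raise PromdivergeError(f"annotation needs columns {sorted(required)}")
        if self.table["gene"].duplicated().any():
            raise PromdivergeError("gene ids must be unique")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise PromdivergeError("strand must be + or -")
        if (self.table["tss"] < 0).any():
            raise PromdivergeError("negative TSS coordinates")

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class IntervalSet:
    """BED-style intervals (chrom, start, end, TF label), 0-based half-open."""

    table: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "label"}
        if not required <= set(self.table.columns):
            raise PromdivergeError(f"intervals need columns {sorted(required)}")
        if (self.table["start"] >= self.table["end"]).any():
            raise PromdivergeError("intervals must satisfy start < end")
        if (self.table["start"] < 0).any():
            raise PromdivergeError("negative interval coordinates")

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        tbl = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "label"])
        return cls(tbl)

    def to_bed(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class ScreenThresholds:
    upstream: int = 2000
    downstream: int = 1000
    meta_q: float = 0.05
    cohort_q: float = 0.05
    tf_family: tuple[str, ...] = AP1_FAMILY


@dataclass
class ScreenResult:
    flags: pd.DataFrame  # per gene: stage flags, candidate, rank, pooled_logfc
    stage_counts: dict[str, int]
    provenance: dict = field(default_factory=dict)

    @property
    def candidates(self) -> list[str]:
        sel = self.flags[self.flags["candidate"]]
        return list(sel.sort_values("rank")["gene"])


def promoter_window(tss: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Strand-aware genomic promoter interval, 0-based half-open."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def map_binding_to_genes(
    intervals: IntervalSet,
    genes: GeneAnnotation,
    upstream: int = 2000,
    downstream: int = 1000,
    tf_family: Sequence[str] = AP1_FAMILY,
) -> tuple[set[str], dict[str, list[tuple[int, int, str]]]]:
    """Genes whose promoter window overlaps >= 1 bp of a family TF interval.

    Returns the flagged gene set plus, per flagged gene, the supporting
    intervals.  Unknown labels in ``tf_family`` (absent from the interval
    set's label vocabulary) raise a labelled error.
    """
    known = set(intervals.table["label"].unique()) | set(AP1_FAMILY)
    unknown = [t for t in tf_family if t not in known]
    if unknown:
        raise PromdivergeError(f"TF labels not present in interval set: {unknown}")
    fam = intervals.table[intervals.table["label"].isin(set(tf_family))]
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in fam.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), lbl)
            for s, e, lbl in zip(sub["start"], sub["end"], sub["label"]))
    flagged: set[str] = set()
    support: dict[str, list[tuple[int, int, str]]] = {}
    for row in genes.table.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        w_start, w_end = promoter_window(int(row.tss), row.strand, upstream, downstream)
        hits = tree.overlap(w_start, w_end)
        if hits:
            flagged.add(row.gene)
            support[row.gene] = sorted(
                (iv.begin, iv.end, iv.data) for iv in hits)
    return flagged, support


def run_screen(
    ap1_genes: set[str],
    meta_results: Sequence[MetaResult],
    cohort_effects: Mapping[str, Sequence[EffectEstimate]],
    specificity: Mapping[str, bool],
    thresholds: ScreenThresholds | None = None,
) -> ScreenResult:
    """Intersect the four screen stages and rank the surviving candidates.

    ``cohort_effects`` maps cohort name -> per-gene effect estimates;
    ``specificity`` maps gene -> cell-type-selective flag.  Stage sets are
    nested by construction, so stage counts are monotone non-increasing.
    """
    thresholds = thresholds or ScreenThresholds()
    meta_by_gene = {m.gene: m for m in meta_results}
    universe = sorted(set(meta_by_gene) | set(ap1_genes))
    stage1 = set(ap1_genes)
    stage2 = {
        g for g in stage1
        if g in meta_by_gene
        and meta_by_gene[g].pooled > 0
        and meta_by_gene[g].q <= thresholds.meta_q
    }
    cohort_pass: dict[str, set[str]] = {}
    for cohort, effects in cohort_effects.items():
        by_gene = {e.gene: e for e in effects}
        if not set(by_gene) & set(universe):
            raise PromdivergeError(f"cohort {cohort!r} shares no genes with the screen")
        cohort_pass[cohort] = {
            g for g, e in by_gene.items()
            if e.logfc > 0 and e.q <= thresholds.cohort_q
        }
    stage3 = {g for g in stage2
              if all(g in passed for passed in cohort_pass.values())}
    stage4 = {g for g in stage3 if specificity.get(g, False)}
    rows = []
    for g in universe:
        pooled = meta_by_gene[g].pooled if g in meta_by_gene else float("nan")
        rows.append({
            "gene": g,
            "ap1_window": g in stage1,
            "meta_up": g in stage2,
            **{f"up_in_{c}": g in cohort_pass[c] for c in cohort_pass},
            "cell_selective": bool(specificity.get(g, False)),
            "candidate": g in stage4,
            "pooled_logfc": pooled,
        })
    flags = pd.DataFrame(rows)
    flags["rank"] = (
        flags["pooled_logfc"].where(flags["candidate"]).rank(ascending=False)
    )
    stage_counts = {
        "stage1_ap1": len(stage1), "stage2_meta_up": len(stage2),
        "stage3_all_cohorts": len(stage3), "stage4_selective": len(stage4),
    }
    provenance = {
        "thresholds": {
            "upstream": thresholds.upstream, "downstream": thresholds.downstream,
            "meta_q": thresholds.meta_q, "cohort_q": thresholds.cohort_q,
            "tf_family": list(thresholds.tf_family),
        },
        "cohorts": sorted(cohort_effects),
        "n_universe": len(universe),
    }
    return ScreenResult(flags=flags, stage_counts=stage_counts, provenance=provenance)


def screen_report(result: ScreenResult, out_tsv, out_manifest, seed: int | None = None) -> None:
    """Write the per-gene flag table (TSV) and the JSON run manifest."""
    result.flags.to_csv(out_tsv, sep="\t", index=False)
    manifest = {
        "stage_counts": result.stage_counts,
        "candidates": result.candidates,
        "provenance": result.provenance,
        "seed": seed,
    }
    with open(out_manifest, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
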