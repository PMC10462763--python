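"""End-to-end composition: synthetic screen world -> four-stage screen result."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .meta import meta_analyse, per_dataset_de
from .screen import (GeneAnnotation, IntervalSet, ScreenResult,
                     ScreenThresholds, map_binding_to_genes, run_screen)
from .simulate import ScreenWorld
from .singlecell import pseudobulk, specificity_table


@dataclass
class ScreenPipelineOutput:
    result: ScreenResult
    meta_table: pd.DataFrame
    specificity: pd.DataFrame


def run_screen_pipeline(
    world: ScreenWorld,
    thresholds: ScreenThresholds | None = None,
) -> ScreenPipelineOutput:
    """Run every analysis stage of the biomarker screen on a synthetic world.

    Computes promoter-window AP1 occupancy from the interval set, per-dataset
    differential expression and the random-effects meta-analysis across the
    stimulation datasets, per-cohort differential expression, pseudobulk
    cell-type specificity, and finally the staged intersection.
    """
    thresholds = thresholds or ScreenThresholds()
    annotation = GeneAnnotation(world.annotation)
    intervals = IntervalSet(world.intervals)
    ap1_genes, _support = map_binding_to_genes(
        intervals, annotation,
        upstream=thresholds.upstream, downstream=thresholds.downstream,
        tf_family=thresholds.tf_family)
    per_gene: dict[str, list] = {}
    for ds in world.meta_datasets:
        for eff in per_dataset_de(ds):
            per_gene.setdefault(eff.gene, []).append(eff)
    meta_results = meta_analyse(per_gene)
    cohort_effects = {ds.dataset_id: per_dataset_de(ds) for ds in world.cohorts}
    pb = pseudobulk(world.cells)
    spec = specificity_table(pb, world.cells.genes, target_type="microglia")
    selective = spec.drop_duplicates("gene").set_index("gene")["selective"]
    result = run_screen(
        ap1_genes=ap1_genes,
        meta_results=meta_results,
        cohort_effects=cohort_effects,
        specificity=selective.to_dict(),
        thresholds=thresholds,
    )
    meta_table = pd.DataFrame([vars(m) for m in meta_results])
    return ScreenPipelineOutput(result=result, meta_table=meta_table,
                                specificity=spec)
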