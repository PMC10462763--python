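"""Ground-truth and determinism properties of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from promdiverge._util import PromdivergeError
from promdiverge.motifs import builtin_motifs, scan_sequence
from promdiverge.simulate import (ScreenWorldConfig, SimulationConfig,
                                  gen_annotation_intervals,
                                  gen_expression_datasets, gen_promoters,
                                  gen_sc_counts, gen_screen_world,
                                  read_sc_counts, write_sc_counts)


class TestPromoters:
    def test_zero_rate_leaves_match_root_outside_clade(self):
        cfg = SimulationConfig(seed=1, substitution_rate_scale=0.0)
        aln, truth = gen_promoters(cfg)
        outside = [s for t, s in zip(aln.taxa, aln.sequences)
                   if not truth.set_index("taxon").loc[t, "in_clade"]]
        assert len(set(outside)) == 1  # all identical to the root sequence

    def test_planted_motif_recovered_by_scanning(self):
        m = builtin_motifs()["AP1"]
        clade_all, fp = 0, []
        for seed in range(20):
            aln, truth = gen_promoters(SimulationConfig(seed=seed))
            info = truth.set_index("taxon")
            in_clade = [t for t in aln.taxa if info.loc[t, "in_clade"]]
            out = [t for t in aln.taxa if not info.loc[t, "in_clade"]]
            seqs = dict(zip(aln.taxa, aln.sequences))
            clade_all += all(
                any(h.start == info.loc[t, "motif_start"]
                    for h in scan_sequence(seqs[t], m, 0.8 * m.max_score))
                for t in in_clade)
            fp.append(np.mean([bool(scan_sequence(seqs[t], m, 0.9 * m.max_score))
                               for t in out]))
        assert clade_all == 20  # every clade leaf carries the planted site
        assert np.mean(fp) <= 0.05  # stringent threshold: rare chance hits

    def test_byte_identical_under_fixed_seed(self):
        a, _ = gen_promoters(SimulationConfig(seed=9))
        b, _ = gen_promoters(SimulationConfig(seed=9))
        assert a.to_fasta() == b.to_fasta()

    def test_unknown_clade_rejected(self):
        with pytest.raises(PromdivergeError):
            gen_promoters(SimulationConfig(planted_clade="Atlantis"))

    def test_motif_overrun_rejected(self):
        with pytest.raises(PromdivergeError):
            gen_promoters(SimulationConfig(motif_offset=499))


class TestExpressionDatasets:
    def test_noise_free_group_difference_equals_theta(self):
        cfg = SimulationConfig(seed=2, sigma=0.0, tau=0.0, n_datasets=2,
                               genes_per_dataset=10, n_planted=3, theta=1.25)
        datasets, truth = gen_expression_datasets(cfg)
        for ds in datasets:
            stim = ds.condition == "stimulated"
            diff = (ds.matrix.loc[:, stim.to_numpy()].mean(axis=1)
                    - ds.matrix.loc[:, (~stim).to_numpy()].mean(axis=1))
            np.testing.assert_allclose(diff.iloc[:3], 1.25, atol=1e-12)
            np.testing.assert_allclose(diff.iloc[3:], 0.0, atol=1e-12)

    def test_column_permutation_leaves_group_means_unchanged(self, rng):
        (ds,), _ = gen_expression_datasets(
            SimulationConfig(seed=3, n_datasets=1, genes_per_dataset=20))
        perm = rng.permutation(ds.matrix.shape[1])
        shuffled = ds.matrix.iloc[:, perm]
        cond = ds.condition.iloc[perm]
        for level in ["control", "stimulated"]:
            a = ds.matrix.loc[:, (ds.condition == level).to_numpy()].mean(axis=1)
            b = shuffled.loc[:, (cond == level).to_numpy()].mean(axis=1)
            np.testing.assert_allclose(a, b)

    def test_counts_platform_flag(self):
        cfg = SimulationConfig(seed=4, n_datasets=3, n_count_datasets=1,
                               genes_per_dataset=10)
        datasets, _ = gen_expression_datasets(cfg)
        assert datasets[0].platform == "counts"
        assert all(d.platform == "log2-array" for d in datasets[1:])
        assert (datasets[0].matrix.to_numpy() % 1 == 0).all()

    def test_non_finite_config_rejected(self):
        with pytest.raises(PromdivergeError):
            SimulationConfig(theta=float("nan"))


class TestScCounts:
    def test_total_count_conservation(self):
        cells, _ = gen_sc_counts(SimulationConfig(
            seed=5, sc_samples=4, sc_cells_per_sample=50))
        per_cell = np.asarray(cells.counts.sum(axis=0)).ravel()
        assert cells.counts.sum() == per_cell.sum()

    def test_poisson_limit_variance_to_mean(self):
        """With infinite dispersion and no library spread, null-gene counts
        within one cell class are Poisson: var/mean within 10% of 1."""
        ratios = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, nb_dispersion=float("inf"),
                                   sc_library_sigma=0.0, sc_samples=4,
                                   sc_cells_per_sample=100)
            cells, truth = gen_sc_counts(cfg)
            null = ~(truth.microglia_specific | truth.activation
                     | truth.homeostatic)
            neurons = (cells.obs["cell_type"] == "neuron").to_numpy()
            X = np.asarray(cells.counts.todense(), dtype=float)
            sel = X[np.ix_(null.to_numpy(), neurons)]
            vm = sel.var(axis=1, ddof=1) / np.maximum(sel.mean(axis=1), 1e-9)
            ratios.append(np.median(vm))
        assert abs(np.mean(ratios) - 1.0) <= 0.10

    def test_activation_genes_higher_in_activated_subcluster(self):
        hits = 0
        for seed in range(20):
            cells, truth = gen_sc_counts(SimulationConfig(
                seed=seed, sc_samples=4, sc_cells_per_sample=100))
            X = np.asarray(cells.counts.todense(), dtype=float)
            act_cells = (cells.obs["subcluster"] == "activated").to_numpy()
            hom_cells = (cells.obs["subcluster"] == "homeostatic").to_numpy()
            act_genes = truth.activation.to_numpy()
            hits += (X[np.ix_(act_genes, act_cells)].mean()
                     > X[np.ix_(act_genes, hom_cells)].mean())
        assert hits >= 19  # >= 95% of seeds

    def test_specific_genes_enriched_in_microglia(self):
        cells, truth = gen_sc_counts(SimulationConfig(
            seed=6, sc_samples=4, sc_cells_per_sample=100))
        X = np.asarray(cells.counts.todense(), dtype=float)
        spec = truth.microglia_specific.to_numpy()
        micro = (cells.obs["cell_type"] == "microglia").to_numpy()
        for other in ["neuron", "astrocyte", "oligodendrocyte"]:
            mask = (cells.obs["cell_type"] == other).to_numpy()
            assert (X[np.ix_(spec, micro)].mean()
                    > 2 * X[np.ix_(spec, mask)].mean())

    def test_bad_dispersion_rejected(self):
        with pytest.raises(PromdivergeError):
            gen_sc_counts(SimulationConfig(nb_dispersion=-1.0, sc_samples=4,
                                           sc_cells_per_sample=10))

    def test_mtx_round_trip(self, tmp_path):
        cells, _ = gen_sc_counts(SimulationConfig(
            seed=7, sc_samples=4, sc_cells_per_sample=30))
        write_sc_counts(cells, tmp_path / "sc")
        back = read_sc_counts(tmp_path / "sc")
        assert (back.counts != cells.counts).nnz == 0
        assert back.genes == cells.genes
        pd.testing.assert_frame_equal(
            back.obs.reset_index(drop=True),
            cells.obs.reset_index(drop=True))


class TestAnnotationIntervals:
    def test_occupied_genes_always_overlap(self):
        cfg = SimulationConfig(seed=8, n_annotation_genes=300)
        annotation, intervals, truth = gen_annotation_intervals(cfg)
        from promdiverge.screen import (AP1_FAMILY, GeneAnnotation,
                                        IntervalSet, map_binding_to_genes)
        flagged, _ = map_binding_to_genes(
            IntervalSet(intervals), GeneAnnotation(annotation))
        assert set(truth[truth.occupied].gene) <= flagged

    def test_bed_byte_determinism(self):
        cfg = SimulationConfig(seed=9, n_annotation_genes=100)
        _, iv1, _ = gen_annotation_intervals(cfg)
        _, iv2, _ = gen_annotation_intervals(cfg)
        assert iv1.to_csv(sep="\t", index=False) == iv2.to_csv(sep="\t", index=False)

    def test_zero_genes_rejected(self):
        with pytest.raises(PromdivergeError):
            gen_annotation_intervals(SimulationConfig(n_annotation_genes=0))


class TestScreenWorld:
    def test_truth_roles_are_consistent(self):
        world = gen_screen_world(ScreenWorldConfig(seed=1, n_genes=200))
        t = world.truth
        assert (t.loc[t.role == "biomarker",
                      ["occupied", "meta_up", "all_cohorts_up", "selective"]]
                .all().all())
        assert not t.loc[t.role == "decoy_ap1", "occupied"].any()
        assert not t.loc[t.role == "decoy_meta", "meta_up"].any()
        assert not t.loc[t.role == "decoy_cohort", "all_cohorts_up"].any()
        assert not t.loc[t.role == "decoy_specificity", "selective"].any()

    def test_generators_draw_independent_streams(self):
        """Changing single-cell parameters must not perturb the promoter or
        expression outputs generated under the same seed."""
        a = gen_screen_world(ScreenWorldConfig(seed=2, n_genes=150))
        b = gen_screen_world(ScreenWorldConfig(seed=2, n_genes=150,
                                               sc_cells_per_sample=100))
        pd.testing.assert_frame_equal(a.meta_datasets[0].matrix,
                                      b.meta_datasets[0].matrix)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
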