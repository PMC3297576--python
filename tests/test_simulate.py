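import numpy as np
import pytest

from isletseq.annotation import build_segments
from isletseq.quantify import deconvolve_gene
from isletseq.simulate import (
    SimConfig,
    baseline_truth,
    expected_segment_counts,
    inject_effects,
    simulate_annotation,
    simulate_counts,
    simulate_dataset,
)


def small_config(**overrides):
    defaults = dict(n_genes=20, n_sample_pairs=2, library_size_range=(10_000, 20_000),
                    background_tissues=("liver",), seed=5)
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestSimulateAnnotation:
    def test_all_single_isoform(self):
        genes = simulate_annotation(small_config(frac_multi_isoform=0.0, n_genes=10))
        assert len(genes) == 10
        assert all(len(g.transcripts) == 1 for g in genes)

    def test_all_multi_isoform_have_distinguishing_segment(self):
        genes = simulate_annotation(small_config(frac_multi_isoform=1.0, n_genes=10))
        for gene in genes:
            assert len(gene.transcripts) >= 2
            segs = build_segments(gene)
            # at least one segment with a proper member subset
            assert any(len(s.members) < len(gene.transcripts) for s in segs)

    def test_multi_isoform_designs_are_identifiable(self):
        genes = simulate_annotation(small_config(frac_multi_isoform=1.0, n_genes=30, seed=9))
        from isletseq.quantify import design_matrix

        for gene in genes:
            a = design_matrix(gene, build_segments(gene))
            assert np.linalg.matrix_rank(a) == len(gene.transcripts)

    def test_same_seed_identical(self):
        cfg = small_config()
        a = simulate_annotation(cfg)
        b = simulate_annotation(cfg)
        assert a == b


class TestExpectedCounts:
    def test_hand_computed_linear_algebra(self, two_isoform_gene, two_isoform_segments):
        """theta=(2,4) reads/base on the skipped-exon segmentation gives
        expected counts (600, 100, 300)."""
        expected = expected_segment_counts(two_isoform_gene, two_isoform_segments, (2.0, 4.0))
        assert expected.tolist() == [600.0, 100.0, 300.0]

    def test_scaling_leaves_proportions_unchanged(self, two_isoform_gene, two_isoform_segments):
        e1 = expected_segment_counts(two_isoform_gene, two_isoform_segments, (2.0, 4.0))
        e2 = expected_segment_counts(two_isoform_gene, two_isoform_segments, (4.0, 8.0))
        np.testing.assert_allclose(e2 / e2.sum(), e1 / e1.sum())


class TestInjectEffects:
    def test_no_de_means_equal_totals(self):
        cfg = small_config(frac_de_genes=0.0, frac_as_genes=0.0)
        genes = simulate_annotation(cfg)
        truth = inject_effects(baseline_truth(genes, cfg), genes, cfg)
        for gt in truth.genes.values():
            assert gt.cytokine_theta == gt.control_theta
            assert gt.de_sign == 0 and not gt.as_flag

    def test_log2fc_scales_gene_total(self):
        cfg = small_config(frac_de_genes=1.0, frac_as_genes=0.0,
                           de_log2fc_magnitude_range=(2.0, 2.0), de_up_probability=1.0)
        genes = simulate_annotation(cfg)
        truth = inject_effects(baseline_truth(genes, cfg), genes, cfg)
        for gene in genes:
            gt = truth.genes[gene.gene_id]
            assert gt.log2fc == 2.0
            ctl = sum(t.length_bp * th for t, th in zip(gene.transcripts, gt.control_theta))
            cyt = sum(t.length_bp * th for t, th in zip(gene.transcripts, gt.cytokine_theta))
            assert cyt == pytest.approx(4.0 * ctl)

    def test_as_shift_preserves_gene_total_and_moves_si(self):
        cfg = small_config(frac_multi_isoform=1.0, frac_de_genes=0.0, frac_as_genes=1.0,
                           as_shift=0.3, n_genes=15)
        genes = simulate_annotation(cfg)
        truth = inject_effects(baseline_truth(genes, cfg), genes, cfg)
        shifted = 0
        for gene in genes:
            gt = truth.genes[gene.gene_id]
            ctl = sum(t.length_bp * th for t, th in zip(gene.transcripts, gt.control_theta))
            cyt = sum(t.length_bp * th for t, th in zip(gene.transcripts, gt.cytokine_theta))
            assert cyt == pytest.approx(ctl, rel=1e-9)  # AS does not change totals
            if gt.as_flag:
                shifted += 1
                si_ctl = np.array(gt.splice_index("control"))
                si_cyt = np.array(gt.splice_index("cytokine"))
                assert np.max(np.abs(si_cyt - si_ctl)) == pytest.approx(0.3, abs=1e-9)
        assert shifted > 0

    def test_even_split_shift(self, two_isoform_gene):
        """SI (0.5, 0.5) shifted by 0.3 becomes (0.8, 0.2) with the gene
        total preserved."""
        from isletseq.simulate import _shift_splice_index

        # theta giving SI = (0.5, 0.5): theta proportional per transcript
        theta = (1.0, 1.0)
        shifted = _shift_splice_index(two_isoform_gene, theta, 0, 0.3)
        total = sum(shifted)
        assert shifted[0] / total == pytest.approx(0.8)
        assert shifted[1] / total == pytest.approx(0.2)
        lengths = [t.length_bp for t in two_isoform_gene.transcripts]
        assert sum(l * t for l, t in zip(lengths, shifted)) == pytest.approx(
            sum(l * t for l, t in zip(lengths, theta))
        )

    def test_infeasible_shift_skipped_with_warning(self):
        # a 0.99 shift is infeasible for nearly every Dirichlet draw
        cfg = small_config(frac_as_genes=1.0, as_shift=0.99, frac_multi_isoform=1.0,
                           n_genes=10)
        genes = simulate_annotation(cfg)
        base = baseline_truth(genes, cfg)
        with pytest.warns(UserWarning, match="infeasible"):
            truth = inject_effects(base, genes, cfg)
        assert any(not gt.as_flag for gt in truth.genes.values())


class TestSimulateCounts:
    def test_conservation_and_reproducibility(self):
        cfg = small_config()
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        for s1, s2 in zip(d1.samples, d2.samples):
            assert s1 == s2
            assert sum(s1.counts.values()) == s1.total_mapped_reads

    def test_expected_counts_mode_matches_deconvolution_truth(self):
        """Noiseless counts deconvolve back to abundances proportional to
        the generator's truth."""
        cfg = small_config(frac_multi_isoform=1.0, n_genes=5,
                           library_size_range=(1_000_000, 1_000_000),
                           frac_de_genes=0.0, frac_as_genes=0.0)
        ds = simulate_dataset(cfg, expected_counts=True)
        sample = ds.samples[0]
        from isletseq.annotation import segment_id

        for gene in ds.genes:
            segs = ds.segments[gene.gene_id]
            counts = [sample.counts[segment_id(gene, s)] for s in segs]
            theta, _, _, identifiable = deconvolve_gene(gene, segs, counts)
            assert identifiable
            truth = np.array(ds.truth.genes[gene.gene_id].control_theta)
            if theta.sum() == 0:
                continue
            np.testing.assert_allclose(
                theta / theta.sum(), truth / truth.sum(), atol=5e-4
            )

    def test_law_of_large_numbers(self):
        # donor variability off so expectations derive from the truth alone
        cfg = small_config(n_genes=5, library_size_range=(2_000_000, 2_000_000),
                           donor_log_sd=0.0, donor_gene_sd=0.0)
        ds = simulate_dataset(cfg)
        sample = ds.samples[0]
        from isletseq.annotation import segment_id
        from isletseq.simulate import _sample_intensities

        profile = {
            gid: tuple(gt.control_theta) for gid, gt in ds.truth.genes.items()
        }
        # donor factor cancels in proportions
        seg_ids, lam = _sample_intensities(ds.genes, ds.segments, profile)
        expected = lam / lam.sum() * sample.total_mapped_reads
        observed = np.array([sample.counts[sid] for sid in seg_ids], dtype=float)
        mask = expected >= 1000
        assert mask.any()
        np.testing.assert_allclose(observed[mask], expected[mask], rtol=0.1)

    def test_all_zero_abundance_is_error(self):
        cfg = small_config(n_genes=3)
        genes = simulate_annotation(cfg)
        from isletseq.annotation import build_segments as bs
        from isletseq.simulate import GeneTruth, GroundTruth

        segments = {g.gene_id: bs(g) for g in genes}
        zero = GroundTruth(
            genes={
                g.gene_id: GeneTruth(
                    g.gene_id,
                    tuple(0.0 for _ in g.transcripts),
                    tuple(0.0 for _ in g.transcripts),
                )
                for g in genes
            },
            background_theta={"liver": {g.gene_id: tuple(0.0 for _ in g.transcripts) for g in genes}},
        )
        with pytest.raises(ValueError, match="all-zero"):
            simulate_counts(genes, segments, zero, cfg)
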