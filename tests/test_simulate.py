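"""Synthetic genome, chromatin placement, fragment emission and gene
metrics: ground-truth recovery and determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnasefrag import simulate as sim
from mnasefrag.io import IntervalFeature


def at_fraction(seq):
    return (seq.count("A") + seq.count("T")) / len(seq)


class TestGenome:
    def test_centromere_at_fraction_recovered(self):
        spec = sim.GenomeSpec(
            {"c": 1000},
            [sim.FeaturePlacement("centromere", "c", 400, 600, at_fraction=0.9)],
        )
        g = sim.build_genome(spec, 7)
        assert 0.85 <= at_fraction(g.sequences["c"][400:600]) <= 0.95

    def test_background_gc_fraction(self):
        g = sim.build_genome(sim.GenomeSpec({"c": 50_000}, background_gc=0.38), 7)
        gc = 1 - at_fraction(g.sequences["c"])
        assert abs(gc - 0.38) < 0.02

    def test_no_features_exact_length_empty_annotations(self):
        g = sim.build_genome(sim.GenomeSpec({"c": 500}), 7)
        assert len(g.sequences["c"]) == 500
        assert g.features == []

    def test_same_seed_identical_sequences(self):
        spec = sim.demo_genome_spec(chrom_length=20_000, n_tfbs=2, n_orfs=4, seed=3)
        assert sim.build_genome(spec, 3).sequences == sim.build_genome(spec, 3).sequences

    def test_overlapping_same_class_rejected_with_coordinates(self):
        spec = sim.GenomeSpec(
            {"c": 1000},
            [
                sim.FeaturePlacement("TFBS", "c", 100, 120),
                sim.FeaturePlacement("TFBS", "c", 110, 130),
            ],
        )
        with pytest.raises(ValueError, match="100-120.*110-130"):
            sim.build_genome(spec, 7)

    def test_feature_beyond_chromosome_rejected(self):
        spec = sim.GenomeSpec(
            {"c": 100}, [sim.FeaturePlacement("TFBS", "c", 90, 120)]
        )
        with pytest.raises(ValueError, match="bounds"):
            sim.build_genome(spec, 7)


def bare_genome(length=1650, name="c"):
    return sim.SyntheticGenome({name: "A" * length}, [], sim.GenomeSpec({name: length}))


def tfbs_genome(length=60_000, positions=(15_000, 30_000, 45_000)):
    feats = [
        IntervalFeature("c", p - 8, p + 8, "+", f"tfbs_{i}", "TFBS")
        for i, p in enumerate(positions)
    ]
    return sim.SyntheticGenome({"c": "A" * length}, feats, sim.GenomeSpec({"c": length}))


class TestChromatin:
    @pytest.mark.parametrize("repeat,linker", [(165, 18), (154, 7)])
    def test_mean_linker_length(self, repeat, linker):
        state = sim.place_chromatin(tfbs_genome(), repeat, 90, 1)
        assert math.isclose(state.mean_linker_length(), linker, abs_tol=1e-9)
        assert state.linker_length == linker

    def test_bare_chromosome_tiles_exactly(self):
        state = sim.place_chromatin(bare_genome(10 * 165), 165, 90, 1)
        dyads = state.dyads["c"]
        assert dyads.size == 10
        assert np.all(np.diff(dyads) == 165)

    def test_repeat_below_core_rejected(self):
        with pytest.raises(ValueError, match="147"):
            sim.place_chromatin(bare_genome(), 140, 90, 1)

    def test_tfbs_centered_in_ndr_and_flanking_nucleosomes_abut(self):
        g = tfbs_genome()
        state = sim.place_chromatin(g, 165, 90, 1)
        for tfbs in g.features:
            ndr = next(n for n in state.ndrs if n.name == f"NDR_{tfbs.name}")
            assert ndr.midpoint == tfbs.midpoint
            dyads = state.dyads["c"]
            left = dyads[dyads < ndr.start].max()
            right = dyads[dyads >= ndr.end].min()
            assert left + 74 == ndr.start  # nucleosome right edge on boundary
            assert right - 73 == ndr.end  # nucleosome left edge on boundary

    def test_ndrs_contain_no_dyads(self):
        state = sim.place_chromatin(tfbs_genome(), 165, 90, 1)
        for ndr in state.ndrs:
            dd = state.dyads[ndr.chrom]
            assert not np.any((dd >= ndr.start) & (dd < ndr.end))

    def test_ndr_width_jitter_varies_widths_deterministically(self):
        g = tfbs_genome()
        a = sim.place_chromatin(g, 165, 90, 5, ndr_half_width_jitter=25)
        b = sim.place_chromatin(g, 165, 90, 5, ndr_half_width_jitter=25)
        widths = [n.width for n in a.ndrs]
        assert len(set(widths)) > 1
        assert widths == [n.width for n in b.ndrs]


@pytest.fixture(scope="module")
def small_state():
    g = tfbs_genome()
    return g, sim.place_chromatin(g, 165, 90, 1)


class TestFragments:
    def test_zero_trim_nucleosome_only_lengths_exact(self):
        # dyads placed clear of chromosome edges so no boundary clipping
        state = sim.ChromatinState(
            {"c": np.array([500, 700, 900])}, 200, 147, [], [], []
        )
        dig = sim.DigestionModel(extent=0.0, overhang=14)
        out = sim.emit_fragments(state, dig, sim.EnrichmentModel.null(), 500,
                                 "input", 1, {"c": 2000})
        assert np.all(out.fragments.lengths() == 147 + 2 * 14)

    def test_fragments_contained_in_source_unit_plus_overhang(self, small_state):
        g, state = small_state
        dig = sim.DigestionModel(extent=5.0)
        out = sim.emit_fragments(state, dig, sim.EnrichmentModel.null(), 2000,
                                 "input", 4, g.chrom_lengths)
        for f, (_, row) in zip(out.fragments, out.provenance.iterrows()):
            assert f.start >= max(row.source_start, 0)
            assert f.end <= row.source_end
        assert set(out.provenance.unit_class) <= {
            sim.CLASS_NUCLEOSOME, sim.CLASS_TF_FOOTPRINT, sim.CLASS_SPANNING
        }

    def test_lengths_within_configured_bounds(self, small_state):
        g, state = small_state
        dig = sim.DigestionModel(extent=20.0, min_length=25, max_length=428)
        out = sim.emit_fragments(state, dig, sim.EnrichmentModel.null(), 5000,
                                 "input", 4, g.chrom_lengths)
        lengths = out.fragments.lengths()
        assert lengths.min() >= 25 and lengths.max() <= 428

    def test_same_seed_byte_identical(self, small_state):
        g, state = small_state
        dig = sim.DigestionModel(extent=5.0)
        a = sim.emit_fragments(state, dig, sim.EnrichmentModel.null(), 1000,
                               "IP", 9, g.chrom_lengths)
        b = sim.emit_fragments(state, dig, sim.EnrichmentModel.null(), 1000,
                               "IP", 9, g.chrom_lengths)
        assert a.fragments.fragments == b.fragments.fragments
        pd.testing.assert_frame_equal(a.provenance, b.provenance)

    def test_null_enrichment_roles_indistinguishable(self, small_state):
        """Equal class weights: IP and input size distributions agree
        (two-sample KS smoke check, not a hard gate on the statistic)."""
        g, state = small_state
        dig = sim.DigestionModel(extent=5.0)
        null = sim.EnrichmentModel.null()
        ip = sim.emit_fragments(state, dig, null, 10_000, "IP", 2, g.chrom_lengths)
        inp = sim.emit_fragments(state, dig, null, 10_000, "input", 2, g.chrom_lengths)
        ks = stats.ks_2samp(ip.fragments.lengths(), inp.fragments.lengths())
        assert ks.pvalue > 0.01
        sup = lambda fs: np.mean(fs.lengths() > 251)
        assert abs(sup(ip.fragments) - sup(inp.fragments)) < 0.02

    def test_digestion_monotonicity(self, small_state):
        g, state = small_state
        null = sim.EnrichmentModel.null()
        means = []
        for extent in (2.0, 5.0, 10.0, 15.0):
            out = sim.emit_fragments(state, sim.DigestionModel(extent=extent), null,
                                     20_000, "input", 6, g.chrom_lengths)
            means.append(out.fragments.lengths().mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_n_fragments_positive_required(self, small_state):
        g, state = small_state
        with pytest.raises(ValueError, match="positive"):
            sim.emit_fragments(state, sim.DigestionModel(), sim.EnrichmentModel.null(),
                               0, "input", 1)


class TestDesignedEnrichment:
    def test_analytic_calibration_is_consistent(self, small_state):
        g, state = small_state
        dig = sim.DigestionModel(extent=5.0)
        model = sim.design_enrichment(state, dig, 2.5)
        assert math.isclose(
            sim.expected_ratio_of_ratios(state, dig, model), 2.5, rel_tol=1e-8
        )

    def test_null_weights_give_unit_expected_ratio(self, small_state):
        g, state = small_state
        dig = sim.DigestionModel(extent=5.0)
        assert sim.expected_ratio_of_ratios(state, dig, sim.EnrichmentModel.null()) == 1.0


class TestGeneCoupling:
    def test_expression_tertiles_separate_in_ranked_heatmap(self):
        """End-to-end recovery: with coupling 0.8 between designed IP
        enrichment and expression, the top-expression tertile of the
        5'-anchored heatmap carries strictly more log2(IP/input) signal
        than the bottom tertile."""
        from mnasefrag import io as fio, profiles as prof

        spec = sim.demo_genome_spec(chrom_length=300_000, n_tfbs=12, n_orfs=60,
                                    seed=3)
        genome = sim.build_genome(spec, 3)
        state = sim.place_chromatin(genome, 165, 90, 3, ndr_half_width_jitter=25)
        metrics = sim.simulate_gene_metrics(genome, 0.8, 3)
        state = sim.couple_state_to_genes(state, metrics)
        dig = sim.DigestionModel(extent=5.0)
        model = sim.design_enrichment(state, dig, 2.5)
        ip = sim.emit_fragments(state, dig, model, 100_000, "IP", 3,
                                genome.chrom_lengths).fragments
        inp = sim.emit_fragments(state, dig, model, 100_000, "input", 3,
                                 genome.chrom_lengths).fragments
        track = prof.log_ratio_track(prof.coverage_track(ip),
                                     prof.coverage_track(inp))
        orfs = [f for f in genome.features_of_class("ORF")
                if f.name in metrics.index]
        hm = prof.heatmap_matrix(track, fio.to_anchors(orfs, "five_prime"),
                                 1000, metrics, "expression")
        third = len(hm.row_ids) // 3
        assert np.nanmean(hm.matrix[:third]) > np.nanmean(hm.matrix[-third:])

    def test_promoter_occupancy_tracks_designed_enrichment(self):
        spec = sim.demo_genome_spec(chrom_length=100_000, n_tfbs=4, n_orfs=20,
                                    seed=2)
        genome = sim.build_genome(spec, 2)
        state = sim.place_chromatin(genome, 165, 90, 2)
        metrics = sim.simulate_gene_metrics(genome, 0.8, 2)
        coupled = sim.couple_state_to_genes(state, metrics)
        occ = {pr.tfbs_name: pr.occupancy for pr in coupled.protections
               if pr.tfbs_name.startswith("p_")}
        assert occ, "expected promoter protections"
        top = metrics.designed_enrichment.max()
        for name, o in occ.items():
            expected = np.clip(metrics.designed_enrichment[name[2:]] / top,
                               0.05, 1.0)
            assert o == pytest.approx(expected)


def orf_only_genome(n_genes):
    feats = [
        IntervalFeature("c", 1000 * i, 1000 * i + 500, "+", f"g{i}", "ORF")
        for i in range(n_genes)
    ]
    return sim.SyntheticGenome({}, feats, sim.GenomeSpec({"c": 1000 * n_genes}))


class TestGeneMetrics:
    def test_zero_coupling_uncorrelated(self):
        df = sim.simulate_gene_metrics(orf_only_genome(1000), 0.0, 5)
        r = np.corrcoef(df.designed_enrichment, df.expression)[0, 1]
        assert abs(r) < 0.1

    def test_strong_coupling_recovered(self):
        df = sim.simulate_gene_metrics(orf_only_genome(1000), 0.8, 5)
        for metric in ("expression", "turnover", "transcription_rate"):
            r = np.corrcoef(df.designed_enrichment, df[metric])[0, 1]
            assert 0.7 <= r <= 0.9

    def test_same_seed_identical_tables(self):
        g = orf_only_genome(50)
        pd.testing.assert_frame_equal(
            sim.simulate_gene_metrics(g, 0.5, 8), sim.simulate_gene_metrics(g, 0.5, 8)
        )

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10"):
            sim.simulate_gene_metrics(orf_only_genome(5), 0.5, 8)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="couplin"):
            sim.simulate_gene_metrics(orf_only_genome(50), 1.5, 8)
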