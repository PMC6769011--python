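import numpy as np
import pytest

from itrcapture.synthetic_data import (
    DecoyLocus,
    PlantedSite,
    SimConfig,
    default_itr_breakpoint_weights,
    make_toy_host,
    make_toy_locus,
    plant_decoy_homology,
    simulate_aavseq_reads,
    simulate_amplicon_reads,
    simulate_clones,
)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(architecture_mix={"type1": 0.8, "type2": 0.4})

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            SimConfig(capture_fraction=1.2)

    def test_bad_weights(self):
        with pytest.raises(ValueError, match="145"):
            SimConfig(itr_breakpoint_weights=np.ones(10))

    def test_weights_normalized(self):
        cfg = SimConfig(itr_breakpoint_weights=np.ones(145) * 7)
        assert np.isclose(cfg.itr_breakpoint_weights.sum(), 1.0)


class TestAmpliconSimulator:
    def test_deterministic_under_seed(self, locus, vector):
        cfg = SimConfig(seed=12, n_reads=60)
        r1, t1 = simulate_amplicon_reads(cfg, locus, vector)
        r2, t2 = simulate_amplicon_reads(SimConfig(seed=12, n_reads=60), locus, vector)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert t1.equals(t2)
        r3, _ = simulate_amplicon_reads(SimConfig(seed=13, n_reads=60), locus, vector)
        assert [r.sequence for r in r1] != [r.sequence for r in r3]

    def test_truth_record_per_read(self, locus, vector):
        reads, truth = simulate_amplicon_reads(SimConfig(seed=1, n_reads=40), locus, vector)
        assert len(reads) == len(truth) == 40

    def test_edited_fraction_zero_all_unmodified(self, locus, vector):
        _, truth = simulate_amplicon_reads(
            SimConfig(seed=1, n_reads=30, edited_fraction=0.0), locus, vector
        )
        assert (truth["planted_class"] == "unmodified").all()

    def test_exact_count_planting(self, locus, vector):
        _, truth = simulate_amplicon_reads(
            SimConfig(
                seed=2, n_reads=100, edited_fraction=0.5, capture_fraction=0.25,
                exact_counts=True,
            ),
            locus, vector,
        )
        counts = truth["planted_class"].value_counts()
        # round-half-to-even: round(0.25 * 50) == 12
        assert counts["vector_fusion"] == 12
        assert counts["small_indel"] == 38
        assert counts["unmodified"] == 50

    def test_paired_mode_emits_pairs(self, locus, vector):
        reads, _ = simulate_amplicon_reads(
            SimConfig(seed=3, n_reads=10, paired=True), locus, vector
        )
        r1, r2 = reads[0]
        assert len(r1.sequence) == 150 and len(r2.sequence) == 150

    def test_fusion_inserts_are_vector_sequence(self, locus, vector):
        _, truth = simulate_amplicon_reads(
            SimConfig(seed=4, n_reads=50, edited_fraction=1.0, capture_fraction=1.0),
            locus, vector,
        )
        assert (truth["planted_class"] == "vector_fusion").all()
        assert (truth["insert_length"] >= 40).all()

    def test_hotspot_weights_concentrate_in_loops(self, locus, vector):
        w = default_itr_breakpoint_weights()
        assert w[20:102].sum() > 0.8  # b/c loop block dominates


class TestAavseqSimulator:
    def test_decoy_overlapping_site_rejected(self, primed_vector):
        host = make_toy_host(seed=5)
        with pytest.raises(ValueError, match="overlaps"):
            simulate_aavseq_reads(
                SimConfig(seed=1), host, primed_vector,
                [PlantedSite("chr1", 10000)], [DecoyLocus("chr1", 10050)],
            )

    def test_deterministic(self, primed_vector):
        host = make_toy_host(seed=5)
        sites = [PlantedSite("chr1", 20000)]
        a, _ = simulate_aavseq_reads(SimConfig(seed=2), host, primed_vector, sites)
        b, _ = simulate_aavseq_reads(SimConfig(seed=2), host, primed_vector, sites)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_read_structure(self, primed_vector):
        host = make_toy_host(seed=5)
        reads, truth = simulate_aavseq_reads(
            SimConfig(seed=2, substitution_error_rate=0.0),
            host, primed_vector, [PlantedSite("chr1", 20000, "+", 2)],
            n_episomal=1, n_primer_only=1,
        )
        primer = primed_vector.primer_sites[0][0]
        for r in reads:
            assert r.sequence.startswith(primer)
        t = truth.set_index("read_id")
        for r in reads:
            if t.loc[r.name, "kind"] == "true_site":
                assert host.sequences["chr1"][20000:20040] in r.sequence


class TestCloneSimulator:
    def test_exact_composition(self, vector, rng):
        flanks = (
            "".join(rng.choice(list("ACGT"), 70)),
            "".join(rng.choice(list("ACGT"), 70)),
        )
        cfg = SimConfig(seed=6, n_reads=20, exact_counts=True)
        _, truth = simulate_clones(cfg, vector, flanks)
        counts = truth["planted_type"].value_counts()
        assert counts["type1"] == 2 and counts["type2"] == 4
        assert counts["type3"] == 5 and counts["type4"] == 9

    def test_empty(self, vector, rng):
        flanks = ("A" * 60, "C" * 60)
        clones, truth = simulate_clones(SimConfig(seed=1, n_reads=0), vector, flanks)
        assert clones == [] and len(truth) == 0

    def test_all_concatemers(self, vector, rng):
        flanks = (
            "".join(rng.choice(list("ACGT"), 70)),
            "".join(rng.choice(list("ACGT"), 70)),
        )
        mix = {"type1": 0.0, "type2": 0.0, "type3": 0.0, "type4": 0.0, "concatemer": 1.0}
        clones, truth = simulate_clones(
            SimConfig(seed=7, n_reads=5, architecture_mix=mix), vector, flanks
        )
        assert (truth["planted_type"] == "concatemer").all()
        for _, seq in clones:
            assert len(seq) > 2 * 465  # two full copies plus flanks


class TestToyHost:
    def test_deterministic(self):
        a = make_toy_host(seed=42)
        b = make_toy_host(seed=42)
        assert a.sequences == b.sequences

    def test_shape(self, toy_host):
        assert len(toy_host.sequences) == 5
        assert all(len(s) == 100_000 for s in toy_host.sequences.values())
        assert len(toy_host.genes) == 20

    def test_exons_inside_genes(self, toy_host):
        for g in toy_host.genes:
            for lo, hi in g.exons:
                assert g.start <= lo < hi <= g.end

    def test_intergenic_fraction_positive(self, toy_host):
        """Some positions lie outside all genes +/- 1 kb."""
        covered = 0
        n = len(toy_host.sequences["chr1"])
        spans = [
            (max(0, g.start - 1000), min(n, g.end + 1000))
            for g in toy_host.genes
            if g.chrom == "chr1"
        ]
        covered = sum(hi - lo for lo, hi in spans)
        assert covered < n
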