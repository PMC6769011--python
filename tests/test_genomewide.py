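import numpy as np
import pytest

from itrcapture.genomewide_analysis import (
    CuratedSite,
    RawSite,
    ReadAccounting,
    RecurrenceTable,
    annotate_sites,
    call_sites,
    cluster_unique_sites,
    filter_itr_evidence,
    filter_shared_homology,
    normalized_count,
    recurrence,
    summarize_condition,
)
from itrcapture.fusion_detection import AlignmentSegment
from itrcapture.synthetic_data import (
    DecoyLocus,
    PlantedSite,
    SimConfig,
    make_toy_host,
    plant_decoy_homology,
    plant_repeat,
    simulate_aavseq_reads,
)
from oracles import category_oracle


def _raw(chrom="chr1", bp=1000, reads=1, vref=(102, 147), flank="", rng=None):
    if not flank:
        flank = "".join(rng.choice(list("ACGT"), 81))
    seg = AlignmentSegment("v", vref, (0, vref[1] - vref[0]), "+", 1.0, 80)
    return RawSite(chrom, bp, "+", [f"r{i}" for i in range(reads)], seg, flank)


@pytest.fixture(scope="module")
def library(primed_vector):
    host = make_toy_host(seed=50)
    sites = [
        PlantedSite("chr1", 25000, "+", 6),
        PlantedSite("chr2", 60000, "-", 4),
        PlantedSite("chr3", 41000, "+", 8),
    ]
    decoys = [DecoyLocus("chr4", 30000, 30, 5)]
    for d in decoys:
        plant_decoy_homology(host, primed_vector, d)
    plant_repeat(host, "chr5", 10000, "chr5", 70000, 60)
    cfg = SimConfig(seed=31, substitution_error_rate=0.0)
    reads, truth = simulate_aavseq_reads(
        cfg, host, primed_vector, sites, decoys,
        n_episomal=15, n_primer_only=8,
        ambiguous_loci=[("chr5", 10005, 3)],
    )
    acct = ReadAccounting()
    raw = call_sites(
        [(r.name, r.sequence) for r in reads],
        primed_vector, host,
        primer=primed_vector.primer_sites[0][0],
        accounting=acct,
    )
    return host, sites, raw, acct, truth


class TestCallSites:
    def test_episomal_reads_excluded(self, library):
        _, _, _, acct, truth = library
        assert acct.n_episomal >= (truth["kind"] == "episomal").sum()

    def test_ambiguous_reads_dropped(self, library):
        host, _, raw, acct, _ = library
        assert acct.n_ambiguous_host == 3
        assert not any(s.chrom == "chr5" and abs(s.breakpoint - 10005) < 100 for s in raw)

    def test_true_sites_recovered_near_truth(self, library):
        _, sites, raw, _, _ = library
        for planted in sites:
            assert any(
                s.chrom == planted.chrom and abs(s.breakpoint - planted.position) <= 5
                for s in raw
            ), planted

    def test_accounting_conserves_reads(self, library):
        _, _, _, acct, truth = library
        acct.check()
        assert acct.n_input == len(truth)


class TestSharedHomologyFilter:
    def test_vector_homologous_flank_fails(self, primed_vector, rng):
        flank = (
            "".join(rng.choice(list("ACGT"), 25))
            + primed_vector.sequence[200:230]
            + "".join(rng.choice(list("ACGT"), 26))
        )
        (site,) = filter_shared_homology([_raw(flank=flank, rng=rng)], primed_vector)
        assert site.filter_status == "fail_shared_homology"

    def test_random_flank_passes(self, primed_vector, rng):
        (site,) = filter_shared_homology([_raw(rng=rng)], primed_vector)
        assert site.filter_status == "pass"

    def test_short_match_below_threshold_passes(self, primed_vector, rng):
        flank = (
            "".join(rng.choice(list("ACGT"), 30))
            + primed_vector.sequence[200:212]  # 12 nt < 20
            + "".join(rng.choice(list("ACGT"), 39))
        )
        (site,) = filter_shared_homology([_raw(flank=flank, rng=rng)], primed_vector)
        assert site.filter_status == "pass"


class TestItrEvidenceFilter:
    @pytest.mark.parametrize(
        "vref,expected",
        [
            ((102, 122), "fail_no_unique_itr"),  # primer interval only
            ((102, 147), "pass"),                # 23 nt of unique ITR
            ((102, 127), "fail_no_unique_itr"),  # 5 nt < 10
        ],
    )
    def test_extension_thresholds(self, primed_vector, rng, vref, expected):
        (site,) = filter_itr_evidence([_raw(vref=vref, rng=rng)], primed_vector)
        assert site.filter_status == expected


class TestFilterAlgebra:
    def test_monotone_and_commutative(self, primed_vector, rng):
        """Filters only shrink the pass-set and their order is irrelevant."""
        sites = [_raw(bp=1000 * i, rng=rng) for i in range(1, 4)]
        sites.append(_raw(bp=9000, vref=(102, 122), rng=rng))
        flank = "".join(rng.choice(list("ACGT"), 20)) + primed_vector.sequence[160:200] + "".join(rng.choice(list("ACGT"), 21))
        sites.append(_raw(bp=12000, flank=flank, rng=rng))

        def passing(seq):
            return {s.breakpoint for s in seq if s.filter_status == "pass"}

        ab = filter_itr_evidence(filter_shared_homology(sites, primed_vector), primed_vector)
        ba = filter_shared_homology(filter_itr_evidence(sites, primed_vector), primed_vector)
        assert passing(ab) == passing(ba)
        assert passing(ab) <= passing(filter_shared_homology(sites, primed_vector))
        assert passing(ab) <= passing(filter_itr_evidence(sites, primed_vector))


class TestAnnotation:
    def test_matches_membership_oracle(self, toy_host):
        rng = np.random.default_rng(99)
        chroms = sorted(toy_host.sequences)
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(len(toy_host.sequences[chrom])))
            assert toy_host.category_of(chrom, pos) == category_oracle(
                toy_host, chrom, pos
            )

    def test_out_of_bounds_rejected(self, toy_host):
        with pytest.raises(ValueError):
            toy_host.category_of("chr1", 10**9)
        with pytest.raises(ValueError):
            toy_host.category_of("chrX", 0)

    def test_annotate_sites_sets_category(self, toy_host, rng):
        gene = toy_host.genes[0]
        exon_pos = gene.exons[0][0]
        sites = annotate_sites([_raw(chrom=gene.chrom, bp=exon_pos, rng=rng)], toy_host)
        assert sites[0].category == "exonic"


class TestClustering:
    def test_window_clustering(self, rng):
        sites = [_raw(bp=b, rng=rng) for b in (1000, 1003, 5000)]
        clusters = cluster_unique_sites([CuratedSite.from_raw(s) for s in sites])
        assert len(clusters) == 2

    def test_empty(self):
        assert cluster_unique_sites([]) == []

    def test_single_coordinate_sums_support(self, rng):
        sites = [CuratedSite.from_raw(_raw(bp=500, reads=3, rng=rng)) for _ in range(4)]
        clusters = cluster_unique_sites(sites)
        assert len(clusters) == 1 and clusters[0].read_count == 12
        assert clusters[0].position == 500


class TestNormalizationAndSummary:
    def test_reads_per_million(self):
        assert normalized_count(250, 10**6) == 250.0
        assert normalized_count(500, 10**6) == 2 * normalized_count(250, 10**6)
        assert normalized_count(250, 2 * 10**6) == normalized_count(250, 10**6) / 2
        with pytest.raises(ValueError):
            normalized_count(1, 0)

    def test_on_target_fraction(self, rng):
        sites = [
            CuratedSite.from_raw(_raw(chrom="chr1", bp=50000, reads=82, rng=rng)),
            CuratedSite.from_raw(_raw(chrom="chr2", bp=10000, reads=18, rng=rng)),
        ]
        summary = summarize_condition(
            sites, total_reads=10**6,
            on_target_chrom="chr1", on_target_pos=50000,
        )
        assert summary.on_target_fraction == 0.82
        assert summary.n_unique_sites == 2
        assert summary.normalized_integrant_reads == 100.0

    def test_no_locus_omits_on_target(self, rng):
        summary = summarize_condition(
            [CuratedSite.from_raw(_raw(rng=rng))], total_reads=1000
        )
        assert summary.on_target_fraction is None


class TestRecurrence:
    def _clusters(self, rng, conds, pos=4000):
        out = {}
        for c in conds:
            site = CuratedSite.from_raw(_raw(bp=pos + int(rng.integers(-10, 11)), rng=rng))
            out[c] = cluster_unique_sites([site])
        return out

    def test_recurrent_at_k3(self, rng):
        per_cond = self._clusters(rng, [f"c{i}" for i in range(4)])
        table = recurrence(per_cond, k=3)
        assert len(table.recurrent_sites()) == 1

    def test_two_conditions_not_recurrent(self, rng):
        table = recurrence(self._clusters(rng, ["a", "b"]), k=3)
        assert table.recurrent_sites() == []

    def test_k1_everything_recurrent(self, rng):
        per_cond = self._clusters(rng, ["a"])
        per_cond["b"] = cluster_unique_sites(
            [CuratedSite.from_raw(_raw(chrom="chr2", bp=9999, rng=rng))]
        )
        table = recurrence(per_cond, k=1)
        assert len(table.recurrent_sites()) == 2
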