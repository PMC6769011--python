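import numpy as np
import pytest

from itrcapture.architecture_profiles import (
    classify_clone,
    detect_concatemer,
    microhomology,
    tile_vector_blocks,
    vector_coverage_profile,
)
from itrcapture.synthetic_data import SimConfig, simulate_clones
from oracles import microhomology_oracle


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def flanks():
    rng = np.random.default_rng(13)
    return random_dna(rng, 80), random_dna(rng, 80)


class TestMicrohomology:
    @pytest.mark.parametrize(
        "host,vec,expected",
        [
            ("TTTTGGCC", "GGCCAATT", 4),
            ("AAAAAA", "CCCCCC", 0),
            ("ACGTAC", "ACGTAC", 6),
        ],
    )
    def test_examples(self, host, vec, expected):
        assert microhomology(host, vec) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            microhomology("", "ACGT")

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            a = random_dna(rng, int(rng.integers(1, 21)))
            b = random_dna(rng, int(rng.integers(1, 21)))
            if rng.random() < 0.5:  # force shared junction sequence
                k = int(rng.integers(1, min(len(a), len(b)) + 1))
                b = a[-k:] + b[k:]
            assert microhomology(a, b) == microhomology_oracle(a, b)


class TestClassifyClone:
    def test_type1_full_both_itrs(self, vector, flanks):
        clone = flanks[0] + vector.sequence + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "type1_full_both_itrs"
        assert call.itr_count >= 2
        assert call.cargo_coverage >= 0.99
        assert call.vector_copies == 1

    def test_type2_full_one_itr(self, vector, flanks):
        clone = flanks[0] + vector.sequence[: vector.cargo_interval[1]] + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "type2_full_one_itr"
        assert call.itr_count == 1

    def test_type3_itr_only(self, vector, flanks):
        clone = flanks[0] + vector.sequence[20:100] + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "type3_itr_only"
        assert call.cargo_coverage < 0.05

    def test_type4_partial_cargo(self, vector, flanks):
        clo, chi = vector.cargo_interval
        clone = flanks[0] + vector.sequence[: clo + int(0.4 * (chi - clo))] + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "type4_partial_one_itr"
        assert 0.05 <= call.cargo_coverage < 0.9

    def test_concatemer(self, vector, flanks):
        clone = flanks[0] + vector.sequence + vector.sequence + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "concatemer"
        assert call.vector_copies == 2

    def test_cargo_without_itr_is_unclassifiable(self, vector, flanks):
        clone = flanks[0] + vector.cargo + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.type == "unclassifiable"

    def test_missing_flank_is_unclassifiable(self, vector, flanks):
        call = classify_clone(vector.sequence, vector, flanks)
        assert call.type == "unclassifiable"

    def test_no_vector(self, vector, flanks):
        call = classify_clone(flanks[0] + flanks[1], vector, flanks)
        assert call.type == "no_vector"

    def test_host_deletion_measured(self, vector, flanks):
        clone = flanks[0][:-5] + vector.sequence + flanks[1][3:]
        call = classify_clone(clone, vector, flanks)
        assert call.host_indel == -(5 + 3)

    def test_planted_microhomology_detected(self, vector, flanks):
        insert = vector.sequence
        left = flanks[0][:-4] + insert[:4]
        clone = left + insert + flanks[1]
        call = classify_clone(clone, vector, flanks)
        assert call.microhomology_left >= 4


class TestConcatemerCounting:
    def test_block_counting_via_clones(self, vector, flanks):
        single = classify_clone(flanks[0] + vector.sequence + flanks[1], vector, flanks)
        assert single.vector_copies == 1
        itr_only = classify_clone(
            flanks[0] + vector.sequence[10:110] + flanks[1], vector, flanks
        )
        assert itr_only.vector_copies == 0
        triple = classify_clone(
            flanks[0] + vector.sequence * 3 + flanks[1], vector, flanks
        )
        assert triple.vector_copies == 3 and triple.type == "concatemer"

    def test_detect_concatemer_on_tiled_blocks(self, vector):
        blocks = tile_vector_blocks(vector.sequence + vector.sequence, vector)
        assert detect_concatemer(blocks, vector) == 2


class TestCoverageProfile:
    def test_full_length_clone_covers_everything(self, vector, flanks):
        call = classify_clone(flanks[0] + vector.sequence + flanks[1], vector, flanks)
        prof = vector_coverage_profile([call], vector)
        assert (prof.counts >= 1).all()

    def test_itr_enrichment_in_mixture(self, vector, flanks):
        calls = [
            classify_clone(flanks[0] + vector.sequence + flanks[1], vector, flanks),
            classify_clone(flanks[0] + vector.sequence[15:115] + flanks[1], vector, flanks),
        ]
        prof = vector_coverage_profile(calls, vector)
        assert prof.counts[50] == 2  # ITR position seen in both
        assert prof.counts[250] == 1  # cargo position only in the full clone

    def test_conservation(self, vector, flanks):
        call = classify_clone(flanks[0] + vector.sequence + flanks[1], vector, flanks)
        prof = vector_coverage_profile([call], vector)
        assert prof.total == sum(
            b.vector_interval[1] - b.vector_interval[0] for b in call.blocks
        )

    def test_empty(self, vector):
        prof = vector_coverage_profile([], vector)
        assert prof.total == 0


class TestSimulatedConfusion:
    def test_identity_confusion_on_clean_clones(self, vector, flanks):
        mix = {"type1": 0.2, "type2": 0.2, "type3": 0.2, "type4": 0.2, "concatemer": 0.2}
        cfg = SimConfig(
            seed=21, n_reads=50, substitution_error_rate=0.0,
            architecture_mix=mix, exact_counts=True,
        )
        clones, truth = simulate_clones(cfg, vector, flanks)
        expected = {
            "type1": "type1_full_both_itrs",
            "type2": "type2_full_one_itr",
            "type3": "type3_itr_only",
            "type4": "type4_partial_one_itr",
            "concatemer": "concatemer",
        }
        for (cid, seq), planted in zip(clones, truth["planted_type"]):
            call = classify_clone(seq, vector, flanks, clone_id=cid)
            assert call.type == expected[planted], (cid, planted, call)
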