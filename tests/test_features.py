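"""Microhomology mapping and breakpoint sequence features."""

import math

import numpy as np
import pytest

from fusionscope.contig import FusionContig
from fusionscope.errors import EdgeBreakpointError, FusionScopeError
from fusionscope.evidence import BreakpointCandidate
from fusionscope.features import (
    FEATURE_NAMES,
    SpliceType,
    assemble_feature_vector,
    breakpoint_dinucleotides,
    compute_breakpoint_features,
    find_microhomologies,
    microhomology_distance,
    reference_agreement,
)
from fusionscope.quantify import ExpressionSummary

from conftest import random_seq


def brute_force_matches(seq_a: str, seq_b: str, k: int):
    """Independent O(n*m*k) scan comparing every k-mer start pair."""
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    wa = np.lib.stride_tricks.sliding_window_view(a, k)
    wb = np.lib.stride_tricks.sliding_window_view(b, k)
    eq = (wa[:, None, :] == wb[None, :, :]).all(axis=-1)
    return sorted(zip(*map(list, np.nonzero(eq))))


def _contig(seq_a: str, seq_b: str, name="A--B") -> FusionContig:
    return FusionContig(
        name=name,
        sequence=seq_a + seq_b,
        geneB_offset=len(seq_a),
        gene_a_id="A",
        gene_b_id="B",
        maps={},
        annotations=[],
    )


def _bp(left, right):
    return BreakpointCandidate(contig="A--B", left_break=left, right_break=right)


class TestFindMicrohomologies:
    def test_planted_unique_kmer(self):
        kmer = "ACGTTGCACA"
        seq_a = list(random_seq(2000, seed=50))
        seq_b = list(random_seq(5000, seed=51))
        seq_a[900:910] = kmer
        seq_b[2900:2910] = kmer
        seq_a, seq_b = "".join(seq_a), "".join(seq_b)
        oracle = brute_force_matches(seq_a, seq_b, 10)
        contig = _contig(seq_a, seq_b)
        mh = find_microhomologies(contig, k=10)
        assert mh.matches == [(pa, 2000 + pb) for pa, pb in oracle]
        assert (900, 4900) in mh.matches

    def test_shared_12mer_gives_three_pairs(self):
        shared = "ACGTACCGGTAC"
        seq_a = "T" * 500 + shared + "T" * 500  # poly-T never matches the 12-mer
        seq_b = "G" * 500 + shared + "G" * 500
        contig = _contig(seq_a, seq_b)
        mh = find_microhomologies(contig, k=10)
        planted = [
            m for m in mh.matches if 495 <= m[0] <= 515 and len(seq_a) + 495 <= m[1]
        ]
        oracle = brute_force_matches(seq_a, seq_b, 10)
        assert len(planted) == 3
        assert mh.matches == [(pa, len(seq_a) + pb) for pa, pb in oracle]

    def test_disjoint_alphabets_share_nothing(self):
        rng = np.random.default_rng(52)
        seq_a = "".join(rng.choice(list("AC"), size=800))
        seq_b = "".join(rng.choice(list("GT"), size=800))
        mh = find_microhomologies(_contig(seq_a, seq_b), k=10)
        assert mh.matches == []

    def test_matches_equal_oracle_random(self):
        rng = np.random.default_rng(53)
        for trial in range(20):
            na, nb = int(rng.integers(60, 400)), int(rng.integers(60, 400))
            seq_a = random_seq(na, seed=1000 + trial)
            seq_b = random_seq(nb, seed=2000 + trial)
            mh = find_microhomologies(_contig(seq_a, seq_b), k=5)
            oracle = brute_force_matches(seq_a, seq_b, 5)
            assert mh.matches == [(pa, na + pb) for pa, pb in oracle]

    def test_n_kmers_excluded(self):
        seq_a = "ACGTACGTAC" + "N" * 10 + "ACGTACGTAC"
        seq_b = "ACGTACGTAC" + "N" * 10
        mh = find_microhomologies(_contig(seq_a, seq_b), k=10)
        assert all("N" not in seq_a[pa : pa + 10] for pa, _ in mh.matches)

    def test_symmetry_transposed(self):
        seq_a = random_seq(300, seed=60)
        seq_b = random_seq(300, seed=61)
        fwd = find_microhomologies(_contig(seq_a, seq_b), k=6)
        rev = find_microhomologies(_contig(seq_b, seq_a), k=6)
        fwd_pairs = {(pa, pb - 300) for pa, pb in fwd.matches}
        rev_pairs = {(pb - 300, pa) for pa, pb in rev.matches}
        assert fwd_pairs == rev_pairs

    def test_small_k_rejected(self):
        with pytest.raises(FusionScopeError):
            find_microhomologies(_contig("ACGT" * 10, "ACGT" * 10), k=3)


class TestBreakpointDinucleotides:
    def test_gt_ag_consensus(self):
        seq_a = random_seq(500, seed=70)[:-2] + "XX"
        seq_a = seq_a[:300] + "AGT" + seq_a[303:]  # donor GT after left_break 300
        seq_b = random_seq(500, seed=71)
        seq_b = seq_b[:198] + "AG" + seq_b[200:]
        contig = _contig(seq_a, seq_b)
        donor, acceptor, consensus = breakpoint_dinucleotides(contig, _bp(300, 700))
        assert (donor, acceptor) == ("GT", "AG")
        assert consensus

    def test_non_consensus(self):
        seq_a = "A" * 200 + "CT" + "A" * 100
        seq_b = "G" * 100 + "AC" + "G" * 200
        contig = _contig(seq_a, seq_b)
        donor, acceptor, consensus = breakpoint_dinucleotides(
            contig, _bp(199, 302 + len(seq_a) - 300)
        )
        assert not consensus

    def test_edge_breakpoint_rejected(self):
        contig = _contig(random_seq(100, seed=72), random_seq(100, seed=73))
        with pytest.raises(EdgeBreakpointError):
            breakpoint_dinucleotides(contig, _bp(1, 101))


class TestReferenceAgreement:
    def test_splice_types(self, toy_contig):
        donor = max(e for e in toy_contig.donor_sites() if e < toy_contig.geneB_offset - 10)
        acceptor = min(toy_contig.acceptor_sites())
        _, _, splice = reference_agreement(_bp(donor, acceptor), toy_contig, True)
        assert splice is SpliceType.ONLY_REF_SPLICE
        _, _, splice = reference_agreement(_bp(donor - 7, acceptor), toy_contig, True)
        assert splice is SpliceType.INCL_NON_REF_SPLICE
        left, right, splice = reference_agreement(
            _bp(donor, acceptor), toy_contig, False
        )
        assert splice is SpliceType.NON_CANONICAL
        assert left and right


class TestMicrohomologyDistance:
    def test_single_match(self):
        from fusionscope.features import MicrohomologyMap

        mh = MicrohomologyMap(k=10, matches=[(900, 4900)],
                              gene_a_length=2000, gene_b_length=5000)
        assert microhomology_distance(_bp(1000, 5000), mh) == pytest.approx(
            141.4214, abs=1e-4
        )

    def test_match_at_breakpoint(self):
        from fusionscope.features import MicrohomologyMap

        mh = MicrohomologyMap(k=10, matches=[(1000, 5000)],
                              gene_a_length=2000, gene_b_length=5000)
        assert microhomology_distance(_bp(1000, 5000), mh) == 0.0

    def test_empty_map_sentinel(self):
        from fusionscope.features import MicrohomologyMap

        mh = MicrohomologyMap(k=10, matches=[], gene_a_length=3000, gene_b_length=4000)
        assert microhomology_distance(_bp(10, 3500), mh) == pytest.approx(5000.0)

    def test_adding_match_never_increases_distance(self):
        from fusionscope.features import MicrohomologyMap

        rng = np.random.default_rng(80)
        matches = []
        bp = _bp(500, 2500)
        prev = math.inf
        for _ in range(30):
            matches.append((int(rng.integers(0, 2000)), int(rng.integers(2000, 6000))))
            mh = MicrohomologyMap(k=10, matches=list(matches),
                                  gene_a_length=2000, gene_b_length=4000)
            d = microhomology_distance(bp, mh)
            assert d <= prev + 1e-12
            prev = d

    def test_exhaustive_minimization_matches(self):
        from fusionscope.features import MicrohomologyMap

        rng = np.random.default_rng(81)
        matches = [(int(rng.integers(0, 900)), int(rng.integers(1000, 3000)))
                   for _ in range(100)]
        mh = MicrohomologyMap(k=10, matches=matches,
                              gene_a_length=900, gene_b_length=2000)
        bp = _bp(450, 1500)
        expected = min(
            math.sqrt((450 - pa) ** 2 + (1500 - pb) ** 2) for pa, pb in matches
        )
        assert microhomology_distance(bp, mh) == pytest.approx(expected)


class TestAssembleFeatureVector:
    def _expr(self):
        return ExpressionSummary(
            ffpm=1.25, counter_ffpm_5p=0.5, counter_ffpm_3p=0.0,
            far_5p=3.0, far_3p=31.0, total_fragments=1_000_000,
        )

    def _feats(self, consensus=True, agree=True):
        from fusionscope.features import BreakpointFeatures

        return BreakpointFeatures(
            donor_dinuc="GT", acceptor_dinuc="AG", consensus=consensus,
            left_ref_agree=agree, right_ref_agree=agree,
            splice_type=SpliceType.ONLY_REF_SPLICE if consensus else SpliceType.NON_CANONICAL,
            n_microhomologies=4, microhomology_distance=141.4214,
        )

    def test_order_and_length(self):
        vec = assemble_feature_vector(self._expr(), self._feats())
        tup = vec.as_tuple()
        assert len(tup) == 9
        assert tup == (1.25, 3.0, 31.0, 0.5, 0.0, 1, 1, 4, 141.4214)
        assert FEATURE_NAMES[0] == "ffpm" and FEATURE_NAMES[-1] == "microhomology_distance"

    def test_indicator_encoding(self):
        vec = assemble_feature_vector(self._expr(), self._feats(False, False))
        assert (vec.consensus_indicator, vec.ref_agree_indicator) == (0, 0)

    def test_missing_attribute_rejected(self):
        with pytest.raises(FusionScopeError):
            assemble_feature_vector(None, self._feats())

    def test_tsv_round_trip_4_decimals(self):
        vec = assemble_feature_vector(self._expr(), self._feats())
        line = "\t".join(f"{v:.4f}" for v in vec.as_tuple())
        parsed = tuple(float(x) for x in line.split("\t"))
        assert parsed == tuple(round(v, 4) for v in vec.as_tuple())


class TestArtifactPattern:
    def test_breakpoint_at_shared_kmer_is_noncanonical_distance_zero(self):
        kmer = "ACCGTTGACA"  # [1:3] = "CC": the junction can never read GT-AG
        seq_a = list(random_seq(1000, seed=90))
        seq_b = list(random_seq(1500, seed=91))
        seq_a[600:610] = kmer
        seq_b[700:710] = kmer
        seq_b[698:700] = "CC"
        contig = _contig("".join(seq_a), "".join(seq_b))
        bp = _bp(600, 1700)
        mh = find_microhomologies(contig, k=10)
        feats = compute_breakpoint_features(contig, bp, mh)
        assert feats.splice_type is SpliceType.NON_CANONICAL
        assert feats.microhomology_distance == 0.0
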