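from collections import Counter

import numpy as np
import pytest

from rbdscope.consensus import (
    ConsensusConfig,
    build_consensus,
    column_summary,
    consensus_agreement,
    conservation_profile,
    render_motif,
)
from rbdscope.io import AMINO_ACIDS, Msa, SequenceRecord

from conftest import random_msa


@pytest.fixture(scope="module")
def cfg():
    return ConsensusConfig()


class TestColumnSummary:
    def test_uniform_column_fully_conserved(self, cfg):
        s = column_summary(["A"] * 10, cfg)
        assert s.modal_residue == "A"
        assert s.conserved_fraction == 1.0
        assert s.is_conserved
        assert s.listed_residues == [("A", 1.0)]

    def test_similar_residues_count_and_listing_threshold_inclusive(self, cfg):
        # 12 L, 5 I, 2 V, 1 G: L/I and L/V score > 0, L/G scores -4.
        column = list("L" * 12 + "I" * 5 + "V" * 2 + "G")
        s = column_summary(column, cfg)
        assert s.modal_residue == "L"
        assert s.conserved_fraction == pytest.approx(19 / 20)
        assert s.is_conserved
        assert s.listed_residues == [("L", 0.60), ("I", 0.25), ("V", 0.10)]

    def test_gaps_count_in_denominator(self, cfg):
        s = column_summary(list("K" * 8 + "--"), cfg)
        assert s.modal_residue == "K"
        assert s.conserved_fraction == pytest.approx(0.80)
        assert not s.is_conserved

    def test_x_never_conserved(self, cfg):
        s = column_summary(list("K" * 8 + "XX"), cfg)
        assert s.conserved_fraction == pytest.approx(0.80)

    def test_all_gap_column(self, cfg):
        s = column_summary(["-"] * 5, cfg)
        assert s.modal_residue is None
        assert not s.is_conserved
        assert s.listed_residues == []

    def test_modal_tie_breaks_alphabetically(self, cfg):
        s = column_summary(list("WWAA"), cfg)
        assert s.modal_residue == "A"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ConsensusConfig(window=4)
        with pytest.raises(ValueError):
            ConsensusConfig(conserve_threshold=0.0)


def _oracle_conserved_count(msa, cfg):
    """Column-by-column re-evaluation of the rule, independent of the package."""
    count = 0
    for c in range(msa.width):
        column = [r.residues[c] for r in msa.records]
        counts = Counter(x for x in column if x in AMINO_ACIDS)
        if not counts:
            continue
        top = max(counts.values())
        modal = sorted(r for r, k in counts.items() if k == top)[0]
        good = sum(k for r, k in counts.items() if cfg.matrix.score(r, modal) > 0)
        if good / len(column) >= cfg.conserve_threshold - 1e-12:
            count += 1
    return count


class TestBuildConsensus:
    def test_identical_sequences_all_conserved(self, cfg):
        msa = Msa([SequenceRecord(f"s{i}", "ACDEFGHK") for i in range(5)])
        motif = build_consensus(msa, cfg)
        assert motif.conserved_count == 8
        assert motif.n_sequences == 5

    def test_uniform_dissimilar_residues_nothing_conserved(self, cfg):
        # Each column: equal parts A, C, D, W -- mutually non-positive pairs.
        rows = ["A" * 8, "C" * 8, "D" * 8, "W" * 8]
        msa = Msa([SequenceRecord(f"s{i}", row) for i, row in enumerate(rows)])
        assert build_consensus(msa, cfg).conserved_count == 0

    def test_matches_bruteforce_oracle_on_random_alignments(self, cfg):
        rng = np.random.default_rng(5)
        for _ in range(25):
            msa = random_msa(rng, 10, 12, gap_prob=0.15)
            motif = build_consensus(msa, cfg)
            assert motif.conserved_count == _oracle_conserved_count(msa, cfg)

    def test_order_and_duplication_invariance(self, cfg):
        rng = np.random.default_rng(9)
        msa = random_msa(rng, 8, 10, gap_prob=0.1)
        motif = build_consensus(msa, cfg)
        shuffled = Msa(list(reversed(msa.records)))
        doubled = Msa(
            msa.records
            + [SequenceRecord(r.id + "_dup", r.residues) for r in msa.records]
        )
        for other in (shuffled, doubled):
            other_motif = build_consensus(other, cfg)
            for a, b in zip(motif.columns, other_motif.columns):
                assert a.modal_residue == b.modal_residue
                assert a.conserved_fraction == pytest.approx(b.conserved_fraction)
                assert a.is_conserved == b.is_conserved
                assert a.listed_residues == b.listed_residues

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            msa = random_msa(rng, 12, 8, gap_prob=0.1)
            counts = []
            lengths = []
            for threshold in (0.5, 0.7, 0.85, 0.95):
                motif = build_consensus(msa, ConsensusConfig(conserve_threshold=threshold))
                counts.append(motif.conserved_count)
            assert counts == sorted(counts, reverse=True)
            for residue_threshold in (0.05, 0.10, 0.25, 0.5):
                motif = build_consensus(
                    msa, ConsensusConfig(residue_threshold=residue_threshold)
                )
                lengths.append([len(c.listed_residues) for c in motif.columns])
            for prev, nxt in zip(lengths, lengths[1:]):
                assert all(a >= b for a, b in zip(prev, nxt))


class TestConservationProfile:
    def test_all_conserved_gives_ones(self, cfg):
        msa = Msa([SequenceRecord(f"s{i}", "ACDEFG") for i in range(4)])
        motif = build_consensus(msa, cfg)
        assert [v for _, v in conservation_profile(motif, cfg)] == [1.0] * 6

    def test_truncated_edges_and_centre_value(self, cfg):
        # indicators (1,1,0,0,1,1,1) with window 5
        class FakeColumn:
            def __init__(self, flag, idx):
                self.is_conserved = flag
                self.column_index = idx

        from rbdscope.consensus import ConsensusMotif

        flags = [1, 1, 0, 0, 1, 1, 1]
        motif = ConsensusMotif(
            columns=[FakeColumn(bool(f), i + 1) for i, f in enumerate(flags)],
            n_sequences=10,
        )
        profile = dict(conservation_profile(motif, cfg))
        assert profile[3] == pytest.approx(0.6)
        assert profile[1] == pytest.approx(2 / 3)

    def test_none_conserved_gives_zeros(self, cfg):
        rows = ["A" * 4, "C" * 4, "D" * 4, "W" * 4]
        motif = build_consensus(Msa([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]), cfg)
        assert [v for _, v in conservation_profile(motif, cfg)] == [0.0] * 4


class TestConsensusAgreement:
    def _motif(self, cfg, row="ACDEFGHK", n=10):
        return build_consensus(Msa([SequenceRecord(f"s{i}", row) for i in range(n)]), cfg)

    def test_identical_others_agree_fully(self, cfg):
        motif = self._motif(cfg)
        others = [SequenceRecord(f"o{i}", "ACDEFGHK") for i in range(3)]
        assert consensus_agreement(motif, others, min_count=3, cfg=cfg) == 1.0

    def test_allgap_others_agree_nowhere(self, cfg):
        motif = self._motif(cfg)
        others = [SequenceRecord(f"o{i}", "-" * 8) for i in range(3)]
        assert consensus_agreement(motif, others, min_count=1, cfg=cfg) == 0.0

    def test_matches_per_column_count(self, cfg):
        motif = self._motif(cfg, row="AAAA", n=10)
        # three others; per column, count sequences scoring > 0 against 'A'
        others = [
            SequenceRecord("o1", "AAWW"),
            SequenceRecord("o2", "ASWW"),
            SequenceRecord("o3", "AWWA"),
        ]
        # column counts vs modal A (A:4, S:1, W:-3): [3, 2, 0, 1]
        assert consensus_agreement(motif, others, 2, cfg) == pytest.approx(2 / 4)
        assert consensus_agreement(motif, others, 1, cfg) == pytest.approx(3 / 4)
        assert consensus_agreement(motif, others, 3, cfg) == pytest.approx(1 / 4)

    def test_no_conserved_columns_is_an_error(self, cfg):
        rows = ["A" * 4, "C" * 4, "D" * 4, "W" * 4]
        motif = build_consensus(Msa([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]), cfg)
        with pytest.raises(ValueError, match="no conserved"):
            consensus_agreement(motif, [SequenceRecord("o", "AAAA")], 1, cfg)

    def test_unaligned_other_rejected(self, cfg):
        motif = self._motif(cfg)
        with pytest.raises(ValueError, match="aligned"):
            consensus_agreement(motif, [SequenceRecord("o", "AC")], 1, cfg)


def test_render_motif_stacks_by_frequency(cfg):
    rows = ["AC", "AC", "AC", "AC", "AC", "AC", "AC", "AC", "AL", "GL"]
    motif = build_consensus(Msa([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]), cfg)
    text = render_motif(motif)
    lines = text.splitlines()
    assert lines[0][0] == "A"  # most frequent residue on top
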