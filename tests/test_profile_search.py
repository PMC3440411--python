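import math

import numpy as np
import pytest

from rbdscope.io import Msa, SequenceRecord, ValidationError
from rbdscope.profile_search import (
    CalibrationConfig,
    CalibrationError,
    Pssm,
    align_to_profile,
    build_pssm,
    calibrate_cutoff,
    iterative_search,
    jackknife_stability,
    scan_sequence,
    uniform_background,
)
from rbdscope.simulate import generate_decoys, make_domain_spec, generate_domain_msa

from conftest import random_msa


def _family_msa(seed=0, n=10, width=24, n_conserved=16):
    """A strongly conserved gap-free family alignment plus its spec."""
    rng = np.random.default_rng(seed)
    spec = make_domain_spec("D1", width, n_conserved, rng, match_prob=0.95)
    msa, _ = generate_domain_msa(spec, n, uniform_background(), rng)
    return msa


class TestBuildPssm:
    def test_single_residue_column_logodds(self):
        msa = Msa([SequenceRecord(f"s{i}", "A") for i in range(10)])
        pssm = build_pssm(msa, pseudocount=1.0)
        expected = math.log2((10 + 0.05) / 11) - math.log2(0.05)
        assert pssm.logodds[0, 0] == pytest.approx(expected)

    def test_background_matching_counts_vanish_as_pseudocount_grows(self):
        # 20 sequences, one of each residue: counts equal the uniform background
        msa = Msa([SequenceRecord(f"s{i}", aa) for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")])
        pssm = build_pssm(msa, pseudocount=1e9)
        assert np.allclose(pssm.logodds, 0.0, atol=1e-6)

    def test_all_gap_column_is_neutral(self):
        msa = Msa([SequenceRecord(f"s{i}", "A-C") for i in range(4)])
        pssm = build_pssm(msa)
        assert np.all(pssm.logodds[1] == 0.0)
        assert np.any(pssm.logodds[0] != 0.0)

    def test_invalid_parameters_rejected(self):
        msa = Msa([SequenceRecord("a", "AC")])
        with pytest.raises(ValueError):
            build_pssm(msa, pseudocount=0.0)
        with pytest.raises(ValueError):
            build_pssm(msa, background=np.zeros(20))


class TestScanSequence:
    def test_consensus_of_zero_entropy_msa_scores_column_maxima(self):
        msa = Msa([SequenceRecord(f"s{i}", "ACDEFGHIK") for i in range(5)])
        pssm = build_pssm(msa)
        hit = scan_sequence(SequenceRecord("q", "ACDEFGHIK"), pssm)
        assert hit.score == pytest.approx(pssm.max_score())
        assert (hit.start, hit.end) == (1, 9)

    def test_match_inside_longer_sequence_localised(self):
        msa = _family_msa()
        pssm = build_pssm(msa)
        core = msa.records[0].residues
        seq = SequenceRecord("q", "W" * 30 + core + "W" * 20)
        hit = scan_sequence(seq, pssm)
        assert (hit.start, hit.end) == (31, 30 + len(core))

    def test_member_outscores_its_shuffle_on_most_trials(self):
        rng = np.random.default_rng(21)
        msa = _family_msa(seed=3)
        pssm = build_pssm(msa)
        wins = 0
        trials = 40
        for _ in range(trials):
            member = msa.records[int(rng.integers(len(msa)))]
            shuffled = "".join(rng.permutation(list(member.residues)))
            s_member = scan_sequence(member, pssm).score
            s_shuffled = scan_sequence(SequenceRecord("shuf", shuffled), pssm).score
            if s_member >= s_shuffled:
                wins += 1
        assert wins / trials >= 0.95

    def test_empty_profile_rejected(self):
        pssm = Pssm(logodds=np.zeros((0, 20)), background=uniform_background())
        with pytest.raises(ValueError, match="width 0"):
            scan_sequence(SequenceRecord("q", "ACD"), pssm)

    def test_tie_break_prefers_smallest_start(self):
        msa = Msa([SequenceRecord(f"s{i}", "AAA") for i in range(3)])
        pssm = build_pssm(msa)
        hit = scan_sequence(SequenceRecord("q", "AAAAAA"), pssm)
        assert (hit.start, hit.end) == (1, 3)

    def test_score_invariant_under_renaming(self):
        msa = _family_msa(seed=5)
        pssm = build_pssm(msa)
        seq = msa.records[0]
        renamed = SequenceRecord("other_name", seq.residues)
        assert scan_sequence(seq, pssm).score == scan_sequence(renamed, pssm).score

    def test_path_projects_member_onto_profile(self):
        msa = _family_msa(seed=7)
        pssm = build_pssm(msa)
        member = msa.records[2]
        row = align_to_profile(member, pssm)
        assert len(row.residues) == pssm.width
        # a gap-free member matching the full profile is reproduced exactly
        assert row.residues == member.residues


class TestCalibrateCutoff:
    def test_lowest_clean_grid_value_chosen_and_matches_bruteforce(self):
        msa = _family_msa(seed=11, n=8)
        pssm = build_pssm(msa)
        positives = [r.ungapped() for r in msa.records]
        decoys = generate_decoys(8, (20, 30), seed=101)
        cfg = CalibrationConfig(grid_start=90, grid_step=5, grid_floor=0)
        cutoff, report = calibrate_cutoff(pssm, positives, decoys, cfg)
        pos_scores = [scan_sequence(p, pssm).score for p in positives]
        dec_scores = [scan_sequence(d, pssm).score for d in decoys]
        clean = [g for g in cfg.values() if not any(s >= g for s in dec_scores)]
        assert cutoff == min(clean)
        row = next(r for r in report if r["cutoff"] == cutoff)
        assert row["decoys_admitted"] == 0
        assert row["positives_admitted"] == sum(s >= cutoff for s in pos_scores)

    def test_no_clean_cutoff_raises_with_report(self):
        msa = _family_msa(seed=13, n=6)
        pssm = build_pssm(msa)
        positives = [r.ungapped() for r in msa.records]
        decoys = [SequenceRecord("traitor", positives[0].residues)]  # scores like a member
        cfg = CalibrationConfig(grid_start=10, grid_step=5, grid_floor=0)
        with pytest.raises(CalibrationError) as err:
            calibrate_cutoff(pssm, positives, decoys, cfg)
        assert err.value.report  # per-grid report carried on the error

    def test_grid_values_descend_to_floor(self):
        cfg = CalibrationConfig(grid_start=90, grid_step=5, grid_floor=60)
        assert cfg.values() == [90, 85, 80, 75, 70, 65, 60]
        with pytest.raises(ValueError):
            CalibrationConfig(grid_start=50, grid_floor=50)

    def test_requires_positives_and_decoys(self):
        msa = _family_msa(seed=1, n=4)
        pssm = build_pssm(msa)
        with pytest.raises(ValueError):
            calibrate_cutoff(pssm, [], [SequenceRecord("d", "ACD")])


class TestJackknife:
    def test_identical_members_all_stable(self):
        msa = Msa([SequenceRecord(f"s{i}", "ACDEFGHIKLMNPQRS") for i in range(5)])
        decoys = generate_decoys(5, (16, 16), seed=3)
        report = jackknife_stability(msa, decoys)
        assert all(r.stable for r in report)

    def test_decoy_copied_into_family_is_unstable(self):
        decoys = generate_decoys(3, (16, 16), seed=5)
        members = [SequenceRecord(f"s{i}", "ACDEFGHIKLMNPQRS") for i in range(4)]
        mole = SequenceRecord("mole", decoys[0].residues)
        report = jackknife_stability(Msa(members + [mole]), decoys)
        by_id = {r.sequence_id: r for r in report}
        assert not by_id["mole"].stable  # ties the identical decoy: strict rule
        assert all(by_id[m.id].stable for m in members)

    def test_matches_external_loo_recomputation(self):
        msa = _family_msa(seed=17, n=6, width=16, n_conserved=10)
        decoys = generate_decoys(4, (14, 18), seed=19)
        report = jackknife_stability(msa, decoys)
        for rec in report:
            rest = Msa([r for r in msa.records if r.id != rec.sequence_id])
            pssm = build_pssm(rest)
            left_out = next(r for r in msa.records if r.id == rec.sequence_id)
            score = scan_sequence(left_out, pssm).score
            max_decoy = max(scan_sequence(d, pssm).score for d in decoys)
            assert rec.score == pytest.approx(score)
            assert rec.stable == (score > max_decoy)

    def test_needs_three_sequences(self):
        msa = Msa([SequenceRecord("a", "ACD"), SequenceRecord("b", "ACD")])
        with pytest.raises(ValidationError):
            jackknife_stability(msa, generate_decoys(1, (3, 3), seed=1))


class TestIterativeSearch:
    def test_copies_of_seed_accepted_in_first_round(self):
        msa = _family_msa(seed=23, n=5)
        database = [SequenceRecord(f"db{i}", r.residues) for i, r in enumerate(msa.records)]
        result = iterative_search(msa, database, cutoff=10.0)
        assert set(result.accepted) == {d.id for d in database}
        assert result.rounds[0].accepted_ids == [d.id for d in database]
        assert len(result.rounds) == 2 and result.converged

    def test_pure_decoys_rejected_in_one_round(self):
        msa = _family_msa(seed=29, n=5)
        database = generate_decoys(6, (20, 30), seed=31)
        result = iterative_search(msa, database, cutoff=30.0)
        assert result.accepted == []
        assert len(result.rounds) == 1 and result.converged

    def test_recovers_planted_membership_among_decoys(self):
        rng = np.random.default_rng(37)
        spec = make_domain_spec("D1", 24, 16, rng, match_prob=0.95)
        seed_msa, _ = generate_domain_msa(spec, 6, uniform_background(), rng, id_prefix="seed")
        extra, _ = generate_domain_msa(spec, 8, uniform_background(), rng, id_prefix="extra")
        decoys = generate_decoys(8, (20, 28), seed=39)
        database = list(extra.records) + decoys
        pssm = build_pssm(seed_msa)
        # grid floor 25 keeps the cutoff well clear of the decoy score range,
        # so it stays discriminative as the profile grows across rounds
        cutoff, _ = calibrate_cutoff(
            pssm,
            [r.ungapped() for r in seed_msa.records],
            decoys,
            CalibrationConfig(grid_start=90, grid_step=5, grid_floor=25),
        )
        result = iterative_search(seed_msa, database, cutoff)
        assert set(result.accepted) == {r.id for r in extra.records}

    def test_accepted_set_grows_monotonically(self):
        msa = _family_msa(seed=41, n=4)
        database = [SequenceRecord(f"db{i}", r.residues) for i, r in enumerate(msa.records)]
        result = iterative_search(msa, database, cutoff=5.0, max_rounds=5)
        seen: set[str] = set()
        for rnd in result.rounds:
            assert not (set(rnd.accepted_ids) & seen)
            seen.update(rnd.accepted_ids)

    def test_adding_decoys_never_removes_accepted(self):
        msa = _family_msa(seed=43, n=5)
        database = [SequenceRecord(f"db{i}", r.residues) for i, r in enumerate(msa.records)]
        base = iterative_search(msa, database, cutoff=10.0)
        widened = iterative_search(
            msa, database + generate_decoys(4, (20, 30), seed=44), cutoff=10.0
        )
        assert set(base.accepted) <= set(widened.accepted)
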