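"""Off-target screen vs brute-force maximal-exact-match oracle and BLAST."""

import random
import subprocess

import pytest

from hcrkit import (
    CandidateProbe,
    DesignConfig,
    FixtureSpec,
    OfftargetConfig,
    TranscriptomeIndex,
    apply_offtarget_filter,
    blastn_screen,
    enumerate_candidates,
    find_offtargets,
    make_target,
    make_transcriptome,
    read_transcriptome,
)
from hcrkit.design import OFFTARGET
from conftest import random_dna
from oracles import maximal_exact_matches


def window_candidate(window: str, start: int = 0, arm_len: int = 25) -> CandidateProbe:
    gap = len(window) - 2 * arm_len
    return CandidateProbe(
        start=start,
        end=start + len(window),
        arm1_seq=window[:arm_len],
        arm2_seq=window[arm_len + gap :],
    )


def index_of(records: dict[str, str], k: int = 15) -> TranscriptomeIndex:
    return TranscriptomeIndex(records=dict(records), k=k)


class TestFindOfftargets:
    def test_planted_verbatim_copy_is_found(self):
        rng = random.Random(0)
        window = random_dna(rng, 52)
        decoy = random_dna(rng, 200) + window[10:35] + random_dna(rng, 200)
        cfg = OfftargetConfig()
        hits = find_offtargets(
            window_candidate(window), index_of({"d1": decoy}), cfg, window=window
        )
        assert any(h.match_len >= 25 and h.subject_id == "d1" for h in hits)

    def test_below_seed_length_is_unseedable(self):
        rng = random.Random(1)
        window = random_dna(rng, 52)
        decoy = "T" * 100 + window[20:32] + "T" * 100  # 12-nt shared segment
        # window must not contain T-runs that match the decoy padding
        window = window[:20] + window[20:32] + window[32:]
        cfg = OfftargetConfig(seed_k=15)
        hits = find_offtargets(
            window_candidate(window), index_of({"d1": decoy}), cfg, window=window
        )
        assert all(h.match_len < 15 for h in hits)

    def test_index_k_mismatch_is_config_error(self):
        cfg = OfftargetConfig(seed_k=15)
        with pytest.raises(ValueError, match="k=12"):
            find_offtargets(
                window_candidate("A" * 52),
                index_of({"d": "ACGT" * 30}, k=12),
                cfg,
                window="A" * 52,
            )

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_bruteforce_oracle(self, trial):
        rng = random.Random(5000 + trial)
        window = random_dna(rng, 52)
        records = {}
        for i in range(rng.randint(1, 3)):
            L = rng.randint(60, 500)
            seq = list(random_dna(rng, L))
            if rng.random() < 0.7:  # plant a shared segment
                m = rng.randint(10, 40)
                qs = rng.randint(0, 52 - m)
                ss = rng.randint(0, L - m)
                seq[ss : ss + m] = window[qs : qs + m]
            records[f"t{i}"] = "".join(seq)
        cfg = OfftargetConfig(seed_k=15)
        hits = find_offtargets(
            window_candidate(window), index_of(records), cfg, window=window
        )
        got = {(h.subject_id, h.query_offset, h.subject_pos, h.match_len)
               for h in hits}
        expected = set()
        for tid, seq in records.items():
            for qs, ss, ln in maximal_exact_matches(window, seq, 15):
                expected.add((tid, qs, ss, ln))
        assert got == expected


class TestApplyFilter:
    @pytest.fixture()
    def planted_fixture(self, tmp_path):
        spec = FixtureSpec(seed=21, plants=((0, 100, 25), (2, 900, 12)))
        _, _, target = make_target(spec, tmp_path)
        fasta, _, truth = make_transcriptome(spec, target, tmp_path)
        return target, fasta, truth

    def test_planted_25mer_fails_exact_truth_set(self, planted_fixture):
        target, fasta, truth = planted_fixture
        idx = read_transcriptome(fasta, k=15)
        cfg = DesignConfig(offtarget=OfftargetConfig(screen_failed=True))
        cands = enumerate_candidates(target, cfg)
        apply_offtarget_filter(cands, idx, cfg.offtarget, target.sequence)
        failed = {c.start for c in cands if OFFTARGET in c.fail_reasons}
        assert failed == set(truth["plants"][0]["failing_window_starts"])

    def test_12nt_plant_fails_nothing(self, planted_fixture):
        _, _, truth = planted_fixture
        assert truth["plants"][1]["failing_window_starts"] == []

    def test_empty_transcriptome_fails_nothing(self):
        rng = random.Random(2)
        window = random_dna(rng, 52)
        cand = window_candidate(window)
        idx = TranscriptomeIndex(records={}, k=15)
        apply_offtarget_filter([cand], idx, OfftargetConfig(), window)
        assert OFFTARGET not in cand.fail_reasons

    def test_self_match_exemption(self):
        rng = random.Random(3)
        target_seq = random_dna(rng, 300)
        idx = index_of({"self_tx": target_seq})
        cfg = OfftargetConfig(exclude_ids=("self_tx",), screen_failed=True)
        cands = [window_candidate(target_seq[s : s + 52], start=s)
                 for s in range(0, 240, 10)]
        apply_offtarget_filter(cands, idx, cfg, target_seq)
        assert all(OFFTARGET not in c.fail_reasons for c in cands)

    def test_lower_threshold_never_passes_more(self):
        rng = random.Random(4)
        target_seq = random_dna(rng, 400)
        decoy = random_dna(rng, 150) + target_seq[60:80] + random_dna(rng, 150)
        idx = index_of({"d": decoy})
        counts = []
        for thresh in (24, 20, 18, 16, 14):
            cfg = OfftargetConfig(
                max_contig_match=thresh, screen_failed=True,
                seed_k=min(15, thresh + 1),
            )
            idx_t = index_of({"d": decoy}, k=cfg.seed_k)
            cands = [window_candidate(target_seq[s : s + 52], start=s)
                     for s in range(0, 348)]
            apply_offtarget_filter(cands, idx_t, cfg, target_seq)
            counts.append(sum(1 for c in cands if not c.fail_reasons))
        assert counts == sorted(counts, reverse=True)

    def test_seed_k_invariant(self):
        with pytest.raises(ValueError, match="seed_k"):
            OfftargetConfig(seed_k=18, max_contig_match=16)
        with pytest.raises(ValueError):
            OfftargetConfig(seed_k=7)


@pytest.mark.skipif(
    subprocess.run(["which", "blastn"], capture_output=True).returncode != 0,
    reason="NCBI BLAST+ not installed",
)
class TestBlastBackend:
    @pytest.fixture()
    def blast_db(self, tmp_path):
        spec = FixtureSpec(seed=31, plants=((0, 200, 30),))
        _, _, target = make_target(spec, tmp_path)
        fasta, _, truth = make_transcriptome(spec, target, tmp_path)
        db = tmp_path / "db" / "decoys"
        db.parent.mkdir()
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl",
             "-out", str(db)],
            check=True, capture_output=True,
        )
        return target, fasta, db, truth

    def test_agrees_with_internal_backend_on_plants(self, blast_db):
        target, fasta, db, truth = blast_db
        cfg = DesignConfig(offtarget=OfftargetConfig(screen_failed=True))
        cands = enumerate_candidates(target, cfg)
        idx = read_transcriptome(fasta, k=15)
        apply_offtarget_filter(cands, idx, cfg.offtarget, target.sequence)
        internal_strong = {
            c.start
            for c in cands
            if any(h.match_len >= 20 for h in c.offtarget_hits)
        }
        hits = blastn_screen(cands, db, cfg.offtarget, target.sequence)
        blast_strong = {h.candidate_start for h in hits if h.match_len >= 20}
        # both backends must agree on windows with a >=20 nt contiguous match
        assert internal_strong == blast_strong
        assert {h.subject_id for h in hits if h.match_len >= 20} == {
            truth["plants"][0]["decoy_id"]
        }

    def test_missing_executable_error(self, monkeypatch):
        import hcrkit.offtarget as ot

        monkeypatch.setattr(ot.shutil, "which", lambda _: None)
        with pytest.raises(ot.BlastNotFoundError, match="internal"):
            blastn_screen([], "db", OfftargetConfig(), "")
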