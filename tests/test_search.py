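"""Alignment engine vs brute-force oracle, score statistics, tabular I/O."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_assign.errors import ConfigError, HitTableError, SearchError
from barcode_assign.search import (
    PRESETS,
    Hit,
    ScoringScheme,
    bit_and_evalue,
    estimate_lambda,
    get_preset,
    local_align,
    read_outfmt6,
    search_all,
    write_outfmt6,
)
from barcode_assign.seqio import BarcodeRecord

from _oracles import lambda_bisection, sw_affine_score

BLASTN = PRESETS["blastn-task"]
MEGA = PRESETS["megablast-like"]


class TestLocalAlign:
    def test_identical_sequences(self, random_seq):
        seq = random_seq(500)
        aln = local_align(seq, seq, BLASTN)
        assert aln.raw_score == 500 * BLASTN.match_reward
        assert aln.pident == 100.0
        assert aln.mismatches == 0 and aln.gap_openings == 0
        assert (aln.qstart, aln.qend, aln.sstart, aln.send) == (1, 500, 1, 500)

    def test_worked_example_matches_oracle(self):
        scheme = ScoringScheme(1, -2, 5, 2, lam=1.28, K=0.46)
        q, s = "ACGTACGT", "ACGAACGT"
        aln = local_align(q, s, scheme)
        assert aln.raw_score == sw_affine_score(q, s, 1, -2, 5, 2)

    @pytest.mark.parametrize("scheme", [BLASTN, MEGA], ids=lambda s: s.preset_name)
    def test_random_pairs_equal_oracle(self, scheme):
        rng = random.Random(99)
        for _ in range(50):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60)))
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60)))
            got = local_align(q, s, scheme).raw_score
            want = sw_affine_score(q, s, scheme.match_reward,
                                   scheme.mismatch_penalty,
                                   scheme.gap_open, scheme.gap_extend)
            assert got == want, (q, s)

    def test_ambiguity_letters_match_only_literally(self):
        assert local_align("NNNN", "NNNN", MEGA).raw_score == 4 * MEGA.match_reward
        # N against a real base scores as mismatch, so the best local
        # alignment of disjoint letters is empty
        assert local_align("NNNN", "AAAA", MEGA).raw_score == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(SearchError):
            local_align("", "ACGT", BLASTN)

    def test_alignment_accounting_consistent(self, random_seq):
        rng = random.Random(7)
        for _ in range(20):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 80)))
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 80)))
            aln = local_align(q, s, BLASTN)
            if aln.length:
                assert aln.identities + aln.mismatches + aln.gap_columns == aln.length
                assert 0 <= aln.pident <= 100


class TestLambda:
    def test_closed_form_plus1_minus1(self):
        scheme = ScoringScheme(1, -1, 5, 2, lam=1.0, K=0.5)
        lam = estimate_lambda(scheme)
        assert lam == pytest.approx(math.log(3), rel=1e-9)

    def test_bisection_oracle_plus1_minus2(self):
        scheme = ScoringScheme(1, -2, 5, 2, lam=1.0, K=0.5)
        assert estimate_lambda(scheme) == pytest.approx(
            lambda_bisection(1, -2), rel=1e-9)

    def test_non_negative_expected_score_rejected(self):
        scheme = ScoringScheme(3, -1, 5, 2, lam=1.0, K=0.5)  # E[s] = 0
        with pytest.raises(ConfigError):
            estimate_lambda(scheme)

    def test_bad_frequency_vector_rejected(self):
        with pytest.raises(ConfigError):
            estimate_lambda(BLASTN, [0.5, 0.5, 0.5, 0.5])


class TestBitAndEvalue:
    def test_zero_raw_score_with_unit_k(self):
        scheme = ScoringScheme(1, -2, 5, 2, lam=1.28, K=1.0)
        bits, evalue = bit_and_evalue(0, scheme, 100, 1000)
        assert bits == 0.0
        assert evalue == 100 * 1000

    def test_monotone_in_raw_score(self):
        b1, e1 = bit_and_evalue(50, BLASTN, 100, 1000)
        b2, e2 = bit_and_evalue(100, BLASTN, 100, 1000)
        assert b2 > b1 and e2 < e1

    def test_matches_direct_formula(self):
        rng = random.Random(3)
        for _ in range(50):
            raw = rng.randint(1, 2000)
            m, n = rng.randint(50, 900), rng.randint(1000, 10**7)
            bits, evalue = bit_and_evalue(raw, BLASTN, m, n)
            want_bits = (BLASTN.lam * raw - math.log(BLASTN.K)) / math.log(2)
            assert bits == pytest.approx(want_bits, rel=1e-12)
            assert evalue == pytest.approx(m * n * 2 ** (-want_bits), rel=1e-9)


hit_strategy = st.builds(
    Hit,
    qseqid=st.from_regex(r"[A-Za-z0-9._-]{1,12}", fullmatch=True),
    sseqid=st.from_regex(r"[A-Za-z0-9._-]{1,12}", fullmatch=True),
    pident=st.floats(0, 100).map(lambda x: round(x, 2)),
    length=st.integers(1, 2000),
    mismatch=st.integers(0, 300),
    gapopen=st.integers(0, 50),
    qstart=st.integers(1, 1000), qend=st.integers(1, 1000),
    sstart=st.integers(1, 1000), send=st.integers(1, 1000),
    evalue=st.floats(0, 10, allow_nan=False),
    bitscore=st.floats(0, 2000).map(lambda x: round(x, 1)),
)


class TestOutfmt6:
    def test_documented_line(self, tmp_path):
        line = "q1\tr1\t100.00\t500\t0\t0\t1\t500\t1\t500\t1e-180\t924"
        path = tmp_path / "hits.tsv"
        path.write_text(line + "\n")
        (hit,) = read_outfmt6(path)
        assert hit.qseqid == "q1" and hit.sseqid == "r1"
        assert hit.pident == 100.0 and hit.length == 500
        assert hit.evalue == 1e-180 and hit.bitscore == 924.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert read_outfmt6(path) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tr1\t100.00\n")
        with pytest.raises(HitTableError, match="line 1"):
            read_outfmt6(path)

    def test_non_numeric_field_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q\tr\tabc\t500\t0\t0\t1\t500\t1\t500\t0.0\t924\n")
        with pytest.raises(HitTableError, match="pident"):
            read_outfmt6(path)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(hit_strategy, max_size=6))
    def test_write_read_identity_at_printed_precision(self, tmp_path_factory, hits):
        path = tmp_path_factory.mktemp("o6") / "hits.tsv"
        write_outfmt6(hits, path)
        back = read_outfmt6(path)
        write_outfmt6(back, path)
        again = read_outfmt6(path)
        assert back == again  # printing is a fixed point after one pass
        for h, b in zip(hits, back):
            assert (h.qseqid, h.sseqid, h.length, h.mismatch, h.gapopen,
                    h.qstart, h.qend, h.sstart, h.send) == \
                   (b.qseqid, b.sseqid, b.length, b.mismatch, b.gapopen,
                    b.qstart, b.qend, b.sstart, b.send)
            assert b.pident == pytest.approx(h.pident, abs=0.005)
            assert b.bitscore == pytest.approx(h.bitscore, abs=0.05)
            assert b.evalue == pytest.approx(h.evalue, rel=0.01, abs=1e-9)


def _records(seqs, marker="rbcLa", prefix="R"):
    return [BarcodeRecord(f"{prefix}{i}", f"Genus_sp{i:02d}", s, marker)
            for i, s in enumerate(seqs)]


class TestSearchAll:
    def test_identical_reference_is_unique_top_hit(self, random_seq):
        target = random_seq(300)
        refs = _records([target, random_seq(300), random_seq(300)])
        query = BarcodeRecord("Q", "Genus_sp00", target, "rbcLa")
        hits = search_all([query], refs, BLASTN)
        assert hits[0].sseqid == "R0"
        assert hits[0].pident == 100.0
        assert hits[0].bitscore == max(h.bitscore for h in hits)

    def test_empty_reference_db_rejected(self, make_record):
        with pytest.raises(SearchError):
            search_all([make_record()], [], BLASTN)

    def test_marker_mismatch_rejected(self, make_record):
        q = make_record("Q", marker="rbcLa")
        r = make_record("R", marker="matK")
        with pytest.raises(SearchError, match="marker"):
            search_all([q], [r], BLASTN)

    def test_word_prefilter_yields_no_hits_without_shared_kmer(self):
        q = BarcodeRecord("Q", "X_y", "A" * 40, "rbcLa")
        r = BarcodeRecord("R", "X_z", "C" * 40, "rbcLa")
        assert search_all([q], [r], BLASTN) == []

    def test_reverse_strand_reported_subject_descending(self, random_seq):
        from Bio.Seq import reverse_complement

        seq = random_seq(200)
        ref = BarcodeRecord("R", "X_y", seq, "rbcLa")
        query = BarcodeRecord("Q", "X_y", reverse_complement(seq), "rbcLa")
        (hit,) = search_all([query], [ref], BLASTN)
        assert hit.pident == 100.0
        assert hit.sstart > hit.send
        assert hit.qstart < hit.qend

    def test_top_hit_equals_exhaustive_oracle_argmax(self, rng):
        # planted nearest neighbours: every query's top hit must be the
        # all-pairs brute-force DP argmax
        def mutate(seq, k):
            out = list(seq)
            for pos in rng.sample(range(len(seq)), k):
                out[pos] = rng.choice("ACGT")
            return "".join(out)

        bases = ["".join(rng.choice("ACGT") for _ in range(120)) for _ in range(4)]
        refs = _records([mutate(b, k) for b in bases for k in (2, 10)])
        queries = [BarcodeRecord(f"Q{i}", f"Genus_sp{i:02d}", mutate(b, 1), "rbcLa")
                   for i, b in enumerate(bases)]
        hits = search_all(queries, refs, BLASTN, exhaustive=True)
        for q in queries:
            scores = {r.record_id: sw_affine_score(q.sequence, r.sequence, 2, -3, 5, 2)
                      for r in refs}
            top_score = max(scores.values())
            best_id = min(i for i, sc in scores.items() if sc == top_score)
            top = [h for h in hits if h.qseqid == q.record_id][0]
            assert top.sseqid == best_id

    def test_max_targets_truncates(self, random_seq):
        base = random_seq(150)
        refs = _records([base] * 1)  # one exact
        refs = refs + _records([base[:100] + random_seq(50) for _ in range(5)],
                               prefix="S")
        q = BarcodeRecord("Q", "X_y", base, "rbcLa")
        hits = search_all([q], refs, BLASTN, max_targets=3)
        assert len(hits) == 3
        assert hits[0].sseqid == "R0"
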