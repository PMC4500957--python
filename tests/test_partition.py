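"""Trimming, threshold-based read classification and library binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trapmeta as tm
from trapmeta.alignment import DEFAULT_SCORES, ReferenceIndex
from trapmeta.partition import (AssignmentParams, CompositionSummary,
                                ReadRecord, classify_read, partition_library,
                                trim_read)

RNG = np.random.default_rng(2024)


def random_seq(n, rng=RNG):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_read(seq, p=0.001, read_id="r"):
    return ReadRecord(read_id, seq, np.full(len(seq), float(p)))


# ---------------------------------------------------------------------------
# trimming

def brute_force_trim(p, limit, tol=1e-9):
    """Independent oracle: enumerate every subsegment, maximize the score
    sum; among segments tied within ``tol``, longest then leftmost."""
    n = len(p)
    scored = [(sum(limit - p[i] for i in range(s, e)), s, e)
              for s in range(n) for e in range(s + 1, n + 1)]
    top = max(sc for sc, _, _ in scored)
    tied = [(s, e) for sc, s, e in scored if abs(sc - top) <= tol]
    s, e = min(tied, key=lambda se: (-(se[1] - se[0]), se[0]))
    return top, s, e


class TestTrim:
    def test_good_read_unchanged(self):
        read = make_read(random_seq(100), p=0.001)
        out = trim_read(read)
        assert out.sequence == read.sequence

    def test_low_quality_tail_cut_at_expected_site(self):
        """100 bp with a p=0.75 tail after base 70 -> first 70 retained;
        verified against the brute-force subsegment oracle."""
        p = np.concatenate([np.full(70, 0.001), np.full(30, 0.75)])
        read = ReadRecord("r", random_seq(100), p)
        out = trim_read(read, quality_limit=0.05, min_len=10)
        score, s, e = brute_force_trim(p, 0.05)
        assert (s, e) == (0, 70)
        assert out.sequence == read.sequence[s:e]

    def test_agrees_with_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            p = rng.choice([0.001, 0.02, 0.3, 0.75], size=n)
            read = ReadRecord("r", random_seq(n, rng), p)
            out = trim_read(read, quality_limit=0.05, min_len=1)
            score, s, e = brute_force_trim(p, 0.05)
            if score <= 0:
                assert out is None
            else:
                assert out.sequence == read.sequence[s:e]

    def test_short_after_trim_dropped(self):
        # 79 good bases then garbage -> retained segment below the minimum
        p = np.concatenate([np.full(79, 0.001), np.full(21, 0.9)])
        assert trim_read(ReadRecord("r", random_seq(100), p)) is None

    def test_empty_read_dropped(self):
        assert trim_read(ReadRecord("r", "", np.array([]))) is None

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([0.001, 0.05, 0.3, 0.75]),
                    min_size=1, max_size=60))
    def test_idempotent(self, probs):
        read = ReadRecord("r", random_seq(len(probs)), np.array(probs))
        once = trim_read(read, min_len=1)
        if once is not None:
            twice = trim_read(once, min_len=1)
            assert twice is not None and twice.sequence == once.sequence


# ---------------------------------------------------------------------------
# classification

def best_local_alignment_oracle(query, target, scores=DEFAULT_SCORES):
    """Exhaustive DP oracle over gap-free local alignments.

    Scans every diagonal and every contiguous segment on it (Kadane over
    the per-column match/mismatch scores), returning the best-scoring
    segment as (score, matches, columns, query_span). On the
    substitution-mutated pairs this suite constructs, gap columns only
    cost score, so the optimum over all local alignments is gap-free and
    this oracle is exhaustive for them.
    """
    m, s = scores["match"], scores["mismatch"]
    nq, nt = len(query), len(target)
    best = (0.0, 0, 0, 0)
    for offset in range(-(nq - 1), nt):
        run_score, run_matches, run_len = 0.0, 0, 0
        i0 = max(0, -offset)
        for i in range(i0, min(nq, nt - offset)):
            hit = query[i] == target[i + offset] and query[i] != "N"
            run_score += m if hit else s
            run_matches += int(hit)
            run_len += 1
            if run_score <= 0:
                run_score, run_matches, run_len = 0.0, 0, 0
                continue
            if run_score > best[0]:
                best = (run_score, run_matches, run_len, run_len)
    return best


class TestClassify:
    def test_exact_substring_unique_identity_one(self):
        ref = random_seq(400)
        idx = ReferenceIndex({"ref1": ref})
        read = make_read(ref[100:200])
        asn = classify_read(read, idx, AssignmentParams())
        assert asn.assigned and asn.unique
        assert asn.hits["ref1"].identity == 1.0
        assert asn.hits["ref1"].read_fraction == 1.0

    def test_ten_interior_mismatches_pass_80_fail_97(self):
        rng = np.random.default_rng(5)
        ref = random_seq(400, rng)
        frag = list(ref[100:200])
        for pos in np.linspace(12, 88, 10).astype(int):
            frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
        read = make_read("".join(frag))
        idx = ReferenceIndex({"ref1": ref})
        at80 = classify_read(read, idx, AssignmentParams(0.90, 0.80))
        at97 = classify_read(read, idx, AssignmentParams(0.90, 0.97))
        assert at80.assigned and not at97.assigned

    def test_two_identical_references_not_unique(self):
        ref = random_seq(300)
        idx = ReferenceIndex({"refA": ref, "refB": ref})
        asn = classify_read(make_read(ref[50:150]), idx, AssignmentParams())
        assert asn.assigned and set(asn.ref_ids) == {"refA", "refB"}
        assert not asn.unique

    def test_threshold_monotonicity_97_subset_of_80(self):
        rng = np.random.default_rng(17)
        refs = {f"ref{i}": random_seq(300, rng) for i in range(4)}
        idx = ReferenceIndex(refs)
        for k in range(20):
            src = refs[f"ref{k % 4}"]
            frag = list(src[20:120])
            for pos in rng.integers(10, 90, size=int(rng.integers(0, 6))):
                frag[pos] = "ACGT"[int(rng.integers(4))]
            read = make_read("".join(frag), read_id=f"r{k}")
            loose = classify_read(read, idx, AssignmentParams(0.90, 0.80))
            strict = classify_read(read, idx, AssignmentParams(0.90, 0.97))
            assert set(strict.ref_ids) <= set(loose.ref_ids)

    def test_agrees_with_dp_oracle(self):
        """Decision agreement with an exhaustive affine-gap DP on 50
        substitution-mutated read/reference pairs."""
        rng = np.random.default_rng(99)
        params = AssignmentParams(0.90, 0.80)
        # mutation sites >= 3 apart so the full-window alignment is the
        # unique score optimum and the decision is tie-free
        sites = np.arange(8, 92, 3)
        for k in range(50):
            ref = random_seq(250, rng)
            n_mut = int(rng.integers(0, len(sites) + 1))
            frag = list(ref[75:175])
            for pos in rng.choice(sites, size=n_mut, replace=False):
                old = frag[pos]
                frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
            read = make_read("".join(frag), read_id=f"r{k}")
            idx = ReferenceIndex({"ref": ref})
            asn = classify_read(read, idx, params)
            score, matches, columns, qspan = best_local_alignment_oracle(
                read.sequence, ref)
            oracle_ok = (columns > 0 and qspan / len(read) >= 0.90
                         and matches / columns >= 0.80)
            assert asn.assigned == oracle_ok, f"pair {k}: {n_mut} mutations"

    def test_read_shorter_than_seed_unassigned(self):
        idx = ReferenceIndex({"ref": random_seq(200)}, k=15)
        asn = classify_read(make_read("ACGTACGTAC"), idx, AssignmentParams())
        assert not asn.assigned


# ---------------------------------------------------------------------------
# library partitioning and the composition summary

class TestPartitionLibrary:
    def test_planted_bins_recovered_at_zero_error(self, taxonomy):
        cfg = tm.SimulationConfig(seed=12, error_rate=0.0, reads_per_sample=80)
        refs = tm.make_references(cfg, taxonomy)
        reads, truth = tm.simulate_reads(cfg, refs)
        sample = "NIG_SS_t"
        res = partition_library(reads[sample],
                                ReferenceIndex(refs["rRNA"]),
                                ReferenceIndex(refs["host"]),
                                sample_id=sample)
        expect = truth.bin_totals[sample]
        assert res.counts["total"] == len(reads[sample])
        assert res.counts["rrna_strict"] == expect["rRNA"]
        assert res.counts["host"] == expect["host"]
        assert res.counts["nonhost"] == expect["nonhost"]

    def test_rrna_priority_over_host(self):
        # a read matching both references counts as rRNA
        seq = random_seq(300)
        read = make_read(seq[50:150])
        res = partition_library([read], ReferenceIndex({"rr": seq}),
                                ReferenceIndex({"h": seq}), trim=False)
        assert res.counts["rrna_strict"] == 1 and res.counts["host"] == 0

    def test_zero_read_sample_all_zero_row(self):
        res = partition_library([], ReferenceIndex({"r": random_seq(200)}),
                                ReferenceIndex({"h": random_seq(200)}),
                                sample_id="empty")
        summary = CompositionSummary.from_partitions([res])
        row = summary.frame.iloc[0]
        assert row["total_reads"] == 0 and row["rrna_reads"] == 0


class TestCompositionArithmetic:
    @pytest.mark.parametrize("total,count,expected", [
        (55_570_966, 18_190_523, 32.73),   # host share, summer trap library
        (83_721_886, 40_547, 0.05),        # non-host share, summer trap library
        (68_905_010, 290_521, 0.42),       # strict rRNA share, summer leaf
        (31_504_414, 21_144_415, 67.12),   # host share, winter leaf
    ])
    def test_published_percentages(self, total, count, expected):
        summary = CompositionSummary.from_counts(
            [{"sample_id": "s", "total": total, "rrna_strict": count,
              "host": count, "nonhost": count}])
        assert summary.frame.at[0, "host_pct"] == expected

    def test_bin_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            CompositionSummary.from_counts(
                [{"sample_id": "s", "total": 10, "rrna_strict": 11,
                  "host": 0, "nonhost": 0}])
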