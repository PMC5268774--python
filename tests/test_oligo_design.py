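"""Capture-oligo enumeration, screening, off-target scan and ranking."""

import random

import pytest

from conftest import MSLN_OLIGOS
from mircatch import thermo
from mircatch.folding import SSRegion
from mircatch.oligo_design import (
    CandidateOligo,
    DesignConstraints,
    design_report,
    enumerate_candidates,
    evaluate_candidate,
    offtarget_scan,
)
from mircatch.seqio import Interval, Transcript, as_dna, reverse_complement


def ss(start, end):
    return SSRegion(Interval(start, end), 1.0, "probability")


def random_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture(scope="module")
def toy_candidates():
    rng = random.Random(5)
    tx = Transcript("toy", random_rna(rng, 60), alphabet="RNA")
    return tx, enumerate_candidates(tx, [ss(16, 45)])


class TestEnumeration:
    def test_combinatorial_window_count(self, toy_candidates):
        """A 30-nt ss region admits sum_L (30 - L + 1) windows, L = 22..25."""
        _, candidates = toy_candidates
        assert len(candidates) == 9 + 8 + 7 + 6

    def test_every_oligo_is_the_antisense_of_its_interval(self, toy_candidates):
        tx, candidates = toy_candidates
        for c in candidates:
            sense = tx.sequence[c.target_interval.start - 1 : c.target_interval.end]
            assert c.sequence == as_dna(reverse_complement(sense, "RNA"))

    def test_short_transcript_yields_nothing(self):
        tx = Transcript("short", "ACGU" * 4, alphabet="RNA")
        assert enumerate_candidates(tx, [ss(1, 16)]) == []

    def test_no_ss_regions_yields_nothing(self):
        tx = Transcript("t", "ACGU" * 20, alphabet="RNA")
        assert enumerate_candidates(tx, []) == []

    def test_candidate_over_n_base_excluded(self):
        rng = random.Random(5)
        seq = list(random_rna(rng, 60))
        seq[30] = "N"
        tx = Transcript("withn", "".join(seq), alphabet="RNA")
        candidates = enumerate_candidates(tx, [ss(16, 45)])
        for c in candidates:
            assert not c.target_interval.contains(31)

    def test_partial_mode_accepts_straddling_windows(self):
        rng = random.Random(6)
        tx = Transcript("t", random_rna(rng, 60), alphabet="RNA")
        # two accessible blocks separated by a paired gap, 13+ ss bases total
        regions = [ss(16, 29), ss(33, 45)]
        contained = enumerate_candidates(tx, regions)
        partial = enumerate_candidates(
            tx, regions, DesignConstraints(ss_mode="partial", min_ss_overlap=13)
        )
        assert contained == []  # no window fits inside a 14- or 13-nt block
        assert partial  # straddling windows qualify by accessible-base count


class TestEvaluation:
    def test_published_oligos_pass_tm_and_dimer_rules(self):
        for seq in MSLN_OLIGOS.values():
            hybrid = thermo.duplex_thermo(seq, "dna:rna")
            anneal = thermo.duplex_thermo(seq, "rna:rna")
            dimer = thermo.self_dimer(seq)
            c = CandidateOligo(
                sequence=seq,
                target_interval=Interval(1, len(seq)),
                hybrid=hybrid,
                anneal=anneal,
                dimer=dimer,
                dimer_ratio_pct=thermo.dimer_ratio(dimer, anneal),
                gc_pct=100.0 * (seq.count("G") + seq.count("C")) / len(seq),
                accessibility=1.0,
            )
            evaluate_candidate(c)
            assert c.flags["tm"] and c.flags["dimer"]

    def test_excessive_dimer_ratio_fails(self, toy_candidates):
        _, candidates = toy_candidates
        c = candidates[0]
        c.dimer_ratio_pct = 20.0
        evaluate_candidate(c)
        assert not c.flags["dimer"]

    def test_perfect_offtarget_match_fails_specificity(self, toy_candidates):
        tx, candidates = toy_candidates
        c = candidates[0]
        from mircatch.oligo_design import OffTargetHit

        c.dimer_ratio_pct = 1.0
        n = len(c.sequence)
        # perfect full-length complementarity to a non-target transcript
        c.offtargets = [
            OffTargetHit("other", n, 0, Interval(1, n), Interval(10, 9 + n))
        ]
        evaluate_candidate(c)
        assert not c.flags["specificity"]
        # one mismatch below length - 1 is tolerated
        c.offtargets = [
            OffTargetHit("other", n - 2, 0, Interval(1, n - 2), Interval(10, 7 + n))
        ]
        evaluate_candidate(c)
        assert c.flags["specificity"]


class TestOffTargetScan:
    def test_self_transcript_gives_full_length_hit(self):
        rng = random.Random(9)
        tx = Transcript("self", random_rna(rng, 80), alphabet="RNA")
        oligo = as_dna(
            reverse_complement(tx.sequence[20:45], "RNA")
        )
        hits = offtarget_scan(oligo, [tx], min_report_len=14)
        full = [h for h in hits if h.match_len == 25 and h.mismatches == 0]
        assert len(full) == 1
        assert full[0].transcript_span == Interval(21, 45)

    def test_central_mismatch_splits_or_spans(self):
        rng = random.Random(10)
        background = random_rna(rng, 120)
        site = "GAUCGAUCGGAUCCGAUCG"  # 19 nt
        mutated = site[:9] + ("A" if site[9] != "A" else "C") + site[10:]
        tx = Transcript("t", background[:50] + mutated + background[50:], "RNA")
        oligo = as_dna(reverse_complement(site, "RNA"))
        with_mismatch = offtarget_scan(oligo, [tx], 8, max_mismatches=1)
        spanning = [h for h in with_mismatch if h.match_len == 19]
        assert len(spanning) == 1 and spanning[0].mismatches == 1
        assert spanning[0].transcript_span == Interval(51, 69)
        exact_only = offtarget_scan(oligo, [tx], 8, max_mismatches=0)
        segments = [
            h for h in exact_only
            if 51 <= h.transcript_span.start and h.transcript_span.end <= 69
        ]
        assert sorted(
            (h.transcript_span.start, h.transcript_span.end) for h in segments
        ) == [(51, 59), (61, 69)]
        assert all(h.mismatches == 0 and h.match_len == 9 for h in segments)

    def test_matches_naive_scan(self, rng):
        """Seeded scan equals the quadratic all-offsets oracle."""
        for trial in range(30):
            tx_seq = "".join(rng.choice("ACGT") for _ in range(200))
            oligo = "".join(rng.choice("ACGT") for _ in range(20))
            if trial % 3 == 0:  # plant a complement so hits exist
                pos = rng.randint(0, 180)
                tx_seq = (
                    tx_seq[:pos]
                    + reverse_complement(oligo, "DNA")
                    + tx_seq[pos + 20 :]
                )
            tx = Transcript("t", tx_seq, alphabet="DNA")
            for max_mm in (0, 1):
                hits = offtarget_scan(oligo, [tx], min_report_len=8,
                                      max_mismatches=max_mm)
                got = {
                    (h.transcript_span.start, h.transcript_span.end, h.mismatches)
                    for h in hits
                }
                query = reverse_complement(oligo, "DNA")
                expected = naive_subject_segments(query, tx_seq, 8, max_mm)
                assert got == expected, (oligo, max_mm)

    def test_empty_oligo_rejected(self):
        with pytest.raises(ValueError):
            offtarget_scan("", [Transcript("t", "ACGT", alphabet="DNA")])


def naive_subject_segments(query, subject, min_len, max_mm):
    """Oracle hits keyed by 1-based subject span + mismatch count."""
    out = set()
    qlen, slen = len(query), len(subject)
    for d in range(-qlen + 1, slen):
        q_lo, q_hi = max(0, -d), min(qlen, slen - d)
        if q_hi - q_lo < 1:
            continue
        match = [query[q] == subject[q + d] for q in range(q_lo, q_hi)]
        w = len(match)
        valid = []
        for a in range(w):
            if not match[a]:
                continue
            mism = 0
            for b in range(a, w):
                if not match[b]:
                    mism += 1
                    continue
                if mism <= max_mm:
                    valid.append((a, b, mism))
        for a, b, mism in valid:
            if any(a2 <= a and b <= b2 and (a2, b2) != (a, b) for a2, b2, _ in valid):
                continue
            if b - a + 1 >= min_len:
                out.add((q_lo + a + d + 1, q_lo + b + d + 1, mism))
    return out


class TestDesignReport:
    def test_all_failing_candidates_give_empty_report(self, toy_candidates):
        _, candidates = toy_candidates
        for c in candidates:
            c.flags = {"tm": False}
        report = design_report(candidates)
        assert report.empty

    def test_higher_tm_ranks_first_at_equal_accessibility(self, toy_candidates):
        _, candidates = toy_candidates
        a, b = candidates[0], candidates[1]
        for c in (a, b):
            c.accessibility = 0.9
            c.flags = {"ok": True}
        report = design_report([a, b] if a.hybrid.tm_c > b.hybrid.tm_c else [b, a])
        assert report.iloc[0]["tm_c"] >= report.iloc[1]["tm_c"]

    def test_report_is_deterministic(self, toy_candidates):
        tx, candidates = toy_candidates
        for c in candidates:
            evaluate_candidate(c)
        r1 = design_report(candidates, top_k=5).to_csv(index=False)
        r2 = design_report(list(reversed(candidates)), top_k=5).to_csv(index=False)
        assert r1 == r2

    def test_no_reported_oligo_violates_hard_flags(self, toy_candidates):
        _, candidates = toy_candidates
        for c in candidates:
            evaluate_candidate(c)
        report = design_report(candidates)
        reported = set(report["sequence"])
        for c in candidates:
            if c.sequence in reported:
                assert c.passes
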