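"""Adapter trimming, miRNA counting, normalisation, testing and 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest

from mircatch.capture_diff import (
    CountMatrix,
    count_mature_mirnas,
    ddct_enrichment,
    differential_capture,
    select_candidates,
    size_factors,
    trim_adapter,
)
from mircatch.seqio import Transcript
from mircatch.synth import synth_counts, synth_mirna_reference, synth_reads

ADAPTER = "AGATCGGAAGAGCACACGTCT"


def rec(seq):
    return ("r", seq, "I" * len(seq))


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        insert = "TAGCTTATCAGACTGATGTTGA"
        trimmed, stats = trim_adapter([rec(insert + ADAPTER)], ADAPTER)
        assert trimmed[0][1] == insert
        assert stats.trimmed == 1

    def test_read_without_adapter_unchanged(self):
        read = "TAGCTTATCAGACTGATGTTGA"
        trimmed, stats = trim_adapter([rec(read)], ADAPTER)
        assert trimmed[0][1] == read
        assert stats.untrimmed == 1

    def test_partial_adapter_at_read_end(self):
        insert = "TAGCTTATCAGACTGATGTTGA"
        trimmed, _ = trim_adapter([rec(insert + ADAPTER[:10])], ADAPTER)
        assert trimmed[0][1] == insert

    def test_one_mismatch_tolerated(self):
        insert = "TAGCTTATCAGACTGATGTTGA"
        bad_adapter = "C" + ADAPTER[1:]
        trimmed, stats = trim_adapter([rec(insert + bad_adapter)], ADAPTER)
        assert trimmed[0][1] == insert

    def test_short_insert_discarded(self):
        trimmed, stats = trim_adapter([rec("ACGTACGT" + ADAPTER)], ADAPTER)
        assert trimmed == []
        assert stats.discarded_short == 1

    def test_adapter_too_short_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter([], "ACGT")

    def test_simulated_reads_recover_inserts(self):
        reference = synth_mirna_reference(7, 40)
        abundances = pd.Series(25, index=[m.id for m in reference])
        reads, _ = synth_reads(7, abundances, reference, ADAPTER, error_rate=0.0)
        trimmed, stats = trim_adapter(reads, ADAPTER)
        by_insert = {m.sequence.replace("U", "T") for m in reference}
        recovered = sum(1 for _, seq, _ in trimmed if seq in by_insert)
        assert recovered / stats.total >= 0.99


class TestCountMatureMirnas:
    def test_exact_read_counts_once(self):
        mature = [Transcript("mir-a", "UAGCUUAUCAGACUGAUGUUGA", "RNA")]
        counts, stats = count_mature_mirnas(["TAGCTTATCAGACTGATGTTGA"], mature)
        assert counts["mir-a"] == 1 and stats.assigned == 1

    def test_identical_family_members_multimap(self):
        seq = "UAGCUUAUCAGACUGAUGUUGA"
        mature = [Transcript("mir-a", seq, "RNA"), Transcript("mir-b", seq, "RNA")]
        counts, stats = count_mature_mirnas([seq.replace("U", "T")], mature)
        assert counts.sum() == 0
        assert stats.multimapped == 1

    def test_length_window_and_mismatch(self):
        mature = [Transcript("mir-a", "UAGCUUAUCAGACUGAUGUUGA", "RNA")]
        read_short = "TAGCTTATCAGACTGATGTT"  # -2 nt
        read_mut = "TAGCTTATCAGACTGATGTTGC"  # 1 mismatch
        read_far = "TAGCTTATCAGACTGAT"  # -5 nt
        counts, stats = count_mature_mirnas([read_short, read_mut, read_far], mature)
        assert counts["mir-a"] == 2
        assert stats.unassigned == 1

    def test_duplicate_reference_ids_rejected(self):
        mature = [
            Transcript("mir-a", "UAGCUUAUCAGACUGAUGUUGA", "RNA"),
            Transcript("mir-a", "ACGUACGUACGUACGUACGU", "RNA"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            count_mature_mirnas([], mature)

    def test_pipeline_identity_with_clean_reads(self):
        """simulate -> trim -> count returns the input column exactly."""
        reference = synth_mirna_reference(3, 30)
        abundances = pd.Series(
            [10 + i for i in range(30)], index=[m.id for m in reference]
        )
        reads, _ = synth_reads(3, abundances, reference, ADAPTER)
        trimmed, _ = trim_adapter(reads, ADAPTER)
        counts, stats = count_mature_mirnas(trimmed, reference)
        assert stats.multimapped == 0
        pd.testing.assert_series_equal(
            counts.sort_index(), abundances.sort_index(), check_names=False
        )


class TestSizeFactors:
    def test_identical_libraries_get_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_library_has_double_factor(self):
        a = pd.Series([10, 25, 40, 55, 100])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.poisson(50, size=(40, 4)),
            columns=list("abcd"),
        ) + 1
        shuffled = df.sample(frac=1.0, random_state=0)
        pd.testing.assert_series_equal(size_factors(df), size_factors(shuffled))

    def test_scaling_one_library_scales_its_relative_factor(self):
        """Tripling one library triples its factor relative to the others."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(100, size=(60, 3)), columns=list("abc")) + 1
        scaled = df.copy()
        scaled["c"] = df["c"] * 3
        before = size_factors(df)
        after = size_factors(scaled)
        rel = (after["c"] / after["a"]) / (before["c"] / before["a"])
        assert rel == pytest.approx(3.0, rel=0.02)

    def test_no_common_positive_feature_is_an_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)


def small_matrix(seed=0, n=60, planted=None):
    cm, _ = synth_counts(
        seed, n_mirnas=n, dispersion=0.05,
        enriched_spec=planted or (), size_multiplier_sigma=0.0,
    )
    return cm


class TestDifferentialCapture:
    def test_all_zero_row_reported_with_na(self):
        cm = small_matrix()
        cm.counts.iloc[0] = 0
        res = differential_capture(cm).set_index("mirna")
        first = res.iloc[0]
        assert np.isnan(first["p_value"]) and not first["selected"]

    def test_missing_group_rejected(self):
        cm = small_matrix()
        cm.groups[:] = "capture"
        with pytest.raises(ValueError):
            differential_capture(cm)

    def test_bh_adjustment_is_monotone_and_above_raw(self):
        cm = small_matrix(seed=4, n=150)
        res = differential_capture(cm).dropna(subset=["p_value"])
        res = res.sort_values("p_value")
        assert (res["p_adj"].to_numpy() >= res["p_value"].to_numpy() - 1e-12).all()
        assert (np.diff(res["p_adj"].to_numpy()) >= -1e-12).all()

    def test_planted_enrichment_is_detected(self):
        planted = ((0, 2.0, 400.0), (1, -2.0, 400.0))
        cm = small_matrix(seed=6, n=200, planted=planted)
        res = differential_capture(cm).set_index("mirna")
        assert res.iloc[0]["selected"]
        assert res.iloc[0]["log2fc"] > 1.0
        assert not res.iloc[1]["selected"]  # depleted: log2fc < 0


class TestSelectCandidates:
    def make_results(self):
        return pd.DataFrame(
            {
                "mirna": ["a", "b", "c", "d"],
                "base_mean": [100.0, 20.0, 300.0, 50.0],
                "log2fc": [1.0, 2.0, 0.8, -1.0],
                "p_value": [0.001, 0.001, 0.002, 0.001],
                "p_adj": [0.01, 0.01, 0.04, 0.01],
                "selected": [True, False, True, False],
            }
        )

    def test_base_mean_exactly_at_floor_is_excluded(self):
        shortlist = select_candidates(self.make_results())
        assert "b" not in set(shortlist["mirna"])  # base_mean == 20, strict

    def test_negative_fold_change_excluded(self):
        shortlist = select_candidates(self.make_results())
        assert "d" not in set(shortlist["mirna"])

    def test_two_qualifying_mirnas_shortlisted_in_order(self):
        shortlist = select_candidates(self.make_results())
        assert list(shortlist["mirna"]) == ["a", "c"]

    def test_empty_results_give_empty_shortlist(self):
        assert select_candidates(pd.DataFrame()).empty


class TestDdct:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["replicate", "condition", "gene", "ct"])

    def full_replicate(self, rep, ct_ct, ct_cr, ct_st, ct_sr):
        return [
            (rep, "capture", "target", ct_ct),
            (rep, "capture", "reference", ct_cr),
            (rep, "scrambled", "target", ct_st),
            (rep, "scrambled", "reference", ct_sr),
        ]

    def test_equal_cts_give_fold_one(self):
        t = self.table(self.full_replicate("r1", 25, 25, 25, 25))
        _, mean, sem = ddct_enrichment(t)
        assert mean == pytest.approx(1.0)

    def test_hand_worked_example(self):
        """capture (20, 18) vs scrambled (22, 18): ddCt = -2, fold = 4."""
        t = self.table(self.full_replicate("r1", 20, 18, 22, 18))
        per_rep, mean, _ = ddct_enrichment(t)
        assert per_rep.iloc[0]["ddct"] == pytest.approx(-2.0)
        assert mean == pytest.approx(4.0)

    def test_constant_ct_shift_cancels(self):
        base = self.full_replicate("r1", 20, 18, 22, 18)
        shifted = [(r, c, g, ct + 3) for r, c, g, ct in base]
        _, m1, _ = ddct_enrichment(self.table(base))
        _, m2, _ = ddct_enrichment(self.table(shifted))
        assert m1 == pytest.approx(m2)

    def test_mean_and_sem_over_replicates(self):
        rows = (
            self.full_replicate("r1", 20, 18, 22, 18)
            + self.full_replicate("r2", 20.5, 18, 22, 18)
            + self.full_replicate("r3", 19.5, 18, 22, 18)
        )
        per_rep, mean, sem = ddct_enrichment(self.table(rows))
        assert len(per_rep) == 3
        folds = per_rep["fold"]
        assert mean == pytest.approx(folds.mean())
        assert sem == pytest.approx(folds.std(ddof=1) / np.sqrt(3))

    def test_incomplete_replicate_named_in_error(self):
        rows = self.full_replicate("r1", 20, 18, 22, 18)[:-1]
        with pytest.raises(ValueError, match="r1"):
            ddct_enrichment(self.table(rows))

    def test_ct_range_validated(self):
        rows = self.full_replicate("r1", 20, 18, 47, 18)
        with pytest.raises(ValueError, match="Ct"):
            ddct_enrichment(self.table(rows))


class TestCountMatrixValidation:
    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"a": [1, -2], "b": [3, 4]})
        groups = pd.Series({"a": "capture", "b": "scrambled"})
        with pytest.raises(ValueError):
            CountMatrix(df, groups)

    def test_unknown_group_label_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        groups = pd.Series({"a": "capture", "b": "mock"})
        with pytest.raises(ValueError, match="unknown group"):
            CountMatrix(df, groups)
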