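import numpy as np
import pytest

from riboscope.evaluation import (
    LibraryEntry,
    OrfLibrary,
    benchmark_library,
    ncorf_cds_correlation,
    pr_auc,
    roc_auc,
    tpm_quantify,
)
from riboscope.ingest import ReadCountMatrix, SampleProfile
from riboscope.orf_calling import OrfCall


def brute_force_roc_auc(scores, labels):
    """All-pairs Mann-Whitney oracle."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_average_precision(scores, labels):
    """Average precision oracle: sum of precision at each positive, in rank
    order, divided by the number of positives (ties broken by stable sort of
    descending score, matching step-wise interpolation)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels)[order]
    scores_sorted = np.asarray(scores, dtype=float)[order]
    # group ties: precision evaluated at each distinct threshold
    ap = 0.0
    tp = 0
    n_pos = labels.sum()
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores_sorted[j] == scores_sorted[i]:
            j += 1
        tp_new = tp + labels[i:j].sum()
        precision = tp_new / j
        ap += precision * (tp_new - tp)
        tp = tp_new
        i = j
    return ap / n_pos


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_interleaved_is_half(self):
        assert roc_auc([0.9, 0.5, 0.1], [1, 0, 1]) == pytest.approx(0.5)

    def test_all_ties_is_half(self):
        assert roc_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_roc_auc(scores, labels), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(8)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels), pr_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels), pr_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_single_positive_ranked_first(self):
        scores = [0.99] + list(np.linspace(0.1, 0.5, 10))
        labels = [1] + [0] * 10
        assert pr_auc(scores, labels) == 1.0

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(10)
        n = 20000
        labels = (rng.random(n) < 0.2).astype(int)
        scores = rng.random(n)
        assert pr_auc(scores, labels) == pytest.approx(0.2, abs=0.02)

    def test_matches_brute_force_average_precision(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                brute_force_average_precision(scores, labels), abs=1e-12
            )


class TestBenchmarkLibrary:
    def _library(self):
        entries = [LibraryEntry("t1", 10, 40, 1), LibraryEntry("t1", 20, 50, 0),
                   LibraryEntry("t2", 5, 35, 1), LibraryEntry("t2", 8, 29, 0)]
        return OrfLibrary(entries, provenance="toy")

    def test_oracle_scorer_gives_auc_one(self):
        lib = self._library()
        scores = {"t1": np.zeros(100), "t2": np.zeros(100)}
        scores["t1"][10] = 1.0
        scores["t2"][5] = 1.0
        roc, pr = benchmark_library(scores, lib)
        assert roc == 1.0 and pr == 1.0

    def test_anti_oracle_gives_zero_roc(self):
        lib = self._library()
        scores = {"t1": np.zeros(100), "t2": np.zeros(100)}
        scores["t1"][20] = 1.0
        scores["t2"][8] = 1.0
        roc, _ = benchmark_library(scores, lib)
        assert roc == 0.0

    def test_unscored_transcript_errors(self):
        with pytest.raises(ValueError, match="t2"):
            benchmark_library({"t1": np.zeros(100)}, self._library())

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OrfLibrary([LibraryEntry("t", 1, 10, 1), LibraryEntry("t", 1, 10, 0)])

    def test_tsv_round_trip(self, tmp_path):
        lib = self._library()
        lib.to_tsv(tmp_path / "lib.tsv")
        loaded = OrfLibrary.from_tsv(tmp_path / "lib.tsv")
        assert [(e.transcript_id, e.tis_index, e.stop_index, e.label)
                for e in loaded.entries] == [
            (e.transcript_id, e.tis_index, e.stop_index, e.label) for e in lib.entries
        ]


def _profile(sample_id, counts_by_tx):
    matrices = {}
    for tid, (length, items) in counts_by_tx.items():
        m = ReadCountMatrix(tid, length)
        for pos, n in items:
            m.add(pos, 28, n)
        matrices[tid] = m
    return SampleProfile(sample_id, matrices)


class TestTpmQuantify:
    def test_single_orf_gets_a_million(self):
        calls = [OrfCall("t1", 0, 27, "ATG")]
        prof = _profile("s1", {"t1": (60, [(3, 5)])})
        tpm = tpm_quantify(calls, [prof])
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_rates_split_evenly(self):
        calls = [OrfCall("t1", 0, 27, "ATG"), OrfCall("t2", 0, 27, "ATG")]
        prof = _profile("s1", {"t1": (60, [(0, 4)]), "t2": (60, [(5, 4)])})
        tpm = tpm_quantify(calls, [prof])
        assert np.allclose(tpm["s1"], [5e5, 5e5])

    def test_depth_invariance(self):
        calls = [OrfCall("t1", 0, 27, "ATG"), OrfCall("t2", 0, 57, "ATG")]
        p1 = _profile("s1", {"t1": (60, [(0, 3)]), "t2": (60, [(5, 9)])})
        p2 = _profile("s2", {"t1": (60, [(0, 6)]), "t2": (60, [(5, 18)])})
        tpm = tpm_quantify(calls, [p1, p2])
        assert np.allclose(tpm["s1"], tpm["s2"])

    def test_zero_total_rate_errors(self):
        calls = [OrfCall("t1", 0, 27, "ATG")]
        with pytest.raises(ValueError, match="zero total"):
            tpm_quantify(calls, [_profile("s1", {"t1": (60, [])})])


class TestSpearman:
    def _tpm(self, a, b):
        import pandas as pd

        return pd.DataFrame(
            {f"s{i}": [x, y] for i, (x, y) in enumerate(zip(a, b))},
            index=["nc", "cds"],
        )

    def test_monotone_increasing_rho_one(self):
        tpm = self._tpm([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        out = ncorf_cds_correlation(tpm, [("nc", "cds")])
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        tpm = self._tpm([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        out = ncorf_cds_correlation(tpm, [("nc", "cds")])
        assert out.rho.iloc[0] == pytest.approx(-1.0)

    def test_hand_ranked_toy_table(self):
        # ranks a: [1,2,3,5,4]; ranks b: [2,1,3,4,5]; d = [-1,1,0,1,-1]
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/120 = 0.8
        tpm = self._tpm([10, 20, 30, 50, 40], [5, 2, 8, 9, 11])
        out = ncorf_cds_correlation(tpm, [("nc", "cds")])
        assert out.rho.iloc[0] == pytest.approx(0.8)

    def test_constant_vector_flagged_undefined(self):
        tpm = self._tpm([1, 1, 1, 1], [1, 2, 3, 4])
        out = ncorf_cds_correlation(tpm, [("nc", "cds")])
        assert not out.defined.iloc[0]
        assert np.isnan(out.rho.iloc[0])

    def test_too_few_samples_errors(self):
        tpm = self._tpm([1, 2], [3, 4])
        with pytest.raises(ValueError):
            ncorf_cds_correlation(tpm, [("nc", "cds")])
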