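"""Mismatch distributions, threshold calibration and single-linkage
family clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mpsspipe as mp
from mpsspipe import families as fam

seq21 = st.text(alphabet="ACGT", min_size=21, max_size=21)


class TestHamming:
    def test_identical_is_zero(self):
        assert mp.hamming("GATCA", "GATCA") == 0

    def test_single_substitution(self):
        assert mp.hamming("GATCA", "GATCC") == 1

    def test_full_length_maximum(self):
        a = "ACGT" * 5 + "A"
        b = "TGCA" * 5 + "T"
        assert mp.hamming(a, b) == 21

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            mp.hamming("ACGT", "ACG")

    @given(seq21, seq21, seq21)
    def test_metric_axioms(self, a, b, c):
        assert mp.hamming(a, b) == mp.hamming(b, a)
        assert (mp.hamming(a, b) == 0) == (a == b)
        assert mp.hamming(a, c) <= mp.hamming(a, b) + mp.hamming(b, c)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(41)
        seqs = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(15)]
        D = mp.pairwise_hamming_matrix(seqs)
        for i in range(15):
            for j in range(15):
                assert D[i, j] == mp.hamming(seqs[i], seqs[j])


class TestMismatchDistributions:
    def test_pair_combinatorics(self):
        seqs = ["AAAA", "AAAT", "CCCC", "CCCG"]
        labels = ["f1", "f1", "f2", "f2"]
        dist = mp.mismatch_distributions(seqs, labels)
        assert dist.n_within == 2
        assert dist.n_between == 4

    def test_identical_family_mass_at_zero(self):
        dist = mp.mismatch_distributions(["AAAA"] * 3 + ["CGCG"],
                                         ["f1"] * 3 + ["f2"])
        assert dist.within[0] == 3 and dist.within[1:].sum() == 0

    def test_planted_families_have_disjoint_distributions(self, small_dataset):
        truth = small_dataset.truth
        multi = truth.groupby("family").filter(lambda g: len(g) > 1)
        dist = mp.mismatch_distributions(list(multi["signature"]),
                                         list(multi["family"]))
        cfg = small_dataset.config
        within_support = np.flatnonzero(dist.within)
        between_support = np.flatnonzero(dist.between)
        assert within_support.max() <= cfg.within_family_max_mm
        assert between_support.min() >= cfg.between_family_min_mm


class TestCalibration:
    @staticmethod
    def _dist(within_at, between_at, L=21):
        w = np.zeros(L + 1, dtype=int)
        b = np.zeros(L + 1, dtype=int)
        for d, n in within_at.items():
            w[d] = n
        for d, n in between_at.items():
            b[d] = n
        return fam.MismatchDistribution(within=w, between=b)

    def test_gap_data_every_threshold_in_gap_significant(self):
        dist = self._dist({3: 200, 5: 100}, {8: 150, 12: 450})
        cal = mp.calibrate_threshold(dist, alpha=1e-10)
        sig_ts = cal.table.loc[cal.table["p"] < 1e-10, "t"].tolist()
        assert {5, 6, 7}.issubset(sig_ts)
        assert cal.chosen == 7       # largest zero-misclassification threshold

    def test_tight_regime_selects_five(self):
        dist = self._dist({1: 50, 4: 80, 5: 70}, {6: 90, 7: 200, 10: 300})
        cal = mp.calibrate_threshold(dist, alpha=1e-10)
        assert cal.chosen == 5

    def test_identical_distributions_fail(self):
        same = {2: 100, 9: 100}
        with pytest.raises(ValueError, match="no threshold"):
            mp.calibrate_threshold(self._dist(same, same), alpha=1e-10)

    def test_generator_regime_selects_five(self, small_dataset):
        truth = small_dataset.truth
        multi = truth.groupby("family").filter(lambda g: len(g) > 1)
        dist = mp.mismatch_distributions(list(multi["signature"]),
                                         list(multi["family"]))
        cal = mp.calibrate_threshold(dist, alpha=1e-10)
        assert cal.chosen == 5


class TestClustering:
    def test_mutually_close_trio_is_one_family(self):
        seqs = ["AAAAA", "AAAAT", "AAATT"]
        a = mp.cluster_families(seqs, t=2)
        assert len(a.partition()) == 1

    def test_single_linkage_is_transitive(self):
        # a-b and b-c within t, a-c beyond t: still one family
        a_, b_, c_ = "AAAAAAAA", "AAAATTAA", "AATTTTAA"
        assert mp.hamming(a_, c_) > 2
        a = mp.cluster_families([a_, b_, c_], t=2)
        assert len(a.partition()) == 1

    def test_input_order_invariant(self):
        rng = np.random.default_rng(43)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(30)]
        p1 = mp.cluster_families(seqs, 3).partition()
        p2 = mp.cluster_families(seqs[::-1], 3).partition()
        assert p1 == p2

    def test_zero_threshold_groups_identical_only(self):
        seqs = ["AAAA", "AAAT", "CCCC"]
        a = mp.cluster_families(seqs, 0)
        assert len(a.partition()) == 3

    def test_full_threshold_single_family(self):
        seqs = ["AAAA", "TTTT", "CGCG"]
        a = mp.cluster_families(seqs, 4)
        assert len(a.partition()) == 1

    def test_family_count_monotone_in_threshold(self):
        rng = np.random.default_rng(44)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(40)]
        counts = [len(mp.cluster_families(seqs, t).partition())
                  for t in range(0, 13)]
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_planted_partition_recovered_exactly(self, small_dataset):
        truth = small_dataset.truth
        a = mp.cluster_families(list(truth["signature"]),
                                small_dataset.config.within_family_max_mm)
        expected = {frozenset(g["signature"])
                    for _, g in truth.groupby("family")}
        assert a.partition() == expected


class TestHistogram:
    def test_singletons(self):
        a = fam.FamilyAssignment(
            families={f"s{i}": f"s{i}" for i in range(5)}, threshold=0)
        h = mp.family_size_histogram(a)
        assert h["family_size"].tolist() == [1]
        assert h["n_families"].tolist() == [5]

    def test_mixed_sizes(self):
        members = (["a"] * 3 + ["b"] * 3 + ["c"] * 7)
        fams = {f"{m}{i}": m for i, m in enumerate(members)}
        h = mp.family_size_histogram(fam.FamilyAssignment(fams, threshold=1))
        assert dict(zip(h["family_size"], h["n_families"])) == {3: 2, 7: 1}
        assert h.attrs["largest_family"] == 7

    def test_histogram_matches_planted_sizes(self, small_dataset):
        truth = small_dataset.truth
        a = mp.cluster_families(list(truth["signature"]),
                                small_dataset.config.within_family_max_mm)
        planted = truth.groupby("family").size().value_counts().sort_index()
        h = mp.family_size_histogram(a)
        assert dict(zip(h["family_size"], h["n_families"])) == \
            {int(k): int(v) for k, v in planted.items()}
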