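"""The synthetic MPSS dataset generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

import mpsspipe as mp
from mpsspipe import families as fam
from mpsspipe.synthetic import SimulationConfig, write_dataset, read_dataset


class TestConfigValidation:
    def test_within_must_be_below_between(self):
        with pytest.raises(ValueError, match="within_family_max_mm"):
            SimulationConfig(seed=1, within_family_max_mm=6,
                             between_family_min_mm=6)

    def test_exclusives_cannot_exceed_genes(self):
        with pytest.raises(ValueError, match="exclusive"):
            SimulationConfig(seed=1, n_genes=100, n_families=10,
                             exclusive_counts={"X": 487})

    def test_depth_positive(self):
        with pytest.raises(ValueError, match="depth"):
            SimulationConfig(seed=1, library_depth=0)

    def test_de_fraction_range(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimulationConfig(seed=1, de_fraction=1.5)


class TestPlantFamilySignatures:
    def _cfg(self, **kw):
        kw.setdefault("exclusive_counts", {})
        return SimulationConfig(seed=5, **kw)

    def test_singleton_family(self):
        sets = mp.plant_family_signatures([1], self._cfg())
        assert len(sets) == 1 and len(sets[0]) == 1
        assert sets[0][0].startswith("GATC")

    def test_two_families_default_geometry_verified_brute_force(self):
        cfg = self._cfg(between_family_min_mm=8)
        sets = mp.plant_family_signatures([4, 5], cfg)
        within_max = max(
            mp.hamming(a, b)
            for group in sets for a in group for b in group if a != b)
        between_min = min(mp.hamming(a, b)
                          for a in sets[0] for b in sets[1])
        assert within_max <= cfg.within_family_max_mm
        assert between_min >= 8

    def test_anchor_never_mutated(self):
        sets = mp.plant_family_signatures([6, 3, 1], self._cfg())
        assert all(s.startswith("GATC") for group in sets for s in group)

    def test_ef1a_like_tight_family(self):
        # six signatures with one or two pairwise mismatches
        cfg = self._cfg(within_family_max_mm=2, between_family_min_mm=6)
        group = mp.plant_family_signatures([6], cfg)[0]
        dists = [mp.hamming(a, b) for i, a in enumerate(group)
                 for b in group[i + 1:]]
        assert max(dists) <= 2 and min(dists) >= 1

    def test_infeasible_size_rejected(self):
        cfg = self._cfg(within_family_max_mm=1, between_family_min_mm=8)
        with pytest.raises(ValueError, match="infeasible"):
            mp.plant_family_signatures([10], cfg)

    def test_sizes_below_one_rejected(self):
        with pytest.raises(ValueError):
            mp.plant_family_signatures([0], self._cfg())


class TestGenerateDataset:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_genes=150, n_families=30,
                               library_depth=50_000, exclusive_counts={})
        for sub in ("a", "b"):
            write_dataset(mp.generate_dataset(cfg), tmp_path / sub)
        for name in ("counts.tsv", "unigenes.fasta", "annotations.tsv",
                     "ground_truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_library_sums_equal_depth(self, small_dataset):
        depth = small_dataset.config.library_depth
        assert (small_dataset.counts.sum(axis=0) == depth).all()

    def test_no_de_no_exclusives_means_flat_expected_tpm(self):
        cfg = SimulationConfig(seed=8, n_genes=120, n_families=20,
                               de_fraction=0.0, exclusive_counts={},
                               library_depth=50_000)
        truth = mp.generate_dataset(cfg).truth
        cols = [f"expected_tpm_{c}" for c in cfg.condition_labels]
        for c in cols[1:]:
            assert np.allclose(truth[cols[0]], truth[c])

    def test_planted_487_xenic_exclusives(self):
        cfg = SimulationConfig(seed=13)   # study defaults: F18 N2 P12 X487
        truth = mp.generate_dataset(cfg).truth
        x = truth[truth["exclusive_to"] == "X"]
        assert len(x) == 487
        assert (x["expected_tpm_X"] > 0).all()
        for other in ("F", "N", "P"):
            assert (x[f"expected_tpm_{other}"] == 0).all()

    def test_all_signatures_anchored(self, small_dataset):
        assert small_dataset.truth["signature"].str.startswith("GATC").all()

    def test_planted_mean_tpm_unbiased_over_seeds(self):
        """Over 20 seeds the mean realized TPM of a planted gene stays
        within 3 standard errors of its expected TPM."""
        base = dict(n_genes=100, n_families=20, library_depth=50_000,
                    de_fraction=0.0, exclusive_counts={})
        deviations = []
        gene = 17
        for seed in range(20):
            ds = mp.generate_dataset(SimulationConfig(seed=1000 + seed, **base))
            m = mp.run_qc(ds.counts, mp.QCConfig(min_tpm=1e-9))
            row = ds.truth.iloc[gene]
            deviations.append(m.tpm.loc[row["signature"], "F"]
                              - row["expected_tpm_F"])
        deviations = np.array(deviations)
        se = deviations.std(ddof=1) / np.sqrt(len(deviations))
        assert abs(deviations.mean()) < 3 * se

    def test_planted_fold_change_materializes(self):
        cfg = SimulationConfig(seed=77, n_genes=400, n_families=40,
                               de_fraction=0.1,
                               log2fc_law=("fixed", 2.0),
                               exclusive_counts={})
        truth = mp.generate_dataset(cfg).truth
        de = truth[truth["de_status_N"] == "up"]
        ratio = de["expected_tpm_N"] / de["expected_tpm_F"]
        # exact on weights; TPM renormalization shifts it by the ratio of
        # library totals (a few percent at this DE fraction)
        assert np.allclose(ratio, 4.0, rtol=0.1)

    def test_noise_tags_present_and_filterable(self, small_dataset):
        counts = small_dataset.counts
        n_gene_tags = len(small_dataset.truth)
        assert len(counts) > n_gene_tags
        clean = mp.filter_sequences(counts)
        assert len(clean) < len(counts)
        assert set(small_dataset.truth["signature"]).issubset(set(clean.index))


class TestRoundTrip:
    def test_write_read_counts_equal(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(back["counts"], small_dataset.counts)

    def test_fasta_annotation_referential_integrity(self, small_dataset,
                                                    tmp_path):
        write_dataset(small_dataset, tmp_path)
        back = read_dataset(tmp_path)
        assert set(back["annotations"]["unigene"]) <= set(back["unigenes"])

    def test_empty_dataset_round_trips(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=0, n_families=0,
                               exclusive_counts={})
        ds = mp.generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        back = read_dataset(tmp_path)
        assert back["counts"].empty
        assert back["unigenes"] == {}


class TestDownstreamRecovery:
    def test_signatures_recovered_by_mapper(self, small_dataset):
        table = mp.match_all(list(small_dataset.truth["signature"]),
                             small_dataset.unigenes)
        best = table[table["rank"] == 1]
        assert (best["mismatches"] == 0).all()
        assert len(best) == len(small_dataset.truth)

    def test_family_partition_recovered_by_clustering(self, small_dataset):
        truth = small_dataset.truth
        a = mp.cluster_families(list(truth["signature"]), 5)
        expected = {frozenset(g["signature"])
                    for _, g in truth.groupby("family")}
        assert a.partition() == expected
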