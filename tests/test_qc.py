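"""QC tests: method-of-moments IBD against pedigree constructions, the
younger-relative pruning rule, and PCA/clustering outlier detection."""

import numpy as np
import pandas as pd
import pytest

import lipidprs as lp
from lipidprs.qc import QCError, qc_accounting


def _hw_genotypes(n_samples, n_variants, seed, freq=None):
    """Unrelated Hardy-Weinberg genotypes (haplotype pairs), plus the haplotypes."""
    rng = np.random.default_rng(seed)
    if freq is None:
        freq = rng.uniform(0.1, 0.5, n_variants)
    h1 = (rng.random((n_samples, n_variants)) < freq).astype(float)
    h2 = (rng.random((n_samples, n_variants)) < freq).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_variants + 1),
            "id": [f"v{j}" for j in range(n_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return lp.GenotypeMatrix(samples, variants, h1 + h2), (h1, h2), freq


class TestEstimateIbd:
    def test_duplicate_sample_has_pi_hat_near_one(self):
        g, _, _ = _hw_genotypes(30, 500, seed=1)
        dup = np.vstack([g.dosages, g.dosages[0]])
        g2 = lp.GenotypeMatrix(g.samples + ["DUP"], g.variants.copy(), dup)
        pairs = lp.estimate_ibd(g2)
        row = pairs[(pairs["sample_a"] == "S000") & (pairs["sample_b"] == "DUP")]
        assert row["pi_hat"].iloc[0] >= 0.95

    def test_parent_offspring_pi_hat_near_half(self):
        g, (h1, h2), freq = _hw_genotypes(100, 2000, seed=2)
        rng = np.random.default_rng(3)
        # child inherits sample 0's first haplotype plus a population haplotype
        child = h1[0] + (rng.random(2000) < freq).astype(float)
        g2 = lp.GenotypeMatrix(
            g.samples + ["CHILD"], g.variants.copy(), np.vstack([g.dosages, child])
        )
        pairs = lp.estimate_ibd(g2)
        row = pairs[(pairs["sample_a"] == "S000") & (pairs["sample_b"] == "CHILD")]
        assert 0.4 <= row["pi_hat"].iloc[0] <= 0.6

    def test_unrelated_pairs_have_low_pi_hat(self):
        g, _, _ = _hw_genotypes(40, 2000, seed=4)
        pairs = lp.estimate_ibd(g)
        assert pairs["pi_hat"].max() < 0.15

    def test_probabilities_normalized(self):
        g, _, _ = _hw_genotypes(20, 300, seed=5)
        pairs = lp.estimate_ibd(g)
        total = pairs[["p_ibd0", "p_ibd1", "p_ibd2"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert pairs["pi_hat"].between(0, 1).all()

    def test_monomorphic_panel_rejected(self):
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1, 2], "id": ["a", "b"], "ref": "A", "alt": "G"}
        )
        g = lp.GenotypeMatrix(["x", "y", "z"], variants, np.zeros((3, 2)))
        with pytest.raises(QCError, match="monomorphic"):
            lp.estimate_ibd(g)


class TestPruneRelatives:
    @staticmethod
    def _pairs(rows):
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pi_hat"]).assign(
            p_ibd0=0.0, p_ibd1=1.0, p_ibd2=0.0
        )

    def test_younger_member_removed(self):
        pairs = self._pairs([("A", "B", 0.4)])
        assert lp.prune_relatives(pairs, {"A": 60, "B": 40}, 0.33) == ["B"]

    def test_no_pairs_above_threshold_is_noop(self):
        pairs = self._pairs([("A", "B", 0.2), ("B", "C", 0.33)])
        assert lp.prune_relatives(pairs, {"A": 1, "B": 2, "C": 3}, 0.33) == []

    def test_age_tie_removes_larger_id(self):
        pairs = self._pairs([("A", "B", 0.5)])
        assert lp.prune_relatives(pairs, {"A": 50, "B": 50}, 0.33) == ["B"]

    def test_triangle_resolved_in_pi_hat_order(self):
        pairs = self._pairs([("A", "B", 0.4), ("B", "C", 0.5)])
        ages = {"A": 70, "B": 50, "C": 30}
        removed = lp.prune_relatives(pairs, ages, 0.33)
        # B-C handled first (higher PI_HAT): C removed; A-B still flagged: B removed
        assert removed == ["C", "B"]

    def test_result_independent_of_input_order(self):
        rng = np.random.default_rng(6)
        samples = list("ABCDEF")
        rows = [
            (a, b, rng.uniform(0.1, 0.7))
            for i, a in enumerate(samples)
            for b in samples[i + 1:]
        ]
        ages = {s: int(rng.integers(20, 80)) for s in samples}
        base = lp.prune_relatives(self._pairs(rows), ages, 0.33)
        for perm_seed in range(5):
            shuffled = self._pairs(rows).sample(frac=1, random_state=perm_seed)
            assert lp.prune_relatives(shuffled, ages, 0.33) == base

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(12)]
        rows = [
            (a, b, rng.uniform(0, 0.8))
            for i, a in enumerate(samples)
            for b in samples[i + 1:]
        ]
        pairs = self._pairs(rows)
        ages = {s: int(rng.integers(20, 80)) for s in samples}
        removed = set(lp.prune_relatives(pairs, ages, 0.33))
        retained = pairs[
            ~pairs["sample_a"].isin(removed) & ~pairs["sample_b"].isin(removed)
        ]
        assert (retained["pi_hat"] <= 0.33).all()

    def test_missing_age_raises_with_sample_name(self):
        pairs = self._pairs([("A", "B", 0.5)])
        with pytest.raises(QCError, match="B"):
            lp.prune_relatives(pairs, {"A": 50}, 0.33)


class TestPcaOutliers:
    def test_homogeneous_cohort_flags_nothing(self):
        flagged = []
        for seed in range(10):
            g = lp.simulate_genotypes(
                300, lp.LDBlockSpec(n_blocks=60, variants_per_block=5), seed=seed
            )
            res = lp.pca_outliers(g, k=5, cut=0.01)
            flagged.append(res.outlier.sum() == 0)
        assert np.mean(flagged) >= 0.95

    def test_planted_frequency_shifted_samples_flagged(self):
        spec = lp.LDBlockSpec(n_blocks=60, variants_per_block=5, within_block_r=0.2)
        main = lp.simulate_genotypes(480, spec, seed=30)
        rng = np.random.default_rng(31)
        freq = np.clip(main.allele_freq() + rng.choice([-0.25, 0.25], main.n_variants), 0.02, 0.95)
        shifted = (
            (rng.random((20, main.n_variants)) < freq).astype(float)
            + (rng.random((20, main.n_variants)) < freq).astype(float)
        )
        g = lp.GenotypeMatrix(
            main.samples + [f"OUT{i}" for i in range(20)],
            main.variants.copy(),
            np.vstack([main.dosages, shifted]),
        )
        res = lp.pca_outliers(g, k=10, cut=0.05)
        flagged = set(res.outlier_ids())
        assert sum(f"OUT{i}" in flagged for i in range(20)) >= 16

    def test_two_separated_populations_recovered_with_one_component(self):
        rng = np.random.default_rng(32)
        n, m = 60, 200
        freq_a = rng.uniform(0.1, 0.3, m)
        freq_b = np.clip(freq_a + 0.5, 0, 0.95)
        pop_a = ((rng.random((n, m)) < freq_a) + (rng.random((n, m)) < freq_a)).astype(float)
        pop_b = ((rng.random((n, m)) < freq_b) + (rng.random((n, m)) < freq_b)).astype(float)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, m + 1), "id": [f"v{j}" for j in range(m)],
             "ref": "A", "alt": "G"}
        )
        g = lp.GenotypeMatrix(
            [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
            variants, np.vstack([pop_a, pop_b]),
        )
        res = lp.pca_outliers(g, k=1, cut=0.01, max_clusters=2)
        labels_a = set(res.cluster_labels[:n])
        labels_b = set(res.cluster_labels[n:])
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_scores_sign_invariant_under_sample_reordering(self, block_genotypes):
        res = lp.pca_outliers(block_genotypes, k=3, cut=0.01)
        order = np.random.default_rng(33).permutation(block_genotypes.n_samples)
        reordered = block_genotypes.subset_samples(
            [block_genotypes.samples[i] for i in order]
        )
        res2 = lp.pca_outliers(reordered, k=3, cut=0.01)
        for c in range(3):
            a, b = res.scores[order, c], res2.scores[:, c]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_invalid_k_rejected(self, tiny_genotypes):
        with pytest.raises(ValueError):
            lp.pca_outliers(tiny_genotypes, k=0)
        with pytest.raises(ValueError):
            lp.pca_outliers(tiny_genotypes, k=5)


class TestAccounting:
    def test_stagewise_accounting(self):
        table = qc_accounting(1858, {"relatives": 173, "pca_outliers": 4, "missing_data": 8})
        assert table.loc[table["stage"] == "final", "remaining"].iloc[0] == 1673

    def test_over_removal_rejected(self):
        with pytest.raises(QCError):
            qc_accounting(10, {"relatives": 11})
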