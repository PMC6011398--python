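"""Cross-validated AUC scoring, epsilon optimization, genome-wide scans."""

import numpy as np
import pytest

from ddascan import (
    GenotypeData,
    ScanConfig,
    SimSpec,
    SnpGroup,
    SnpInfo,
    auc,
    cv_auc,
    cv_auc_curve,
    optimize_epsilon,
    scan_groups,
    scan_snps,
    simulate_genotypes,
)
from ddascan.scan import fold_indices


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 10, 50).astype(float)  # integer scores force ties
        labels = rng.integers(0, 2, 50)
        cases = scores[labels == 1]
        ctrls = scores[labels == 0]
        total = 0.0
        for c in cases:
            for d in ctrls:
                total += 1.0 if c > d else (0.5 if c == d else 0.0)
        expected = total / (len(cases) * len(ctrls))
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        assert auc(s, y) == pytest.approx(auc(s + 123.4, y), abs=1e-12)


class TestFoldIndices:
    def test_partition_and_stratification(self):
        labels = np.array([1] * 37 + [0] * 63)
        folds = fold_indices(labels, 5, seed=3)
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(all_test, np.arange(100))
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(100))
            assert not set(tr) & set(te)
            # class ratio per fold within one individual of global
            assert abs((labels[te] == 1).sum() - 37 / 5) <= 1

    def test_balance_matches_sklearn_guarantee(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.random.default_rng(5).integers(0, 2, 101)
        ours = fold_indices(labels, 5, seed=1)
        theirs = list(
            StratifiedKFold(5, shuffle=True, random_state=1).split(np.zeros(101), labels)
        )
        ours_sizes = sorted((labels[te] == 1).sum() for _, te in ours)
        theirs_sizes = sorted((labels[te] == 1).sum() for _, te in theirs)
        assert ours_sizes == theirs_sizes

    def test_depends_only_on_labels_folds_seed(self):
        labels = np.random.default_rng(2).integers(0, 2, 60)
        a = fold_indices(labels, 4, seed=9)
        b = fold_indices(labels.copy(), 4, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_holds_out_one_kth_of_samples(self):
        labels = np.array([0, 1] * 250)
        folds = fold_indices(labels, 5, seed=0)
        for _, te in folds:
            assert te.size == 100  # exactly 20% held out


class TestCvAuc:
    def test_null_band(self, null_dataset, whole_group):
        G, labels = null_dataset
        val = cv_auc(G, labels, whole_group(20), 0.5, ScanConfig(seed=17))
        assert 0.4 <= val <= 0.6

    def test_perfect_predictor(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 100)
        matrix = np.where(labels[:, None] == 1, 2, 0).astype(np.int8)
        matrix = np.hstack([matrix, rng.integers(0, 3, size=(200, 3), dtype=np.int8)])
        snps = [SnpInfo(f"s{i}", "1", 100 + i) for i in range(4)]
        G = GenotypeData(matrix, snps, [f"x{i}" for i in range(200)])
        grp = SnpGroup("g", "custom", np.arange(4))
        assert cv_auc(G, labels, grp, 0.0, ScanConfig(seed=5)) >= 0.99

    def test_bitwise_deterministic(self, null_dataset, whole_group):
        G, labels = null_dataset
        cfg = ScanConfig(seed=23)
        a = cv_auc(G, labels, whole_group(15), 0.3, cfg)
        b = cv_auc(G, labels, whole_group(15), 0.3, cfg)
        assert a == b

    def test_row_permutation_with_matched_folds_preserves_auc(self, null_dataset, whole_group):
        """Permuting rows while carrying the fold assignment along is a no-op."""
        G, labels = null_dataset
        grp = whole_group(10)
        cfg = ScanConfig(seed=31)
        folds = fold_indices(labels, cfg.n_folds, cfg.seed)
        base = cv_auc_curve(G, labels, grp, [0.0, 0.5], cfg, folds=folds)
        perm = np.random.default_rng(6).permutation(G.n_samples)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        G2 = GenotypeData(G.matrix[perm], G.snps, [G.sample_ids[i] for i in perm])
        folds2 = [(inv[tr], inv[te]) for tr, te in folds]
        moved = cv_auc_curve(G2, labels[perm], grp, [0.0, 0.5], cfg, folds=folds2)
        assert np.allclose(base, moved, atol=1e-12)


class TestOptimizeEpsilon:
    def test_degenerate_grid(self, null_dataset, whole_group):
        G, labels = null_dataset
        cfg = ScanConfig(seed=2, epsilon_grid=(0.0,))
        eps, best, zero = optimize_epsilon(G, labels, whole_group(10), cfg)
        assert eps == 0.0 and best == zero

    def test_cl_never_below_il(self, null_dataset, whole_group):
        G, labels = null_dataset
        for seed in range(5):
            _, best, zero = optimize_epsilon(
                G, labels, whole_group(12), ScanConfig(seed=seed)
            )
            assert best >= zero - 1e-15

    def test_main_effects_prefer_epsilon_zero(self):
        """With purely additive signal, eps* = 0 is the modal selection."""
        from ddascan import EffectSpec, simulate_case_control

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = SimSpec(n_samples=400, n_snps=12, seed=100 + seed)
            effects = EffectSpec(beta0=0.0, beta={0: 0.7, 1: 0.7, 2: 0.7})
            G = simulate_case_control(spec, effects, 200, 200, seed=200 + seed)
            grp = SnpGroup("g", "custom", np.arange(12))
            eps, _, _ = optimize_epsilon(G, G.labels, grp, ScanConfig(seed=seed))
            wins += eps == 0.0
        assert wins > n_seeds / 2


class TestScanGroups:
    def test_null_groups_land_in_null_band(self, null_dataset):
        G, labels = null_dataset
        groups = [
            SnpGroup(f"g{k}", "custom", np.arange(5 * k, 5 * k + 5)) for k in range(3)
        ]
        scores = scan_groups(G, labels, groups, ScanConfig(seed=4))
        assert len(scores) == 3
        for s in scores:
            assert 0.35 <= s.auc_cl <= 0.65
            assert s.auc_cl >= s.auc_il

    def test_duplicate_names_rejected_before_scanning(self, null_dataset, whole_group):
        G, labels = null_dataset
        groups = [whole_group(5, "dup"), whole_group(8, "dup")]
        with pytest.raises(ValueError, match="dup"):
            scan_groups(G, labels, groups, ScanConfig(seed=0))

    def test_failed_group_reported_as_na_row(self, null_dataset, whole_group):
        G, labels = null_dataset
        # a group pointing at a monomorphic artificial column triggers a
        # per-group failure without killing the scan
        matrix = G.matrix.copy()
        bad = GenotypeData(matrix, G.snps, G.sample_ids)
        groups = [whole_group(6, "ok"), SnpGroup("empty", "custom", np.array([], dtype=int))]
        scores = scan_groups(bad, labels, groups, ScanConfig(seed=1))
        by_name = {s.name: s for s in scores}
        assert by_name["ok"].error is None
        assert by_name["empty"].error is not None
        assert np.isnan(by_name["empty"].auc_cl)

    def test_optional_ld_pruning_shrinks_reported_group(self):
        G = simulate_genotypes(
            SimSpec(n_samples=400, n_snps=10, ld_blocks=[(10, 0.98)], seed=77)
        )
        labels = np.tile([0, 1], 200)
        groups = [SnpGroup("block", "custom", np.arange(10))]
        scores = scan_groups(G, labels, groups, ScanConfig(seed=0, r2_max=0.5))
        assert scores[0].n_snps < 10  # pruning happened before scoring

    def test_sorted_by_cl_auc_descending(self, null_dataset):
        G, labels = null_dataset
        groups = [SnpGroup(f"g{k}", "custom", np.arange(4 * k, 4 * k + 4)) for k in range(4)]
        scores = scan_groups(G, labels, groups, ScanConfig(seed=8))
        aucs = [s.auc_cl for s in scores]
        assert aucs == sorted(aucs, reverse=True)


class TestScanSnps:
    def test_strong_snp_tiny_p(self):
        labels = np.repeat([0, 1], 1000)
        matrix = np.where(labels[:, None] == 1, 2, 0).astype(np.int8)
        G = GenotypeData(matrix, [SnpInfo("hit", "1", 1)], [f"x{i}" for i in range(2000)])
        frame = scan_snps(G, labels)
        assert frame.loc[0, "p"] < 1e-10

    def test_monomorphic_reported_na(self):
        matrix = np.column_stack([np.zeros(40, dtype=int), np.tile([0, 1, 2, 1], 10)])
        snps = [SnpInfo("mono", "1", 1), SnpInfo("poly", "1", 2)]
        G = GenotypeData(matrix.astype(np.int8), snps, [f"x{i}" for i in range(40)])
        frame = scan_snps(G, np.tile([0, 1], 20))
        assert np.isnan(frame.loc[0, "p"])
        assert np.isfinite(frame.loc[1, "p"])

    def test_null_type_i_error_near_nominal(self):
        G = simulate_genotypes(SimSpec(n_samples=800, n_snps=1000, seed=44))
        labels = np.tile([0, 1], 400)
        frame = scan_snps(G, labels)
        frac = (frame["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
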