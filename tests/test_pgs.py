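"""LD clumping, scoring, cross-validation and transfer checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coralmme.data import AnalysisConfig, ParameterError
from coralmme.association import GwasDesign, GwasResult, gwas
from coralmme.pgs import (
    PgsModel,
    build_pgs,
    compare_models,
    jackknife_cv,
    ld_clump,
    ld_r2,
    null_pgs,
    score_samples,
    transfer_pgs,
)

from conftest import make_matrix


def fake_gwas_table(locus_ids, chrom, pos, p, beta=None):
    n = len(locus_ids)
    return pd.DataFrame({
        "locus_id": locus_ids, "chrom": chrom, "pos": pos,
        "beta": beta if beta is not None else np.ones(n),
        "se": np.ones(n), "p": p, "n_used": np.full(n, 10),
        "fallback": np.zeros(n, bool),
    })


class TestLdR2:
    def test_identical_columns(self):
        g = make_matrix(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        g = make_matrix(np.array([[0, 2], [1, 1], [2, 0], [1, 1]]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_hand_pearson(self):
        x = np.array([0, 1, 2, 0])
        y = np.array([0, 2, 2, 1])
        g = make_matrix(np.column_stack([x, y]))
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(g, 0, 1) == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_defined_as_zero(self):
        g = make_matrix(np.array([[1, 0], [1, 1], [1, 2]]))
        assert ld_r2(g, 0, 1) == 0.0


def brute_clump(table, g, p_threshold, window, r2max):
    """Independent greedy oracle using explicit pairwise loops."""
    cand = table[table["p"] < p_threshold].sort_values(
        ["p", "chrom", "pos"], kind="mergesort")
    kept = []
    col_of = {l: j for j, l in enumerate(g.locus_ids)}
    for _, row in cand.iterrows():
        ok = True
        for kid in kept:
            krow = table.set_index("locus_id").loc[kid]
            if krow["chrom"] != row["chrom"]:
                continue
            if abs(int(krow["pos"]) - int(row["pos"])) > window:
                continue
            if ld_r2(g, col_of[row["locus_id"]], col_of[kid]) > r2max:
                ok = False
                break
        if ok:
            kept.append(row["locus_id"])
    return kept


class TestLdClump:
    def test_hand_run_of_greedy_rule(self, rng):
        # A (p=1e-5) and B (p=1e-3) 10 kb apart in strong LD; C (p=1e-4)
        # nearby but unlinked -> keep {A, C}
        n = 40
        a = rng.binomial(2, 0.5, size=n)
        b = a.copy()
        flip = rng.random(n) < 0.05
        b[flip] = rng.binomial(2, 0.5, size=flip.sum())  # r2 ~ 0.9
        c = rng.binomial(2, 0.5, size=n)
        g = make_matrix(np.column_stack([a, b, c]),
                        chrom=["1", "1", "1"], pos=[100, 10_100, 20_000],
                        locus_ids=["A", "B", "C"])
        assert ld_r2(g, 0, 1) > 0.5
        assert ld_r2(g, 0, 2) < 0.3
        table = fake_gwas_table(["A", "B", "C"], ["1"] * 3,
                                [100, 10_100, 20_000], [1e-5, 1e-3, 1e-4])
        kept = ld_clump(table, g, 0.05, clump_window_bp=250_000,
                        clump_r2_max=0.5)
        assert kept == ["A", "C"]

    def test_unlinked_keeps_all_passing(self, rng):
        d = rng.binomial(2, 0.5, size=(60, 20))
        g = make_matrix(d)
        table = fake_gwas_table(g.locus_ids, g.chrom, g.pos,
                                np.full(20, 1e-4))
        kept = ld_clump(table, g, 0.05, clump_window_bp=10,
                        clump_r2_max=0.5)
        assert len(kept) == 20

    def test_below_threshold_empty(self, rng):
        g = make_matrix(rng.binomial(2, 0.5, size=(10, 5)))
        table = fake_gwas_table(g.locus_ids, g.chrom, g.pos, np.full(5, 0.5))
        assert ld_clump(table, g, 1e-4) == []

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            L = 30
            d = rng.binomial(2, rng.uniform(0.2, 0.8, L), size=(25, L))
            # induce some LD by copying columns with noise
            for j in range(0, L - 1, 5):
                d[:, j + 1] = np.where(rng.random(25) < 0.8, d[:, j],
                                       d[:, j + 1])
            pos = np.sort(rng.choice(10 ** 6, size=L, replace=False))
            g = make_matrix(d, pos=pos)
            table = fake_gwas_table(g.locus_ids, g.chrom, g.pos,
                                    rng.uniform(0, 0.1, L))
            for window, r2max in ((50_000, 0.3), (200_000, 0.6)):
                kept = ld_clump(table, g, 0.05, window, r2max)
                oracle = brute_clump(table, g, 0.05, window, r2max)
                assert kept == oracle


class TestScoring:
    def test_dot_product(self):
        g = make_matrix(np.array([[0, 1, 2]]))
        model = PgsModel(g.locus_ids, np.array([0.5, -0.2, 0.1]), 0.05,
                         250_000, 0.5)
        assert score_samples(model, g)[0] == pytest.approx(0.0)

    def test_linearity_in_betas(self, rng):
        d = rng.binomial(2, 0.5, size=(10, 6))
        g = make_matrix(d)
        betas = rng.normal(size=6)
        m1 = PgsModel(g.locus_ids, betas, 0.05, 250_000, 0.5)
        m2 = PgsModel(g.locus_ids, 2 * betas, 0.05, 250_000, 0.5)
        np.testing.assert_allclose(2 * score_samples(m1, g),
                                   score_samples(m2, g), atol=1e-12)

    def test_zero_betas_zero_scores(self, rng):
        g = make_matrix(rng.binomial(2, 0.5, size=(5, 4)))
        model = PgsModel(g.locus_ids, np.zeros(4), 0.05, 250_000, 0.5)
        assert np.all(score_samples(model, g) == 0)

    def test_mostly_absent_model_errors(self, rng):
        g = make_matrix(rng.binomial(2, 0.5, size=(5, 4)))
        model = PgsModel(np.array(["x1", "x2", "x3", g.locus_ids[0]],
                                  dtype=object),
                         np.ones(4), 0.05, 250_000, 0.5)
        with pytest.raises(ParameterError):
            score_samples(model, g)

    def test_allele_flip_equivariance(self, rng):
        d = rng.binomial(2, 0.5, size=(12, 8))
        g = make_matrix(d)
        gf = make_matrix(2 - d)
        betas = rng.normal(size=8)
        m = PgsModel(g.locus_ids, betas, 0.05, 250_000, 0.5)
        mf = PgsModel(g.locus_ids, -betas, 0.05, 250_000, 0.5)
        s, sf = score_samples(m, g), score_samples(mf, gf)
        np.testing.assert_allclose(s - s.mean(), sf - sf.mean(), atol=1e-10)


@pytest.fixture(scope="module")
def cv_cohort():
    """Strong-signal cohort for CV checks: h2=0.5, 40 causal loci."""
    rng = np.random.default_rng(11)
    n, L = 300, 600
    d = rng.binomial(2, rng.uniform(0.2, 0.8, L), size=(n, L))
    causal = rng.choice(L, 40, replace=False)
    betas = rng.normal(size=40)
    gterm = d[:, causal] @ betas
    gterm = (gterm - gterm.mean()) / gterm.std() * np.sqrt(0.5)
    y = gterm + rng.normal(0, np.sqrt(0.5), n)
    per = L // 14 + 1
    g = make_matrix(d, chrom=[f"c{j // per}" for j in range(L)],
                    pos=[(j % per + 1) * 100_000 for j in range(L)],
                    locus_ids=[f"L{j}" for j in range(L)])
    return g, y


def _sorted_matrix(rng, n, L):
    d = rng.binomial(2, rng.uniform(0.2, 0.8, L), size=(n, L))
    per = L // 14 + 1
    chrom = [f"c{j // per}" for j in range(L)]
    pos = [(j % per + 1) * 100_000 for j in range(L)]
    return make_matrix(d, chrom=chrom, pos=pos,
                       locus_ids=[f"L{j}" for j in range(L)])


class TestJackknifeCv:
    def test_requires_forty_samples(self, rng):
        g = _sorted_matrix(rng, 20, 30)
        design = GwasDesign(rng.normal(size=20), None, np.arange(20))
        with pytest.raises(ParameterError):
            jackknife_cv(design, g)

    def test_signal_cohort_beats_null(self, cv_cohort):
        g, y = cv_cohort
        design = GwasDesign(y, None, np.arange(len(y)))
        cfg = AnalysisConfig(n_cv_partitions=30)
        report, model = jackknife_cv(design, g, cfg, rng=5)
        assert report.real_r2.mean() > report.null_r2.mean()
        assert report.mannwhitney_p < 0.05
        assert not model.empty

    def test_deterministic_given_seed(self, cv_cohort):
        g, y = cv_cohort
        design = GwasDesign(y, None, np.arange(len(y)))
        cfg = AnalysisConfig(n_cv_partitions=8)
        r1, m1 = jackknife_cv(design, g, cfg, rng=3)
        r2, m2 = jackknife_cv(design, g, cfg, rng=3)
        np.testing.assert_array_equal(r1.real_r2, r2.real_r2)
        np.testing.assert_array_equal(m1.locus_ids, m2.locus_ids)
        pd.testing.assert_frame_equal(r1.r2_by_threshold, r2.r2_by_threshold)

    def test_no_train_test_leak(self, cv_cohort):
        g, y = cv_cohort
        design = GwasDesign(y, None, np.arange(len(y)))
        cfg = AnalysisConfig(n_cv_partitions=5)
        report, _ = jackknife_cv(design, g, cfg, rng=2)
        n = len(y)
        for test in report.partitions:
            train = np.setdiff1d(np.arange(n), test)
            assert len(np.intersect1d(train, test)) == 0
            assert len(test) == round(0.15 * n)


class TestNullPgs:
    def test_disjoint_seeded_draws(self, cv_cohort):
        g, y = cv_cohort
        design = GwasDesign(y, None, np.arange(len(y)))
        res = gwas(design, g)
        model = build_pgs(res, g, 0.01)
        r1 = null_pgs(res, g, model, 20, y, rng=4)
        r2 = null_pgs(res, g, model, 20, y, rng=4)
        np.testing.assert_array_equal(r1, r2)
        assert np.ptp(r1) > 0  # different sets give different R2

    def test_model_larger_than_universe_errors(self, rng):
        g = _sorted_matrix(rng, 50, 10)
        design = GwasDesign(rng.normal(size=50), None, np.arange(50))
        res = gwas(design, g)
        model = PgsModel(np.array([f"x{i}" for i in range(20)], dtype=object),
                         np.ones(20), 0.05, 250_000, 0.5)
        with pytest.raises(ParameterError):
            null_pgs(res, g, model, 5, design.trait)


class TestCompareModels:
    def test_mannwhitney_exact_enumeration(self):
        # U = 0 for [1,2,3] vs [4,5,6]: 2 / C(6,3) = 0.1 two-sided
        res = stats.mannwhitneyu([1, 2, 3], [4, 5, 6],
                                 alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(0.1)

    def test_noise_pgs_not_significant(self, rng):
        n = 200
        cov = rng.normal(size=(n, 2))
        y = cov @ np.array([0.5, -0.3]) + rng.normal(size=n)
        noise_pgs = rng.normal(size=n)
        out = compare_models(y, {"noise": noise_pgs}, cov, n_partitions=40,
                             rng=1)
        assert out.loc[0, "p_adj"] > 0.05
        assert abs(out.loc[0, "delta_r2"]) < 0.05

    def test_real_pgs_significant_null_not(self, cv_cohort, rng):
        g, y = cv_cohort
        design = GwasDesign(y, None, np.arange(len(y)))
        res = gwas(design, g)
        model = build_pgs(res, g, 1e-3)
        real = score_samples(model, g)
        perm = rng.permutation(len(y))
        null = real[perm]  # same distribution, no association
        cov = rng.normal(size=(len(y), 2))
        out = compare_models(y, {"real": real, "null": null}, cov,
                             n_partitions=60, rng=2).set_index("pgs")
        assert out.loc["real", "p_adj"] < 0.05
        assert out.loc["real", "delta_r2"] > out.loc["null", "delta_r2"]

    def test_singular_covariates_rejected(self, rng):
        cov = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ParameterError):
            compare_models(rng.normal(size=30), {"a": rng.normal(size=30)},
                           cov)


class TestTransfer:
    def test_identical_train_target_equals_in_sample(self, cv_cohort):
        g, y = cv_cohort
        n = len(y)
        design = GwasDesign(y, None, np.arange(n))
        out = transfer_pgs(design, g, np.arange(n), y,
                           thresholds=(1e-3,), n_random_sets=20, rng=1)
        res = gwas(design, g)
        model = build_pgs(res, g, 1e-3)
        score = score_samples(model, g)
        r = np.corrcoef(score, y)[0, 1]
        assert out.loc[0, "r2"] == pytest.approx(r * r, abs=1e-12)

    def test_shared_architecture_transfers_disjoint_does_not(self, rng):
        n, L = 250, 400
        p = rng.uniform(0.2, 0.8, L)
        dA = rng.binomial(2, p, size=(n, L))
        dB = rng.binomial(2, p, size=(n, L))
        causal = rng.choice(L, 30, replace=False)
        betas = rng.normal(size=30)
        def liab(d):
            v = d[:, causal] @ betas
            return (v - v.mean()) / v.std() * np.sqrt(0.6) + \
                rng.normal(0, np.sqrt(0.4), n)
        yA, yB_shared = liab(dA), liab(dB)
        yB_disjoint = rng.normal(size=n)  # different architecture entirely
        per = L // 14 + 1
        gAB = make_matrix(np.vstack([dA, dB]),
                          chrom=[f"c{j // per}" for j in range(L)],
                          pos=[(j % per + 1) * 100_000 for j in range(L)],
                          locus_ids=[f"L{j}" for j in range(L)])
        design = GwasDesign(yA, None, np.arange(n))
        idxB = np.arange(n, 2 * n)
        shared = transfer_pgs(design, gAB, idxB, yB_shared,
                              thresholds=(1e-2,), n_random_sets=100, rng=3)
        disjoint = transfer_pgs(design, gAB, idxB, yB_disjoint,
                                thresholds=(1e-2,), n_random_sets=100, rng=3)
        assert shared.loc[0, "r2"] > shared.loc[0, "null_q95"]
        assert disjoint.loc[0, "r2"] <= disjoint.loc[0, "null_q95"]
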