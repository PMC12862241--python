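"""Convergent shifts, enrichment tests, DAPC, and the forward simulation."""

import numpy as np
import pandas as pd
import pytest

from coralmme.data import ParameterError
from coralmme.association import GwasDesign, gwas
from coralmme.simulate import simulate_shift_pair
from coralmme.temporal import (
    ShiftVector,
    allele_frequency_shift,
    convergent_correlation,
    dapc_train_predict,
    effect_size_sum_test,
    intermediate_frequency_dapc,
    juvenile_assignment_report,
    overlap_adaptive_loci,
    rapid_evolution_simulation,
)

from conftest import make_matrix


def _shift(vals, site="s"):
    vals = np.asarray(vals, dtype=float)
    ids = np.array([f"L{i}" for i in range(len(vals))], dtype=object)
    return ShiftVector(site=site, delta_p=vals, locus_ids=ids)


class TestConvergentCorrelation:
    def test_proportional_shifts_r_one(self, rng):
        x = rng.normal(0, 0.05, 100)
        res = convergent_correlation(_shift(x, "a"), _shift(2 * x, "b"),
                                     n_bootstrap=100, rng=0)
        assert res.r == pytest.approx(1.0)

    def test_opposite_shifts_r_minus_one(self, rng):
        x = rng.normal(0, 0.05, 100)
        res = convergent_correlation(_shift(x, "a"), _shift(-x, "b"),
                                     n_bootstrap=100, rng=0)
        assert res.r == pytest.approx(-1.0)

    def test_self_correlation_exactly_one_and_symmetric(self, rng):
        x, y = rng.normal(0, 0.05, 200), rng.normal(0, 0.05, 200)
        a, b = _shift(x, "a"), _shift(y, "b")
        assert convergent_correlation(a, a, 100, rng=0).r == 1.0
        r_ab = convergent_correlation(a, b, 100, rng=0).r
        r_ba = convergent_correlation(b, a, 100, rng=0).r
        assert r_ab == pytest.approx(r_ba, abs=1e-15)

    def test_ci_contains_r_and_needs_50_loci(self, rng):
        x = rng.normal(0, 0.05, 100)
        y = x + rng.normal(0, 0.05, 100)
        res = convergent_correlation(_shift(x), _shift(y), 500, rng=1)
        assert res.ci_low <= res.r <= res.ci_high
        with pytest.raises(ParameterError):
            convergent_correlation(_shift(x[:20]), _shift(y[:20]), 100)

    def test_zero_variance_errors(self):
        with pytest.raises(ParameterError):
            convergent_correlation(_shift(np.zeros(60)),
                                   _shift(np.ones(60) * 0.1), 100)

    def test_bootstrap_ci_narrows_with_loci(self, rng):
        x1 = rng.normal(0, 0.05, 100)
        y1 = x1 + rng.normal(0, 0.05, 100)
        x2 = rng.normal(0, 0.05, 10_000)
        y2 = x2 + rng.normal(0, 0.05, 10_000)
        w1 = convergent_correlation(_shift(x1), _shift(y1), 500, rng=1)
        w2 = convergent_correlation(_shift(x2), _shift(y2), 500, rng=1)
        width1 = w1.ci_high - w1.ci_low
        width2 = w2.ci_high - w2.ci_low
        assert width2 < width1 / 5  # ~ sqrt(100) shrinkage

    def test_shared_selection_positive_drift_covers_zero(self):
        a, b = simulate_shift_pair(seed=0, shared_selection=True)
        res = convergent_correlation(a, b, 1000, rng=0)
        assert res.r > 0 and res.ci_low > 0
        a, b = simulate_shift_pair(seed=0, shared_selection=False)
        res = convergent_correlation(a, b, 1000, rng=0)
        assert res.ci_low <= 0 <= res.ci_high


@pytest.fixture(scope="module")
def null_gwas():
    rng = np.random.default_rng(3)
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(80, 400))
    g = make_matrix(d)
    design = GwasDesign(rng.normal(size=80), None, np.arange(80))
    return gwas(design, g), g


class TestEffectSizeSum:
    def test_null_calibration(self, null_gwas):
        res, g = null_gwas
        rng = np.random.default_rng(1)
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            loci = rng.choice(g.locus_ids, 50, replace=False)
            rep = effect_size_sum_test(loci, res, n_random_sets=200, rng=s)
            hits += rep.exceeds_95
        assert 1 <= hits <= 13  # ~5% of 100 with binomial slack

    def test_untested_loci_error(self, null_gwas):
        res, g = null_gwas
        with pytest.raises(ParameterError):
            effect_size_sum_test(["nope"], res)

    def test_signed_option_differs(self, null_gwas):
        res, g = null_gwas
        loci = g.locus_ids[:50]
        a = effect_size_sum_test(loci, res, 50, rng=0, signed=False)
        b = effect_size_sum_test(loci, res, 50, rng=0, signed=True)
        assert a.observed != b.observed


class TestOverlap:
    def _toy_gwas(self, p, ids=None):
        from coralmme.association import GwasResult
        n = len(p)
        ids = ids if ids is not None else [f"L{i}" for i in range(n)]
        return GwasResult(pd.DataFrame({
            "locus_id": ids, "chrom": ["1"] * n,
            "pos": np.arange(1, n + 1), "beta": np.zeros(n),
            "se": np.ones(n), "p": p, "n_used": np.full(n, 10),
            "fallback": np.zeros(n, bool)}), "binary")

    def test_self_overlap_is_idempotent(self, rng):
        p = rng.uniform(0, 1, 100)
        res = self._toy_gwas(p)
        out = overlap_adaptive_loci(res, res, p_cut=0.1)
        assert set(out["locus_id"]) == set(
            res.table[res.table.p < 0.1]["locus_id"])

    def test_empty_overlap_is_not_error(self):
        a = self._toy_gwas([0.001, 0.9])
        b = self._toy_gwas([0.9, 0.001])
        # locus sets disjoint in significance but shared universe
        out = overlap_adaptive_loci(a, b, p_cut=0.01)
        assert len(out) == 0

    def test_disjoint_universe_errors(self):
        a = self._toy_gwas([0.5], ids=["x"])
        b = self._toy_gwas([0.5], ids=["y"])
        with pytest.raises(ParameterError):
            overlap_adaptive_loci(a, b)

    def test_independent_null_overlap_rate(self, rng):
        L = 20_000
        a = self._toy_gwas(rng.uniform(0, 1, L))
        b = self._toy_gwas(rng.uniform(0, 1, L))
        out = overlap_adaptive_loci(a, b, p_cut=0.01)
        expect = L * 1e-4
        assert len(out) <= expect + 4 * np.sqrt(expect) + 1

    def test_gene_annotation_window(self):
        a = self._toy_gwas([1e-3, 0.9])
        ann = pd.DataFrame({"chrom": ["1"], "start": [400_000],
                            "end": [420_000], "gene": ["tfap2a"]})
        out = overlap_adaptive_loci(a, a, p_cut=0.01, annotation=ann,
                                    window_bp=500_000)
        assert out.loc[0, "genes"] == "tfap2a"


def _two_pop_matrix(rng, fst=0.1, n=60, L=400):
    p = rng.uniform(0.2, 0.8, L)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    d = []
    for _ in range(2):
        ps = rng.beta(a, b)
        d.append(rng.binomial(2, ps, size=(n, L)))
    return make_matrix(np.vstack(d)), np.array(["p1"] * n + ["p2"] * n)


class TestDapc:
    def test_duplicated_training_sample_assigned_with_confidence(self, rng):
        g, groups = _two_pop_matrix(rng)
        query = g.take_samples(np.array([0]))
        query = make_matrix(query.dosages, sample_ids=["q0"])
        out = dapc_train_predict(g, groups, query)
        assert out.loc["q0", "assigned"] == "p1"
        assert out.loc["q0", "p1"] > 0.99

    def test_differentiated_populations_high_accuracy(self, rng):
        g, groups = _two_pop_matrix(rng, fst=0.1)
        # hold out 15 samples per population
        held = np.concatenate([np.arange(45, 60), np.arange(105, 120)])
        train = np.setdiff1d(np.arange(120), held)
        out = dapc_train_predict(g, groups[train], g,
                                 training_idx=train, query_idx=held)
        acc = (out["assigned"].to_numpy() == groups[held]).mean()
        assert acc >= 0.95

    def test_panmictic_accuracy_near_chance(self, rng):
        L, n = 400, 120
        d = rng.binomial(2, rng.uniform(0.2, 0.8, L), size=(n, L))
        g = make_matrix(d)
        groups = np.array(["a", "b"] * (n // 2))  # arbitrary labels
        held = rng.choice(n, size=30, replace=False)
        train = np.setdiff1d(np.arange(n), held)
        out = dapc_train_predict(g, groups[train], g, training_idx=train,
                                 query_idx=held)
        acc = (out["assigned"].to_numpy() == groups[held]).mean()
        assert abs(acc - 0.5) < 0.25

    def test_singleton_group_rejected(self, rng):
        g = make_matrix(rng.binomial(2, 0.5, size=(5, 30)))
        with pytest.raises(ParameterError):
            dapc_train_predict(g, np.array(["a", "a", "a", "a", "b"]), g)


class TestAssignmentReport:
    def test_even_counts_chi2_zero(self):
        rep = juvenile_assignment_report(
            np.repeat(["a", "b", "c", "d"], 10))
        assert rep["chi2"] == pytest.approx(0.0)

    def test_hand_computed_chi2(self):
        rep = juvenile_assignment_report(np.array(["a"] * 30 + ["b"] * 10))
        # expected [20, 20]: (10^2/20)*2 = 10, df = 1
        assert rep["chi2"] == pytest.approx(10.0)
        assert rep["df"] == 1

    def test_zero_assignments_error(self):
        with pytest.raises(ParameterError):
            juvenile_assignment_report(np.array([]))

    def test_skewed_source_significant(self, small_cohort):
        g, meta, truth = small_cohort
        adults = meta[meta.timepoint.isin(["pre", "post"])]
        juv = meta[meta.timepoint == "juvenile"]
        groups = (adults["site"] + "_" + adults["habitat"]).to_numpy()
        out = dapc_train_predict(
            g, groups, g, training_idx=g.sample_index(adults["sample_id"]),
            query_idx=g.sample_index(juv["sample_id"]))
        rep = juvenile_assignment_report(out["assigned"].to_numpy(),
                                         np.unique(groups))
        assert rep["p"] < 1e-4  # fecundity-skewed recruitment is uneven


class TestIntermediateDapc:
    def _cohorts(self, rng):
        L = 150
        p = rng.uniform(0.2, 0.8, L)
        pre = rng.binomial(2, p, size=(30, L))
        shift = np.clip(p + rng.normal(0, 0.12, L), 0.05, 0.95)
        post = rng.binomial(2, shift, size=(30, L))
        return pre, post, p, shift, L

    def test_copy_of_pre_sits_at_pre(self, rng):
        pre, post, p, shift, L = self._cohorts(rng)
        juv = pre[:15]
        g = make_matrix(np.vstack([pre, post, juv]))
        rep = intermediate_frequency_dapc(
            g, np.arange(30), np.arange(30, 60), np.arange(60, 75))
        d_pre = abs(rep.mean_ld1["juvenile"] - rep.mean_ld1["pre"])
        d_post = abs(rep.mean_ld1["juvenile"] - rep.mean_ld1["post"])
        assert d_pre < d_post
        assert rep.juvenile_assignments["pre"] > rep.juvenile_assignments["post"]

    def test_copy_of_post_assigned_post(self, rng):
        pre, post, p, shift, L = self._cohorts(rng)
        juv = post[:15]
        g = make_matrix(np.vstack([pre, post, juv]))
        rep = intermediate_frequency_dapc(
            g, np.arange(30), np.arange(30, 60), np.arange(60, 75))
        assert rep.juvenile_assignments["post"] >= 13

    def test_bred_juveniles_intermediate(self, small_cohort):
        g, meta, truth = small_cohort
        dfr = meta[meta.habitat == "deep_forereef"]
        pre = g.sample_index(dfr[dfr.timepoint == "pre"]["sample_id"])
        post = g.sample_index(dfr[dfr.timepoint == "post"]["sample_id"])
        juv = g.sample_index(dfr[dfr.timepoint == "juvenile"]["sample_id"])
        rep = intermediate_frequency_dapc(g, pre, post, juv,
                                          pgs_loci=truth.causal_locus_ids)
        lo, hi = sorted([rep.mean_ld1["pre"], rep.mean_ld1["post"]])
        assert lo < rep.mean_ld1["juvenile"] < hi


class TestRapidEvolution:
    def test_mean_pre_frequency_matches_p0(self):
        res = rapid_evolution_simulation(N=800, L=600, n_adaptive=30,
                                         n_sample=20, seed=1)
        p = res.freq["population_pre"].to_numpy()
        se = np.sqrt(0.1 * 0.9 / (2 * 800 * 600))
        assert abs(p.mean() - 0.1) < 3 * se * 30  # loose 3-SE band

    def test_exact_survivor_count(self):
        res = rapid_evolution_simulation(N=1000, L=100, n_adaptive=10,
                                         n_sample=20, seed=2)
        assert res.n_survivors == 300

    def test_survivor_freq_dominates_at_adaptive_loci(self):
        # truncation on the summed dosage cannot lower the mean causal
        # frequency among survivors
        for seed in range(5):
            res = rapid_evolution_simulation(N=500, L=300, n_adaptive=20,
                                             n_sample=20, run_dapc=False,
                                             seed=seed)
            f = res.freq
            ad = f[f.adaptive]
            assert (ad["survivors"].mean() >= ad["population_pre"].mean())

    def test_deterministic_given_seed(self):
        r1 = rapid_evolution_simulation(N=400, L=200, n_adaptive=10,
                                        n_sample=15, seed=9)
        r2 = rapid_evolution_simulation(N=400, L=200, n_adaptive=10,
                                        n_sample=15, seed=9)
        np.testing.assert_array_equal(r1.outlier_idx, r2.outlier_idx)
        pd.testing.assert_frame_equal(r1.freq, r2.freq)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            rapid_evolution_simulation(survival_top_frac=1.5)
        with pytest.raises(ParameterError):
            rapid_evolution_simulation(N=100, n_sample=90,
                                       survival_top_frac=0.3)


class TestShiftVector:
    def test_shift_from_cohort(self, small_cohort):
        g, meta, truth = small_cohort
        grp = meta[(meta.site == "LTER1") & (meta.habitat == "deep_forereef")]
        pre = g.sample_index(grp[grp.timepoint == "pre"]["sample_id"])
        post = g.sample_index(grp[grp.timepoint == "post"]["sample_id"])
        sv = allele_frequency_shift(g, pre, post, site="LTER1")
        assert len(sv.delta_p) == g.n_loci
        assert np.all(np.abs(sv.delta_p) <= 1.0)
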