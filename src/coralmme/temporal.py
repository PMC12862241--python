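"""Temporal signatures of selection across the mortality event.

Includes the convergent-correlation statistic (Pearson correlation of
per-locus allele-frequency shifts between two sites over the same time
interval — concordance indicates shared selection, discordance drift), the
effect-size-sum enrichment test against random locus sets, pre/post GWAS
overlap, DAPC source assignment, and the forward simulation of truncation
selection that explains why next-generation allele frequencies sit between
the pre- and post-mortality subsamples at outlier loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data import MISSING, GenotypeMatrix, ParameterError
from .association import GwasResult, _logistic_scan_chunk, _P_FLOOR

logger = logging.getLogger(__name__)


@dataclass
class ShiftVector:
    """Per-locus allele-frequency change p_post - p_pre for one site."""

    site: str
    delta_p: np.ndarray
    locus_ids: np.ndarray


def allele_frequency_shift(
    g: GenotypeMatrix,
    idx_pre: np.ndarray,
    idx_post: np.ndarray,
    site: str = "",
) -> ShiftVector:
    """Allele-frequency shift on loci called in both timepoint groups."""
    p_pre = g.allele_freq(np.asarray(idx_pre))
    p_post = g.allele_freq(np.asarray(idx_post))
    ok = np.isfinite(p_pre) & np.isfinite(p_post)
    return ShiftVector(site=site, delta_p=(p_post - p_pre)[ok],
                       locus_ids=g.locus_ids[ok])


@dataclass
class ConvergenceResult:
    site_pair: tuple
    r: float
    ci_low: float
    ci_high: float
    n_loci: int
    n_bootstrap: int


def convergent_correlation(
    shift_a: ShiftVector,
    shift_b: ShiftVector,
    n_bootstrap: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> ConvergenceResult:
    """Pearson correlation of two sites' allele-frequency shifts with a
    percentile bootstrap CI from resampling loci with replacement."""
    rng = np.random.default_rng(rng)
    common, ia, ib = np.intersect1d(shift_a.locus_ids, shift_b.locus_ids,
                                    return_indices=True)
    if len(common) < 50:
        raise ParameterError("need >=50 shared loci")
    x, y = shift_a.delta_p[ia], shift_b.delta_p[ib]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero-variance shift vector: correlation undefined")
    if np.array_equal(x, y):
        r = 1.0  # self-comparison is exact, not subject to rounding
    else:
        r = float(stats.pearsonr(x, y).statistic)
    L = len(x)
    idx = rng.integers(0, L, size=(n_bootstrap, L))
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xs, ys)
    den = np.sqrt(np.einsum("ij,ij->i", xs, xs) * np.einsum("ij,ij->i", ys, ys))
    boot = np.where(den > 0, num / den, 0.0)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return ConvergenceResult(
        site_pair=(shift_a.site, shift_b.site), r=r,
        ci_low=float(lo), ci_high=float(hi), n_loci=L, n_bootstrap=n_bootstrap,
    )


@dataclass
class EffectSumReport:
    observed: float
    null_sums: np.ndarray
    percentile: float
    exceeds_95: bool
    set_size: int


def effect_size_sum_test(
    loci_set,
    gwas_result: GwasResult,
    n_random_sets: int = 500,
    rng: np.random.Generator | int | None = None,
    signed: bool = False,
) -> EffectSumReport:
    """Are GWAS effect sizes at a locus set collectively larger than at
    random sets of the same size?

    Statistic: sum over the set of |beta| (or signed beta with
    ``signed=True``); null from ``n_random_sets`` random equal-size locus
    draws; reports the observed percentile and exceedance of the null 95th
    percentile.
    """
    rng = np.random.default_rng(rng)
    table = gwas_result.table
    ids = table["locus_id"].to_numpy()
    loci_set = np.asarray(list(loci_set), dtype=object)
    mask = np.isin(ids, loci_set)
    if mask.sum() != len(loci_set):
        raise ParameterError("loci_set contains untested loci")
    if len(loci_set) > len(ids):
        raise ParameterError("set_size larger than available loci")
    betas = table["beta"].to_numpy()
    vals = betas if signed else np.abs(betas)
    observed = float(vals[mask].sum())
    k = len(loci_set)
    null_sums = np.empty(n_random_sets)
    for i in range(n_random_sets):
        null_sums[i] = vals[rng.choice(len(ids), size=k, replace=False)].sum()
    q95 = float(np.quantile(null_sums, 0.95))
    return EffectSumReport(
        observed=observed, null_sums=null_sums,
        percentile=float(np.mean(null_sums < observed)),
        exceeds_95=observed > q95, set_size=k,
    )


def overlap_adaptive_loci(
    gwas1: GwasResult,
    gwas2: GwasResult,
    p_cut: float = 1e-2,
    annotation: pd.DataFrame | None = None,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Loci below ``p_cut`` in both GWAS ("overlapping loci").

    With an annotation table (chrom, start, end, gene) supplied, genes
    within +/- ``window_bp`` of each overlapping locus are attached.
    """
    t1, t2 = gwas1.table, gwas2.table
    shared = np.intersect1d(t1["locus_id"], t2["locus_id"])
    if len(shared) == 0:
        raise ParameterError("disjoint locus universes")
    s1 = t1[t1["p"] < p_cut]["locus_id"]
    s2 = t2[t2["p"] < p_cut]["locus_id"]
    hits = np.intersect1d(s1, s2)
    out = t1.set_index("locus_id").loc[hits, ["chrom", "pos", "p"]].reset_index()
    out = out.rename(columns={"p": "p1"})
    out = out.merge(t2[["locus_id", "p"]].rename(columns={"p": "p2"}), on="locus_id")
    if annotation is not None:
        genes = []
        for _, row in out.iterrows():
            near = annotation[
                (annotation["chrom"] == row["chrom"])
                & (annotation["end"] >= row["pos"] - window_bp)
                & (annotation["start"] <= row["pos"] + window_bp)
            ]["gene"]
            genes.append(",".join(near))
        out["genes"] = genes
    return out


@dataclass
class DapcModel:
    """Fitted DAPC: PCA axes + linear discriminants on group labels."""

    mean: np.ndarray
    scale: np.ndarray
    pca: PCA
    lda: LinearDiscriminantAnalysis
    classes: np.ndarray
    n_pca: int


def _dosage_matrix_imputed(g: GenotypeMatrix, idx=None) -> np.ndarray:
    d = g.dosages if idx is None else g.dosages[np.asarray(idx)]
    d = d.astype(np.float64)
    called = d != MISSING
    col_mean = np.where(called, d, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    return np.where(called, d, col_mean[None, :])


def dapc_fit(
    training: GenotypeMatrix,
    groups: np.ndarray,
    n_pca: int | None = None,
    n_da: int | None = None,
    training_idx: np.ndarray | None = None,
) -> DapcModel:
    """Train a DAPC: standardized dosages -> PCA -> LDA on group labels.

    ``n_pca`` defaults to the number of axes explaining 80% of variance
    (capped below the training sample count).
    """
    groups = np.asarray(groups)
    X = _dosage_matrix_imputed(training, training_idx)
    if X.shape[0] != len(groups):
        raise ParameterError("groups length mismatch")
    classes, counts = np.unique(groups, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("need >=2 groups")
    if counts.min() < 2:
        raise ParameterError("every group needs >=2 training samples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    max_pca = X.shape[0] - 1
    pca = PCA(n_components=min(max_pca, Xs.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Xs)
    if n_pca is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pca = int(np.searchsorted(cum, 0.8) + 1)
    if n_pca >= X.shape[0]:
        raise ParameterError("n_pca must be below the training sample count")
    n_pca = max(n_pca, len(classes) - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(scores[:, :n_pca], groups)
    return DapcModel(mean=mean, scale=scale, pca=pca, lda=lda,
                     classes=classes, n_pca=n_pca)


def dapc_project(model: DapcModel, g: GenotypeMatrix, idx=None) -> np.ndarray:
    """Discriminant coordinates for query samples."""
    X = _dosage_matrix_imputed(g, idx)
    Xs = (X - model.mean) / model.scale
    scores = model.pca.transform(Xs)[:, : model.n_pca]
    return model.lda.transform(scores)


def dapc_train_predict(
    training: GenotypeMatrix,
    groups: np.ndarray,
    query: GenotypeMatrix,
    n_pca: int | None = None,
    n_da: int | None = None,
    training_idx: np.ndarray | None = None,
    query_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign query samples to the training groups by maximum posterior.

    Returns a frame with one posterior column per group plus ``assigned``.
    """
    model = dapc_fit(training, groups, n_pca=n_pca, n_da=n_da,
                     training_idx=training_idx)
    X = _dosage_matrix_imputed(query, query_idx)
    Xs = (X - model.mean) / model.scale
    scores = model.pca.transform(Xs)[:, : model.n_pca]
    post = model.lda.predict_proba(scores)
    sample_ids = query.sample_ids if query_idx is None else query.sample_ids[np.asarray(query_idx)]
    out = pd.DataFrame(post, columns=model.lda.classes_, index=sample_ids)
    out["assigned"] = model.lda.classes_[np.argmax(post, axis=1)]
    return out


def juvenile_assignment_report(
    assignments: np.ndarray, candidate_groups=None
) -> dict:
    """Counts per predicted source plus a chi-squared evenness test.

    Tests the observed source counts against a uniform expectation across
    the candidate groups (df = k - 1).
    """
    assignments = np.asarray(assignments)
    if assignments.size == 0:
        raise ParameterError("zero assignments")
    if candidate_groups is None:
        candidate_groups = np.unique(assignments)
    candidate_groups = np.asarray(candidate_groups)
    if len(candidate_groups) < 2:
        raise ParameterError("need >=2 candidate source groups")
    counts = np.array([(assignments == c).sum() for c in candidate_groups])
    chi2, p = stats.chisquare(counts)
    return {
        "counts": pd.Series(counts, index=candidate_groups),
        "chi2": float(chi2),
        "p": float(p),
        "df": len(candidate_groups) - 1,
    }


@dataclass
class IntermediateDapcReport:
    mean_ld1: dict  # cohort -> mean LD1
    juvenile_assignments: pd.Series  # counts per timepoint
    ld1: dict  # cohort -> per-sample LD1 coordinates
    is_intermediate: bool


def intermediate_frequency_dapc(
    g: GenotypeMatrix,
    idx_pre: np.ndarray,
    idx_post: np.ndarray,
    idx_juvenile: np.ndarray,
    pgs_loci=None,
    n_pca: int | None = None,
) -> IntermediateDapcReport:
    """Do juveniles sit between the pre- and post-mortality cohorts?

    Trains a DAPC on pre vs post at the given loci (juveniles excluded from
    training), projects all three cohorts onto LD1, and naively assigns each
    juvenile to its closer timepoint.
    """
    if pgs_loci is not None:
        g = g.take_loci(np.sort(g.locus_index(list(pgs_loci))))
    idx_pre, idx_post = np.asarray(idx_pre), np.asarray(idx_post)
    idx_juvenile = np.asarray(idx_juvenile)
    train_idx = np.concatenate([idx_pre, idx_post])
    labels = np.array(["pre"] * len(idx_pre) + ["post"] * len(idx_post))
    model = dapc_fit(g, labels, n_pca=n_pca, n_da=1, training_idx=train_idx)
    ld1 = {}
    for name, idx in (("pre", idx_pre), ("post", idx_post),
                      ("juvenile", idx_juvenile)):
        ld1[name] = dapc_project(model, g, idx)[:, 0]
    means = {k: float(v.mean()) for k, v in ld1.items()}
    # naive assignment to the nearer timepoint mean
    juv = ld1["juvenile"]
    nearer_post = np.abs(juv - means["post"]) < np.abs(juv - means["pre"])
    counts = pd.Series(
        {"pre": int((~nearer_post).sum()), "post": int(nearer_post.sum())}
    )
    lo, hi = sorted([means["pre"], means["post"]])
    return IntermediateDapcReport(
        mean_ld1=means, juvenile_assignments=counts, ld1=ld1,
        is_intermediate=bool(lo < means["juvenile"] < hi),
    )


@dataclass
class RapidEvolutionResult:
    """Outcome of the truncation-selection forward simulation."""

    freq: pd.DataFrame  # per-locus allele frequencies by cohort
    outlier_idx: np.ndarray
    adaptive_idx: np.ndarray
    scan_p: np.ndarray
    n_survivors: int
    dapc: IntermediateDapcReport | None
    seed: int | None


def rapid_evolution_simulation(
    N: int = 1000,
    L: int = 1000,
    n_adaptive: int = 50,
    p0: float = 0.1,
    survival_top_frac: float = 0.3,
    n_sample: int = 20,
    outlier_p_cut: float = 0.01,
    n_juveniles: int | None = None,
    run_dapc: bool = True,
    seed: int | None = None,
) -> RapidEvolutionResult:
    """Forward simulation of an MME as truncation selection.

    1. Genotypes ~ Binomial(2, p0) per locus per individual.
    2. Score = summed dosage over the adaptive loci (unit effects).
    3. Survivors = top ``survival_top_frac`` by score (seeded random
       tie-break).
    4. Pre-subsample of ``n_sample`` from the full population, post-subsample
       of ``n_sample`` from the survivors (emulating field subsampling).
    5. Per-locus logistic regression pre- vs post-subsample; outliers at
       p < ``outlier_p_cut`` mix true adaptive loci with subsampling false
       positives.
    6. Juveniles: per locus, dosage ~ Binomial(2, survivor allele frequency).
    7. Allele frequencies of outlier loci reported across all cohorts; an
       optional DAPC shows juveniles intermediate between the subsamples.
    """
    if not 0.0 < survival_top_frac < 1.0:
        raise ParameterError("survival_top_frac must lie in (0, 1)")
    if n_adaptive > L:
        raise ParameterError("n_adaptive > L")
    n_surv = int(round(N * survival_top_frac))
    if n_sample > n_surv:
        raise ParameterError("n_sample exceeds the survivor count")
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, p0, size=(N, L)).astype(np.int8)
    adaptive_idx = rng.choice(L, size=n_adaptive, replace=False) if n_adaptive else np.empty(0, int)
    score = geno[:, adaptive_idx].sum(axis=1) if n_adaptive else np.zeros(N)
    # seeded random tie-break at the truncation cut
    order = np.lexsort((rng.random(N), -score))
    survivors = order[:n_surv]
    pre_sub = rng.choice(N, size=n_sample, replace=False)
    post_sub = rng.choice(survivors, size=n_sample, replace=False)
    # per-locus logistic scan pre-subsample vs post-subsample
    y = np.concatenate([np.zeros(n_sample), np.ones(n_sample)])
    Z = np.vstack([geno[pre_sub], geno[post_sub]]).astype(np.float64)
    scan_p = _scan_binary(y, Z)
    outlier_idx = np.flatnonzero(scan_p < outlier_p_cut)
    # next generation from survivor allele frequencies
    p_surv = geno[survivors].mean(axis=0) / 2.0
    if n_juveniles is None:
        n_juveniles = n_sample
    juv = rng.binomial(2, p_surv[None, :].repeat(n_juveniles, axis=0)).astype(np.int8)
    freq = pd.DataFrame({
        "population_pre": geno.mean(axis=0) / 2.0,
        "pre_subsample": geno[pre_sub].mean(axis=0) / 2.0,
        "survivors": p_surv,
        "post_subsample": geno[post_sub].mean(axis=0) / 2.0,
        "juveniles": juv.mean(axis=0) / 2.0,
    })
    freq["adaptive"] = np.isin(np.arange(L), adaptive_idx)
    freq["outlier"] = np.isin(np.arange(L), outlier_idx)

    dapc_report = None
    if run_dapc and len(outlier_idx) >= 2:
        dosages = np.vstack([geno[pre_sub], geno[post_sub], juv])
        ids = np.array([f"s{i}" for i in range(dosages.shape[0])], dtype=object)
        lids = np.array([f"L{j}" for j in range(L)], dtype=object)
        gm = GenotypeMatrix(
            dosages, ids, lids,
            np.array(["1"] * L, dtype=object), np.arange(1, L + 1),
            np.array(["A"] * L, dtype=object), np.array(["T"] * L, dtype=object),
        ).take_loci(outlier_idx)
        n = n_sample
        dapc_report = intermediate_frequency_dapc(
            gm, np.arange(n), np.arange(n, 2 * n),
            np.arange(2 * n, 2 * n + n_juveniles),
        )
    return RapidEvolutionResult(
        freq=freq, outlier_idx=outlier_idx, adaptive_idx=np.sort(adaptive_idx),
        scan_p=scan_p, n_survivors=n_surv, dapc=dapc_report, seed=seed,
    )


def _scan_binary(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-locus logistic likelihood-ratio p (no covariates).

    The LRT keeps the null outlier rate calibrated at the small subsample
    sizes of the forward simulation, where the Wald statistic is badly
    conservative.  Under (quasi-)separation the coefficient diverges but
    the log-likelihood still converges to its supremum, so the LRT remains
    usable; only loci whose likelihood is degenerate fall back to a
    Firth-penalized fit.
    """
    p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll0 = len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
    L = Z.shape[1]
    p = np.ones(L)
    chunk = 1024
    for start in range(0, L, chunk):
        sl = slice(start, min(start + chunk, L))
        _, _, _, ll, _ = _logistic_scan_chunk(y, Z[:, sl],
                                              np.empty((len(y), 0)))
        lrt = np.maximum(2.0 * (ll - ll0), 0.0)
        p[sl] = np.clip(stats.chi2.sf(lrt, 1), _P_FLOOR, 1.0)
        bad = ~np.isfinite(ll)
        for j in np.flatnonzero(bad):
            col = Z[:, sl][:, j]
            if np.ptp(col) == 0:
                p[start + j] = 1.0
            else:
                p[start + j] = _firth_logistic_p(y, col)
    return p


def _firth_logistic_p(y: np.ndarray, x: np.ndarray, max_iter: int = 50) -> float:
    """Wald p for the slope of a Firth-penalized logistic fit y ~ 1 + x.

    Jeffreys-prior penalty keeps the estimate finite under separation.
    """
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    for _ in range(max_iter):
        eta = np.clip(X @ b, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        H = XtW @ X + 1e-10 * np.eye(2)
        Hinv = np.linalg.inv(H)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], Hinv,
                      X * np.sqrt(w)[:, None])
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ U
        b += np.clip(step, -5, 5)
        if np.abs(step).max() < 1e-8:
            break
    eta = np.clip(X @ b, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (mu * (1 - mu))) @ X + 1e-10 * np.eye(2)
    se = np.sqrt(np.linalg.inv(H)[1, 1])
    z = b[1] / se if se > 0 else 0.0
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))
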