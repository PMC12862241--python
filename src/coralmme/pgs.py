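"""Polygenic scores: p-value thresholding + LD clumping, jackknife
cross-validation against null-PGS baselines, covariate model comparison,
and cross-habitat transfer.

A PGS is the sum of allele dosages weighted by training-GWAS effect sizes
at approximately independent loci.  "Independent" is the greedy clump rule:
iterate loci passing the p threshold in ascending p order and drop any
candidate within ``clump_window_bp`` of an already kept locus on the same
chromosome with r^2 above ``clump_r2_max``.

Predictive accuracy is the squared Pearson correlation between score and
trait on held-out samples — for a binary trait this is the squared
point-biserial correlation, used for both trait kinds so real and null PGS
distributions are directly comparable.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, AnalysisConfig, GenotypeMatrix, ParameterError
from .association import GwasDesign, GwasResult, gwas

logger = logging.getLogger(__name__)


class LdCalculator:
    """Pairwise dosage r^2 with a fast path for complete-call matrices."""

    def __init__(self, g: GenotypeMatrix, sample_idx: np.ndarray | None = None):
        d = g.dosages if sample_idx is None else g.dosages[np.asarray(sample_idx)]
        self.d = d.astype(np.float64)
        self.called = d != MISSING
        self.complete = bool(self.called.all())
        if self.complete:
            zc = self.d - self.d.mean(axis=0)
            norms = np.sqrt(np.einsum("ij,ij->j", zc, zc))
            self._zc, self._norms = zc, norms

    def r2(self, i: int, j: int) -> float:
        """Squared Pearson correlation of dosages over jointly called samples."""
        if self.complete:
            ni, nj = self._norms[i], self._norms[j]
            if ni == 0 or nj == 0:
                logger.warning("ld_r2: zero-variance locus; r2 defined as 0")
                return 0.0
            r = float(self._zc[:, i] @ self._zc[:, j] / (ni * nj))
            return r * r
        m = self.called[:, i] & self.called[:, j]
        if m.sum() < 2:
            raise ParameterError("fewer than 2 jointly called samples")
        x, y = self.d[m, i], self.d[m, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("ld_r2: zero-variance locus; r2 defined as 0")
            return 0.0
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)


def ld_r2(g: GenotypeMatrix, locus_a, locus_b, sample_idx=None) -> float:
    """r^2 between two loci, given as column indices or locus ids."""
    if not isinstance(locus_a, (int, np.integer)):
        locus_a, locus_b = g.locus_index([locus_a, locus_b])
    return LdCalculator(g, sample_idx).r2(int(locus_a), int(locus_b))


@dataclass
class PgsModel:
    """Selected loci and weights of a polygenic score."""

    locus_ids: np.ndarray
    betas: np.ndarray
    p_threshold: float
    clump_window_bp: int
    clump_r2_max: float
    trait_kind: str = "quantitative"
    training_sample_ids: np.ndarray | None = None

    @property
    def empty(self) -> bool:
        return len(self.locus_ids) == 0

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"locus_id": self.locus_ids, "beta": self.betas})


def ld_clump(
    gwas_result: GwasResult | pd.DataFrame,
    g: GenotypeMatrix,
    p_threshold: float,
    clump_window_bp: int = 250_000,
    clump_r2_max: float = 0.5,
    sample_idx: np.ndarray | None = None,
    ld: LdCalculator | None = None,
) -> list:
    """Greedy LD clumping: keep-list of approximately independent loci.

    Candidates with p < ``p_threshold`` are visited in ascending p order
    (ties by chrom, pos); a candidate is kept unless an already kept locus
    on the same chromosome lies within ``clump_window_bp`` and has
    r^2 > ``clump_r2_max`` with it.
    """
    table = gwas_result.table if isinstance(gwas_result, GwasResult) else gwas_result
    if ld is None:
        ld = LdCalculator(g, sample_idx)
    col_of = {lid: j for j, lid in enumerate(g.locus_ids)}
    cand = table[table["p"].to_numpy() < p_threshold]
    cand = cand.sort_values(["p", "chrom", "pos"], kind="mergesort")
    kept: list = []
    by_chrom: dict = {}  # chrom -> (sorted positions, parallel col indices)
    for lid, chrom, pos in zip(cand["locus_id"], cand["chrom"], cand["pos"]):
        j = col_of[lid]
        positions, cols = by_chrom.setdefault(chrom, ([], []))
        lo = bisect.bisect_left(positions, pos - clump_window_bp)
        hi = bisect.bisect_right(positions, pos + clump_window_bp)
        if any(ld.r2(j, cols[t]) > clump_r2_max for t in range(lo, hi)):
            continue
        at = bisect.bisect_left(positions, pos)
        positions.insert(at, pos)
        cols.insert(at, j)
        kept.append(lid)
    if not kept:
        logger.info("ld_clump: empty keep-list at p<%.3g", p_threshold)
    return kept


def build_pgs(
    gwas_result: GwasResult,
    g: GenotypeMatrix,
    p_threshold: float,
    cfg: AnalysisConfig | None = None,
    sample_idx: np.ndarray | None = None,
    ld: LdCalculator | None = None,
) -> PgsModel:
    """Threshold + clump a GWAS into a PGS model."""
    cfg = cfg or AnalysisConfig()
    kept = ld_clump(
        gwas_result, g, p_threshold, cfg.clump_window_bp, cfg.clump_r2_max,
        sample_idx=sample_idx, ld=ld,
    )
    table = gwas_result.table.set_index("locus_id")
    betas = table.loc[kept, "beta"].to_numpy() if kept else np.empty(0)
    return PgsModel(
        locus_ids=np.array(kept, dtype=object),
        betas=betas,
        p_threshold=p_threshold,
        clump_window_bp=cfg.clump_window_bp,
        clump_r2_max=cfg.clump_r2_max,
        trait_kind=gwas_result.trait_kind,
    )


def score_samples(
    model: PgsModel, g: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """PGS_i = sum_l dosage_il * beta_l.

    Model loci absent from the matrix are dropped (error if more than half
    are); missing dosage cells are mean-imputed from called genotypes.
    """
    if model.empty:
        return np.zeros(g.n_samples if sample_idx is None else len(sample_idx))
    present = np.isin(model.locus_ids, g.locus_ids)
    if present.mean() < 0.5:
        raise ParameterError(
            f"{(~present).sum()}/{len(present)} model loci absent from genotypes"
        )
    if not present.all():
        logger.info("score_samples: dropping %d absent model loci", int((~present).sum()))
    ids = model.locus_ids[present]
    betas = model.betas[present]
    cols = g.locus_index(ids)
    d = g.dosages[:, cols].astype(np.float64)
    called = g.dosages[:, cols] != MISSING
    if not called.all():
        logger.info("score_samples: mean-imputing %d missing dosages",
                    int((~called).sum()))
        col_mean = np.where(called, d, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
        d = np.where(called, d, col_mean[None, :])
    scores = d @ betas
    if sample_idx is not None:
        scores = scores[np.asarray(sample_idx)]
    return scores


def _r2_score_trait(score: np.ndarray, trait: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when the score is degenerate."""
    if np.ptp(score) == 0 or np.ptp(trait) == 0:
        return 0.0
    r = np.corrcoef(score, trait)[0, 1]
    return float(r * r)


def _subset_design(design: GwasDesign, rows: np.ndarray) -> GwasDesign:
    return GwasDesign(
        design.trait[rows], design.covariates[rows], design.sample_idx[rows],
        design.trait_kind, design.covariate_names,
    )


@dataclass
class CvReport:
    """Jackknife cross-validation outcome."""

    r2_by_threshold: pd.DataFrame  # partitions x thresholds
    best_threshold: float
    real_r2: np.ndarray  # test R^2 at best threshold per partition
    null_r2: np.ndarray  # matched random-locus PGS R^2 per partition
    mannwhitney_p: float
    partitions: list  # test-row indices per partition
    model_sizes: np.ndarray


def _partitions(
    design: GwasDesign, n_partitions: int, test_frac: float,
    rng: np.random.Generator,
) -> list:
    n = design.n
    n_test = max(2, int(round(test_frac * n)))
    parts = []
    for _ in range(n_partitions):
        for _attempt in range(100):
            test = rng.choice(n, size=n_test, replace=False)
            if np.ptp(design.trait[test]) > 0:
                break
            logger.info("jackknife_cv: resampling partition with constant test trait")
        parts.append(np.sort(test))
    return parts


def jackknife_cv(
    design: GwasDesign,
    g: GenotypeMatrix,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[CvReport, PgsModel]:
    """Jackknife cross-validated PGS construction.

    100 random 85/15 train/test partitions; per partition the training GWAS
    is thresholded and clumped over the threshold grid, the test set scored,
    and R^2 (trait ~ PGS alone) recorded.  The threshold maximizing mean
    test R^2 wins; its per-partition R^2 distribution is compared with a
    matched null PGS (random loci, training betas) by Mann-Whitney U.
    Returns the report and a final model trained on all samples at the best
    threshold.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng)
    if design.n < 40:
        raise ParameterError("need >=40 samples for jackknife CV")
    grid = sorted(cfg.pgs_threshold_grid)
    parts = _partitions(design, cfg.n_cv_partitions, cfg.cv_test_frac, rng)
    r2 = np.zeros((len(parts), len(grid)))
    null_r2_grid = np.zeros((len(parts), len(grid)))
    sizes_grid = np.zeros((len(parts), len(grid)), dtype=int)
    all_rows = np.arange(design.n)
    col_of = {lid: j for j, lid in enumerate(g.locus_ids)}
    # the null PGS maps each selected set through one fixed random locus
    # permutation, so the random sets share the real sets' persistence
    # across partitions and the Mann-Whitney comparison stays calibrated
    null_map = rng.permutation(g.n_loci)
    dall = g.dosages.astype(np.float64)
    called = g.dosages != MISSING
    if not called.all():
        logger.info("jackknife_cv: mean-imputing missing dosages for scoring")
        col_mean = np.where(called, dall, 0).sum(axis=0) / np.maximum(
            called.sum(axis=0), 1)
        dall = np.where(called, dall, col_mean[None, :])
    for pi, test in enumerate(parts):
        train = np.setdiff1d(all_rows, test)
        tr_design = _subset_design(design, train)
        res = gwas(tr_design, g)
        ld = LdCalculator(g, tr_design.sample_idx)
        # the greedy keep-list at a tighter threshold is the loose-threshold
        # keep-list filtered to p < threshold (candidates are visited in
        # ascending p, so acceptance never depends on larger-p loci)
        kept_all = ld_clump(res, g, max(grid), cfg.clump_window_bp,
                            cfg.clump_r2_max, ld=ld)
        kept_cols = np.array([col_of[l] for l in kept_all], dtype=int)
        all_p = res.table["p"].to_numpy()
        all_beta = res.table["beta"].to_numpy()
        kept_p = all_p[kept_cols] if len(kept_cols) else np.empty(0)
        test_idx = design.sample_idx[test]
        yt = design.trait[test]
        dtest = dall[test_idx]
        for ti, thr in enumerate(grid):
            sel = kept_cols[kept_p < thr] if len(kept_cols) else kept_cols
            sizes_grid[pi, ti] = len(sel)
            if len(sel):
                score = dtest[:, sel] @ all_beta[sel]
                r2[pi, ti] = _r2_score_trait(score, yt)
                null_cols = null_map[sel]
                null_score = dtest[:, null_cols] @ all_beta[null_cols]
                null_r2_grid[pi, ti] = _r2_score_trait(null_score, yt)
    best_ti = int(np.argmax(r2.mean(axis=0)))
    best_thr = grid[best_ti]
    # the null undergoes the identical maximize-mean-R2 selection so the
    # comparison is free of winner's-curse asymmetry
    null_best_ti = int(np.argmax(null_r2_grid.mean(axis=0)))
    null_r2 = null_r2_grid[:, null_best_ti]
    sizes = sizes_grid[:, best_ti]
    if np.ptp(r2[:, best_ti]) == 0 and np.ptp(null_r2) == 0:
        mw_p = 1.0
    else:
        mw_p = float(stats.mannwhitneyu(r2[:, best_ti], null_r2,
                                        alternative="greater").pvalue)
    report = CvReport(
        r2_by_threshold=pd.DataFrame(r2, columns=[str(t) for t in grid]),
        best_threshold=best_thr,
        real_r2=r2[:, best_ti],
        null_r2=null_r2,
        mannwhitney_p=mw_p,
        partitions=parts,
        model_sizes=sizes,
    )
    full_res = gwas(design, g)
    best_model = build_pgs(full_res, g, best_thr, cfg,
                           sample_idx=design.sample_idx)
    best_model.training_sample_ids = g.sample_ids[design.sample_idx]
    return report, best_model


def null_pgs(
    gwas_result: GwasResult,
    g: GenotypeMatrix,
    model: PgsModel,
    n_random_sets: int,
    trait: np.ndarray,
    sample_idx: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null R^2 distribution from random locus sets of the model's size.

    Each set is drawn without replacement, keeps its training betas, and is
    scored on the given samples.
    """
    rng = np.random.default_rng(rng)
    if model.n_loci > g.n_loci:
        raise ParameterError("fewer loci available than the model size")
    if model.empty:
        raise ParameterError("cannot build a null for an empty model")
    table = gwas_result.table.set_index("locus_id")
    out = np.empty(n_random_sets)
    for i in range(n_random_sets):
        ids = rng.choice(g.locus_ids, size=model.n_loci, replace=False)
        nm = PgsModel(np.asarray(ids, dtype=object),
                      table.loc[ids, "beta"].to_numpy(),
                      model.p_threshold, model.clump_window_bp,
                      model.clump_r2_max, model.trait_kind)
        out[i] = _r2_score_trait(score_samples(nm, g, sample_idx), trait)
    return out


def compare_models(
    trait: np.ndarray,
    pgs: dict[str, np.ndarray],
    covariates: np.ndarray,
    n_partitions: int = 100,
    test_frac: float = 0.15,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Does adding a PGS to the covariate model improve prediction?

    Per partition, ``trait ~ covariates`` and ``trait ~ covariates + PGS``
    are fit on the test samples; the two R^2 distributions are compared with
    a one-sided Mann-Whitney U test, Benjamini-Hochberg adjusted across the
    supplied PGS family (e.g. real vs null as the overfitting control).
    """
    trait = np.asarray(trait, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n = len(trait)
    C = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ParameterError("singular covariate matrix")
    rng = np.random.default_rng(rng)
    n_test = max(C.shape[1] + 2, int(round(test_frac * n)))
    rows = []
    base_r2, full_r2 = [], {k: [] for k in pgs}
    for _ in range(n_partitions):
        test = rng.choice(n, size=n_test, replace=False)
        yt = trait[test]
        if np.ptp(yt) == 0:
            continue
        Ct = C[test]
        base_r2.append(_ols_r2(Ct, yt))
        for name, score in pgs.items():
            Xf = np.column_stack([Ct, np.asarray(score)[test]])
            full_r2[name].append(_ols_r2(Xf, yt))
    base = np.array(base_r2)
    for name in pgs:
        full = np.array(full_r2[name])
        mw = stats.mannwhitneyu(full, base, alternative="greater")
        rows.append({
            "pgs": name,
            "mean_r2_covariates": float(base.mean()),
            "mean_r2_with_pgs": float(full.mean()),
            "delta_r2": float(full.mean() - base.mean()),
            "mannwhitney_u": float(mw.statistic),
            "p": float(mw.pvalue),
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss) if tss > 0 else 0.0


def transfer_pgs(
    design_train: GwasDesign,
    g: GenotypeMatrix,
    target_idx: np.ndarray,
    target_trait: np.ndarray,
    thresholds: tuple = (1e-2, 1e-3, 1e-4),
    n_random_sets: int = 500,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Score one habitat's samples with another habitat's PGS betas.

    Trains a GWAS on ``design_train``, builds a PGS at each p threshold,
    scores the target samples, and places the observed R^2 within the
    distribution from ``n_random_sets`` random locus sets of the same size
    (with their training betas).
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng)
    res = gwas(design_train, g)
    ld = LdCalculator(g, design_train.sample_idx)
    target_idx = np.asarray(target_idx)
    rows = []
    for thr in thresholds:
        model = build_pgs(res, g, thr, cfg, ld=ld)
        if model.empty:
            rows.append({"p_threshold": thr, "n_loci": 0, "r2": 0.0,
                         "null_mean": np.nan, "null_q95": np.nan,
                         "percentile": np.nan})
            continue
        score = score_samples(model, g, target_idx)
        r2 = _r2_score_trait(score, target_trait)
        nulls = null_pgs(res, g, model, n_random_sets, target_trait,
                         sample_idx=target_idx, rng=rng)
        rows.append({
            "p_threshold": thr,
            "n_loci": model.n_loci,
            "r2": r2,
            "null_mean": float(nulls.mean()),
            "null_q95": float(np.quantile(nulls, 0.95)),
            "percentile": float(np.mean(nulls < r2)),
        })
    return pd.DataFrame(rows)
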