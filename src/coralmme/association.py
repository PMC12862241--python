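"""Covariate-adjusted GWAS with permutation-derived significance thresholds.

Quantitative traits (quantile-normalized bleaching health score) are tested
with per-locus ordinary least squares; the binary survival trait (pre- vs
post-mortality membership) with per-locus logistic maximum likelihood, with
a flagged linear-probability fallback when separation prevents convergence.

The per-locus linear model is computed via Frisch-Waugh-Lovell
residualization so a whole genome scan (and the 10,000-permutation null
used for the genome-wide threshold) reduces to dense matrix products; loci
with missing dosages are refit exactly on their called subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeMatrix, ParameterError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300
_SEPARATION_BETA = 12.0


def quantile_normalize(trait: np.ndarray) -> np.ndarray:
    """Map trait values through the standard normal quantile function.

    Ranks (average for ties) are transformed as Phi^-1((rank - 0.5) / n).
    """
    x = np.asarray(trait, dtype=float)
    if np.isnan(x).any():
        raise ParameterError("trait contains missing values")
    if len(x) < 3:
        raise ParameterError("need >=3 values to quantile-normalize")
    if np.ptp(x) == 0:
        raise ParameterError("constant trait cannot be quantile-normalized")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


@dataclass
class GwasDesign:
    """Trait, covariates and sample selection for a GWAS.

    ``sample_idx`` indexes rows of the genotype matrix; ``trait`` and
    ``covariates`` are aligned to that selection.
    """

    trait: np.ndarray
    covariates: np.ndarray
    sample_idx: np.ndarray
    trait_kind: str = "quantitative"
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        self.sample_idx = np.asarray(self.sample_idx, dtype=int)
        n = len(self.trait)
        if self.covariates is None or np.size(self.covariates) == 0:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if len(self.sample_idx) != n or self.covariates.shape[0] != n:
            raise ParameterError("trait/covariates/sample_idx lengths differ")
        if self.trait_kind not in ("quantitative", "binary"):
            raise ParameterError(f"unknown trait_kind {self.trait_kind!r}")
        if np.isnan(self.trait).any() or np.isnan(self.covariates).any():
            raise ParameterError("missing trait or covariate values among included samples")
        if self.trait_kind == "binary" and not np.isin(self.trait, [0, 1]).all():
            raise ParameterError("binary trait must be coded 0/1")
        C = np.column_stack([np.ones(n), self.covariates])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ParameterError("covariate matrix collinear after adding intercept")

    @property
    def n(self) -> int:
        return len(self.trait)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class GwasResult:
    """Per-locus effect sizes with the design that produced them."""

    table: pd.DataFrame  # locus_id, chrom, pos, beta, se, p, n_used, fallback
    trait_kind: str
    threshold: float | None = None
    n_permutations: int | None = None

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy()


def _ortho_basis(covariates: np.ndarray) -> np.ndarray:
    """Orthonormal basis for [intercept | covariates]."""
    n = covariates.shape[0]
    C = np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(C)
    return Q


def _residualize(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def _linear_scan(
    y: np.ndarray, Z: np.ndarray, Q: np.ndarray, n_covariates: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS slope/SE/p of y ~ intercept + z + covariates.

    Exact via FWL: residualize y and each dosage column on the covariate
    span, then a univariate regression with df = n - n_covariates - 2.
    """
    n = len(y)
    df = n - n_covariates - 2
    if df < 1:
        raise ParameterError("not enough samples for the covariate design")
    yr = _residualize(Q, y[:, None])[:, 0]
    Zr = _residualize(Q, Z)
    zss = np.einsum("ij,ij->j", Zr, Zr)
    ok = zss > 1e-12
    beta = np.zeros(Z.shape[1])
    se = np.full(Z.shape[1], np.nan)
    p = np.ones(Z.shape[1])
    beta[ok] = (Zr[:, ok] * yr[:, None]).sum(axis=0) / zss[ok]
    rss = np.maximum((yr @ yr) - beta[ok] ** 2 * zss[ok], 0.0)
    se[ok] = np.sqrt(rss / df / zss[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    p[ok] = np.clip(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR, 1.0)
    return beta, se, p


def _logistic_scan_chunk(
    y: np.ndarray, Z: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton-Raphson logistic fits y ~ 1 + z + covariates.

    Returns (beta, se, p, loglik, failed) for the dosage coefficient per
    column of Z; ``failed`` marks non-convergence or separation.
    """
    nloci = Z.shape[1]
    n = len(y)
    k2 = 2 + C.shape[1]
    X = np.empty((nloci, n, k2))
    X[:, :, 0] = 1.0
    X[:, :, 1] = Z.T
    X[:, :, 2:] = C[None, :, :]
    b = np.zeros((nloci, k2))
    active = np.ones(nloci, dtype=bool)
    failed = np.zeros(nloci, dtype=bool)
    var = np.full(nloci, np.nan)
    # zero-variance dosage columns carry no information: skip them cleanly
    degenerate = np.ptp(Z, axis=0) == 0
    active[degenerate] = False
    for _ in range(30):
        if not active.any():
            break
        Xa, ba = X[active], b[active]
        eta = np.einsum("bnk,bk->bn", Xa, ba)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        grad = np.einsum("bnk,bn->bk", Xa, y[None, :] - mu)
        H = np.einsum("bnk,bn,bnj->bkj", Xa, w, Xa)
        H += 1e-10 * np.eye(k2)[None]
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # degrade to per-locus solves; flag only the singular fits
            step = np.zeros_like(grad)
            for t in range(H.shape[0]):
                try:
                    step[t] = np.linalg.solve(H[t], grad[t])
                except np.linalg.LinAlgError:
                    step[t] = 0.0
                    failed[np.flatnonzero(active)[t]] = True
        step = np.clip(step, -5.0, 5.0)
        b[active] = ba + step
        conv = np.abs(step).max(axis=1) < 1e-8
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
    failed |= active  # never converged
    failed |= np.abs(b[:, 1]) > _SEPARATION_BETA
    ok = ~failed
    if ok.any():
        eta = np.einsum("bnk,bk->bn", X[ok], b[ok])
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        H = np.einsum("bnk,bn,bnj->bkj", X[ok], w, X[ok])
        try:
            cov = np.linalg.inv(H)
            var[ok] = cov[:, 1, 1]
        except np.linalg.LinAlgError:
            failed[ok] = True
    beta = b[:, 1]
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    p[failed] = np.nan
    p[degenerate] = 1.0
    se[degenerate] = np.nan
    # log-likelihood at the final iterate (used by likelihood-ratio scans)
    eta = np.clip(np.einsum("bnk,bk->bn", X, b), -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = np.einsum("bn->b", y[None, :] * np.log(mu) + (1 - y[None, :]) * np.log(1 - mu))
    return beta, se, p, ll, failed


def _impute_mean(Z: np.ndarray, called: np.ndarray) -> np.ndarray:
    col_mean = np.where(called, Z, 0.0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    return np.where(called, Z, col_mean[None, :])


def gwas(design: GwasDesign, g: GenotypeMatrix) -> GwasResult:
    """Per-locus association scan of the designed trait on allele dosage.

    Quantitative traits use OLS Wald tests; binary traits logistic Wald
    tests with a per-locus linear-probability fallback (flagged) when the
    likelihood does not converge (e.g. quasi-separation).
    """
    d = g.dosages[design.sample_idx].astype(np.float64)
    called = g.dosages[design.sample_idx] != MISSING
    complete = called.all(axis=0)
    y = design.trait
    n = design.n
    L = g.n_loci
    beta = np.zeros(L)
    se = np.full(L, np.nan)
    p = np.ones(L)
    n_used = called.sum(axis=0)
    fallback = np.zeros(L, dtype=bool)
    Q = _ortho_basis(design.covariates)

    if design.trait_kind == "quantitative":
        if complete.any():
            b, s, pv = _linear_scan(y, d[:, complete], Q, design.n_covariates)
            beta[complete], se[complete], p[complete] = b, s, pv
        for j in np.flatnonzero(~complete):
            m = called[:, j]
            if m.sum() < design.n_covariates + 3:
                continue
            Qj = _ortho_basis(design.covariates[m])
            b, s, pv = _linear_scan(y[m], d[m, j][:, None], Qj, design.n_covariates)
            beta[j], se[j], p[j] = b[0], s[0], pv[0]
    else:
        zfill = _impute_mean(d, called)
        chunk = 512
        fail_all = np.zeros(L, dtype=bool)
        for start in range(0, L, chunk):
            sl = slice(start, min(start + chunk, L))
            b, s, pv, _, failed = _logistic_scan_chunk(y, zfill[:, sl], design.covariates)
            beta[sl], se[sl], p[sl] = b, s, pv
            fail_all[sl] = failed
        if fail_all.any():
            logger.info("gwas: linear-probability fallback at %d loci", int(fail_all.sum()))
            b, s, pv = _linear_scan(y, zfill[:, fail_all], Q, design.n_covariates)
            beta[fail_all], se[fail_all], p[fail_all] = b, s, pv
            fallback = fail_all
        # exact per-locus handling of missing dosages for non-fallback loci
        for j in np.flatnonzero(~complete & ~fail_all):
            m = called[:, j]
            if m.sum() < design.n_covariates + 3 or len(np.unique(y[m])) < 2:
                continue
            b, s, pv, _, failed = _logistic_scan_chunk(
                y[m], d[m, j][:, None], design.covariates[m]
            )
            if failed[0]:
                Qj = _ortho_basis(design.covariates[m])
                b, s, pv = _linear_scan(y[m], d[m, j][:, None], Qj, design.n_covariates)
                fallback[j] = True
            beta[j], se[j], p[j] = b[0], s[0], pv[0]

    table = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "beta": beta,
            "se": se,
            "p": p,
            "n_used": n_used,
            "fallback": fallback,
        }
    )
    return GwasResult(table=table, trait_kind=design.trait_kind)


@dataclass
class PermutationThreshold:
    """Genome-wide p-value cutoff from trait permutations.

    ``threshold`` is the 5% quantile of the per-permutation minimum p-value
    distribution: only 5% of null scans produce any p below it, i.e. the
    family-wise 5% genome-wide significance cutoff.
    """

    threshold: float
    min_p: np.ndarray
    n_permutations: int
    seed: int | None


def permutation_threshold(
    design: GwasDesign,
    g: GenotypeMatrix,
    n_permutations: int = 200,
    rng: np.random.Generator | int | None = None,
) -> PermutationThreshold:
    """Permutation-derived genome-wide significance threshold.

    Trait values are shuffled across samples (covariates stay attached to
    their samples), the full scan is re-run, and the minimum p recorded per
    permutation.  Missing dosages are mean-imputed for the permuted scans.
    """
    if n_permutations < 20:
        raise ParameterError("n_permutations < 20 makes the 5% quantile unstable")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    d = g.dosages[design.sample_idx].astype(np.float64)
    called = g.dosages[design.sample_idx] != MISSING
    if not called.all():
        logger.info("permutation_threshold: mean-imputing missing dosages")
    Z = _impute_mean(d, called)
    Q = _ortho_basis(design.covariates)
    min_p = np.empty(n_permutations)
    y = design.trait
    if design.trait_kind == "quantitative":
        # residualized dosages are permutation-invariant: precompute once
        Zr = _residualize(Q, Z)
        zss = np.einsum("ij,ij->j", Zr, Zr)
        ok = zss > 1e-12
        df = design.n - design.n_covariates - 2
        for i in range(n_permutations):
            yp = rng.permutation(y)
            yr = _residualize(Q, yp[:, None])[:, 0]
            b = (Zr[:, ok] * yr[:, None]).sum(axis=0) / zss[ok]
            rss = np.maximum((yr @ yr) - b ** 2 * zss[ok], 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = b / np.sqrt(rss / df / zss[ok])
            min_p[i] = np.clip(2.0 * stats.t.sf(np.abs(t), df).min(), _P_FLOOR, 1.0)
    else:
        for i in range(n_permutations):
            yp = rng.permutation(y)
            pd_ = gwas(
                GwasDesign(yp, design.covariates, design.sample_idx,
                           design.trait_kind, design.covariate_names),
                g,
            ).p
            min_p[i] = np.nanmin(pd_)
    threshold = float(np.quantile(min_p, 0.05))
    logger.info("permutation threshold %.3e from %d permutations (seed=%s)",
                threshold, n_permutations, seed)
    return PermutationThreshold(threshold, min_p, n_permutations, seed)


def design_from_cohort(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    trait_kind: str = "quantitative",
    timepoints: tuple = ("pre",),
    habitat: str | None = None,
    use_pcos: bool = True,
    use_symbionts: bool = True,
    survival_timepoints: tuple = ("pre", "post"),
) -> GwasDesign:
    """Build the study's standard GWAS design from cohort metadata.

    Quantitative: quantile-normalized health score of pre-mortality samples.
    Binary: timepoint membership (pre=0 vs the later timepoint=1).
    Covariates: first two genetic PCos, colony surface area, collection
    depth (dropped automatically when constant, e.g. single-habitat
    subsets), and the proportions of Symbiodinium and Cladocopium reads.
    """
    from .diversity import pcoa_ordination
    from .symbiont import symbiont_proportions

    meta = meta.reset_index(drop=True)
    mask = np.ones(len(meta), dtype=bool)
    if habitat is not None:
        mask &= (meta["habitat"] == habitat).to_numpy()
    if trait_kind == "quantitative":
        mask &= meta["timepoint"].isin(timepoints).to_numpy()
        mask &= meta["health_score"].notna().to_numpy()
    else:
        mask &= meta["timepoint"].isin(survival_timepoints).to_numpy()
    sub = meta[mask]
    sample_idx = g.sample_index(sub["sample_id"])
    if trait_kind == "quantitative":
        trait = quantile_normalize(sub["health_score"].to_numpy(float))
    else:
        trait = (sub["timepoint"] == survival_timepoints[1]).to_numpy(float)

    cov_cols, names = [], []
    if use_pcos:
        ords = pcoa_ordination(g, sample_idx)
        k = min(2, ords.coordinates.shape[1])
        for a in range(k):
            cov_cols.append(ords.coordinates[:, a])
            names.append(f"PCo{a + 1}")
    for col in ("surface_area", "depth_m"):
        v = sub[col].to_numpy(float)
        if np.ptp(v) > 0:
            cov_cols.append(v)
            names.append(col)
        else:
            logger.info("design_from_cohort: dropping constant covariate %s", col)
    if use_symbionts:
        props = symbiont_proportions(sub)
        for genus in ("Symbiodinium", "Cladocopium"):
            v = props[f"prop_{genus}"].to_numpy(float)
            if np.isnan(v).any():
                v = np.where(np.isnan(v), np.nanmean(v), v)
            cov_cols.append(v)
            names.append(f"prop_{genus}")
    covariates = np.column_stack(cov_cols) if cov_cols else np.empty((len(sub), 0))
    return GwasDesign(trait, covariates, sample_idx, trait_kind, names)
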