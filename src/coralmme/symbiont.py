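"""Symbiont-genus read proportions and their association with bleaching.

WGS reads mapping to the Symbiodinium, Cladocopium and Durusdinium genomes
approximate each colony's symbiont community; proportions are the read
counts normalized per sample.  Associations with the 1-5 bleaching health
score are tested per habitat (Pearson), across habitats (interaction GLM
with the shallow forereef as the reference level), between timepoints
(Mann-Whitney U), and jointly via a redundancy-analysis variance partition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .data import SYMBIONT_GENERA, ParameterError

logger = logging.getLogger(__name__)


def symbiont_proportions(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample genus proportions from read counts.

    Adds ``prop_<genus>`` columns and ``total_symbiont_reads``; samples with
    zero total reads get NaN proportions (flagged, excluded downstream).
    """
    cols = [f"reads_{g}" for g in SYMBIONT_GENERA]
    missing = [c for c in cols if c not in meta.columns]
    if missing:
        raise ParameterError(f"metadata missing read-count columns: {missing}")
    counts = meta[cols].to_numpy(float)
    if (counts < 0).any():
        raise ParameterError("negative symbiont read counts")
    total = counts.sum(axis=1)
    if (total == 0).any():
        logger.warning("%d samples with zero symbiont reads flagged undefined",
                       int((total == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(total[:, None] > 0, counts / total[:, None], np.nan)
    out = meta.copy()
    for k, g in enumerate(SYMBIONT_GENERA):
        out[f"prop_{g}"] = props[:, k]
    out["total_symbiont_reads"] = total
    return out


def health_symbiont_correlation(meta: pd.DataFrame, habitat: str) -> pd.DataFrame:
    """Pearson correlation between health score and each genus proportion
    within one habitat (two-sided p from the t transform)."""
    props = symbiont_proportions(meta)
    sub = props[(props["habitat"] == habitat) & props["health_score"].notna()
                & (props["total_symbiont_reads"] > 0)]
    if len(sub) < 5:
        raise ParameterError(f"need >=5 scored samples in {habitat!r}")
    rows = []
    hs = sub["health_score"].to_numpy(float)
    for g in SYMBIONT_GENERA:
        x = sub[f"prop_{g}"].to_numpy(float)
        if np.ptp(x) == 0:
            logger.warning("constant %s proportion in %s: r undefined", g, habitat)
            rows.append({"genus": g, "r": np.nan, "p": np.nan, "n": len(sub)})
            continue
        res = stats.pearsonr(hs, x)
        rows.append({"genus": g, "r": float(res.statistic),
                     "p": float(res.pvalue), "n": len(sub)})
    return pd.DataFrame(rows)


def habitat_interaction_glm(meta: pd.DataFrame) -> pd.DataFrame:
    """Linear model of health on habitat x symbiont-proportion interactions.

    health ~ habitat * (prop_Symbiodinium + prop_Cladocopium)
             + surface_area + site,
    with the shallow forereef as the reference habitat.  Returns the
    coefficient table (beta, SE, p).
    """
    props = symbiont_proportions(meta)
    sub = props[props["health_score"].notna()
                & (props["total_symbiont_reads"] > 0)].copy()
    if sub["habitat"].nunique() < 2:
        raise ParameterError("need >=2 habitats")
    formula = (
        "health_score ~ C(habitat, Treatment('shallow_forereef'))"
        " * (prop_Symbiodinium + prop_Cladocopium)"
        " + surface_area + C(site)"
    )
    fit = smf.ols(formula, data=sub).fit()
    # aliased (collinear) terms surface as NaN coefficients
    if np.isnan(fit.params).any():
        bad = fit.params.index[np.isnan(fit.params)].tolist()
        raise ParameterError(f"rank-deficient design; aliased terms: {bad}")
    out = pd.DataFrame({
        "term": fit.params.index,
        "beta": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    out.attrs["r2"] = float(fit.rsquared)
    out.attrs["fitted"] = fit.fittedvalues.to_numpy()
    out.attrs["resid"] = fit.resid.to_numpy()
    return out


def timepoint_shift_test(
    meta: pd.DataFrame,
    genus: str,
    timepoint_a: str,
    timepoint_b: str,
    habitat: str | None = None,
) -> dict:
    """Mann-Whitney U test of a genus-proportion shift between timepoints.

    Exact two-sided p for small groups (n <= 10 on both sides), normal
    approximation with tie correction otherwise.
    """
    props = symbiont_proportions(meta)
    sub = props[props["total_symbiont_reads"] > 0]
    if habitat is not None:
        sub = sub[sub["habitat"] == habitat]
    col = f"prop_{genus}"
    a = sub[sub["timepoint"] == timepoint_a][col].dropna().to_numpy()
    b = sub[sub["timepoint"] == timepoint_b][col].dropna().to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("need >=3 samples per timepoint")
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "n_a": len(a), "n_b": len(b), "method": method}


def rda_variance_partition(
    response: np.ndarray,
    predictors: pd.DataFrame,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Redundancy analysis: variance in a response matrix explained by a
    predictor design, with a row-permutation p-value.

    R^2 = trace(fitted' fitted) / trace(Yc' Yc) for the centered response
    regressed on the (dummy-coded) predictors; the null permutes predictor
    rows against response rows.
    """
    if n_permutations < 99:
        logger.warning("n_permutations < 99: permutation p poorly resolved")
    rng = np.random.default_rng(rng)
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0)
    X = pd.get_dummies(predictors, drop_first=True).to_numpy(float)
    if X.shape[0] != Y.shape[0]:
        raise ParameterError("response and predictors have different sample counts")
    tss = float(np.sum(Yc ** 2))
    if tss == 0:
        raise ParameterError("constant response matrix")

    def _r2(Xm: np.ndarray) -> float:
        Xd = np.column_stack([np.ones(Xm.shape[0]), Xm])
        beta, *_ = np.linalg.lstsq(Xd, Yc, rcond=None)
        fitted = Xd @ beta
        return float(np.sum(fitted ** 2) / tss)

    r2_obs = _r2(X)
    exceed = 0
    for _ in range(n_permutations):
        if _r2(X[rng.permutation(X.shape[0])]) >= r2_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return {"r2": r2_obs, "p": float(p), "n_permutations": n_permutations}


def dominant_genus(meta: pd.DataFrame) -> pd.Series:
    """Genus with the maximum read proportion per sample (for RDA encoding)."""
    props = symbiont_proportions(meta)
    cols = [f"prop_{g}" for g in SYMBIONT_GENERA]
    arr = props[cols].to_numpy(float)
    dom = pd.Series(
        np.where(np.isnan(arr).all(axis=1), None,
                 np.array(SYMBIONT_GENERA, dtype=object)[np.nanargmax(
                     np.where(np.isnan(arr), -np.inf, arr), axis=1)]),
        index=props.index, name="dominant_genus",
    )
    return dom
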