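"""Site-frequency-spectrum diversity and differentiation statistics.

All estimators operate on called hard genotypes; loci with too few calls are
dropped from the relevant denominator (pairwise-complete deletion).  Theta
and pi are reported per usable locus so groups with unequal locus counts are
comparable.  F_ST is the Hudson estimator in the Bhatia parameterization,
aggregated genome-wide as a ratio of averages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, EmptyResultError, GenotypeMatrix, ParameterError

logger = logging.getLogger(__name__)


def wattersons_theta(g: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> float:
    """Watterson's theta per locus: S / a_{2n} / L.

    S counts loci segregating among called genotypes, a_{2n} is the harmonic
    number over 2n - 1 chromosomes (n diploid samples in the group), and L is
    the number of loci with at least two called samples.
    """
    d = g.dosages if sample_idx is None else g.dosages[np.asarray(sample_idx)]
    n = d.shape[0]
    if n < 2:
        raise ParameterError("need >=2 diploid samples")
    called = d != MISSING
    n_called = called.sum(axis=0)
    usable = n_called >= 2
    if not usable.any():
        raise EmptyResultError("no loci with >=2 called samples")
    alt = np.where(called, d, 0).sum(axis=0)
    seg = usable & (alt > 0) & (alt < 2 * n_called)
    a = np.sum(1.0 / np.arange(1, 2 * n))
    return float(seg.sum() / a / usable.sum())


def nucleotide_diversity_pi(
    g: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> float:
    """Pairwise nucleotide diversity per locus with the small-sample
    correction 2n/(2n-1) applied per locus from its called allele count."""
    d = g.dosages if sample_idx is None else g.dosages[np.asarray(sample_idx)]
    if d.shape[0] < 2:
        raise ParameterError("need >=2 diploid samples")
    called = d != MISSING
    n_called = called.sum(axis=0)
    usable = n_called >= 2
    if not usable.any():
        raise EmptyResultError("no loci with >=2 called samples")
    two_n = 2.0 * n_called[usable]
    p = np.where(called, d, 0).sum(axis=0)[usable] / two_n
    per_locus = 2.0 * p * (1.0 - p) * two_n / (two_n - 1.0)
    return float(per_locus.mean())


def individual_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of called loci that are heterozygous, per sample.

    Samples with zero called loci get ``nan`` with a warning.
    """
    called = g.dosages != MISSING
    n_called = called.sum(axis=1)
    het = (g.dosages == 1).sum(axis=1)
    if (n_called == 0).any():
        logger.warning("%d samples with zero called loci", int((n_called == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, het / n_called, np.nan)


def hudson_fst(
    g: GenotypeMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    return_components: bool = False,
):
    """Hudson F_ST between two sample groups (ratio of averages).

    Per locus, with p1/p2 the called alt frequencies and n1/n2 the called
    allele counts:

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    Genome-wide F_ST = sum(N) / sum(D) over loci where both groups have at
    least two called samples.  The raw estimate is returned (slightly
    negative values are expected under the null); :func:`pairwise_fst` clips
    its report matrix into [0, 1] and logs any pre-clip value.
    """
    da = g.dosages[np.asarray(group_a)]
    db = g.dosages[np.asarray(group_b)]
    ca, cb = da != MISSING, db != MISSING
    n1 = 2.0 * ca.sum(axis=0)
    n2 = 2.0 * cb.sum(axis=0)
    usable = (n1 >= 4) & (n2 >= 4)
    if not usable.any():
        raise EmptyResultError("no loci with >=2 called samples in both groups")
    p1 = np.where(ca, da, 0).sum(axis=0)[usable] / n1[usable]
    p2 = np.where(cb, db, 0).sum(axis=0)[usable] / n2[usable]
    n1, n2 = n1[usable], n2[usable]
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    denom = D.sum()
    if denom == 0:
        raise EmptyResultError("jointly monomorphic groups: F_ST denominator is 0")
    fst = float(N.sum() / denom)
    if return_components:
        return fst, N, D
    return fst


def pairwise_fst(g: GenotypeMatrix, groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric matrix of genome-wide Hudson F_ST between labelled groups."""
    labels = list(groups)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        f = hudson_fst(g, groups[a], groups[b])
        if not 0.0 <= f <= 1.0:
            logger.info("pairwise_fst %s-%s: clipping %.6f into [0, 1]", a, b, f)
            f = float(np.clip(f, 0.0, 1.0))
        out.loc[a, b] = out.loc[b, a] = f
    return out


@dataclass
class Ordination:
    """PCoA coordinates (samples x axes) ordered by eigenvalue."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: np.ndarray


def pcoa_ordination(g: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> Ordination:
    """Principal coordinates on the 1 - correlation transform of the genetic
    covariance matrix.

    Standardized (mean-imputed) dosages -> sample correlation matrix r ->
    distance d = 1 - r -> classical double-centered eigendecomposition.
    Axes with non-positive eigenvalues are dropped.
    """
    gm = g if sample_idx is None else g.take_samples(np.asarray(sample_idx))
    if gm.n_samples < 3:
        raise ParameterError("need >=3 samples for ordination")
    d = gm.dosages.astype(np.float64)
    called = d != MISSING
    p = gm.allele_freq()
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    d, called, p = d[:, keep], called[:, keep], p[keep]
    z = np.where(called, (d - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
    r = np.corrcoef(z)
    dist = 1.0 - r
    n = dist.shape[0]
    # Gower double centering of squared distances
    d2 = dist ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    return Ordination(coordinates=coords, eigenvalues=evals[pos], sample_ids=gm.sample_ids)


def dunns_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc test of stochastic group differences on ranks.

    Pairwise z statistics from mean ranks with the tie correction, two-sided
    p-values, Benjamini-Hochberg adjusted across pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ParameterError("need >=2 groups")
    N = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ia, ib = groups == a, groups == b
        na, nb = ia.sum(), ib.sum()
        diff = ranks[ia].mean() - ranks[ib].mean()
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def diversity_by_window(
    g: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    window_loci: int = 1000,
    statistic: str = "theta",
) -> pd.DataFrame:
    """Per-window diversity for each group, for timepoint comparisons.

    Splits loci into consecutive windows of ``window_loci`` loci and computes
    Watterson's theta or pi per window and group; feed the result to
    :func:`dunns_test`.
    """
    fn = {"theta": wattersons_theta, "pi": nucleotide_diversity_pi}[statistic]
    rows = []
    for start in range(0, g.n_loci, window_loci):
        gw = g.take_loci(np.arange(start, min(start + window_loci, g.n_loci)))
        for label, idx in groups.items():
            try:
                val = fn(gw, idx)
            except EmptyResultError:
                continue
            rows.append({"window": start // window_loci, "group": label, "value": val})
    return pd.DataFrame(rows)
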