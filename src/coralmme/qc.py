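"""Quality filters: MAF/missingness locus filters, clone detection by
identity-by-state clustering, and relatedness pruning.

Clone detection follows the field's standard recipe — average-linkage
hierarchical clustering of pairwise IBS distances, cut at a calibrated
height — on hard genotype calls.  Relatedness is a method-of-moments
estimate from standardized-dosage covariance (two times kinship), so
full sibs sit near 0.5 and duplicates near 1; pairs at or above the
cutoff (default 0.25, the sib/half-sib boundary) are treated as kin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import (
    MISSING,
    EmptyResultError,
    GenotypeMatrix,
    ParameterError,
)

logger = logging.getLogger(__name__)


def filter_loci(
    g: GenotypeMatrix, maf_min: float = 0.05, max_missing_frac: float = 0.2
) -> GenotypeMatrix:
    """Keep loci with minor-allele frequency >= ``maf_min`` among called
    genotypes and missing fraction <= ``max_missing_frac``.

    Idempotent; raises :class:`EmptyResultError` if nothing survives.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ParameterError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ParameterError("max_missing_frac must lie in [0, 1]")
    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    miss = 1.0 - g.call_rate_loci()
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (miss <= max_missing_frac) & ~np.isnan(p)
    n_maf = int(np.sum(~(maf >= maf_min) | np.isnan(p)))
    n_miss = int(np.sum(miss > max_missing_frac))
    logger.info(
        "filter_loci: %d/%d retained (%d below MAF, %d above missingness)",
        int(keep.sum()), g.n_loci, n_maf, n_miss,
    )
    if not keep.any():
        raise EmptyResultError("all loci removed by MAF/missingness filter")
    return g.take_loci(keep)


def ibs_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS distance: fraction of jointly called loci with unequal
    dosage.  Pairs with no jointly called locus get ``nan``."""
    d = g.dosages
    called = (d != MISSING).astype(np.float64)
    # mismatch indicator summed over jointly called loci, via one-hot trick
    n = g.n_samples
    match = np.zeros((n, n))
    for dos in (0, 1, 2):
        ind = ((d == dos) & (d != MISSING)).astype(np.float64)
        match += ind @ ind.T
    joint = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(joint > 0, 1.0 - match / joint, np.nan)
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass
class ClonePartition:
    """Clonal groups and the representative kept from each."""

    groups: list[list]  # lists of sample ids
    keep: list  # one representative per group

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def detect_clones(g: GenotypeMatrix, clone_ibs_cutoff: float = 0.05) -> ClonePartition:
    """Partition samples into clonal groups.

    Average-linkage hierarchical clustering on pairwise IBS distance, cut at
    ``clone_ibs_cutoff``.  Within each group the sample with the highest call
    rate is flagged as the representative (ties broken by sample id order).
    """
    if not 0.0 <= clone_ibs_cutoff <= 1.0:
        raise ParameterError("clone_ibs_cutoff must lie in [0, 1]")
    if g.n_samples < 2:
        raise ParameterError("need at least 2 samples for clone detection")
    dist = ibs_distance_matrix(g)
    if np.isnan(dist).any():
        raise ParameterError("sample pair with no jointly called loci")
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=clone_ibs_cutoff, criterion="distance")
    call_rate = g.call_rate_samples()
    groups, keep = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        # representative: max call rate, then first by sample id
        order = sorted(idx, key=lambda i: (-call_rate[i], str(g.sample_ids[i])))
        groups.append([g.sample_ids[i] for i in idx])
        keep.append(g.sample_ids[order[0]])
    return ClonePartition(groups=groups, keep=keep)


def relatedness_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise relatedness (2x kinship) from standardized-dosage covariance.

    r_ij = mean over jointly called polymorphic loci of
    (d_i - 2p)(d_j - 2p) / (2p(1-p)).  Duplicates ~1, full sibs ~0.5,
    unrelated ~0.
    """
    p = g.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ParameterError("no polymorphic loci; cannot standardize dosages")
    d = g.dosages[:, poly].astype(np.float64)
    pp = p[poly]
    called = d != MISSING
    z = np.where(called, (d - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp)), 0.0)
    num = z @ z.T
    joint = called.astype(np.float64) @ called.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(joint > 0, num / joint, np.nan)


def prune_relatives(
    g: GenotypeMatrix, relatedness_cutoff: float = 0.25
) -> np.ndarray:
    """Return sample ids to keep after greedily pruning related pairs.

    Pairs with relatedness >= cutoff are flagged as kin; the member with
    more flagged pairs is dropped first (ties: lower call rate dropped).
    """
    if not 0.0 <= relatedness_cutoff <= 1.0:
        raise ParameterError("relatedness_cutoff must lie in [0, 1]")
    r = relatedness_matrix(g)
    n = g.n_samples
    flagged = (r >= relatedness_cutoff)
    np.fill_diagonal(flagged, False)
    call_rate = g.call_rate_samples()
    active = np.ones(n, dtype=bool)
    while True:
        counts = (flagged & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max() == 0:
            break
        worst = counts.max()
        cand = np.flatnonzero(counts == worst)
        # among the most-flagged, drop the one with the lowest call rate
        drop = cand[np.lexsort((cand, call_rate[cand]))][0]
        active[drop] = False
        logger.info("prune_relatives: dropping %s (%d flagged pairs)",
                    g.sample_ids[drop], worst)
    return g.sample_ids[active]
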