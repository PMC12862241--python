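"""Core containers: genotype dosage matrix, sample metadata, analysis config.

Dosages are hard calls in {0, 1, 2} with ``MISSING`` (-1) as the sentinel for
uncalled genotypes.  Every statistic in the package excludes MISSING entries
from its denominator (pairwise-complete deletion, per statistic).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype.
MISSING: int = -1

#: Reef habitats recognised in sample metadata.
HABITATS = ("backreef", "shallow_forereef", "deep_forereef")

#: Cohort timepoints: adults during the bleaching event, adults after
#: mortality subsided, and the next-generation recruits two years later.
TIMEPOINTS = ("pre", "post", "juvenile")

#: Symbiodiniaceae genera tracked from WGS read counts (Breviolum excluded:
#: it is not detected in this system).
SYMBIONT_GENERA = ("Symbiodinium", "Cladocopium", "Durusdinium")


class CoralmmeError(Exception):
    """Base class for package errors."""


class ParseError(CoralmmeError):
    """Malformed input file."""


class EmptyResultError(CoralmmeError):
    """An operation removed or excluded every locus/sample."""


class ParameterError(CoralmmeError):
    """A parameter is outside its valid range."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of allele dosages with locus coordinates.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2, MISSING}``.
    sample_ids, locus_ids
        Unique identifiers for rows and columns.
    chrom, pos
        Per-locus contig label and 1-based position (VCF convention);
        positions must be strictly increasing within each contig, and the
        internal locus order is file order.
    ref_allele, alt_allele
        Single-character allele labels; dosage counts the alt allele.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    locus_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D samples x loci array")
        n, L = self.dosages.shape
        if n < 1 or L < 1:
            raise ParameterError("need at least one sample and one locus")
        if len(self.sample_ids) != n:
            raise ParameterError("sample_ids length mismatch")
        for name in ("locus_ids", "chrom", "pos", "ref_allele", "alt_allele"):
            if len(getattr(self, name)) != L:
                raise ParameterError(f"{name} length mismatch")
        vals = np.unique(self.dosages)
        bad = vals[~np.isin(vals, [MISSING, 0, 1, 2])]
        if bad.size:
            raise ParameterError(f"invalid dosage values: {bad.tolist()}")
        if len(set(self.locus_ids)) != L:
            raise ParameterError("locus_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ParameterError("sample_ids must be unique")
        # positions strictly increasing within each contig (file order)
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ParameterError(f"positions not strictly increasing on {c}")

    # -- basic shape/introspection -------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) genotypes."""
        return self.dosages != MISSING

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per locus among called genotypes.

        Loci with no called genotype in the selection get ``nan``.
        """
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        called = d != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def call_rate_samples(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def call_rate_loci(self) -> np.ndarray:
        return self.called().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[idx],
            self.sample_ids[idx],
            self.locus_ids,
            self.chrom,
            self.pos,
            self.ref_allele,
            self.alt_allele,
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.sample_ids,
            self.locus_ids[idx],
            self.chrom[idx],
            self.pos[idx],
            self.ref_allele[idx],
            self.alt_allele[idx],
        )

    def sample_index(self, ids: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def locus_index(self, ids: Sequence) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.locus_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} locus ids not present, e.g. {missing[0]!r}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if not np.array_equal(self.locus_ids, other.locus_ids):
            raise ParameterError("locus sets differ; cannot concatenate samples")
        return GenotypeMatrix(
            np.vstack([self.dosages, other.dosages]),
            np.concatenate([self.sample_ids, other.sample_ids]),
            self.locus_ids,
            self.chrom,
            self.pos,
            self.ref_allele,
            self.alt_allele,
        )


SAMPLE_COLUMNS = [
    "sample_id",
    "site",
    "habitat",
    "timepoint",
    "depth_m",
    "surface_area",
    "health_score",
    "reads_Symbiodinium",
    "reads_Cladocopium",
    "reads_Durusdinium",
]


def validate_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample metadata table (the SampleTable contract).

    Required columns: sample_id, site, habitat, timepoint, depth_m,
    surface_area; optional: health_score (1-5 or NaN) and
    reads_<genus> symbiont read counts.
    """
    required = ["sample_id", "site", "habitat", "timepoint", "depth_m", "surface_area"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParameterError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ParameterError("sample_id values must be unique")
    bad_hab = set(meta["habitat"]) - set(HABITATS)
    if bad_hab:
        raise ParameterError(f"unknown habitats: {sorted(bad_hab)}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ParameterError(f"unknown timepoints: {sorted(bad_tp)}")
    if "health_score" in meta.columns:
        hs = meta["health_score"].dropna()
        if len(hs) and ((hs < 1) | (hs > 5)).any():
            raise ParameterError("health_score must lie in [1, 5]")
    for g in SYMBIONT_GENERA:
        col = f"reads_{g}"
        if col in meta.columns and (meta[col].fillna(0) < 0).any():
            raise ParameterError(f"{col} must be non-negative")
    return meta.reset_index(drop=True)


@dataclass
class AnalysisConfig:
    """Tuning knobs shared across the pipeline.

    Defaults are desk-scale: permutation and bootstrap counts can be raised
    to the study-scale values (10,000 permutations, 1000 bootstraps) via
    config file or CLI flags.
    """

    maf_min: float = 0.05
    max_missing_frac: float = 0.2
    clone_ibs_cutoff: float = 0.05
    relatedness_cutoff: float = 0.25
    rng_seed: int = 0
    n_permutations: int = 200
    pgs_threshold_grid: tuple = (5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 5e-2, 0.1, 0.5)
    clump_window_bp: int = 250_000
    clump_r2_max: float = 0.5
    n_bootstrap: int = 1000
    n_random_sets: int = 500
    n_cv_partitions: int = 100
    cv_test_frac: float = 0.15

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing_frac", "clone_ibs_cutoff",
                     "relatedness_cutoff", "clump_r2_max", "cv_test_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_permutations", "clump_window_bp", "n_bootstrap",
                     "n_random_sets", "n_cv_partitions"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key=value`` config file (# comments allowed)."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParseError(f"{path}:{ln}: unknown config key {key!r}")
            f = fields[key]
            if key == "pgs_threshold_grid":
                kwargs[key] = tuple(float(x) for x in val.split(","))
            elif f.type in ("int", int):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)
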