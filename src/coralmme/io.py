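"""Reading and writing genotype matrices and sample metadata.

Two on-disk genotype dialects are supported:

* VCF 4.2 with bi-allelic SNP records and a GT field (parsed with cyvcf2);
  multi-allelic records are skipped with a logged count.
* A dosage TSV: tab-separated, first column ``sample_id``, header row of
  locus ids, cells in ``{0, 1, 2, NA}``.  When locus ids look like
  ``chrom:pos`` the coordinates are recovered from the ids; otherwise loci
  are placed on a single pseudo-contig at consecutive positions.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, ParseError, validate_samples

logger = logging.getLogger(__name__)

_COORD_RE = re.compile(r"^(?P<chrom>.+):(?P<pos>\d+)$")


def read_genotypes(path: str | Path, config=None) -> GenotypeMatrix:
    """Read genotypes from a VCF (.vcf) or dosage TSV (anything else)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples, dtype=object)
    dosage_cols, locus_ids, chrom, pos, ref, alt = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        d = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage_cols.append(d.astype(np.int8))
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not dosage_cols:
        raise ParseError(f"{path}: no bi-allelic SNP records")
    return GenotypeMatrix(
        np.column_stack(dosage_cols), sample_ids,
        np.array(locus_ids, dtype=object), np.array(chrom, dtype=object),
        np.array(pos), np.array(ref, dtype=object), np.array(alt, dtype=object),
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no locus columns")
    arr = df.to_numpy(dtype=object)
    arr[pd.isna(arr)] = "NA"
    arr = arr.astype(str)
    mat = np.full(df.shape, MISSING, dtype=np.int8)
    for val, dos in (("0", 0), ("1", 1), ("2", 2)):
        mat[arr == val] = dos
    bad = (mat == MISSING) & ~np.isin(arr, ("NA", "."))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: line {i + 2}: invalid dosage {arr[i, j]!r} "
            f"for locus {df.columns[j]!r}"
        )
    locus_ids = np.array(df.columns, dtype=object)
    matches = [_COORD_RE.match(str(l)) for l in locus_ids]
    if all(m is not None for m in matches):
        chrom = np.array([m["chrom"] for m in matches], dtype=object)
        pos = np.array([int(m["pos"]) for m in matches])
    else:
        chrom = np.array(["0"] * len(locus_ids), dtype=object)
        pos = np.arange(1, len(locus_ids) + 1)
    n = len(locus_ids)
    return GenotypeMatrix(
        mat, np.array(df.index, dtype=object), locus_ids, chrom, pos,
        np.array(["A"] * n, dtype=object), np.array(["T"] * n, dtype=object),
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as VCF (.vcf) or dosage TSV (anything else)."""
    path = Path(path)
    if path.suffix == ".vcf":
        _write_vcf(g, path)
    else:
        _write_dosage_tsv(g, path)


def _write_dosage_tsv(g: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        g.dosages.astype(object), index=g.sample_ids, columns=g.locus_ids
    )
    df[g.dosages == MISSING] = "NA"
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coralmme\n")
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(str(s) for s in g.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(g.n_loci):
            gts = "\t".join(_GT[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.locus_ids[j]}\t{g.ref_allele[j]}"
                f"\t{g.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV."""
    meta = pd.read_csv(path, sep="\t")
    return validate_samples(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
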