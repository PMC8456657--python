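"""Genotype matrix container, readers/writers and run configuration.

Two on-disk formats are supported:

* VCF v4.x (read via :mod:`cyvcf2`, written directly).  Only biallelic
  records are retained; multi-allelic records are skipped with a warning.
* A plain TSV dialect: one header row, columns ``chrom  pos  ref  alt``
  followed by one column per sample holding the alt-allele count
  (``0``/``1``/``2``) or ``NA`` for a missing call.

All positions are 1-based and must be strictly increasing within a
chromosome.  Missing genotypes are encoded internally as ``-1``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes for one population.

    Attributes
    ----------
    sample_ids:
        One label per sample.
    chrom, pos, ref, alt:
        Per-SNP metadata arrays; ``pos`` is 1-based.
    geno:
        ``(n_samples, n_snps)`` int8 array of alt-allele counts, ``-1``
        meaning a missing call.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n_snps = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n_snps):
            raise ValueError("SNP metadata arrays disagree in length")
        if self.geno.shape != (len(self.sample_ids), n_snps):
            raise ValueError(
                f"genotype array shape {self.geno.shape} does not match "
                f"({len(self.sample_ids)} samples, {n_snps} SNPs)"
            )
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,-1}")
        # strictly increasing positions within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                i = int(np.where(np.diff(p) <= 0)[0][0]) + 1
                raise ValueError(
                    f"positions not strictly increasing on {c} at record "
                    f"{c}:{p[i]}"
                )

    # -- derived quantities -----------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return (self.geno != MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, called allele count)."""
        called = self.geno != MISSING
        alt = np.where(called, self.geno, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele sample frequency (NaN where no calls)."""
        alt, n = self.allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def is_polymorphic(self) -> np.ndarray:
        """Per-SNP flag: both alleles observed among called genotypes."""
        alt, n = self.allele_counts()
        return (alt > 0) & (alt < n)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            geno=self.geno[:, index],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.geno, other.geno)
        )


def empty_genotype_matrix(sample_ids: Sequence[str]) -> GenotypeMatrix:
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        chrom=np.array([], dtype=object),
        pos=np.array([], dtype=np.int64),
        ref=np.array([], dtype=object),
        alt=np.array([], dtype=object),
        geno=np.zeros((len(sample_ids), 0), dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named format."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    gm.validate()
    if format == "tsv":
        _write_tsv(gm, path)
    elif format == "vcf":
        _write_vcf(gm, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


def _read_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                     na_values=["NA"], keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"TSV must start with columns {required}")
    samples = list(df.columns[4:])
    geno = df[samples].to_numpy(dtype=float) if samples else np.zeros((len(df), 0))
    geno = np.where(np.isnan(geno), MISSING, geno).T.astype(np.int8)
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        geno=geno,
    )


def _write_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": gm.chrom, "pos": gm.pos, "ref": gm.ref, "alt": gm.alt})
    g = gm.geno.astype(object)
    for i, s in enumerate(gm.sample_ids):
        col = g[i].copy()
        col[col == MISSING] = "NA"
        df[s] = col
    df.to_csv(path, sep="\t", index=False)


_GT_TYPE_MAP = {0: 0, 1: 1, 2: MISSING, 3: 2}  # cyvcf2 gt_types -> alt count


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append([_GT_TYPE_MAP[t] for t in v.gt_types])
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records in %s", n_multi, path)
    geno = (np.array(rows, dtype=np.int8).T if rows
            else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        geno=geno,
    )


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(gm.sample_ids)) + "\n")
        for j in range(gm.n_snps):
            gts = "\t".join(_VCF_GT[int(g)] for g in gm.geno[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_by_call_rate(gm: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Keep SNPs whose non-missing genotype fraction is >= ``min_rate``."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    keep = np.where(gm.call_rate() >= min_rate)[0]
    return gm.take_snps(keep)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``admixed/source_p/source_a`` point at genotype files, or
    ``demography`` carries simulation parameters (see
    :class:`admixscan.simulate.DemographyConfig`).
    """

    admixed: str | None = None
    source_p: str | None = None
    source_a: str | None = None
    format: str = "tsv"
    demography: dict = field(default_factory=dict)
    generations: int = 100
    recombination_rate: float = 1.3e-8
    eps: float = 0.005
    min_call_rate: float = 0.95
    scan_k: float = 5.0
    target_snps: int | None = None
    n_null_runs: int = 0
    exclude_samples: list[str] = field(default_factory=list)
    seed: int = 0
    out_dir: str = "admixscan_out"

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.recombination_rate <= 0:
            raise ValueError("recombination_rate must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
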