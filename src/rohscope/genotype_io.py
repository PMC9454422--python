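"""Genotype container, VCF input/output and site-level quality control.

The canonical in-memory object is :class:`GenotypeMatrix`: a samples x sites
array of alternate-allele dosages (0/1/2, ``-1`` for a missing call) together
with per-site chromosome/position/alleles and per-sample population labels.
All genomic coordinates are 1-based and inclusive, matching VCF.

Only biallelic SNPs are represented; multiallelic or indel records are
skipped at read time.  Phase in the GT field is ignored: every downstream
statistic in this package is genotype-based.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")

# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)

_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class EmptyMatrixError(ValueError):
    """An operation produced (or was given) a genotype matrix with no sites."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class QCParams:
    """Site-level quality-control thresholds.

    maf_min
        Minimum minor-allele frequency; a site is kept when
        ``min(freq, 1 - freq) >= maf_min`` (inclusive boundary).
    geno_max
        Maximum per-site missing-call rate; a site is kept when its
        missing rate is ``<= geno_max`` (inclusive boundary).
    """

    maf_min: float = 0.05
    geno_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.geno_max <= 1.0:
            raise ValueError(f"geno_max must be in [0, 1], got {self.geno_max}")


@dataclass(frozen=True)
class QCReport:
    """Counts of sites removed by each quality-control filter."""

    n_sites_in: int
    n_fail_maf: int
    n_fail_missing: int
    n_fail_both: int
    n_kept: int


@dataclass(eq=False)
class GenotypeMatrix:
    """Samples x biallelic-sites dosage matrix with site and sample metadata.

    ``dosages`` holds the alternate-allele count per (sample, site) as int8;
    ``MISSING`` (-1) marks an uncalled genotype.  Sites are sorted by
    chromosome group with strictly increasing positions within each
    chromosome, and each chromosome occupies one contiguous block.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    populations: dict[str, str] = field(default_factory=dict)

    # -- basic introspection ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        """Check shape and ordering invariants; raise ``ValueError`` on failure."""
        if self.dosages.shape != (self.n_samples, self.n_sites):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({self.n_samples}, {self.n_sites})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        seen: set[str] = set()
        prev_chrom = None
        for c in self.chrom:
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} is not a contiguous block")
                seen.add(c)
                prev_chrom = c
        for c, sl in self.chrom_slices():
            p = self.pos[sl]
            if len(p) and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.populations:
            missing = [s for s in self.samples if s not in self.populations]
            if missing:
                raise ValueError(f"samples without population label: {missing[:5]}")

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks in site order."""
        out: list[tuple[str, slice]] = []
        if self.n_sites == 0:
            return out
        start = 0
        for i in range(1, self.n_sites + 1):
            if i == self.n_sites or self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        return out

    def chromosomes(self) -> list[str]:
        return [c for c, _ in self.chrom_slices()]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sites(self) -> Iterator[Site]:
        for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt):
            yield Site(str(c), int(p), str(r), str(a))

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )

    # -- derived views ------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping sites where ``mask`` is True; order preserved."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosages=self.dosages[:, mask],
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return replace(
            self,
            samples=list(keep),
            dosages=self.dosages[idx, :],
            populations={s: self.populations[s] for s in keep if s in self.populations},
        )

    def with_populations(self, populations: Mapping[str, str]) -> "GenotypeMatrix":
        return replace(self, populations=dict(populations))

    def population_samples(self, population: str) -> list[str]:
        out = [s for s in self.samples if self.populations.get(s) == population]
        if not out:
            raise KeyError(f"no samples with population label {population!r}")
        return out

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom.astype(str), other.chrom.astype(str))
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref.astype(str), other.ref.astype(str))
            and np.array_equal(self.alt.astype(str), other.alt.astype(str))
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, populations: Mapping[str, str] | str | Path | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records (single-nucleotide REF and ALT) are retained;
    multiallelic and indel records are skipped with a debug log.  ``./.``
    genotypes become :data:`MISSING`.  Site order follows the file.

    Parameters
    ----------
    path
        VCF 4.x file, plain, gzip- or bgzip-compressed.
    populations
        Optional sample -> population mapping, or a path to a two-column
        TSV (sample, population).
    """
    from cyvcf2 import VCF  # deferred: import cost and cleaner error paths

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or variant.REF not in _NUCLEOTIDES
            or variant.ALT[0] not in _NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        dosage_cols.append(_GT_TYPE_TO_DOSAGE[variant.gt_types])
    vcf.close()
    if not dosage_cols:
        raise EmptyMatrixError(f"no biallelic SNP records in {path}")
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=np.column_stack(dosage_cols).astype(np.int8),
    )
    if populations is not None:
        if not isinstance(populations, Mapping):
            populations = read_populations(populations)
        gm = gm.with_populations(populations)
    gm.validate()
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write ``gm`` as a minimal VCF 4.2 file (gzip when the suffix is .gz).

    Round-trips through :func:`read_vcf`: sites, samples and dosages are
    preserved exactly; ``MISSING`` cells are emitted as ``./.``.
    """
    if gm.n_sites == 0:
        raise EmptyMatrixError("refusing to write a VCF with no sites")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    contigs = dict.fromkeys(str(c) for c in gm.chrom)
    try:
        fh = opener(path, "wt")
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscope\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_sites):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def read_populations(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV; '#' lines are comments."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


def write_populations(populations: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")
    return path


# ---------------------------------------------------------------------------
# Allele frequencies and QC
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site alternate-allele frequency over non-missing genotypes.

    Sites where every genotype is missing get ``nan``.
    """
    if gm.n_sites == 0:
        raise EmptyMatrixError("empty genotype matrix")
    d = gm.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    alt_sum = np.where(observed, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = alt_sum / (2.0 * n_obs)
    freq[n_obs == 0] = np.nan
    return freq


def missing_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site fraction of missing genotype calls."""
    return (gm.dosages == MISSING).mean(axis=0)


def qc_mask(gm: GenotypeMatrix, qc: QCParams = QCParams()) -> tuple[np.ndarray, QCReport]:
    """Boolean keep-mask for the MAF and missingness filters, plus a report.

    Both thresholds are inclusive: a site at exactly ``maf_min`` minor-allele
    frequency, or exactly ``geno_max`` missing rate, is kept.
    """
    freq = allele_frequencies(gm)
    minor = np.fmin(freq, 1.0 - freq)
    miss = missing_rate(gm)
    fail_maf = ~(minor >= qc.maf_min)  # nan (all-missing) fails here too
    fail_miss = miss > qc.geno_max
    keep = ~fail_maf & ~fail_miss
    report = QCReport(
        n_sites_in=gm.n_sites,
        n_fail_maf=int(fail_maf.sum()),
        n_fail_missing=int(fail_miss.sum()),
        n_fail_both=int((fail_maf & fail_miss).sum()),
        n_kept=int(keep.sum()),
    )
    n_boundary_maf = int(np.sum(minor == qc.maf_min))
    n_boundary_miss = int(np.sum(miss == qc.geno_max))
    if n_boundary_maf or n_boundary_miss:
        logger.info(
            "QC boundary sites kept (inclusive thresholds): %d at maf=%g, %d at geno=%g",
            n_boundary_maf, qc.maf_min, n_boundary_miss, qc.geno_max,
        )
    return keep, report


def apply_qc(gm: GenotypeMatrix, qc: QCParams = QCParams()) -> GenotypeMatrix:
    """Drop sites failing the minor-allele-frequency or missingness filter.

    Surviving sites keep their original order; the sample set is unchanged.
    Raises :class:`EmptyMatrixError` when no site survives.
    """
    keep, report = qc_mask(gm, qc)
    logger.info(
        "QC: %d sites in, %d failed maf<%g, %d failed missing>%g (%d both), %d kept",
        report.n_sites_in, report.n_fail_maf, qc.maf_min,
        report.n_fail_missing, qc.geno_max, report.n_fail_both, report.n_kept,
    )
    if report.n_kept == 0:
        raise EmptyMatrixError("all sites removed by QC filters")
    return gm.subset_sites(keep)
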