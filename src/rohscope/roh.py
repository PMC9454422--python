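"""Runs of homozygosity: detection, inbreeding coefficients, ROH islands.

A run of homozygosity (ROH) is a contiguous stretch of one individual's
genome where both haplotypes are identical.  Here a run is a window of
consecutive SNPs satisfying five explicit criteria (defaults in
:class:`ROHCriteria`):

1. at least ``min_snps`` SNPs (default 100);
2. SNP density of at least one SNP per ``min_density_bp_per_snp`` bp
   (default 100 kb), i.e. ``length / n_snps <= min_density_bp_per_snp``;
3. total length at least ``min_length_bp`` (default 1 Mb);
4. at most ``max_missing`` missing (default 2) and ``max_het``
   heterozygous (default 1) genotypes inside the window;
5. no gap between consecutive SNPs larger than ``max_gap_bp``
   (default 1 Mb).

Detection is an exact criteria-based maximal-segment search, not a
sliding-window heuristic: scanning left to right, the earliest start with
any qualifying window is extended to the largest qualifying end, the
segment is emitted, and the scan resumes after it.  Window boundaries must
be homozygous SNPs, so heterozygous/missing calls never inflate segment
termini.  Results can therefore differ at segment margins from heuristic
tools applied to the same data.

F_ROH, the genomic inbreeding coefficient, divides the summed ROH length
by the SNP-covered autosomal length (first-to-last SNP per chromosome).
A ROH *island* is a maximal run of consecutive SNPs whose ROH incidence
(fraction of all individuals whose ROH cover the SNP) meets a threshold,
0.30 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHCriteria:
    """The five ROH definition rules (bp units, counts)."""

    min_snps: int = 100
    min_density_bp_per_snp: int = 100_000
    min_length_bp: int = 1_000_000
    max_missing: int = 2
    max_het: int = 1
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_density_bp_per_snp,
               self.min_length_bp, self.max_gap_bp) < 1:
            raise ValueError("size criteria must be positive")
        if self.max_missing < 0 or self.max_het < 0:
            raise ValueError("tolerance counts must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one individual (1-based inclusive bp)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int = 0
    n_missing: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class FrohResult:
    """Per-individual genomic inbreeding coefficient."""

    sample: str
    sum_roh_bp: int
    denominator_bp: int

    @property
    def froh(self) -> float:
        return self.sum_roh_bp / self.denominator_bp


@dataclass(frozen=True)
class IslandRegion:
    """A ROH island: consecutive SNPs with incidence >= threshold.

    start/end are the positions of the first and last member SNP, so the
    reported length is ``end - start + 1``.
    """

    chrom: str
    start: int
    end: int
    n_snps: int
    incidence_profile: tuple[float, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _scan_chromosome(
    pos: np.ndarray, hom: np.ndarray, het: np.ndarray, miss: np.ndarray,
    c: ROHCriteria,
) -> list[tuple[int, int]]:
    """Greedy maximal-window scan on one chromosome.

    Returns (i, j) site-index pairs.  Uses prefix sums for het/missing
    counts and gap-break blocks so that, for each candidate start, the
    furthest end compatible with the tolerance and gap rules is found in
    O(log n); the density/length rules are then checked scanning ends
    downward (stopping once the window is shorter than ``min_length_bp``,
    below which no smaller end can qualify).
    """
    n = len(pos)
    if n == 0:
        return []
    het_cum = np.concatenate([[0], np.cumsum(het)])
    miss_cum = np.concatenate([[0], np.cumsum(miss)])
    gap_breaks = np.flatnonzero(np.diff(pos) > c.max_gap_bp)  # gap after index g

    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        # furthest j satisfying the monotone rules (het, missing, gap)
        j_het = int(np.searchsorted(het_cum, het_cum[i] + c.max_het, side="right")) - 2
        j_miss = int(np.searchsorted(miss_cum, miss_cum[i] + c.max_missing, side="right")) - 2
        k = int(np.searchsorted(gap_breaks, i, side="left"))
        j_gap = int(gap_breaks[k]) if k < len(gap_breaks) else n - 1
        j_max = min(j_het, j_miss, j_gap)

        found = -1
        j = j_max
        j_floor = i + c.min_snps - 1
        while j >= j_floor:
            if hom[j]:
                length = int(pos[j] - pos[i]) + 1
                if length < c.min_length_bp:
                    break
                if length <= c.min_density_bp_per_snp * (j - i + 1):
                    found = j
                    break
            j -= 1
        if found < 0:
            i += 1
            continue
        segments.append((i, found))
        i = found + 1
    return segments


def detect_roh_individual(
    gm: GenotypeMatrix, sample: str, criteria: ROHCriteria = ROHCriteria()
) -> list[ROHSegment]:
    """Detect ROH for one sample; empty list when nothing qualifies.

    Segment boundaries are SNP positions; within each chromosome the
    segments are non-overlapping and ordered by start.
    """
    row = gm.dosages[gm.sample_index(sample)]
    out: list[ROHSegment] = []
    for chrom, sl in gm.chrom_slices():
        d = row[sl]
        pos = gm.pos[sl]
        hom = (d == 0) | (d == 2)
        het = d == 1
        miss = d == MISSING
        for i, j in _scan_chromosome(pos, hom, het, miss, criteria):
            out.append(
                ROHSegment(
                    sample=sample,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_snps=j - i + 1,
                    n_het=int(het[i : j + 1].sum()),
                    n_missing=int(miss[i : j + 1].sum()),
                )
            )
    return out


def detect_roh_cohort(
    gm: GenotypeMatrix, criteria: ROHCriteria = ROHCriteria()
) -> list[ROHSegment]:
    """Per-sample detection over the whole cohort.

    Stable ordering: sample (input order), then chromosome, then start.
    """
    out: list[ROHSegment] = []
    for sample in gm.samples:
        segs = detect_roh_individual(gm, sample, criteria)
        segs.sort(key=lambda s: (s.chrom, s.start))
        out.extend(segs)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_breed_counts(
    segments: Sequence[ROHSegment], populations: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-breed ROH counts and shares, plus per-sample total ROH length.

    Returns ``(per_breed, per_sample_bp)`` where ``per_breed`` has columns
    ``count`` and ``share_pct`` (percent of all segments, rounded to two
    decimals) indexed by breed, and ``per_sample_bp`` sums segment lengths
    per sample.  Zero segments yields an all-zero summary with a warning.
    """
    for seg in segments:
        if seg.sample not in populations:
            raise KeyError(f"segment sample {seg.sample!r} has no population label")
    breeds = sorted(set(populations.values()))
    counts = {b: 0 for b in breeds}
    per_sample: dict[str, int] = {}
    for seg in segments:
        counts[populations[seg.sample]] += 1
        per_sample[seg.sample] = per_sample.get(seg.sample, 0) + seg.length
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no ROH segments: breed summary is all zero", stacklevel=2)
        shares = {b: 0.0 for b in breeds}
    else:
        shares = {b: round(100.0 * counts[b] / total, 2) for b in breeds}
    per_breed = pd.DataFrame(
        {"count": pd.Series(counts), "share_pct": pd.Series(shares)}
    )
    per_breed.index.name = "breed"
    return per_breed, pd.Series(per_sample, name="total_roh_bp", dtype="int64")


def snp_covered_length(gm: GenotypeMatrix, autosomes: Iterable[str] | None = None) -> int:
    """Total SNP-covered length: sum over chromosomes of
    (last SNP position - first SNP position + 1)."""
    chroms = set(map(str, autosomes)) if autosomes is not None else None
    total = 0
    for c, sl in gm.chrom_slices():
        if chroms is not None and c not in chroms:
            continue
        p = gm.pos[sl]
        total += int(p[-1] - p[0]) + 1
    return total


def compute_froh(
    segments: Sequence[ROHSegment],
    gm: GenotypeMatrix,
    autosomes: Iterable[str] | None = None,
) -> list[FrohResult]:
    """F_ROH per sample: summed ROH length over SNP-covered autosomal length.

    ``autosomes`` restricts both numerator and denominator to the given
    chromosomes; by default every chromosome in the matrix counts as an
    autosome (the convention of the synthetic cohorts).
    """
    chroms = (
        set(map(str, autosomes)) if autosomes is not None else set(gm.chromosomes())
    )
    if not chroms & set(gm.chromosomes()):
        raise ValueError("autosome list shares no chromosome with the matrix")
    denom = snp_covered_length(gm, chroms)
    sums = {s: 0 for s in gm.samples}
    for seg in segments:
        if seg.chrom in chroms:
            sums[seg.sample] += seg.length
    return [FrohResult(s, sums[s], denom) for s in gm.samples]


def froh_table(results: Sequence[FrohResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "sum_roh_bp": [r.sum_roh_bp for r in results],
            "denominator_bp": [r.denominator_bp for r in results],
            "froh": [r.froh for r in results],
        }
    )


def snp_roh_incidence(
    segments: Sequence[ROHSegment], gm: GenotypeMatrix
) -> np.ndarray:
    """Per-site ROH incidence: fraction of all samples (pooled over
    populations) with at least one ROH covering the site's position."""
    counts = np.zeros(gm.n_sites, dtype=np.int64)
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    slices = dict(gm.chrom_slices())
    for segs in by_sample.values():
        covered = np.zeros(gm.n_sites, dtype=bool)
        for seg in segs:
            sl = slices[seg.chrom]
            p = gm.pos[sl]
            i0 = int(np.searchsorted(p, seg.start, side="left"))
            i1 = int(np.searchsorted(p, seg.end, side="right"))
            covered[sl.start + i0 : sl.start + i1] = True
        counts += covered
    return counts / gm.n_samples


def call_islands(
    incidence: np.ndarray, gm: GenotypeMatrix, threshold: float = 0.30
) -> list[IslandRegion]:
    """Maximal runs of consecutive SNPs with incidence >= threshold.

    The comparison is inclusive.  Runs are never merged across a
    below-threshold SNP.  Region start/end are the first/last member-SNP
    positions (1-based inclusive), so length = end - start + 1.
    """
    if len(incidence) != gm.n_sites:
        raise ValueError("incidence vector not aligned to matrix sites")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    islands: list[IslandRegion] = []
    for chrom, sl in gm.chrom_slices():
        inc = incidence[sl]
        above = inc >= threshold
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]]).astype(np.int8)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1) - 1
        p = gm.pos[sl]
        for a, b in zip(starts, ends):
            islands.append(
                IslandRegion(
                    chrom=chrom,
                    start=int(p[a]),
                    end=int(p[b]),
                    n_snps=int(b - a + 1),
                    incidence_profile=tuple(float(x) for x in inc[a : b + 1]),
                )
            )
    return islands


# ---------------------------------------------------------------------------
# Verification helper and output writers
# ---------------------------------------------------------------------------

def verify_segment(
    seg: ROHSegment, gm: GenotypeMatrix, criteria: ROHCriteria = ROHCriteria()
) -> bool:
    """Independently re-check every criterion for a reported segment."""
    sl = dict(gm.chrom_slices())[seg.chrom]
    p = gm.pos[sl]
    i0 = int(np.searchsorted(p, seg.start, side="left"))
    i1 = int(np.searchsorted(p, seg.end, side="right")) - 1
    if i0 > i1 or p[i0] != seg.start or p[i1] != seg.end:
        return False
    d = gm.dosages[gm.sample_index(seg.sample), sl][i0 : i1 + 1]
    n = len(d)
    n_het = int(np.sum(d == 1))
    n_miss = int(np.sum(d == MISSING))
    length = seg.end - seg.start + 1
    gaps = np.diff(p[i0 : i1 + 1])
    hom_ends = d[0] in (0, 2) and d[-1] in (0, 2)
    return (
        hom_ends
        and n == seg.n_snps
        and n >= criteria.min_snps
        and length >= criteria.min_length_bp
        and n_het <= criteria.max_het
        and n_miss <= criteria.max_missing
        and length <= criteria.min_density_bp_per_snp * n
        and (len(gaps) == 0 or int(gaps.max()) <= criteria.max_gap_bp)
    )


def segments_table(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "n_het": [s.n_het for s in segments],
            "n_missing": [s.n_missing for s in segments],
            "length": [s.length for s in segments],
        }
    )


def write_segments(segments: Sequence[ROHSegment], tsv: str | Path, bed: str | Path | None = None) -> None:
    segments_table(segments).to_csv(tsv, sep="\t", index=False)
    if bed is not None:
        with open(bed, "w") as fh:
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample}\n")


def islands_table(islands: Sequence[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": [i.start for i in islands],
            "end": [i.end for i in islands],
            "n_snps": [i.n_snps for i in islands],
            "length": [i.length for i in islands],
            "mean_incidence": [float(np.mean(i.incidence_profile)) for i in islands],
        }
    )


def write_islands(islands: Sequence[IslandRegion], tsv: str | Path, bed: str | Path | None = None) -> None:
    islands_table(islands).to_csv(tsv, sep="\t", index=False)
    if bed is not None:
        with open(bed, "w") as fh:
            for k, i in enumerate(islands, 1):
                fh.write(f"{i.chrom}\t{i.start - 1}\t{i.end}\tisland_{k}\n")
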