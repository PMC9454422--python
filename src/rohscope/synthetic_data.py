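"""Synthetic SNP cohorts with known population structure and autozygosity.

The generator emulates the statistical structure the downstream analyses
assume, with ground truth recorded for recovery tests:

* population differentiation — per-population allele frequencies drawn
  around an ancestral frequency under the Balding–Nichols model, with an
  F_ST-like drift parameter per population;
* inbreeding — either site-wise (each genotype independently autozygous
  with probability ``f_inbreed``; exact for Hardy–Weinberg arithmetic) or
  segmental (per-individual autozygous runs copied from a small pool of
  population founder haplotypes; this is what creates run-length structure
  and linkage disequilibrium, as real inbreeding does);
* shared autozygous segments — intervals planted in a chosen fraction of a
  population's individuals, the substrate for ROH-island calling;
* optional two-way admixture for designated individuals.

Coordinates in :class:`SimTruth` are 1-based inclusive SNP positions, the
same convention the ROH detector reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = np.array(["A", "G", "C", "T"], dtype=object)


@dataclass(frozen=True)
class PlantedSegment:
    """A shared autozygous interval planted into one population.

    ``carrier_fraction`` of the population's individuals (rounded to the
    nearest count, seeded choice) become homozygous across every SNP in
    ``[start, end]`` (1-based inclusive bp).
    """

    population: str
    chrom: str
    start: int
    end: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.end < self.start or self.start < 1:
            raise ValueError(f"bad segment interval [{self.start}, {self.end}]")


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two-way admixture for one sample: each allele copy comes from
    ``pop_a`` with probability ``alpha``, else from ``pop_b``."""

    sample: str
    pop_a: str
    pop_b: str
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 4 populations x 30 diploid individuals, 2 x 50 Mb chromosomes,
    2e4 SNP sites (one SNP per ~5 kb on average).

    fst / f_inbreed / f_autozygous accept a scalar (shared by all
    populations) or one value per population.  ``f_autozygous`` is the
    fraction of the SNP-covered genome placed inside per-individual
    autozygous segments of ~``auto_segment_bp`` each; ``hap_pool`` founder
    haplotypes per population are the copy sources, which gives autozygous
    individuals of one population correlated alleles (block LD).
    """

    n_pops: int = 4
    n_per_pop: int = 30
    n_sites: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "2": 50_000_000}
    )
    fst: float | Sequence[float] = 0.05
    f_inbreed: float | Sequence[float] = 0.0
    f_autozygous: float | Sequence[float] = 0.0
    auto_segment_bp: int = 2_500_000
    hap_pool: int = 4
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    admixture: list[AdmixtureSpec] = field(default_factory=list)
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    @property
    def pop_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_pops)]

    def per_pop(self, value: float | Sequence[float]) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * self.n_pops
        vals = [float(v) for v in value]  # type: ignore[union-attr]
        if len(vals) != self.n_pops:
            raise ValueError(f"expected {self.n_pops} per-population values")
        return vals

    def validate(self) -> None:
        for c in self.per_pop(self.fst):
            if not 0.0 < c < 1.0:
                raise ValueError(f"fst must be in (0, 1), got {c}")
        for f in self.per_pop(self.f_inbreed) + self.per_pop(self.f_autozygous):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inbreeding level must be in [0, 1], got {f}")
        total = sum(self.chrom_lengths.values())
        if self.n_sites > total:
            raise ValueError(
                f"n_sites={self.n_sites} exceeds genome capacity {total}"
            )
        for seg in self.planted_segments:
            if seg.chrom not in self.chrom_lengths:
                raise ValueError(f"planted segment on unknown chromosome {seg.chrom}")
            if seg.end > self.chrom_lengths[seg.chrom]:
                raise ValueError("planted segment exceeds chromosome length")
            if seg.population not in self.pop_names:
                raise ValueError(f"planted segment in unknown population {seg.population}")
        pops = set(self.pop_names)
        for adm in self.admixture:
            if adm.pop_a not in pops or adm.pop_b not in pops:
                raise ValueError(f"admixture references unknown population: {adm}")


@dataclass
class SimTruth:
    """Ground truth recorded while simulating.

    ``autozygous_intervals`` rows carry (sample, chrom, start, end, kind)
    with start/end the 1-based positions of the first and last SNP inside
    the autozygous stretch, kind in {"individual", "planted"}.
    """

    ancestral_freqs: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    autozygous_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "chrom", "start", "end", "kind"]
        )
    )
    admixture: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    founder_haplotypes: dict[str, np.ndarray] = field(default_factory=dict)

    def add_interval(self, sample: str, chrom: str, start: int, end: int, kind: str) -> None:
        row = pd.DataFrame(
            [{"sample": sample, "chrom": chrom, "start": int(start),
              "end": int(end), "kind": kind}]
        )
        if self.autozygous_intervals.empty:
            self.autozygous_intervals = row
        else:
            self.autozygous_intervals = pd.concat(
                [self.autozygous_intervals, row], ignore_index=True
            )


# ---------------------------------------------------------------------------
# Core draws
# ---------------------------------------------------------------------------

def draw_population_frequencies(
    ancestral_freq: np.ndarray,
    fst: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Balding–Nichols draw of population allele frequencies.

    Each population frequency is Beta(p(1-c)/c, (1-p)(1-c)/c) with
    p the ancestral frequency and c the F_ST-like drift parameter, so the
    mean is p and the variance c*p*(1-p).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be strictly inside (0, 1), got {fst}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p = np.asarray(ancestral_freq, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("ancestral frequencies must lie strictly inside (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def _place_sites(
    rng: np.random.Generator, chrom_lengths: dict[str, int], n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random site placement, sorted, strictly increasing per chromosome."""
    total = sum(chrom_lengths.values())
    if n_sites > total:
        raise ValueError(f"n_sites={n_sites} exceeds genome capacity {total}")
    names = list(chrom_lengths)
    # apportion sites proportionally to length, largest-remainder rounding
    raw = np.array([chrom_lengths[c] / total * n_sites for c in names])
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for k in order[: n_sites - counts.sum()]:
        counts[k] += 1
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for c, k in zip(names, counts):
        length = chrom_lengths[c]
        if k > length:
            raise ValueError(f"chromosome {c} too short for {k} sites")
        pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=k))
        while len(pos) < k:  # top up collisions
            extra = rng.integers(1, length + 1, size=k - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(k, c, dtype=object))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the base cohort: drifted frequencies + (site-wise) inbreeding.

    Per individual and site, with probability ``f_inbreed`` the genotype is
    autozygous (dosage 2 with probability q, else 0, q the population
    alternate-allele frequency); otherwise it is a Hardy–Weinberg binomial
    draw.  Site-wise autozygosity leaves sites independent; use
    ``f_autozygous`` (via :func:`simulate_cohort`) for run-length structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom, pos = _place_sites(rng, config.chrom_lengths, config.n_sites)
    m = len(pos)
    lo, hi = config.ancestral_range
    ancestral = rng.uniform(lo, hi, size=m)
    fsts = config.per_pop(config.fst)
    f_in = config.per_pop(config.f_inbreed)

    ref = rng.choice(_ALLELE_PAIRS, size=m)
    # alt drawn from the three other nucleotides
    alt = np.empty(m, dtype=object)
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    pick = rng.integers(0, 3, size=m)
    for j in range(m):
        alt[j] = others[ref[j]][pick[j]]

    samples: list[str] = []
    populations: dict[str, str] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    rows: list[np.ndarray] = []
    for p_idx, pop in enumerate(config.pop_names):
        q = draw_population_frequencies(ancestral, fsts[p_idx], rng)
        pop_freqs[pop] = q
        f = f_in[p_idx]
        for i in range(config.n_per_pop):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            populations[name] = pop
            hw = rng.binomial(2, q).astype(np.int8)
            if f > 0.0:
                auto = rng.random(m) < f
                autod = (2 * rng.binomial(1, q)).astype(np.int8)
                hw = np.where(auto, autod, hw)
            rows.append(hw)

    gm = GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        dosages=np.vstack(rows),
        populations=populations,
    )
    gm.validate()
    truth = SimTruth(ancestral_freqs=ancestral, pop_freqs=pop_freqs)
    return gm, truth


# ---------------------------------------------------------------------------
# Autozygosity planting
# ---------------------------------------------------------------------------

def _founders(
    truth: SimTruth, pop: str, q: np.ndarray, pool: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population founder haplotypes (pool x n_sites, 0/1 alleles)."""
    if pop not in truth.founder_haplotypes:
        truth.founder_haplotypes[pop] = rng.binomial(
            1, q, size=(pool, len(q))
        ).astype(np.int8)
    return truth.founder_haplotypes[pop]


def _site_range(gm: GenotypeMatrix, chrom: str, start: int, end: int) -> tuple[int, int]:
    """Global site-index half-open range [i0, i1) inside [start, end] on chrom."""
    for c, sl in gm.chrom_slices():
        if c == chrom:
            p = gm.pos[sl]
            i0 = int(np.searchsorted(p, start, side="left"))
            i1 = int(np.searchsorted(p, end, side="right"))
            return sl.start + i0, sl.start + i1
    raise KeyError(f"chromosome {chrom!r} not in matrix")


def plant_autozygous_segments(
    gm: GenotypeMatrix, truth: SimTruth, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Plant the shared autozygous segments of ``config.planted_segments``.

    For each segment, a seeded choice of ``round(carrier_fraction * n)``
    individuals of the population copies one founder haplotype homozygously
    across every SNP in the interval; non-carriers are untouched.  Realized
    carrier intervals (first/last SNP positions) are appended to the truth.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    for seg in config.planted_segments:
        i0, i1 = _site_range(gm, seg.chrom, seg.start, seg.end)
        members = gm.population_samples(seg.population)
        n_carriers = int(round(seg.carrier_fraction * len(members)))
        carriers = rng.choice(len(members), size=n_carriers, replace=False)
        if i1 <= i0:
            warnings.warn(
                f"planted segment {seg.chrom}:{seg.start}-{seg.end} contains no SNPs",
                stacklevel=2,
            )
            continue
        q = truth.pop_freqs[seg.population]
        H = _founders(truth, seg.population, q, config.hap_pool, rng)
        first, last = int(gm.pos[i0]), int(gm.pos[i1 - 1])
        for ci in sorted(carriers):
            sample = members[ci]
            h = int(rng.integers(0, config.hap_pool))
            row = gm.sample_index(sample)
            gm.dosages[row, i0:i1] = 2 * H[h, i0:i1]
            truth.add_interval(sample, seg.chrom, first, last, "planted")
    return gm, truth


def plant_individual_autozygosity(
    gm: GenotypeMatrix, truth: SimTruth, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Give each individual autozygous segments covering ``f_autozygous`` of
    the SNP-covered genome.

    Segments of roughly ``auto_segment_bp`` are placed uniformly at random
    (non-overlapping, padded so neighbouring segments cannot merge into one
    detected run), each copied homozygously from one founder haplotype of
    the individual's population.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    fracs = dict(zip(config.pop_names, config.per_pop(config.f_autozygous)))
    slices = gm.chrom_slices()
    covered = {c: (int(gm.pos[sl][0]), int(gm.pos[sl][-1])) for c, sl in slices}
    total_covered = sum(e - s + 1 for s, e in covered.values())
    chrom_names = [c for c, _ in slices]
    weights = np.array([covered[c][1] - covered[c][0] + 1 for c in chrom_names], float)
    weights /= weights.sum()
    pad = 1_500_000  # keeps planted runs from fusing across the gap

    for sample in gm.samples:
        pop = gm.populations[sample]
        f = fracs[pop]
        if f <= 0.0:
            continue
        target = f * total_covered
        n_seg = max(1, int(round(target / config.auto_segment_bp)))
        seg_len = int(round(target / n_seg))
        q = truth.pop_freqs[pop]
        H = _founders(truth, pop, q, config.hap_pool, rng)
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        row = gm.sample_index(sample)
        attempts = 0
        k = 0
        while k < n_seg and attempts < 200 * n_seg:
            attempts += 1
            c = chrom_names[rng.choice(len(chrom_names), p=weights)]
            lo, hi = covered[c]
            if hi - lo + 1 < seg_len:
                continue
            start = int(rng.integers(lo, hi - seg_len + 2))
            end = start + seg_len - 1
            if any(start - pad <= e and end + pad >= s for s, e in placed[c]):
                continue
            i0, i1 = _site_range(gm, c, start, end)
            if i1 - i0 < 2:
                continue
            h = int(rng.integers(0, config.hap_pool))
            gm.dosages[row, i0:i1] = 2 * H[h, i0:i1]
            placed[c].append((start, end))
            truth.add_interval(sample, c, int(gm.pos[i0]), int(gm.pos[i1 - 1]), "individual")
            k += 1
        if k < n_seg:
            logger.warning("placed only %d/%d autozygous segments for %s", k, n_seg, sample)
    return gm, truth


def simulate_admixed_individuals(
    gm: GenotypeMatrix, truth: SimTruth, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite designated samples with two-way admixed genotypes.

    Each of the two allele copies at every site is drawn from ``pop_a``'s
    frequency with probability alpha, else from ``pop_b``'s.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    m = gm.n_sites
    for adm in config.admixture:
        qa, qb = truth.pop_freqs[adm.pop_a], truth.pop_freqs[adm.pop_b]
        row = gm.sample_index(adm.sample)
        dosage = np.zeros(m, dtype=np.int8)
        for _copy in range(2):
            from_a = rng.random(m) < adm.alpha
            q = np.where(from_a, qa, qb)
            dosage += rng.binomial(1, q).astype(np.int8)
        gm.dosages[row, :] = dosage
        truth.admixture[adm.sample] = (adm.pop_a, adm.pop_b, adm.alpha)
    return gm, truth


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Full generator: base genotypes, admixture, per-individual autozygous
    segments, then shared planted segments.  Bit-identical under a fixed seed."""
    gm, truth = simulate_genotypes(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    if config.admixture:
        simulate_admixed_individuals(gm, truth, config, rng)
    if any(f > 0 for f in config.per_pop(config.f_autozygous)):
        plant_individual_autozygosity(gm, truth, config, rng)
    if config.planted_segments:
        plant_autozygous_segments(gm, truth, config, rng)
    return gm, truth


# ---------------------------------------------------------------------------
# Truth files
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write truth files: autozygous intervals as BED (0-based half-open,
    converted from internal 1-based inclusive), frequencies and admixture
    proportions as TSV.  Empty truth gives header-only files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bed = outdir / "autozygous_truth.bed"
    with open(bed, "w") as fh:
        fh.write("#chrom\tstart\tend\tsample\tkind\n")
        for _, r in truth.autozygous_intervals.iterrows():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r['sample']}\t{r.kind}\n")
    paths["intervals_bed"] = bed

    freq = outdir / "population_freqs.tsv"
    df = pd.DataFrame({"ancestral": truth.ancestral_freqs})
    for pop, q in truth.pop_freqs.items():
        df[pop] = q
    df.to_csv(freq, sep="\t", index=False)
    paths["freqs_tsv"] = freq

    adm = outdir / "admixture_truth.tsv"
    with open(adm, "w") as fh:
        fh.write("sample\tpop_a\tpop_b\talpha\n")
        for sample, (a, b, alpha) in truth.admixture.items():
            fh.write(f"{sample}\t{a}\t{b}\t{alpha}\n")
    paths["admixture_tsv"] = adm
    return paths


def read_truth_intervals(path: str | Path) -> pd.DataFrame:
    """Read an autozygosity-truth BED back to 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, sample, kind = line.rstrip("\n").split("\t")
            rows.append(
                {"sample": sample, "chrom": chrom, "start": int(start) + 1,
                 "end": int(end), "kind": kind}
            )
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "kind"])
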