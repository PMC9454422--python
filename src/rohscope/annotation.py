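"""Gene annotation of ROH islands by interval overlap.

Gene intervals come from BED (0-based half-open, converted on read) or
GFF3 (1-based inclusive, rows with feature type ``gene``).  A gene is
reported for an island when the two intervals share at least one base
pair; fractional-overlap thresholds are deliberately not offered.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .roh import IslandRegion

logger = logging.getLogger(__name__)

_GFF_ATTR_KEYS = ("Name", "gene", "gene_id", "ID")


def _gff_gene_id(attrs: str) -> str | None:
    for key in _GFF_ATTR_KEYS:
        m = re.search(rf"(?:^|;)\s*{key}=([^;]+)", attrs)
        if m:
            return m.group(1)
    return None


@dataclass(frozen=True)
class GeneInterval:
    """One gene interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")


def _open_text(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def read_gene_intervals(path: str | Path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from a BED4+ or GFF3 file (plain or gzip).

    ``fmt`` is 'bed' or 'gff3'; inferred from the file name when omitted.
    BED coordinates are converted to 1-based inclusive; GFF3 rows are
    filtered to feature type ``gene``.  Malformed rows raise with their
    line number.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        if stem.endswith(".bed"):
            fmt = "bed"
        elif stem.endswith((".gff", ".gff3")):
            fmt = "gff3"
        else:
            raise ValueError(f"cannot infer format of {path.name}; pass fmt=")
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown gene-interval format {fmt!r}")

    genes: list[GeneInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED needs >= 4 columns (chrom start end name)")
                    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else None
                    genes.append(GeneInterval(chrom, start + 1, end, name, strand))
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    gene_id = _gff_gene_id(fields[8]) or fields[8]
                    strand = fields[6] if fields[6] in "+-" else None
                    genes.append(
                        GeneInterval(fields[0], int(fields[3]), int(fields[4]), gene_id, strand)
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    logger.info("read %d gene intervals from %s", len(genes), path)
    return genes


def overlap_islands(
    islands: Sequence[IslandRegion], genes: Sequence[GeneInterval]
) -> list[list[GeneInterval]]:
    """Genes intersecting each island by at least one base pair.

    Returns one list per island (aligned with the input order), sorted by
    gene start; islands without genes get an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree uses half-open intervals; +1 makes the end inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out: list[list[GeneInterval]] = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = [iv.data for iv in tree.overlap(isl.start, isl.end + 1)] if tree else []
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        out.append(hits)
    return out
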