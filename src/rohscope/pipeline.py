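"""End-to-end orchestration: QC -> ROH -> islands -> LD -> structure -> genes.

A single :class:`RunConfig` (loadable from YAML) carries every parameter;
the run is deterministic under its seed and writes, into one output
directory: the filtered VCF, ROH segment TSV/BED, F_ROH TSV, island
TSV/BED with gene lists, per-population LD curves with fitted trends, the
bootstrapped NJ tree (Newick), PCA coordinates and eigenvalues, a
parameter-echoing manifest with input checksums, and report tables
(per-breed ROH counts/shares, per-breed F_ROH five-number summaries, and
an island table in Chr / Num of SNPs / Start / End / Length / Genes
order).

Stages are re-entrant: with ``resume=True`` a stage whose outputs already
exist is skipped, so a run can continue after any completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import overlap_islands, read_gene_intervals
from .genotype_io import QCParams, apply_qc, read_vcf, write_vcf
from .ld import population_decay
from .roh import (
    ROHCriteria,
    call_islands,
    compute_froh,
    detect_roh_cohort,
    froh_table,
    islands_table,
    snp_roh_incidence,
    summarize_breed_counts,
    write_islands,
    write_segments,
)
from .structure import bootstrap_support, ibs_distance, k2p_distance, pca

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    vcf: str
    populations: str
    out_dir: str
    seed: int
    genes: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHCriteria = field(default_factory=ROHCriteria)
    island_threshold: float = 0.30
    autosomes: list[str] | None = None
    ld_bin_bp: int = 200_000
    ld_max_dist_bp: int = 5_000_000
    distance_kind: str = "ibs"
    bootstrap_reps: int = 1000
    pca_components: int = 10
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "roh" in raw:
            raw["roh"] = ROHCriteria(**raw["roh"])
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("vcf", "populations", "genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if not 0.0 <= self.island_threshold <= 1.0:
            raise ValueError(
                f"island_threshold must be in [0, 1], got {self.island_threshold}"
            )
        if self.distance_kind not in ("ibs", "k2p"):
            raise ValueError(f"distance_kind must be 'ibs' or 'k2p'")
        if self.bootstrap_reps < 1 or self.pca_components < 1:
            raise ValueError("bootstrap_reps and pca_components must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(paths: list[Path], resume: bool) -> bool:
    return resume and all(p.exists() for p in paths)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("qc")
        gm = read_vcf(config.vcf, populations=config.populations)
        n_before = gm.n_sites
        gm = apply_qc(gm, config.qc)
        logger.info("QC kept %d/%d sites", gm.n_sites, n_before)
        filtered_vcf = out / "filtered.vcf"
        if not _stage_done([filtered_vcf], config.resume):
            write_vcf(gm, filtered_vcf)
    except Exception as exc:
        raise PipelineError(f"stage 'qc' failed: {exc}") from exc

    try:
        stage("roh")
        segments = detect_roh_cohort(gm, config.roh)
        write_segments(segments, out / "roh.tsv", out / "roh.bed")
        froh = compute_froh(segments, gm, config.autosomes)
        froh_table(froh).to_csv(out / "froh.tsv", sep="\t", index=False)
        incidence = snp_roh_incidence(segments, gm)
        pd.DataFrame(
            {"chrom": gm.chrom, "pos": gm.pos, "incidence": incidence}
        ).to_csv(out / "snp_incidence.tsv", sep="\t", index=False)
        islands = call_islands(incidence, gm, config.island_threshold)
        write_islands(islands, out / "islands.tsv", out / "islands.bed")
    except Exception as exc:
        raise PipelineError(f"stage 'roh' failed: {exc}") from exc

    try:
        stage("annotation")
        if config.genes is not None:
            genes = read_gene_intervals(config.genes)
            gene_lists = overlap_islands(islands, genes)
        else:
            gene_lists = [[] for _ in islands]
        isl_tab = islands_table(islands)
        isl_tab["genes"] = [",".join(g.gene_id for g in lst) for lst in gene_lists]
        isl_tab.to_csv(out / "islands.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'annotation' failed: {exc}") from exc

    try:
        stage("ld")
        fits = {}
        for pop in sorted(set(gm.populations.values())):
            curve, fit = population_decay(
                gm, pop, config.ld_bin_bp, config.ld_max_dist_bp
            )
            curve.to_csv(out / f"ld_{pop}.tsv", sep="\t", index=False)
            fits[pop] = dataclasses.asdict(fit)
        with open(out / "ld_fit.json", "w") as fh:
            json.dump(fits, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError(f"stage 'ld' failed: {exc}") from exc

    try:
        stage("structure")
        dm = (
            ibs_distance(gm)
            if config.distance_kind == "ibs"
            else k2p_distance(gm, seed=rng_seed)
        )
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "distances.tsv", sep="\t"
        )
        tree = bootstrap_support(
            gm, config.distance_kind, n_reps=config.bootstrap_reps, seed=rng_seed
        )
        tree.write(str(out / "tree.nwk"))
        pca_res = pca(gm, config.pca_components)
        coords = pd.DataFrame(
            pca_res.coordinates,
            index=pca_res.samples,
            columns=[f"PC{i + 1}" for i in range(pca_res.coordinates.shape[1])],
        )
        coords.insert(0, "population", [gm.populations[s] for s in pca_res.samples])
        coords.to_csv(out / "pca.tsv", sep="\t", index_label="sample")
        pd.DataFrame(
            {
                "eigenvalue": pca_res.eigenvalues,
                "variance_explained": pca_res.variance_explained,
            }
        ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage 'structure' failed: {exc}") from exc

    try:
        stage("report")
        render_report(out, gm.populations)
    except Exception as exc:
        raise PipelineError(f"stage 'report' failed: {exc}") from exc

    manifest = {
        "rohscope_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("vcf", config.vcf),
                ("populations", config.populations),
                ("genes", config.genes),
            )
            if p is not None
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
        "n_sites_input": n_before,
        "n_sites_after_qc": gm.n_sites,
        "n_samples": gm.n_samples,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def render_report(out_dir: str | Path, populations: dict[str, str] | None = None) -> None:
    """Summary tables from the stage outputs in ``out_dir``.

    Writes ``report_breeds.tsv`` (per-breed ROH count/share with a total
    row), ``report_froh.tsv`` (per-breed five-number F_ROH summary) and
    ``report_islands.tsv`` (columns Chr, Num of SNPs, Start, End, Length,
    Genes).  Raises when an upstream file is missing.
    """
    out = Path(out_dir)
    for name in ("roh.tsv", "froh.tsv", "islands.tsv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"missing upstream output: {out / name}")
    if populations is None:
        from .genotype_io import read_populations

        pops_file = out / "populations.tsv"
        if not pops_file.exists():
            raise FileNotFoundError("populations mapping required to render the report")
        populations = read_populations(pops_file)

    roh = pd.read_csv(out / "roh.tsv", sep="\t")
    from .roh import ROHSegment

    segments = [
        ROHSegment(str(r.sample), str(r.chrom), int(r.start), int(r.end),
                   int(r.n_snps), int(r.n_het), int(r.n_missing))
        for r in roh.itertuples(index=False)
    ]
    per_breed, _per_sample = summarize_breed_counts(segments, populations)
    per_breed = per_breed.reset_index()
    total_row = pd.DataFrame(
        [{"breed": "total", "count": per_breed["count"].sum(), "share_pct": 100.0 if per_breed["count"].sum() else 0.0}]
    )
    pd.concat([per_breed, total_row], ignore_index=True).to_csv(
        out / "report_breeds.tsv", sep="\t", index=False
    )

    froh = pd.read_csv(out / "froh.tsv", sep="\t")
    froh["breed"] = froh["sample"].map(populations)
    summary = (
        froh.groupby("breed")["froh"]
        .quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        .unstack()
    )
    summary.columns = ["min", "q1", "median", "q3", "max"]
    summary.insert(0, "mean", froh.groupby("breed")["froh"].mean())
    summary.reset_index().to_csv(out / "report_froh.tsv", sep="\t", index=False)

    islands = pd.read_csv(out / "islands.tsv", sep="\t")
    report = pd.DataFrame(
        {
            "Chr": islands["chrom"],
            "Num of SNPs": islands["n_snps"],
            "Start": islands["start"],
            "End": islands["end"],
            "Length": islands["length"],
            "Genes": islands.get("genes", pd.Series([""] * len(islands))).fillna(""),
        }
    )
    report.to_csv(out / "report_islands.tsv", sep="\t", index=False)
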