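"""Linkage-disequilibrium decay: pairwise r-squared, distance binning, trend fit.

r-squared is the squared Pearson correlation between the unphased genotype
dosage vectors of two SNPs on the same chromosome, computed over the
samples non-missing at both sites (the genotype-correlation convention for
unphased data; no haplotype phasing or EM frequency estimation).  Pairs
are binned by physical distance (200 kb bins by default, half-open
``[0, w), [w, 2w), ...``) and the per-bin mean r-squared forms the decay
curve, summarised by an ordinary-least-squares line over bin means plus a
Spearman rank statistic of mean r-squared against bin midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_BLOCK = 512


@dataclass(frozen=True)
class DecayFit:
    """OLS line over (bin midpoint, mean r2) plus a monotone-trend statistic."""

    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float


def _block_r2(
    X: np.ndarray, M: np.ndarray, a: slice, b: slice
) -> np.ndarray:
    """Pairwise Pearson r^2 between site blocks ``a`` and ``b``.

    ``X`` is samples x sites dosage with missing zero-filled, ``M`` the
    non-missing mask.  Missingness is handled exactly through pairwise
    complete observations; zero-variance pairs come out as nan.
    """
    Xa, Xb = X[:, a], X[:, b]
    Ma, Mb = M[:, a], M[:, b]
    n = Ma.T @ Mb
    sx = Xa.T @ Mb
    sy = Ma.T @ Xb
    sxx = (Xa * Xa).T @ Mb
    syy = Ma.T @ (Xb * Xb)
    sxy = Xa.T @ Xb
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2


def pairwise_r2(
    gm: GenotypeMatrix,
    population: str | None = None,
    max_dist_bp: int = 5_000_000,
) -> pd.DataFrame:
    """All same-chromosome SNP pairs within ``max_dist_bp``, with r-squared.

    Restricted to the samples of ``population`` when given (requires at
    least two).  Returns a DataFrame with columns ``site_a``, ``site_b``
    (global site indices, a < b), ``chrom``, ``distance_bp`` and ``r2``;
    zero-variance pairs are skipped.
    """
    if population is not None:
        sub = gm.subset_samples(gm.population_samples(population))
    else:
        sub = gm
    if sub.n_samples < 2:
        raise ValueError("need at least two samples for LD")
    D = sub.dosages.astype(np.float64)
    M = (sub.dosages != MISSING).astype(np.float64)
    X = np.where(sub.dosages == MISSING, 0.0, D)

    frames: list[pd.DataFrame] = []
    for chrom, sl in sub.chrom_slices():
        pos = sub.pos[sl]
        m = len(pos)
        for a0 in range(0, m, _BLOCK):
            a1 = min(a0 + _BLOCK, m)
            for b0 in range(a0, m, _BLOCK):
                if pos[b0] - pos[a1 - 1] > max_dist_bp:
                    break
                b1 = min(b0 + _BLOCK, m)
                r2 = _block_r2(
                    X, M, slice(sl.start + a0, sl.start + a1),
                    slice(sl.start + b0, sl.start + b1),
                )
                dist = pos[b0:b1][None, :] - pos[a0:a1][:, None]
                keep = (dist > 0) & (dist <= max_dist_bp) & np.isfinite(r2)
                ia, ib = np.nonzero(keep)
                if len(ia) == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "site_a": sl.start + a0 + ia,
                            "site_b": sl.start + b0 + ib,
                            "chrom": chrom,
                            "distance_bp": dist[ia, ib],
                            "r2": r2[ia, ib],
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["site_a", "site_b", "chrom", "distance_bp", "r2"]
        )
    return pd.concat(frames, ignore_index=True)


def bin_decay(pairs: pd.DataFrame, bin_width_bp: int = 200_000) -> pd.DataFrame:
    """Bin pairs by distance: bin k covers ``[k*w, (k+1)*w)``.

    Returns one row per bin from 0 to the furthest non-empty bin, with
    ``bin_start``, ``bin_end``, ``mean_r2`` (nan when empty) and
    ``n_pairs``.
    """
    if len(pairs) == 0:
        raise ValueError("no LD pairs to bin")
    idx = (pairs["distance_bp"].to_numpy() // bin_width_bp).astype(np.int64)
    n_bins = int(idx.max()) + 1
    count = np.bincount(idx, minlength=n_bins)
    total = np.bincount(idx, weights=pairs["r2"].to_numpy(), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins, dtype=np.int64) * bin_width_bp,
            "bin_end": (np.arange(n_bins, dtype=np.int64) + 1) * bin_width_bp,
            "mean_r2": mean,
            "n_pairs": count,
        }
    )


def fit_decay(curve: pd.DataFrame) -> DecayFit:
    """OLS of mean r-squared against bin midpoint over non-empty bins,
    with the Spearman rank correlation reported alongside."""
    nonempty = curve[curve["n_pairs"] > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty bins to fit a trend")
    mid = (nonempty["bin_start"] + nonempty["bin_end"]).to_numpy() / 2.0
    y = nonempty["mean_r2"].to_numpy()
    ols = stats.linregress(mid, y)
    if np.allclose(y, y[0]):
        rho, p = 0.0, 1.0  # constant curve: no rank trend
    else:
        rho, p = stats.spearmanr(mid, y)
    return DecayFit(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        spearman_rho=float(rho),
        spearman_p=float(p),
    )


def population_decay(
    gm: GenotypeMatrix,
    population: str,
    bin_width_bp: int = 200_000,
    max_dist_bp: int = 5_000_000,
) -> tuple[pd.DataFrame, DecayFit]:
    """Convenience: pairwise r2 -> binned curve -> fitted trend for one population."""
    pairs = pairwise_r2(gm, population, max_dist_bp)
    curve = bin_decay(pairs, bin_width_bp)
    return curve, fit_decay(curve)
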