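"""Diversity and divergence statistics for candidate validation.

Observed heterozygosity per SNP within karyotype groups, nucleotide
diversity per probe region (per-site π averaged over the region's
effective length, invariant sites contributing zero), between-arrangement
divergence d_XY recovered from the within/between mixture identity

    N(N−1)·π_t = 2·n_x·n_y·d_XY + n_x(n_x−1)·π_x + n_y(n_y−1)·π_y,

and group comparisons by two-sided Wilcoxon rank-sum tests under the
sequential Bonferroni (Holm) correction.  All π formulas use haplotype
counts (2 × diploid individuals), which makes the mixture identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from invfinder.datatypes import MISSING, GenotypeMatrix

__all__ = [
    "observed_heterozygosity",
    "site_pi",
    "pi_regions",
    "dxy_mixture",
    "dxy_regions",
    "compare_groups",
    "TestResult",
]


def observed_heterozygosity(
    gm: GenotypeMatrix, rows: np.ndarray, cols: np.ndarray | None = None
) -> np.ndarray:
    """H_obs per SNP in a group of individuals: heterozygote count over
    called individuals; SNPs with zero calls in the group are NaN."""
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("empty group")
    G = gm.calls[rows]
    if cols is not None:
        G = G[:, np.asarray(cols)]
    called = (G != MISSING).sum(axis=0)
    het = (G == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def site_pi(G: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity from allele counts of unphased
    genotypes: with n called haplotypes and a alternate alleles,
    π = 2·a·(n−a) / (n·(n−1)) — the mean pairwise difference."""
    called = (G != MISSING).sum(axis=0)
    n = 2.0 * called
    a = np.where(G != MISSING, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, 2.0 * a * (n - a) / (n * (n - 1.0)), np.nan)


def _region_columns(gm: GenotypeMatrix, regions: pd.DataFrame) -> list[np.ndarray]:
    """Column indices per region; regions are BED-like (contig, start,
    end; 0-based half-open)."""
    contig = gm.loci["contig"].to_numpy()
    pos = gm.loci["contig_pos"].to_numpy(dtype=float)  # 1-based
    out = []
    for _, reg in regions.iterrows():
        sel = (contig == reg["contig"]) & (pos - 1 >= reg["start"]) & (pos - 1 < reg["end"])
        out.append(np.flatnonzero(sel))
    return out


def pi_regions(
    gm: GenotypeMatrix,
    rows: np.ndarray,
    regions: pd.DataFrame,
    effective_length: float = 120.0,
) -> np.ndarray:
    """Region π for one group: sum of per-SNP site π over the region
    divided by the effective region length (~probe length in bp);
    invariant sites contribute zero."""
    if effective_length <= 0:
        raise ValueError("effective region length must be positive")
    rows = np.asarray(rows)
    G = gm.calls[rows]
    pi = site_pi(G)
    lengths = (
        regions["effective_length"].to_numpy(dtype=float)
        if "effective_length" in regions.columns
        else np.full(len(regions), effective_length)
    )
    out = np.empty(len(regions))
    for i, cols in enumerate(_region_columns(gm, regions)):
        vals = pi[cols]
        out[i] = np.nansum(vals) / lengths[i]
    return out


def dxy_mixture(
    pi_t: float, pi_x: float, pi_y: float, n_x: int, n_y: int
) -> tuple[float, bool]:
    """d_XY from total and within-group diversity via the mixture
    identity; n_x, n_y are haplotype counts.  Returns (d_XY, floored)
    where ``floored`` flags a negative result clipped to 0."""
    if n_x < 1 or n_y < 1:
        raise ValueError("both groups need at least one haplotype")
    N = n_x + n_y
    num = N * (N - 1) * pi_t - n_x * (n_x - 1) * pi_x - n_y * (n_y - 1) * pi_y
    d = num / (2.0 * n_x * n_y)
    if d < 0:
        return 0.0, True
    return float(d), False


def dxy_regions(
    gm: GenotypeMatrix,
    rows_x: np.ndarray,
    rows_y: np.ndarray,
    regions: pd.DataFrame,
    effective_length: float = 120.0,
) -> np.ndarray:
    """Region d_XY between two homokaryotype groups, built per SNP from
    the mixture identity with haplotype counts and averaged over the
    effective region length."""
    rows_x, rows_y = np.asarray(rows_x), np.asarray(rows_y)
    Gx, Gy = gm.calls[rows_x], gm.calls[rows_y]
    Gt = np.vstack([Gx, Gy])
    lengths = (
        regions["effective_length"].to_numpy(dtype=float)
        if "effective_length" in regions.columns
        else np.full(len(regions), effective_length)
    )
    # per-site d_xy directly from allele frequencies of each group:
    # mean difference between one haplotype from each pool
    site_d = _site_dxy(Gx, Gy)
    out = np.empty(len(regions))
    for i, cols in enumerate(_region_columns(gm, regions)):
        out[i] = np.nansum(site_d[cols]) / lengths[i]
    return out


def _site_dxy(Gx: np.ndarray, Gy: np.ndarray) -> np.ndarray:
    nx = 2.0 * (Gx != MISSING).sum(axis=0)
    ny = 2.0 * (Gy != MISSING).sum(axis=0)
    ax = np.where(Gx != MISSING, Gx, 0).sum(axis=0)
    ay = np.where(Gy != MISSING, Gy, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        px, py = ax / nx, ay / ny
        d = px * (1 - py) + py * (1 - px)
        return np.where((nx > 0) & (ny > 0), d, np.nan)


@dataclass
class TestResult:
    comparison: str
    statistic: float  # rank-sum W of the first sample
    p_value: float
    p_adjusted: float = np.nan
    significant: bool = False


def compare_groups(
    comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> list[TestResult]:
    """Two-sided Wilcoxon rank-sum test per comparison with Holm
    (sequential Bonferroni) adjustment across the declared family.

    Each comparison maps a name to two vectors of per-SNP or per-region
    statistics; NaNs are dropped.  The exact null distribution is used
    for small samples without ties.
    """
    results: list[TestResult] = []
    for name, (x, y) in comparisons.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"comparison {name!r}: each vector needs >= 2 values")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        # rank-sum statistic W for the first sample = U1 + n1(n1+1)/2
        W = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
        results.append(TestResult(comparison=name, statistic=W, p_value=float(res.pvalue)))
    if results:
        reject, p_adj, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="holm"
        )
        for r, pa, rej in zip(results, p_adj, reject):
            r.p_adjusted = float(pa)
            r.significant = bool(rej)
    return results
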