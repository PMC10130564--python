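"""Genomic relationships (Yang estimator), LD pruning, PCA and Welch's t.

The relationship matrix uses Yang's estimator as implemented by PLINK
``--make-rel``: off-diagonal entries are per-site standardized
cross-products ``(x_i - 2p)(x_j - 2p)/(2p(1-p))`` averaged over sites where
both samples are genotyped, and the diagonal uses Yang's distinct estimator
``1 + (x^2 - (1+2p)x + 2p^2)/(2p(1-p))`` whose population-level expectation
is ``1 + F``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .diversity import _dosage_float, _pairwise_r2


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.15,
    window: int = 50_000,
    step: int = 10_000,
    unit: str = "bp",
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of surviving sites.

    Within each window (``unit="bp"``: physical span; ``unit="snp"``: site
    count), pairs with r^2 > ``r2_max`` are broken by removing the
    lower-MAF site (ties: the right-hand site), then the window advances by
    ``step``. The surviving set has no intra-window pair above threshold.
    """
    if not (0 <= r2_max <= 1):
        raise ValueError("r2_max must be in [0, 1]")
    freq = gm.allele_frequencies()
    maf = np.fmin(freq, 1 - freq)
    removed = np.zeros(gm.n_sites, bool)
    d = _dosage_float(gm)
    d = np.where(np.isnan(d), np.nanmean(d, axis=0, keepdims=True), d)
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        sidx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(sidx)
        if unit == "bp":
            starts = range(0, int(pos.max()), step)
            windows = (
                np.arange(*np.searchsorted(pos, [s + 1, s + window + 1]))
                for s in starts
            )
        elif unit == "snp":
            windows = (np.arange(s, min(s + window, n)) for s in range(0, n, step))
        else:
            raise ValueError('unit must be "bp" or "snp"')
        for local in windows:
            local = local[~removed[sidx[local]]]
            if len(local) < 2:
                continue
            block = d[:, sidx[local]]
            blockc = block - block.mean(axis=0)
            norms = np.sqrt((blockc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (blockc.T @ blockc) / np.outer(norms, norms)
            r2 = r * r
            r2 = np.where(np.isfinite(r2), r2, 0.0)
            np.fill_diagonal(r2, 0.0)
            alive = np.ones(len(local), bool)
            while True:
                masked = np.where(np.outer(alive, alive), r2, 0.0)
                i, j = np.unravel_index(np.nanargmax(masked), masked.shape)
                if not masked[i, j] > r2_max:
                    break
                mi, mj = maf[sidx[local[i]]], maf[sidx[local[j]]]
                drop = i if (mi < mj) else (j if mj < mi else max(i, j))
                alive[drop] = False
            removed[sidx[local[~alive]]] = True
    return np.flatnonzero(~removed)


def _standardized(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed standardized genotypes and the polymorphic-site mask."""
    p = gm.allele_frequencies()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    d = _dosage_float(gm)[:, poly]
    pp = p[poly]
    d = np.where(np.isnan(d), 2 * pp[None, :], d)
    z = (d - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    return z, poly


def grm(gm: GenotypeMatrix) -> pd.DataFrame:
    """Yang genomic relationship matrix (samples x samples DataFrame).

    Monomorphic sites are excluded; entries are pairwise-complete averages
    over sites where both samples are genotyped.
    """
    p = gm.allele_frequencies()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    x = _dosage_float(gm)[:, poly]
    pp = p[poly]
    denom = 2 * pp * (1 - pp)
    obs = ~np.isnan(x)
    zc = np.where(obs, (x - 2 * pp) / np.sqrt(denom), 0.0)
    num = zc @ zc.T
    cnt = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = num / cnt
    diag_terms = (x**2 - (1 + 2 * pp) * x + 2 * pp**2) / denom
    rel[np.diag_indices_from(rel)] = 1.0 + np.nanmean(diag_terms, axis=1)
    return pd.DataFrame(rel, index=gm.samples, columns=gm.samples)


def pca(gm: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of standardized genotypes (centered by 2p, scaled by
    sqrt(2p(1-p)), missing mean-imputed).

    Returns per-sample coordinates and the explained-variance proportions
    (non-increasing, summing to <= 1).
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    z, _ = _standardized(gm)
    z = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    evr = (s**2 / (s**2).sum())[:k]
    df = pd.DataFrame(coords, index=gm.samples, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "population", [gm.populations[s_] for s_ in gm.samples])
    return df, evr


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: ``(t, df, p_two_sided)``.

    The Welch-Satterthwaite degrees of freedom are returned alongside the
    scipy test statistic and two-sided p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    sem2 = vx / len(x) + vy / len(y)
    df = sem2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)
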