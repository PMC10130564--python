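"""Heterozygosity, LD decay and LD-based historical effective population size.

LD is computed on genotype dosages (squared Pearson correlation), matching
the default input regime of popLDdecay-style tools; the historical Ne
inversion follows the Sved expectation ``E[r^2_adj] = 1/(alpha + 4 N c)``
with a ``1/(2n)`` sample-size correction, a constant cM/Mb map and Haldane
distance scaling (all configurable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def observed_heterozygosity(gm: GenotypeMatrix, per: str = "individual") -> pd.DataFrame:
    """Fraction of non-missing sites with a heterozygous call.

    ``per="individual"`` returns one row per sample; ``per="population"``
    averages the per-individual values over population members.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    het = (gm.dosages == 1).sum(axis=1)
    obs = (gm.dosages != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        h = np.where(obs > 0, het / obs, np.nan)
    table = pd.DataFrame(
        {
            "sample": gm.samples,
            "population": [gm.populations[s] for s in gm.samples],
            "het_obs": h,
        }
    )
    if per == "individual":
        return table
    if per == "population":
        return table.groupby("population", sort=False, as_index=False)["het_obs"].mean()
    raise ValueError('per must be "individual" or "population"')


def _dosage_float(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    d = gm.dosages if sample_idx is None else gm.dosages[sample_idx]
    out = d.astype(float)
    out[d == MISSING] = np.nan
    return out


def ld_r2_pair(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of dosages over samples non-missing at
    both sites; NaN when either site is monomorphic in that subset."""
    x = _dosage_float(gm)[:, [site_i, site_j]]
    ok = ~np.isnan(x).any(axis=1)
    x = x[ok]
    if len(x) < 2 or x[:, 0].std() == 0 or x[:, 1].std() == 0:
        return float("nan")
    r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
    return float(r * r)


def _pairwise_r2(d: np.ndarray, i: int, j_slice: slice) -> np.ndarray:
    """r^2 between column i and a block of columns (no missing data path)."""
    x = d[:, i]
    y = d[:, j_slice]
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return r * r


def ld_decay(
    gm: GenotypeMatrix,
    population: str,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
    sample_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean r^2 of all intra-chromosomal site pairs within ``max_dist``,
    binned by physical distance.

    ``sample_idx`` restricts the panel to an arbitrary caller-supplied
    subset (e.g. one sex) instead of the population's members.

    Returns a DataFrame with columns ``bin_lo, bin_hi, mean_r2, n_pairs``;
    monomorphic-pair r^2 values are excluded from the bins.
    """
    idx = gm.sample_indices(population) if sample_idx is None else np.asarray(sample_idx)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    has_missing = (gm.dosages[idx] == MISSING).any()
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        sidx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        d = _dosage_float(gm, idx)[:, sidx]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for a in range(len(pos) - 1):
            b = hi[a]
            if b <= a + 1:
                continue
            if has_missing:
                r2 = np.array(
                    [ld_r2_pair(gm, sidx[a], sidx[j]) for j in range(a + 1, b)]
                )
            else:
                r2 = _pairwise_r2(d, a, slice(a + 1, b))
            dist = pos[a + 1:b] - pos[a]
            which = np.minimum((dist - 1) // bin_width, n_bins - 1)
            ok = ~np.isnan(r2)
            np.add.at(sums, which[ok], r2[ok])
            np.add.at(counts, which[ok], 1)
    lo = np.arange(n_bins) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": lo,
            "bin_hi": np.minimum(lo + bin_width, max_dist),
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def estimate_ne_history(
    curve: pd.DataFrame,
    n_samples: int,
    alpha: float = 1.0,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Invert an LD-decay curve into a historical Ne trajectory.

    For each distance bin: midpoint bp -> Morgans at ``cm_per_mb`` ->
    Haldane recombination fraction ``c = (1 - exp(-2m))/2``; the sample-size
    corrected ``r2_adj = mean_r2 - 1/(2 n_samples)`` is inverted through the
    Sved expectation to ``Ne = (1/r2_adj - alpha)/(4c)``, dated at
    ``t = 1/(2c)`` generations ago. Bins with non-positive ``r2_adj`` or
    ``Ne`` are dropped with a warning.
    """
    rows = []
    for _, bin_ in curve.iterrows():
        if bin_["n_pairs"] <= 0 or not np.isfinite(bin_["mean_r2"]):
            continue
        mid = 0.5 * (bin_["bin_lo"] + bin_["bin_hi"])
        morgans = mid * cm_per_mb * 1e-8
        c = 0.5 * (1.0 - np.exp(-2.0 * morgans))
        if c <= 0:
            continue
        r2_adj = bin_["mean_r2"] - 1.0 / (2.0 * n_samples)
        if r2_adj <= 0:
            logger.warning("estimate_ne_history: dropped bin at %.0f bp (r2_adj <= 0)", mid)
            continue
        ne = (1.0 / r2_adj - alpha) / (4.0 * c)
        if ne <= 0:
            logger.warning("estimate_ne_history: dropped bin at %.0f bp (Ne <= 0)", mid)
            continue
        rows.append((1.0 / (2.0 * c), ne, int(bin_["n_pairs"])))
    return pd.DataFrame(rows, columns=["generations_ago", "ne", "n_pairs"])
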