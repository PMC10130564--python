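"""Selection-signature scan: Weir-Cockerham FST, XP-EHH and the DCMS composite.

Two complementary per-site statistics are averaged over 50 kb sliding
windows with 25 kb overlap:

* the Weir & Cockerham (1984) variance-component estimator of FST
  (``theta = a / (a + b + c)`` from among-population, among-individual and
  within-individual components), and
* cross-population extended haplotype homozygosity: the log-ratio of the
  integrated EHH curves of two phased panels, standardized genome-wide,
  with two-sided normal p-values whose -log10 is window-averaged.

Windows holding at least 30 SNPs receive per-statistic empirical
right-tail p-values, combined by the de-correlated composite of multiple
signals:

    DCMS_w = sum_t log((1 - p_wt) / p_wt) / sum_i |r_it|

where ``r`` is the correlation matrix of the statistics across windows.
Windows above the 99.5% empirical quantile of each statistic are candidate
sweep windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm, rankdata

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------

def wc_fst_components(
    gm: GenotypeMatrix, pops: tuple[str, str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two
    populations, from per-site sample sizes, allele frequencies and
    observed heterozygosity (missing genotypes drop out per site)."""
    labels = pops or tuple(gm.population_labels)
    if len(labels) != 2:
        raise ValueError("exactly two populations required")
    r = 2.0
    n_is, p_is, h_is = [], [], []
    for lab in labels:
        d = gm.dosages[gm.sample_indices(lab)]
        obs = d != MISSING
        n_i = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_i)
            h_i = np.where(obs & (d == 1), 1, 0).sum(axis=0) / n_i
        n_is.append(n_i); p_is.append(p_i); h_is.append(h_i)
    n1, n2 = n_is
    p1, p2 = p_is
    h1, h2 = h_is
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c


def wc_fst_sites(gm: GenotypeMatrix, pops: tuple[str, str] | None = None) -> np.ndarray:
    """Per-site theta = a/(a+b+c); NaN where the denominator is zero."""
    a, b, c = wc_fst_components(gm, pops)
    den = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, a / den, np.nan)


def wc_fst_site(gm: GenotypeMatrix, pops: tuple[str, str], site: int) -> float:
    """Theta at a single site (NaN when undefined)."""
    return float(wc_fst_sites(gm.take_sites(np.array([site])), pops)[0])


def global_fst(gm: GenotypeMatrix, pops: tuple[str, str] | None = None) -> float:
    """Multi-locus Weir-Cockerham estimator: summed components over sites,
    ``sum(a) / sum(a + b + c)`` — the genome-wide fixation index."""
    a, b, c = wc_fst_components(gm, pops)
    den = a + b + c
    ok = np.isfinite(den) & (den != 0) & np.isfinite(a)
    return float(a[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------
# windowed means
# ---------------------------------------------------------------------

def windowed_mean(
    positions: np.ndarray,
    values: np.ndarray,
    window: int = 50_000,
    step: int = 25_000,
    min_snps: int = 1,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Sliding-window arithmetic means on one chromosome.

    Windows ``[start, start + window)`` (0-based) start every ``step`` bp
    from 0 while ``start < chrom_length`` (default: last SNP position).
    ``n_snps`` counts sites in the window; the mean ignores NaN values and
    is NaN when fewer than ``min_snps`` sites fall in the window.
    """
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    values = np.asarray(values, float)
    pos0 = positions - 1  # 1-based -> 0-based
    length = chrom_length if chrom_length is not None else (int(pos0.max()) + 1 if len(pos0) else 0)
    starts = np.arange(0, max(length, 1), step)
    lo = np.searchsorted(pos0, starts)
    hi = np.searchsorted(pos0, starts + window)
    finite = np.isfinite(values)
    vsum = np.concatenate([[0.0], np.cumsum(np.where(finite, values, 0.0))])
    vcnt = np.concatenate([[0], np.cumsum(finite)])
    n_all = hi - lo
    n_fin = vcnt[hi] - vcnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_fin > 0, (vsum[hi] - vsum[lo]) / np.maximum(n_fin, 1), np.nan)
    mean = np.where(n_all >= min_snps, mean, np.nan)
    return pd.DataFrame(
        {"start": starts, "end": starts + window, "n_snps": n_all,
         "n_finite": n_fin, "mean": mean}
    )


# ---------------------------------------------------------------------
# EHH / iES / XP-EHH
# ---------------------------------------------------------------------

@njit(cache=True)
def _ehh_side(H, pos, core, step, min_ehh, max_gap):  # pragma: no cover - jitted
    """EHH values scanning from ``core`` in ``step`` direction.

    Records each flanking site's EHH (including the first value below
    ``min_ehh``, after which the scan stops); stops at gaps > ``max_gap``.
    Returns (positions, ehh) arrays.
    """
    n_hap, n_sites = H.shape
    denom = n_hap * (n_hap - 1) / 2.0
    out_pos = np.empty(n_sites, np.int64)
    out_ehh = np.empty(n_sites, np.float64)
    ids = np.zeros(n_hap, np.int64)
    key = np.zeros(n_hap, np.int64)
    m = 0
    prev = core
    j = core + step
    while 0 <= j < n_sites:
        if abs(pos[j] - pos[prev]) > max_gap:
            break
        for h in range(n_hap):
            key[h] = ids[h] * 2 + H[h, j]
        order = np.argsort(key, kind="mergesort")
        same = 0.0
        rank = 0
        cnt = 1
        ids[order[0]] = 0
        for t in range(1, n_hap):
            if key[order[t]] == key[order[t - 1]]:
                cnt += 1
            else:
                same += cnt * (cnt - 1) / 2.0
                cnt = 1
                rank += 1
            ids[order[t]] = rank
        same += cnt * (cnt - 1) / 2.0
        ehh_val = same / denom
        out_pos[m] = pos[j]
        out_ehh[m] = ehh_val
        m += 1
        if ehh_val < min_ehh or ehh_val == 0.0:
            break
        prev = j
        j += step
    return out_pos[:m], out_ehh[:m]


@njit(cache=True)
def _ies_all(H, pos, min_ehh, max_gap):  # pragma: no cover - jitted
    """Integrated EHH (both directions, trapezoid over bp) per core site."""
    n_hap, n_sites = H.shape
    out = np.zeros(n_sites, np.float64)
    for core in range(n_sites):
        total = 0.0
        for step in (-1, 1):
            p_arr, e_arr = _ehh_side(H, pos, core, step, min_ehh, max_gap)
            prev_e = 1.0
            prev_p = pos[core]
            for k in range(len(e_arr)):
                total += (prev_e + e_arr[k]) / 2.0 * abs(p_arr[k] - prev_p)
                prev_e = e_arr[k]
                prev_p = p_arr[k]
        out[core] = total
    return out


@dataclass
class EHHCurve:
    """EHH decay curve around a core site (both directions; EHH at the
    core is 1 by definition and values are non-increasing outward)."""

    core_pos: int
    left: pd.DataFrame  # columns pos, ehh; outward order
    right: pd.DataFrame


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
) -> EHHCurve:
    """Extended haplotype homozygosity around ``core_site``.

    EHH at distance x is the probability that two random haplotypes from
    the panel are identical at every site from the core out to x:
    ``sum_h C(n_h, 2) / C(n, 2)`` over identity classes h. The curve is
    truncated once EHH falls below ``min_ehh`` (that point is kept) or an
    adjacent-site gap exceeds ``max_gap``.
    """
    H = np.ascontiguousarray(haplotypes, dtype=np.int8)
    pos = np.ascontiguousarray(positions, dtype=np.int64)
    if H.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    lp, le = _ehh_side(H, pos, core_site, -1, min_ehh, max_gap)
    rp, re_ = _ehh_side(H, pos, core_site, 1, min_ehh, max_gap)
    return EHHCurve(
        core_pos=int(pos[core_site]),
        left=pd.DataFrame({"pos": lp, "ehh": le}),
        right=pd.DataFrame({"pos": rp, "ehh": re_}),
    )


def ies(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
) -> float:
    """Trapezoidal integral of the EHH curve over physical distance, both
    directions summed; 0 (with a warning) when the curve truncates
    immediately on both sides."""
    curve = ehh(haplotypes, positions, core_site, min_ehh, max_gap)
    total = 0.0
    for side in (curve.left, curve.right):
        prev_e, prev_p = 1.0, curve.core_pos
        for p, e in side.itertuples(index=False):
            total += (prev_e + e) / 2.0 * abs(int(p) - prev_p)
            prev_e, prev_p = e, int(p)
    if total == 0.0:
        logger.warning("ies: EHH truncated immediately on both sides of core %d", core_site)
    return total


def _phased_panel(gm: GenotypeMatrix, population: str, site_idx: np.ndarray) -> np.ndarray:
    if gm.haplotypes is None:
        raise ValueError("XP-EHH requires phased haplotypes")
    if gm.phased_sites is not None and not gm.phased_sites[site_idx].all():
        raise ValueError("XP-EHH requires every analysed site to be phased")
    return np.ascontiguousarray(gm.haplotypes[np.ix_(gm.haplotype_indices(population), site_idx)], np.int8)


def xpehh(
    panel_a: np.ndarray,
    panel_b: np.ndarray,
    positions: np.ndarray,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-site XP-EHH between two phased panels on one chromosome.

    raw = ln(iES_a / iES_b); the standardized score subtracts the mean and
    divides by the SD of raw over the analysed sites, and the p-value is
    the two-sided standard-normal tail. Sites where either panel's iES is
    zero are dropped.
    """
    pos = np.ascontiguousarray(positions, np.int64)
    ia = _ies_all(np.ascontiguousarray(panel_a, np.int8), pos, min_ehh, max_gap)
    ib = _ies_all(np.ascontiguousarray(panel_b, np.int8), pos, min_ehh, max_gap)
    ok = (ia > 0) & (ib > 0)
    out = pd.DataFrame({"pos": pos[ok], "raw": np.log(ia[ok] / ib[ok])})
    if standardize:
        out = standardize_xpehh(out)
    return out


def standardize_xpehh(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Attach genome-wide standardized scores and two-sided p-values."""
    raw = raw_table["raw"].to_numpy()
    sd = raw.std()
    if sd == 0:
        raise ValueError("XP-EHH raw scores are constant; cannot standardize")
    std = (raw - raw.mean()) / sd
    p = 2.0 * norm.sf(np.abs(std))
    out = raw_table.copy()
    out["std"] = std
    out["p"] = p
    out["neglog10p"] = -np.log10(np.clip(p, 1e-300, None))
    return out


def xpehh_scan(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
) -> pd.DataFrame:
    """Genome-wide XP-EHH: raw scores per chromosome, standardization and
    p-values over all analysed sites jointly."""
    frames = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        sidx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        pa = _phased_panel(gm, pop_a, sidx)
        pb = _phased_panel(gm, pop_b, sidx)
        tab = xpehh(pa, pb, pos, min_ehh, max_gap, standardize=False)
        tab.insert(0, "chrom", chrom)
        frames.append(tab)
    raw = pd.concat(frames, ignore_index=True)
    return standardize_xpehh(raw)


# ---------------------------------------------------------------------
# empirical p-values, DCMS, hit calling
# ---------------------------------------------------------------------

def empirical_right_tail_p(values: np.ndarray) -> np.ndarray:
    """Empirical right-tail p: ``p_i = (1 + #{j != i : v_j >= v_i}) / (N+1)``.

    Never exactly 0 or 1; the sample maximum of N=999 values gets 1/1000.
    """
    v = np.asarray(values, float)
    if len(v) < 2 or not np.isfinite(v).all():
        raise ValueError("need >= 2 finite values")
    order = np.sort(v)
    n_ge_incl_self = len(v) - np.searchsorted(order, v, side="left")
    return (n_ge_incl_self) / (len(v) + 1.0)


def dcms(
    window_stats: pd.DataFrame,
    stat_p_pairs: list[tuple[str, str]],
    correlation: str = "pearson",
    p_clip: float = 1e-10,
) -> np.ndarray:
    """De-correlated composite of multiple signals per window.

    For each statistic t (a ``(stat_column, p_column)`` pair), the logit
    score ``ln((1 - p_wt)/p_wt)`` is divided by ``sum_i |r_it|``, the
    summed absolute correlation (Pearson by default, Spearman optional) of
    statistic t with every statistic across the supplied windows; DCMS is
    the sum over statistics. p-values are clipped to
    ``[p_clip, 1 - p_clip]``. Windows failing eligibility (e.g. < 30 SNPs)
    must be excluded by the caller before this computation.
    """
    if not stat_p_pairs:
        raise ValueError("at least one statistic required")
    stat_cols = [s for s, _ in stat_p_pairs]
    X = window_stats[stat_cols].to_numpy(float)
    for col, x in zip(stat_cols, X.T):
        if np.nanstd(x) == 0:
            raise ValueError(f"statistic column {col!r} is constant; correlation undefined")
    if correlation == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    elif correlation != "pearson":
        raise ValueError('correlation must be "pearson" or "spearman"')
    R = np.corrcoef(X, rowvar=False).reshape(len(stat_cols), len(stat_cols))
    weights = np.abs(R).sum(axis=0)
    out = np.zeros(len(window_stats))
    for t, (_, p_col) in enumerate(stat_p_pairs):
        p = np.clip(window_stats[p_col].to_numpy(float), p_clip, 1 - p_clip)
        out += np.log((1 - p) / p) / weights[t]
    return out


def call_hits(values: np.ndarray, quantile: float = 0.995) -> tuple[float, np.ndarray]:
    """Empirical-quantile cutoff (linear interpolation) and the flag mask
    ``value >= cutoff`` (ties at the cutoff are all included)."""
    v = np.asarray(values, float)
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    if len(v) < 1.0 / (1.0 - quantile):
        logger.warning(
            "call_hits: only %d values for quantile %.4f; cutoff is unstable",
            len(v), quantile,
        )
    cutoff = float(np.quantile(v, quantile))
    hits = v >= cutoff
    if hits.all():
        logger.warning("call_hits: all %d values flagged (degenerate distribution)", len(v))
    return cutoff, hits


def intersect_hits(hit_sets: dict[str, set]) -> pd.DataFrame:
    """Exact set intersections of named window sets keyed by
    (chrom, start, end): for every non-empty combination of names reports
    the plain intersection size and the Venn-exclusive count."""
    names = list(hit_sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(hit_sets[n] for n in combo))
            others = set().union(*(hit_sets[n] for n in names if n not in combo)) if k < len(names) else set()
            rows.append(("&".join(combo), len(inter), len(inter - others)))
    return pd.DataFrame(rows, columns=["sets", "n_intersection", "n_exclusive"])


# ---------------------------------------------------------------------
# full scan driver
# ---------------------------------------------------------------------

def selection_scan(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    window: int = 50_000,
    step: int = 25_000,
    min_snps_dcms: int = 30,
    quantile: float = 0.995,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
    correlation: str = "pearson",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Windowed FST + XP-EHH + DCMS scan.

    Returns the per-window table (chrom, start, end, n_snps, fst_mean,
    fst_ratio_of_sums, xpehh_neglogp_mean, p_fst, p_xpehh, dcms and hit
    flags at the requested quantile) and the three cutoffs. Empirical
    p-values, DCMS and hit calling operate on the windows holding at least
    ``min_snps_dcms`` SNPs with both statistics defined.
    """
    theta = wc_fst_sites(gm, (pop_a, pop_b))
    a_comp, b_comp, c_comp = wc_fst_components(gm, (pop_a, pop_b))
    den = a_comp + b_comp + c_comp
    xp = xpehh_scan(gm, pop_a, pop_b, min_ehh, max_gap)

    frames = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        sidx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length = (gm.chrom_lengths or {}).get(chrom)
        win_theta = windowed_mean(pos, theta[sidx], window, step, 1, length)
        win_a = windowed_mean(pos, a_comp[sidx], window, step, 1, length)
        win_den = windowed_mean(pos, den[sidx], window, step, 1, length)
        xp_chrom = xp[xp["chrom"] == chrom]
        win_xp = windowed_mean(
            xp_chrom["pos"].to_numpy(),
            xp_chrom["neglog10p"].to_numpy(),
            window, step, 1, length,
        )
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": win_theta["start"],
                "end": win_theta["end"],
                "n_snps": win_theta["n_snps"],
                "fst_mean": win_theta["mean"],
            }
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            df["fst_ratio_of_sums"] = (
                win_a["mean"] * win_a["n_finite"]
            ) / (win_den["mean"] * win_den["n_finite"])
        n = min(len(df), len(win_xp))
        df = df.iloc[:n].copy()
        df["xpehh_neglogp_mean"] = win_xp["mean"].to_numpy()[:n]
        frames.append(df)
    windows = pd.concat(frames, ignore_index=True)

    eligible = (
        (windows["n_snps"] >= min_snps_dcms)
        & windows["fst_mean"].notna()
        & windows["xpehh_neglogp_mean"].notna()
    )
    windows["eligible"] = eligible
    sub = windows[eligible]
    windows["p_fst"] = np.nan
    windows["p_xpehh"] = np.nan
    windows.loc[eligible, "p_fst"] = empirical_right_tail_p(sub["fst_mean"].to_numpy())
    windows.loc[eligible, "p_xpehh"] = empirical_right_tail_p(
        sub["xpehh_neglogp_mean"].to_numpy()
    )
    windows["dcms"] = np.nan
    windows.loc[eligible, "dcms"] = dcms(
        windows[eligible],
        [("fst_mean", "p_fst"), ("xpehh_neglogp_mean", "p_xpehh")],
        correlation=correlation,
    )

    cutoffs: dict[str, float] = {}
    for stat, col in [("fst", "fst_mean"), ("xpehh", "xpehh_neglogp_mean"), ("dcms", "dcms")]:
        windows[f"hit_{stat}"] = False
        vals = windows.loc[eligible, col].to_numpy()
        cut, mask = call_hits(vals, quantile)
        cutoffs[stat] = cut
        windows.loc[eligible, f"hit_{stat}"] = mask
    return windows, cutoffs
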