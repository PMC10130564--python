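"""Sliding-window detection of runs of homozygosity and F_ROH.

The detector mirrors the detectRUNS-style sliding-window scan: a window of
``window_snps`` consecutive SNPs slides one SNP at a time along each
chromosome of each individual; a window is *homozygous* when its count of
heterozygous (and, by default, missing) genotypes does not exceed
``max_opposite_per_window`` and it spans no adjacent-SNP gap larger than
``max_gap_bp``. A SNP belongs to a run when at least
``min_window_hit_fraction`` of the windows covering it are homozygous;
maximal such stretches are reported when they are at least
``min_length_bp`` long and contain at least ``min_snps_in_run`` SNPs.

The genomic inbreeding coefficient is the summed physical length of an
individual's runs divided by the genome length:
``F_ROH = sum(L_ROH) / L_genome``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, total_genome_length

logger = logging.getLogger(__name__)

#: (label, lower bound Mb inclusive, upper bound Mb exclusive) — the first
#: class starts at the 1 Mb minimum-length default but keeps the
#: conventional "0-2 Mb" label.
LENGTH_CLASSES = [
    ("0-2 Mb", 1.0, 2.0),
    ("2-4 Mb", 2.0, 4.0),
    ("4-8 Mb", 4.0, 8.0),
    ("8-16 Mb", 8.0, 16.0),
]
OVERFLOW_CLASS = ">16 Mb"


@dataclass
class RohParams:
    """Sliding-window ROH parameters (defaults are the scan settings for
    dense whole-genome data: 2500-SNP windows, 10 kb max gap, 1 Mb minimum
    length, 150 opposite genotypes per window ~ 6% of the window)."""

    window_snps: int = 2500
    max_gap_bp: int = 10_000
    min_length_bp: int = 1_000_000
    max_opposite_per_window: int = 150
    min_snps_in_run: int | None = None  # None -> window_snps
    min_window_hit_fraction: float = 0.05
    missing_as_opposite: bool = True

    def __post_init__(self) -> None:
        if min(self.window_snps, self.max_gap_bp, self.min_length_bp) <= 0:
            raise ValueError("window_snps, max_gap_bp, min_length_bp must be positive")
        if not (0 <= self.max_opposite_per_window <= self.window_snps):
            raise ValueError("max_opposite_per_window must be in [0, window_snps]")
        if not (0 < self.min_window_hit_fraction <= 1):
            raise ValueError("min_window_hit_fraction must be in (0, 1]")

    @property
    def min_snps(self) -> int:
        return self.window_snps if self.min_snps_in_run is None else self.min_snps_in_run


def _runs_one(
    opp: np.ndarray, pos: np.ndarray, params: RohParams
) -> list[tuple[int, int, int]]:
    """Runs for one individual/chromosome: (start_pos, end_pos, n_snps)."""
    n = len(pos)
    w = params.window_snps
    n_win = n - w + 1
    cs = np.concatenate([[0], np.cumsum(opp)])
    opp_count = cs[w:] - cs[:-w]
    gap_bad = (np.diff(pos) > params.max_gap_bp).astype(np.int64)
    gs = np.concatenate([[0], np.cumsum(gap_bad)])
    bad_in_win = gs[w - 1:] - gs[: n_win]  # gaps between SNPs w..w+W-2
    win_ok = (opp_count <= params.max_opposite_per_window) & (bad_in_win == 0)
    # per-SNP: windows covering SNP i are w in [max(0, i-w+1), min(i, n_win-1)]
    ok_cs = np.concatenate([[0], np.cumsum(win_ok)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    ok_count = ok_cs[hi + 1] - ok_cs[lo]
    frac = ok_count / (hi - lo + 1)
    in_run = frac >= params.min_window_hit_fraction

    runs = []
    boundaries = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
    for a, b in boundaries.reshape(-1, 2):
        start, end, n_snps = int(pos[a]), int(pos[b - 1]), b - a
        if end - start >= params.min_length_bp and n_snps >= params.min_snps:
            runs.append((start, end, n_snps))
    return runs


def detect_roh(gm: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    """Detect runs of homozygosity for every individual.

    Returns a DataFrame with columns ``individual, population, chrom,
    start, end, length, n_snps`` (start/end are the 1-based positions of
    the first/last SNP of the run; length = end - start). Chromosomes with
    fewer SNPs than the window are skipped with a warning.
    """
    params = params or RohParams()
    rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        sidx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if len(pos) < params.window_snps:
            logger.warning(
                "detect_roh: chromosome %s has %d SNPs < window of %d; skipped",
                chrom, len(pos), params.window_snps,
            )
            continue
        d = gm.dosages[:, sidx]
        het = d == 1
        if params.missing_as_opposite:
            opp_all = het | (d == MISSING)
        else:
            opp_all = het
        for i, sample in enumerate(gm.samples):
            for start, end, n_snps in _runs_one(opp_all[i], pos, params):
                rows.append(
                    (sample, gm.populations[sample], chrom, start, end, end - start, n_snps)
                )
    return pd.DataFrame(
        rows,
        columns=["individual", "population", "chrom", "start", "end", "length", "n_snps"],
    )


def classify_roh(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-population, per-length-class run counts and mean lengths (Mb).

    Classes are [1,2), [2,4), [4,8), [8,16) Mb; segments of >= 16 Mb are
    flagged into an overflow class with a warning. Empty input yields an
    all-zero table.
    """
    labels = [c[0] for c in LENGTH_CLASSES]
    pops = sorted(segments["population"].unique()) if len(segments) else []
    if len(segments):
        length_mb = segments["length"] / 1e6
        edges = [c[1] for c in LENGTH_CLASSES] + [LENGTH_CLASSES[-1][2]]
        cls = pd.cut(length_mb, bins=edges, right=False, labels=labels)
        overflow = length_mb >= LENGTH_CLASSES[-1][2]
        if overflow.any():
            logger.warning("classify_roh: %d segments exceed 16 Mb", int(overflow.sum()))
        cls = cls.cat.add_categories([OVERFLOW_CLASS])
        cls[overflow] = OVERFLOW_CLASS
        seg = segments.assign(length_class=cls, length_mb=length_mb)
    rows = []
    all_labels = labels + ([OVERFLOW_CLASS] if len(segments) and overflow.any() else [])
    for label in all_labels:
        for pop in pops:
            sub = seg[(seg["length_class"] == label) & (seg["population"] == pop)]
            rows.append((label, pop, len(sub), sub["length_mb"].mean() if len(sub) else 0.0))
    if not rows:
        rows = [(label, None, 0, 0.0) for label in labels]
    return pd.DataFrame(rows, columns=["length_class", "population", "count", "mean_length_mb"])


def froh(segments: pd.DataFrame, genome_length_bp: int) -> float:
    """F_ROH of one individual: summed run length over genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if len(segments) == 0:
        return 0.0
    keys = ["individual", "chrom"] if "individual" in segments.columns else ["chrom"]
    for key, grp in segments.groupby(keys):
        iv = grp.sort_values("start")[["start", "end"]].to_numpy()
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError(f"overlapping segments for {key}")
    return float(segments["length"].sum() / genome_length_bp)


def froh_table(
    segments: pd.DataFrame, gm: GenotypeMatrix, genome_length_bp: int | None = None
) -> pd.DataFrame:
    """Per-individual F_ROH for every sample in the matrix (individuals with
    no detected runs get 0). Genome length defaults to the summed contig
    lengths of the analysed chromosomes."""
    L = genome_length_bp if genome_length_bp is not None else total_genome_length(gm)
    by_ind = dict(tuple(segments.groupby("individual"))) if len(segments) else {}
    rows = [
        (
            s,
            gm.populations[s],
            froh(by_ind[s], L) if s in by_ind else 0.0,
        )
        for s in gm.samples
    ]
    return pd.DataFrame(rows, columns=["individual", "population", "froh"])
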