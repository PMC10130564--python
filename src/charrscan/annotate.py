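"""Sweep-region construction, gene intersection, enrichment and Jaccard.

Candidate windows are merged when they share at least a configurable
fraction of overlap (default 50%, so two 50 kb windows offset by 25 kb
collapse into one 75 kb region), extended by 10 kb on either side (clipped
at chromosome bounds) and intersected with GFF3 gene features using the
>= 1 bp overlap rule. Enrichment of the genes hit is a generic
hypergeometric test against a user-supplied term -> gene map, and term
similarity is the Jaccard index |A n B| / |A u B| of the enriched sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


# ---------------------------------------------------------------------
# region merging / extension
# ---------------------------------------------------------------------

def merge_extend(
    windows: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    extend: int = 10_000,
    merge_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Merge overlapping candidate windows and extend the result.

    Windows (0-based half-open ``chrom, start, end``) are unioned whenever
    their overlap is at least ``merge_overlap_fraction`` of the shorter
    interval; merging is run to closure so the output is independent of
    input order. Merged regions are then extended by ``extend`` bp on each
    side and clipped to ``[0, chrom_length]``.
    """
    if not (0 < merge_overlap_fraction <= 1):
        raise ValueError("merge_overlap_fraction must be in (0, 1]")
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        iv = sorted(map(tuple, grp[["start", "end"]].to_numpy()))
        merged: list[list[int]] = []
        for s, e in iv:
            if merged:
                ps, pe = merged[-1]
                overlap = min(pe, e) - max(ps, s)
                if overlap >= merge_overlap_fraction * min(pe - ps, e - s):
                    merged[-1][1] = max(pe, e)
                    continue
            merged.append([s, e])
        # run to closure: growing a region can create new qualifying overlaps
        changed = True
        while changed:
            changed = False
            out: list[list[int]] = []
            for s, e in merged:
                if out:
                    ps, pe = out[-1]
                    overlap = min(pe, e) - max(ps, s)
                    if overlap >= merge_overlap_fraction * min(pe - ps, e - s):
                        out[-1][1] = max(pe, e)
                        changed = True
                        continue
                out.append([s, e])
            merged = out
        length = (chrom_lengths or {}).get(chrom)
        for s, e in merged:
            s2 = max(0, s - extend)
            e2 = e + extend if length is None else min(length, e + extend)
            rows.append((chrom, s2, e2, s, e))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "core_start", "core_end"]
    ).sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------
# GFF3 gene intersection
# ---------------------------------------------------------------------

def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene features from a GFF3 file as 0-based half-open intervals with
    ID and Name attributes."""
    names = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names, dtype={"chrom": str})
    df = df[df["type"] == feature_type].copy()

    def attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k.strip() == key:
                return v
        return None

    df["gene_id"] = df["attrs"].map(lambda s: attr(s, "ID"))
    df["gene_name"] = df["attrs"].map(lambda s: attr(s, "Name") or attr(s, "ID"))
    df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
    return df[["chrom", "start", "end", "gene_id", "gene_name"]].reset_index(drop=True)


def intersect_genes(
    regions: pd.DataFrame, gff3: str | Path | pd.DataFrame, feature_type: str = "gene"
) -> pd.DataFrame:
    """Assign genes to regions on >= 1 bp interval overlap.

    ``gff3`` is a file path or a pre-parsed gene table. Returns one row per
    (region, gene) pair plus gene-less regions with null gene columns.
    """
    genes = gff3 if isinstance(gff3, pd.DataFrame) else read_gff3_genes(gff3, feature_type)
    rows = []
    for reg in regions.itertuples(index=False):
        g = genes[
            (genes["chrom"] == reg.chrom)
            & (genes["start"] < reg.end)
            & (genes["end"] > reg.start)
        ]
        if len(g) == 0:
            rows.append((reg.chrom, reg.start, reg.end, None, None))
        for gr in g.itertuples(index=False):
            rows.append((reg.chrom, reg.start, reg.end, gr.gene_id, gr.gene_name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "gene_name"])


# ---------------------------------------------------------------------
# enrichment / Jaccard
# ---------------------------------------------------------------------

@dataclass
class TermGeneSets:
    """Term -> gene-set mapping over a background gene universe."""

    sets: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(f"term {term!r} has genes outside the background: {sorted(stray)[:5]}")

    @property
    def n_background(self) -> int:
        return len(self.background)


def read_term_map(path: str | Path, background: set[str] | None = None) -> TermGeneSets:
    """Read a term<TAB>gene table; background defaults to the union of all
    mapped genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    sets: dict[str, set[str]] = {}
    for term, grp in df.groupby("term", sort=False):
        sets[term] = set(grp["gene"])
    return TermGeneSets(sets, background or set(df["gene"]))


def enrich(
    gene_hits: set[str] | list[str],
    term_sets: TermGeneSets,
    mode: str = "fisher",
) -> pd.DataFrame:
    """Per-term fold enrichment and hypergeometric p.

    For k hits of an n-gene list in a K-gene term over an N-gene
    background: ``fold = (k/n) / (K/N)`` and p is the hypergeometric upper
    tail of k (``mode="fisher"``) or of k-1 (``mode="ease"``, the
    conservative DAVID-style variant). p-values are unadjusted; a
    Benjamini-Hochberg column is included for convenience.
    """
    hits = set(gene_hits)
    stray = hits - term_sets.background
    if stray:
        raise ValueError(f"hit genes outside background: {sorted(stray)[:5]}")
    if mode not in ("fisher", "ease"):
        raise ValueError('mode must be "fisher" or "ease"')
    N = term_sets.n_background
    n = len(hits)
    rows = []
    for term, genes in term_sets.sets.items():
        K = len(genes)
        k = len(hits & genes)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        if k == 0:
            p = 1.0
        else:
            k_eff = k if mode == "fisher" else k - 1
            p = float(hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append((term, k, n, K, N, fold, p))
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "fold", "p"])
    m = len(out)
    if m:
        order = np.argsort(out["p"].to_numpy(), kind="mergesort")
        adj = np.empty(m)
        ranked = out["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["p_bh"] = np.minimum(adj, 1.0)
    return out


def jaccard_matrix(term_sets: TermGeneSets | dict[str, set[str]]) -> pd.DataFrame:
    """Symmetric Jaccard similarity ``J(A,B) = |A n B| / |A u B|`` between
    every pair of term gene sets (unit diagonal; zero marks an empty
    intersection)."""
    sets = term_sets.sets if isinstance(term_sets, TermGeneSets) else term_sets
    terms = list(sets)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    mat = np.ones((len(terms), len(terms)))
    for i, a in enumerate(terms):
        for j in range(i + 1, len(terms)):
            b = terms[j]
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            mat[i, j] = mat[j, i] = inter / union if union else 0.0
    return pd.DataFrame(mat, index=terms, columns=terms)
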