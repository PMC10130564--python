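"""End-to-end orchestration: filter -> diversity -> GRM/PCA -> ROH -> scan
-> DCMS -> annotate -> report.

Every stage writes its table under the run directory; a manifest records
versions, the seed and a parameter hash so a run can be reproduced or any
stage re-run from its serialized inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import enrich, intersect_genes, jaccard_matrix, merge_extend, read_term_map
from .diversity import estimate_ne_history, ld_decay, observed_heterozygosity
from .genotypes import GenotypeMatrix, total_genome_length
from .mito import build_network, collapse_haplotypes, read_fasta, write_dot, write_graphml
from .relatedness import grm, ld_prune, pca, welch_t
from .roh import RohParams, classify_roh, detect_roh, froh_table
from .scan import intersect_hits, selection_scan
from .vcfio import filter_sites, read_population_map, read_vcf, snp_density

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults (MAF > 0.05,
    call rate 1.0, 50 kb / 25 kb scan windows, 2500-SNP ROH windows,
    DCMS >= 30 SNPs, 99.5% hit quantile, 10 kb region extension)."""

    vcf: str
    population_map: str
    gff3: str | None = None
    term_map: str | None = None
    mito_fasta: str | None = None
    out_dir: str = "charrscan_run"
    seed: int = 0
    # filtering
    maf_min: float = 0.05
    call_rate_min: float = 1.0
    # diversity / LD
    density_window: int = 100_000
    ld_max_dist: int = 500_000
    ld_bin_width: int = 10_000
    ne_alpha: float = 1.0
    cm_per_mb: float = 1.0
    # pruning / structure
    prune_r2: float = 0.15
    prune_window: int = 50_000
    prune_step: int = 10_000
    n_pcs: int = 10
    # ROH
    roh: RohParams = field(default_factory=RohParams)
    # scan
    scan_window: int = 50_000
    scan_step: int = 25_000
    min_snps_dcms: int = 30
    hit_quantile: float = 0.995
    # annotation
    region_extend: int = 10_000
    merge_overlap_fraction: float = 0.5
    make_plots: bool = True

    def validate(self) -> None:
        for p, name in [(self.vcf, "vcf"), (self.population_map, "population_map"),
                        (self.gff3, "gff3"), (self.term_map, "term_map"),
                        (self.mito_fasta, "mito_fasta")]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if not (0 < self.hit_quantile < 1):
            raise ValueError("hit_quantile must be in (0, 1)")
        if not (0 <= self.maf_min <= 1 and 0 <= self.call_rate_min <= 1):
            raise ValueError("filter thresholds must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "roh" in data and isinstance(data["roh"], dict):
            data["roh"] = RohParams(**data["roh"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    logger.info("reading VCF %s", config.vcf)
    gm = read_vcf(config.vcf, read_population_map(config.population_map))
    n_raw = gm.n_sites
    gm = filter_sites(gm, config.maf_min, config.call_rate_min)
    logger.info("filtering: %d -> %d SNPs (MAF > %g, call rate >= %g)",
                n_raw, gm.n_sites, config.maf_min, config.call_rate_min)
    pops = gm.population_labels
    if len(pops) != 2:
        raise ValueError(f"pipeline expects exactly 2 populations, found {pops}")

    # -- diversity ----------------------------------------------------
    density = snp_density(gm, config.density_window)
    _write(density, out / "snp_density.tsv")
    het = observed_heterozygosity(gm, per="individual")
    _write(het, out / "heterozygosity.tsv")
    _write(observed_heterozygosity(gm, per="population"), out / "heterozygosity_pop.tsv")

    curves = {}
    for pop in pops:
        curve = ld_decay(gm, pop, config.ld_max_dist, config.ld_bin_width)
        curves[pop] = curve
        _write(curve, out / f"ld_decay_{pop}.tsv")
        n_pop = len(gm.sample_indices(pop))
        _write(
            estimate_ne_history(curve, n_pop, config.ne_alpha, config.cm_per_mb),
            out / f"ne_history_{pop}.tsv",
        )

    # -- structure ----------------------------------------------------
    kept = ld_prune(gm, config.prune_r2, config.prune_window, config.prune_step)
    logger.info("LD pruning kept %d / %d SNPs", len(kept), gm.n_sites)
    gm_pruned = gm.take_sites(kept)
    rel = grm(gm_pruned)
    rel.to_csv(out / "grm.tsv", sep="\t")
    coords, evr = pca(gm_pruned, config.n_pcs)
    coords.to_csv(out / "pca.tsv", sep="\t")
    np.savetxt(out / "pca_explained_variance.tsv", evr, fmt="%.6g")
    within = {}
    for pop in pops:
        idx = gm.sample_indices(pop)
        block = rel.to_numpy()[np.ix_(idx, idx)]
        within[pop] = block[np.triu_indices_from(block, k=1)]
    t, df_w, p = welch_t(within[pops[0]], within[pops[1]])
    with open(out / "welch_within_relatedness.json", "w") as fh:
        json.dump({"t": t, "df": df_w, "p": p,
                   "mean_" + pops[0]: float(np.mean(within[pops[0]])),
                   "mean_" + pops[1]: float(np.mean(within[pops[1]]))}, fh, indent=1)

    # -- ROH ----------------------------------------------------------
    segments = detect_roh(gm, config.roh)
    _write(segments, out / "roh_segments.tsv")
    _write(classify_roh(segments), out / "roh_classes.tsv")
    froh = froh_table(segments, gm)
    _write(froh, out / "froh.tsv")

    # -- selection scan ----------------------------------------------
    windows, cutoffs = selection_scan(
        gm, pops[0], pops[1],
        window=config.scan_window, step=config.scan_step,
        min_snps_dcms=config.min_snps_dcms, quantile=config.hit_quantile,
    )
    _write(windows, out / "scan_windows.tsv")
    with open(out / "scan_cutoffs.json", "w") as fh:
        json.dump(cutoffs, fh, indent=1)
    key = ["chrom", "start", "end"]
    hit_sets = {
        stat: set(map(tuple, windows.loc[windows[f"hit_{stat}"], key].to_numpy()))
        for stat in ("fst", "xpehh", "dcms")
    }
    _write(intersect_hits(hit_sets), out / "hit_intersections.tsv")

    # -- annotation ---------------------------------------------------
    common = windows[windows["hit_fst"] & windows["hit_xpehh"]]
    regions = merge_extend(
        common[key], gm.chrom_lengths,
        extend=config.region_extend,
        merge_overlap_fraction=config.merge_overlap_fraction,
    )
    regions[["chrom", "start", "end"]].to_csv(
        out / "sweep_regions.bed", sep="\t", header=False, index=False
    )
    if config.gff3:
        annotated = intersect_genes(regions, config.gff3)
        _write(annotated, out / "sweep_region_genes.tsv")
        if config.term_map:
            term_sets = read_term_map(config.term_map)
            dcms_regions = merge_extend(
                windows.loc[windows["hit_dcms"], key], gm.chrom_lengths,
                extend=config.region_extend,
                merge_overlap_fraction=config.merge_overlap_fraction,
            )
            dcms_genes = set(
                intersect_genes(dcms_regions, config.gff3)["gene_id"].dropna()
            ) & term_sets.background
            if dcms_genes:
                _write(enrich(dcms_genes, term_sets), out / "enrichment.tsv")
            jaccard_matrix(term_sets).to_csv(out / "term_jaccard.tsv", sep="\t")

    # -- mitogenomes --------------------------------------------------
    if config.mito_fasta:
        seqs = read_fasta(config.mito_fasta)
        pmap = read_population_map(config.population_map)
        pmap = {k: v for k, v in pmap.items() if k in seqs}
        table = collapse_haplotypes(seqs, pmap)
        table.counts.to_csv(out / "mito_haplotypes.tsv", sep="\t")
        net = build_network(table)
        write_graphml(net, out / "mito_network.graphml")
        write_dot(net, out / "mito_network.dot")

    if config.make_plots:
        _make_plots(out, coords, evr, curves, froh, windows, cutoffs)

    manifest = {
        "charrscan_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_snps_input": int(n_raw),
        "n_snps_filtered": int(gm.n_sites),
        "n_samples": gm.n_samples,
        "populations": pops,
        "genome_length_bp": total_genome_length(gm),
        "parameter_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _make_plots(out, coords, evr, curves, froh, windows, cutoffs) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, grp in coords.groupby("population"):
        ax.scatter(grp["PC1"], grp["PC2"], label=pop, s=18)
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend()
    fig.savefig(out / "pca.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, curve in curves.items():
        mid = (curve["bin_lo"] + curve["bin_hi"]) / 2000.0
        ax.plot(mid, curve["mean_r2"], label=pop)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend()
    fig.savefig(out / "ld_decay.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    froh.boxplot(column="froh", by="population", ax=ax)
    ax.set_ylabel("$F_{ROH}$")
    fig.suptitle("")
    fig.savefig(out / "froh.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    x = np.arange(len(windows))
    for ax, col, cut in zip(
        axes, ["fst_mean", "xpehh_neglogp_mean", "dcms"],
        [cutoffs["fst"], cutoffs["xpehh"], cutoffs["dcms"]],
    ):
        ax.plot(x, windows[col], ".", ms=2)
        ax.axhline(cut, color="green", lw=0.8)
        ax.set_ylabel(col)
    axes[-1].set_xlabel("window index")
    fig.savefig(out / "scan_manhattan.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
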