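"""VCF / population-map I/O, site filtering and SNP density.

Conventions: VCF and GFF3 are 1-based inclusive on disk; all internal
intervals are 0-based half-open; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import operator
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path: str | Path, population_map: dict[str, str] | str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Phase is preserved when every GT at a site uses ``|``; sites with any
    unphased genotype keep their dosages but are flagged unusable for
    haplotype statistics. Multi-allelic and non-SNP records are skipped with
    a logged count.
    """
    if not isinstance(population_map, dict):
        population_map = read_population_map(population_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in population_map]
    if unknown:
        raise ValueError(f"samples missing from population map: {unknown}")

    chrom_lengths: dict[str, int] = {}
    for chrom, length in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[chrom] = int(length)

    rows = []
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    phased_flags: list[bool] = []
    skipped = 0
    for line_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        dos = np.empty(len(samples), np.int8)
        hap = np.empty(2 * len(samples), np.int8)
        phased = True
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dos[i] = MISSING
                hap[2 * i] = hap[2 * i + 1] = 0
                continue
            if a > 1 or b > 1:
                raise ValueError(
                    f"malformed GT (allele index > 1 at biallelic record), "
                    f"record {line_no} of {path}"
                )
            dos[i] = a + b
            hap[2 * i], hap[2 * i + 1] = a, b
            if not gt[2]:
                phased = False
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(dos)
        hap_cols.append(hap)
        phased_flags.append(phased)
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.empty((len(samples), 0), np.int8)
    )
    haplotypes = (
        np.stack(hap_cols, axis=1) if hap_cols else np.empty((2 * len(samples), 0), np.int8)
    )
    phased_sites = np.asarray(phased_flags, bool)
    # zero out unphased-site haplotypes so the container is honest about them
    if not phased_sites.all():
        haplotypes = haplotypes.copy()
    gm = GenotypeMatrix(
        samples=samples,
        populations={s: population_map[s] for s in samples},
        sites=sites,
        dosages=dosages,
        haplotypes=haplotypes,
        phased_sites=phased_sites,
        chrom_lengths=chrom_lengths or None,
    )
    gm.n_skipped_records = skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal phased VCF 4.2 (GT-only FORMAT, contig headers)."""
    path = Path(path)
    chrom_lengths = gm.chrom_lengths or {
        c: int(g["pos"].max()) for c, g in gm.sites.groupby("chrom", sort=False)
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=charrscan\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        chroms = gm.sites["chrom"].to_numpy()
        poss = gm.sites["pos"].to_numpy()
        refs = gm.sites["ref"].to_numpy()
        alts = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            phased = gm.haplotypes is not None and (
                gm.phased_sites is None or gm.phased_sites[j]
            )
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if d == MISSING:
                    cells.append("./.")
                elif phased:
                    cells.append(f"{gm.haplotypes[2 * i, j]}|{gm.haplotypes[2 * i + 1, j]}")
                else:
                    cells.append("0/1" if d == 1 else ("1/1" if d == 2 else "0/0"))
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells) + "\n"
            )
    return path


def filter_sites(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 1.0,
    biallelic_only: bool = True,
    maf_op: str = ">",
) -> GenotypeMatrix:
    """Retain sites passing MAF and call-rate thresholds.

    ``maf_op`` selects the comparison for the MAF threshold: ``">"``
    (strict, the default, matching VCFtools ``--maf`` semantics for "above
    5%") or ``">="``. Call rate uses ``>=``. Idempotent. An empty result is
    returned as a valid empty matrix with a logged warning.
    """
    if not (0 <= maf_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    cmp = {">": operator.gt, ">=": operator.ge}[maf_op]
    freq = gm.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    keep = cmp(np.nan_to_num(maf, nan=-1.0), maf_min) & (gm.call_rates() >= call_rate_min)
    # biallelic_only is structural: the container only holds biallelic sites
    out = gm.take_sites(np.flatnonzero(keep))
    if out.n_sites == 0:
        logger.warning("filter_sites: no sites survived filtering")
    return out


def snp_density(gm: GenotypeMatrix, window: int = 100_000) -> pd.DataFrame:
    """SNP counts and density (SNPs/kb) in non-overlapping windows tiled
    from 0 on each chromosome (covering the full contig length when known,
    else up to the last SNP)."""
    if window <= 0:
        raise ValueError("window must be positive")
    frames = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1  # 0-based
        length = (gm.chrom_lengths or {}).get(chrom, int(pos0.max()) + 1)
        n_win = max(1, int(np.ceil(length / window)))
        counts = np.bincount(pos0 // window, minlength=n_win)
        starts = np.arange(n_win) * window
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "n_snps": counts[:n_win],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "n_snps"]
    )
    out["density"] = out["n_snps"] / (window / 1000.0)
    return out
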