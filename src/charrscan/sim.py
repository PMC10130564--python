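"""Synthetic two-population genotype and mitogenome generator.

The generator emulates the study design the package targets: two farmed
populations of 24 diploids each, differentiated at a mean fixation index of
~0.12, with SNP density of ~2.6 SNPs/kb, linkage disequilibrium decaying to
r^2 ~ 0.1 at 100 kb, optional injected selective sweeps and runs of
homozygosity, and small sets of aligned mitogenome haplotypes.

Model
-----
Per-site ancestral frequencies are drawn uniformly on a configurable range
(default (0.1, 0.9), avoiding near-fixed sites that destabilise the
Weir-Cockerham estimator). Each population's frequency is drawn from the
Balding-Nichols Beta distribution ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that
``Var(p_pop) = F p(1-p)``; ``F = 0`` bypasses the Beta draw.

Linkage disequilibrium is produced by a Gaussian-copula AR(1) haplotype
model: each haplotype carries a latent stationary Gaussian path with
site-to-site correlation ``exp(-d / ld_block_scale)`` and the allele is the
indicator ``z < Phi^-1(p_pop)``. This keeps the marginal allele frequency
exactly at the Balding-Nichols draw (so the divergence target is honoured),
yields monotone r^2 decay with a tunable physical scale, and degenerates to
independent (unlinked) sites when ``ld_block_scale <= 0``. It matches no
explicit demographic model; see docs/methods.md for what it does and does
not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the two-population genotype simulation.

    Defaults mirror the study conditions the package emulates: 24 diploids
    per population, divergence F = 0.12, ~385 bp mean SNP spacing
    (~2.6 SNPs/kb) and a 150 kb LD correlation scale (r^2 ~ 0.1 at 100 kb).
    """

    n_per_pop: int = 24
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 5_000_000)]
    )
    snp_spacing_mean: float = 385.0
    fst_target: float = 0.12
    ld_block_scale: float = 150_000.0
    seed: int = 0
    p_ancestral_range: tuple[float, float] = (0.1, 0.9)
    pop_labels: tuple[str, str] = ("NOR", "SWE")
    #: "exponential" gives a Poisson position process; "uniform" draws
    #: gaps ~ U(0.5*mean, 1.5*mean), i.e. near-regular spacing with no
    #: long gaps (used for run-of-homozygosity experiments where a gap cap
    #: would otherwise fragment megabase-scale runs; see docs/methods.md).
    snp_spacing_distribution: str = "exponential"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be positive")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_spacing_mean <= 0:
            raise ValueError("snp_spacing_mean must be positive")


@dataclass
class SweepSpec:
    """A hard selective sweep: replace ``carrier_fraction`` of one
    population's haplotypes by a single core haplotype inside ``interval``
    (0-based half-open bp)."""

    population: str
    chrom: str
    interval: tuple[int, int]
    carrier_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.interval[0] >= self.interval[1]:
            raise ValueError("interval must be non-empty")


@dataclass
class RohSpec:
    """One homozygous tract to inject for ``individual`` (0-based half-open bp)."""

    individual: str
    chrom: str
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.interval[1] - self.interval[0] < 1:
            raise ValueError("interval length must be >= 1 bp")


def _site_positions(
    rng: np.random.Generator, length: int, spacing: float, distribution: str
) -> np.ndarray:
    n_expect = int(length / spacing * 1.3) + 20
    if distribution == "exponential":
        draw = lambda: rng.exponential(spacing, n_expect)
    elif distribution == "uniform":
        draw = lambda: rng.uniform(0.5 * spacing, 1.5 * spacing, n_expect)
    else:
        raise ValueError('snp_spacing_distribution must be "exponential" or "uniform"')
    pos = np.cumsum(draw())
    while pos[-1] < length:  # pragma: no cover - rare top-up
        pos = np.concatenate([pos, pos[-1] + np.cumsum(draw())])
    pos = np.floor(pos[pos < length]).astype(np.int64) + 1  # 1-based
    pos = np.unique(pos)
    return pos


def _ar1_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    pos: np.ndarray,
    p_site: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Haplotypes with AR(1) latent correlation exp(-d/scale) between sites."""
    n_sites = len(pos)
    if scale <= 0:
        return (rng.random((n_hap, n_sites)) < p_site).astype(np.int8)
    tau = norm.ppf(np.clip(p_site, 1e-12, 1 - 1e-12))
    rho = np.exp(-np.diff(pos) / scale)
    innov_sd = np.sqrt(1.0 - rho**2)
    z = np.empty((n_hap, n_sites))
    eps = rng.standard_normal((n_hap, n_sites))
    z[:, 0] = eps[:, 0]
    for j in range(1, n_sites):
        z[:, j] = rho[j - 1] * z[:, j - 1] + innov_sd[j - 1] * eps[:, j]
    return (z < tau[None, :]).astype(np.int8)


def simulate_divergent_populations(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate phased genotypes for two diverged populations.

    Child RNG streams are spawned from the root seed in a fixed order
    (positions, frequencies, population-1 haplotypes, population-2
    haplotypes, alleles) so identical config + seed gives bit-identical
    output.
    """
    root = np.random.SeedSequence(config.seed)
    ss_pos, ss_freq, ss_hap1, ss_hap2, ss_allele = root.spawn(5)
    rng_pos = np.random.default_rng(ss_pos)
    rng_freq = np.random.default_rng(ss_freq)
    rng_haps = [np.random.default_rng(ss_hap1), np.random.default_rng(ss_hap2)]
    rng_allele = np.random.default_rng(ss_allele)

    F = config.fst_target
    lab_a, lab_b = config.pop_labels
    n = config.n_per_pop
    samples = [f"{lab_a}_{i + 1:03d}" for i in range(n)] + [
        f"{lab_b}_{i + 1:03d}" for i in range(n)
    ]
    populations = {s: (lab_a if i < n else lab_b) for i, s in enumerate(samples)}

    site_frames = []
    hap_blocks: list[list[np.ndarray]] = [[], []]
    lo, hi = config.p_ancestral_range
    for chrom, length in config.chrom_lengths:
        pos = _site_positions(
            rng_pos, length, config.snp_spacing_mean, config.snp_spacing_distribution
        )
        p_anc = rng_freq.uniform(lo, hi, len(pos))
        if F == 0.0:
            p_pops = [p_anc, p_anc]
        else:
            shape = (1.0 - F) / F
            p_pops = [
                rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape),
                rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape),
            ]
        ref_idx = rng_allele.integers(0, 4, len(pos))
        alt_off = rng_allele.integers(1, 4, len(pos))
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[(ref_idx + alt_off) % 4],
                }
            )
        )
        for k in range(2):
            hap_blocks[k].append(
                _ar1_haplotypes(rng_haps[k], 2 * n, pos, p_pops[k], config.ld_block_scale)
            )

    sites = pd.concat(site_frames, ignore_index=True)
    haps_by_pop = [np.concatenate(blocks, axis=1) for blocks in hap_blocks]
    haplotypes = np.concatenate(haps_by_pop, axis=0)
    dosages = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    return GenotypeMatrix(
        samples=samples,
        populations=populations,
        sites=sites,
        dosages=dosages,
        haplotypes=haplotypes,
        chrom_lengths=dict(config.chrom_lengths),
    )


def inject_sweep(gm: GenotypeMatrix, spec: SweepSpec, seed: int) -> GenotypeMatrix:
    """Overwrite part of one population's haplotypes with a core haplotype.

    ``carrier_fraction`` of the target population's haplotypes (rounded to
    the nearest count, at least one) are replaced inside the interval by one
    randomly chosen haplotype from that population. The other population is
    untouched.
    """
    if gm.haplotypes is None:
        raise ValueError("inject_sweep requires phased haplotypes")
    site_idx = gm.site_indices(spec.chrom, spec.interval[0], spec.interval[1])
    if len(site_idx) == 0:
        raise ValueError(
            f"sweep interval {spec.chrom}:{spec.interval} contains no SNPs"
        )
    hap_rows = gm.haplotype_indices(spec.population)
    rng = np.random.default_rng(seed)
    core = hap_rows[rng.integers(len(hap_rows))]
    k = max(1, int(round(spec.carrier_fraction * len(hap_rows))))
    carriers = rng.choice(hap_rows, size=k, replace=False)
    out = gm.copy()
    core_alleles = out.haplotypes[core, site_idx].copy()
    for row in carriers:
        out.haplotypes[row, site_idx] = core_alleles
    out.dosages = (out.haplotypes[0::2] + out.haplotypes[1::2]).astype(np.int8)
    out.validate()
    return out


def inject_roh(gm: GenotypeMatrix, specs: list[RohSpec]) -> GenotypeMatrix:
    """Copy haplotype 1 over haplotype 2 inside each tract (forcing
    homozygosity there). Overlapping tracts for one individual are an error;
    tracts containing no SNPs are a no-op with a logged warning."""
    if gm.haplotypes is None:
        raise ValueError("inject_roh requires phased haplotypes")
    by_ind: dict[str, list[RohSpec]] = {}
    for spec in specs:
        by_ind.setdefault(spec.individual, []).append(spec)
    for ind, ss in by_ind.items():
        intervals = sorted((s.chrom, s.interval) for s in ss)
        for (c1, i1), (c2, i2) in zip(intervals, intervals[1:]):
            if c1 == c2 and i2[0] < i1[1]:
                raise ValueError(f"overlapping ROH specs for individual {ind!r}")
    out = gm.copy()
    sample_pos = {s: i for i, s in enumerate(out.samples)}
    for spec in specs:
        if spec.individual not in sample_pos:
            raise KeyError(f"unknown individual: {spec.individual!r}")
        site_idx = out.site_indices(spec.chrom, spec.interval[0], spec.interval[1])
        if len(site_idx) == 0:
            logger.warning(
                "ROH spec %s %s:%s contains no SNPs; genotypes unchanged",
                spec.individual, spec.chrom, spec.interval,
            )
            continue
        i = sample_pos[spec.individual]
        out.haplotypes[2 * i + 1, site_idx] = out.haplotypes[2 * i, site_idx]
    out.dosages = (out.haplotypes[0::2] + out.haplotypes[1::2]).astype(np.int8)
    out.validate()
    return out


# ---------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------

def write_fixture(
    gm: GenotypeMatrix,
    out_dir: str | Path,
    gene_spacing: int = 200_000,
    gene_length: int = 20_000,
    n_terms: int = 20,
) -> dict[str, Path]:
    """Write a complete analysis fixture: phased VCF 4.2, population map,
    toy GFF3 with genes tiled every ``gene_spacing`` bp, and a term -> gene
    TSV assigning every gene to 1-3 of ``n_terms`` synthetic terms.

    Returns the mapping of fixture kind to written path. Output is
    byte-deterministic for a given matrix.
    """
    from .vcfio import write_vcf  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "pop_map": out_dir / "populations.tsv",
        "gff3": out_dir / "annotation.gff3",
        "term_map": out_dir / "terms.tsv",
    }
    write_vcf(gm, paths["vcf"])
    with open(paths["pop_map"], "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{gm.populations[s]}\n")

    chrom_lengths = gm.chrom_lengths or {
        c: int(g["pos"].max()) for c, g in gm.sites.groupby("chrom", sort=False)
    }
    genes: list[tuple[str, int, int, str]] = []
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom, length in chrom_lengths.items():
            k = 0
            for start0 in range(0, length - gene_length, gene_spacing):
                k += 1
                gid = f"gene_{chrom}_{k:04d}"
                start1, end1 = start0 + 1, start0 + gene_length  # 1-based inclusive
                genes.append((chrom, start1, end1, gid))
                fh.write(
                    f"{chrom}\tcharrscan\tgene\t{start1}\t{end1}\t.\t+\t.\t"
                    f"ID={gid};Name={gid}\n"
                )
    # deterministic term assignment (fixed internal stream; the fixture is
    # a function of the matrix only)
    rng = np.random.default_rng(987654321)
    with open(paths["term_map"], "w") as fh:
        for i, (_, _, _, gid) in enumerate(genes):
            n_assign = 1 + int(rng.integers(0, 3))
            terms = rng.choice(n_terms, size=n_assign, replace=False)
            for t in sorted(terms):
                fh.write(f"TERM_{t + 1:02d}\t{gid}\n")
    return paths


# ---------------------------------------------------------------------
# mitogenome haplotype sets
# ---------------------------------------------------------------------

def simulate_mito_sequences(
    n_groups: int,
    counts_per_hap: list[list[int]],
    inter_group_mutations: int,
    intra_group_mutations: list[int],
    length: int = 2000,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate aligned mitogenome sequences with exact pairwise distances.

    Each group ``g`` has ``len(counts_per_hap[g])`` haplotypes built from a
    group founder by substitutions at mutually disjoint positions: haplotype
    ``i`` carries ``d_i`` private mutations with ``d_0 = 0`` and the two
    largest ``d`` summing to ``intra_group_mutations[g]`` (the group's
    maximum pairwise distance). Consecutive group founders differ at
    ``inter_group_mutations`` further disjoint positions, so the closest
    between-group pair is exactly that count and every pairwise Hamming
    distance is the sum of the relevant private/founder mutation counts.

    Returns ``(sequences, population_map)`` with one entry per replicated
    individual (``counts_per_hap[g][i]`` copies of haplotype ``i``).
    """
    if len(counts_per_hap) != n_groups or len(intra_group_mutations) != n_groups:
        raise ValueError("counts_per_hap and intra_group_mutations must have n_groups entries")
    labels = group_labels or [f"G{g + 1}" for g in range(n_groups)]

    offsets: list[list[int]] = []
    for g, counts in enumerate(counts_per_hap):
        m = len(counts)
        target = intra_group_mutations[g]
        if m == 1:
            if target != 0:
                raise ValueError("single-haplotype group must have intra mutations 0")
            offsets.append([0])
            continue
        d = list(range(m - 1))  # 0, 1, ..., m-2
        last = target - d[-1]
        if last <= d[-1]:
            raise ValueError(
                f"intra_group_mutations[{g}]={target} too small for {m} distinct haplotypes"
            )
        offsets.append(d + [last])
    total_needed = (n_groups - 1) * inter_group_mutations + sum(sum(d) for d in offsets)
    if length <= total_needed:
        raise ValueError(f"length {length} too short for {total_needed} mutations")

    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, length)
    mut_positions = rng.permutation(length)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = mut_positions[cursor:cursor + k]
        cursor += k
        return out

    def mutate(seq: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = seq.copy()
        out[pos] = (out[pos] + rng.integers(1, 4, len(pos))) % 4
        return out

    sequences: dict[str, str] = {}
    pop_map: dict[str, str] = {}
    founder = base
    for g in range(n_groups):
        if g > 0:
            founder = mutate(founder, take(inter_group_mutations))
        for i, (count, d) in enumerate(zip(counts_per_hap[g], offsets[g])):
            hap = mutate(founder, take(d)) if d else founder
            seq = "".join(_BASES[hap])
            for rep in range(count):
                name = f"{labels[g]}_h{i + 1}_{rep + 1}"
                sequences[name] = seq
                pop_map[name] = labels[g]
    return sequences, pop_map


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    """Write aligned sequences as FASTA (insertion order, 70-col wrap)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path
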