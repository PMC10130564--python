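"""Core genotype container shared by every analysis stage.

A :class:`GenotypeMatrix` holds biallelic SNP dosages (samples x sites,
values 0/1/2 with -1 for missing), the site map, sample -> population
labels, and — when the input was phased — the underlying haplotypes as a
``2*n_samples x n_sites`` 0/1 array (rows ``2i`` and ``2i+1`` belong to
sample ``i``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage/phase container.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    populations
        Mapping sample id -> population label; must cover every sample.
    sites
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based
        and strictly increasing within each chromosome.
    dosages
        ``(n_samples, n_sites)`` int8 array in {0, 1, 2, -1}.
    haplotypes
        Optional ``(2*n_samples, n_sites)`` int8 array in {0, 1}; consistent
        with dosages wherever the site is phased and non-missing.
    phased_sites
        Boolean mask over sites; False marks sites whose haplotypes are not
        trustworthy (e.g. an unphased GT was seen). ``None`` means all
        phased when haplotypes are present.
    chrom_lengths
        Optional chromosome lengths in bp (from VCF contig headers or the
        simulation config); used for window tiling and interval clipping.
    """

    samples: list[str]
    populations: dict[str, str]
    sites: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    phased_sites: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if list(self.sites.columns[:4]) != SITE_COLUMNS:
            raise ValueError(f"sites must have columns {SITE_COLUMNS}")
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * len(self.samples), len(self.sites)):
                raise ValueError("haplotypes shape inconsistent with samples/sites")
            ok = self.dosages != MISSING
            if self.phased_sites is not None:
                ok = ok & self.phased_sites[None, :]
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(hsum[ok], self.dosages[ok]):
                raise ValueError("hap1 + hap2 != dosage at a phased non-missing cell")

    # -- basic views --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.populations[s] == population]
        if not idx:
            raise KeyError(f"unknown population: {population!r}")
        return np.asarray(idx)

    def haplotype_indices(self, population: str) -> np.ndarray:
        si = self.sample_indices(population)
        return np.sort(np.concatenate([2 * si, 2 * si + 1]))

    def site_indices(self, chrom: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Indices of sites on ``chrom`` with 0-based half-open [start, end)."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        if start is not None:
            mask &= self.sites["pos"].to_numpy() - 1 >= start
        if end is not None:
            mask &= self.sites["pos"].to_numpy() - 1 < end
        return np.flatnonzero(mask)

    def allele_frequencies(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """ALT allele frequency per site over non-missing genotypes (NaN if none)."""
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        obs = d != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def call_rates(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    # -- subsetting ---------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            phased_sites=None if self.phased_sites is None else self.phased_sites[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx]
        hap_idx = np.concatenate([[2 * i, 2 * i + 1] for i in idx]) if len(idx) else np.array([], int)
        return replace(
            self,
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            dosages=self.dosages[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            samples=list(self.samples),
            populations=dict(self.populations),
            sites=self.sites.copy(),
            dosages=self.dosages.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
            phased_sites=None if self.phased_sites is None else self.phased_sites.copy(),
            chrom_lengths=None if self.chrom_lengths is None else dict(self.chrom_lengths),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality on samples, populations, site map, dosages and phase."""
        if self.samples != other.samples or self.populations != other.populations:
            return False
        if not self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS]):
            return False
        if not np.array_equal(self.dosages, other.dosages):
            return False
        a, b = self.haplotypes, other.haplotypes
        if (a is None) != (b is None):
            return False
        return a is None or np.array_equal(a, b)


def total_genome_length(gm: GenotypeMatrix) -> int:
    """Sum of known contig lengths, falling back to the last SNP position."""
    if gm.chrom_lengths:
        return int(sum(gm.chrom_lengths.values()))
    return int(gm.sites.groupby("chrom", sort=False)["pos"].max().sum())
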