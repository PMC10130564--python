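import numpy as np
import pytest

import charrscan as cs


@pytest.fixture(scope="session")
def sim_gm():
    """Two diverged populations with LD on two small chromosomes."""
    cfg = cs.SimulationConfig(
        n_per_pop=12,
        chrom_lengths=[("chr1", 1_500_000), ("chr2", 1_000_000)],
        fst_target=0.12,
        seed=11,
    )
    return cs.simulate_divergent_populations(cfg)


@pytest.fixture(scope="session")
def unlinked_gm():
    """Unlinked sites, no divergence — a null panel."""
    cfg = cs.SimulationConfig(
        n_per_pop=24,
        chrom_lengths=[("chr1", 2_000_000)],
        fst_target=0.0,
        ld_block_scale=0.0,
        seed=5,
    )
    return cs.simulate_divergent_populations(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_gm):
    """On-disk fixture set (VCF, pop map, GFF3, term map) for I/O tests."""
    out = tmp_path_factory.mktemp("fixture")
    return cs.write_fixture(sim_gm, out)


def make_gm(dosages, positions=None, chrom="chr1", haplotypes=None, pops=None):
    """Hand-build a GenotypeMatrix from a dosage array (samples x sites)."""
    import pandas as pd

    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = np.arange(1, m + 1) * 1000 if positions is None else np.asarray(positions)
    samples = [f"s{i}" for i in range(n)]
    if pops is None:
        pops = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(samples)}
    else:
        pops = {s: p for s, p in zip(samples, pops)}
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return cs.GenotypeMatrix(
        samples=samples,
        populations=pops,
        sites=sites,
        dosages=dosages,
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, np.int8),
    )
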