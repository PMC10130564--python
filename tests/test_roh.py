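"""ROH detection vs a brute-force oracle, length classes and F_ROH."""

import numpy as np
import pandas as pd
import pytest

import charrscan as cs
from charrscan.roh import _runs_one
from conftest import make_gm


def brute_force_runs(opp, pos, params):
    """Independent loop-based implementation of the sliding-window rule."""
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    win_ok = []
    for s in range(n - w + 1):
        ok = sum(opp[s:s + w]) <= params.max_opposite_per_window
        ok = ok and all(pos[k + 1] - pos[k] <= params.max_gap_bp for k in range(s, s + w - 1))
        win_ok.append(ok)
    in_run = []
    for i in range(n):
        cover = [win_ok[s] for s in range(max(0, i - w + 1), min(i, n - w) + 1)]
        in_run.append(sum(cover) / len(cover) >= params.min_window_hit_fraction)
    runs, i = [], 0
    while i < n:
        if in_run[i]:
            j = i
            while j + 1 < n and in_run[j + 1]:
                j += 1
            if pos[j] - pos[i] >= params.min_length_bp and j - i + 1 >= params.min_snps:
                runs.append((int(pos[i]), int(pos[j]), j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


class TestDetectRoh:
    def test_fully_homozygous_chromosome_is_one_run(self):
        pos = np.arange(1, 3_000_002, 15_000)
        d = np.zeros((1, len(pos)), np.int8)
        gm = make_gm(d, positions=pos, pops=["A"])
        params = cs.RohParams(window_snps=50, max_gap_bp=20_000, min_length_bp=1_000_000,
                              max_opposite_per_window=3)
        seg = cs.detect_roh(gm, params)
        assert len(seg) == 1
        assert seg["start"].iloc[0] == pos[0]
        assert seg["end"].iloc[0] == pos[-1]

    def test_alternating_heterozygote_has_no_runs(self):
        pos = np.arange(1, 2_000_002, 10_000)
        d = np.tile([1], (1, len(pos))).astype(np.int8)
        gm = make_gm(d, positions=pos, pops=["A"])
        params = cs.RohParams(window_snps=20, max_gap_bp=50_000, min_length_bp=500_000,
                              max_opposite_per_window=1)
        assert len(cs.detect_roh(gm, params)) == 0

    def test_chromosome_shorter_than_window_skipped_with_warning(self, caplog):
        gm = make_gm(np.zeros((1, 10), np.int8), pops=["A"])
        with caplog.at_level("WARNING"):
            seg = cs.detect_roh(gm, cs.RohParams(window_snps=50, max_opposite_per_window=3))
        assert len(seg) == 0
        assert "skipped" in caplog.text

    def test_injected_tract_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000, 1_000), 200, replace=False))
        opp = rng.random(200) < 0.4
        tract = (pos >= 1_000_000) & (pos < 2_500_000)
        opp[tract] = False
        params = cs.RohParams(window_snps=25, max_gap_bp=100_000, min_length_bp=1_000_000,
                              max_opposite_per_window=2, min_snps_in_run=25)
        fast = _runs_one(opp, pos, params)
        assert fast == brute_force_runs(opp, pos, params)
        assert len(fast) == 1

    def test_detector_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(30, 300))
            pos = np.sort(rng.choice(np.arange(1, 5_000_000, 500), n, replace=False))
            opp = rng.random(n) < rng.uniform(0.02, 0.5)
            params = cs.RohParams(
                window_snps=int(rng.integers(5, min(60, n))),
                max_gap_bp=int(rng.integers(20_000, 400_000)),
                min_length_bp=int(rng.integers(100_000, 1_500_000)),
                max_opposite_per_window=int(rng.integers(0, 5)),
                min_snps_in_run=int(rng.integers(1, 40)),
                min_window_hit_fraction=float(rng.uniform(0.05, 0.9)),
            )
            assert _runs_one(opp, pos, params) == brute_force_runs(opp, pos, params)


class TestClassifyRoh:
    def test_class_boundaries(self):
        seg = pd.DataFrame(
            {
                "individual": ["a", "a", "b", "b"],
                "population": ["P", "P", "P", "P"],
                "chrom": "chr1",
                "start": [0, 0, 0, 0],
                "end": [1_400_000, 1_380_000, 2_700_000, 5_060_000],
                "length": [1_400_000, 1_380_000, 2_700_000, 5_060_000],
                "n_snps": 100,
            }
        )
        table = cs.classify_roh(seg)
        first = table[(table["length_class"] == "0-2 Mb") & (table["population"] == "P")]
        assert first["count"].iloc[0] == 2
        assert first["mean_length_mb"].iloc[0] == pytest.approx(1.39)

    def test_overflow_segment_flagged(self, caplog):
        seg = pd.DataFrame(
            {
                "individual": ["a"], "population": ["P"], "chrom": ["chr1"],
                "start": [0], "end": [17_000_000], "length": [17_000_000], "n_snps": [10],
            }
        )
        with caplog.at_level("WARNING"):
            table = cs.classify_roh(seg)
        assert "exceed 16 Mb" in caplog.text
        assert (table[table["length_class"] == ">16 Mb"]["count"] == 1).any()

    def test_empty_input_gives_zero_table(self):
        table = cs.classify_roh(pd.DataFrame(columns=["population", "length"]))
        assert (table["count"] == 0).all()


class TestFroh:
    def test_direct_arithmetic(self):
        seg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000_000],
                            "length": [10_000_000]})
        assert cs.froh(seg, 100_000_000) == pytest.approx(0.10)

    def test_two_segments(self):
        seg = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0],
                            "end": [1_500_000, 2_500_000], "length": [1_500_000, 2_500_000]})
        assert cs.froh(seg, 80_000_000) == pytest.approx(0.05)

    def test_empty_segments_give_zero(self):
        assert cs.froh(pd.DataFrame(columns=["chrom", "start", "end", "length"]), 1000) == 0.0

    def test_overlapping_segments_rejected(self):
        seg = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500_000],
                            "end": [1_000_000, 1_200_000], "length": [1_000_000, 700_000]})
        with pytest.raises(ValueError, match="overlap"):
            cs.froh(seg, 10_000_000)

    def test_adding_a_segment_never_decreases_froh(self):
        base = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2_000_000],
                             "length": [2_000_000]})
        extra = pd.concat([base, pd.DataFrame({"chrom": ["chr2"], "start": [0],
                                               "end": [1_000_000], "length": [1_000_000]})])
        assert cs.froh(extra, 50_000_000) >= cs.froh(base, 50_000_000)

    def test_parameter_recovery_on_injected_fractions(self):
        chroms = [(f"chr{i}", 10_000_000) for i in range(4)]
        cfg = cs.SimulationConfig(
            n_per_pop=4, chrom_lengths=chroms, snp_spacing_mean=2_000,
            fst_target=0.0, ld_block_scale=0.0, seed=21,
            snp_spacing_distribution="uniform",
        )
        gm = cs.simulate_divergent_populations(cfg)
        genome = 40_000_000
        rng = np.random.default_rng(4)
        for f in [0.0623, 0.15]:
            total = f * genome
            k = max(1, int(np.ceil(total / 2.5e6)))
            L = int(round(total / k))
            specs = []
            for s in gm.samples:
                for t in range(k):
                    c = chroms[t % len(chroms)][0]
                    start = int(rng.integers(0, 10_000_000 - L))
                    specs.append(cs.RohSpec(s, c, (start, start + L)))
            injected = cs.inject_roh(gm, specs)
            params = cs.RohParams(window_snps=50, max_gap_bp=10_000,
                                  min_length_bp=1_000_000, max_opposite_per_window=3)
            seg = cs.detect_roh(injected, params)
            ftab = cs.froh_table(seg, injected, genome_length_bp=genome)
            assert abs(ftab["froh"].mean() - f) < 0.005
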