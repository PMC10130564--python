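"""Selection-scan statistics vs independent oracles."""

import numpy as np
import pandas as pd
import pytest

import charrscan as cs
from charrscan.scan import wc_fst_components
from conftest import make_gm


# ---------------------------------------------------------------------
# independent Weir & Cockerham oracle (scalar, straight off the 1984
# component formulas; no code shared with the implementation)
# ---------------------------------------------------------------------

def wc_theta_oracle(geno1, geno2):
    r = 2
    n1, n2 = len(geno1), len(geno2)
    p1 = sum(geno1) / (2 * n1)
    p2 = sum(geno2) / (2 * n2)
    h1 = sum(1 for g in geno1 if g == 1) / n1
    h2 = sum(1 for g in geno2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    den = a + b + c
    return None if den == 0 else a / den


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        d = np.array([[2]] * 12 + [[0]] * 12, np.int8)
        gm = make_gm(d)
        assert cs.wc_fst_site(gm, ("A", "B"), 0) == pytest.approx(1.0)

    def test_identical_populations_give_non_positive_theta(self):
        block = np.array([0, 1, 2, 1, 0, 2] * 2, np.int8).reshape(-1, 1)
        d = np.vstack([block, block])
        gm = make_gm(d)
        assert cs.wc_fst_site(gm, ("A", "B"), 0) <= 0.0

    def test_matches_component_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(100):
            n1, n2 = rng.integers(4, 30, 2)
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            g1 = rng.binomial(2, p1, n1)
            g2 = rng.binomial(2, p2, n2)
            d = np.concatenate([g1, g2]).reshape(-1, 1).astype(np.int8)
            gm = make_gm(d, pops=["A"] * n1 + ["B"] * n2)
            expected = wc_theta_oracle(list(g1), list(g2))
            got = cs.wc_fst_site(gm, ("A", "B"), 0)
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
                checked += 1
        assert checked > 50

    def test_multilocus_estimator_recovers_divergence(self):
        vals = []
        for seed in range(3):
            cfg = cs.SimulationConfig(
                n_per_pop=24, chrom_lengths=[("chr1", 4_000_000)],
                fst_target=0.3, ld_block_scale=0.0, seed=seed,
            )
            vals.append(cs.global_fst(cs.simulate_divergent_populations(cfg)))
        assert abs(np.mean(vals) - 0.3) < 0.02


class TestWindowedMean:
    def test_constant_values_give_constant_windows(self):
        pos = np.arange(1, 100_000, 5_000)
        win = cs.windowed_mean(pos, np.full(len(pos), 3.5), 50_000, 25_000)
        assert np.allclose(win["mean"].dropna(), 3.5)

    def test_tiling_of_100kb_chromosome(self):
        pos = np.array([10, 99_000])
        win = cs.windowed_mean(pos, np.zeros(2), 50_000, 25_000, chrom_length=100_000)
        assert win["start"].tolist() == [0, 25_000, 50_000, 75_000]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 20, replace=False))
        vals = rng.normal(size=20)
        win = cs.windowed_mean(pos, vals, 50_000, 25_000, chrom_length=200_000)
        for row in win.itertuples(index=False):
            inside = [(p, v) for p, v in zip(pos, vals) if row.start <= p - 1 < row.end]
            assert row.n_snps == len(inside)
            if inside:
                assert row.mean == pytest.approx(np.mean([v for _, v in inside]))
            else:
                assert np.isnan(row.mean)


class TestEhhIes:
    def test_identical_haplotypes_keep_ehh_one(self):
        H = np.tile(np.array([0, 1, 0, 1, 1], np.int8), (6, 1))
        pos = np.array([100, 200, 300, 400, 500])
        curve = cs.ehh(H, pos, 2)
        assert (curve.left["ehh"] == 1).all() and (curve.right["ehh"] == 1).all()
        assert cs.ies(H, pos, 2) == pytest.approx(400.0)  # full span

    def test_two_identical_pairs_give_one_third(self):
        # 4 haplotypes forming 2 identical pairs beyond the core
        H = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 1, 1], [0, 1, 1]], np.int8
        )
        pos = np.array([100, 200, 300])
        curve = cs.ehh(H, pos, 0, min_ehh=0.0)
        assert curve.right["ehh"].tolist() == [pytest.approx(1 / 3)] * 2

    def test_all_distinct_drops_to_zero(self):
        # first flanking site separates every haplotype pair
        H = np.array([[0, 0], [0, 1]], np.int8)
        pos = np.array([100, 200])
        curve = cs.ehh(H, pos, 0)
        assert curve.right["ehh"].tolist() == [0.0]

    def test_degenerate_single_point_curve_has_zero_ies(self, caplog):
        H = np.array([[0], [1]], np.int8)
        with caplog.at_level("WARNING"):
            assert cs.ies(H, np.array([100]), 0) == 0.0
        assert "truncated" in caplog.text

    def test_piecewise_linear_toy_integral(self):
        # engineered EHH: 4 haplotypes; at +100 bp two pairs (1/3), at
        # +200 bp all distinct (0) -> right integral = (1+1/3)/2*100 + (1/3+0)/2*100
        H = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], np.int8)
        pos = np.array([0, 100, 200])
        got = cs.ies(H, pos, 0, min_ehh=0.0)
        expected = (1 + 1 / 3) / 2 * 100 + (1 / 3 + 0) / 2 * 100
        assert got == pytest.approx(expected)

    def test_curves_non_increasing_away_from_core(self, sim_gm):
        idx = sim_gm.site_indices("chr1")
        H = sim_gm.haplotypes[:24][:, idx]
        pos = sim_gm.sites.loc[idx, "pos"].to_numpy()
        for core in [10, len(pos) // 2, len(pos) - 10]:
            curve = cs.ehh(H, pos, core)
            for side in (curve.left, curve.right):
                vals = np.concatenate([[1.0], side["ehh"].to_numpy()])
                assert np.all(np.diff(vals) <= 1e-12)


class TestXpehh:
    def test_identical_panels_give_zero_raw(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, (10, 50)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        tab = cs.xpehh(H, H.copy(), pos, standardize=False)
        assert np.allclose(tab["raw"], 0.0)

    def test_swapping_panels_negates_raw_keeps_p(self, sim_gm):
        idx = sim_gm.site_indices("chr1")[:300]
        pos = sim_gm.sites.loc[idx, "pos"].to_numpy()
        Ha = sim_gm.haplotypes[np.ix_(sim_gm.haplotype_indices("NOR"), idx)]
        Hb = sim_gm.haplotypes[np.ix_(sim_gm.haplotype_indices("SWE"), idx)]
        ab = cs.xpehh(Ha, Hb, pos)
        ba = cs.xpehh(Hb, Ha, pos)
        assert np.allclose(ab["raw"].to_numpy(), -ba["raw"].to_numpy())
        assert np.allclose(ab["p"].to_numpy(), ba["p"].to_numpy())

    def test_standardization_is_exact_null_calibration(self, sim_gm):
        tab = cs.xpehh_scan(sim_gm, "NOR", "SWE")
        assert abs(tab["std"].mean()) < 0.05
        assert abs(tab["std"].std() - 1.0) < 0.05


class TestEmpiricalP:
    def test_maximum_of_999_values(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=999)
        p = cs.empirical_right_tail_p(v)
        assert p[np.argmax(v)] == pytest.approx(1 / 1000)

    def test_all_equal_values(self):
        p = cs.empirical_right_tail_p(np.ones(10))
        assert np.allclose(p, 10 / 11)

    def test_monotone_and_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=200)
        p = cs.empirical_right_tail_p(v)
        oracle = np.array(
            [(1 + sum(1 for u in v if u >= x) - 1) / (len(v) + 1) for x in v]
        )
        assert np.allclose(p, oracle)
        order = np.argsort(v)
        assert np.all(np.diff(p[order]) <= 0)


class TestDcms:
    @staticmethod
    def direct_eq(df, pairs, clip=1e-10):
        """Direct evaluation: logit sum weighted by summed |correlation|."""
        stats_ = df[[s for s, _ in pairs]].to_numpy(float)
        n = len(pairs)
        R = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                R[i, j] = np.corrcoef(stats_[:, i], stats_[:, j])[0, 1]
        out = np.zeros(len(df))
        for w in range(len(df)):
            total = 0.0
            for t, (_, pcol) in enumerate(pairs):
                p = min(max(df[pcol].iloc[w], clip), 1 - clip)
                total += np.log((1 - p) / p) / sum(abs(R[i, t]) for i in range(n))
            out[w] = total
        return out

    def test_all_half_pvalues_give_zero(self):
        df = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [2.0, 1, 3],
                           "p1": 0.5, "p2": 0.5})
        got = cs.dcms(df, [("s1", "p1"), ("s2", "p2")])
        assert np.allclose(got, 0.0)

    def test_single_statistic_direct_value(self):
        df = pd.DataFrame({"s": [1.0, 2.0], "p": [0.01, 0.5]})
        got = cs.dcms(df, [("s", "p")])
        assert got[0] == pytest.approx(np.log(99))
        assert got[1] == pytest.approx(0.0)

    def test_duplicating_single_statistic_leaves_dcms_unchanged(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=50)
        p = cs.empirical_right_tail_p(s)
        df = pd.DataFrame({"s": s, "s_dup": s, "p": p, "p_dup": p})
        single = cs.dcms(df, [("s", "p")])
        doubled = cs.dcms(df, [("s", "p"), ("s_dup", "p_dup")])
        assert np.allclose(single, doubled, atol=1e-10)

    def test_matches_direct_formula_on_random_windows(self):
        rng = np.random.default_rng(10)
        s1 = rng.normal(size=80)
        s2 = 0.5 * s1 + rng.normal(size=80)
        df = pd.DataFrame({
            "s1": s1, "s2": s2,
            "p1": cs.empirical_right_tail_p(s1),
            "p2": cs.empirical_right_tail_p(s2),
        })
        got = cs.dcms(df, [("s1", "p1"), ("s2", "p2")])
        assert np.allclose(got, self.direct_eq(df, [("s1", "p1"), ("s2", "p2")]), atol=1e-10)

    def test_uncorrelated_statistics_reduce_to_logit_sum(self):
        rng = np.random.default_rng(11)
        n = 20_000
        s1, s2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({
            "s1": s1, "s2": s2,
            "p1": cs.empirical_right_tail_p(s1),
            "p2": cs.empirical_right_tail_p(s2),
        })
        got = cs.dcms(df, [("s1", "p1"), ("s2", "p2")])
        p1 = np.clip(df["p1"], 1e-10, 1 - 1e-10)
        p2 = np.clip(df["p2"], 1e-10, 1 - 1e-10)
        plain = np.log((1 - p1) / p1) + np.log((1 - p2) / p2)
        # empirical correlation ~ 1/sqrt(n); weights are 1 + O(1/sqrt(n))
        assert np.allclose(got, plain, rtol=0.02, atol=0.05)

    def test_constant_statistic_column_is_an_error(self):
        df = pd.DataFrame({"s1": [1.0, 1.0], "p1": [0.2, 0.4]})
        with pytest.raises(ValueError, match="s1"):
            cs.dcms(df, [("s1", "p1")])


class TestCallHits:
    def test_thousand_windows_give_five_hits(self):
        v = np.arange(1000, dtype=float)
        cutoff, hits = cs.call_hits(v, 0.995)
        assert hits.sum() == 5

    def test_all_equal_flags_everything_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            _, hits = cs.call_hits(np.ones(50), 0.995)
        assert hits.all()


class TestIntersectHits:
    def test_identical_and_disjoint_sets(self):
        a = {("chr1", 0, 50_000), ("chr1", 25_000, 75_000)}
        table = cs.intersect_hits({"x": a, "y": set(a)})
        row = table[table["sets"] == "x&y"]
        assert row["n_intersection"].iloc[0] == 2
        table2 = cs.intersect_hits({"x": a, "y": {("chr2", 0, 50_000)}})
        assert table2[table2["sets"] == "x&y"]["n_intersection"].iloc[0] == 0

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        universe = [("chr1", int(s), int(s) + 50_000) for s in range(0, 400 * 25_000, 25_000)]
        sets = {
            name: {universe[i] for i in rng.choice(len(universe), 303, replace=False)}
            for name in ("fst", "xpehh", "dcms")
        }
        table = cs.intersect_hits(sets)
        for _, row in table.iterrows():
            names = row["sets"].split("&")
            inter = set.intersection(*(sets[n] for n in names))
            assert row["n_intersection"] == len(inter)
            others = set().union(*(sets[n] for n in sets if n not in names))
            assert row["n_exclusive"] == len(inter - others)
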