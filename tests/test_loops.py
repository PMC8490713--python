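"""Loop calling: diagonal fits, NB tails, BH, union, differential, APA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cohloop as cl
from cohloop.loops import fit_diagonal, pixel_pvalue, write_bedpe, read_bedpe


def nb_tail_bruteforce(r, mu, x, upto=5000):
    """Independent oracle: sum the NB PMF from x upward."""
    p = r / (r + mu)
    ks = np.arange(x, upto)
    return float(stats.nbinom.pmf(ks, r, p).sum())


def poisson_tail_bruteforce(mu, x, upto=5000):
    ks = np.arange(x, upto)
    return float(stats.poisson.pmf(ks, mu).sum())


class TestDiagonalFit:
    def test_constant_counts_force_poisson_fallback(self):
        model = fit_diagonal(np.full(20, 5.0), distance=3)
        assert model.is_poisson
        assert model.mean == 5.0

    def test_moment_closed_form(self):
        # sample mean 5, population variance 10 -> r = 25/5 = 5
        counts = np.array([5 - math.sqrt(10), 5 + math.sqrt(10)])
        model = fit_diagonal(counts, distance=2)
        assert model.mean == pytest.approx(5.0)
        assert model.dispersion_size == pytest.approx(5.0)

    def test_underdispersed_counts_fall_back_to_poisson(self):
        model = fit_diagonal(np.array([4.0, 5.0, 6.0, 5.0]), distance=2)
        assert model.is_poisson


class TestPixelPvalue:
    def test_zero_count_has_pvalue_one(self):
        model = fit_diagonal(np.array([1.0, 3.0, 9.0, 2.0]), distance=2)
        assert pixel_pvalue(model, 0) == 1.0

    @pytest.mark.parametrize("mu,x", [(5.0, 10), (0.5, 3), (20.0, 35)])
    def test_poisson_tail_matches_bruteforce(self, mu, x):
        model = cl.DiagonalModel(2, 100, mu, mu, math.inf)
        assert pixel_pvalue(model, x) == pytest.approx(
            poisson_tail_bruteforce(mu, x), abs=1e-12)
        assert pixel_pvalue(model, x) == pytest.approx(
            1 - stats.poisson.cdf(x - 1, mu), abs=1e-12)

    @pytest.mark.parametrize("r,mu,x", [(5.0, 5.0, 20), (2.0, 10.0, 40),
                                        (50.0, 3.0, 9)])
    def test_nb_tail_matches_bruteforce(self, r, mu, x):
        model = cl.DiagonalModel(2, 100, mu, mu + mu * mu / r, r)
        assert pixel_pvalue(model, x) == pytest.approx(
            nb_tail_bruteforce(r, mu, x), abs=1e-9)


class TestCallLoops:
    def test_null_matrix_yields_no_or_few_loops(self, null_sim):
        _, _, _, matrix = null_sim
        caller = cl.LoopCaller().fit(matrix)
        assert len(caller.loops_) / max(caller.n_tested_, 1) <= 0.1

    def test_planted_loops_recovered(self, planted_sim):
        cfg, truth, matrix, called = planted_sim
        called_set = set(zip(called["chrom"], called["bin1"], called["bin2"]))
        by_enr = {4.0: [], 8.0: []}
        for lp in truth.loops:
            by_enr[lp.enrichment["A"]].append(
                (lp.chrom, lp.bin1, lp.bin2) in called_set)
        assert np.mean(by_enr[4.0]) >= 0.8
        assert np.mean(by_enr[8.0]) >= 0.95

    def test_cpm_gate_excludes_significant_but_weak_pixels(self):
        """A pixel can clear FDR yet fail CPM>threshold and must be dropped."""
        sizes = {"chr1": 20_000_000}
        mat = cl.ContactMatrix(20_000, sizes, total_depth=10_000_000)
        rng = np.random.default_rng(0)
        n = mat.n_bins("chr1")
        for d in range(2, 10):
            i = np.arange(n - d)
            mat.add_pixels("chr1", i, i + d,
                           rng.poisson(20.0, size=n - d).astype(np.int64))
        mat.add_pixels("chr1", np.array([10]), np.array([14]), np.array([40]))
        caller = cl.LoopCaller(min_dist=2, max_dist=9, cpm_threshold=30.0).fit(mat)
        px = caller.pixels_.set_index(["chrom", "bin1", "bin2"])
        spike = px.loc[("chr1", 10, 14)]
        assert spike["fdr"] < 0.1
        assert spike["cpm"] < 30.0  # 60 counts / 1e7 depth = 6 CPM
        keys = set(zip(caller.loops_["chrom"], caller.loops_["bin1"],
                       caller.loops_["bin2"]))
        assert ("chr1", 10, 14) not in keys

    def test_bh_adjustment_dominates_pvalue_and_is_monotone(self, planted_sim):
        _, _, _, called = planted_sim
        assert (called["fdr"] >= called["pvalue"]).all()
        srt = called.sort_values("pvalue")
        assert (np.diff(srt["fdr"].to_numpy()) >= -1e-12).all()

    def test_invalid_distance_range_rejected(self, null_sim):
        _, _, _, matrix = null_sim
        with pytest.raises(ValueError):
            cl.LoopCaller(min_dist=0).fit(matrix)
        with pytest.raises(ValueError):
            cl.LoopCaller(min_dist=5, max_dist=5).fit(matrix)


class TestUnionAndDifferential:
    def frame(self, keys, res=20_000):
        df = pd.DataFrame(keys, columns=["chrom", "bin1", "bin2"])
        df.attrs["resolution"] = res
        return df

    def test_disjoint_union(self):
        a = self.frame([("chr1", 1, 5), ("chr1", 2, 8), ("chr2", 3, 9)])
        b = self.frame([("chr1", 4, 9), ("chr2", 1, 7), ("chr2", 2, 8),
                        ("chr2", 5, 11)])
        u = cl.union_loops(a, b)
        assert len(u) == 7
        assert set(u["source"]) == {"a", "b"}

    def test_identical_sets_idempotent(self):
        a = self.frame([("chr1", 1, 5), ("chr1", 2, 8)])
        u = cl.union_loops(a, a)
        assert len(u) == 2
        assert (u["source"] == "both").all()

    def test_resolution_mismatch_rejected(self):
        a = self.frame([("chr1", 1, 5)], res=20_000)
        b = self.frame([("chr1", 1, 5)], res=100_000)
        with pytest.raises(ValueError, match="resolution"):
            cl.union_loops(a, b)

    def test_log2fc_closed_forms(self):
        sizes = {"chr1": 200_000}
        ma = cl.ContactMatrix(20_000, sizes, total_depth=1_000_000)
        mb = cl.ContactMatrix(20_000, sizes, total_depth=1_000_000)
        ma.add_pixels("chr1", np.array([0, 1]), np.array([3, 4]),
                      np.array([60, 60]))
        mb.add_pixels("chr1", np.array([0, 1]), np.array([3, 4]),
                      np.array([30, 60]))
        union = self.frame([("chr1", 0, 3), ("chr1", 1, 4)])
        diff = cl.differential_loops(union, ma, mb, pseudocount=0.0)
        assert diff["log2fc"].tolist() == pytest.approx([1.0, 0.0])
        # zero CPM in one sample stays finite with the pseudocount
        mb2 = cl.ContactMatrix(20_000, sizes, total_depth=1_000_000)
        diff2 = cl.differential_loops(self.frame([("chr1", 0, 3)]), ma, mb2,
                                      pseudocount=1.0)
        assert diff2["log2fc"].iloc[0] == pytest.approx(math.log2(61), abs=1e-9)

    def test_swapping_samples_negates_exactly(self, planted_sim):
        cfg, truth, matrix, called = planted_sim
        union = cl.union_loops(called, called)
        fwd = cl.differential_loops(union, matrix, matrix)
        assert (fwd["log2fc"] == 0).all()


class TestAPA:
    def test_loop_near_edge_excluded(self):
        sizes = {"chr1": 400_000}  # 20 bins
        mat = cl.ContactMatrix(20_000, sizes, total_depth=1000)
        rng = np.random.default_rng(0)
        n = 20
        for d in range(0, n):
            i = np.arange(n - d)
            mat.add_pixels("chr1", i, i + d,
                           rng.poisson(5, n - d).astype(np.int64))
        loops = pd.DataFrame([("chr1", 2, 16)], columns=["chrom", "bin1", "bin2"])
        with pytest.raises(ValueError, match="eligible"):
            cl.aggregate_peak_analysis(mat, loops, half_window=5)

    def test_planted_loops_score_above_random_anchors(self):
        rng = np.random.default_rng(4)
        anchors = []
        while len(anchors) < 50:
            b1 = int(rng.integers(15, 940))
            d = int(rng.integers(15, 41))
            anchors.append(("chr1" if len(anchors) % 2 else "chr2", b1, b1 + d))
        random_loops = pd.DataFrame(anchors, columns=["chrom", "bin1", "bin2"])
        cfg0 = cl.default_toy_config(depth=2_000_000, seed=14)
        pairs0, _ = cl.simulate_contacts(cfg0, "A")
        null_matrix = cl.bin_pairs(pairs0, cfg0.chrom_sizes, cfg0.resolution)
        _, null_score = cl.aggregate_peak_analysis(null_matrix, random_loops)
        assert null_score == pytest.approx(1.0, abs=0.2)

        planted = [cl.PlantedLoop(c, b1, b2, {"A": 8.0}) for c, b1, b2 in anchors]
        cfg = cl.default_toy_config(depth=2_000_000, seed=13,
                                    planted_loops=planted)
        pairs, _ = cl.simulate_contacts(cfg, "A")
        mat = cl.bin_pairs(pairs, cfg.chrom_sizes, cfg.resolution)
        _, score = cl.aggregate_peak_analysis(mat, random_loops)
        assert score > 1.5


def test_bedpe_round_trip(tmp_path, planted_sim):
    _, _, _, called = planted_sim
    path = tmp_path / "loops.bedpe"
    write_bedpe(called, path)
    again = read_bedpe(path)
    assert again[["chrom", "bin1", "bin2"]].equals(
        called[["chrom", "bin1", "bin2"]].reset_index(drop=True))
    assert again["cpm"].to_numpy() == pytest.approx(called["cpm"].to_numpy())
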