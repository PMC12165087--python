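import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introkit import fstats
from introkit.errors import InsufficientDataError
from introkit.genio import MISSING, GenomicWindow, PopulationMap, SVRecord

from . import oracles
from .conftest import make_panel


def window(start, end):
    return GenomicWindow("chr1", start, end)


def quartet(p1, p2, p3, po, positions=None):
    p1, p2, p3, po = (np.asarray(x, dtype=float) for x in (p1, p2, p3, po))
    if positions is None:
        positions = np.arange(1, p1.size + 1)
    return fstats.QuartetFreqs(p1, p2, p3, po, np.asarray(positions))


class TestWindowDstats:
    def test_symmetric_p1_p2_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        q = quartet(p, p, rng.random(30), np.zeros(30))
        d, fd, n = fstats.window_dstats(q, window(0, 100), min_sites=1)
        assert d == pytest.approx(0.0)
        assert fd == pytest.approx(0.0)

    def test_single_fixed_abba_site(self):
        q = quartet([0.0], [1.0], [1.0], [0.0])
        d, fd, _ = fstats.window_dstats(q, window(0, 10), min_sites=1)
        assert d == pytest.approx(1.0)
        assert fd == pytest.approx(1.0)

    def test_two_site_worked_example(self):
        # frozen from direct evaluation of the ABBA/BABA sums
        q = quartet([0.2, 0.5], [0.8, 0.5], [0.5, 0.5], [0.0, 0.0])
        d, fd, _ = fstats.window_dstats(q, window(0, 10), min_sites=1)
        assert d == pytest.approx(0.3 / 0.59)
        assert fd == pytest.approx(0.625)

    def test_fd_zeroed_when_d_negative(self):
        q = quartet([0.9], [0.1], [0.8], [0.0])
        d, fd, _ = fstats.window_dstats(q, window(0, 10), min_sites=1)
        assert d < 0
        assert fd == 0.0

    def test_min_sites_gate(self):
        q = quartet([0.2] * 5, [0.8] * 5, [0.5] * 5, [0.0] * 5)
        d, fd, n = fstats.window_dstats(q, window(0, 10), min_sites=10)
        assert np.isnan(d) and np.isnan(fd)
        assert n == 5

    def test_zero_denominator_is_missing_not_error(self):
        q = quartet([0.5], [0.5], [0.0], [0.0])  # p3 = 0 -> no weight
        d, fd, _ = fstats.window_dstats(q, window(0, 10), min_sites=1)
        assert np.isnan(d)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_direct_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        p1, p2, p3 = rng.random((3, n))
        po = rng.choice([0.0, 0.1, 0.9, 1.0], n)
        q = quartet(p1, p2, p3, po)
        d, fd, _ = fstats.window_dstats(q, window(0, n + 1), min_sites=1)
        d_o, fd_o = oracles.dstat_direct(p1, p2, p3, po)
        if np.isnan(d_o):
            assert np.isnan(d)
        else:
            assert d == pytest.approx(d_o, abs=1e-12)
            if np.isnan(fd_o):
                assert np.isnan(fd)
            else:
                assert fd == pytest.approx(fd_o, abs=1e-12)


class TestJackknife:
    def test_identical_blocks_inf_sentinel(self):
        z = fstats.jackknife_z(np.full(10, 0.3), np.ones(10))
        assert z == np.inf

    def test_symmetric_blocks_near_zero(self):
        d = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        z = fstats.jackknife_z(d, np.ones(5))
        assert abs(z) < 1e-12

    def test_matches_delete_one_oracle(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.1, 0.05, 20)
        w = np.ones(20)
        assert fstats.jackknife_z(d, w) == pytest.approx(
            oracles.jackknife_direct(d), abs=1e-10
        )

    def test_weighted_matches_weighted_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.05, 0.1, 12)
        w = rng.uniform(0.5, 2.0, 12)
        assert fstats.jackknife_z(d, w) == pytest.approx(
            oracles.jackknife_direct(d, w), abs=1e-10
        )

    def test_too_few_blocks(self):
        with pytest.raises(InsufficientDataError):
            fstats.jackknife_z(np.array([0.1] * 4), np.ones(4))

    def test_nan_blocks_dropped(self):
        d = np.array([0.1, 0.2, np.nan, 0.15, 0.12, 0.18])
        z = fstats.jackknife_z(d, np.ones(6))
        z_ref = fstats.jackknife_z(d[~np.isnan(d)], np.ones(5))
        assert z == pytest.approx(z_ref)


class TestF4Ratio:
    def test_x_equals_b_gives_one(self):
        rng = np.random.default_rng(3)
        pa, po, pb, pc = rng.random((4, 50))
        assert fstats.f4_ratio(pa, po, pb, pb, pc) == pytest.approx(1.0)

    def test_x_equals_c_gives_zero(self):
        rng = np.random.default_rng(4)
        pa, po, pb, pc = rng.random((4, 50))
        assert fstats.f4_ratio(pa, po, pc, pb, pc) == pytest.approx(0.0)

    def test_degenerate_denominator_missing(self):
        p = np.full(10, 0.5)
        assert np.isnan(fstats.f4_ratio(p, p, p, p, p))

    def test_linear_mixture_recovered_exactly(self):
        rng = np.random.default_rng(5)
        pa, po, pb, pc = rng.random((4, 200))
        for alpha in (0.1, 0.45, 0.9):
            px = alpha * pb + (1 - alpha) * pc
            assert fstats.f4_ratio(pa, po, px, pb, pc) == pytest.approx(alpha)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        f = fstats.wc_fst(np.array([10.0, 10.0]), np.array([1.0, 0.0]), np.zeros(2))
        assert f == pytest.approx(1.0)

    def test_identical_hwe_populations_near_zero(self):
        # the finite-sample WC84 value for identical HWE populations is
        # exactly -1/(2(n-1)), which vanishes as n grows
        p = 0.3
        h = 2 * p * (1 - p)
        for n in (50.0, 500.0):
            f = fstats.wc_fst(np.array([n, n]), np.array([p, p]), np.array([h, h]))
            assert f == pytest.approx(-1.0 / (2 * (n - 1)), abs=1e-12)
        assert abs(f) < 2e-3

    def test_worked_example_components(self):
        # n1 = n2 = 10 diploids, p = 0.8 / 0.2, HWE heterozygosity
        n = np.array([10.0, 10.0])
        p = np.array([0.8, 0.2])
        h = np.array([0.32, 0.32])
        a, b, c = fstats.wc_fst_components(n, p, h)
        assert a == pytest.approx(0.17111, abs=1e-5)
        assert b == pytest.approx(0.00889, abs=1e-5)
        assert c == pytest.approx(0.16, abs=1e-12)
        assert fstats.wc_fst(n, p, h) == pytest.approx(0.5033, abs=1e-4)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = int(rng.integers(2, 5))
        n = rng.integers(2, 50, r).astype(float)
        p = rng.random(r)
        h = np.minimum(rng.random(r), 2 * p * (1 - p))
        a, b, c = fstats.wc_fst_components(n, p, h)
        a_o, b_o, c_o, theta_o = oracles.wc_fst_direct(n, p, h)
        assert a == pytest.approx(a_o, abs=1e-12)
        assert b == pytest.approx(b_o, abs=1e-12)
        assert c == pytest.approx(c_o, abs=1e-12)
        got = fstats.wc_fst(n, p, h)
        if np.isnan(theta_o):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(theta_o, abs=1e-12)


class TestFstScan:
    def test_windowed_ratio_of_sums(self):
        # two populations of 2 diploids each over 4 sites
        alleles = np.array(
            [
                [1, 1, 0, 1],
                [1, 0, 0, 1],
                [1, 1, 0, 1],
                [1, 0, 1, 0],
                [0, 0, 0, 0],
                [0, 1, 0, 0],
                [0, 0, 0, 1],
                [0, 1, 1, 0],
            ],
            dtype=np.int8,
        )
        panel = make_panel(alleles, positions=[10, 20, 30, 40])
        popmap = PopulationMap(
            assignments={"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"}
        )
        df = fstats.fst_scan(panel, popmap, ["X", "Y"], [window(0, 100)])
        # oracle: component sums over usable polymorphic sites
        num = den = 0.0
        for j in range(4):
            stats = []
            for rows in ([0, 1, 2, 3], [4, 5, 6, 7]):
                alle = alleles[rows, j]
                dip = alle.reshape(2, 2)
                p = alle.mean()
                het = float(np.mean(dip.sum(axis=1) == 1))
                stats.append((2.0, p, het))
            pooled = (stats[0][1] + stats[1][1]) / 2
            if pooled in (0.0, 1.0):
                continue
            a, b, c, _ = oracles.wc_fst_direct(
                [s[0] for s in stats], [s[1] for s in stats], [s[2] for s in stats]
            )
            num += a
            den += a + b + c
        assert df.fst_raw[0] == pytest.approx(num / den, abs=1e-12)

    def test_negative_estimates_floored_for_reporting(self):
        # both populations: one 0/0 and one 1/1 diploid (p = 0.5, no hets)
        alleles = np.array(
            [[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [0, 0], [1, 1], [1, 1]],
            dtype=np.int8,
        )
        panel = make_panel(alleles, positions=[10, 20])
        popmap = PopulationMap(
            assignments={"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"}
        )
        df = fstats.fst_scan(panel, popmap, ["X", "Y"], [window(0, 100)])
        assert df.fst_raw[0] < 0
        assert df.fst[0] == 0.0


class TestSvSnpMaxR2:
    def _sv(self, genos, pos=500, end=600):
        return SVRecord(
            sv_id="sv",
            svtype="DEL",
            chrom="chr1",
            pos=pos,
            end=end,
            genotypes=np.array(genos, dtype=np.int8),
            sample_ids=[f"s{i}" for i in range(len(genos))],
        )

    def _panel_from_dosages(self, columns, positions):
        """columns: list of per-sample dosage vectors, one per SNP."""
        cols = []
        for dos in columns:
            hapcol = []
            for d in dos:
                hapcol.extend([1, 1] if d == 2 else [1, 0] if d == 1 else [0, 0])
            cols.append(hapcol)
        alleles = np.array(cols, dtype=np.int8).T
        return make_panel(alleles, positions=positions)

    def test_identical_dosages_r2_one(self):
        sv = self._sv([0, 1, 2, 0, 1, 2])
        panel = self._panel_from_dosages([[0, 1, 2, 0, 1, 2]], [550])
        r2, best = fstats.sv_snp_max_r2(sv, panel)
        assert r2 == pytest.approx(1.0)
        assert best == 550

    def test_monomorphic_sv_missing(self):
        sv = self._sv([1, 1, 1, 1, 1, 1])
        panel = self._panel_from_dosages([[0, 1, 2, 0, 1, 2]], [550])
        r2, best = fstats.sv_snp_max_r2(sv, panel)
        assert np.isnan(r2) and best is None

    def test_worked_example_and_max_over_flank(self):
        sv = self._sv([0, 1, 2, 0, 1, 2])
        panel = self._panel_from_dosages(
            [[0, 0, 1, 0, 0, 1], [0, 1, 1, 0, 1, 2], [2, 2, 2, 2, 2, 2]],
            [100, 550, 900],
        )
        r2, best = fstats.sv_snp_max_r2(sv, panel)
        assert best == 550
        assert r2 == pytest.approx(
            oracles.pearson_r2([0, 1, 2, 0, 1, 2], [0, 1, 1, 0, 1, 2]), abs=1e-12
        )
        assert r2 == pytest.approx(0.794, abs=1e-3)

    def test_no_snp_in_flank(self):
        sv = self._sv([0, 1, 2, 0, 1, 2], pos=500_000, end=500_100)
        panel = self._panel_from_dosages([[0, 1, 2, 0, 1, 2]], [100])
        r2, best = fstats.sv_snp_max_r2(sv, panel, flank=1000)
        assert np.isnan(r2) and best is None

    def test_tie_breaks_to_smallest_position(self):
        sv = self._sv([0, 1, 2, 0, 1, 2])
        panel = self._panel_from_dosages(
            [[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2]], [400, 700]
        )
        _, best = fstats.sv_snp_max_r2(sv, panel)
        assert best == 400


class TestQuartetFreqs:
    def test_polarization_band_drops_ambiguous_sites(self):
        # outgroup freqs: 0.0 keep, 0.5 drop, 1.0 keep-and-flip
        alleles = np.array(
            [
                # P1 haps
                [1, 0, 0],
                [1, 0, 0],
                # P2 haps
                [0, 1, 1],
                [0, 1, 1],
                # P3 haps
                [1, 1, 0],
                [0, 1, 0],
                # OUT haps
                [0, 0, 1],
                [0, 1, 1],
            ],
            dtype=np.int8,
        )
        panel = make_panel(alleles, positions=[10, 20, 30])
        popmap = PopulationMap(
            assignments={"s0": "P1", "s1": "P2", "s2": "P3", "s3": "O"}
        )
        q = fstats.quartet_freqs(panel, popmap, "P1", "P2", "P3", "O")
        assert list(q.positions) == [10, 30]
        # site 30: outgroup freq 1.0 -> flipped, derived freq of P2 = 0
        assert q.p2[1] == pytest.approx(0.0)
        assert q.p_out[1] == pytest.approx(0.0)


class TestFdPulseInvariant:
    def test_fd_elevated_on_truth_windows(self):
        # pooled across replicates, mean f_d over truth-tract windows exceeds
        # the mean over tract-free windows (per-replicate the comparison can
        # be vacuous when surviving tracts blanket the chromosome)
        from introkit.genio import make_windows
        from introkit.pipeline import pulse_config, truth_union
        from introkit.simdata import combined_panel, simulate_history

        fd_truth, fd_clean = [], []
        for seed in range(1, 5):
            cfg = pulse_config(seed, chromosome_length=5_000_000, n_sites=6_000)
            panels, tracts = simulate_history(cfg)
            panel, popmap = combined_panel(panels)
            freqs = fstats.quartet_freqs(panel, popmap, "W_B", "P_B", "P_A", "OUT")
            tu = truth_union(
                [t for t in tracts if t.recipient_sample.startswith("P_B")]
            )
            for w in make_windows(5_000_000):
                _, fd, _ = fstats.window_dstats(freqs, w)
                if np.isnan(fd):
                    continue
                hit = any(w.start < e and s < w.end for s, e in tu)
                (fd_truth if hit else fd_clean).append(fd)
        assert len(fd_truth) > 50 and len(fd_clean) > 50
        assert np.mean(fd_truth) > np.mean(fd_clean)
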