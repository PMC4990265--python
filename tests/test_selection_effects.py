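"""Lookup tables vs naive per-position oracles; closed-form kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkedsel.genome_data import GeneticMap, NeutralSiteTable, SubstitutionSet
from linkedsel.selection_effects import (
    EffectiveSizeContext,
    SelectionGrid,
    bs_exponent_single,
    bs_factor,
    build_bs_lookup,
    build_sweep_lookup,
    fixation_time,
    load_lookups,
    save_lookups,
    sweep_rate_scaled,
)

EULER = 0.5772156649015329


def naive_bs(table, annotations, grid, gmap):
    """Independent double-loop oracle for the BS lookup."""
    out = np.zeros((len(table), grid.n_t, len(annotations.classes)))
    for x in range(len(table)):
        chrom = str(table.chrom[x])
        for ci, cls_ in enumerate(annotations.classes):
            for blk_chrom, arr in annotations.intervals[cls_].items():
                if blk_chrom != chrom:
                    continue
                for s, e in arr:
                    for y in range(s, e):
                        r = abs(gmap.cum_morgans(chrom, table.pos[x])
                                - gmap.cum_morgans(chrom, y))
                        for gi, t in enumerate(grid.t_values):
                            out[x, gi, ci] += t / (t + r * (1 - t)) ** 2
    return out


def naive_sweep(table, subs, grid, gmap, ctx):
    """Independent double-loop oracle for the sweep lookup."""
    taus = [2 * (np.log(4 * ctx.Ne * s) + EULER - 1 / (4 * ctx.Ne * s)) / s
            for s in grid.s_values]
    out = np.zeros((len(table), grid.n_s, len(subs.classes)))
    for x in range(len(table)):
        chrom = str(table.chrom[x])
        for ci, cls_ in enumerate(subs.classes):
            for sub_chrom, poss in subs.positions[cls_].items():
                if sub_chrom != chrom:
                    continue
                for y in poss:
                    r = abs(gmap.cum_morgans(chrom, table.pos[x])
                            - gmap.cum_morgans(chrom, int(y)))
                    for ki, tau in enumerate(taus):
                        out[x, ki, ci] += np.exp(-r * tau)
    return out


class TestKernels:
    def test_bs_exponent_closed_form(self):
        t = 10 ** -3.5
        assert bs_exponent_single(t, 1e-3) == pytest.approx(182.619273, rel=1e-8)
        assert bs_exponent_single(0.01, 0.0) == pytest.approx(100.0)
        # with u_d = 1e-8 the exponent is u_d / t at r = 0
        assert 1e-8 * bs_exponent_single(0.01, 0.0) == pytest.approx(1e-6)

    def test_bs_exponent_decreasing_in_r(self):
        r = np.linspace(0, 0.01, 100)
        v = bs_exponent_single(3e-4, r)
        assert np.all(np.diff(v) < 0)

    def test_bs_exponent_domain(self):
        with pytest.raises(ValueError):
            bs_exponent_single(0.0, 0.1)
        with pytest.raises(ValueError):
            bs_exponent_single(-0.1, 0.1)

    @pytest.mark.parametrize("s,Ne,expect", [
        (0.01, 1e6, 2234.765080),
        (10 ** -1.5, 1e6, 779.509984),
        (1e-4, 1e6, 131323.604240),
    ])
    def test_fixation_time_values(self, s, Ne, expect):
        assert fixation_time(s, Ne) == pytest.approx(expect, rel=1e-9)

    def test_fixation_time_matches_formula_to_machine_precision(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = 10 ** rng.uniform(-4.5, -1)
            Ne = 10 ** rng.uniform(5, 7)
            x = 4 * Ne * s
            expect = 2 * (np.log(x) + EULER - 1 / x) / s
            assert fixation_time(s, Ne) == pytest.approx(expect, rel=1e-15)

    def test_fixation_time_monotone_decreasing(self):
        s = np.logspace(-5, -1, 200)
        Ne = 1e6
        s = s[4 * Ne * s >= 10]
        tau = fixation_time(s, Ne)
        assert np.all(np.diff(tau) < 0)

    def test_fixation_time_domain(self):
        with pytest.raises(ValueError):
            fixation_time(1e-8, 1e6)   # 4 Ne s <= 1
        with pytest.warns(RuntimeWarning):
            fixation_time(5e-7, 1e6)   # 4 Ne s = 2 < 10


class TestOracleEquivalence:
    def test_bs_lookup_matches_double_loop(self, sparse_toy, grid):
        lk = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                             grid, sparse_toy["gmap"], method="exact",
                             eps_trunc=0.0)
        oracle = naive_bs(sparse_toy["table"], sparse_toy["annotations"],
                          grid, sparse_toy["gmap"])
        np.testing.assert_allclose(lk.b, oracle, rtol=1e-12)

    def test_sweep_lookup_matches_double_loop(self, sparse_toy, grid, ctx):
        lk = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                sparse_toy["gmap"], ctx, method="exact",
                                eps_trunc=0.0)
        oracle = naive_sweep(sparse_toy["table"], sparse_toy["subs"], grid,
                             sparse_toy["gmap"], ctx)
        np.testing.assert_allclose(lk.s, oracle, rtol=1e-12, atol=1e-300)

    def test_default_truncation_error_below_1e6(self, sparse_toy, grid, ctx):
        bs0 = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                              grid, sparse_toy["gmap"], method="exact",
                              eps_trunc=0.0)
        bs1 = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                              grid, sparse_toy["gmap"], method="exact")
        # truncation drops per-position contributions < eps = 1e-10, so the
        # absolute error is bounded by eps * (selected positions); entries
        # above a floor comfortably clearing that bound must agree to 1e-6
        mask = bs0.b > 1.0     # floor >> 1e-10 * 8e3 selected bp
        rel = np.abs(bs1.b - bs0.b)[mask] / bs0.b[mask]
        assert rel.max() < 1e-6
        sw0 = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                 sparse_toy["gmap"], ctx, method="exact",
                                 eps_trunc=0.0)
        sw1 = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                 sparse_toy["gmap"], ctx, method="exact")
        mask = sw0.s > 1e-3    # floor >> 1e-10 * 5 substitutions
        rel = np.abs(sw1.s - sw0.s)[mask] / sw0.s[mask]
        assert rel.max() < 1e-6

    def test_binned_path_tracks_exact_path(self, sparse_toy, grid, ctx):
        bs_e = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                               grid, sparse_toy["gmap"], method="exact",
                               eps_trunc=0.0)
        bs_b = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                               grid, sparse_toy["gmap"], method="binned",
                               eps_trunc=0.0)
        rel = np.abs(bs_b.b - bs_e.b) / np.maximum(bs_e.b, 1e-30)
        assert np.median(rel[bs_e.b > 0]) < 5e-3
        assert rel[bs_e.b > 0].max() < 0.05
        sw_e = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                  sparse_toy["gmap"], ctx, method="exact",
                                  eps_trunc=0.0)
        sw_b = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                  sparse_toy["gmap"], ctx, method="binned",
                                  eps_trunc=0.0)
        # kernel-tail entries (tiny s) have large relative but tiny absolute
        # error with a lone substitution; meaningful entries track closely
        assert np.abs(sw_b.s - sw_e.s).max() < 0.01
        mask = sw_e.s > 0.05
        rel = np.abs(sw_b.s - sw_e.s)[mask] / sw_e.s[mask]
        assert np.median(rel) < 1e-2
        assert rel.max() < 0.05


class TestLookupStructure:
    def test_single_block_example(self, grid):
        # one 100 bp block at r ~ 0.001 M from the focal site:
        # b ~ 100 * 182.62 (the per-position kernel), site on a 1 cM/Mb map
        gmap = GeneticMap.from_rates({"c": (np.array([0.0]), np.array([3e5]),
                                            np.array([1.0]))})
        from linkedsel.genome_data import AnnotationSet, GenomicInterval
        ann = AnnotationSet.from_records(
            [GenomicInterval("c", 200_000, 200_100, "coding")], ["coding"])
        table = NeutralSiteTable.from_arrays(
            np.array(["c"], dtype=object), np.array([100_000]),
            np.array([0]), np.array([1]))
        lk = build_bs_lookup(table, ann, grid, gmap, method="exact",
                             eps_trunc=0.0)
        gi = int(np.argmin(np.abs(grid.t_values - 10 ** -3.5)))
        # distances span 0.001 .. 0.001001 M; compare against the direct sum
        t = grid.t_values[gi]
        r = (np.arange(200_000, 200_100) - 100_000) * 1e-8
        expect = np.sum(t / (t + r * (1 - t)) ** 2)
        assert lk.b[0, gi, 0] == pytest.approx(expect, rel=1e-12)
        assert lk.b[0, gi, 0] == pytest.approx(18262, rel=1e-3)

    def test_no_selected_sites_on_chromosome(self, grid, ctx):
        gmap = GeneticMap.from_rates({
            "a": (np.array([0.0]), np.array([1e5]), np.array([1.0])),
            "b": (np.array([0.0]), np.array([1e5]), np.array([1.0]))})
        from linkedsel.genome_data import AnnotationSet, GenomicInterval
        ann = AnnotationSet.from_records(
            [GenomicInterval("b", 0, 100, "coding")], ["coding"])
        subs = SubstitutionSet.from_records([("b", 50, "nonsyn")], ["nonsyn"])
        table = NeutralSiteTable.from_arrays(
            np.array(["a"], dtype=object), np.array([500]),
            np.array([0]), np.array([1]))
        bs = build_bs_lookup(table, ann, grid, gmap, method="exact")
        sw = build_sweep_lookup(table, subs, grid, gmap, ctx, method="exact")
        assert np.all(bs.b == 0.0)
        assert np.all(sw.s == 0.0)
        assert bs_factor(np.full((grid.n_t, 1), 1e-8), bs)[0] == 1.0

    def test_two_blocks_additive(self, grid):
        from linkedsel.genome_data import AnnotationSet, GenomicInterval
        gmap = GeneticMap.from_rates({"c": (np.array([0.0]), np.array([1e6]),
                                            np.array([2.0]))})
        table = NeutralSiteTable.from_arrays(
            np.array(["c"], dtype=object), np.array([500_000]),
            np.array([0]), np.array([1]))
        blocks = [(100_000, 101_000), (800_000, 800_500)]
        lks = []
        for blk in [blocks[:1], blocks[1:], blocks]:
            ann = AnnotationSet.from_records(
                [GenomicInterval("c", s, e, "coding") for s, e in blk],
                ["coding"])
            lks.append(build_bs_lookup(table, ann, grid, gmap, method="exact",
                                       eps_trunc=0.0))
        np.testing.assert_allclose(lks[0].b + lks[1].b, lks[2].b, rtol=1e-12)

    def test_substitution_at_focal_site(self, grid, ctx, const_map):
        subs = SubstitutionSet.from_records([("chr1", 1000, "nonsyn")],
                                            ["nonsyn"])
        table = NeutralSiteTable.from_arrays(
            np.array(["chr1"], dtype=object), np.array([1000]),
            np.array([0]), np.array([1]))
        lk = build_sweep_lookup(table, subs, grid, const_map, ctx,
                                method="exact")
        assert np.allclose(lk.s[0, :, 0], 1.0)
        lkb = build_sweep_lookup(table, subs, grid, const_map, ctx,
                                 method="binned")
        # the binned path places the focal substitution at half the first
        # bin width (5e-10 M), a relative error below tau * 5e-10
        assert np.allclose(lkb.s[0, :, 0], 1.0, atol=2e-3)

    def test_sweep_kernel_value(self, grid, ctx):
        # substitution at r = 1e-3 M, s = 0.01 (tau = 2234.77): e^{-2.23477}
        gmap = GeneticMap.from_rates({"c": (np.array([0.0]), np.array([2e5]),
                                            np.array([1.0]))})
        subs = SubstitutionSet.from_records([("c", 150_000, "nonsyn")],
                                            ["nonsyn"])
        table = NeutralSiteTable.from_arrays(
            np.array(["c"], dtype=object), np.array([50_000]),
            np.array([0]), np.array([1]))
        g2 = SelectionGrid(t_values=np.array([0.01]), s_values=np.array([0.01]))
        lk = build_sweep_lookup(table, subs, g2, gmap, ctx, method="exact",
                                eps_trunc=0.0)
        assert lk.s[0, 0, 0] == pytest.approx(0.10701727, rel=1e-6)

    def test_moving_element_away_monotone(self, grid, ctx):
        from linkedsel.genome_data import AnnotationSet, GenomicInterval
        gmap = GeneticMap.from_rates({"c": (np.array([0.0]), np.array([5e6]),
                                            np.array([2.0]))})
        table = NeutralSiteTable.from_arrays(
            np.array(["c"], dtype=object), np.array([0]),
            np.array([0]), np.array([1]))
        prev_b, prev_s = None, None
        for offset in [10_000, 50_000, 200_000, 1_000_000, 4_000_000]:
            ann = AnnotationSet.from_records(
                [GenomicInterval("c", offset, offset + 1000, "coding")],
                ["coding"])
            subs = SubstitutionSet.from_records([("c", offset, "nonsyn")],
                                                ["nonsyn"])
            bs = build_bs_lookup(table, ann, grid, gmap, method="exact",
                                 eps_trunc=0.0)
            sw = build_sweep_lookup(table, subs, grid, gmap, ctx,
                                    method="exact", eps_trunc=0.0)
            B = bs_factor(np.full((grid.n_t, 1), 1e-8), bs)[0]
            S = sweep_rate_scaled(np.full((grid.n_s, 1), 0.1), sw, 0.02, 0.1)[0]
            if prev_b is not None:
                assert B >= prev_b      # farther away never decreases B
                assert S <= prev_s      # and never increases the sweep rate
            prev_b, prev_s = B, S


class TestWeightCombination:
    def test_bs_factor_bounds_and_linearity(self, sparse_toy, grid):
        lk = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                             grid, sparse_toy["gmap"], method="exact")
        w0 = np.zeros((grid.n_t, 2))
        assert np.all(bs_factor(w0, lk) == 1.0)
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1e-8, size=(grid.n_t, 2))
        B = bs_factor(w, lk)
        assert np.all((B > 0) & (B <= 1))
        # doubling the weights squares B (log-linearity)
        np.testing.assert_allclose(bs_factor(2 * w, lk), B ** 2, rtol=1e-12)

    def test_bs_factor_single_term(self):
        lk_b = np.zeros((1, 1, 1))
        lk_b[0, 0, 0] = 18262.0
        from linkedsel.selection_effects import BSLookup
        lk = BSLookup(b=lk_b, classes=["coding"], t_values=np.array([1e-3]),
                      eps_trunc=0.0, method="exact")
        B = bs_factor(np.array([[1e-8]]), lk)
        assert B[0] == pytest.approx(np.exp(-1.8262e-4), rel=1e-10)

    def test_sweep_rate_scaling(self, sparse_toy, grid, ctx):
        lk = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                sparse_toy["gmap"], ctx, method="exact")
        w0 = np.zeros((grid.n_s, 2))
        assert np.all(sweep_rate_scaled(w0, lk, 0.02, 0.1) == 0.0)
        w = np.zeros((grid.n_s, 2))
        w[2, 0] = 0.5
        S1 = sweep_rate_scaled(w, lk, 0.02, 0.1)
        S2 = sweep_rate_scaled(w, lk, 0.01, 0.1)
        np.testing.assert_allclose(S2, 0.5 * S1, rtol=1e-12)
        assert np.all(S1 >= 0)

    def test_sweep_unit_lookup_value(self):
        from linkedsel.selection_effects import SweepLookup
        lk = SweepLookup(s=np.ones((1, 1, 1)), classes=["nonsyn"],
                         s_values=np.array([0.01]),
                         tau_values=np.array([2234.77]), eps_trunc=0.0,
                         method="exact")
        # w = 1, lookup = 1, pi0 = 0.02, k_bar = 0.1 -> (2*0.02/0.1) = 0.4
        assert sweep_rate_scaled(np.array([[1.0]]), lk, 0.02, 0.1)[0] == \
            pytest.approx(0.4)

    def test_weight_constraints_enforced(self, sparse_toy, grid, ctx):
        bs = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"],
                             grid, sparse_toy["gmap"], method="exact")
        sw = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                                sparse_toy["gmap"], ctx, method="exact")
        with pytest.raises(ValueError):
            bs_factor(np.full((grid.n_t, 2), -1e-9), bs)
        w_bad = np.full((grid.n_s, 2), 0.5)   # per-class sum 2.5 > 1
        with pytest.raises(ValueError):
            sweep_rate_scaled(w_bad, sw, 0.02, 0.1)


def test_lookup_persistence_roundtrip(tmp_path, sparse_toy, grid, ctx):
    bs = build_bs_lookup(sparse_toy["table"], sparse_toy["annotations"], grid,
                         sparse_toy["gmap"], method="exact")
    sw = build_sweep_lookup(sparse_toy["table"], sparse_toy["subs"], grid,
                            sparse_toy["gmap"], ctx, method="exact")
    save_lookups(tmp_path / "lk", bs=bs, sweep=sw)
    bs2, sw2 = load_lookups(tmp_path / "lk")
    np.testing.assert_array_equal(bs.b, bs2.b)
    np.testing.assert_array_equal(sw.s, sw2.s)
    assert bs2.classes == bs.classes and sw2.classes == sw.classes
    assert bs2.meta["map_checksum"] == bs.meta["map_checksum"]


@given(st.floats(1e-5, 0.5), st.floats(0.0, 0.1))
@settings(max_examples=100, deadline=None)
def test_bs_exponent_range_property(t, r):
    v = bs_exponent_single(t, r)
    assert 0 < v <= 1 / t + 1e-12
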