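import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import norm

import sweepscan as sw
from sweepscan.haplostats import (STATUS_OK, SiteCurve, ehh_at_site,
                                  ehhs_at_site, ihs_scan, infer_ancestral,
                                  integrate_curve, p_score_from_z, rsb_scan,
                                  xpehh_scan)
from conftest import make_panel
from oracles import ehh_pairwise, ehhs_pairwise


class TestInferAncestral:
    def test_majority_allele_becomes_ancestral(self):
        alleles = np.zeros((10, 1), dtype=np.uint8)
        alleles[:4, 0] = 1            # 60:40 in favour of allele 0
        panel = make_panel(alleles)
        anc, ambiguous = infer_ancestral(panel)
        assert not ambiguous[0]
        np.testing.assert_array_equal(anc.alleles, alleles)
        flipped = make_panel(1 - alleles)  # now allele 1 is the majority
        anc2, _ = infer_ancestral(flipped)
        np.testing.assert_array_equal(anc2.alleles, alleles)

    def test_exact_tie_is_flagged_ambiguous(self):
        alleles = np.zeros((4, 2), dtype=np.uint8)
        alleles[:2, 0] = 1
        alleles[0, 1] = 1
        panel = make_panel(alleles)
        anc, ambiguous = infer_ancestral(panel)
        assert list(ambiguous) == [True, False]
        assert anc.coding == "ancestral"


class TestEhhCurves:
    def test_four_carriers_classes_2_1_1_give_one_sixth(self):
        # 4 carriers of allele 1 at the focal site; over focal..t the
        # sub-haplotypes fall into identity classes {2,1,1}: 1 of 6 pairs
        alleles = np.array([[1, 0, 0],
                            [1, 0, 0],
                            [1, 0, 1],
                            [1, 1, 0]], dtype=np.uint8)
        panel = make_panel(alleles)
        curve = ehh_at_site(panel, 0, core_allele=1)
        assert curve.values_right[0] == 1.0
        assert curve.values_right[1] == pytest.approx(3 / 6)  # classes {3,1}
        assert curve.values_right[2] == pytest.approx(1 / 6)  # {2,1,1}

    def test_all_identical_carriers_stay_at_one(self):
        alleles = np.tile(np.array([1, 0, 1, 1], dtype=np.uint8), (6, 1))
        panel = make_panel(alleles)
        curve = ehh_at_site(panel, 0, 1)
        assert np.all(curve.values_right == 1.0)
        assert np.all(curve.values_left == 1.0)

    def test_fewer_than_two_carriers_is_undefined(self):
        alleles = np.zeros((4, 2), dtype=np.uint8)
        alleles[0, 0] = 1
        with pytest.raises(ValueError):
            ehh_at_site(make_panel(alleles), 0, 1)

    def test_ehhs_normalized_and_unnormalized_example(self):
        # focal classes {2,2} -> hh0 = 2/6; at t classes {2,1,1} -> 1/6
        alleles = np.array([[0, 0], [0, 0], [1, 1], [1, 0]],
                           dtype=np.uint8)
        panel = make_panel(alleles)
        un = ehhs_at_site(panel, 0, "unnormalized")
        assert un.values_right[0] == pytest.approx(2 / 6)
        assert un.values_right[1] == pytest.approx(1 / 6)
        no = ehhs_at_site(panel, 0, "normalized")
        assert no.values_right[0] == 1.0
        assert no.values_right[1] == pytest.approx(0.5)

    def test_monotone_non_increasing_away_from_focal(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            alleles = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
            panel = make_panel(alleles)
            focal = int(rng.integers(0, 15))
            curve = ehhs_at_site(panel, focal, "normalized")
            assert np.all(np.diff(curve.values_right) <= 1e-12)
            assert np.all(np.diff(curve.values_left) <= 1e-12)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            if n % 2:
                n += 1
            m = int(rng.integers(3, 9))
            alleles = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
            panel = make_panel(alleles)
            focal = int(rng.integers(0, m))
            for est in ("normalized", "unnormalized"):
                curve = ehhs_at_site(panel, focal, est)
                # the walk may stop after reaching zero: beyond that point
                # the pooled pair fraction is identically zero
                for k, t in enumerate(range(focal, m)):
                    expect = ehhs_pairwise(alleles, focal, t,
                                           est == "normalized")
                    if k < len(curve.values_right):
                        assert curve.values_right[k] == pytest.approx(
                            expect, abs=1e-12)
                    else:
                        assert curve.values_right[-1] == 0.0
                        assert expect == 0.0
            for core in (0, 1):
                if (alleles[:, focal] == core).sum() < 2:
                    continue
                curve = ehh_at_site(panel, focal, core)
                for k, t in enumerate(range(focal, -1, -1)):
                    if k >= len(curve.values_left):
                        break
                    assert curve.values_left[k] == pytest.approx(
                        ehh_pairwise(alleles, focal, core, t), abs=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    alleles=hnp.arrays(np.uint8,
                       st.tuples(st.integers(2, 6).map(lambda x: 2 * x),
                                 st.integers(2, 10)),
                       elements=st.integers(0, 1)),
    data=st.data())
def test_homozygosity_curves_never_increase_outward(alleles, data):
    """Identity classes only refine with span, so EHH and normalized EHHS
    are monotone non-increasing away from the focal marker — for any panel
    and any focal choice."""
    panel = make_panel(alleles)
    focal = data.draw(st.integers(0, alleles.shape[1] - 1))
    curve = ehhs_at_site(panel, focal, "normalized")
    assert np.all(np.diff(curve.values_right) <= 1e-12)
    assert np.all(np.diff(curve.values_left) <= 1e-12)
    for core in (0, 1):
        if (alleles[:, focal] == core).sum() >= 2:
            c = ehh_at_site(panel, focal, core)
            assert c.values_right[0] == 1.0
            assert np.all(np.diff(c.values_right) <= 1e-12)
            assert np.all(np.diff(c.values_left) <= 1e-12)


class TestIntegrateCurve:
    @staticmethod
    def _curve(pos, vals, complete=True):
        pos = np.asarray(pos)
        vals = np.asarray(vals, dtype=float)
        return SiteCurve(int(pos[0]), pos[:1], vals[:1], pos, vals,
                         True, complete)

    def test_simple_trapezoid(self):
        c = self._curve([0, 1000], [1.0, 0.5])
        val, status = integrate_curve(c, cutoff=0.05, edge_rule="truncate")
        assert val == pytest.approx(750.0)

    def test_stops_at_first_sub_cutoff_marker_inclusive(self):
        c = self._curve([0, 1000], [1.0, 0.04])
        val, status = integrate_curve(c, cutoff=0.05)
        assert status == STATUS_OK
        assert val == pytest.approx(520.0)

    def test_focal_at_chromosome_end_contributes_zero(self):
        c = SiteCurve(0, np.array([0]), np.array([1.0]),
                      np.array([0, 1000]), np.array([1.0, 0.04]),
                      True, True)
        val, _ = integrate_curve(c, cutoff=0.05)
        assert val == pytest.approx(520.0)  # left side adds nothing

    def test_edge_rule_discard_suppresses(self):
        c = self._curve([0, 1000], [1.0, 0.5], complete=False)
        val, status = integrate_curve(c, cutoff=0.05, edge_rule="discard")
        assert status == "edge_truncated"
        assert np.isnan(val)

    def test_unsorted_positions_rejected(self):
        c = SiteCurve(0, np.array([0]), np.array([1.0]),
                      np.array([0, 500, 300]), np.array([1.0, 0.5, 0.02]),
                      True, True)
        with pytest.raises(ValueError):
            integrate_curve(c)


class TestPTransform:
    def test_zero_and_symmetry(self):
        assert p_score_from_z(0.0) == pytest.approx(0.0)
        z = np.array([-2.3, 2.3, -0.7, 0.7])
        p = p_score_from_z(z)
        assert p[0] == pytest.approx(p[1])
        assert p[2] == pytest.approx(p[3])

    def test_value_at_196(self):
        assert p_score_from_z(1.96) == pytest.approx(1.301, abs=2e-3)

    def test_threshold_four_corresponds_to_z_3_89(self):
        z_star = norm.isf(0.5e-4)
        assert z_star == pytest.approx(3.8906, abs=1e-3)
        assert p_score_from_z(z_star) == pytest.approx(4.0, abs=1e-9)

    def test_strictly_increasing_in_magnitude(self):
        z = np.linspace(0, 6, 200)
        p = p_score_from_z(z)
        assert np.all(np.diff(p) > 0)


def _sim_panel(seed, n_hap=40, n_sites=400, length=4_000_000):
    pool = sw.simulate_founder_pool(15, n_sites, {"1": length},
                                    maf_floor=0.05, seed=seed)
    return sw.mosaic_haplotypes(pool, n_hap, 2e-5, 1e-3, seed=seed + 1)


class TestIhsScan:
    def test_bins_standardized_to_zero_mean_unit_sd(self):
        panel = _sim_panel(10)
        anc, ambiguous = infer_ancestral(panel)
        tbl = ihs_scan(anc, group="g", ambiguous=ambiguous)
        ok = tbl[np.isfinite(tbl["raw"]) & np.isfinite(tbl["z"])]
        bins = np.minimum((ok["derived_freq"] * 20).astype(int), 19)
        for b in np.unique(bins):
            zs = ok["z"][bins == b].to_numpy()
            if len(zs) >= 2:
                assert abs(zs.mean()) < 1e-9
                assert abs(zs.std() - 1) < 1e-9

    def test_raw_coding_rejected(self):
        panel = _sim_panel(11)
        with pytest.raises(sw.ConfigError):
            ihs_scan(panel)

    def test_ambiguous_sites_carry_no_statistic(self):
        panel = _sim_panel(12)
        anc, ambiguous = infer_ancestral(panel)
        ambiguous = ambiguous.copy()
        ambiguous[5] = True
        tbl = ihs_scan(anc, group="g", ambiguous=ambiguous)
        assert tbl.iloc[5]["status"] == "undefined"
        assert np.isnan(tbl.iloc[5]["z"])


class TestBetweenGroupScans:
    def test_identical_panels_give_zero_raw(self):
        panel = _sim_panel(13, n_hap=20, n_sites=120, length=1_200_000)
        for fn in (rsb_scan, xpehh_scan):
            tbl = fn(panel, panel, edge_rule="truncate")
            raw = tbl["raw"].to_numpy()
            assert np.nanmax(np.abs(raw)) < 1e-12

    def test_group_swap_negates_raw(self):
        # the two group panels must share one marker map: same founder
        # pool, independent mosaic draws
        pool = sw.simulate_founder_pool(15, 120, {"1": 1_200_000},
                                        maf_floor=0.05, seed=14)
        p1 = sw.mosaic_haplotypes(pool, 20, 2e-5, 1e-3, seed=15)
        p2 = sw.mosaic_haplotypes(pool, 20, 2e-5, 1e-3, seed=16)
        for fn in (rsb_scan, xpehh_scan):
            a = fn(p1, p2, edge_rule="truncate")["raw"].to_numpy()
            b = fn(p2, p1, edge_rule="truncate")["raw"].to_numpy()
            both = np.isfinite(a) & np.isfinite(b)
            np.testing.assert_allclose(a[both], -b[both], atol=1e-12)

    def test_raw_matches_pair_count_integral_oracle(self):
        """Small two-group panel: ln(iES1/iES2) recomputed from exhaustive
        pairwise EHHS curves and trapezoid integration."""
        rng = np.random.default_rng(16)
        pos = np.sort(rng.choice(100_000, 5, replace=False)) + 1
        a1 = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
        a2 = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
        p1 = make_panel(a1, positions=pos)
        p2 = make_panel(a2, positions=pos)
        tbl = rsb_scan(p1, p2, cutoff=0.05, maf_min=0.0,
                       edge_rule="truncate")
        for j in range(5):
            ies = []
            for alle in (a1, a2):
                total = 0.0
                for sign in (-1, 1):
                    ts = range(j, -1, -1) if sign < 0 else range(j, 5)
                    pts = [(abs(int(pos[t]) - int(pos[j])),
                            ehhs_pairwise(alle, j, t, True)) for t in ts]
                    for (d0, v0), (d1, v1) in zip(pts, pts[1:]):
                        total += (v0 + v1) / 2 * (d1 - d0)
                        if v1 < 0.05:
                            break
                ies.append(total)
            if ies[0] > 0 and ies[1] > 0:
                expect = np.log(ies[0] / ies[1])
                assert tbl.iloc[j]["raw"] == pytest.approx(expect,
                                                           abs=1e-10)

    def test_mismatched_maps_rejected(self):
        p1 = _sim_panel(17, n_hap=10, n_sites=50, length=500_000)
        p2 = _sim_panel(18, n_hap=10, n_sites=60, length=500_000)
        with pytest.raises(sw.ConfigError):
            rsb_scan(p1, p2)
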