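"""Atypia features: ideal boundary, signature, PIPs, regions, cytoplasm."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ductmorph as dm
from ductmorph import atypia
from ductmorph.geometry import Boundary, NucleusSet, Region
from conftest import random_signature
from oracles import brute_pips, prune_pips


def circle_boundary(r=100.0, c=(150.0, 150.0), n=720):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Boundary(np.c_[c[0] + r * np.sin(th), c[1] + r * np.cos(th)])


class TestIdealBoundary:
    def test_convex_input_is_its_own_ideal(self):
        b = circle_boundary()
        B_C, B_I, s = atypia.ideal_boundary(b)
        assert s == pytest.approx(1.0, abs=1e-3)
        from shapely.geometry import Polygon

        assert Polygon(b.xy).hausdorff_distance(Polygon(B_I.xy)) <= 1.0

    def test_notched_square_scaling_factor(self):
        # 20x20 bite in the middle of the top edge: the hull restores the
        # full square, so Area(R_O) = 9600 while Area(R_C) = 10000
        sq = [(0, 0), (100, 0), (100, 100), (60, 100), (60, 80),
              (40, 80), (40, 100), (0, 100)]
        b = Boundary(np.array(sq, dtype=float))
        _, B_I, s = atypia.ideal_boundary(b)
        assert s == pytest.approx(np.sqrt(0.96), abs=1e-6)
        assert B_I.area == pytest.approx(9600.0, rel=0.01)

    def test_area_preserved_on_random_star_polygons(self, rng):
        for _ in range(20):
            th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
            r = rng.uniform(40, 100, size=24)
            b = Boundary(np.c_[200 + r * np.sin(th), 200 + r * np.cos(th)])
            _, B_I, _ = atypia.ideal_boundary(b)
            assert abs(B_I.area - b.area) / b.area <= 0.01

    def test_collinear_boundary_rejected(self):
        with pytest.raises(ValueError):
            atypia.ideal_boundary(
                Boundary(np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]]))
            )


class TestSignature:
    def test_identical_boundaries_give_zero_amplitude(self):
        b = circle_boundary(n=360)
        _, B_I, _ = atypia.ideal_boundary(b)
        sig = atypia.atypia_signature(B_I, b)
        assert np.abs(sig.A).max() < 0.75  # rasterless: resampling only

    def test_radial_bulge_measured_with_sign(self):
        th = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
        r = np.full_like(th, 100.0)
        arc = th < np.deg2rad(30)
        r[arc] = 110.0
        B_O = Boundary(np.c_[200 + r * np.sin(th), 200 + r * np.cos(th)])
        B_I = circle_boundary(100.0, (200, 200), 1440).resample(1.0)
        sig = atypia.atypia_signature(B_I, B_O)
        bulge = np.abs(sig.A - 10.0) < 0.5
        assert bulge.sum() > 0.8 * (np.deg2rad(30) / (2 * np.pi)) * len(sig)
        assert (np.abs(sig.A) < 0.5).sum() > 0.9 * (len(sig) - bulge.sum())
        assert sig.A.max() > 9.0  # bulge is positive (outside)

    def test_arc_length_telescopes_to_perimeter(self):
        b = circle_boundary(80.0, n=500)
        _, B_I, _ = atypia.ideal_boundary(b)
        sig = atypia.atypia_signature(B_I, b)
        last_gap = np.hypot(*(B_I.points[-1] - B_I.points[0]))
        assert sig.L[-1] + last_gap == pytest.approx(B_I.perimeter, abs=1e-9)
        assert sig.L[0] == 0.0
        assert np.all(np.diff(sig.L) > 0)

    def test_signature_length_matches_ideal_boundary(self):
        b = circle_boundary(60.0, n=400)
        _, B_I, _ = atypia.ideal_boundary(b)
        assert len(atypia.atypia_signature(B_I, b)) == len(B_I)


class TestRmsaa:
    def test_hand_arithmetic(self):
        sig = dm.AtypiaSignature(L=[0.0, 1.0], A=[3.0, -4.0])
        assert atypia.rmsaa(sig) == pytest.approx(np.sqrt(12.5))

    def test_zero_and_constant(self):
        assert atypia.rmsaa(dm.AtypiaSignature(L=[0, 1, 2], A=[0, 0, 0])) == 0.0
        assert atypia.rmsaa(
            dm.AtypiaSignature(L=[0, 1, 2], A=[-2.5, -2.5, -2.5])
        ) == pytest.approx(2.5)

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            atypia.rmsaa(dm.AtypiaSignature(L=[], A=[]))


class TestPips:
    def test_collinear_signature_keeps_only_endpoints(self):
        sig = dm.AtypiaSignature(L=np.arange(10.0), A=2.0 * np.arange(10.0))
        pips = atypia.detect_pips(sig, T=0.1)
        assert pips.indices == [0, 9]

    def test_triangle_wave_single_apex(self):
        L = np.arange(21.0)
        A = 10.0 - np.abs(L - 10.0)
        pips = atypia.detect_pips(dm.AtypiaSignature(L=L, A=A), T=1.0)
        assert pips.indices == [0, 10, 20]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            atypia.detect_pips(dm.AtypiaSignature(L=[0, 1], A=[0, 0]), T=-1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_recursive_oracle(self, s):
        r = np.random.default_rng(s)
        sig = random_signature(r, n=50)
        T = r.uniform(0, 8)
        raw = atypia.detect_pips(sig, T=T, theta_min=0.0)
        assert raw.indices == brute_pips(sig.points, T)
        theta_min = np.deg2rad(5)
        pruned = atypia.detect_pips(sig, T=T, theta_min=theta_min)
        assert pruned.indices == prune_pips(
            sig.points, brute_pips(sig.points, T), theta_min
        )


class TestTsav:
    def test_no_interior_pips_means_zero(self):
        p = dm.PIPSequence(indices=[0, 5], points=np.array([[0, 0], [5, 1.0]]))
        assert atypia.tsav(p) == 0.0

    def test_collinear_pips_zero(self):
        pts = np.array([[0, 0], [1, 2], [2, 4], [3, 6.0]])
        assert atypia.tsav(dm.PIPSequence(indices=[0, 1, 2, 3], points=pts)) == (
            pytest.approx(0.0, abs=1e-6)
        )

    def test_right_angle_turn(self):
        pts = np.array([[0, 0], [1, 1], [2, 0.0]])
        p = dm.PIPSequence(indices=[0, 1, 2], points=pts)
        assert atypia.tsav(p) == pytest.approx(np.pi / 2)

    def test_duplicate_pips_rejected(self):
        pts = np.array([[0, 0], [0, 0], [2, 0.0]])
        with pytest.raises(ValueError):
            atypia.tsav(dm.PIPSequence(indices=[0, 1, 2], points=pts))


class TestAtypiaRegions:
    RES = 0.492

    @staticmethod
    def _disk(shape=(300, 300), r=100):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return (yy - 150) ** 2 + (xx - 150) ** 2 <= r**2

    def test_identical_regions_are_silent(self):
        d = Region(self._disk(), self.RES)
        ar, ratio, count = atypia.atypia_regions(d, d)
        assert len(ar) == 0 and ratio == 0.0 and count == 0

    def test_constructed_tab_and_bite(self):
        res = self.RES
        tab_px = int(round(2000.0 / res**2))    # supra-threshold, outside
        bite_px = int(round(1500.0 / res**2))   # supra-threshold, inside
        ri = self._disk()
        ro = ri.copy()
        ro[110:190, 250:250 + tab_px // 80] = True     # 80-row tab
        ro[110:190, 70 : 70 + bite_px // 80] = False   # 80-row bite
        tab_area = (ro & ~ri).sum() * res**2
        bite_area = (ri & ~ro).sum() * res**2
        ar, ratio, count = atypia.atypia_regions(
            Region(ro, res), Region(ri, res)
        )
        assert count == 2
        want = (tab_area + bite_area) / (ro.sum() * res**2)
        assert ratio == pytest.approx(want, rel=1e-6)
        sides = sorted(r.side for r in ar.supra_threshold())
        assert sides == ["inside", "outside"]

    def test_threshold_applies_to_count_only(self):
        res = self.RES
        ri = self._disk()
        ro = ri.copy()
        ro[140:160, 250:270] = True  # ~97 um^2 < 300
        _, ratio, count = atypia.atypia_regions(Region(ro, res), Region(ri, res))
        assert count == 0
        assert ratio > 0


class TestCytoplasm:
    def test_centroid_on_boundary_has_zero_length(self):
        b = circle_boundary(100.0, (150, 150), 720)
        n = NucleusSet([_nuc(150.0, 250.0)])  # on the circle
        lengths, mean, sd = atypia.cytoplasm_features(n, b)
        assert mean == pytest.approx(0.0, abs=0.05)

    def test_radial_offset_recovered(self):
        b = circle_boundary(100.0, (150, 150), 720)
        n = NucleusSet([_nuc(150.0, 150.0 + 110.0)])
        _, mean, _ = atypia.cytoplasm_features(n, b)
        assert mean == pytest.approx(10.0, abs=0.5)

    def test_population_sd(self):
        b = circle_boundary(100.0, (150, 150), 720)
        n = NucleusSet([_nuc(150, 260), _nuc(150, 264)])  # lengths 10 and 14
        _, mean, sd = atypia.cytoplasm_features(n, b)
        assert mean == pytest.approx(12.0, abs=0.5)
        assert sd == pytest.approx(2.0, abs=0.1)  # divisor m, not m-1

    def test_identical_lengths_have_zero_sd(self):
        b = circle_boundary(100.0, (150, 150), 720)
        n = NucleusSet([_nuc(150, 260), _nuc(150, 40)])
        _, _, sd = atypia.cytoplasm_features(n, b)
        assert sd == pytest.approx(0.0, abs=0.05)

    def test_empty_set_warns_and_zeroes(self):
        b = circle_boundary()
        with pytest.warns(UserWarning):
            lengths, mean, sd = atypia.cytoplasm_features(NucleusSet([]), b)
        assert mean == 0.0 and sd == 0.0 and len(lengths) == 0


def _nuc(row, col):
    from ductmorph.geometry import Nucleus

    return Nucleus(
        mask=np.ones((3, 3), bool),
        offset=(int(row) - 1, int(col) - 1),
        centroid=(float(row), float(col)),
        area_px2=9.0,
    )


class TestDuctFeatureInvariance:
    @staticmethod
    def _rotated_truth(truth):
        import copy

        rot = copy.deepcopy(truth)
        rot.lumen_mask = np.rot90(truth.lumen_mask).copy()
        h = truth.lumen_mask.shape[1]
        for nuc in rot.nuclei:
            r0, c0 = nuc.offset
            ph, pw = nuc.mask.shape
            nuc.mask = np.rot90(nuc.mask).copy()
            # (r, c) -> (h-1-c, r) under rot90
            nuc.offset = (h - 1 - (c0 + pw - 1), r0)
            cr, cc = nuc.centroid
            nuc.centroid = (h - 1 - cc, cr)
        return rot

    def test_rigid_motion_changes_features_below_one_percent(self):
        cfg = dm.PhantomConfig(
            image_size=(640, 640), lumen_radius=200, n_lobes=0,
            boundary_noise_amp=6.0, n_epithelial=30, n_stromal=15,
            cytoplasm_offset_mean=10.0, cytoplasm_offset_sd=3.0, rng_seed=21,
        )
        image, truth = dm.generate_duct_phantom(cfg)
        params = dm.FeatureParams()
        row = dm.features_from_truth(image, truth, params)
        rot = self._rotated_truth(truth)
        row_rot = dm.features_from_truth(np.rot90(image).copy(), rot, params)
        for key in ("RMSAA", "AtypiaRatio", "CytoplasmLength",
                    "CytoplasmLength_SD"):
            assert row_rot[key] == pytest.approx(row[key], rel=0.01, abs=1e-3)
        assert row_rot["#AtypiaRegions"] == row["#AtypiaRegions"]
        assert row_rot["TSAV"] == pytest.approx(row["TSAV"], rel=0.01, abs=0.1)

    def test_rigid_motion_preserves_papillary_count(self, papillary_phantom):
        cfg, image, truth = papillary_phantom
        params = dm.FeatureParams()
        row = dm.features_from_truth(image, truth, params)
        rot = self._rotated_truth(truth)
        row_rot = dm.features_from_truth(np.rot90(image).copy(), rot, params)
        assert row_rot["#AtypiaRegions"] == row["#AtypiaRegions"]
        assert row_rot["AtypiaRatio"] == pytest.approx(row["AtypiaRatio"], rel=0.01)
        assert row_rot["RMSAA"] == pytest.approx(row["RMSAA"], rel=0.01)

    def test_noise_amplitude_monotonicity(self):
        """Median RMSAA and TSAV increase with boundary perturbation."""
        params = dm.FeatureParams()
        med_rmsaa, med_tsav = [], []
        for amp in (0.0, 4.0, 10.0):
            r_vals, t_vals = [], []
            for seed in range(5):
                cfg = dm.PhantomConfig(
                    image_size=(384, 384), lumen_radius=120, n_lobes=0,
                    boundary_noise_amp=amp, n_epithelial=12, n_stromal=6,
                    rng_seed=100 + seed,
                )
                image, truth = dm.generate_duct_phantom(cfg)
                row = dm.features_from_truth(image, truth, params)
                r_vals.append(row["RMSAA"])
                t_vals.append(row["TSAV"])
            med_rmsaa.append(np.median(r_vals))
            med_tsav.append(np.median(t_vals))
        assert med_rmsaa[0] < med_rmsaa[1] < med_rmsaa[2]
        assert med_tsav[0] < med_tsav[1] < med_tsav[2]
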