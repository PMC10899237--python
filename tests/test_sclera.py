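"""Sclera segmentation, palette extraction, staining and vein synthesis."""

import numpy as np
import pytest

from ocuprost import iris, sclera
from ocuprost.errors import InsufficientDataError


@pytest.fixture(scope="module")
def segmentation(eye_photo):
    seg = iris.detect_iris(eye_photo["lab"])
    return sclera.segment_sclera(eye_photo["lab"],
                                 seg.iris_mask(eye_photo["lab"].shape[:2]))


@pytest.fixture(scope="module")
def flat_palette():
    colours = np.array([[78.0 - 2 * i, 2.0, 6.0 + i] for i in range(9)])
    base, w = sclera.palette_base_colour(colours)
    return sclera.ScleraPalette(colours=colours, weights=w, base_colour=base)


class TestSegmentSclera:
    def test_labels_agree_with_ground_truth(self, eye_photo, segmentation):
        truth = eye_photo["labels"]
        agree = (segmentation.labels == truth).mean()
        assert agree >= 0.90

    def test_sclera_mask_within_sclera_label(self, segmentation):
        M_W = segmentation.sclera_mask
        assert np.all(segmentation.labels[M_W] == sclera.LABEL_SCLERA)

    def test_dark_pixels_excluded(self, segmentation, eye_photo):
        L = eye_photo["lab"][..., 0]
        assert np.all(L[segmentation.sclera_mask] >= 50.0)

    def test_vein_filter_thresholds(self):
        from skimage import color as skcolor
        # achromatic pixel: C* = 0 -> never removed by the vein filter
        # L = 49.9 -> dropped by the darkness rule; L = 50.1, C = 5 -> kept
        lab = np.zeros((3, 1, 3))
        lab[0] = [70.0, 0.0, 0.0]
        lab[1] = [49.9, 0.0, 0.0]
        lab[2] = [50.1, 5.0, 0.0]
        lch = skcolor.lab2lch(lab)
        C = lch[..., 1][:, 0]
        hdeg = np.rad2deg(lch[..., 2][:, 0]) % 360
        veiny = (C > 8.0) & ((hdeg >= 345.0) | (hdeg <= 60.0))
        dark = lab[:, 0, 0] < 50.0
        keep = ~dark & ~veiny
        assert keep.tolist() == [True, False, True]

    def test_flat_image_raises(self):
        flat = np.full((64, 64, 3), 50.0)
        with pytest.raises(Exception):
            sclera.segment_sclera(flat, np.zeros((64, 64), bool))


class TestExtractPalette:
    def test_two_colour_mixture_recovered(self):
        from skimage import color as skcolor
        rng = np.random.default_rng(0)
        A, B = np.array([70.0, 4.0, 10.0]), np.array([60.0, 8.0, 16.0])
        pix = np.vstack([np.tile(A, (600, 1)), np.tile(B, (400, 1))])
        pix = pix + rng.normal(0, 0.05, pix.shape)
        pal = sclera.extract_palette(pix, n_colours=2, seed=0, min_pixels=100)
        got = pal.colours[np.argsort(-pal.colours[:, 0])]
        for truth, centre in zip((A, B), got):
            dE = skcolor.deltaE_ciede2000(truth[None], centre[None])[0]
            assert dE < 0.5

    def test_base_colour_matches_direct_arithmetic(self):
        rng = np.random.default_rng(1)
        G = np.stack([rng.uniform(55, 85, 9), rng.uniform(-3, 8, 9),
                      rng.uniform(2, 14, 9)], axis=1)
        base, w = sclera.palette_base_colour(G)
        # independent elementwise evaluation of the weighting rule
        L = G[:, 0]
        w_ref = (L - L.min()) / (L.max() - L.min())
        num = np.zeros(3)
        for i in range(9):
            num += w_ref[i] * G[i]
        assert np.allclose(w, w_ref)
        assert np.allclose(base, num / w_ref.sum(), atol=1e-12)

    def test_equal_lightness_degenerates_to_uniform(self):
        G = np.tile(np.array([[70.0, 3.0, 6.0]]), (9, 1))
        G[:, 1] = np.arange(9)  # same L*, different a*
        base, w = sclera.palette_base_colour(G)
        assert np.all(w == 1.0)
        assert np.allclose(base, G.mean(axis=0))

    def test_too_few_pixels_raise(self):
        with pytest.raises(InsufficientDataError):
            sclera.extract_palette(np.zeros((10, 3)))


class TestRenderStaining:
    def test_coverage_and_equal_areas(self, flat_palette):
        for seed in (0, 1, 2):
            tex = sclera.render_staining(flat_palette, seed=seed,
                                         width=1024, height=512)
            assert 0.88 <= tex.stain_fraction <= 0.92
            areas = np.array([(tex.colour_index == i).sum() for i in range(9)])
            assert np.abs(areas / areas.mean() - 1.0).max() < 0.2

    def test_bit_identical_for_fixed_seed(self, flat_palette):
        a = sclera.render_staining(flat_palette, seed=5, width=256, height=128)
        b = sclera.render_staining(flat_palette, seed=5, width=256, height=128)
        assert np.array_equal(a.lab, b.lab)

    def test_seam_continuity_across_u_border(self, flat_palette):
        seams, nbs = [], []
        for seed in range(6):
            tex = sclera.render_staining(flat_palette, seed=seed,
                                         width=512, height=256)
            seams.append(np.abs(tex.lab[:, 0] - tex.lab[:, -1]).mean())
            nbs.append(0.5 * (np.abs(tex.lab[:, 1:] - tex.lab[:, :-1]).mean()
                              + np.abs(tex.lab[1:] - tex.lab[:-1]).mean()))
        assert np.mean(seams) < np.mean(nbs)


class TestGrowVeins:
    def test_zero_branching_keeps_single_layer(self):
        net = sclera.grow_veins(br=0.0, seed=4)
        assert {v.layer for v in net.veins} == {1}
        assert len(net.veins) == len(sclera.SEED_POSITIONS)

    def test_thickness_parameter_scales_exactly(self):
        n1 = sclera.grow_veins(th=1.0, seed=4)
        n2 = sclera.grow_veins(th=2.0, seed=4)
        assert len(n1.veins) == len(n2.veins)
        for a, b in zip(n1.veins, n2.veins):
            assert np.allclose(2.0 * a.thickness, b.thickness)
            assert np.array_equal(a.nodes, b.nodes)

    def test_roots_at_seed_positions_and_limbus_stop(self):
        net = sclera.grow_veins(seed=9)
        for v in net.veins:
            if v.layer == 1:
                assert any(np.allclose(v.nodes[0], sp)
                           for sp in sclera.SEED_POSITIONS)
            assert v.nodes[:, 1].min() >= sclera.VEIN_LIMBUS_Y
            assert np.all(np.diff(v.thickness) <= 1e-12)

    def test_branches_share_depth_with_parent(self):
        net = sclera.grow_veins(br=2.0, seed=3)
        depths_by_layer = {}
        for v in net.veins:
            depths_by_layer.setdefault(v.layer, set()).add(round(v.depth, 6))
        if 2 in depths_by_layer:
            assert depths_by_layer[2] <= depths_by_layer[1]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sclera.grow_veins(th=0.0)
        with pytest.raises(ValueError):
            sclera.grow_veins(br=5.0)


class TestRenderVeins:
    def test_profile_selection_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for t, d in zip(rng.uniform(0.001, 0.02, 50), rng.uniform(0, 1, 50)):
            costs = [5.0 * (w - t) ** 2 + (pd - d) ** 2
                     for w, pd in zip(sclera.PROFILE_WIDTHS, sclera.PROFILE_DEPTHS)]
            assert sclera.select_profile(t, d) == int(np.argmin(costs))

    def test_straight_vein_renders_collinear(self, flat_palette):
        stain = sclera.render_staining(flat_palette, seed=0, width=256, height=128)
        vein = sclera.Vein(nodes=np.array([[0.5, 0.8], [0.5, 0.2]]),
                           thickness=np.array([0.01, 0.01]), depth=0.5,
                           layer=1, recipe_id=0)
        net = sclera.VeinNetwork(veins=[vein], th=1.0, br=1.0, seed=0)
        out = sclera.render_veins(net, stain, jitter_amplitude=0.0)
        drawn = np.isfinite(out.vein_depth)
        cols = [np.nonzero(row)[0] for row in drawn if row.any()]
        centres = np.array([c.mean() for c in cols])
        assert centres.max() - centres.min() < 1.0  # vertical centreline

    def test_shallow_vein_wins_at_crossing(self, flat_palette):
        stain = sclera.render_staining(flat_palette, seed=0, width=256, height=128)
        deep = sclera.Vein(nodes=np.array([[0.3, 0.5], [0.7, 0.5]]),
                           thickness=np.array([0.012, 0.012]), depth=0.9,
                           layer=1, recipe_id=0)
        shallow = sclera.Vein(nodes=np.array([[0.5, 0.8], [0.5, 0.2]]),
                              thickness=np.array([0.012, 0.012]), depth=0.1,
                              layer=3, recipe_id=10)
        net = sclera.VeinNetwork(veins=[deep, shallow], th=1.0, br=1.0, seed=0)
        out = sclera.render_veins(net, stain, jitter_amplitude=0.0)
        # the crossing pixel carries the shallow vein's depth and colour
        cx, cy = int(0.5 * 128), int(0.5 * 128)
        assert out.vein_depth[cy, cx] == pytest.approx(0.1)
        pid = sclera.select_profile(0.012, 0.1)
        core = sclera.PROFILE_COLOURS[pid][10]
        assert np.abs(out.lab[cy, cx] - core).max() < 3.0

    def test_vein_fraction_increases_with_th_and_br(self, flat_palette):
        stain = sclera.render_staining(flat_palette, seed=0, width=256, height=128)

        def fraction(th, br, seeds=(0, 1, 2)):
            fr = []
            for s in seeds:
                net = sclera.grow_veins(th=th, br=br, seed=s)
                out = sclera.render_veins(net, stain)
                fr.append(np.isfinite(out.vein_depth).mean())
            return np.mean(fr)

        base = fraction(1.0, 1.0)
        assert fraction(2.0, 1.0) > base
        assert fraction(1.0, 2.5) > base
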