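"""Layer composition, alpha blending, eigenvector two-color mode, and
chromHMM state layers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hicpaint import (
    BinnedTrack,
    ChromHMMSegmentation,
    ColorLayer,
    ContactMatrix,
    GenomicRegion,
    SignalMatrix,
    assign_bins_to_states,
    blend_layers,
    chromhmm_layers,
    compose_layer,
    eigen_layers,
    parse_color,
)


def unit_contacts(values, tag="unit-scaled"):
    n = np.asarray(values).shape[0]
    region = GenomicRegion("chrT", 0, 100 * n, 100)
    return ContactMatrix(region, np.asarray(values, float), normalization_tag=tag)


def blend_oracle(layers, background=(255, 255, 255)):
    """Naive per-pixel, per-layer blend: alpha sums, ratios, mixed channels,
    8-bit clip. Works in exact integer arithmetic so the half-away rounding
    of sum_b rgb_b * (alpha_b / total) has no float drift."""
    n = layers[0].alpha.shape[0]
    rgb = np.zeros((n, n, 3), dtype=np.uint8)
    alpha = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = sum(int(ly.alpha[i, j]) for ly in layers)
            if total == 0:
                rgb[i, j] = background
                continue
            for k in range(3):
                numer = sum(int(ly.rgb[k]) * int(ly.alpha[i, j]) for ly in layers)
                rgb[i, j, k] = (2 * numer + total) // (2 * total)
            alpha[i, j] = min(total, 255)
    return rgb, alpha.astype(np.uint8)


class TestComposeLayer:
    def test_saturated_inputs_give_opaque_alpha(self):
        m = SignalMatrix(np.ones((3, 3)))
        c = unit_contacts(np.ones((3, 3)))
        layer = compose_layer(m, c, "#FF0000", overlay_strength=1.0)
        assert (layer.alpha == 255).all()

    def test_zero_signal_is_fully_transparent(self):
        m = SignalMatrix(np.zeros((3, 3)))
        layer = compose_layer(m, unit_contacts(np.ones((3, 3))), "red")
        assert (layer.alpha == 0).all()

    def test_scalar_arithmetic_oracle(self):
        # alpha = round(m * c * strength * 255), half away from zero
        m = SignalMatrix(np.full((2, 2), 0.5))
        c = unit_contacts(np.full((2, 2), 0.5))
        layer = compose_layer(m, c, "red", overlay_strength=1.0)
        assert (layer.alpha == round(0.25 * 255)).all() and layer.alpha[0, 0] == 64

    def test_overlay_strength_scales_alpha(self):
        m = SignalMatrix(np.ones((2, 2)))
        layer = compose_layer(m, unit_contacts(np.ones((2, 2))), "red",
                              overlay_strength=0.5)
        assert (layer.alpha == 128).all()  # 127.5 rounds half away from zero

    def test_missing_pixels_get_alpha_zero(self):
        m = SignalMatrix(np.array([[np.nan, 1.0], [1.0, 1.0]]))
        layer = compose_layer(m, unit_contacts(np.ones((2, 2))), "red")
        assert layer.alpha[0, 0] == 0 and layer.alpha[1, 1] == 255

    def test_requires_unit_scaled_contacts(self):
        m = SignalMatrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="unit-scaled"):
            compose_layer(m, unit_contacts(np.ones((2, 2)), tag="raw"), "red")

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose_layer(SignalMatrix(np.ones((3, 3))),
                          unit_contacts(np.ones((2, 2))), "red")


def random_layers(seed, n=16, n_layers=3):
    rng = np.random.default_rng(seed)
    return [
        ColorLayer(tuple(int(v) for v in rng.integers(0, 256, 3)),
                   rng.integers(0, 256, (n, n)).astype(np.uint8), label=f"L{b}")
        for b in range(n_layers)
    ]


class TestBlendLayers:
    def test_single_layer_identity(self):
        (layer,) = random_layers(0, n=8, n_layers=1)
        out = blend_layers([layer])
        np.testing.assert_array_equal(out.alpha, layer.alpha)
        nz = layer.alpha > 0
        assert (out.rgb_channels[nz] == np.array(layer.rgb)).all()

    def test_transparent_layer_is_neutral(self):
        (layer,) = random_layers(1, n=8, n_layers=1)
        empty = ColorLayer((0, 255, 0), np.zeros((8, 8), dtype=np.uint8))
        out_pair = blend_layers([layer, empty])
        out_solo = blend_layers([layer])
        np.testing.assert_array_equal(out_pair.alpha, out_solo.alpha)
        np.testing.assert_array_equal(out_pair.rgb_channels, out_solo.rgb_channels)

    def test_equal_alpha_red_blue_mixes_midway(self):
        red = ColorLayer((255, 0, 0), np.full((1, 1), 100, dtype=np.uint8))
        blue = ColorLayer((0, 0, 255), np.full((1, 1), 100, dtype=np.uint8))
        out = blend_layers([red, blue])
        assert out.alpha[0, 0] == 200
        # each ratio 0.5 -> 127.5 per contributing channel, rounds to 128
        np.testing.assert_array_equal(out.rgb_channels[0, 0], [128, 0, 128])

    def test_matches_per_pixel_loop_oracle(self):
        for seed in range(10):
            layers = random_layers(seed, n=16, n_layers=3)
            out = blend_layers(layers)
            rgb, alpha = blend_oracle(layers)
            np.testing.assert_array_equal(out.rgb_channels, rgb)
            np.testing.assert_array_equal(out.alpha, alpha)

    @given(st.integers(0, 1000), st.permutations([0, 1, 2]))
    def test_invariant_under_layer_order(self, seed, perm):
        layers = random_layers(seed, n=8, n_layers=3)
        a = blend_layers(layers)
        b = blend_layers([layers[k] for k in perm])
        np.testing.assert_array_equal(a.rgb_channels, b.rgb_channels)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    @pytest.mark.parametrize("copies", [2, 3, 5])
    def test_n_copies_keep_color_and_clip_alpha(self, copies):
        (layer,) = random_layers(2, n=8, n_layers=1)
        out = blend_layers([layer] * copies)
        expected_alpha = np.clip(layer.alpha.astype(int) * copies, 0, 255)
        np.testing.assert_array_equal(out.alpha, expected_alpha)
        nz = layer.alpha > 0
        assert (out.rgb_channels[nz] == np.array(layer.rgb)).all()

    def test_mixed_color_within_convex_hull(self):
        for seed in range(5):
            layers = random_layers(seed, n=12, n_layers=4)
            out = blend_layers(layers)
            colors = np.array([ly.rgb for ly in layers])
            total = sum(ly.alpha.astype(int) for ly in layers)
            nz = total > 0
            for k in range(3):
                ch = out.rgb_channels[..., k][nz]
                assert (ch >= colors[:, k].min()).all()
                assert (ch <= colors[:, k].max()).all()
            assert (out.alpha <= 255).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            blend_layers([])


class TestEigenLayers:
    def region(self, n):
        return GenomicRegion("chrT", 0, 100 * n, 100)

    def eig(self, values):
        return BinnedTrack(self.region(len(values)), np.asarray(values, float),
                           name="eigen", signed_flag=True)

    def test_all_positive_track_gives_transparent_b_layer(self):
        c = unit_contacts(np.ones((4, 4)))
        la, lb = eigen_layers(self.eig([3.0, 2.0, 1.0, 0.5]), c)
        assert (lb.alpha == 0).all()
        assert la.alpha.max() > 0

    def test_zero_bin_transparent_in_both_layers(self):
        c = unit_contacts(np.ones((3, 3)))
        la, lb = eigen_layers(self.eig([1.0, 0.0, -1.0]), c)
        assert (la.alpha[1, :] == 0).all() and (la.alpha[:, 1] == 0).all()
        assert (lb.alpha[1, :] == 0).all() and (lb.alpha[:, 1] == 0).all()

    def test_sign_enumeration_oracle_block_support(self):
        c = unit_contacts(np.ones((4, 4)))
        la, lb = eigen_layers(self.eig([2.0, 1.0, -1.0, -2.0]), c)
        a_support = la.alpha > 0
        b_support = lb.alpha > 0
        expect_a = np.zeros((4, 4), bool)
        expect_a[:2, :2] = True
        expect_b = np.zeros((4, 4), bool)
        expect_b[2:, 2:] = True
        np.testing.assert_array_equal(a_support, expect_a)
        np.testing.assert_array_equal(b_support, expect_b)

    def test_supports_disjoint_and_same_sign_for_random_tracks(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(3, 20))
            vals = rng.normal(0, 2, n)
            c = unit_contacts(rng.random((n, n)) * 0 + 1.0)
            la, lb = eigen_layers(self.eig(vals), c)
            a_s, b_s = la.alpha > 0, lb.alpha > 0
            assert not (a_s & b_s).any()
            sign = np.sign(vals)
            same_sign = (sign[:, None] == sign[None, :]) & (sign[:, None] != 0)
            assert not (a_s & ~same_sign).any()
            assert not (b_s & ~same_sign).any()

    def test_unsigned_track_rejected(self):
        t = BinnedTrack(self.region(3), np.ones(3), name="chip")
        with pytest.raises(ValueError, match="signed"):
            eigen_layers(t, unit_contacts(np.ones((3, 3))))


class TestChromHMMLayers:
    def seg(self, rows):
        return ChromHMMSegmentation(rows)

    def test_single_state_layer_equals_contact_alpha(self):
        region = GenomicRegion("chrT", 0, 400, 100)
        c = unit_contacts(np.full((4, 4), 0.5))
        seg = self.seg([("chrT", 0, 400, "Quies", (200, 200, 200))])
        (layer,) = chromhmm_layers(seg, region, c)
        assert (layer.alpha == round(0.5 * 255)).all()
        assert layer.rgb == (200, 200, 200)

    def test_two_states_have_disjoint_block_support(self):
        region = GenomicRegion("chrT", 0, 600, 100)
        c = unit_contacts(np.ones((6, 6)))
        seg = self.seg([
            ("chrT", 0, 200, "Enh", (255, 200, 0)),
            ("chrT", 400, 600, "Het", (100, 100, 100)),
        ])
        enh, het = chromhmm_layers(seg, region, c)
        assert not ((enh.alpha > 0) & (het.alpha > 0)).any()
        assert (enh.alpha[:2, :2] > 0).all() and (het.alpha[4:, 4:] > 0).all()
        assert enh.alpha[:, 2:].sum() == 0 and het.alpha[:, :4].sum() == 0

    def test_majority_assignment_matches_per_base_oracle(self):
        rng = np.random.default_rng(13)
        region = GenomicRegion("chrT", 0, 3000, 100)
        labels = [f"S{k}" for k in range(15)]
        colors = {lab: tuple(int(v) for v in rng.integers(0, 256, 3)) for lab in labels}
        # random segmentation with breakpoints off the bin grid
        cuts = sorted(rng.choice(np.arange(1, 3000), size=40, replace=False))
        bounds = [0] + list(int(c) for c in cuts) + [3000]
        rows = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            lab = labels[int(rng.integers(0, 15))]
            rows.append(("chrT", s, e, lab, colors[lab]))
        seg = self.seg(rows)
        assigned = assign_bins_to_states(seg, region)

        # per-base oracle: label of the majority of bases, first-seen tie-break
        order = list(seg.states)
        base_label = np.empty(3000, dtype=object)
        for chrom, s, e, lab, _ in rows:
            base_label[s:e] = lab
        for b in range(30):
            chunk = base_label[b * 100 : (b + 1) * 100]
            counts = {lab: int((chunk == lab).sum()) for lab in order}
            best = max(order, key=lambda lab: (counts[lab], -order.index(lab)))
            assert assigned[b] == best, f"bin {b}"

    def test_requested_state_absent(self):
        region = GenomicRegion("chrT", 0, 200, 100)
        seg = self.seg([("chrT", 0, 200, "Enh", (1, 2, 3))])
        with pytest.raises(ValueError, match="absent"):
            chromhmm_layers(seg, region, unit_contacts(np.ones((2, 2))),
                            states=["Het"])


@pytest.mark.parametrize("color,rgb", [
    ("#FF8000", (255, 128, 0)),
    ("red", (255, 0, 0)),
    ((10, 20, 30), (10, 20, 30)),
])
def test_parse_color(color, rgb):
    assert parse_color(color) == rgb


def test_parse_color_invalid():
    with pytest.raises(ValueError):
        parse_color("#GGGGGG")
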