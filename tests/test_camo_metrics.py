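import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preyevo import (
    FULL_BOX,
    BackgroundSpec,
    GranularitySpectrum,
    ReceptorCatch,
    TargetImage,
    VisualSystem,
    gabrat_disruption,
    generate_background,
    granularity_spectrum,
    lab_to_srgb,
    mean_colour_difference,
    pattern_difference,
    random_genome,
    render_genome,
    rnl_achromatic,
    rnl_chromatic,
    weighted_colour_difference,
)
from preyevo.camo_metrics import background_colour_clusters, compute_metrics
from preyevo.colour_vision import srgb_to_linear
from preyevo.genome_pattern import _ellipse_mask

from conftest import solid_target, uniform_background


def rect_target(rows_of_lab, target_id="rect"):
    """Full-rectangle-mask target built from a list of per-row Lab colours."""
    h = len(rows_of_lab)
    w = 40
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for r, lab in enumerate(rows_of_lab):
        rgb[r, :] = lab_to_srgb(np.asarray(lab, float))
    return TargetImage(rgb, np.ones((h, w), dtype=bool), target_id)


class TestMeanColourDifference:
    def test_background_coloured_target_scores_zero(self, vs):
        lab = (55.0, 5.0, 20.0)
        t = solid_target(lab)
        bg = uniform_background(lab)
        ds, dl = mean_colour_difference(t, bg, vs)
        assert ds == pytest.approx(0.0, abs=1e-9)
        assert dl == pytest.approx(0.0, abs=1e-9)

    def test_two_patch_target_matches_hand_average(self, vs):
        lab1, lab2 = (40.0, 10.0, 0.0), (70.0, -10.0, 30.0)
        t = rect_target([lab1] * 10 + [lab2] * 10)
        bg = uniform_background((55.0, 0.0, 15.0))
        # independent oracle: average pixel linear RGB by hand, then the
        # trichromat closed form via a separately-coded quadratic
        lin_t = srgb_to_linear(t.rgb.reshape(-1, 3).astype(float) / 255.0).mean(0)
        lin_b = srgb_to_linear(bg.reshape(-1, 3).astype(float) / 255.0).mean(0)
        qA = ReceptorCatch(vs.receptor_matrix @ lin_t)
        qB = ReceptorCatch(vs.receptor_matrix @ lin_b)
        df = np.log(qA.q / qB.q)
        e = vs.weber
        num = (e[0] ** 2 * (df[1] - df[2]) ** 2 + e[1] ** 2 * (df[0] - df[2]) ** 2
               + e[2] ** 2 * (df[0] - df[1]) ** 2)
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        expect_ds = np.sqrt(num / den)
        expect_dl = abs(np.log((vs.lum_weights @ lin_t) /
                               (vs.lum_weights @ lin_b))) / vs.weber_lum
        ds, dl = mean_colour_difference(t, bg, vs)
        assert ds == pytest.approx(expect_ds, rel=1e-9)
        assert dl == pytest.approx(expect_dl, rel=1e-9)

    def test_pixel_permutation_invariance(self, vs, rng):
        t = render_genome(random_genome(rng, FULL_BOX), FULL_BOX, (64, 48))
        bg = uniform_background((55.0, 0.0, 15.0))
        ds, dl = mean_colour_difference(t, bg, vs)
        # shuffle masked pixels in place
        rgb = t.rgb.copy()
        vals = rgb[t.alpha_mask]
        rgb[t.alpha_mask] = vals[rng.permutation(len(vals))]
        t2 = TargetImage(rgb, t.alpha_mask, "shuffled")
        ds2, dl2 = mean_colour_difference(t2, bg, vs)
        assert ds2 == pytest.approx(ds, rel=1e-12)
        assert dl2 == pytest.approx(dl, rel=1e-12)

    def test_empty_mask_raises(self, vs):
        t = TargetImage(np.zeros((16, 16, 3), np.uint8),
                        np.zeros((16, 16), bool), "empty")
        with pytest.raises(ValueError):
            mean_colour_difference(t, uniform_background((50, 0, 0)), vs)


class TestWeightedColourDifference:
    def test_zero_when_all_target_colours_in_background(self, vs):
        lab1, lab2 = (40.0, 10.0, 0.0), (70.0, -10.0, 30.0)
        t = rect_target([lab1] * 8 + [lab2] * 8)
        bg1 = uniform_background(lab1, (32, 32))
        bg2 = uniform_background(lab2, (32, 32))
        bg = np.concatenate([bg1, bg2], axis=0)
        assert weighted_colour_difference(t, bg, vs) == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_single_colour_target_reduces_to_min(self, vs):
        lab_t = (50.0, 0.0, 10.0)
        t = rect_target([lab_t] * 8)
        bg_labs = [(30.0, 20.0, 0.0), (52.0, 1.0, 12.0), (80.0, -20.0, 40.0)]
        bg = np.concatenate([uniform_background(l, (32, 16)) for l in bg_labs],
                            axis=0)
        got = weighted_colour_difference(t, bg, vs)
        # brute force over all background colours
        from preyevo.camo_metrics import _lab_to_catches
        from preyevo.colour_vision import srgb_to_lab
        qt = _lab_to_catches(srgb_to_lab(lab_to_srgb(np.array(lab_t)))[None, :], vs)[0]
        dmins = []
        for l in bg_labs:
            qb = _lab_to_catches(srgb_to_lab(lab_to_srgb(np.array(l)))[None, :], vs)[0]
            dmins.append(rnl_chromatic(ReceptorCatch(qt), ReceptorCatch(qb), vs))
        assert got == pytest.approx(min(dmins), rel=1e-6)

    def test_two_colour_frequencies_oracle(self, vs):
        lab1, lab2 = (35.0, 15.0, -5.0), (75.0, -15.0, 45.0)
        t = rect_target([lab1] * 12 + [lab2] * 4)  # 75% / 25%
        bg_labs = [(40.0, 10.0, 0.0), (70.0, -10.0, 40.0)]
        bg = np.concatenate([uniform_background(l, (32, 16)) for l in bg_labs],
                            axis=0)
        got = weighted_colour_difference(t, bg, vs)
        # brute force over every (target colour, background colour) pair
        from preyevo.camo_metrics import _lab_to_catches
        from preyevo.colour_vision import srgb_to_lab

        def catch(lab):
            return ReceptorCatch(_lab_to_catches(
                srgb_to_lab(lab_to_srgb(np.array(lab)))[None, :], vs)[0])

        d1 = min(rnl_chromatic(catch(lab1), catch(l), vs) for l in bg_labs)
        d2 = min(rnl_chromatic(catch(lab2), catch(l), vs) for l in bg_labs)
        assert got == pytest.approx(0.75 * d1 + 0.25 * d2, rel=1e-6)

    def test_bounded_by_worst_single_colour(self, vs, rng):
        t = render_genome(random_genome(rng, FULL_BOX), FULL_BOX, (64, 48))
        bg = generate_background(BackgroundSpec(size=(128, 128), seed=9))
        clusters = background_colour_clusters(bg, seed=0)
        got = weighted_colour_difference(t, bg, vs, bg_clusters=clusters)
        # the weighted average cannot exceed the max per-colour minimum
        from preyevo.camo_metrics import _colour_clusters, _lab_to_catches
        from preyevo.colour_vision import srgb_to_lab
        t_lab = srgb_to_lab(t.rgb)[t.alpha_mask]
        cents, freqs = _colour_clusters(t_lab, 4, 0)
        qt = _lab_to_catches(cents, vs)
        qb = _lab_to_catches(clusters, vs)
        dmins = [min(rnl_chromatic(ReceptorCatch(a), ReceptorCatch(b), vs)
                     for b in qb) for a in qt]
        assert got <= max(dmins) + 1e-9

    def test_invalid_cluster_count(self, vs):
        t = solid_target((50, 0, 0))
        with pytest.raises(ValueError):
            weighted_colour_difference(t, uniform_background((50, 0, 0)), vs,
                                       n_bg_clusters=0)


class TestGranularity:
    def test_uniform_image_all_zero(self):
        img = np.full((128, 128), 0.5)
        spec = granularity_spectrum(img)
        assert np.allclose(spec.energy, 0.0, atol=1e-12)

    def test_grating_peaks_at_matching_band(self):
        x = np.arange(128)
        img = np.tile(0.5 + 0.4 * np.sin(2 * np.pi * x / 16.0), (128, 1))
        spec = granularity_spectrum(img, scales=(2, 4, 8, 16, 32, 64))
        assert spec.scales[int(np.argmax(spec.energy))] == 16

    def test_dc_invariance(self, rng):
        img = rng.random((64, 64))
        e1 = granularity_spectrum(img, scales=(2, 4, 8, 16)).energy
        e2 = granularity_spectrum(img + 3.7, scales=(2, 4, 8, 16)).energy
        assert np.allclose(e1, e2, atol=1e-9)

    def test_scale_larger_than_image_raises(self):
        with pytest.raises(ValueError):
            granularity_spectrum(np.zeros((32, 32)), scales=(2, 64))


class TestPatternDifference:
    def test_identical_spectra_zero(self):
        s = GranularitySpectrum((2, 4, 8), np.array([1.0, 2.0, 0.5]))
        assert pattern_difference(s, s) == 0.0

    def test_symmetry(self):
        a = GranularitySpectrum((2, 4, 8), np.array([1.0, 0.0, 3.0]))
        b = GranularitySpectrum((2, 4, 8), np.array([0.5, 2.0, 1.0]))
        assert pattern_difference(a, b) == pattern_difference(b, a)

    def test_unit_vectors(self):
        a = GranularitySpectrum((2, 4, 8), np.array([1.0, 0.0, 0.0]))
        b = GranularitySpectrum((2, 4, 8), np.array([0.0, 1.0, 0.0]))
        assert pattern_difference(a, b) == 2.0

    def test_scale_mismatch_raises(self):
        a = GranularitySpectrum((2, 4), np.array([1.0, 0.0]))
        b = GranularitySpectrum((2, 8), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            pattern_difference(a, b)

    @given(st.lists(st.floats(0, 10), min_size=4, max_size=4),
           st.lists(st.floats(0, 10), min_size=4, max_size=4),
           st.lists(st.floats(0, 10), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, x, y, z):
        scales = (2, 4, 8, 16)
        a = GranularitySpectrum(scales, np.array(x))
        b = GranularitySpectrum(scales, np.array(y))
        c = GranularitySpectrum(scales, np.array(z))
        assert pattern_difference(a, c) <= \
            pattern_difference(a, b) + pattern_difference(b, c) + 1e-9


class TestGabRat:
    def test_invisible_target_is_zero_by_convention(self, vs):
        lab = (50.0, 0.0, 20.0)
        assert gabrat_disruption(solid_target(lab, (96, 72)),
                                 uniform_background(lab, (192, 192))) == 0.0

    def test_uniform_disc_has_coherent_outline(self):
        g = gabrat_disruption(solid_target((90.0, 0.0, 20.0), (96, 72)),
                              uniform_background((50.0, 0.0, 20.0), (192, 192)))
        assert 0.0 < g < 0.3

    def test_stripes_crossing_outline_raise_disruption(self):
        bg = uniform_background((50.0, 0.0, 20.0), (192, 192))
        disc = gabrat_disruption(solid_target((90.0, 0.0, 20.0), (96, 72)), bg)
        w, h = 96, 72
        mask = _ellipse_mask(w, h)
        rgb = np.zeros((h, w, 3), np.uint8)
        c1 = lab_to_srgb(np.array([95.0, 0.0, 20.0]))
        c2 = lab_to_srgb(np.array([5.0, 0.0, 20.0]))
        for r in range(h):
            rgb[r, mask[r]] = c1 if (r // 4) % 2 else c2
        striped = gabrat_disruption(TargetImage(rgb, mask, "striped"), bg)
        assert striped > disc

    def test_bounded_on_random_fixtures(self, rng):
        for i in range(25):
            t = render_genome(random_genome(rng, FULL_BOX, f"g{i}"), FULL_BOX,
                              (64, 48))
            bg = generate_background(BackgroundSpec(size=(160, 160), seed=i))
            g = gabrat_disruption(t, bg)
            assert 0.0 <= g <= 1.0

    def test_degenerate_mask_raises(self):
        t = TargetImage(np.zeros((16, 16, 3), np.uint8),
                        np.zeros((16, 16), bool), "none")
        with pytest.raises(ValueError):
            gabrat_disruption(t, uniform_background((50, 0, 0)))


class TestComputeMetrics:
    def test_deterministic(self, vs, rng):
        t = render_genome(random_genome(rng, FULL_BOX), FULL_BOX, (128, 96))
        bg = generate_background(BackgroundSpec(size=(160, 160), seed=1))
        m1 = compute_metrics(t, bg, vs, seed=3)
        m2 = compute_metrics(t, bg, vs, seed=3)
        assert m1 == m2

    def test_all_fields_finite_and_nonnegative(self, vs, rng):
        t = render_genome(random_genome(rng, FULL_BOX), FULL_BOX, (128, 96))
        bg = generate_background(BackgroundSpec(size=(160, 160), seed=2))
        m = compute_metrics(t, bg, vs)
        for v in (m.delta_s_mean, m.delta_l_mean, m.delta_s_weighted,
                  m.pattern_difference, m.gabrat):
            assert np.isfinite(v) and v >= 0
        assert m.gabrat <= 1.0
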