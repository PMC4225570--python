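"""Product-form similarity, similarity maps and threshold segmentation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specseg import simmap, spectra_core as sc, synth

unit_vec = st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8)


class TestSimilarity:
    def test_hand_value(self):
        # (1 - 0.2^2)(1 - 0.1^2) = 0.96 * 0.99
        assert simmap.similarity([0.2, 0.8], [0.4, 0.7], 2) == pytest.approx(0.9504)

    def test_identity_is_one(self):
        R = np.array([0.1, 0.4, 0.9])
        for alpha in (0.5, 1.0, 1.7):
            assert simmap.similarity(R, R, alpha) == 1.0

    def test_maximal_single_channel_difference_annihilates(self):
        assert simmap.similarity([0.0], [1.0], 1.3) == 0.0

    def test_domain_and_shape_errors(self):
        with pytest.raises(ValueError, match="rescale"):
            simmap.similarity([1.2], [0.5], 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            simmap.similarity([0.2, 0.3], [0.5], 1.0)

    @settings(max_examples=200, deadline=None)
    @given(unit_vec, unit_vec, st.floats(0.2, 3.0))
    def test_bounded_and_symmetric(self, r, s, alpha):
        n = min(len(r), len(s))
        R, S = np.array(r[:n]), np.array(s[:n])
        v = simmap.similarity(R, S, alpha)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(simmap.similarity(S, R, alpha))

    def test_monotone_in_channel_differences(self):
        rng = np.random.default_rng(2)
        R = rng.random(6)
        S = rng.random(6)
        closer = R + 0.5 * (S - R)  # shrink every |R_i - S_i|
        assert simmap.similarity(R, closer, 1.5) >= simmap.similarity(R, S, 1.5)

    def test_alpha_monotonicity(self):
        # larger alpha lessens the product's tendency to vanish
        rng = np.random.default_rng(3)
        for _ in range(200):
            R, S = rng.random(5), rng.random(5)
            s1 = simmap.similarity(R, S, 1.0)
            s2 = simmap.similarity(R, S, 1.5)
            s3 = simmap.similarity(R, S, 2.0)
            assert s1 <= s2 <= s3


class TestPowerDistance:
    def test_reflexive_and_hand_value(self):
        X = np.array([0.2, 0.8])
        assert simmap.power_distance(X, X, 2) == 0.0
        assert simmap.power_distance(X, [0.4, 0.7], 2) == pytest.approx(0.0496)

    def test_triangle_inequality_at_alpha_one(self):
        rng = np.random.default_rng(4)
        X = rng.random((20000, 3, 6))
        d = lambda a, b: 1 - np.prod(1 - np.abs(a - b), axis=-1)
        viol = d(X[:, 0], X[:, 2]) - d(X[:, 0], X[:, 1]) - d(X[:, 1], X[:, 2])
        assert viol.max() <= 1e-12

    def test_triangle_inequality_fails_above_alpha_one(self):
        # the distance is a true metric only for alpha <= 1: the classic
        # one-channel counterexample 0, 0.5, 1 violates it at alpha = 2
        d = lambda a, b: simmap.power_distance(np.array([a]), np.array([b]), 2.0)
        assert d(0.0, 1.0) > d(0.0, 0.5) + d(0.5, 1.0)

    def test_pairwise_matches_scalar_route(self):
        rng = np.random.default_rng(5)
        X = rng.random((12, 9))
        D = simmap.pairwise_power_distance(X, alpha=1.5)
        for i, j in [(0, 3), (2, 11), (7, 7), (4, 5)]:
            assert D[i, j] == pytest.approx(
                simmap.power_distance(X[i], X[j], 1.5), abs=1e-6)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)


class TestComputeMap:
    def test_map_is_one_at_reference_pixel(self, small_phantom):
        _spec, img, _gt = small_phantom
        from specseg.spectra_core import qc_filter, rescale_unit

        img = rescale_unit(qc_filter(img).image)
        r, c = map(int, np.argwhere(img.valid_mask)[0])
        m = simmap.compute_map(img, (r, c), alpha=1.5)
        assert m.intensities[r, c] == pytest.approx(1.0)
        assert np.isnan(m.intensities[~img.valid_mask]).all()

    def test_constant_image_maps_to_one(self):
        img = sc.SpectralImage(np.full((3, 3, 4), 0.5), np.arange(4.0))
        m = simmap.compute_map(img, (0, 0), alpha=1.0)
        np.testing.assert_allclose(m.intensities, 1.0)

    def test_reference_on_invalid_pixel_rejected(self):
        img = sc.SpectralImage(np.full((2, 2, 3), 0.5), np.arange(3.0))
        img.valid_mask[0, 0] = False
        with pytest.raises(ValueError, match="invalid"):
            simmap.compute_map(img, (0, 0))

    def test_map_higher_inside_own_class_region(self, small_phantom):
        _spec, img, gt = small_phantom
        from specseg.spectra_core import qc_filter, rescale_unit

        img = rescale_unit(qc_filter(img).image)
        cls = 0
        inside = (gt.labels == cls) & img.valid_mask
        outside = (gt.labels >= 0) & (gt.labels != cls) & img.valid_mask
        r, c = map(int, np.argwhere(inside)[0])
        m = simmap.compute_map(img, (r, c)).intensities
        assert np.nanmean(m[inside]) > np.nanmean(m[outside])


class TestSegment:
    def _rescaled(self, small_phantom):
        from specseg.spectra_core import qc_filter, rescale_unit

        spec, img, gt = small_phantom
        return spec, rescale_unit(qc_filter(img).image), gt

    def test_threshold_zero_assigns_every_valid_pixel(self, small_phantom):
        _spec, img, _gt = self._rescaled(small_phantom)
        R = img.valid_spectra()[0]
        refs = simmap.ReferenceSet([simmap.ReferenceEntry(7, R, threshold=0.0)])
        seg = simmap.segment(img, refs)
        assert np.all(seg.labels[img.valid_mask] == 7)
        assert np.all(seg.labels[~img.valid_mask] == sc.BACKGROUND)

    def test_threshold_one_keeps_only_the_reference_pixel(self):
        rng = np.random.default_rng(8)
        vals = np.clip(0.5 + rng.normal(0, 0.01, (6, 6, 10)), 0, 1)
        img = sc.SpectralImage(vals, np.arange(10.0))
        refs = simmap.ReferenceSet(
            [simmap.ReferenceEntry(0, img.values[2, 3], threshold=1.0)])
        seg = simmap.segment(img, refs)
        assigned = np.argwhere(seg.labels == 0)
        np.testing.assert_array_equal(assigned, [[2, 3]])

    def test_phantom_two_class_agreement(self, small_phantom):
        spec, img, gt = self._rescaled(small_phantom)
        means = synth.class_mean_spectra(spec)
        entries = []
        for cls in range(spec.K):
            region = (gt.labels == cls) & img.valid_mask
            pix = np.argwhere(region)
            specs = img.values[region]
            # reference = pixel nearest its class's mean shape
            target = means[cls]
            target = (target - target.min()) / (target.max() - target.min())
            best = np.argmin(((specs - specs.mean(0)) ** 2).sum(1))
            r, c = map(int, pix[best])
            entries.append(simmap.ReferenceEntry(cls, img.values[r, c], 0.5))
        seg = simmap.segment(img, simmap.ReferenceSet(entries, alpha=1.5))
        m = img.valid_mask & (gt.labels >= 0)
        agree = (seg.labels[m] == gt.labels[m]).mean()
        assert agree >= 0.95

    def test_raising_threshold_never_grows_a_class(self, small_phantom):
        _spec, img, _gt = self._rescaled(small_phantom)
        R = img.valid_spectra()[10]
        region = lambda t: simmap.segment(
            img, simmap.ReferenceSet([simmap.ReferenceEntry(0, R, t)])
        ).labels == 0
        lo, hi = region(0.3), region(0.6)
        assert np.all(hi <= lo)

    def test_at_most_two_references_per_class(self):
        R = np.full(4, 0.5)
        entries = [simmap.ReferenceEntry(1, R, 0.5) for _ in range(3)]
        with pytest.raises(ValueError, match="more than two"):
            simmap.ReferenceSet(entries)


def test_reference_csv_round_trip(tmp_path, small_phantom):
    from specseg.spectra_core import qc_filter, rescale_unit

    _spec, img, _gt = small_phantom
    img = rescale_unit(qc_filter(img).image)
    pos = [tuple(map(int, p)) for p in np.argwhere(img.valid_mask)[:2]]
    entries = [
        simmap.ReferenceEntry(0, img.values[pos[0]], 0.4, "crypts", pos[0]),
        simmap.ReferenceEntry(1, img.values[pos[1]], 0.6, "tumour", pos[1]),
    ]
    refs = simmap.ReferenceSet(entries, alpha=1.2)
    path = tmp_path / "refs.csv"
    refs.to_csv(path)
    back = simmap.ReferenceSet.from_csv(path, img, alpha=1.2)
    assert [e.class_id for e in back.entries] == [0, 1]
    np.testing.assert_allclose(back.entries[0].spectrum, entries[0].spectrum)
    assert back.entries[1].threshold == 0.6
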