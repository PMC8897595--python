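"""Image primitives against brute-force oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage import morphology

from majorsat.foci import (
    compare_groups,
    detect_foci,
    enhance_speckles,
    max_project,
    otsu_threshold,
    relate_objects,
    robust_background_threshold,
)


def otsu_oracle(image, nbins=256):
    """Exhaustive search over all histogram splits for the threshold that
    maximizes between-class variance (first maximizer wins)."""
    values = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
        if between > best:
            best, best_t = between, centers[k]
    return best_t


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        img = rng.uniform(size=(1, 8, 8))
        assert np.array_equal(max_project(img), img[0])

    def test_two_slices_elementwise(self):
        a = np.array([[1, 5], [3, 0]])
        b = np.array([[2, 4], [3, 7]])
        assert np.array_equal(max_project(np.stack([a, b])), [[2, 5], [3, 7]])

    def test_matches_per_pixel_loop(self, rng):
        stack = rng.uniform(size=(5, 12, 10))
        proj = max_project(stack)
        for r in range(12):
            for c in range(10):
                assert proj[r, c] == max(stack[z, r, c] for z in range(5))


class TestOtsu:
    def test_two_valued_image(self):
        img = np.array([[0.0] * 5, [1000.0] * 5])
        t = otsu_threshold(img)
        assert 0 < t < 1000
        assert ((img > t) == (img == 1000)).all()

    def test_constant_image_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            t = otsu_threshold(np.full((4, 4), 7.0))
        assert t == 7.0
        assert not (np.full((4, 4), 7.0) > t).any()

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, size=(16, 16)).astype(float)
            assert otsu_threshold(img) == pytest.approx(otsu_oracle(img))

    def test_agrees_with_skimage(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(20):
            img = rng.normal(size=(20, 20))
            assert otsu_threshold(img) == pytest.approx(
                threshold_otsu(img, nbins=256)
            )


class TestEnhanceSpeckles:
    def test_constant_image_gives_zero(self):
        assert np.allclose(enhance_speckles(np.full((20, 20), 3.0), 7), 0.0)

    def test_small_disk_preserved(self):
        img = np.zeros((40, 40))
        rr, cc = np.mgrid[:40, :40]
        small = (rr - 20) ** 2 + (cc - 20) ** 2 <= 3**2
        img[small] = 1.0
        out = enhance_speckles(img, 15)
        assert out[20, 20] == pytest.approx(1.0)
        assert np.allclose(out[~small], 0.0, atol=1e-12)

    def test_matches_composed_morphology_oracle(self, rng):
        fp = morphology.disk(3)
        for _ in range(50):
            img = rng.uniform(size=(24, 24))
            oracle = img - ndimage.grey_dilation(
                ndimage.grey_erosion(img, footprint=fp), footprint=fp
            )
            assert np.allclose(enhance_speckles(img, 7), oracle)


class TestRobustBackground:
    def test_constant_pixels(self):
        assert robust_background_threshold(np.full(50, 7.0)) == pytest.approx(7.0)

    def test_worked_example(self):
        """1..100 trimmed at 5% each end retains 6..95: mean 50.5,
        SD ~25.98, threshold ~102.46."""
        t = robust_background_threshold(np.arange(1, 101, dtype=float))
        assert t == pytest.approx(102.458, abs=0.01)

    def test_monotone_in_n_sd(self, rng):
        pixels = rng.normal(size=500)
        ts = [robust_background_threshold(pixels, n_sd=k) for k in (0, 1, 2, 3)]
        assert all(a <= b for a, b in zip(ts, ts[1:]))

    def test_all_trimmed_rejected(self):
        with pytest.raises(ValueError, match="trimmed"):
            robust_background_threshold(np.arange(10.0), trim_low=0.7, trim_high=0.7)


class TestDetectFoci:
    @staticmethod
    def scene(spots, shape=(64, 64), sigma=2.5, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(0, noise, size=shape)
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        for r, c in spots:
            img += np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
        return img

    def test_planted_spots_found(self):
        spots = [(15, 15), (15, 45), (45, 30)]
        records, _ = detect_foci(self.scene(spots), (5, 35))
        assert len(records) == 3
        for r, c in spots:
            d = np.hypot(records.centroid_row - r, records.centroid_col - c)
            assert d.min() <= 2.0

    def test_subminimal_focus_gated_out(self):
        # a 2x2 plateau (area 4) is below the pi*(5/2)^2 ~ 19.6 px area gate
        img = np.random.default_rng(1).normal(0, 0.01, size=(64, 64))
        img[30:32, 30:32] += 5.0
        records, _ = detect_foci(img, (5, 35))
        assert records.empty

    def test_noise_only_image(self):
        img = np.random.default_rng(2).normal(0, 0.01, size=(64, 64))
        records, _ = detect_foci(img, (5, 35))
        assert records.empty

    def test_intensity_measured_on_original(self):
        spots = [(32, 32)]
        enhanced = self.scene(spots, noise=0.0)
        original = enhanced + 10.0  # pre-enhancement image has an offset
        records, _ = detect_foci(enhanced, (5, 35), intensity_image=original)
        assert records["mean_intensity"].iloc[0] > 10.0


def _labels_from(mask_specs, shape=(30, 30)):
    lab = np.zeros(shape, dtype=int)
    for idx, (r0, r1, c0, c1) in mask_specs.items():
        lab[r0:r1, c0:c1] = idx
    return lab


class TestRelateObjects:
    @staticmethod
    def records(centroids):
        return pd.DataFrame(
            [
                {"focus_id": i + 1, "centroid_row": r, "centroid_col": c}
                for i, (r, c) in enumerate(centroids)
            ]
        )

    def test_child_inside_parent_both_rules(self):
        parents = _labels_from({1: (5, 20, 5, 20)})
        children = _labels_from({1: (8, 12, 8, 12)})
        recs = self.records([(9.5, 9.5)])
        for rule in ("centroid_in_parent", "max_overlap"):
            out = relate_objects(recs, children, parents, rule)
            assert out["parent_id"].iloc[0] == 1

    def test_rule_contrast_on_partial_overlap(self):
        """Child straddling a parent edge: centroid on background gives no
        parent; max_overlap assigns the overlapped parent."""
        parents = _labels_from({1: (0, 10, 0, 30)})
        children = _labels_from({1: (8, 13, 10, 14)})  # rows 8-12, 40% inside
        recs = self.records([(10.0, 11.5)])  # centroid row 10: background
        out_centroid = relate_objects(recs, children, parents, "centroid_in_parent")
        assert out_centroid["parent_id"].isna().iloc[0]
        out_overlap = relate_objects(recs, children, parents, "max_overlap")
        assert out_overlap["parent_id"].iloc[0] == 1

    def test_overlap_tie_breaks_to_lower_parent_id(self):
        parents = _labels_from({2: (0, 10, 0, 15), 1: (0, 10, 15, 30)})
        children = _labels_from({1: (2, 4, 13, 17)})  # 2 px in each parent
        out = relate_objects(self.records([(2.5, 14.5)]), children, parents, "max_overlap")
        assert out["parent_id"].iloc[0] == 1

    def test_matches_per_pixel_oracle(self, rng):
        """Random label scenes: both rules agree with a brute-force loop
        over every pixel."""
        for _ in range(50):
            parents = rng.integers(0, 4, size=(20, 20))
            parents = ndimage.grey_dilation(parents, size=3)  # chunkier regions
            children = np.zeros((20, 20), dtype=int)
            recs = []
            for cid in (1, 2, 3):
                r, c = rng.integers(2, 18, size=2)
                children[r : r + 2, c : c + 2] = cid
                recs.append({"focus_id": cid, "centroid_row": r + 0.5,
                             "centroid_col": c + 0.5})
            recs = pd.DataFrame(recs)
            got = relate_objects(recs, children, parents, "max_overlap")
            for row in recs.itertuples():
                votes = {}
                for r in range(20):
                    for c in range(20):
                        if children[r, c] == row.focus_id and parents[r, c] > 0:
                            votes[parents[r, c]] = votes.get(parents[r, c], 0) + 1
                expected = (
                    min(p for p, v in votes.items() if v == max(votes.values()))
                    if votes
                    else None
                )
                val = got.loc[got.focus_id == row.focus_id, "parent_id"].iloc[0]
                assert (pd.isna(val) and expected is None) or val == expected
            got_c = relate_objects(recs, children, parents, "centroid_in_parent")
            for row in recs.itertuples():
                p = parents[int(round(row.centroid_row)), int(round(row.centroid_col))]
                val = got_c.loc[got_c.focus_id == row.focus_id, "parent_id"].iloc[0]
                assert (pd.isna(val) and p == 0) or val == p


class TestCompareGroups:
    def test_identical_samples(self):
        g = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert g.p_value == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        """{5,6,7} vs {1,2,3}: U = 9 and exact two-sided p = 2/C(6,3) = 0.1."""
        g = compare_groups([5, 6, 7], [1, 2, 3])
        assert g.u_statistic == 9.0
        assert g.p_value == pytest.approx(0.1)
        assert g.method == "exact"

    def test_rank_invariance_under_scaling(self):
        a, b = [1.0, 3.0, 5.0, 9.0], [2.0, 4.0, 6.0]
        g1 = compare_groups(a, b)
        g2 = compare_groups([2 * x for x in a], [2 * x for x in b])
        assert g1.u_statistic == g2.u_statistic
        assert g1.p_value == pytest.approx(g2.p_value)

    def test_median_iqr(self):
        g = compare_groups([1, 2, 3, 4, 100], [5, 6, 7])
        assert g.medians == (3.0, 6.0)
        assert g.q1[0] == 2.0 and g.q3[0] == 4.0
        assert g.q1[0] <= g.medians[0] <= g.q3[0]

    def test_ties_switch_to_asymptotic(self):
        g = compare_groups([1, 1, 2, 3], [1, 2, 2, 4])
        assert g.method == "asymptotic"
        assert 0 <= g.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
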