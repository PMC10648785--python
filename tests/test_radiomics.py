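"""Texture matrices and features against brute-force oracles and invariants."""

import numpy as np
import pytest

from scintrec.radiomics import (
    DEFAULT_CATALOGUE,
    discretize,
    extract_features,
    extract_view_features,
    first_order,
    glcm,
    glrlm,
    glszm,
    ngldm,
)
from scintrec.radiomics.matrices import DIRECTIONS

from oracles import (
    first_order_oracle,
    glcm_oracle,
    glrlm_oracle,
    glszm_oracle,
    ngldm_oracle,
)


def _roi(levels, mask=None, ng=None):
    levels = np.asarray(levels, dtype=np.int32)
    mask = np.ones_like(levels, bool) if mask is None else np.asarray(mask, bool)
    from scintrec.radiomics.matrices import DiscretizedROI

    lv = np.where(mask, levels, 0).astype(np.int32)
    return DiscretizedROI(lv, mask, int(lv.max()), ng or int(lv.max()))


class TestDiscretize:
    def test_two_bins(self):
        img = np.array([[0.0, 0.5, 1.0]])
        roi = discretize(img, np.ones((1, 3), bool), bin_count=2)
        assert roi.levels.tolist() == [[1, 2, 2]]

    def test_constant_roi_single_level(self):
        roi = discretize(np.full((3, 3), 0.4), np.ones((3, 3), bool), bin_count=8)
        assert roi.n_levels == 1 and np.all(roi.levels == 1)

    def test_single_bin_collapses_everything(self):
        img = np.random.default_rng(0).random((4, 4))
        roi = discretize(img, np.ones((4, 4), bool), bin_count=1)
        assert np.all(roi.levels == 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            discretize(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestGlcm:
    def test_two_by_two_horizontal(self):
        roi = _roi([[1, 1], [2, 2]])
        m = glcm(roi, directions=((0, 1),))[0]
        assert np.allclose(m.values, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_roi_single_entry(self):
        roi = _roi(np.ones((3, 3), int))
        m = glcm(roi, directions=((0, 1),))[0]
        assert m.values[0, 0] == 1.0 and m.values.sum() == 1.0

    def test_matches_oracle_all_directions(self, rng):
        levels = rng.integers(1, 5, size=(6, 6))
        mask = rng.random((6, 6)) < 0.8
        mask[0, 0] = True  # keep the mask nonempty
        roi = _roi(levels, mask)
        for m, (dr, dc) in zip(glcm(roi), DIRECTIONS):
            assert np.allclose(m.values, glcm_oracle(roi.levels, mask, dr, dc))


class TestGlrlm:
    def test_hand_enumerated_runs(self):
        roi = _roi([[1, 1, 2]])
        m = glrlm(roi, directions=((0, 1),))[0].values
        assert m[0, 1] == 1 and m[1, 0] == 1 and m.sum() == 2

    def test_constant_row_run_percentage(self):
        roi = _roi(np.ones((1, 7), int))
        m = glrlm(roi, directions=((0, 1),))[0].values
        assert m[0, 6] == 1 and m.sum() == 1

    def test_conservation_and_oracle(self, rng):
        levels = rng.integers(1, 4, size=(6, 6))
        mask = rng.random((6, 6)) < 0.7
        mask[2, 2] = True
        roi = _roi(levels, mask)
        n_pix = mask.sum()
        for m, (dr, dc) in zip(glrlm(roi), DIRECTIONS):
            v = m.values
            run_mass = (v * np.arange(1, v.shape[1] + 1)[None, :]).sum()
            assert run_mass == n_pix
            assert np.allclose(v, glrlm_oracle(roi.levels, mask, dr, dc))


class TestGlszm:
    def test_two_zones(self):
        roi = _roi([[1, 1, 2], [1, 0, 0]], mask=[[1, 1, 1], [1, 0, 0]])
        m = glszm(roi).values
        assert m[0, 2] == 1 and m[1, 0] == 1 and m.sum() == 2

    def test_constant_roi_single_zone(self):
        roi = _roi(np.ones((3, 4), int))
        m = glszm(roi).values
        assert m[0, 11] == 1 and m.sum() == 1

    def test_conservation_and_oracle(self, rng):
        levels = rng.integers(1, 4, size=(6, 6))
        mask = rng.random((6, 6)) < 0.7
        mask[3, 3] = True
        roi = _roi(levels, mask)
        m = glszm(roi).values
        s = np.arange(1, m.shape[1] + 1)
        assert (m * s[None, :]).sum() == mask.sum()
        assert np.allclose(m, glszm_oracle(roi.levels, mask))


class TestNgldm:
    def test_constant_three_by_three(self):
        roi = _roi(np.ones((3, 3), int))
        m = ngldm(roi).values
        # centre has 8 dependent neighbours, corners 3, edges 5
        assert m[0, 8] == 1 and m[0, 3] == 4 and m[0, 5] == 4

    def test_single_pixel_roi(self):
        roi = _roi([[1]])
        m = ngldm(roi).values
        assert m[0, 0] == 1 and m.sum() == 1

    def test_conservation_and_oracle(self, rng):
        levels = rng.integers(1, 4, size=(6, 6))
        mask = rng.random((6, 6)) < 0.7
        mask[1, 4] = True
        roi = _roi(levels, mask)
        for alpha in (0, 1):
            m = ngldm(roi, alpha=alpha).values
            assert m.sum() == mask.sum()
            assert np.allclose(m, ngldm_oracle(roi.levels, mask, alpha=alpha))


class TestFirstOrder:
    def test_symmetric_sample(self):
        img = np.array([[1.0, 2.0, 3.0]])
        f = first_order(img, np.ones((1, 3), bool))
        assert f["Range"] == 2 and f["Mean"] == 2 and f["Skewness"] == 0

    def test_energy_with_pixel_area(self):
        img = np.array([[2.0, 2.0]])
        f = first_order(img, np.ones((1, 2), bool), pixel_area=1.0)
        assert f["Energy"] == 8 and f["TotalEnergy"] == 8
        f2 = first_order(img, np.ones((1, 2), bool), pixel_area=0.5)
        assert f2["TotalEnergy"] == 4

    def test_matches_naive_oracle(self, rng):
        img = rng.random((8, 8))
        mask = rng.random((8, 8)) < 0.75
        mask[4, 4] = True
        f = first_order(img, mask)
        ref = first_order_oracle(img[mask])
        for k, v in ref.items():
            assert f[k] == pytest.approx(v, rel=1e-10), k

    def test_constant_roi_degenerate_moments(self):
        f = first_order(np.full((3, 3), 2.0), np.ones((3, 3), bool))
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0 and f["Variance"] == 0


class TestExtractFeatures:
    def test_catalogue_totals_64(self):
        assert DEFAULT_CATALOGUE.per_view_count == 64

    def test_counts_and_prefixes(self, phantom_pair):
        p, mask_a, mask_p = phantom_pair
        fv = extract_features(
            p.images.anterior.pixels, p.images.posterior.pixels, mask_a, mask_p
        )
        assert len(fv) == 128
        assert sum(k.startswith("front_") for k in fv) == 64
        assert sum(k.startswith("back_") for k in fv) == 64
        assert all(np.isfinite(v) for v in fv.values())

    def test_identical_views_give_identical_values(self, phantom_pair):
        p, mask_a, _ = phantom_pair
        img = p.images.anterior.pixels
        fv = extract_features(img, img, mask_a, mask_a)
        for k in [k for k in fv if k.startswith("front_")]:
            assert fv[k] == fv["back_" + k[len("front_"):]]

    def test_translation_invariance(self, phantom_pair):
        p, mask_a, _ = phantom_pair
        img = p.images.anterior.pixels
        base = extract_view_features(img, mask_a)
        shifted = extract_view_features(
            np.roll(img, (5, 3), axis=(0, 1)), np.roll(mask_a, (5, 3), axis=(0, 1))
        )
        for k, v in base.items():
            assert shifted[k] == pytest.approx(v, rel=1e-9), k

    def test_mirror_invariance(self, phantom_pair):
        p, mask_a, _ = phantom_pair
        img = p.images.anterior.pixels
        base = extract_view_features(img, mask_a)
        mirrored = extract_view_features(img[:, ::-1], mask_a[:, ::-1])
        for k, v in base.items():
            assert mirrored[k] == pytest.approx(v, rel=1e-9), k

    def test_deterministic(self, phantom_pair):
        p, mask_a, mask_p = phantom_pair
        args = (p.images.anterior.pixels, p.images.posterior.pixels, mask_a, mask_p)
        assert extract_features(*args) == extract_features(*args)
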