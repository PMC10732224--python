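"""Feature tensors, splits and standardization."""

import numpy as np
import pytest

from writhenet.features import (FEATURE_KINDS, Standardizer, featurize,
                                split_dataset)
from writhenet.fixtures import circle, parametric_knot
from writhenet.writhe import sts_writhe


@pytest.fixture(scope="module")
def small_set():
    return [parametric_knot("3_1", 120), parametric_knot("4_1", 120),
            circle(120)]


class TestFeaturize:
    def test_shapes_per_kind(self, small_set):
        n = 120
        expect = {"xyz": (3, n, 3), "sta_signed": (3, n), "sta_unsigned": (3, n),
                  "sts": (3, n, n), "curvature": (3, n), "density": (3, n)}
        for kind in FEATURE_KINDS:
            t = featurize(small_set, kind)
            assert t.values.shape == expect[kind]
            assert t.values.dtype == np.float32

    def test_xyz_is_com_corrected(self, small_set):
        t = featurize(small_set, "xyz")
        assert np.allclose(t.values.mean(axis=1), 0.0, atol=1e-4)

    def test_centred_conformation_unchanged(self):
        conf = parametric_knot("3_1", 100).centred()
        t = featurize([conf], "xyz")
        assert np.allclose(t.values[0], conf.positions, atol=1e-5)

    def test_circle_sta_zero(self):
        t = featurize([circle(100)], "sta_signed")
        assert np.max(np.abs(t.values)) < 1e-10

    def test_sts_map_row_sums_give_raw_sta(self, small_set):
        # definitional consistency of the raw map before smoothing
        from writhenet.writhe import raw_sta
        for conf in small_set:
            m = sts_writhe(conf).values
            assert np.allclose(m.sum(axis=1), raw_sta(conf), atol=1e-9)

    def test_smoothed_sts_rows_match_smoothed_sta(self, small_set):
        # the periodic box filter commutes with row summation
        from writhenet.writhe import sta_writhe
        t = featurize(small_set, "sts", window=10.0)
        for conf, m in zip(small_set, t.values):
            sta = sta_writhe(conf, window=10.0, signed=True).values
            assert np.allclose(m.sum(axis=1), sta, atol=1e-4)

    def test_mixed_bead_counts_rejected(self):
        with pytest.raises(ValueError):
            featurize([circle(100), circle(120)], "sta_signed")

    def test_rotation_invariance_of_writhe_features(self, small_set):
        conf = small_set[0]
        from writhenet.conformation import RingConformation
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = conf.transformed(rotation=rot, translation=np.array([1., 2., 3.]))
        for kind in ("sta_signed", "sts", "curvature"):
            a = featurize([conf], kind).values
            b = featurize([moved], kind).values
            assert np.allclose(a, b, atol=1e-6)
        xyz_a = featurize([conf], "xyz").values
        xyz_b = featurize([moved], "xyz").values
        assert not np.allclose(xyz_a, xyz_b, atol=1e-3)


class TestSplits:
    def test_fractions_and_disjointness(self):
        labels = np.repeat(np.arange(5), 200)
        tr, va, te = split_dataset(labels, (0.8, 0.1, 0.1), seed=3)
        assert len(tr) == 800 and len(va) == 100 and len(te) == 100
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        assert len(set(tr) | set(va) | set(te)) == 1000

    def test_stratification_within_one_item(self):
        labels = np.repeat(np.arange(4), 97)
        tr, va, te = split_dataset(labels, (0.8, 0.1, 0.1), seed=0)
        for cls in range(4):
            n_tr = (labels[tr] == cls).sum()
            assert abs(n_tr - 0.8 * 97) <= 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.zeros(10), (0.5, 0.2, 0.2))


class TestStandardizer:
    def test_statistics_from_training_split_only(self, small_set):
        t = featurize(small_set * 4, "sta_signed")
        train_idx = np.arange(6)
        std = Standardizer.fit(t, train_idx)
        applied = std.apply(t)
        flat = applied.flat()
        # train rows standardize to mean 0 per dimension
        assert np.allclose(flat[train_idx].mean(axis=0), 0.0, atol=1e-5)
        assert applied.standardized

    def test_constant_dimensions_left_finite(self):
        t = featurize([circle(100)] * 5, "sta_signed")
        std = Standardizer.fit(t, np.arange(4))
        out = std.apply(t)
        assert np.all(np.isfinite(out.values))
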