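import itertools

import numpy as np
import pytest
from scipy import stats

from lnmap.connectivity import SATURATION, TMap
from lnmap.mapping import (
    LesionNetworkMapper,
    SignFlipPermutation,
    binarize_tmap,
    dice,
    lnm_from_overlap,
    min_count_for_fraction,
    overlap_maps,
    signflip_onesample,
)
from lnmap.synthetic import demo_grid


@pytest.fixture(scope="module")
def grid():
    return demo_grid((6, 6, 6))


def tmap_of(grid, values, case_id="c", defined=None):
    vals = np.zeros(grid.n_in_mask)
    vals[: len(values)] = values
    if defined is None:
        defined = np.ones(grid.n_in_mask, bool)
    return TMap(case_id, grid, vals, df=9, defined=defined)


class TestBinarize:
    def test_strictly_greater_than_threshold(self, grid):
        tm = tmap_of(grid, [7.5, 7.0, -8.0, 2.0])
        assert binarize_tmap(tm, 7.0)[:4].tolist() == [1, 0, 0, 0]

    def test_zero_map_stays_zero(self, grid):
        assert binarize_tmap(tmap_of(grid, []), 7.0).sum() == 0

    def test_saturation_sentinel_binarizes_to_one(self, grid):
        tm = tmap_of(grid, [SATURATION, -SATURATION])
        assert binarize_tmap(tm, 7.0)[:2].tolist() == [1, 0]

    def test_undefined_voxels_are_zero(self, grid):
        defined = np.ones(grid.n_in_mask, bool)
        defined[0] = False
        tm = tmap_of(grid, [100.0, 100.0], defined=defined)
        assert binarize_tmap(tm, 7.0)[:2].tolist() == [0, 1]


class TestOverlap:
    def test_counts_sum_and_commute(self, grid):
        maps = [np.zeros(grid.n_in_mask, np.uint8) for _ in range(23)]
        for m in maps:
            m[0] = 1
        maps[1][5] = 1
        ov = overlap_maps(maps, grid)
        assert ov.values[0] == 23
        assert ov.values[5] == 1
        ov_perm = overlap_maps(maps[::-1], grid)
        assert np.array_equal(ov.values, ov_perm.values)

    def test_disjoint_maps_max_one(self, grid):
        maps = []
        for i in range(4):
            m = np.zeros(grid.n_in_mask, np.uint8)
            m[i] = 1
            maps.append(m)
        assert overlap_maps(maps, grid).values.max() == 1

    def test_threshold_monotonicity(self, grid):
        """Raising the t-threshold never increases any overlap count."""
        rng = np.random.default_rng(0)
        tmaps = [tmap_of(grid, rng.normal(0, 5, 20), case_id=f"c{i}")
                 for i in range(6)]
        lo = overlap_maps([binarize_tmap(t, 2.0) for t in tmaps], grid)
        hi = overlap_maps([binarize_tmap(t, 4.0) for t in tmaps], grid)
        assert (hi.values <= lo.values).all()


class TestMinCount:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [(23, 0.95, 22), (20, 0.95, 19), (1, 0.5, 1), (1, 1.0, 1),
         (100, 0.95, 95), (10, 0.91, 10)],
    )
    def test_ceil_rule(self, n, frac, expected):
        assert min_count_for_fraction(n, frac) == expected

    def test_invalid_fraction_rejected(self):
        for frac in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                min_count_for_fraction(10, frac)

    def test_raising_frac_never_grows_lnm(self, grid):
        rng = np.random.default_rng(1)
        tmaps = [tmap_of(grid, rng.normal(0, 5, 30), case_id=f"c{i}")
                 for i in range(10)]
        ov = overlap_maps([binarize_tmap(t, 2.0) for t in tmaps], grid)
        sets = []
        for frac in (0.5, 0.7, 0.9, 1.0):
            sets.append(lnm_from_overlap(ov, frac).volume.data.astype(bool))
        for small, large in zip(sets[1:], sets[:-1]):
            assert (small <= large).all()


class TestLesionNetworkMapper:
    def test_estimator_params_roundtrip(self):
        m = LesionNetworkMapper(t_threshold=5.0, frac=0.9)
        assert m.get_params() == {"t_threshold": 5.0, "frac": 0.9}
        m.set_params(frac=0.95)
        assert m.frac == 0.95

    def test_fit_attributes(self, grid):
        rng = np.random.default_rng(2)
        tmaps = [tmap_of(grid, rng.normal(0, 5, 30), case_id=f"c{i}")
                 for i in range(23)]
        m = LesionNetworkMapper().fit(tmaps)
        assert m.lnm_.min_count == 22
        assert m.overlap_.n_cases == 23
        assert (m.lnm_.volume.data.astype(bool)
                <= (m.overlap_.to_volume().data >= 22)).all()


class TestSignFlip:
    def test_mirrored_maps_have_no_signal(self, grid):
        rng = np.random.default_rng(3)
        base = rng.normal(size=grid.n_in_mask)
        tmaps = [
            TMap("a", grid, base, 9, np.ones(grid.n_in_mask, bool)),
            TMap("b", grid, -base, 9, np.ones(grid.n_in_mask, bool)),
            TMap("c", grid, base, 9, np.ones(grid.n_in_mask, bool)),
            TMap("d", grid, -base, 9, np.ones(grid.n_in_mask, bool)),
        ]
        res = signflip_onesample(tmaps, n_perm=100, seed=0)
        assert np.allclose(res.observed_stat, 0)
        assert not res.significant.any()

    def test_exhaustive_minimal_p_is_one_over_sixteen(self, grid):
        """Four identical strongly positive maps: all 16 sign patterns are
        enumerated and only the identity attains the observed maximum."""
        rng = np.random.default_rng(4)
        tmaps = []
        for i in range(4):
            vals = rng.normal(0, 0.1, grid.n_in_mask)
            vals[0] = 50.0  # the identical strong signal voxel
            tmaps.append(TMap(f"c{i}", grid, vals, 9,
                              np.ones(grid.n_in_mask, bool)))
        res = signflip_onesample(tmaps, n_perm=5000, tail="greater", seed=0)
        assert res.exhaustive
        assert res.n_perm == 16
        assert res.fwe_p[0] == pytest.approx(1 / 16)

    def test_exhaustive_enumeration_oracle(self, grid):
        """FWE p-values match a literal loop over all sign patterns on a
        5-voxel, 5-case instance to 1e-10."""
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 1.0, size=(5, 5))
        n_vox = grid.n_in_mask
        tmaps = []
        for i in range(5):
            vals = np.zeros(n_vox)
            vals[:5] = x[i]
            defined = np.zeros(n_vox, bool)
            defined[:5] = True
            tmaps.append(TMap(f"c{i}", grid, vals, 9, defined))
        res = signflip_onesample(tmaps, n_perm=5000, tail="greater", seed=0)

        def tstat(y):
            return y.mean(0) / (y.std(0, ddof=1) / np.sqrt(len(y)))

        obs = tstat(x)
        expected = np.zeros(5)
        for signs in itertools.product([1, -1], repeat=5):
            m = tstat(np.asarray(signs)[:, None] * x).max()
            expected += m >= obs - 1e-12
        expected /= 2 ** 5
        assert np.allclose(res.fwe_p[:5], expected, atol=1e-10)

    def test_deterministic_given_seed(self, grid):
        rng = np.random.default_rng(6)
        tmaps = [
            TMap(f"c{i}", grid, rng.normal(size=grid.n_in_mask), 9,
                 np.ones(grid.n_in_mask, bool))
            for i in range(15)
        ]
        a = signflip_onesample(tmaps, n_perm=300, seed=42)
        b = signflip_onesample(tmaps, n_perm=300, seed=42)
        assert np.array_equal(a.fwe_p, b.fwe_p)

    def test_all_zero_maps_warn_p_one(self, grid):
        tmaps = [TMap(f"c{i}", grid, np.zeros(grid.n_in_mask), 9,
                      np.ones(grid.n_in_mask, bool)) for i in range(3)]
        with pytest.warns(UserWarning, match="zero"):
            res = signflip_onesample(tmaps, n_perm=50, seed=0)
        assert (res.fwe_p == 1).all()

    def test_defaults_match_published_configuration(self):
        est = SignFlipPermutation()
        assert est.n_perm == 5000
        assert est.alpha == 0.05

    def test_undefined_voxels_excluded_from_pool(self, grid):
        """A huge value at a voxel undefined in one case must not drive
        the max-statistic null."""
        rng = np.random.default_rng(7)
        n_vox = grid.n_in_mask
        tmaps = []
        for i in range(6):
            vals = rng.normal(size=n_vox)
            defined = np.ones(n_vox, bool)
            if i == 0:
                vals[3] = 1e6
                defined[3] = False
            tmaps.append(TMap(f"c{i}", grid, vals, 9, defined))
        res = signflip_onesample(tmaps, n_perm=200, seed=0)
        assert res.fwe_p[3] == 1.0
        assert not res.significant[3]


class TestDice:
    def test_known_overlap(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([1, 0, 1, 0], bool)
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_sets_dice_one(self):
        assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0
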