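import numpy as np
import pandas as pd
import pytest

from lnmap.connectivity import Connectome, TMap
from lnmap.experiments import parcel_strength_experiment, wta_recovery_experiment
from lnmap.parcellation import (
    DEFAULT_PARCEL_LABELS,
    WinnerTakesAllParcellation,
    lesion_parcel_strengths,
    mask_out_region,
    parcel_anova,
    winner_takes_all,
)
from lnmap.synthetic import demo_grid
from lnmap.volumes import Volume, in_mask_indices

from conftest import make_lesion


@pytest.fixture(scope="module")
def grid():
    return demo_grid((8, 8, 8))


def _setup_labels(grid, n_roi_voxels=2):
    """ROI label volume with 4 groups on the first in-mask voxels and a
    3-voxel target immediately after."""
    idx = in_mask_indices(grid)
    roi = np.zeros(grid.shape, np.int16)
    flat = roi.ravel(order="C")
    for g in range(4):
        flat[idx[g * n_roi_voxels:(g + 1) * n_roi_voxels]] = g + 1
    target = np.zeros(grid.shape, np.uint8)
    target.ravel(order="C")[idx[8:11]] = 1
    return Volume(grid, roi, kind="label"), Volume(grid, target, kind="binary")


class TestWinnerTakesAll:
    def test_identical_series_wins_its_label(self, grid):
        """A target voxel that copies the motor-ROI mean series in every
        subject must be labelled motor."""
        roi, target = _setup_labels(grid)
        rng = np.random.default_rng(0)
        subjects = []
        for _ in range(3):
            s = rng.normal(size=(grid.n_in_mask, 30))
            motor_mean = s[0:2].mean(0)
            s[8] = motor_mean
            subjects.append(s)
        atlas = winner_takes_all(Connectome(grid, subjects), roi, target)
        idx = in_mask_indices(grid)
        assert atlas.labels_volume.data.ravel(order="C")[idx[8]] == 1
        assert atlas.label_names == DEFAULT_PARCEL_LABELS

    def test_planted_assignment_fully_recovered(self):
        """Noiseless planted assignment: every target voxel carries exactly
        one ROI's latent -> 100% label recovery."""
        out = wta_recovery_experiment(seed=3)
        assert out["recovery"] == 1.0

    def test_exact_tie_takes_lowest_label_and_flags(self, grid):
        """All four ROI groups share one series, so every target voxel ties
        across the four labels exactly."""
        roi, target = _setup_labels(grid)
        rng = np.random.default_rng(1)
        subjects = []
        for _ in range(2):
            s = rng.normal(size=(grid.n_in_mask, 20))
            shared = rng.normal(size=20)
            for g in range(4):
                s[2 * g] = shared
                s[2 * g + 1] = shared
            subjects.append(s)
        atlas = winner_takes_all(Connectome(grid, subjects), roi, target)
        idx = in_mask_indices(grid)
        labels = atlas.labels_volume.data.ravel(order="C")[idx[8:11]]
        flags = atlas.tie_flags.data.ravel(order="C")[idx[8:11]]
        assert (labels == 1).all()
        assert (flags == 1).all()

    def test_subject_order_invariance(self, grid):
        roi, target = _setup_labels(grid)
        rng = np.random.default_rng(2)
        subjects = [rng.normal(size=(grid.n_in_mask, 25)) for _ in range(4)]
        a = winner_takes_all(Connectome(grid, subjects), roi, target)
        b = winner_takes_all(Connectome(grid, subjects[::-1]), roi, target)
        assert np.array_equal(a.labels_volume.data, b.labels_volume.data)

    def test_empty_roi_group_rejected(self, grid):
        roi, target = _setup_labels(grid)
        roi_data = roi.data.copy()
        roi_data[roi_data == 3] = 0  # limbic group emptied
        rng = np.random.default_rng(3)
        subjects = [rng.normal(size=(grid.n_in_mask, 20)) for _ in range(2)]
        with pytest.raises(ValueError, match="limbic"):
            WinnerTakesAllParcellation().fit(
                Connectome(grid, subjects),
                Volume(grid, roi_data, kind="label"), target,
            )


class TestParcelStrengths:
    def _atlas(self, grid):
        roi, target = _setup_labels(grid)
        idx = in_mask_indices(grid)
        labels = np.zeros(grid.shape, np.int16)
        flat = labels.ravel(order="C")
        flat[idx[8]] = 1
        flat[idx[9]] = 2
        flat[idx[10]] = 2
        from lnmap.parcellation import ParcellationAtlas

        return ParcellationAtlas(
            labels_volume=Volume(grid, labels, kind="label"),
            label_names=("motor", "associative"),
            tie_flags=Volume(grid, np.zeros(grid.shape, np.uint8),
                             kind="binary"),
        )

    def test_constant_tmap_constant_strengths(self, grid):
        atlas = self._atlas(grid)
        vals = np.full(grid.n_in_mask, 3.5)
        tm = TMap("c", grid, vals, 9, np.ones(grid.n_in_mask, bool))
        table = lesion_parcel_strengths([tm], atlas)
        assert np.allclose(table["strength"], 3.5)

    def test_hand_arithmetic_two_parcel_toy(self, grid):
        """Motor parcel = voxel value 2; associative = mean(4, 6) = 5."""
        atlas = self._atlas(grid)
        vals = np.zeros(grid.n_in_mask)
        vals[8], vals[9], vals[10] = 2.0, 4.0, 6.0
        tm = TMap("c", grid, vals, 9, np.ones(grid.n_in_mask, bool))
        table = lesion_parcel_strengths([tm], atlas).set_index("parcel")
        assert table.loc["motor", "strength"] == pytest.approx(2.0)
        assert table.loc["associative", "strength"] == pytest.approx(5.0)

    def test_parcel_without_usable_voxels_is_nan(self, grid):
        atlas = self._atlas(grid)
        vals = np.ones(grid.n_in_mask)
        defined = np.ones(grid.n_in_mask, bool)
        defined[8] = False  # the only motor voxel
        tm = TMap("c", grid, vals, 9, defined)
        table = lesion_parcel_strengths([tm], atlas).set_index("parcel")
        assert np.isnan(table.loc["motor", "strength"])


class TestParcelAnova:
    def _table(self, strengths: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = []
        for parcel, vals in strengths.items():
            for i, v in enumerate(vals):
                rows.append({"case_id": f"c{i}", "parcel": parcel,
                             "strength": v})
        return pd.DataFrame(rows)

    def test_no_within_case_variation_means_no_effect(self):
        base = np.random.default_rng(0).normal(size=5)
        table = self._table({p: base for p in DEFAULT_PARCEL_LABELS})
        out = parcel_anova(table)
        assert out["omnibus_p"] == 1.0
        assert all(p == 1.0 for p in out["pairwise_bonferroni"].values())

    def test_shifted_motor_detected_at_effect_size_two(self):
        """motor shifted by 2 sigma over 23 cases: corrected p < 0.001
        against every other parcel."""
        rng = np.random.default_rng(1)
        sigma, n = 1.0, 23
        base = rng.normal(0, sigma, n)
        table = self._table({
            "motor": base + 2 * sigma + rng.normal(0, sigma, n),
            "associative": base + rng.normal(0, sigma, n),
            "limbic": base + rng.normal(0, sigma, n),
            "other": base + rng.normal(0, sigma, n),
        })
        out = parcel_anova(table)
        assert out["omnibus_p"] < 0.001
        for pair, p in out["pairwise_bonferroni"].items():
            if "motor" in pair:
                assert p < 0.001

    def test_bonferroni_is_six_times_raw(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        table = self._table({
            p: rng.normal(i * 0.5, 1.0, 12)
            for i, p in enumerate(DEFAULT_PARCEL_LABELS)
        })
        out = parcel_anova(table)
        wide = table.pivot(index="case_id", columns="parcel",
                           values="strength")
        raw = stats.ttest_rel(wide["associative"], wide["limbic"]).pvalue
        corrected = out["pairwise_bonferroni"]["associative_vs_limbic"]
        assert corrected == pytest.approx(min(1.0, raw * 6))

    def test_too_few_cases_rejected(self):
        table = self._table({p: np.array([1.0]) for p in DEFAULT_PARCEL_LABELS})
        with pytest.raises(ValueError, match="2 complete cases"):
            parcel_anova(table)

    def test_motor_parcel_wins_on_planted_cohorts(self):
        """The parcel hosting the lesion-coupled latent has the maximal
        mean strength across simulated cohorts."""
        wins = sum(
            parcel_strength_experiment(seed=200 + s)["motor_is_max"]
            for s in range(5)
        )
        assert wins == 5


class TestMaskOutRegion:
    def test_disjoint_region_leaves_lesion_unchanged(self, grid):
        les = make_lesion(grid, in_mask_indices(grid)[:3].tolist(), "a")
        region_arr = np.zeros(grid.shape, np.uint8)
        region_arr.ravel(order="C")[in_mask_indices(grid)[10:12]] = 1
        out = mask_out_region([les], Volume(grid, region_arr, kind="binary"))
        assert np.array_equal(out[0].volume.data, les.volume.data)

    def test_contained_lesion_dropped_with_notice(self, grid, caplog):
        import logging

        idx = in_mask_indices(grid)
        inside = make_lesion(grid, idx[:2].tolist(), "inside")
        outside = make_lesion(grid, idx[5:8].tolist(), "outside")
        region_arr = np.zeros(grid.shape, np.uint8)
        region_arr.ravel(order="C")[idx[:4]] = 1
        with caplog.at_level(logging.INFO, logger="lnmap.parcellation"):
            out = mask_out_region([inside, outside],
                                  Volume(grid, region_arr, kind="binary"))
        assert [l.case_id for l in out] == ["outside"]
        assert any("inside" in rec.message for rec in caplog.records)

    def test_partial_overlap_shrinks_by_overlap_size(self, grid):
        idx = in_mask_indices(grid)
        les = make_lesion(grid, idx[:6].tolist(), "half")
        region_arr = np.zeros(grid.shape, np.uint8)
        region_arr.ravel(order="C")[idx[3:6]] = 1
        out = mask_out_region([les], Volume(grid, region_arr, kind="binary"))
        assert out[0].n_voxels == 6 - 3

    def test_all_empty_rejected(self, grid):
        idx = in_mask_indices(grid)
        les = make_lesion(grid, idx[:2].tolist(), "a")
        region_arr = np.zeros(grid.shape, np.uint8)
        region_arr.ravel(order="C")[idx[:2]] = 1
        with pytest.raises(ValueError, match="all lesions empty"):
            mask_out_region([les], Volume(grid, region_arr, kind="binary"))
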