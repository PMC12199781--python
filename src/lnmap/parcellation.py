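"""Winner-takes-all functional parcellation and per-lesion parcel stats.

Each target-structure voxel (typically thalamus) is assigned to the
cortical ROI group (motor, associative, limbic, other) whose mean time
series correlates with it most strongly, averaged across connectome
subjects.  Per-lesion connectivity strength to each parcel is the mean
case T-map value over the parcel's voxels; a repeated-measures ANOVA and
Bonferroni-corrected paired t-tests compare parcels across cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .connectivity import Connectome, TMap, fisher_z
from .volumes import LesionMask, Volume, VolumeGrid, in_mask_indices

__all__ = [
    "DEFAULT_PARCEL_LABELS",
    "ParcellationAtlas",
    "WinnerTakesAllParcellation",
    "winner_takes_all",
    "lesion_parcel_strengths",
    "parcel_anova",
    "mask_out_region",
]

logger = logging.getLogger(__name__)

#: Ordered parcel names and their integer codes in label volumes.
DEFAULT_PARCEL_LABELS = ("motor", "associative", "limbic", "other")


@dataclass
class ParcellationAtlas:
    """Label volume over the target mask plus tie bookkeeping."""

    labels_volume: Volume  # 0 outside target, 1..n_labels inside
    label_names: tuple[str, ...]
    tie_flags: Volume
    mean_corr: np.ndarray | None = None  # (n_labels, n_target) mean r

    def __post_init__(self) -> None:
        if self.labels_volume.kind != "label":
            raise ValueError("labels_volume must be a label volume")
        codes = np.unique(self.labels_volume.data)
        if codes.max(initial=0) > len(self.label_names):
            raise ValueError("label codes exceed the label list")

    def parcel_mask(self, name: str) -> np.ndarray:
        code = self.label_names.index(name) + 1
        return self.labels_volume.data == code

    @property
    def target_mask(self) -> np.ndarray:
        return self.labels_volume.data > 0


class WinnerTakesAllParcellation:
    """Parcellate a target structure by strongest cortical-ROI coupling.

    Per subject, each ROI group's mean BOLD series is correlated with
    every target voxel's series; correlations are averaged across
    subjects (optionally after Fisher z) and each voxel takes the argmax
    label.  Exact ties go to the lowest-index label and are flagged.

    Deterministic given connectome and labels; subject order does not
    affect the assignment (the average is symmetric).
    """

    def __init__(self, use_fisher_z: bool = False,
                 label_names: tuple[str, ...] = DEFAULT_PARCEL_LABELS):
        self.use_fisher_z = use_fisher_z
        self.label_names = label_names

    def get_params(self, deep: bool = True) -> dict:
        return {"use_fisher_z": self.use_fisher_z,
                "label_names": self.label_names}

    def set_params(self, **params) -> "WinnerTakesAllParcellation":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        connectome: Connectome,
        roi_labels: Volume,
        target_mask: Volume,
    ) -> "WinnerTakesAllParcellation":
        grid = connectome.grid
        idx = in_mask_indices(grid)
        roi_flat = roi_labels.data.ravel(order="C")[idx]
        target_flat = target_mask.data.ravel(order="C")[idx].astype(bool)
        if not target_flat.any():
            raise ValueError("target mask has no in-mask voxel")
        n_labels = len(self.label_names)
        group_rows = []
        for code in range(1, n_labels + 1):
            rows = np.flatnonzero(roi_flat == code)
            if rows.size == 0:
                raise ValueError(
                    f"ROI group {self.label_names[code - 1]!r} is empty"
                )
            group_rows.append(rows)
        target_rows = np.flatnonzero(target_flat)
        acc = np.zeros((n_labels, target_rows.size))
        for subj in connectome.subjects:
            tgt = subj[target_rows].astype(np.float64)
            tgt -= tgt.mean(axis=1, keepdims=True)
            tn = np.sqrt((tgt * tgt).sum(axis=1))
            tn[tn == 0] = np.inf  # zero-variance target voxel -> r = 0
            r_sub = np.empty((n_labels, target_rows.size))
            for g, rows in enumerate(group_rows):
                ts = subj[rows].mean(axis=0, dtype=np.float64)
                ts -= ts.mean()
                sn = np.sqrt((ts * ts).sum())
                if sn == 0:
                    raise ValueError(
                        f"ROI group {self.label_names[g]!r} has a "
                        "zero-variance mean series"
                    )
                r_sub[g] = np.clip((tgt @ ts) / (tn * sn), -1.0, 1.0)
            acc += fisher_z(r_sub) if self.use_fisher_z else r_sub
        acc /= connectome.n_subjects
        winner = np.argmax(acc, axis=0)  # lowest index wins exact ties
        is_tie = (acc == acc.max(axis=0, keepdims=True)).sum(axis=0) > 1
        labels_flat = np.zeros(idx.size, dtype=np.int32)
        labels_flat[target_rows] = winner + 1
        ties_flat = np.zeros(idx.size, dtype=np.uint8)
        ties_flat[target_rows] = is_tie.astype(np.uint8)
        self.atlas_ = ParcellationAtlas(
            labels_volume=Volume.from_vector(grid, labels_flat, kind="label"),
            label_names=tuple(self.label_names),
            tie_flags=Volume.from_vector(grid, ties_flat, kind="binary"),
            mean_corr=acc,
        )
        return self


def winner_takes_all(
    connectome: Connectome,
    roi_labels: Volume,
    target_mask: Volume,
    use_fisher_z: bool = False,
) -> ParcellationAtlas:
    """Winner-takes-all parcellation of ``target_mask`` from ROI groups."""
    est = WinnerTakesAllParcellation(use_fisher_z=use_fisher_z)
    return est.fit(connectome, roi_labels, target_mask).atlas_


def lesion_parcel_strengths(
    tmaps: list[TMap],
    atlas: ParcellationAtlas,
    reduction: str = "mean",
) -> pd.DataFrame:
    """Per-case connectivity strength to each parcel.

    strength(case, parcel) = mean (or, with ``reduction='peak'``, max) of
    the case T-map over the parcel's voxels, excluding undefined voxels.
    A parcel with no usable voxel yields NaN (row marked missing).
    """
    if reduction not in ("mean", "peak"):
        raise ValueError("reduction must be 'mean' or 'peak'")
    grid = atlas.labels_volume.grid
    idx = in_mask_indices(grid)
    labels_flat = atlas.labels_volume.data.ravel(order="C")[idx]
    rows = []
    for tm in tmaps:
        for code, name in enumerate(atlas.label_names, start=1):
            sel = (labels_flat == code) & tm.defined
            if sel.any():
                vals = tm.values[sel]
                strength = float(vals.max() if reduction == "peak" else vals.mean())
            else:
                strength = float("nan")
            rows.append({"case_id": tm.case_id, "parcel": name,
                         "strength": strength})
    return pd.DataFrame(rows)


def parcel_anova(table: pd.DataFrame) -> dict:
    """Repeated-measures ANOVA plus Bonferroni-corrected paired t-tests.

    The within-case factor is the parcel; cases with any missing strength
    are dropped.  Pairwise p-values are multiplied by the number of
    parcel pairs (6 for four parcels) and capped at 1.
    """
    wide = table.pivot(index="case_id", columns="parcel", values="strength")
    wide = wide.dropna(axis=1, how="all")  # parcels with no usable voxels
    wide = wide.dropna()
    if wide.shape[1] < 2:
        raise ValueError("need >= 2 parcels with usable voxels")
    if len(wide) < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete cases")
    parcels = list(wide.columns)
    n_pairs = len(parcels) * (len(parcels) - 1) // 2
    long = wide.reset_index().melt(
        id_vars="case_id", var_name="parcel", value_name="strength"
    )
    # degenerate: no within-case variation at all -> no effect
    if np.allclose(wide.to_numpy().std(axis=1), 0):
        omnibus_p = 1.0
        pairwise = {
            f"{a}_vs_{b}": 1.0 for a, b in combinations(parcels, 2)
        }
        return {"omnibus_p": omnibus_p, "pairwise_bonferroni": pairwise,
                "n_cases": len(wide)}
    res = AnovaRM(long, depvar="strength", subject="case_id",
                  within=["parcel"]).fit()
    omnibus_p = float(res.anova_table["Pr > F"].iloc[0])
    pairwise = {}
    for a, b in combinations(parcels, 2):
        da, db = wide[a].to_numpy(), wide[b].to_numpy()
        if np.allclose(da - db, (da - db)[0]):
            p = 1.0 if np.allclose(da, db) else 0.0
        else:
            p = float(stats.ttest_rel(da, db).pvalue)
        pairwise[f"{a}_vs_{b}"] = min(1.0, p * n_pairs)
    return {"omnibus_p": omnibus_p, "pairwise_bonferroni": pairwise,
            "n_cases": len(wide)}


def mask_out_region(
    lesions: list[LesionMask], region: Volume
) -> list[LesionMask]:
    """Remove a region's voxels from every lesion seed.

    Cases left empty are dropped with a logged notice (the control
    analysis that removes thalamic seed voxels can empty a seed); an
    all-empty cohort is an error.
    """
    reg = region.data.astype(bool)
    kept = []
    for les in lesions:
        new = les.volume.data.astype(bool) & ~reg
        if new.any():
            kept.append(
                LesionMask(
                    les.case_id,
                    Volume(les.volume.grid, new.astype(np.uint8), kind="binary"),
                )
            )
        else:
            logger.info("case %s empty after masking out region; dropped",
                        les.case_id)
    if not kept:
        raise ValueError("all lesions empty after masking out the region")
    return kept
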