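"""Seed-based functional connectivity: per-subject correlation maps and
per-lesion one-sample T-maps.

For each lesion (seed), the BOLD signal of a normative-connectome subject
is averaged over the seed voxels and Pearson-correlated with every other
in-mask voxel's time series.  The per-subject r values are then summarised
voxel-wise across subjects with a one-sample t-test (optionally after
Fisher z-transform), yielding the lesion's connectivity T-map.

Voxels whose time series have zero variance in any subject are flagged
undefined and excluded from every downstream stage, so absent signal can
never masquerade as connectivity.  A voxel where the r values have zero
sample variance but nonzero mean receives a saturation sentinel
(±`SATURATION`) instead of an infinite t-score; it binarises correctly and
is documented as a sentinel, not a finite statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumes import LesionMask, Volume, VolumeGrid, in_mask_indices

__all__ = [
    "SATURATION",
    "Connectome",
    "RMap",
    "TMap",
    "LesionTMapper",
    "seed_timeseries",
    "correlation_map",
    "lesion_tmap",
    "cohort_tmaps",
    "tmap_threshold_pvalue",
    "fisher_z",
]

#: Sentinel t-value for zero-variance, nonzero-mean voxels (sd = 0, mean != 0).
SATURATION = 1e9


@dataclass
class Connectome:
    """An ordered collection of per-subject voxel x time BOLD matrices.

    Rows of every subject matrix follow :func:`lnmap.volumes.in_mask_indices`
    order on the shared grid.  Time-series length may differ across
    subjects; each subject needs at least 3 timepoints.
    """

    grid: VolumeGrid
    subjects: list[np.ndarray]

    def __post_init__(self) -> None:
        n_vox = self.grid.n_in_mask
        if len(self.subjects) < 1:
            raise ValueError("connectome has no subjects")
        for i, s in enumerate(self.subjects):
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[0] != n_vox:
                raise ValueError(
                    f"subject {i}: expected ({n_vox}, T) matrix, got {s.shape}"
                )
            if s.shape[1] < 3:
                raise ValueError(f"subject {i}: needs >= 3 timepoints")
            self.subjects[i] = s

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class RMap:
    """Per-subject seed correlation map over in-mask voxels."""

    case_id: str
    subject_index: int
    grid: VolumeGrid
    values: np.ndarray
    defined: np.ndarray  # False where a voxel series had zero variance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        finite = self.values[self.defined]
        if finite.size and (np.abs(finite) > 1 + 1e-8).any():
            raise ValueError("r values outside [-1, 1]")


@dataclass
class TMap:
    """Voxel-wise one-sample t-scores for one lesion across subjects.

    ``defined`` is False at voxels undefined in any subject; those voxels
    carry value 0 and are excluded from overlap and permutation stages.
    """

    case_id: str
    grid: VolumeGrid
    values: np.ndarray
    df: int
    defined: np.ndarray
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("t-map needs df >= 1 (at least 2 subjects)")
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)

    def to_volume(self) -> Volume:
        vals = np.where(self.defined, self.values, 0.0)
        return Volume.from_vector(self.grid, vals, kind="statistic")


# ---------------------------------------------------------------------------
# elementary operations


def lesion_rows(grid: VolumeGrid, lesion: LesionMask) -> np.ndarray:
    """Row positions of a lesion's voxels within the in-mask ordering."""
    idx = in_mask_indices(grid)
    fg = lesion.volume.foreground_indices()
    pos = np.searchsorted(idx, fg)
    if (pos >= idx.size).any() or (idx[pos] != fg).any():
        raise ValueError(f"lesion {lesion.case_id!r} has voxels outside the brain mask")
    return pos


def seed_timeseries(subject: np.ndarray, lesion: LesionMask) -> np.ndarray:
    """Average the subject's BOLD signal over the lesion (seed) voxels.

    Multi-focal lesions are pooled into a single unweighted mean series.
    """
    rows = lesion_rows(lesion.volume.grid, lesion)
    if rows.size == 0:
        raise ValueError(f"lesion {lesion.case_id!r} is empty after masking")
    subject = np.asarray(subject)
    return subject[rows].mean(axis=0)


def correlation_map(
    subject: np.ndarray,
    seed_ts: np.ndarray,
    grid: VolumeGrid,
    case_id: str = "",
    subject_index: int = 0,
) -> RMap:
    """Pearson r between the seed series and every in-mask voxel series.

    Zero-variance voxel series are flagged undefined (not set to 0); a
    zero-variance seed is an error.
    """
    subject = np.asarray(subject, dtype=float)
    seed_ts = np.asarray(seed_ts, dtype=float)
    sc = seed_ts - seed_ts.mean()
    sn = np.sqrt((sc * sc).sum())
    if sn == 0:
        raise ValueError("seed time series has zero variance")
    c = subject - subject.mean(axis=1, keepdims=True)
    norms = np.sqrt((c * c).sum(axis=1))
    defined = norms > 0
    r = np.zeros(subject.shape[0])
    r[defined] = (c[defined] @ sc) / (norms[defined] * sn)
    np.clip(r, -1.0, 1.0, out=r)
    return RMap(case_id, subject_index, grid, r, defined)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising arctanh, clipped so |r| = 1 stays finite."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def _one_sample_t(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """t = mean / (sd / sqrt(n)) with the zero-variance sentinel contract."""
    x = np.asarray(x)
    n = x.shape[axis]
    mean = x.mean(axis=axis, dtype=np.float64)
    sd = x.std(axis=axis, ddof=1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t = np.where(degenerate, np.sign(mean) * SATURATION, t)
    return t


def lesion_tmap(rmaps: list[RMap], use_fisher_z: bool = False) -> TMap:
    """Summarise per-subject r maps into a one-sample T-map.

    Per voxel, t = mean(x) / (sd(x)/sqrt(n)) over subjects, where x are
    the raw r values or, with ``use_fisher_z``, their Fisher z transform;
    sd uses the n-1 denominator and df = n - 1.
    """
    if len(rmaps) < 2:
        raise ValueError("one-sample t-map needs at least 2 subjects")
    case_ids = {m.case_id for m in rmaps}
    if len(case_ids) != 1:
        raise ValueError(f"r maps mix case ids: {sorted(case_ids)}")
    grid = rmaps[0].grid
    x = np.stack([m.values for m in rmaps])
    defined = np.logical_and.reduce([m.defined for m in rmaps])
    if use_fisher_z:
        x = fisher_z(x)
    t = _one_sample_t(x, axis=0)
    t = np.where(defined, t, 0.0)
    return TMap(rmaps[0].case_id, grid, t, df=len(rmaps) - 1,
                defined=defined, fisher_z=use_fisher_z)


def tmap_threshold_pvalue(
    t_threshold: float, df: int, sides: str = "two-sided"
) -> float:
    """Student-t tail probability of a binarisation threshold.

    Reports the uncorrected significance a given t-threshold corresponds
    to (e.g. t = 7 at df = 99 is far below p = 0.001 two-sided).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if sides not in ("one-sided", "two-sided"):
        raise ValueError(f"sides must be one-/two-sided, got {sides!r}")
    tail = float(stats.t.sf(abs(t_threshold), df))
    return min(1.0, 2.0 * tail) if sides == "two-sided" else tail


# ---------------------------------------------------------------------------
# batched cohort path


class LesionTMapper:
    """Map a cohort of lesion seeds to connectivity T-maps.

    A fit/transform-style estimator: :meth:`fit` stores per-subject
    standardised time series, :meth:`transform` turns lesion masks into
    T-maps.  Numerically equivalent to composing :func:`seed_timeseries`,
    :func:`correlation_map` and :func:`lesion_tmap` per case, but
    standardises each subject once for the whole cohort.

    Parameters
    ----------
    use_fisher_z
        Apply Fisher z to r values before the voxel-wise t-test.  Default
        False: the t-test is run on raw r values, with the z-transform
        exposed as the conventional variance-stabilising alternative.
    """

    def __init__(self, use_fisher_z: bool = False):
        self.use_fisher_z = use_fisher_z

    def get_params(self, deep: bool = True) -> dict:
        return {"use_fisher_z": self.use_fisher_z}

    def set_params(self, **params) -> "LesionTMapper":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, connectome: Connectome, y=None) -> "LesionTMapper":
        if connectome.n_subjects < 2:
            raise ValueError("cohort T-maps need >= 2 connectome subjects")
        self.connectome_ = connectome
        self.centered_: list[np.ndarray] = []
        self.norms_: list[np.ndarray] = []
        defined = np.ones(connectome.grid.n_in_mask, dtype=bool)
        for s in connectome.subjects:
            c = s - s.mean(axis=1, keepdims=True, dtype=np.float64)
            c = c.astype(s.dtype, copy=False)  # keep float32 inputs float32
            n = np.sqrt((c * c).sum(axis=1, dtype=np.float64))
            self.centered_.append(c)
            self.norms_.append(n)
            defined &= n > 0
        self.defined_ = defined
        return self

    def transform(self, lesions: list[LesionMask]) -> list[TMap]:
        if not hasattr(self, "centered_"):
            raise RuntimeError("LesionTMapper is not fitted")
        conn = self.connectome_
        grid = conn.grid
        rows = [lesion_rows(grid, les) for les in lesions]
        n_sub = conn.n_subjects
        r_stack = np.empty((len(lesions), n_sub, grid.n_in_mask))
        for j, (c, norms, subj) in enumerate(
            zip(self.centered_, self.norms_, conn.subjects)
        ):
            # all seeds of this subject in one (T, L) matrix -> one matmul
            seeds = np.stack([subj[rr].mean(axis=0, dtype=np.float64)
                              for rr in rows])
            sc = seeds - seeds.mean(axis=1, keepdims=True)
            sn = np.sqrt((sc * sc).sum(axis=1))
            if (sn == 0).any():
                bad = lesions[int(np.flatnonzero(sn == 0)[0])].case_id
                raise ValueError(
                    f"seed of lesion {bad!r} has zero variance in subject {j}"
                )
            with np.errstate(invalid="ignore"):
                r = (c @ sc.T.astype(c.dtype)) / np.outer(norms, sn)
            r_stack[:, j, :] = np.clip(np.nan_to_num(r), -1.0, 1.0).T
        x = fisher_z(r_stack) if self.use_fisher_z else r_stack
        t = _one_sample_t(x, axis=1)
        t[:, ~self.defined_] = 0.0
        self.tmaps_ = [
            TMap(les.case_id, grid, t[i], df=n_sub - 1,
                 defined=self.defined_.copy(), fisher_z=self.use_fisher_z)
            for i, les in enumerate(lesions)
        ]
        return self.tmaps_

    def fit_transform(
        self, connectome: Connectome, lesions: list[LesionMask]
    ) -> list[TMap]:
        return self.fit(connectome).transform(lesions)


def cohort_tmaps(
    connectome: Connectome,
    lesions: list[LesionMask],
    use_fisher_z: bool = False,
) -> list[TMap]:
    """Compute one connectivity T-map per lesion mask (batched)."""
    return LesionTMapper(use_fisher_z=use_fisher_z).fit_transform(
        connectome, lesions
    )
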