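"""Specificity and stability of the lesion network map.

Specificity: case T-maps of the disease cohort are contrasted against a
control cohort (e.g. grey-matter sphere seeds) with a voxel-wise
two-sample t-test whose null is built by randomly relabelling cases into
groups of the original sizes, with max-statistic FWE correction.

Stability: the overlap analysis is repeated over random leave-k-out
subsets of the cases and each subset's overlap-fraction map is compared
to the full-cohort map by spatial Pearson correlation.  Continuous
overlap-fraction maps (count / subset size) are correlated rather than
the binary thresholded maps, whose near-degenerate variance makes
Pearson r unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .connectivity import SATURATION, TMap
from .mapping import OverlapMap, PermutationResult, binarize_tmap, overlap_maps
from .volumes import Volume, VolumeGrid

__all__ = [
    "CohortContrast",
    "StabilityReport",
    "TwoSamplePermutation",
    "two_sample_perm",
    "leave_k_out_stability",
    "spatial_correlation",
]


@dataclass
class CohortContrast:
    """Two-sample contrast between cohorts of case T-maps."""

    result: PermutationResult
    n_a: int
    n_b: int

    @property
    def specific_set(self) -> np.ndarray:
        """Bool per in-mask voxel: a > b with FWE p < alpha."""
        return self.result.significant

    def specific_volume(self) -> Volume:
        return self.result.significant_volume()


@dataclass
class StabilityReport:
    """Spatial correlations of leave-k-out maps with the full-cohort map."""

    k: int
    n_subsets: int
    correlations: np.ndarray
    seed: int
    subsets: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.correlations.shape != (self.n_subsets,):
            raise ValueError("one correlation per subset required")

    def median(self) -> float:
        return float(np.median(self.correlations))

    def summary(self) -> dict:
        q1, q3 = np.percentile(self.correlations, [25, 75])
        return {
            "k": self.k,
            "n_subsets": self.n_subsets,
            "median": self.median(),
            "iqr": [float(q1), float(q3)],
        }


def spatial_correlation(
    x: np.ndarray | Volume, y: np.ndarray | Volume,
    mask: np.ndarray | Volume | None = None,
) -> float:
    """Pearson correlation of two statistic maps over (masked) voxels."""
    xv = x.data if isinstance(x, Volume) else np.asarray(x, dtype=float)
    yv = y.data if isinstance(y, Volume) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("maps have different shapes")
    if mask is not None:
        mv = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        xv, yv = xv[mv.astype(bool)], yv[mv.astype(bool)]
    xv, yv = xv.ravel(), yv.ravel()
    if xv.size < 3:
        raise ValueError("need at least 3 voxels for a spatial correlation")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("spatial correlation undefined for a constant map")
    return float(np.corrcoef(xv, yv)[0, 1])


class TwoSamplePermutation:
    """Two-sample permutation test with max-statistic FWE correction.

    Observed statistic: voxel-wise two-sample t (pooled variance by
    default, Welch with ``equal_var=False``) for group a minus group b.
    Null: random relabelling of the pooled cases into groups of the
    original sizes; exhaustively enumerated when C(n, n_a) fits within
    ``n_perm`` (identity labelling included, smallest p = 1/C(n, n_a)).

    tail 'greater' targets voxels where a exceeds b.
    """

    def __init__(
        self,
        n_perm: int = 5000,
        alpha: float = 0.05,
        tail: str = "greater",
        equal_var: bool = True,
        random_state: int | None = 0,
    ):
        self.n_perm = n_perm
        self.alpha = alpha
        self.tail = tail
        self.equal_var = equal_var
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "tail": self.tail,
            "equal_var": self.equal_var,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "TwoSamplePermutation":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _t_for_labels(
        self, labels: np.ndarray, x: np.ndarray, x2: np.ndarray, n_a: int
    ) -> np.ndarray:
        """Two-sample t for a (P, n) block of 0/1 group-a label rows."""
        n = x.shape[0]
        n_b = n - n_a
        tot = x.sum(axis=0)
        tot2 = x2.sum(axis=0)
        sa = labels @ x
        sa2 = labels @ x2
        ma = sa / n_a
        mb = (tot - sa) / n_b
        ssa = sa2 - n_a * ma * ma
        ssb = (tot2 - sa2) - n_b * mb * mb
        ssa = np.maximum(ssa, 0.0)
        ssb = np.maximum(ssb, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.equal_var:
                sp2 = (ssa + ssb) / (n - 2)
                se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            else:
                se = np.sqrt(ssa / (n_a * (n_a - 1)) + ssb / (n_b * (n_b - 1)))
            t = (ma - mb) / se
        bad = se == 0
        if bad.any():
            t = np.where(bad, np.sign(ma - mb) * SATURATION, t)
        return t

    def fit(self, tmaps_a: list[TMap], tmaps_b: list[TMap]) -> "TwoSamplePermutation":
        n_a, n_b = len(tmaps_a), len(tmaps_b)
        if n_a < 2 or n_b < 2:
            raise ValueError("each group needs >= 2 T-maps")
        if self.tail not in ("greater", "two-sided"):
            raise ValueError(f"tail must be greater/two-sided, got {self.tail!r}")
        grid = tmaps_a[0].grid
        all_maps = tmaps_a + tmaps_b
        defined = np.logical_and.reduce([t.defined for t in all_maps])
        x = np.stack([t.values for t in all_maps])[:, defined].astype(np.float64)
        x2 = x * x
        n = n_a + n_b
        obs_labels = np.zeros((1, n))
        obs_labels[0, :n_a] = 1.0
        obs = self._t_for_labels(obs_labels, x, x2, n_a)[0]
        n_comb = math.comb(n, n_a)
        self.exhaustive_ = n_comb <= self.n_perm
        if self.exhaustive_:
            labels = np.zeros((n_comb, n))
            for i, combo in enumerate(combinations(range(n), n_a)):
                labels[i, list(combo)] = 1.0
            blocks = [labels]
            n_used = n_comb
        else:
            rng = np.random.default_rng(self.random_state)
            n_used = self.n_perm
            block = 512
            blocks = []
            for s in range(0, n_used, block):
                b = min(block, n_used - s)
                lab = np.zeros((b, n))
                for i in range(b):
                    lab[i, rng.permutation(n)[:n_a]] = 1.0
                blocks.append(lab)
        crit = np.abs(obs) if self.tail == "two-sided" else obs
        exceed = np.zeros(x.shape[1], dtype=np.int64)
        for lab in blocks:
            t_perm = self._t_for_labels(lab, x, x2, n_a)
            maxstat = (
                np.abs(t_perm).max(axis=1)
                if self.tail == "two-sided"
                else t_perm.max(axis=1)
            )
            exceed += (maxstat[:, None] >= crit[None, :]).sum(axis=0)
        p = exceed / n_used if self.exhaustive_ else (1 + exceed) / (1 + n_used)
        fwe_p = np.ones(defined.size)
        stat = np.zeros(defined.size)
        fwe_p[defined] = p
        stat[defined] = obs
        sig = defined & (fwe_p < self.alpha)
        if self.tail == "greater":
            sig &= stat > 0
        result = PermutationResult(
            grid=grid,
            observed_stat=stat,
            fwe_p=fwe_p,
            significant=sig,
            defined=defined,
            n_perm=n_used,
            alpha=self.alpha,
            seed=self.random_state,
            tail=self.tail,
            exhaustive=self.exhaustive_,
        )
        self.contrast_ = CohortContrast(result=result, n_a=n_a, n_b=n_b)
        return self


def two_sample_perm(
    a: list[TMap],
    b: list[TMap],
    n_perm: int = 5000,
    alpha: float = 0.05,
    tail: str = "greater",
    seed: int | None = 0,
    equal_var: bool = True,
) -> CohortContrast:
    """Permutation two-sample contrast of two T-map cohorts (a vs b)."""
    est = TwoSamplePermutation(
        n_perm=n_perm, alpha=alpha, tail=tail, equal_var=equal_var,
        random_state=seed,
    )
    return est.fit(a, b).contrast_


def leave_k_out_stability(
    tmaps: list[TMap],
    k: int,
    n_subsets: int,
    reference: OverlapMap,
    seed: int = 0,
) -> StabilityReport:
    """Leave-k-out stability of the overlap map.

    Draws ``n_subsets`` distinct random subsets of size n-k, recomputes
    the overlap-fraction map for each and correlates it with the
    full-cohort overlap-fraction map over in-mask voxels.
    """
    n = len(tmaps)
    if not 0 <= k < n:
        raise ValueError("k must satisfy 0 <= k < n_cases")
    size = n - k
    n_distinct = math.comb(n, size)
    if n_subsets > n_distinct:
        raise ValueError(
            f"only {n_distinct} distinct subsets of size {size} exist"
        )
    binary = np.stack(
        [binarize_tmap(t, reference.t_threshold) for t in tmaps]
    ).astype(np.float64)
    full_frac = reference.values / reference.n_cases
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    subsets: list[tuple[int, ...]] = []
    while len(subsets) < n_subsets:
        combo = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
        if combo not in seen:
            seen.add(combo)
            subsets.append(combo)
    corrs = np.empty(n_subsets)
    for i, combo in enumerate(subsets):
        frac = binary[list(combo)].mean(axis=0)
        corrs[i] = spatial_correlation(frac, full_frac)
    return StabilityReport(
        k=k, n_subsets=n_subsets, correlations=corrs, seed=seed, subsets=subsets
    )
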