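"""Reusable synthetic experiments that validate the pipeline end to end.

Each routine builds its inputs from the synthetic-data module, runs the
real estimators and returns scalar quality metrics: planted-hub recovery
(Dice), agreement between the overlap LNM and the sign-flip significant
set, family-wise false-positive rate under a global-null connectome,
winner-takes-all label recovery, leave-k-out stability medians and the
specificity contrast.  The study conditions (sample sizes, coupling,
noise, cohort sizes) default to the desk-scale study design documented
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import cohort_tmaps
from .inference import leave_k_out_stability, two_sample_perm
from .mapping import LesionNetworkMapper, dice, signflip_onesample
from .parcellation import winner_takes_all
from .synthetic import (
    NetworkSpec,
    PlantedStudy,
    SphereCohortSpec,
    demo_grid,
    generate_connectome,
    generate_sphere_cohort,
    planted_network_study,
    sphere_indices,
)
from .volumes import Volume, VolumeGrid, in_mask_indices

__all__ = [
    "PlantedRecoveryResult",
    "planted_recovery_experiment",
    "null_fwe_experiment",
    "wta_recovery_experiment",
    "stability_experiment",
    "specificity_experiment",
]


def _rows_of(grid: VolumeGrid, flat: np.ndarray) -> np.ndarray:
    idx = in_mask_indices(grid)
    return np.searchsorted(idx, flat)


@dataclass
class PlantedRecoveryResult:
    study: PlantedStudy
    tmaps: list
    overlap_lnm: np.ndarray  # bool per in-mask voxel
    signflip_significant: np.ndarray
    hub: np.ndarray
    dice_lnm_vs_hub: float
    dice_lnm_vs_signflip: float
    min_count: int


def planted_recovery_experiment(
    seed: int,
    n_subjects: int = 100,
    n_timepoints: int = 150,
    coupling: float = 0.8,
    noise_sd: float = 1.0,
    n_lesions: int = 23,
    t_threshold: float = 7.0,
    frac: float = 0.95,
    n_perm: int = 5000,
    alpha: float = 0.05,
) -> PlantedRecoveryResult:
    """Full pipeline on the planted-network study.

    Returns the Dice of the binary-overlap LNM against the lesion-free
    planted hub, and against the sign-flip FWE significant set (the
    replication check between the two mapping routes).
    """
    study = planted_network_study(
        seed=seed, n_subjects=n_subjects, n_timepoints=n_timepoints,
        coupling=coupling, noise_sd=noise_sd, n_lesions=n_lesions,
    )
    tmaps = cohort_tmaps(study.connectome, study.lesions)
    mapper = LesionNetworkMapper(t_threshold=t_threshold, frac=frac).fit(tmaps)
    lnm_vec = mapper.overlap_.values >= mapper.lnm_.min_count
    perm = signflip_onesample(tmaps, n_perm=n_perm, alpha=alpha, seed=seed)
    hub = np.zeros(study.grid.n_in_mask, dtype=bool)
    hub[_rows_of(study.grid, study.hub_flat)] = True
    return PlantedRecoveryResult(
        study=study,
        tmaps=tmaps,
        overlap_lnm=lnm_vec,
        signflip_significant=perm.significant,
        hub=hub,
        dice_lnm_vs_hub=dice(lnm_vec, hub),
        dice_lnm_vs_signflip=dice(lnm_vec, perm.significant),
        min_count=mapper.lnm_.min_count,
    )


def null_fwe_experiment(
    seed: int,
    n_runs: int = 200,
    n_perm: int = 200,
    alpha: float = 0.05,
    grid_shape: tuple[int, int, int] = (14, 14, 14),
    n_subjects: int = 20,
    n_timepoints: int = 60,
    n_seeds: int = 12,
    seed_radius_mm: float = 0.1,
) -> dict:
    """Family-wise false-positive rate of the sign-flip test under a
    global-null connectome (no latent structure anywhere).

    Seeds default to single voxels at distinct centers, hence pairwise
    disjoint, so case maps are independent as the sign-flip
    exchangeability argument requires (overlapping seeds share signal and
    would make cases dependent); each run uses a fresh connectome and
    cohort.  Returns the empirical rate and the binomial-CI bound
    alpha + 1.96*sqrt(alpha(1-alpha)/n_runs).
    """
    grid = demo_grid(grid_shape)
    grey = Volume(grid, grid.brain_mask.astype(np.uint8), kind="binary")
    null_spec = NetworkSpec([], [], noise_sd=1.0, n_timepoints=n_timepoints)
    hits = 0
    for i in range(n_runs):
        conn = generate_connectome(grid, n_subjects, null_spec,
                                   seed=seed + 7919 * i)
        cohort = generate_sphere_cohort(
            grid,
            SphereCohortSpec(grey_mask=grey, n_masks=n_seeds,
                             radius_mm=seed_radius_mm,
                             seed=seed + 7919 * i + 1),
        )
        tmaps = cohort_tmaps(conn, cohort)
        res = signflip_onesample(tmaps, n_perm=n_perm, alpha=alpha,
                                 seed=seed + i)
        hits += bool(res.significant.any())
    rate = hits / n_runs
    bound = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / n_runs)
    return {"rate": rate, "n_runs": n_runs, "alpha": alpha, "bound": bound}


def wta_recovery_experiment(
    seed: int,
    grid_shape: tuple[int, int, int] = (16, 18, 16),
    n_subjects: int = 10,
    n_timepoints: int = 60,
    noise_sd: float = 1e-6,
    coupling: float = 1.0,
) -> dict:
    """Label recovery of the winner-takes-all parcellation.

    Four cortical ROI blobs each carry their own latent; every target
    (pseudo-thalamic) voxel is planted to carry exactly one ROI's latent.
    With (near-)noiseless signals the parcellation must recover the
    planted assignment exactly.
    """
    grid = demo_grid(grid_shape)
    center = (np.array(grid.shape) - 1) // 2
    semi = 0.9 * np.array(grid.shape) / 2.0
    roi_centers = [
        np.round(center + 0.6 * semi * d).astype(int)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))
    ]
    roi_flats = [sphere_indices(grid, c, 3.0) for c in roi_centers]
    target_flat = sphere_indices(grid, center, 5.0)
    rng = np.random.default_rng(seed)
    planted = rng.integers(0, 4, size=target_flat.size)
    regions = [
        np.unique(np.concatenate([roi_flats[g], target_flat[planted == g]]))
        for g in range(4)
    ]
    spec = NetworkSpec(regions, [coupling] * 4, noise_sd=noise_sd,
                       n_timepoints=n_timepoints)
    conn = generate_connectome(grid, n_subjects, spec, seed=seed + 1)
    roi_labels = np.zeros(grid.shape, dtype=np.int16)
    for g, f in enumerate(roi_flats, start=1):
        roi_labels.ravel(order="C")[f] = g
    target = np.zeros(grid.shape, dtype=np.uint8)
    target.ravel(order="C")[target_flat] = 1
    atlas = winner_takes_all(
        conn,
        Volume(grid, roi_labels, kind="label"),
        Volume(grid, target, kind="binary"),
    )
    assigned = atlas.labels_volume.data.ravel(order="C")[target_flat] - 1
    recovery = float((assigned == planted).mean())
    return {"recovery": recovery, "n_target_voxels": int(target_flat.size)}


def parcel_strength_experiment(
    seed: int,
    grid_shape: tuple[int, int, int] = (16, 18, 16),
    n_subjects: int = 15,
    n_timepoints: int = 60,
    coupling: float = 0.8,
    noise_sd: float = 1.0,
    n_lesions: int = 8,
) -> dict:
    """Lesions coupled to the motor network must be maximally connected
    to the motor parcel of the winner-takes-all atlas.

    Four cortical ROI blobs carry their own latents; target voxels are
    split between the parcels; a remote lesion focus carries the motor
    latent.  Returns the parcel-strength table, the repeated-measures
    post-hoc and whether the motor parcel has the maximal mean strength.
    """
    from .mapping import LesionNetworkMapper  # noqa: F401  (kept local)
    from .parcellation import lesion_parcel_strengths, parcel_anova
    from .synthetic import generate_lesion_cohort

    grid = demo_grid(grid_shape)
    center = (np.array(grid.shape) - 1) // 2
    semi = 0.9 * np.array(grid.shape) / 2.0
    roi_centers = [
        np.round(center + 0.6 * semi * d).astype(int)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))
    ]
    roi_flats = [sphere_indices(grid, c, 3.0) for c in roi_centers]
    target_flat = sphere_indices(grid, center, 5.0)
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, 4, size=target_flat.size)
    lesion_focus = sphere_indices(
        grid, np.round(center + 0.6 * semi * (0, 0, 1)).astype(int), 3.0
    )
    regions = []
    for g in range(4):
        parts = [roi_flats[g], target_flat[assignment == g]]
        if g == 0:  # motor network also spans the lesion focus
            parts.append(lesion_focus)
        regions.append(np.unique(np.concatenate(parts)))
    spec = NetworkSpec(regions, [coupling] * 4, noise_sd=noise_sd,
                       n_timepoints=n_timepoints)
    conn = generate_connectome(grid, n_subjects, spec, seed=seed + 1)
    lesions = generate_lesion_cohort(
        grid,
        NetworkSpec([lesion_focus], [coupling], noise_sd=noise_sd,
                    n_timepoints=n_timepoints),
        n_lesions, seed=seed + 2, blob_radius_mm=3.0,
    )
    roi_labels = np.zeros(grid.shape, dtype=np.int16)
    for g, f in enumerate(roi_flats, start=1):
        roi_labels.ravel(order="C")[f] = g
    target = np.zeros(grid.shape, dtype=np.uint8)
    target.ravel(order="C")[target_flat] = 1
    atlas = winner_takes_all(
        conn,
        Volume(grid, roi_labels, kind="label"),
        Volume(grid, target, kind="binary"),
    )
    tmaps = cohort_tmaps(conn, lesions)
    table = lesion_parcel_strengths(tmaps, atlas)
    means = table.groupby("parcel")["strength"].mean()
    stats = parcel_anova(table) if n_lesions >= 2 else None
    return {
        "table": table,
        "parcel_means": means.to_dict(),
        "motor_is_max": bool(means.idxmax() == "motor"),
        "anova": stats,
    }


def stability_experiment(
    result: PlantedRecoveryResult,
    ks: tuple[int, ...] = (5, 7, 9),
    n_subsets: int = 100,
    seed: int = 0,
) -> dict:
    """Leave-k-out stability medians on a planted-recovery result."""
    mapper = LesionNetworkMapper().fit(result.tmaps)
    out = {}
    for k in ks:
        rep = leave_k_out_stability(
            result.tmaps, k=k, n_subsets=n_subsets,
            reference=mapper.overlap_, seed=seed + k,
        )
        out[k] = rep.median()
    return out


def specificity_experiment(
    result: PlantedRecoveryResult,
    n_spheres: int = 30,
    sphere_radius_mm: float = 6.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Contrast the planted lesion cohort against a sphere control cohort.

    Control spheres are placed outside the planted network (emulating
    control lesions that do not sit on the disease network, as with an
    unrelated lesion cohort), so the contrast isolates network-specific
    connectivity.  Returns the number of cohort-specific voxels inside
    and outside the planted hub.
    """
    study = result.study
    grid = study.grid
    grey_arr = grid.brain_mask.copy()
    network = np.concatenate([study.hub_flat] + list(study.node_flats))
    grey_arr.ravel(order="C")[network] = False
    grey = Volume(grid, grey_arr.astype(np.uint8), kind="binary")
    spheres = generate_sphere_cohort(
        grid,
        SphereCohortSpec(grey_mask=grey, n_masks=n_spheres,
                         radius_mm=sphere_radius_mm, seed=seed),
    )
    ctrl_tmaps = cohort_tmaps(study.connectome, spheres)
    contrast = two_sample_perm(result.tmaps, ctrl_tmaps, n_perm=n_perm,
                               alpha=alpha, seed=seed)
    spec_set = contrast.specific_set
    return {
        "n_specific": int(spec_set.sum()),
        "n_specific_in_hub": int((spec_set & result.hub).sum()),
        "control_tmaps": ctrl_tmaps,
    }
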