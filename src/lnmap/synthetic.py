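"""Synthetic connectomes and lesion cohorts with known ground truth.

The generator emulates the statistical structure the mapping analysis
relies on: groups of voxels ("node regions") that share latent
resting-state fluctuations.  Each node region carries its own i.i.d.
standard-Gaussian latent signal per subject and timepoint; a voxel's
series is ``coupling * latent(region) + N(0, noise_sd)``, and voxels in
no region are pure noise.  A distributed functional network — a hub plus
several remote foci that fluctuate together — is therefore modelled as a
single region whose voxel set is spatially disconnected.

No temporal autocorrelation or haemodynamics is modelled: the analysis
consumes only spatial correlation structure, so this is the simplest
process that exercises the estimators.

:func:`planted_network_study` packages the full desk-scale study design
used throughout the tests: a 100-subject connectome with one planted
network (a large pseudo-thalamic hub plus eight small peripheral foci)
and a 23-case lesion cohort overlapping the peripheral foci, leaving the
hub lesion-free so that hub recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import Connectome
from .volumes import LesionMask, Volume, VolumeGrid, in_mask_indices, write_volume

__all__ = [
    "NetworkSpec",
    "SphereCohortSpec",
    "PlantedStudy",
    "demo_grid",
    "sphere_indices",
    "generate_connectome",
    "generate_lesion_cohort",
    "generate_sphere_cohort",
    "planted_network_study",
    "write_cohort",
]


@dataclass
class NetworkSpec:
    """Latent-network structure of a synthetic connectome.

    node_regions are flat C-order voxel indices (within the full grid);
    each region loads on its own latent signal with its coupling.
    """

    node_regions: list[np.ndarray]
    coupling: list[float]
    noise_sd: float = 1.0
    n_timepoints: int = 150

    def __post_init__(self) -> None:
        self.node_regions = [np.asarray(r, dtype=np.intp) for r in self.node_regions]
        if np.isscalar(self.coupling):
            self.coupling = [float(self.coupling)] * len(self.node_regions)
        self.coupling = [float(c) for c in self.coupling]
        if len(self.coupling) != len(self.node_regions):
            raise ValueError("one coupling per node region required")
        if any(not 0 <= c <= 1 for c in self.coupling):
            raise ValueError("coupling must lie in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints < 3: correlation undefined")

    def validate_against(self, grid: VolumeGrid) -> None:
        mask_flat = grid.brain_mask.ravel(order="C")
        for i, reg in enumerate(self.node_regions):
            if reg.size and not mask_flat[reg].all():
                raise ValueError(f"node region {i} leaves the brain mask")


@dataclass
class SphereCohortSpec:
    """Control cohort of grey-matter-masked spheres (12 mm radius, n=100)."""

    grey_mask: Volume
    n_masks: int = 100
    radius_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_masks < 1:
            raise ValueError("n_masks must be >= 1")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be > 0")
        if self.grey_mask.kind != "binary":
            raise ValueError("grey_mask must be a binary volume")
        if not self.grey_mask.data.any():
            raise ValueError("grey_mask is empty")


def demo_grid(
    shape: tuple[int, int, int] = (24, 28, 24), voxel_mm: float = 2.0
) -> VolumeGrid:
    """Default desk-scale grid: 24x28x24 voxels at 2 mm isotropic with an
    ellipsoidal brain mask (semi-axes 90% of the half-dimensions)."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    center = (np.array(shape) - 1) / 2.0
    semi = 0.9 * np.array(shape) / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    rad2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return VolumeGrid(tuple(shape), affine, rad2 <= 1.0)


def sphere_indices(
    grid: VolumeGrid,
    center_ijk: np.ndarray,
    radius_mm: float,
    restrict: np.ndarray | None = None,
) -> np.ndarray:
    """Flat indices of voxels whose world coordinates lie within
    ``radius_mm`` of the center voxel's world coordinates, optionally
    intersected with a boolean ``restrict`` volume."""
    center_ijk = np.asarray(center_ijk, dtype=int)
    vs = np.asarray(grid.voxel_size)
    half = np.ceil(radius_mm / vs).astype(int)
    lo = np.maximum(center_ijk - half, 0)
    hi = np.minimum(center_ijk + half + 1, grid.shape)
    ranges = [np.arange(l, h) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d = np.linalg.norm(
        grid.world_coords(ijk) - grid.world_coords(center_ijk)[0], axis=1
    )
    ijk = ijk[d <= radius_mm + 1e-9]
    flat = np.ravel_multi_index(ijk.T, grid.shape)
    keep = grid.brain_mask.ravel(order="C")[flat]
    if restrict is not None:
        keep &= restrict.ravel(order="C")[flat]
    return np.sort(flat[keep])


def generate_connectome(
    grid: VolumeGrid,
    n_subjects: int,
    spec: NetworkSpec,
    seed: int,
    dtype=np.float32,
) -> Connectome:
    """Simulate a resting-state connectome with planted latent networks.

    Deterministic given ``seed``.  Row order follows
    :func:`lnmap.volumes.in_mask_indices`.
    """
    if n_subjects < 2:
        raise ValueError("a connectome needs >= 2 subjects")
    spec.validate_against(grid)
    rng = np.random.default_rng(seed)
    idx = in_mask_indices(grid)
    # map region flat indices -> row positions in the in-mask ordering
    region_rows = []
    for reg in spec.node_regions:
        pos = np.searchsorted(idx, reg)
        region_rows.append(pos)
    n_vox, n_t = idx.size, spec.n_timepoints
    subjects = []
    for _ in range(n_subjects):
        data = rng.normal(0.0, spec.noise_sd, size=(n_vox, n_t))
        for rows, c in zip(region_rows, spec.coupling):
            if rows.size and c > 0:
                data[rows] += c * rng.standard_normal(n_t)
        subjects.append(data.astype(dtype))
    return Connectome(grid, subjects)


def generate_lesion_cohort(
    grid: VolumeGrid,
    spec: NetworkSpec,
    n_lesions: int,
    seed: int,
    blob_radius_mm: float = 3.0,
) -> list[LesionMask]:
    """Plant small lesion blobs centred in randomly chosen network nodes.

    Each mask is a sphere of ``blob_radius_mm`` around a random voxel of a
    random node region, clipped to the brain mask; radius 0 gives
    single-voxel masks.  Deterministic given ``seed``.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    regions = [r for r in spec.node_regions if r.size]
    if not regions:
        raise ValueError("spec has no non-empty node regions")
    rng = np.random.default_rng(seed)
    masks = []
    for i in range(n_lesions):
        reg = regions[int(rng.integers(len(regions)))]
        center_flat = int(reg[int(rng.integers(reg.size))])
        center_ijk = np.unravel_index(center_flat, grid.shape)
        if blob_radius_mm > 0:
            flat = sphere_indices(grid, np.array(center_ijk), blob_radius_mm)
        else:
            flat = np.array([center_flat])
        vol = np.zeros(grid.shape, dtype=np.uint8)
        vol.ravel(order="C")[flat] = 1
        masks.append(LesionMask(f"case-{i:03d}", Volume(grid, vol, kind="binary")))
    return masks


def generate_sphere_cohort(
    grid: VolumeGrid, spec: SphereCohortSpec
) -> list[LesionMask]:
    """Control cohort: spheres masked to grey matter.

    Centers are drawn uniformly over grey-mask voxels without replacement
    (so all masks are distinct); each mask keeps exactly the voxels within
    ``radius_mm`` of its center, intersected with grey matter.
    """
    grey = spec.grey_mask.data.astype(bool) & grid.brain_mask
    grey_flat = np.flatnonzero(grey.ravel(order="C"))
    if grey_flat.size < spec.n_masks:
        raise ValueError(
            f"only {grey_flat.size} grey voxels for {spec.n_masks} masks"
        )
    rng = np.random.default_rng(spec.seed)
    centers = rng.choice(grey_flat, size=spec.n_masks, replace=False)
    masks = []
    for i, cf in enumerate(centers):
        center_ijk = np.array(np.unravel_index(int(cf), grid.shape))
        flat = sphere_indices(grid, center_ijk, spec.radius_mm, restrict=grey)
        if flat.size == 0:  # center itself is grey, so this cannot trigger
            flat = np.array([int(cf)])
        vol = np.zeros(grid.shape, dtype=np.uint8)
        vol.ravel(order="C")[flat] = 1
        masks.append(
            LesionMask(f"sphere-{i:03d}", Volume(grid, vol, kind="binary"))
        )
    return masks


@dataclass
class PlantedStudy:
    """A full synthetic study: connectome + lesion cohort + ground truth."""

    grid: VolumeGrid
    connectome: Connectome
    lesions: list[LesionMask]
    network_spec: NetworkSpec
    hub_flat: np.ndarray  # flat indices of the lesion-free hub
    node_flats: list[np.ndarray]  # peripheral foci (lesion targets)

    def hub_mask(self) -> Volume:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        vol.ravel(order="C")[self.hub_flat] = 1
        return Volume(self.grid, vol, kind="binary")


def _default_node_centers(grid: VolumeGrid) -> tuple[np.ndarray, list[np.ndarray]]:
    """Hub at the grid center; eight peripheral foci at 55% of the mask
    half-axes along the corner diagonals (all inside the ellipsoid)."""
    center = (np.array(grid.shape) - 1) / 2.0
    semi = 0.9 * np.array(grid.shape) / 2.0
    corners = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                corners.append(
                    np.round(center + 0.55 / np.sqrt(3) * semi * (sx, sy, sz))
                    .astype(int)
                )
    return center.astype(int), corners


def planted_network_study(
    seed: int,
    grid: VolumeGrid | None = None,
    n_subjects: int = 100,
    n_timepoints: int = 150,
    coupling: float = 0.8,
    noise_sd: float = 1.0,
    n_lesions: int = 23,
    hub_radius_mm: float = 8.0,
    node_radius_mm: float = 3.0,
    lesion_radius_mm: float = 3.0,
) -> PlantedStudy:
    """Build the desk-scale planted-network study.

    Eight peripheral foci each carry their own latent signal, and every
    focus's network region also includes the central hub sphere
    (pseudo-thalamus), so the hub fluctuates with all eight foci while
    the foci stay mutually independent.  Lesions are planted only on the
    peripheral foci, so the hub — the voxels functionally connected to
    every lesion — stays lesion-free and hub recovery can be scored.
    Heterogeneously placed lesions thereby yield distinct connectivity
    maps that agree only at the hub, which is the structure the mapping
    analysis is designed to detect.  With coupling 0 the connectome is a
    pure-noise global null (the lesion cohort is still planted at the
    foci).
    """
    grid = grid or demo_grid()
    hub_center, node_centers = _default_node_centers(grid)
    hub_flat = sphere_indices(grid, hub_center, hub_radius_mm)
    node_flats = [sphere_indices(grid, c, node_radius_mm) for c in node_centers]
    node_flats = [f for f in node_flats if f.size]
    regions = [np.unique(np.concatenate([hub_flat, f])) for f in node_flats]
    conn_spec = NetworkSpec(
        regions, [coupling] * len(regions),
        noise_sd=noise_sd, n_timepoints=n_timepoints,
    )
    lesion_spec = NetworkSpec(
        node_flats, [coupling] * len(node_flats),
        noise_sd=noise_sd, n_timepoints=n_timepoints,
    )
    connectome = generate_connectome(grid, n_subjects, conn_spec, seed=seed)
    lesions = generate_lesion_cohort(
        grid, lesion_spec, n_lesions, seed=seed + 1,
        blob_radius_mm=lesion_radius_mm,
    )
    return PlantedStudy(grid, connectome, lesions, conn_spec, hub_flat, node_flats)


def write_cohort(
    masks: list[LesionMask], out_dir: str | Path, meta: dict | None = None
) -> Path:
    """Write a lesion cohort as NIfTI masks plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": {}, "meta": meta or {}}
    for m in masks:
        fname = f"{m.case_id}.nii.gz"
        write_volume(m.volume, out_dir / fname)
        manifest["cases"][m.case_id] = fname
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
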