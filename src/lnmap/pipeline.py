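"""End-to-end pipeline orchestration with YAML config and provenance.

``run_pipeline`` executes the configured stages in order — seed T-maps,
binary overlap + LNM, sign-flip permutation test, specificity contrast
against a sphere control cohort, leave-k-out stability, winner-takes-all
parcellation with the parcel post-hoc, and the review tabulation —
writing NIfTI maps, TSV tables and a JSON manifest (config, seed, file
hashes) into a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import Connectome, cohort_tmaps, tmap_threshold_pvalue
from .inference import leave_k_out_stability, two_sample_perm
from .mapping import LesionNetworkMapper, signflip_onesample
from .parcellation import lesion_parcel_strengths, parcel_anova, winner_takes_all
from .review import load_findings, summaries_frame, tabulate
from .synthetic import SphereCohortSpec, generate_sphere_cohort
from .volumes import (
    LesionMask,
    Volume,
    VolumeGrid,
    read_lesion_masks,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_connectome_dir",
           "write_connectome_dir"]


@dataclass
class RunConfig:
    """All paths and analysis parameters of one pipeline run.

    Parameter defaults are the published analysis settings: T-threshold 7,
    95% overlap fraction, 5000 permutations at FWE alpha 0.05, leave-5/7/9
    out with 100 subsets each, and a 100-sphere 12 mm control cohort.
    """

    connectome_dir: str = ""
    lesion_dir: str = ""
    brain_mask: str = ""
    grey_mask: str = ""
    roi_labels: str = ""
    target_mask: str = ""
    findings_tsv: str = ""
    out_dir: str = "lnm-run"

    t_threshold: float = 7.0
    frac: float = 0.95
    n_perm: int = 5000
    alpha: float = 0.05
    tail: str = "greater"
    fisher_z: bool = False
    k_list: list[int] = field(default_factory=lambda: [5, 7, 9])
    n_subsets: int = 100
    sphere_radius_mm: float = 12.0
    sphere_n: int = 100
    run_specificity: bool = True
    run_stability: bool = True
    run_parcellation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not 0 < self.frac <= 1:
            raise ValueError("frac must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1 or self.n_subsets < 1 or self.sphere_n < 1:
            raise ValueError("n_perm, n_subsets and sphere_n must be >= 1")
        if self.run_specificity and not self.grey_mask:
            raise ValueError(
                "specificity stage needs a grey_mask to build the sphere cohort"
            )


def write_connectome_dir(conn: Connectome, out_dir: str | Path) -> Path:
    """Write a connectome as per-subject 4-D NIfTIs plus the brain mask."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = conn.grid
    write_volume(
        Volume(grid, grid.brain_mask.astype(np.uint8), kind="binary"),
        out_dir / "brain_mask.nii.gz",
    )
    from .volumes import in_mask_indices

    idx = in_mask_indices(grid)
    for i, s in enumerate(conn.subjects):
        vol4 = np.zeros((*grid.shape, s.shape[1]), dtype=np.float32)
        vol4.reshape(-1, s.shape[1])[idx] = s
        nib.Nifti1Image(vol4, grid.affine).to_filename(
            str(out_dir / f"sub-{i:03d}.nii.gz")
        )
    return out_dir


def read_connectome_dir(path: str | Path) -> Connectome:
    """Read a connectome directory written by :func:`write_connectome_dir`."""
    import nibabel as nib

    path = Path(path)
    mask_img = nib.load(str(path / "brain_mask.nii.gz"))
    mask = np.asanyarray(mask_img.dataobj).astype(bool)
    grid = VolumeGrid(mask.shape, np.asarray(mask_img.affine), mask)
    from .volumes import in_mask_indices

    idx = in_mask_indices(grid)
    subjects = []
    for f in sorted(path.glob("sub-*.nii*")):
        img = nib.load(str(f))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"{f}: expected 4-D BOLD volume")
        subjects.append(data.reshape(-1, data.shape[3])[idx])
    if not subjects:
        raise ValueError(f"no sub-*.nii[.gz] files under {path}")
    return Connectome(grid, subjects)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure aborts with the stage name and cause.  A rerun with
    the same config and seed reproduces the statistic maps exactly.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        conn = read_connectome_dir(config.connectome_dir)
        grid = conn.grid
        lesion_files = sorted(Path(config.lesion_dir).glob("*.nii*"))
        lesions = read_lesion_masks(lesion_files, grid)
        if not lesions:
            raise ValueError(f"no lesion masks under {config.lesion_dir}")

        stage = "map"
        tmaps = cohort_tmaps(conn, lesions, use_fisher_z=config.fisher_z)
        tmap_dir = out / "tmaps"
        tmap_dir.mkdir(exist_ok=True)
        for tm in tmaps:
            write_volume(tm.to_volume(), tmap_dir / f"{tm.case_id}_tmap.nii.gz")
        sidecar = {
            "df": tmaps[0].df,
            "fisher_z": config.fisher_z,
            "t_threshold": config.t_threshold,
            "threshold_uncorrected_p_two_sided": tmap_threshold_pvalue(
                config.t_threshold, tmaps[0].df
            ),
        }
        (tmap_dir / "tmaps.json").write_text(json.dumps(sidecar, indent=2))

        stage = "overlap"
        mapper = LesionNetworkMapper(
            t_threshold=config.t_threshold, frac=config.frac
        ).fit(tmaps)
        write_volume(mapper.overlap_.to_volume(), out / "overlap.nii.gz")
        write_volume(mapper.lnm_.volume, out / "lnm.nii.gz")

        stage = "permtest"
        perm = signflip_onesample(
            tmaps, n_perm=config.n_perm, alpha=config.alpha,
            tail=config.tail, seed=config.seed,
        )
        write_volume(perm.stat_volume(), out / "perm_tstat.nii.gz")
        write_volume(perm.p_volume(), out / "perm_fwe_p.nii.gz")
        write_volume(perm.significant_volume(), out / "perm_significant.nii.gz")

        contrast_summary = None
        if config.run_specificity:
            stage = "specificity"
            grey = read_volume(config.grey_mask, grid=grid, kind="binary")
            spheres = generate_sphere_cohort(
                grid,
                SphereCohortSpec(
                    grey_mask=grey, n_masks=config.sphere_n,
                    radius_mm=config.sphere_radius_mm, seed=config.seed,
                ),
            )
            sphere_tmaps = cohort_tmaps(conn, spheres,
                                        use_fisher_z=config.fisher_z)
            contrast = two_sample_perm(
                tmaps, sphere_tmaps, n_perm=config.n_perm,
                alpha=config.alpha, tail="greater", seed=config.seed,
            )
            write_volume(contrast.specific_volume(), out / "specific.nii.gz")
            contrast_summary = {
                "n_specific_voxels": int(contrast.specific_set.sum())
            }

        stability_summary = None
        if config.run_stability:
            stage = "stability"
            rows, stability_summary = [], []
            for k in config.k_list:
                rep = leave_k_out_stability(
                    tmaps, k=k, n_subsets=config.n_subsets,
                    reference=mapper.overlap_, seed=config.seed + k,
                )
                stability_summary.append(rep.summary())
                rows += [
                    {"k": k, "subset": i, "pearson_r": float(r)}
                    for i, r in enumerate(rep.correlations)
                ]
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "stability.tsv", sep="\t",
                                      index=False)

        parcel_summary = None
        if config.run_parcellation and config.roi_labels and config.target_mask:
            stage = "parcellate"
            roi = read_volume(config.roi_labels, grid=grid, kind="label")
            target = read_volume(config.target_mask, grid=grid, kind="binary")
            atlas = winner_takes_all(conn, roi, target,
                                     use_fisher_z=config.fisher_z)
            write_volume(atlas.labels_volume, out / "thalamus_parcels.nii.gz")
            (out / "thalamus_parcels.json").write_text(
                json.dumps({"labels": list(atlas.label_names)}, indent=2)
            )
            table = lesion_parcel_strengths(tmaps, atlas)
            table.to_csv(out / "parcel_strengths.tsv", sep="\t", index=False)
            parcel_summary = parcel_anova(table)

        review_summary = None
        if config.findings_tsv:
            stage = "review"
            summaries = tabulate(load_findings(config.findings_tsv))
            summaries_frame(summaries).to_csv(
                out / "review_summary.tsv", sep="\t", index=False
            )
            review_summary = {s.finding: s.percent for s in summaries}

        stage = "manifest"
        manifest = {
            "lnmap_version": __version__,
            "config": config.to_dict(),
            "n_cases": len(lesions),
            "n_subjects": conn.n_subjects,
            "min_count": mapper.lnm_.min_count,
            "n_lnm_voxels": int(mapper.lnm_.volume.data.sum()),
            "n_perm_significant_voxels": int(perm.significant.sum()),
            "specificity": contrast_summary,
            "stability": stability_summary,
            "parcellation": parcel_summary,
            "review_percent": review_summary,
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(out.glob("*.nii.gz"))
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline finished -> %s", out)
    return out
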