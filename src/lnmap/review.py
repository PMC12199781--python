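"""Tabulation of MRICS-style imaging findings pooled across studies.

Findings follow the MRI classification system for cerebral palsy
(MRICS): the general categories (white matter injury, grey matter
injury, maldevelopment, miscellaneous, normal), the grey-matter
sub-patterns (basal ganglia with/without thalamus, cortical/subcortical,
focal infarcts) and specific subcortical sites.  For each finding the
summary pools, over the non-excluded studies reporting it, the number of
studies, the total patients in those studies, the affected patients and
the affected percentage (rounded half-up to an integer).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "FINDING_VOCABULARY",
    "StudyFinding",
    "FindingSummary",
    "load_findings",
    "tabulate",
    "summaries_frame",
    "bundled_counts_path",
]

#: Controlled vocabulary: MRICS categories plus specific subcortical sites.
FINDING_VOCABULARY = (
    "white_matter_injury",
    "grey_matter_injury",
    "maldevelopment",
    "miscellaneous",
    "normal",
    "bg_thalamus",
    "cortical_subcortical",
    "focal_infarct",
    "thalamus",
    "pallidum",
    "putamen",
    "subthalamic_nucleus",
    "corpus_callosum",
    "internal_capsule",
    "brainstem",
    "substantia_nigra",
    "caudate",
    "cerebellum",
    "hippocampus",
)


@dataclass(frozen=True)
class StudyFinding:
    """One study's report of one finding."""

    study_id: str
    finding: str
    n_total: int
    n_affected: int
    excluded_for_bias: bool = False

    def __post_init__(self) -> None:
        if self.finding not in FINDING_VOCABULARY:
            raise ValueError(f"unknown finding {self.finding!r}")
        if self.n_total < 0 or self.n_affected < 0:
            raise ValueError("counts must be non-negative")
        if self.n_affected > self.n_total:
            raise ValueError(
                f"{self.study_id}/{self.finding}: "
                f"n_affected {self.n_affected} > n_total {self.n_total}"
            )


@dataclass(frozen=True)
class FindingSummary:
    """Pooled counts and rounded percentage for one finding."""

    finding: str
    n_studies: int
    N_total: int
    n_affected: int
    percent: int


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (51% from 451/893)."""
    import math

    return int(math.floor(x + 0.5))


def tabulate(findings: list[StudyFinding]) -> list[FindingSummary]:
    """Pool findings across studies into per-finding summaries.

    Studies flagged ``excluded_for_bias`` are dropped first; counts are
    pooled only over studies reporting the finding.  Output order follows
    the controlled vocabulary, so the result is invariant to input row
    order.
    """
    kept = [f for f in findings if not f.excluded_for_bias]
    out = []
    for name in FINDING_VOCABULARY:
        rows = [f for f in kept if f.finding == name]
        if not rows:
            continue
        n_total = sum(f.n_total for f in rows)
        n_aff = sum(f.n_affected for f in rows)
        pct = _round_half_up(100.0 * n_aff / n_total) if n_total else 0
        out.append(
            FindingSummary(
                finding=name,
                n_studies=len(rows),
                N_total=n_total,
                n_affected=n_aff,
                percent=pct,
            )
        )
    return out


def summaries_frame(summaries: list[FindingSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


_COLUMNS = ("study_id", "finding", "n_total", "n_affected", "excluded_for_bias")


def load_findings(path: str | Path) -> list[StudyFinding]:
    """Load and validate a findings TSV.

    Expects a header with study_id, finding, n_total, n_affected and an
    optional excluded_for_bias column; malformed rows are reported with
    their line numbers in one error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            excluded = str(row.get("excluded_for_bias", "")).strip().lower() in (
                "1", "true", "yes",
            )
            records.append(
                StudyFinding(
                    study_id=str(row["study_id"]),
                    finding=str(row["finding"]).strip(),
                    n_total=int(row["n_total"]),
                    n_affected=int(row["n_affected"]),
                    excluded_for_bias=excluded,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(errors))
    return records


def write_findings(findings: list[StudyFinding], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([f.__dict__ for f in findings]).to_csv(
        path, sep="\t", index=False
    )
    return path


def bundled_counts_path() -> Path:
    """Path of the bundled pooled-counts fixture (one row per finding,
    pooled over the non-excluded studies of the dyskinetic-CP review)."""
    return Path(resources.files("lnmap") / "data" / "dcp_review_counts.tsv")
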