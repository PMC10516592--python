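"""Per-scan cohort table: schema, CSV I/O, QC exclusions, response variables.

The in-memory container is a long-format :class:`pandas.DataFrame` with one
row per imaging visit.  Metadata columns are fixed (see
:data:`META_COLUMNS`); every other numeric column is treated as a
region-of-interest (ROI) volume in mm³.  Bilateral structures may arrive as
``<roi>_left`` / ``<roi>_right`` pairs; the reader sums them, since the two
hemispheres are analysed together.

Two response variables can be built for any ROI: the raw volume (mm³), with
intracranial volume entering the regression as a covariate, or the
whole-brain-normalized ratio ``roi / whole_brain``, which isolates atrophy
in excess of global parenchymal loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "subject_id",
    "study",
    "group",
    "visit_index",
    "age",
    "icv",
    "whole_brain",
)

#: Optional clinical scores carried through without modelling.
CLINICAL_COLUMNS = ("tms", "sdmt", "tfc", "bdi")

META_COLUMNS = MANDATORY_COLUMNS + ("cag", "cap", "qc_pass") + CLINICAL_COLUMNS

GROUPS = ("control", "premanifest", "manifest")

#: Subcortical analysis set plus the five paired cortical gyrus / white
#: matter regions (precentral, superior frontal/parietal/occipital/temporal).
CORE_ROIS = (
    "putamen",
    "caudate",
    "globus_pallidus",
    "nucleus_accumbens",
    "substantia_nigra",
    "thalamus",
    "prcg",
    "prcwm",
    "sfg",
    "sfwm",
    "spg",
    "spwm",
    "sog",
    "sowm",
    "stg",
    "stwm",
)

BASAL_GANGLIA_ROIS = (
    "putamen",
    "caudate",
    "globus_pallidus",
    "nucleus_accumbens",
    "substantia_nigra",
)


@dataclass(frozen=True)
class RoiCatalog:
    """Ordered list of ROI column names under analysis."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate ROI names in catalog")

    @classmethod
    def default(cls) -> "RoiCatalog":
        return cls(names=CORE_ROIS)

    def require_core(self) -> None:
        """Raise if the catalog is missing any region of the core analysis set."""
        missing = [r for r in CORE_ROIS if r not in self.names]
        if missing:
            raise ValueError(f"catalog missing core analysis regions: {missing}")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def roi_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns of ``cohort`` that are ROI volumes (everything non-meta)."""
    return [c for c in cohort.columns if c not in META_COLUMNS]


def _merge_hemispheres(df: pd.DataFrame) -> pd.DataFrame:
    bases = {}
    for col in df.columns:
        for suffix in ("_left", "_right"):
            if col.endswith(suffix):
                bases.setdefault(col[: -len(suffix)], []).append(col)
    for base, cols in bases.items():
        if len(cols) == 2:
            df[base] = df[cols[0]].astype(float) + df[cols[1]].astype(float)
            df = df.drop(columns=cols)
            logger.info("summed hemisphere columns %s into %r", cols, base)
    return df


def validate_volumes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Flag rows violating volumetric sanity as ``qc_pass=False``.

    Checks ``icv > whole_brain > 0`` and ``0 < roi < whole_brain`` for every
    ROI column.  Returns a new frame; violations are logged.
    """
    out = cohort.copy()
    if "qc_pass" not in out.columns:
        out["qc_pass"] = True
    icv = out["icv"].to_numpy(float)
    wbv = out["whole_brain"].to_numpy(float)
    bad = ~((icv > wbv) & (wbv > 0))
    for col in roi_columns(out):
        v = out[col].to_numpy(float)
        bad |= ~((v > 0) & (v < wbv))
    if bad.any():
        logger.warning(
            "%d rows violate volume invariants (icv > whole_brain > roi > 0); "
            "flagged qc_pass=False",
            int(bad.sum()),
        )
        out.loc[bad, "qc_pass"] = False
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (one row per scan) into a validated DataFrame.

    Hemisphere column pairs are summed, mandatory columns checked, numeric
    fields coerced (rows that fail coercion are dropped with their row
    numbers logged), duplicate ``(subject_id, visit_index)`` pairs rejected,
    and volumetric invariants checked via :func:`validate_volumes`.
    """
    df = pd.read_csv(path)
    df = _merge_hemispheres(df)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing mandatory columns: {missing}")

    numeric = ["visit_index", "age", "icv", "whole_brain", "cag", "cap"] + list(
        CLINICAL_COLUMNS
    )
    numeric = [c for c in numeric if c in df.columns] + roi_columns(df)
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    must_be_finite = ["visit_index", "age", "icv", "whole_brain"] + roi_columns(df)
    bad_rows = df.index[df[must_be_finite].isna().any(axis=1)]
    if len(bad_rows):
        logger.warning(
            "dropping %d rows failing numeric coercion (rows %s)",
            len(bad_rows),
            bad_rows.tolist(),
        )
        df = df.drop(index=bad_rows).reset_index(drop=True)

    dup = df.duplicated(subset=["subject_id", "visit_index"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "visit_index"]].drop_duplicates()
        raise ValueError(
            f"duplicate (subject_id, visit_index) pairs: {pairs.to_dict('records')}"
        )

    if "qc_pass" in df.columns:
        df["qc_pass"] = df["qc_pass"].astype(bool)
    df["visit_index"] = df["visit_index"].astype(int)

    # ages must increase within subject across visits
    for sid, sub in df.sort_values("visit_index").groupby("subject_id"):
        ages = sub["age"].to_numpy(float)
        if len(ages) > 1 and not np.all(np.diff(ages) > 0):
            logger.warning("subject %r: ages not strictly increasing across visits", sid)

    return validate_volumes(df)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort to CSV (full float precision, round-trip safe)."""
    cohort.to_csv(path, index=False)


@dataclass(frozen=True)
class ExclusionRules:
    """Declarative scan-level exclusion rules, applied in order.

    ``volume_z_threshold`` excludes scans whose ROI volume lies more than
    this many SDs from the column mean (any ROI); ``None`` disables it.
    """

    require_qc_pass: bool = True
    required_columns: tuple[str, ...] = ("age", "icv", "whole_brain")
    volume_z_threshold: Optional[float] = None


def apply_exclusions(
    cohort: pd.DataFrame, rules: ExclusionRules = ExclusionRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the cohort into kept rows and excluded rows with reasons.

    The partition is exhaustive and disjoint; each excluded row carries the
    first rule it violated in ``exclusion_reason``.  Per-rule counts are
    logged, mirroring study QC accounting.
    """
    reason = pd.Series("", index=cohort.index, dtype=object)

    if rules.require_qc_pass and "qc_pass" in cohort.columns:
        mask = ~cohort["qc_pass"].astype(bool)
        reason[mask & reason.eq("")] = "qc_fail"

    for col in rules.required_columns:
        if col in cohort.columns:
            mask = cohort[col].isna()
            reason[mask & reason.eq("")] = f"missing_{col}"

    if rules.volume_z_threshold is not None:
        for col in roi_columns(cohort):
            v = cohort[col].astype(float)
            sd = v.std(ddof=1)
            if sd > 0:
                z = (v - v.mean()).abs() / sd
                mask = z > rules.volume_z_threshold
                reason[mask & reason.eq("")] = f"volume_outlier_{col}"

    excluded = cohort.loc[reason.ne("")].copy()
    excluded["exclusion_reason"] = reason[reason.ne("")]
    kept = cohort.loc[reason.eq("")].copy()

    counts = excluded["exclusion_reason"].value_counts().to_dict() if len(excluded) else {}
    logger.info("exclusions: %d kept, %d excluded %s", len(kept), len(excluded), counts)
    return kept, excluded


def exclusion_report(
    kept: pd.DataFrame, excluded: pd.DataFrame, path=None
) -> dict:
    """Summarize an exclusion partition; optionally write it as JSON."""
    report = {
        "n_input": int(len(kept) + len(excluded)),
        "n_kept": int(len(kept)),
        "n_excluded": int(len(excluded)),
        "by_reason": (
            {k: int(v) for k, v in excluded["exclusion_reason"].value_counts().items()}
            if len(excluded)
            else {}
        ),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report


def make_response(
    cohort: pd.DataFrame, roi: str, normalize_wbv: bool = False
) -> np.ndarray:
    """Response vector for one ROI.

    ``normalize_wbv=False`` returns the raw volume in mm³ (head size is
    handled downstream by the ICV covariate); ``normalize_wbv=True`` returns
    the dimensionless ratio ``roi / whole_brain``, strictly in (0, 1) for
    valid records and invariant to any global rescaling of the volumetric
    columns.
    """
    if roi not in cohort.columns:
        raise KeyError(f"ROI column {roi!r} not present in cohort")
    v = cohort[roi].to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"ROI {roi!r} missing on {int(np.isnan(v).sum())} records")
    if normalize_wbv:
        return v / cohort["whole_brain"].to_numpy(dtype=float)
    return v
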