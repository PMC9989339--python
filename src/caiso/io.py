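"""CSV schemas and readers/writers for sessions, cohorts and reduced results.

Session CSV: one row per cycle with columns block_id, block_type, run_index,
cycle_index, intensity_42, intensity_43, intensity_43p5, intensity_44, label.

Cohort CSV: one row per subject; empty cells are missing values.

Reduced CSV: one row per sample analysis with deltas on both the in-house and
SRM 915a scales, the internal precision, the four QC statistics and flags,
and the overall accept flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, StructureError
from .reduction import AnalysisSession, BlockType, DeltaMeasurement, IsotopeCycleBlock
from .scales import DEFAULT_REGISTRY, SRM915A, ScaleRegistry

SESSION_COLUMNS = [
    "block_id",
    "block_type",
    "run_index",
    "cycle_index",
    "intensity_42",
    "intensity_43",
    "intensity_43p5",
    "intensity_44",
    "label",
]

COHORT_REQUIRED = ["subject_id", "group"]
COHORT_ENUMS = {
    "group": {"control", "mild_moderate", "dialysis", "transplant"},
    "sex": {"female", "male"},
}
COHORT_NUMERIC = [
    "age_years", "sbp_mmhg", "bmi_kg_m2", "egfr", "ca_mmol_l", "po4",
    "albumin", "pth_pmol_l", "alp_u_l", "creatinine_umol_l", "fgf23_log10",
    "vitd", "abi", "ba_pwv_cm_s", "urine_ca_ug_g", "urine_delta44_42",
    "serum_delta44_42",
]


@dataclass
class Violation:
    row: int | None  # 0-based data row, None for file-level problems
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = f"row {self.row}, " if self.row is not None else ""
        col = f"column {self.column!r}: " if self.column else ""
        return f"{loc}{col}{self.message}"


# ---------------------------------------------------------------------------
# session CSV
# ---------------------------------------------------------------------------

def write_session_csv(session: AnalysisSession, path: str | Path) -> None:
    rows = []
    for b in session.blocks:
        for ci in range(b.n_cycles):
            rows.append(
                {
                    "block_id": b.block_id,
                    "block_type": b.block_type.value,
                    "run_index": b.run_index,
                    "cycle_index": ci,
                    "intensity_42": b.intensity_42[ci],
                    "intensity_43": b.intensity_43[ci],
                    "intensity_43p5": b.intensity_43p5[ci],
                    "intensity_44": b.intensity_44[ci],
                    "label": b.label,
                }
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_session_csv(path: str | Path) -> AnalysisSession:
    df, violations = validate_session_table(path)
    if violations:
        raise DataError(
            f"{path}: invalid session file: " + "; ".join(str(v) for v in violations)
        )
    return session_from_frame(df)


def session_from_frame(df: pd.DataFrame) -> AnalysisSession:
    blocks = []
    for (run_index, block_id), sub in df.sort_values(["run_index", "cycle_index"]).groupby(
        ["run_index", "block_id"], sort=True
    ):
        blocks.append(
            IsotopeCycleBlock(
                block_id=str(block_id),
                block_type=BlockType(sub["block_type"].iloc[0]),
                run_index=int(run_index),
                intensity_42=sub["intensity_42"].to_numpy(float),
                intensity_43=sub["intensity_43"].to_numpy(float),
                intensity_43p5=sub["intensity_43p5"].to_numpy(float),
                intensity_44=sub["intensity_44"].to_numpy(float),
                label=str(sub["label"].iloc[0]) if "label" in sub else "",
            )
        )
    return AnalysisSession(blocks=blocks)


def validate_session_table(path: str | Path) -> tuple[pd.DataFrame | None, list[Violation]]:
    """Parse and validate a session CSV; returns (frame-or-None, violations)."""
    violations: list[Violation] = []
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        return None, [Violation(None, None, f"unreadable file: {exc}")]
    missing = [c for c in SESSION_COLUMNS if c not in df.columns and c != "label"]
    for c in missing:
        violations.append(Violation(None, c, "missing required column"))
    if missing:
        return None, violations
    if "label" not in df.columns:
        df["label"] = ""
    for col in ("run_index", "cycle_index", "intensity_42", "intensity_43",
                "intensity_43p5", "intensity_44"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        for row in bad[:10]:
            violations.append(Violation(int(row), col, f"non-numeric cell {df[col].iloc[row]!r}"))
        df[col] = parsed
    bad_types = ~df["block_type"].isin([t.value for t in BlockType])
    for row in np.nonzero(bad_types.to_numpy())[0][:10]:
        violations.append(
            Violation(int(row), "block_type", f"bad enum value {df['block_type'].iloc[row]!r}")
        )
    if violations:
        return None, violations
    # structural bracketing check
    try:
        session_from_frame(df).validate()
    except (StructureError, DataError) as exc:
        violations.append(Violation(None, None, str(exc)))
    return df, violations


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df, violations = validate_cohort_table(path)
    if violations:
        raise DataError(
            f"{path}: invalid cohort file: " + "; ".join(str(v) for v in violations)
        )
    return df


def validate_cohort_table(path: str | Path) -> tuple[pd.DataFrame | None, list[Violation]]:
    """Parse and validate a cohort CSV; empty cells are missing values."""
    violations: list[Violation] = []
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        return None, [Violation(None, None, f"unreadable file: {exc}")]
    for c in COHORT_REQUIRED:
        if c not in df.columns:
            violations.append(Violation(None, c, "missing required column"))
    if violations:
        return None, violations
    for col, allowed in COHORT_ENUMS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna().astype(str)
        bad = vals[~vals.isin(allowed)]
        for row, v in list(bad.items())[:10]:
            violations.append(Violation(int(row), col, f"bad enum value {v!r}"))
    for col in COHORT_NUMERIC:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        newly_bad = parsed.isna() & df[col].notna()
        for row in np.nonzero(newly_bad.to_numpy())[0][:10]:
            violations.append(Violation(int(row), col, f"non-numeric cell {df[col].iloc[row]!r}"))
        df[col] = parsed
    if violations:
        return None, violations
    return df, violations


# ---------------------------------------------------------------------------
# reduced output CSV
# ---------------------------------------------------------------------------

def reduced_frame(
    measurements: list[DeltaMeasurement], registry: ScaleRegistry = DEFAULT_REGISTRY
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        srm = m.on_scale(SRM915A, registry)
        rows.append(
            {
                "block_id": m.block_id,
                "label": m.label,
                "delta44_42_wigl": m.delta44_42,
                "delta43_42_wigl": m.delta43_42,
                "delta44_42_srm915a": srm.delta44_42,
                "delta43_42_srm915a": srm.delta43_42,
                "internal_2se": m.internal_2se,
                "qc_interference_value": m.qc.interference.value,
                "qc_interference_pass": m.qc.interference.passed,
                "qc_intensity_value": m.qc.intensity.value,
                "qc_intensity_pass": m.qc.intensity.passed,
                "qc_massbias_spread_value": m.qc.massbias_spread.value,
                "qc_massbias_spread_pass": m.qc.massbias_spread.passed,
                "qc_massdependence_value": m.qc.massdependence.value,
                "qc_massdependence_pass": m.qc.massdependence.passed,
                "overall_accept": m.qc.overall_accept,
            }
        )
    return pd.DataFrame(rows)


def write_reduced_csv(
    measurements: list[DeltaMeasurement],
    path: str | Path,
    registry: ScaleRegistry = DEFAULT_REGISTRY,
) -> None:
    reduced_frame(measurements, registry).to_csv(path, index=False)
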