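"""Reading and writing of TAC tables, cohort manifests, and matrices.

All on-disk formats are delimited text. A TAC table is one scan: columns
``frame_start, frame_end, input`` followed by one column per atlas region,
in atlas order, activities in kBq/mL and times in minutes. The manifest is
one row per scan with identifiers, group, covariates, and the TAC filename.
Matrices are written as CSV with region labels as header row and first
column so round-trips preserve both values and ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas

__all__ = [
    "RegionalTacSet", "SubjectRecord", "read_tac_table", "read_manifest",
    "manifest_to_frame", "write_matrix", "read_matrix",
]

GROUPS = ("HC", "TBI", "MS", "cLBP", "SCZ", "FEP", "DEP", "AD")
SEXES = ("M", "F")
GENOTYPES = ("HAB", "MAB", "NA")
SESSIONS = ("single", "test", "retest", "baseline", "block")


@dataclass
class RegionalTacSet:
    """One scan's regional time-activity curves plus its input function."""

    scan_id: str
    subject_id: str
    tracer: str
    batch: str
    frame_start: np.ndarray     # minutes
    frame_end: np.ndarray       # minutes
    activity: np.ndarray        # [n_frames, n_roi], kBq/mL
    input_curve: np.ndarray     # [n_frames], kBq/mL
    injected_dose: float        # MBq
    body_weight: float          # kg
    roi_names: tuple = ()

    def __post_init__(self):
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_end = np.asarray(self.frame_end, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.input_curve = np.asarray(self.input_curve, dtype=float)
        mids = self.frame_mid_times
        if mids.ndim != 1 or len(mids) != self.activity.shape[0]:
            raise ValueError("frame times and activity row count disagree")
        if np.any(np.diff(mids) <= 0) or np.any(mids <= 0):
            raise ValueError("frame mid-times must be strictly increasing and > 0")
        if np.any(self.frame_end <= self.frame_start):
            raise ValueError("frame_end must exceed frame_start")
        if not np.all(np.isfinite(self.activity)) or np.any(self.activity < 0):
            raise ValueError("activities must be finite and non-negative")
        if not np.all(np.isfinite(self.input_curve)) or np.any(self.input_curve < 0):
            raise ValueError("input curve must be finite and non-negative")
        if self.injected_dose <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        if self.roi_names and len(self.roi_names) != self.activity.shape[1]:
            raise ValueError("roi_names length does not match activity columns")

    @property
    def frame_mid_times(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2.0

    @property
    def frame_durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def n_roi(self) -> int:
        return self.activity.shape[1]


@dataclass
class SubjectRecord:
    """One scan's manifest row: identity, group, and covariates."""

    scan_id: str
    subject_id: str
    tracer: str
    batch: str
    group: str
    sex: str
    age: float
    genotype: str
    injected_dose: float       # MBq
    body_weight: float         # kg
    session: str = "single"
    tac_file: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group token {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex token {self.sex!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype token {self.genotype!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session token {self.session!r}")
        if self.injected_dose <= 0 or self.body_weight <= 0:
            raise ValueError("dose and weight must be positive")
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError("age must be a non-negative number")

    @property
    def dose_over_weight(self) -> float:
        """Injected dose normalized by body weight, MBq/kg."""
        return self.injected_dose / self.body_weight


def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a CSV/TSV table, auto-detecting the delimiter from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_tac_table(path, atlas: RoiAtlas, *, scan_id="", subject_id="",
                   tracer="", batch="", injected_dose=1.0,
                   body_weight=1.0) -> RegionalTacSet:
    """Read one scan's TAC table and validate it against the atlas.

    The file must contain ``frame_start``, ``frame_end``, ``input`` and one
    column per atlas region, in atlas order. Scan metadata (ids, dose,
    weight) come from the manifest, not the TAC file.
    """
    path = Path(path)
    df = _read_delimited(path)
    for col in ("frame_start", "frame_end", "input"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    roi_cols = [c for c in df.columns
                if c not in ("frame_start", "frame_end", "input")]
    missing = [n for n in atlas.roi_names if n not in roi_cols]
    if missing:
        raise ValueError(f"{path.name}: missing ROI columns {missing}")
    extra = [c for c in roi_cols if c not in atlas.roi_names]
    if extra:
        raise ValueError(f"{path.name}: unknown ROI columns {extra}")
    if tuple(roi_cols) != atlas.roi_names:
        raise ValueError(f"{path.name}: ROI columns are not in atlas order")
    return RegionalTacSet(
        scan_id=scan_id or path.stem,
        subject_id=subject_id,
        tracer=tracer,
        batch=batch,
        frame_start=df["frame_start"].to_numpy(float),
        frame_end=df["frame_end"].to_numpy(float),
        activity=df[list(atlas.roi_names)].to_numpy(float),
        input_curve=df["input"].to_numpy(float),
        injected_dose=injected_dose,
        body_weight=body_weight,
        roi_names=atlas.roi_names,
    )


_MANIFEST_COLUMNS = ("scan_id", "subject_id", "tracer", "batch", "group",
                     "sex", "age", "genotype", "injected_dose", "body_weight",
                     "session")


def read_manifest(path) -> list:
    """Read a cohort manifest into validated :class:`SubjectRecord` rows."""
    path = Path(path)
    df = _read_delimited(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing manifest columns {missing}")
    if df["scan_id"].duplicated().any():
        dupes = sorted(df.loc[df["scan_id"].duplicated(), "scan_id"])
        raise ValueError(f"{path.name}: duplicate scan ids {dupes}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            scan_id=str(row["scan_id"]),
            subject_id=str(row["subject_id"]),
            tracer=str(row["tracer"]),
            batch=str(row["batch"]),
            group=str(row["group"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            genotype=str(row["genotype"]),
            injected_dose=float(row["injected_dose"]),
            body_weight=float(row["body_weight"]),
            session=str(row["session"]),
            tac_file=str(row["tac_file"]) if "tac_file" in df.columns else "",
        ))
    return records


def manifest_to_frame(records) -> pd.DataFrame:
    """Tabular view of manifest records, indexed by scan id, with the
    derived dose-over-weight column."""
    df = pd.DataFrame([{
        "scan_id": r.scan_id, "subject_id": r.subject_id, "tracer": r.tracer,
        "batch": r.batch, "group": r.group, "sex": r.sex, "age": r.age,
        "genotype": r.genotype, "injected_dose": r.injected_dose,
        "body_weight": r.body_weight, "dose_over_weight": r.dose_over_weight,
        "session": r.session,
    } for r in records])
    return df.set_index("scan_id")


def write_matrix(matrix: np.ndarray, labels, path) -> None:
    """Write a labelled square matrix as CSV (labels in header and first
    column)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if len(labels) != matrix.shape[0]:
        raise ValueError("label count does not match matrix size")
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, float_format="%.17g")


def read_matrix(path, atlas: RoiAtlas | None = None):
    """Read a labelled square matrix; optionally check label order against
    an atlas. Returns ``(values, labels)``."""
    df = pd.read_csv(path, index_col=0)
    labels = tuple(df.columns)
    if tuple(df.index) != labels:
        raise ValueError("matrix row labels differ from column labels")
    if atlas is not None and labels != atlas.roi_names:
        raise ValueError("matrix labels do not match the atlas ROI order")
    return df.to_numpy(float), labels
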