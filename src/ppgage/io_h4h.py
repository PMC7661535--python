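"""Reading and writing of per-subject recordings and cohort feature tables.

Recording dialect: an optional block of ``# key: value`` comment lines
(sex, age, weight, height, smoking), then the header
``time,red,green,blue,accX,accY,accZ`` and one numeric row per sample.
Metadata may alternatively live in a sidecar ``<id>.meta.csv`` with
``key,value`` rows.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, EmptyInputError, FormatError

__all__ = [
    "RawRecording",
    "CovariateRecord",
    "COVARIATE_KEYS",
    "RECORDING_COLUMNS",
    "read_recording",
    "write_recording",
    "assemble_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_truth_table",
]

RECORDING_COLUMNS = ("time", "red", "green", "blue", "accX", "accY", "accZ")
COVARIATE_KEYS = ("sex", "age", "weight", "height", "smoking")


@dataclass
class CovariateRecord:
    """Per-subject metadata; ``None`` encodes a missing value."""

    sex: str | None = None  # "male" | "female"
    age: float | None = None  # years
    weight: float | None = None  # kg
    height: float | None = None  # cm
    smoking: str | None = None  # "yes" | "no"

    def __post_init__(self):
        if self.age is not None and not 18.0 <= self.age <= 120.0:
            raise FormatError(f"age {self.age} outside [18, 120]")
        if self.weight is not None and self.weight <= 0:
            raise FormatError("weight must be positive")
        if self.height is not None and self.height <= 0:
            raise FormatError("height must be positive")
        if self.sex not in (None, "male", "female"):
            raise FormatError(f"unrecognized sex value {self.sex!r}")
        if self.smoking not in (None, "yes", "no"):
            raise FormatError(f"unrecognized smoking value {self.smoking!r}")

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, k) is not None for k in COVARIATE_KEYS
        )


@dataclass
class RawRecording:
    """One subject's 7-column time series plus covariate metadata."""

    subject_id: str
    time: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    meta: CovariateRecord = field(default_factory=CovariateRecord)

    def __post_init__(self):
        vecs = [self.time, self.red, self.green, self.blue,
                self.acc_x, self.acc_y, self.acc_z]
        arrays = [np.asarray(v, dtype=float) for v in vecs]
        lengths = {a.size for a in arrays}
        if len(lengths) != 1:
            raise FormatError("recording columns have unequal lengths")
        if arrays[0].size < 2:
            raise EmptyInputError("recording needs at least 2 samples")
        (self.time, self.red, self.green, self.blue,
         self.acc_x, self.acc_y, self.acc_z) = arrays
        if np.any(np.diff(self.time) < 0):
            raise FormatError("time must be non-decreasing")

    def __len__(self) -> int:
        return self.time.size


def _parse_meta_value(key: str, raw: str):
    raw = raw.strip()
    if raw in ("", "missing", "NA", "nan"):
        return None
    if key in ("age", "weight", "height"):
        try:
            return float(raw)
        except ValueError as exc:
            raise FormatError(f"bad numeric value for {key!r}: {raw!r}") from exc
    return raw


def _read_meta_lines(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower()
                if key in COVARIATE_KEYS:
                    meta[key] = _parse_meta_value(key, value)
    sidecar = os.path.splitext(path)[0] + ".meta.csv"
    if os.path.exists(sidecar):
        side = pd.read_csv(sidecar, header=None, names=["key", "value"],
                           dtype=str, skipinitialspace=True)
        for _, row in side.iterrows():
            key = str(row["key"]).strip().lower()
            if key in COVARIATE_KEYS:
                meta[key] = _parse_meta_value(key, str(row["value"]))
    return meta


def read_recording(path: str) -> RawRecording:
    """Parse a recording CSV into a :class:`RawRecording`.

    Only time and the red channel are used downstream, but all seven
    columns are retained.
    """
    if os.path.getsize(path) == 0:
        raise EmptyInputError(f"{path} is empty")
    meta = _read_meta_lines(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} has no data rows") from exc
    df.columns = [c.strip() for c in df.columns]
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path} has a header but no samples")
    for col in RECORDING_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    subject_id = os.path.splitext(os.path.basename(path))[0]
    return RawRecording(
        subject_id=subject_id,
        time=df["time"].to_numpy(float),
        red=df["red"].to_numpy(float),
        green=df["green"].to_numpy(float),
        blue=df["blue"].to_numpy(float),
        acc_x=df["accX"].to_numpy(float),
        acc_y=df["accY"].to_numpy(float),
        acc_z=df["accZ"].to_numpy(float),
        meta=CovariateRecord(**meta),
    )


def write_recording(rec: RawRecording, path: str) -> None:
    """Write a recording in the same dialect :func:`read_recording` parses."""
    buf = io.StringIO()
    for key in COVARIATE_KEYS:
        value = getattr(rec.meta, key)
        if value is not None:
            buf.write(f"# {key}: {value}\n")
    buf.write(",".join(RECORDING_COLUMNS) + "\n")
    data = np.column_stack([rec.time, rec.red, rec.green, rec.blue,
                            rec.acc_x, rec.acc_y, rec.acc_z])
    np.savetxt(buf, data, delimiter=",", fmt="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _process_one(rec: RawRecording, q_threshold: float):
    """preprocess -> peaks -> quality -> features for one recording."""
    from .beats import detect_peaks, quality_score
    from .features import extract_features
    from .preprocess import preprocess_recording

    signal = preprocess_recording(rec.time, rec.red)
    peaks = detect_peaks(signal)
    quality = quality_score(signal, peaks, threshold=q_threshold)
    if not quality.passed:
        return None, quality, "quality"
    fv = extract_features(signal, peaks)
    return fv, quality, None


def assemble_cohort(paths, q_threshold: float = 0.01) -> tuple[pd.DataFrame, list]:
    """Run the full extraction per recording and assemble the cohort table.

    Subjects are kept only with complete metadata and quality ``q`` below
    the threshold; the exclusion log records ``(subject_id, reason)`` per
    dropped subject, with reasons in {"incomplete metadata", "quality",
    "features"}.
    """
    from .errors import FeatureMissingError, PPGAgeError
    from .features import FEATURE_NAMES

    if q_threshold <= 0:
        raise ValueError("q_threshold must be positive")
    rows, log = [], []
    for path in paths:
        rec = read_recording(path) if not isinstance(path, RawRecording) else path
        if not rec.meta.complete:
            log.append((rec.subject_id, "incomplete metadata"))
            continue
        try:
            fv, quality, reason = _process_one(rec, q_threshold)
        except FeatureMissingError:
            log.append((rec.subject_id, "features"))
            continue
        except PPGAgeError:
            log.append((rec.subject_id, "quality"))
            continue
        if reason is not None:
            log.append((rec.subject_id, reason))
            continue
        row = {"subject_id": rec.subject_id, **fv.features}
        row.update({
            "sex": rec.meta.sex, "weight": rec.meta.weight,
            "height": rec.meta.height, "smoking": rec.meta.smoking,
            "age": rec.meta.age,
        })
        from .cohort_ml import dichotomize_age

        label = dichotomize_age(rec.meta.age)
        row["label"] = math.nan if label is None else float(label)
        rows.append(row)
    if not rows:
        raise EmptyCohortError("no subject survived cohort assembly")
    columns = (["subject_id"] + list(FEATURE_NAMES)
               + ["sex", "weight", "height", "smoking", "age", "label"])
    cohort = pd.DataFrame(rows, columns=columns)
    cohort["label"] = cohort["label"].astype(float)
    return cohort, log


def write_feature_table(cohort: pd.DataFrame, path: str) -> None:
    """Write the cohort table (id + 38 features + 4 covariates + age + label)."""
    if len(cohort) == 0:
        raise EmptyInputError("refusing to write an empty cohort table")
    cohort.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise EmptyInputError(f"{path} holds no subjects")
    return df


def write_truth_table(truths, path: str) -> None:
    """Persist the scalar part of a synthetic cohort's ground truth."""
    rows = [{
        "subject_id": t.subject_id,
        "age": t.age,
        "sex": t.meta.sex,
        "weight": t.meta.weight,
        "height": t.meta.height,
        "smoking": t.meta.smoking,
        "stiffness": t.stiffness,
        "rr_randomness": t.rr_randomness,
        "n_beats": len(t.beat_times),
        "mean_rr_ms": float(np.mean(t.rr_ms)) if len(t.rr_ms) else math.nan,
        "seed": t.seed,
    } for t in truths]
    pd.DataFrame(rows).to_csv(path, index=False)
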