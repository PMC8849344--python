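"""Shared data model for multi-batch tissue-microarray (TMA) biomarker studies.

Two long-format tables carry everything the toolkit needs:

* :class:`BiomarkerTable` — one row per (tumor, core, marker) measurement,
  with the TMA slide identifier as the batch key.  Tumors contribute several
  0.6 mm cores, and all cores of a tumor normally sit on the same TMA; the
  rare cores deliberately placed on a second TMA (used to separate batch
  variance from intratumoral heterogeneity) carry an explicit
  ``cross_batch`` flag.
* :class:`CovariateTable` — one row per tumor with the clinical covariates
  (Gleason grade group, pathological stage, diagnosis year) and the
  time-to-event outcome (lethal disease indicator plus follow-up time).

Values are stored on whatever scale the caller declares (``raw``,
``log_e``, or ``zscore``); missing measurements are absent rows, never
sentinel values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

BIOMARKER_COLUMNS = ["tumor_id", "core_id", "batch_id", "marker_id", "value"]
COVARIATE_COLUMNS = [
    "tumor_id",
    "batch_id",
    "gleason_group",
    "stage_category",
    "diagnosis_year",
    "event",
    "follow_up_time",
]

#: Ordered Gleason grade-group labels (grade group 1 through 5).
GLEASON_LEVELS = ["5-6", "3+4", "4+3", "8", "9-10"]
#: Pathological stage categories.
STAGE_LEVELS = ["pT1/T2", "pT3/T3a", "pT3b/T4/N1", "missing/TURP"]

VALUE_SCALES = ("raw", "log_e", "zscore")


def gleason_score(series: pd.Series) -> pd.Series:
    """Map Gleason grade-group labels to the ordinal scores 1..5."""
    mapping = {lvl: i + 1 for i, lvl in enumerate(GLEASON_LEVELS)}
    out = series.map(mapping)
    if out.isna().any():
        bad = sorted(set(series[out.isna()].astype(str)))
        raise SchemaError(f"unknown Gleason grade group label(s): {bad}")
    return out.astype(int)


@dataclass
class BiomarkerTable:
    """Long-format per-core biomarker measurements.

    ``df`` must contain :data:`BIOMARKER_COLUMNS`; an optional boolean
    ``cross_batch`` column flags cores of tumors intentionally split across
    TMAs.  (tumor_id, core_id, marker_id) is the row key.
    """

    df: pd.DataFrame
    value_scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in BIOMARKER_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"biomarker table missing column(s): {missing}")
        if self.value_scale not in VALUE_SCALES:
            raise SchemaError(f"unknown value_scale {self.value_scale!r}")
        values = self.df["value"]
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise IntegrityError("non-finite biomarker values present")
        key = ["tumor_id", "core_id", "marker_id"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            offenders = self.df.loc[dup, key].drop_duplicates()
            raise IntegrityError(
                "duplicate (tumor, core, marker) keys: "
                + "; ".join(map(str, offenders.itertuples(index=False, name=None)))
            )
        # every non-flagged (tumor, core) pair lives on exactly one batch
        core_df = self.df
        if "cross_batch" in core_df.columns:
            core_df = core_df[~core_df["cross_batch"].astype(bool)]
        n_batches = core_df.groupby(["tumor_id", "core_id"])["batch_id"].nunique()
        if (n_batches > 1).any():
            bad = n_batches[n_batches > 1].index.tolist()
            raise IntegrityError(
                f"cores mapped to multiple batches without cross_batch flag: {bad}"
            )

    @property
    def markers(self) -> list:
        return sorted(self.df["marker_id"].unique().tolist())

    @property
    def batches(self) -> list:
        return sorted(self.df["batch_id"].unique().tolist())

    def subset_marker(self, marker_id) -> pd.DataFrame:
        """Rows for one marker, restricted to batches where it was measured."""
        sub = self.df[self.df["marker_id"] == marker_id]
        if sub.empty:
            raise SchemaError(f"marker {marker_id!r} not present")
        return sub.copy()

    def with_values(self, new_values: np.ndarray, value_scale: str | None = None) -> "BiomarkerTable":
        """Copy of the table with the value column replaced (keys untouched)."""
        df = self.df.copy()
        df["value"] = np.asarray(new_values, dtype=float)
        return BiomarkerTable(df, value_scale or self.value_scale)


@dataclass
class CovariateTable:
    """Tumor-level clinical covariates and the time-to-event outcome."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"covariate table missing column(s): {missing}")
        if self.df["tumor_id"].duplicated().any():
            dups = self.df.loc[self.df["tumor_id"].duplicated(), "tumor_id"].tolist()
            raise IntegrityError(f"duplicate tumor_id rows: {dups}")
        bad_g = set(self.df["gleason_group"].astype(str)) - set(GLEASON_LEVELS)
        if bad_g:
            raise SchemaError(f"unknown Gleason grade group label(s): {sorted(bad_g)}")
        bad_s = set(self.df["stage_category"].astype(str)) - set(STAGE_LEVELS)
        if bad_s:
            raise SchemaError(f"unknown stage label(s): {sorted(bad_s)}")
        has_event = self.df["event"].notna()
        t = self.df.loc[has_event, "follow_up_time"]
        if (t <= 0).any():
            raise IntegrityError("follow_up_time must be positive where event is defined")

    def check_consistent_batches(self, bm: BiomarkerTable) -> None:
        """Raise if a tumor's batch disagrees between the two tables."""
        core_df = bm.df
        if "cross_batch" in core_df.columns:
            core_df = core_df[~core_df["cross_batch"].astype(bool)]
        bm_batch = core_df.drop_duplicates("tumor_id").set_index("tumor_id")["batch_id"]
        cov_batch = self.df.set_index("tumor_id")["batch_id"]
        shared = bm_batch.index.intersection(cov_batch.index)
        mismatch = shared[(bm_batch.loc[shared] != cov_batch.loc[shared])]
        if len(mismatch):
            raise IntegrityError(f"batch_id mismatch for tumors: {mismatch.tolist()}")


@dataclass
class PreprocessSpec:
    """How raw biomarker values are prepared for analysis.

    Right-skewed staining scores are natural-log transformed; cores of a
    tumor are summarized as their mean; markers may be scaled to overall
    mean 0 / SD 1 (sample SD, ``ddof=1``) to make batch effects comparable
    across markers.  ``order`` controls whether aggregation happens before
    scaling (default) or after.
    """

    log_markers: frozenset = field(default_factory=frozenset)
    log_offset: float = 0.0
    scale_to_z: bool = False
    aggregate_cores: str = "mean"  # or "none"
    order: str = "aggregate_then_scale"  # or "scale_then_aggregate"


def _aggregate_cores(df: pd.DataFrame) -> pd.DataFrame:
    keep = ["tumor_id", "batch_id", "marker_id"]
    out = df.groupby(keep, as_index=False, sort=False)["value"].mean()
    out["core_id"] = "pooled"
    return out[BIOMARKER_COLUMNS]


def _zscale(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for marker, sub in df.groupby("marker_id"):
        mu = sub["value"].mean()
        sd = sub["value"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DomainError(f"marker {marker!r} has zero variance; cannot z-scale")
        df.loc[sub.index, "value"] = (sub["value"] - mu) / sd
    return df


def preprocess(bm: BiomarkerTable, spec: PreprocessSpec) -> BiomarkerTable:
    """Apply log transform, core aggregation, and z-scaling per ``spec``."""
    df = bm.df.copy()
    scale = bm.value_scale

    if spec.log_markers:
        mask = df["marker_id"].isin(spec.log_markers)
        shifted = df.loc[mask, "value"] + spec.log_offset
        if (shifted <= 0).any():
            bad = df.loc[mask & (df["value"] + spec.log_offset <= 0)]
            first = bad.iloc[0]
            raise DomainError(
                f"log transform of nonpositive value for marker "
                f"{first['marker_id']!r}, tumor {first['tumor_id']!r}"
            )
        df.loc[mask, "value"] = np.log(shifted)
        scale = "log_e"

    steps = []
    if spec.aggregate_cores == "mean":
        steps.append("aggregate")
    if spec.scale_to_z:
        steps.append("scale")
    if spec.order == "scale_then_aggregate":
        steps = steps[::-1]

    for step in steps:
        if step == "aggregate":
            df = _aggregate_cores(df)
        else:
            df = _zscale(df)
            scale = "zscore"

    return BiomarkerTable(df.reset_index(drop=True), scale)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Dialect: comma-separated, UTF-8, "." decimal, header
# required.  "NA" tokens in the value column are treated as missing
# measurements and dropped with a logged count; any other non-numeric value
# is a hard parse error.
# ---------------------------------------------------------------------------

NA_TOKENS = {"NA", "NaN", "nan", ""}


def read_biomarker_table(path, value_scale: str = "raw") -> BiomarkerTable:
    """Read a long-format biomarker CSV and validate its keys."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {missing}")
    is_na = df["value"].isin(NA_TOKENS)
    if is_na.any():
        logger.info("%s: dropped %d rows with NA biomarker values", path, int(is_na.sum()))
        df = df[~is_na]
    try:
        values = df["value"].to_numpy().astype(float)  # correctly-rounded strtod
    except ValueError:
        ok = df["value"].str.fullmatch(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")
        bad_rows = (df.index[~ok.fillna(False)] + 2).tolist()  # 1-based incl. header
        raise ParseError(f"{path}: non-numeric value in row(s) {bad_rows}") from None
    df = df.assign(value=values)
    if "cross_batch" in df.columns:
        df["cross_batch"] = df["cross_batch"].str.lower().isin({"true", "1", "yes"})
    return BiomarkerTable(df.reset_index(drop=True), value_scale)


def write_biomarker_table(bm: BiomarkerTable, path) -> None:
    # shortest digit string that round-trips a float64
    bm.df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_covariate_table(path) -> CovariateTable:
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {missing}")
    return CovariateTable(df)


def write_covariate_table(cov: CovariateTable, path) -> None:
    cov.df.to_csv(path, index=False)
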