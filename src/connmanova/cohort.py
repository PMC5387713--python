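"""Cohort and metric-panel data model with delimited-text readers/writers.

A cohort table holds one row per subject: acquisition site, sex and diagnosis
as +/-1 codes (+1 male / -1 female; +1 ASD / -1 TD), age in years, the five
DAS cognitive scores (V, NV, S, GCA, SNC) and total intracranial volume
(TICV, cm^3). A metric panel is a subjects x parcels value grid for one
neuroimaging metric, keyed to a :class:`~connmanova.atlas.ParcelAtlas`.

On disk everything is tab- or comma-delimited text with a header; the
delimiter is auto-detected and can be forced. Rows and columns may appear in
any order in a file: readers align panels to the cohort's subject order and
the atlas's parcel order. Missing values are a hard error everywhere - the
downstream model has no missingness mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .exceptions import (
    AlignmentError,
    IntegrityError,
    ParseError,
    SchemaError,
)

DAS_SCALES = ("v", "nv", "s", "gca", "snc")
DAS_COLUMNS = tuple(f"das_{s}" for s in DAS_SCALES)
COHORT_COLUMNS = ("subject_id", "site", "sex", "diagnosis", "age") + DAS_COLUMNS + ("ticv",)

METRICS = ("area", "thickness", "curvature", "volume", "CD")

_SEX_MAP = {"M": 1, "MALE": 1, "F": -1, "FEMALE": -1, "1": 1, "+1": 1, "-1": -1}
_DX_MAP = {"ASD": 1, "TD": -1, "1": 1, "+1": 1, "-1": -1}


def _coerce_code(series: pd.Series, mapping: dict, what: str) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        key = str(v).strip().upper()
        # tolerate numeric 1.0 / -1.0
        try:
            fv = float(key)
            key = str(int(fv)) if fv in (1.0, -1.0) else key
            if key == "1":
                key = "+1"
        except ValueError:
            pass
        if key not in mapping:
            raise ParseError(f"row {i}: cannot interpret {what} value {v!r}")
        out.append(mapping[key])
    return pd.Series(out, index=series.index, dtype=int)


@dataclass
class CohortTable:
    """Validated per-subject demographics table.

    ``frame`` holds the columns of :data:`COHORT_COLUMNS` with sex/diagnosis
    already coded as +/-1 integers. Validation runs on construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in COHORT_COLUMNS if c not in f.columns]
        if missing:
            raise SchemaError(f"cohort table missing column(s): {missing}")
        if len(f) == 0:
            raise SchemaError("cohort table has no rows")
        f = f.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True).copy()
        if f.isna().any().any():
            bad = f.columns[f.isna().any()].tolist()
            raise IntegrityError(f"missing values in cohort column(s): {bad}")
        if f["subject_id"].duplicated().any():
            dupes = f.loc[f["subject_id"].duplicated(), "subject_id"].tolist()
            raise IntegrityError(f"duplicate subject_id(s): {dupes}")
        for col, mapping in (("sex", _SEX_MAP), ("diagnosis", _DX_MAP)):
            if f[col].dtype == object:
                f[col] = _coerce_code(f[col], mapping, col)
            vals = set(f[col].astype(int))
            if not vals <= {-1, 1}:
                raise IntegrityError(f"{col} codes must be in {{-1, +1}}, got {sorted(vals)}")
            f[col] = f[col].astype(int)
        for col in ("age", "ticv") + DAS_COLUMNS:
            try:
                f[col] = pd.to_numeric(f[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-numeric value in column {col!r}: {exc}") from exc
        if (f["age"] <= 0).any():
            raise IntegrityError("age must be > 0 for all subjects")
        if (f["ticv"] <= 0).any():
            raise IntegrityError("ticv must be > 0 for all subjects")
        f["subject_id"] = f["subject_id"].astype(str)
        f["site"] = f["site"].astype(str)
        object.__setattr__(self, "frame", f)

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["subject_id"])

    @property
    def sex(self) -> np.ndarray:
        """+1 male / -1 female codes."""
        return self.frame["sex"].to_numpy(int)

    @property
    def diagnosis(self) -> np.ndarray:
        """+1 ASD / -1 TD codes."""
        return self.frame["diagnosis"].to_numpy(int)

    @property
    def interaction(self) -> np.ndarray:
        """Elementwise sex * diagnosis product code."""
        return self.sex * self.diagnosis

    @property
    def age(self) -> np.ndarray:
        return self.frame["age"].to_numpy(float)

    @property
    def ticv(self) -> np.ndarray:
        return self.frame["ticv"].to_numpy(float)

    def group_counts(self) -> dict[str, int]:
        dx, sex = self.diagnosis, self.sex
        return {
            "asd": int((dx == 1).sum()),
            "td": int((dx == -1).sum()),
            "asd_female": int(((dx == 1) & (sex == -1)).sum()),
            "td_female": int(((dx == -1) & (sex == -1)).sum()),
        }


@dataclass
class MetricPanel:
    """Subjects x parcels values for one metric, aligned to an atlas.

    ``values`` is a DataFrame indexed by subject_id whose columns are exactly
    the atlas labels, in atlas order. All values must be finite.
    """

    metric_name: str
    values: pd.DataFrame
    atlas: ParcelAtlas
    normalized: bool = False

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != self.atlas.labels:
            raise AlignmentError(
                f"panel {self.metric_name!r}: columns must equal atlas labels in atlas order"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError(f"panel {self.metric_name!r}: non-numeric values")

    def check_finite(self) -> None:
        """Raise :class:`ParseError` at the first non-finite cell, with coordinates."""
        finite = np.isfinite(self.values.to_numpy(float))
        if not finite.all():
            i, j = np.argwhere(~finite)[0]
            raise ParseError(
                f"panel {self.metric_name!r}: non-finite value at subject "
                f"{self.values.index[i]!r}, parcel {self.values.columns[j]!r}"
            )

    @property
    def data(self) -> np.ndarray:
        return self.values.to_numpy(float)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.atlas.p

    def with_values(self, arr: np.ndarray, normalized: bool | None = None) -> "MetricPanel":
        """Copy of this panel with replaced values (same subjects/parcels)."""
        values = pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)
        return replace(
            self,
            values=values,
            normalized=self.normalized if normalized is None else normalized,
        )


# -- readers / writers ---------------------------------------------------------


def _detect_sep(path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_cohort(path, dialect: str | None = None) -> CohortTable:
    """Read a cohort file; sex/diagnosis may be text labels or +/-1 codes."""
    sep = _detect_sep(path, dialect)
    try:
        df = pd.read_csv(
            path, sep=sep, dtype={"subject_id": str, "site": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cohort file: {path}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing column(s): {missing}")
    df["sex"] = _coerce_code(df["sex"], _SEX_MAP, "sex")
    df["diagnosis"] = _coerce_code(df["diagnosis"], _DX_MAP, "diagnosis")
    for col in ("age", "ticv") + DAS_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(f"row {row}: non-numeric {col} value {df[col].iloc[row]!r}")
        df[col] = parsed
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path, sep: str = "\t") -> None:
    f = cohort.frame.copy()
    f["sex"] = np.where(f["sex"] == 1, "M", "F")
    f["diagnosis"] = np.where(f["diagnosis"] == 1, "ASD", "TD")
    f.to_csv(path, sep=sep, index=False)


def read_metric_panel(
    path,
    atlas: ParcelAtlas,
    cohort: CohortTable,
    metric_name: str | None = None,
    dialect: str | None = None,
) -> MetricPanel:
    """Read a panel file and align it to the cohort's subjects and atlas order.

    The file's first column must be ``subject_id``; the remaining header
    fields are parcel labels. Row/column order in the file is irrelevant.
    """
    sep = _detect_sep(path, dialect)
    try:
        df = pd.read_csv(
            path, sep=sep, dtype={"subject_id": str}, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty panel file: {path}") from exc
    if "subject_id" not in df.columns:
        raise SchemaError("panel file must have a 'subject_id' column")
    df = df.set_index("subject_id")

    file_parcels = set(df.columns)
    atlas_parcels = set(atlas.labels)
    unknown = sorted(file_parcels - atlas_parcels)
    if unknown:
        raise AlignmentError(f"panel columns not in atlas: {unknown[:5]}")
    absent = sorted(atlas_parcels - file_parcels)
    if absent:
        raise AlignmentError(f"atlas parcel(s) missing from panel: {absent[:5]}")

    file_subjects = set(df.index)
    cohort_subjects = set(cohort.subject_ids)
    extra = sorted(file_subjects - cohort_subjects)
    if extra:
        raise AlignmentError(f"panel subject(s) not in cohort: {extra[:5]}")
    lacking = sorted(cohort_subjects - file_subjects)
    if lacking:
        raise AlignmentError(f"cohort subject(s) missing from panel: {lacking[:5]}")

    df = df.loc[list(cohort.subject_ids), list(atlas.labels)]
    if metric_name is None:
        metric_name = _metric_from_filename(str(path))
    panel = MetricPanel(metric_name=metric_name, values=df, atlas=atlas)
    panel.check_finite()
    return panel


def _metric_from_filename(path: str) -> str:
    import os

    stem = os.path.splitext(os.path.basename(path))[0]
    for m in METRICS:
        if m.lower() in stem.lower().split("_"):
            return m
    return stem


def write_metric_panel(panel: MetricPanel, path, sep: str = "\t") -> None:
    panel.values.to_csv(path, sep=sep, index=True, index_label="subject_id")


# -- dataset validation --------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only consistency check of a cohort plus its metric panels."""

    n_subjects: int
    n_parcels: int
    n_metrics: int
    group_counts: dict[str, int]
    value_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        status = "OK" if self.ok else f"{len(self.violations)} violation(s)"
        return (
            f"{self.n_metrics} metrics x {self.n_parcels} parcels x "
            f"{self.n_subjects} subjects [{status}]"
        )


def validate_dataset(cohort: CohortTable, panels: list[MetricPanel]) -> ValidationReport:
    """Check subject/parcel alignment, finiteness and group counts; never raises."""
    violations: list[str] = []
    ranges: dict[str, tuple[float, float]] = {}
    n_parcels = panels[0].atlas.p if panels else 0
    for panel in panels:
        name = panel.metric_name
        if tuple(panel.values.index) != cohort.subject_ids:
            violations.append(f"panel {name}: subject order does not match cohort")
        if panel.atlas.p != n_parcels:
            violations.append(f"panel {name}: atlas size {panel.atlas.p} != {n_parcels}")
        arr = panel.values.to_numpy(float)
        bad = ~np.isfinite(arr)
        for i, j in np.argwhere(bad):
            violations.append(
                f"panel {name}: non-finite value at subject "
                f"{panel.values.index[i]!r}, parcel {panel.values.columns[j]!r}"
            )
        good = arr[np.isfinite(arr)]
        if good.size:
            ranges[name] = (float(good.min()), float(good.max()))
    counts = cohort.group_counts()
    if counts["asd"] == 0 or counts["td"] == 0:
        violations.append("cohort must contain both diagnosis groups")
    return ValidationReport(
        n_subjects=cohort.n,
        n_parcels=n_parcels,
        n_metrics=len(panels),
        group_counts=counts,
        value_ranges=ranges,
        violations=violations,
    )
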