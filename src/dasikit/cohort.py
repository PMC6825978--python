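"""Patient-level data model, cohort table I/O and categorical grouping rules.

A cohort is one row per admitted cancer patient: demographics, index-admission
metadata, an admission laboratory panel, the 30-day unplanned readmission flag
(the primary exposure) and the survival outcome (days from index admission to
death, or censoring at last follow-up). Missingness is first-class: any field
other than the identifier, the readmission flag and the outcome may be absent,
and per-variable missing counts are part of the reporting surface.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import RowError, SchemaError, ValidationError

SEXES = frozenset({"female", "male"})
MARITAL_STATUSES = frozenset({"single", "divorced", "widowed", "married"})
LANGUAGES = frozenset({"english", "not_english"})
RACES = frozenset({"white", "not_white"})
FALL_RISKS = frozenset({"low", "moderate", "high", "universal"})

ADMISSION_REASONS = (
    "pain",
    "neurologic",
    "dyspnea",
    "chemo_side_effect",
    "abnormal_findings",
    "dehydration",
    "fever",
    "other",
)

#: Default missing-value sentinels accepted in cohort files (besides empty cells).
NA_SENTINELS = ("", "NA")

LAB_FIELDS = (
    "wbc",
    "hemoglobin",
    "platelets",
    "neutrophils",
    "lymphocytes",
    "sodium",
    "creatinine",
    "corrected_calcium",
    "albumin",
)


@dataclass(frozen=True)
class LabPanel:
    """Admission laboratory panel; every value strictly positive or missing.

    Units: wbc, platelets, neutrophils, lymphocytes in k/uL; hemoglobin and
    albumin in g/dL; sodium in mmol/L; creatinine and corrected_calcium in
    mg/dL.
    """

    wbc: Optional[float] = None
    hemoglobin: Optional[float] = None
    platelets: Optional[float] = None
    neutrophils: Optional[float] = None
    lymphocytes: Optional[float] = None
    sodium: Optional[float] = None
    creatinine: Optional[float] = None
    corrected_calcium: Optional[float] = None
    albumin: Optional[float] = None

    def __post_init__(self):
        for name in LAB_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"lab '{name}' must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One admitted patient; invariants are enforced at construction."""

    patient_id: str
    readmitted_30d: bool
    survival_time: float  # days from index admission to death or last follow-up
    event: bool  # True = death observed, False = censored
    sex: Optional[str] = None
    age: Optional[float] = None
    marital_status: Optional[str] = None
    language: Optional[str] = None
    race: Optional[str] = None
    fall_risk: Optional[str] = None
    ecog_ps: Optional[int] = None
    karnofsky: Optional[int] = None
    healthcare_visits_6mo: Optional[int] = None
    length_of_index_admission: Optional[float] = None
    chief_complaint: Optional[str] = None
    cancer_type_raw: Optional[str] = None
    metastasis: Optional[bool] = None
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    n_medications: Optional[int] = None
    labs: LabPanel = field(default_factory=LabPanel)

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.event is None or self.readmitted_30d is None:
            raise ValidationError("event and readmitted_30d are required")
        if not (math.isfinite(self.survival_time) and self.survival_time > 0):
            raise ValidationError(f"survival_time must be > 0, got {self.survival_time!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValidationError(f"age must be nonnegative, got {self.age!r}")
        if self.marital_status is not None and self.marital_status not in MARITAL_STATUSES:
            raise ValidationError(f"invalid marital_status {self.marital_status!r}")
        if self.language is not None and self.language not in LANGUAGES:
            raise ValidationError(f"invalid language {self.language!r}")
        if self.race is not None and self.race not in RACES:
            raise ValidationError(f"invalid race {self.race!r}")
        if self.fall_risk is not None and self.fall_risk not in FALL_RISKS:
            raise ValidationError(f"invalid fall_risk {self.fall_risk!r}")
        if self.ecog_ps is not None and self.ecog_ps not in (0, 1, 2, 3, 4):
            raise ValidationError(f"ecog_ps must be in 0..4, got {self.ecog_ps!r}")
        if self.karnofsky is not None and (
            self.karnofsky not in range(0, 101) or self.karnofsky % 10 != 0
        ):
            raise ValidationError(f"karnofsky must be a multiple of 10 in 0..100, got {self.karnofsky!r}")
        for name in ("healthcare_visits_6mo", "n_medications"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v!r}")
        if self.length_of_index_admission is not None and self.length_of_index_admission < 0:
            raise ValidationError("length_of_index_admission must be >= 0")
        for name in ("weight_kg", "height_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")


# Column dictionary of the on-disk cohort table, in file order. Booleans are
# encoded 0/1; empty cells and the "NA" sentinel are missing.
COLUMNS = (
    "patient_id",
    "readmitted_30d",
    "sex",
    "age",
    "marital_status",
    "language",
    "race",
    "fall_risk",
    "ecog_ps",
    "karnofsky",
    "healthcare_visits_6mo",
    "length_of_index_admission",
    "chief_complaint",
    "cancer_type_raw",
    "metastasis",
    "weight_kg",
    "height_cm",
    *LAB_FIELDS,
    "n_medications",
    "survival_time",
    "event",
)

_BOOL_COLS = ("readmitted_30d", "metastasis", "event")
_INT_COLS = ("ecog_ps", "karnofsky", "healthcare_visits_6mo", "n_medications")
_STR_COLS = (
    "patient_id",
    "sex",
    "marital_status",
    "language",
    "race",
    "fall_risk",
    "chief_complaint",
    "cancer_type_raw",
)


@dataclass
class Cohort:
    """Ordered collection of patient records with unique identifiers."""

    records: list[PatientRecord]
    provenance: str = "unspecified"

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to one row per patient using the documented column order."""
        rows = []
        for r in self.records:
            row = {}
            for col in COLUMNS:
                if col in LAB_FIELDS:
                    row[col] = getattr(r.labs, col)
                else:
                    row[col] = getattr(r, col)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "dataframe") -> "Cohort":
        missing = [c for c in COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in COLUMNS]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if extra:
            raise SchemaError(f"unknown columns: {extra}")
        records = []
        for i, (_, row) in enumerate(df.iterrows()):
            records.append(_record_from_row(row, i))
        return cls(records, provenance=provenance)


def _cell(row, col):
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return v


def _record_from_row(row, idx: int) -> PatientRecord:
    kwargs = {}
    for col in COLUMNS:
        v = _cell(row, col)
        if col in LAB_FIELDS:
            continue
        if v is None:
            kwargs[col] = None
            continue
        try:
            if col in _BOOL_COLS:
                iv = int(float(v))
                if iv not in (0, 1):
                    raise ValueError(f"boolean cell must be 0/1, got {v!r}")
                kwargs[col] = bool(iv)
            elif col in _INT_COLS:
                fv = float(v)
                if fv != int(fv):
                    raise ValueError(f"expected integer, got {v!r}")
                kwargs[col] = int(fv)
            elif col in _STR_COLS:
                kwargs[col] = str(v)
            else:
                kwargs[col] = float(v)
        except (TypeError, ValueError) as exc:
            raise RowError(idx, col, str(exc)) from exc
    labs = {}
    for col in LAB_FIELDS:
        v = _cell(row, col)
        if v is None:
            labs[col] = None
        else:
            try:
                labs[col] = float(v)
            except (TypeError, ValueError) as exc:
                raise RowError(idx, col, f"non-numeric cell {v!r}") from exc
    try:
        return PatientRecord(labs=LabPanel(**labs), **kwargs)
    except ValidationError as exc:
        raise RowError(idx, "<record>", str(exc)) from exc


def read_cohort(
    path: str | Path,
    delimiter: Optional[str] = None,
    na_sentinels: Sequence[str] = NA_SENTINELS,
) -> Cohort:
    """Read a cohort table from delimited text (comma default, tab accepted).

    Empty cells and any of ``na_sentinels`` map to missing. The header must
    match the documented column dictionary exactly; violations raise
    :class:`SchemaError`, bad cells raise :class:`RowError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=list(na_sentinels),
        encoding="utf-8",
    )
    return Cohort.from_dataframe(df, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write the cohort in the documented column dictionary; booleans as 0/1."""
    df = cohort.to_dataframe()
    for col in _BOOL_COLS:
        df[col] = df[col].map(lambda v: None if v is None else int(v))
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Categorical grouping rules
# ---------------------------------------------------------------------------

def _load_packaged_yaml(name: str):
    with resources.files("dasikit.data").joinpath(name).open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_DEFAULT_LEXICON: Optional[dict] = None


def default_complaint_lexicon() -> Mapping[str, list[str]]:
    """Keyword table mapping admission-reason category -> keyword list.

    Shipped as package data so the lexicon is configuration, not code; the
    match is case-insensitive substring, first category in table order wins.
    """
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = _load_packaged_yaml("complaint_lexicon.yaml")
    return _DEFAULT_LEXICON


def group_admission_reason(
    chief_complaint: str, lexicon: Optional[Mapping[str, list[str]]] = None
) -> str:
    """Map a free-text chief complaint to one of the 8 admission-reason groups.

    Unmatched text falls through to ``"other"``, so the mapping is total on
    non-empty strings.
    """
    if not chief_complaint or not chief_complaint.strip():
        raise ValidationError("chief complaint must be non-empty")
    if lexicon is None:
        lexicon = default_complaint_lexicon()
    text = chief_complaint.casefold()
    for category, keywords in lexicon.items():
        for kw in keywords:
            if kw.casefold() in text:
                return category
    return "other"


def collapse_rare_levels(labels: Sequence[str], min_count: int = 10) -> list[str]:
    """Relabel every level occurring fewer than ``min_count`` times as "other".

    The default threshold of 10 matches the convention of pooling any category
    with a count below 10; order is preserved and the operation is idempotent.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    labels = list(labels)
    if not labels:
        raise ValidationError("labels must be non-empty")
    counts = pd.Series(labels).value_counts()
    return [lab if counts[lab] >= min_count else "other" for lab in labels]


#: Standard Karnofsky -> ECOG band conversion (Oken scale); Karnofsky 0 (dead)
#: has no ECOG band and is rejected.
KARNOFSKY_ECOG_BANDS: Mapping[int, int] = {
    100: 0, 90: 0, 80: 1, 70: 1, 60: 2, 50: 2, 40: 3, 30: 3, 20: 4, 10: 4,
}


def karnofsky_to_ecog(karnofsky: int, bands: Mapping[int, int] = KARNOFSKY_ECOG_BANDS) -> int:
    """Convert a Karnofsky score (multiples of 10) to an ECOG grade 0-4."""
    if karnofsky not in range(0, 101) or karnofsky % 10 != 0:
        raise ValidationError(f"karnofsky must be a multiple of 10 in 0..100, got {karnofsky!r}")
    if karnofsky not in bands:
        raise ValidationError(f"karnofsky {karnofsky} has no ECOG band; flag for review")
    return bands[karnofsky]


def cohort_hash(cohort: Cohort) -> str:
    """Stable content hash of a cohort table, for provenance headers."""
    payload = cohort.to_dataframe().to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]
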