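"""Deficit-accumulation survival index (DASI) scoring engine.

Each of 23 prespecified factors — demographics, utilization, performance
status, anthropometry and admission labs — contributes a binary deficit when
its value crosses an adverse cutoff. The index is the deficit sum divided by
the number of factors (Rockwood-style accumulation), so it lives in [0, 1];
higher means frailer. Scores are banded into low / moderate / high risk at
0.30 and 0.48.

Two denominator policies are supported when factors are missing:

``fixed_23``
    divide the observed deficit sum by all 23 factors (the literal
    construction rule; missing factors can only lower the score);
``evaluable``
    divide by the number of evaluable factors (the usual frailty-index
    convention).

Either way a score is reported only when at least ``completeness_floor``
factors (default 18 of 23) are evaluable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .cohort import Cohort, PatientRecord
from .errors import SchemaError, ValidationError
from .indices import DerivedIndices, compute_indices

CATEGORY_LOW = "low"
CATEGORY_MODERATE = "moderate"
CATEGORY_HIGH = "high"

#: Risk-band boundaries: low <= 0.30 < moderate <= 0.48 < high (contiguous
#: partition of [0, 1], so every valid score is classifiable).
LOW_MODERATE_BOUNDARY = 0.30
MODERATE_HIGH_BOUNDARY = 0.48

DEFAULT_COMPLETENESS_FLOOR = 18

_RULE_OPS = {"is_true", "gt", "lt", "ge", "in_set", "outside"}


@dataclass(frozen=True)
class FactorDefinition:
    """One registered deficit factor: where its value lives and when it fires."""

    name: str
    kind: str  # record | lab | index
    source: str
    rule: Mapping
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("record", "lab", "index"):
            raise ValidationError(f"factor {self.name!r}: unknown kind {self.kind!r}")
        op = self.rule.get("op")
        if op not in _RULE_OPS:
            raise ValidationError(f"factor {self.name!r}: unknown rule op {op!r}")

    def evaluate(self, value) -> Optional[int]:
        """0/1 deficit for a value, or None when the value is missing."""
        if value is None:
            return None
        op = self.rule["op"]
        if op == "is_true":
            return int(bool(value))
        if op == "gt":
            return int(value > self.rule["threshold"])
        if op == "lt":
            return int(value < self.rule["threshold"])
        if op == "ge":
            return int(value >= self.rule["threshold"])
        if op == "in_set":
            return int(value in self.rule["values"])
        if op == "outside":
            return int(value < self.rule["lo"] or value > self.rule["hi"])
        raise AssertionError(op)


class FactorRegistry:
    """Ordered collection of factor definitions with a provenance checksum."""

    def __init__(self, factors: Sequence[FactorDefinition]):
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValidationError("factor names must be unique")
        if not factors:
            raise ValidationError("registry must contain at least one factor")
        self.factors = list(factors)

    def __len__(self):
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def checksum(self) -> str:
        payload = yaml.safe_dump(
            [
                {"name": f.name, "kind": f.kind, "source": f.source,
                 "rule": dict(f.rule), "units": f.units}
                for f in self.factors
            ],
            sort_keys=True,
        ).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FactorRegistry":
        with open(path, encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
        return cls._from_spec(spec)

    @classmethod
    def _from_spec(cls, spec) -> "FactorRegistry":
        factors = [
            FactorDefinition(
                name=item["name"], kind=item["kind"], source=item["source"],
                rule=item["rule"], units=item.get("units", ""),
            )
            for item in spec["factors"]
        ]
        return cls(factors)


_DEFAULT_REGISTRY: Optional[FactorRegistry] = None


def default_registry() -> FactorRegistry:
    """The frozen 23-factor registry shipped as package data."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        with resources.files("dasikit.data").joinpath("factors.yaml").open(
            encoding="utf-8"
        ) as fh:
            spec = yaml.safe_load(fh)
        reg = FactorRegistry._from_spec(spec)
        if len(reg) != 23:
            raise ValidationError(f"default registry must have 23 factors, found {len(reg)}")
        _DEFAULT_REGISTRY = reg
    return _DEFAULT_REGISTRY


def score_deficits(
    record: PatientRecord,
    indices: Optional[DerivedIndices] = None,
    registry: Optional[FactorRegistry] = None,
) -> dict[str, Optional[int]]:
    """Evaluate every registered factor for one patient.

    Returns factor name -> 0/1 deficit, or None when any input the factor
    needs is missing. ``indices`` is computed from the record's labs when not
    supplied.
    """
    if registry is None:
        registry = default_registry()
    if indices is None:
        indices = compute_indices(record.labs, record.weight_kg, record.height_cm)
    out: dict[str, Optional[int]] = {}
    for f in registry:
        if f.kind == "record":
            value = getattr(record, f.source)
        elif f.kind == "lab":
            value = getattr(record.labs, f.source)
        else:
            value = getattr(indices, f.source)
        out[f.name] = f.evaluate(value)
    return out


def dasi_score(
    deficits: Mapping[str, Optional[int]],
    denominator_policy: str = "fixed_23",
    completeness_floor: int = DEFAULT_COMPLETENESS_FLOOR,
    registry: Optional[FactorRegistry] = None,
) -> Optional[float]:
    """Deficit sum over the denominator chosen by policy; None if too sparse.

    The deficit map must cover exactly the registered factors.
    """
    if registry is None:
        registry = default_registry()
    if denominator_policy not in ("fixed_23", "evaluable"):
        raise ValidationError(f"unknown denominator_policy {denominator_policy!r}")
    expected = set(registry.names)
    got = set(deficits)
    if got != expected:
        unknown = sorted(got - expected)
        missing = sorted(expected - got)
        raise SchemaError(f"deficit map mismatch: unknown={unknown}, absent={missing}")
    values = [deficits[n] for n in registry.names]
    evaluable = [v for v in values if v is not None]
    n_eval = len(evaluable)
    if n_eval < completeness_floor:
        return None
    total = sum(evaluable)
    denom = len(registry) if denominator_policy == "fixed_23" else n_eval
    return total / denom


def categorize_dasi(score: float) -> str:
    """Band a DASI score: low <= 0.30 < moderate <= 0.48 < high."""
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must lie in [0, 1], got {score!r}")
    if score <= LOW_MODERATE_BOUNDARY:
        return CATEGORY_LOW
    if score <= MODERATE_HIGH_BOUNDARY:
        return CATEGORY_MODERATE
    return CATEGORY_HIGH


@dataclass(frozen=True)
class DasiResult:
    """Per-patient deficit vector, evaluable count, score and risk band."""

    deficits: Mapping[str, Optional[int]]
    n_evaluable: int
    score: Optional[float]
    category: Optional[str]


def score_patient(
    record: PatientRecord,
    registry: Optional[FactorRegistry] = None,
    denominator_policy: str = "fixed_23",
    completeness_floor: int = DEFAULT_COMPLETENESS_FLOOR,
) -> DasiResult:
    deficits = score_deficits(record, registry=registry)
    n_eval = sum(1 for v in deficits.values() if v is not None)
    score = dasi_score(
        deficits,
        denominator_policy=denominator_policy,
        completeness_floor=completeness_floor,
        registry=registry,
    )
    category = categorize_dasi(score) if score is not None else None
    return DasiResult(deficits=deficits, n_evaluable=n_eval, score=score, category=category)


def score_cohort(
    cohort: Cohort,
    registry: Optional[FactorRegistry] = None,
    denominator_policy: str = "fixed_23",
    completeness_floor: int = DEFAULT_COMPLETENESS_FLOOR,
) -> pd.DataFrame:
    """Per-patient scoring table: one deficit column per factor, plus
    n_evaluable, score and category; indexed by patient_id order."""
    if registry is None:
        registry = default_registry()
    rows = []
    for record in cohort:
        res = score_patient(
            record, registry=registry,
            denominator_policy=denominator_policy,
            completeness_floor=completeness_floor,
        )
        row = {"patient_id": record.patient_id}
        row.update({f"deficit_{k}": v for k, v in res.deficits.items()})
        row["n_evaluable"] = res.n_evaluable
        row["dasi_score"] = res.score
        row["dasi_category"] = res.category
        rows.append(row)
    return pd.DataFrame(rows)
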