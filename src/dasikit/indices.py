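"""Composite laboratory and anthropometric indices.

The inflammation ratios (NLR, PLR, SII) and the nutrition index (PNI) are the
derived inputs to both the deficit-accumulation score and the survival models:

    NLR = neutrophils / lymphocytes
    PLR = platelets / lymphocytes
    SII = PLR x neutrophils  (= platelets x neutrophils / lymphocytes)
    PNI = albumin x lymphocytes

Note the PNI here is a simple albumin-lymphocyte product, not the conventional
Onodera form (10*albumin + 5*lymphocytes); set ``pni_convention="onodera"`` for
the latter. Any index with a missing input is itself missing — never NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .cohort import LabPanel
from .errors import ComputationError, ValidationError


@dataclass(frozen=True)
class DerivedIndices:
    nlr: Optional[float] = None
    plr: Optional[float] = None
    sii: Optional[float] = None
    pni: Optional[float] = None
    bmi: Optional[float] = None  # kg/m^2
    corrected_calcium: Optional[float] = None  # mg/dL, passed through

    def __post_init__(self):
        for name in ("nlr", "plr", "sii", "pni", "bmi", "corrected_calcium"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"index '{name}' must be finite, got {v!r}")


def compute_indices(
    labs: LabPanel,
    weight_kg: Optional[float] = None,
    height_cm: Optional[float] = None,
    pni_convention: str = "product",
) -> DerivedIndices:
    """Compute NLR/PLR/SII/PNI/BMI from an admission lab panel.

    Missing inputs propagate to missing outputs; a zero or negative lymphocyte
    count is a :class:`ComputationError` (division-by-zero guard) rather than
    a silent NaN. ``pni_convention`` is ``"product"`` (albumin x lymphocytes)
    or ``"onodera"`` (10*albumin + 5*lymphocytes).
    """
    if pni_convention not in ("product", "onodera"):
        raise ValidationError(f"unknown pni_convention {pni_convention!r}")
    ly = labs.lymphocytes
    if ly is not None and ly <= 0:
        raise ComputationError(f"lymphocyte count must be > 0 to form ratios, got {ly}")

    nlr = plr = sii = pni = bmi = None
    if labs.neutrophils is not None and ly is not None:
        nlr = labs.neutrophils / ly
    if labs.platelets is not None and ly is not None:
        plr = labs.platelets / ly
    # full-precision SII: algebraically platelets * neutrophils / lymphocytes
    if plr is not None and labs.neutrophils is not None:
        sii = plr * labs.neutrophils
    if labs.albumin is not None and ly is not None:
        if pni_convention == "product":
            pni = labs.albumin * ly
        else:
            pni = 10.0 * labs.albumin + 5.0 * ly
    if weight_kg is not None and height_cm is not None:
        if weight_kg <= 0 or height_cm <= 0:
            raise ComputationError("weight and height must be positive for BMI")
        bmi = weight_kg / (height_cm / 100.0) ** 2
    return DerivedIndices(
        nlr=nlr, plr=plr, sii=sii, pni=pni, bmi=bmi,
        corrected_calcium=labs.corrected_calcium,
    )


def albumin_corrected_calcium(total_calcium: float, albumin: float) -> float:
    """Albumin-corrected calcium: measured + 0.8 * (4.0 - albumin), mg/dL.

    Helper for cohorts supplying only total calcium; the cohort model itself
    expects corrected calcium as a collected field.
    """
    if total_calcium <= 0 or albumin <= 0:
        raise ComputationError("total calcium and albumin must be positive")
    return total_calcium + 0.8 * (4.0 - albumin)
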