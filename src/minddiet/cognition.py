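"""MCI classification and derived covariate categories.

Classification follows Petersen-style operational criteria: subjective
memory complaint, objective memory impairment (RAVLT at least 1.5 SD below
a reference mean), intact instrumental activities of daily living,
preserved global function (MMSE cutoff), and no dementia diagnosis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional


class MciStatus(enum.Enum):
    MCI = "MCI"
    NON_MCI = "non-MCI"
    EXCLUDED_DEMENTIA = "excluded-dementia"


class BmiCategory(enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


@dataclass(frozen=True)
class NeuropsychProfile:
    """Neuropsychological battery scores."""

    mmse: float
    digit_span: float
    ravlt: float
    digit_symbol: float
    vr1: float
    vr2: float

    def __post_init__(self) -> None:
        for name in ("mmse", "digit_span", "ravlt", "digit_symbol", "vr1", "vr2"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"required neuropsych field missing: {name}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must lie in [0, 30], got {self.mmse}")


@dataclass(frozen=True)
class FunctionalProfile:
    """Functional status, mood, and clinical flags."""

    iadl: float
    gds15: int
    subjective_memory_complaint: bool
    dementia_diagnosis: bool = False

    def __post_init__(self) -> None:
        for name in ("iadl", "gds15", "subjective_memory_complaint", "dementia_diagnosis"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"required functional field missing: {name}")
        if not 0 <= self.gds15 <= 15:
            raise ValueError(f"gds15 must lie in [0, 15], got {self.gds15}")


@dataclass(frozen=True)
class MciCriteriaConfig:
    """Tunable thresholds for the classification rule.

    ravlt_z_threshold: z at or below which memory is impaired (default -1.5).
    iadl_intact_cutoff: minimum IADL counted as "no limitations".
    global_function_mmse_cutoff: minimum MMSE counted as preserved global
    function.
    """

    ravlt_z_threshold: float = -1.5
    iadl_intact_cutoff: float = 14.0
    global_function_mmse_cutoff: float = 19.0

    def __post_init__(self) -> None:
        if not self.ravlt_z_threshold < 0:
            raise ValueError("ravlt_z_threshold must be negative")


def ravlt_zscore(score: float, ref_mean: float, ref_sd: float) -> float:
    """Standardise a memory-test score against a reference population."""
    if ref_sd <= 0:
        raise ValueError(f"reference sd must be positive, got {ref_sd}")
    return (score - ref_mean) / ref_sd


def classify_mci(
    neuro: NeuropsychProfile,
    func: FunctionalProfile,
    cfg: Optional[MciCriteriaConfig] = None,
    reference: tuple[float, float] = (0.0, 1.0),
) -> MciStatus:
    """Apply the five-criterion rule; dementia excludes outright.

    ``reference`` is the (mean, sd) used to standardise the RAVLT score.
    """
    cfg = cfg or MciCriteriaConfig()
    if func.dementia_diagnosis:
        return MciStatus.EXCLUDED_DEMENTIA
    z = ravlt_zscore(neuro.ravlt, *reference)
    memory_impaired = z <= cfg.ravlt_z_threshold
    iadl_intact = func.iadl >= cfg.iadl_intact_cutoff
    global_preserved = neuro.mmse >= cfg.global_function_mmse_cutoff
    if memory_impaired and iadl_intact and global_preserved and func.subjective_memory_complaint:
        return MciStatus.MCI
    return MciStatus.NON_MCI


def bmi_category(bmi: float) -> BmiCategory:
    """WHO-style categories with half-open boundaries at 18.5 / 25 / 30."""
    if not (isinstance(bmi, (int, float)) and math.isfinite(bmi) and bmi > 0):
        raise ValueError(f"bmi must be a positive number, got {bmi!r}")
    if bmi < 18.5:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25.0:
        return BmiCategory.NORMAL
    if bmi < 30.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE
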