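"""Pathogen-growth (CFU) and qPCR relative-expression computations.

Small and exact.  CFU per leaf area back-calculates plate counts through
dilution, plated/extract volumes and the sampled disk area (default disk
diameter 6.25 mm from a #2 cork borer).  Relative expression uses the
delta-delta-CT construction with 18S as reference.  Group comparisons use
Welch's two-sample t-test — the source never names its test; this is a
documented implementation choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError

__all__ = [
    "GrowthObservation",
    "QpcrObservation",
    "cfu_per_cm2",
    "disk_area_cm2",
    "delta_ct",
    "relative_expression",
    "log_cfu",
    "compare_groups",
]

DEFAULT_DISK_DIAMETER_MM = 6.25


@dataclass(frozen=True)
class GrowthObservation:
    colony_count: float
    dilution_factor: float
    plated_volume_ul: float
    extract_volume_ul: float
    n_disks: int = 1
    disk_diameter_mm: float = DEFAULT_DISK_DIAMETER_MM
    insect_pretreatment: bool | None = None
    strain: str | None = None
    day: int | None = None

    def __post_init__(self):
        if self.colony_count < 0:
            raise ParameterError("colony_count must be >= 0")
        if self.dilution_factor <= 0:
            raise ParameterError("dilution_factor must be > 0")
        if self.plated_volume_ul <= 0 or self.extract_volume_ul <= 0:
            raise ParameterError("volumes must be > 0")
        if self.n_disks <= 0 or self.disk_diameter_mm <= 0:
            raise ParameterError("n_disks and disk_diameter_mm must be > 0")


@dataclass(frozen=True)
class QpcrObservation:
    sample_id: str
    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValidationError(f"non-finite CT values for {self.sample_id}")


def disk_area_cm2(diameter_mm: float, n_disks: int = 1) -> float:
    """Leaf area sampled by ``n_disks`` disks of the given diameter (mm)."""
    radius_cm = diameter_mm / 20.0
    return n_disks * math.pi * radius_cm**2


def cfu_per_cm2(obs: GrowthObservation) -> float:
    """Colony-forming units per cm^2 of leaf.

    ``count * dilution * (extract/plated) / sampled_area`` — linear in both
    colony count and dilution factor.
    """
    area = disk_area_cm2(obs.disk_diameter_mm, obs.n_disks)
    return (obs.colony_count * obs.dilution_factor
            * (obs.extract_volume_ul / obs.plated_volume_ul) / area)


def log_cfu(cfu: float) -> float:
    """log10(CFU + 1); the +1 keeps day-zero style zeros finite."""
    if cfu < 0:
        raise ParameterError("CFU must be >= 0")
    return math.log10(cfu + 1.0)


def delta_ct(obs: QpcrObservation) -> float:
    """CT(target) - CT(reference)."""
    return obs.ct_target - obs.ct_reference


def relative_expression(treated: QpcrObservation, control: QpcrObservation) -> float:
    """Fold change 2**(-ddCT) of treated vs control."""
    if treated is None or control is None:
        raise ValidationError("both treated and control observations are required")
    ddct = delta_ct(treated) - delta_ct(control)
    return 2.0 ** (-ddct)


def compare_groups(values_a, values_b, alpha: float = 0.05):
    """Welch two-sample comparison; returns (statistic, p, significant)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.inf, 0.0, True
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p), bool(p < alpha)
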