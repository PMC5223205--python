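"""Driver inference: concordance of environmental and biological shifts.

A regime shift in an assemblage series is labelled extrinsically driven when
its response-function type matches the environmental series' type and the
two STARS shift moments coincide (within a small tolerance of cycles);
otherwise the shift is attributed to an internal or unmeasured driver —
the dichotomy offers no finer resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .regime import ShiftResult
from .response import ModelComparison

__all__ = ["DriverReport", "compare_drivers"]

EXTRINSIC = "extrinsic"
INTERNAL = "internal or unmeasured driver"


def _shift_years(result: ShiftResult) -> list[float]:
    out = []
    for lab in result.shifts:
        if isinstance(lab, str):
            out.append(float(lab.split("-")[0].split("–")[0]))
        else:
            out.append(float(lab))
    return out


@dataclass
class DriverReport:
    """Per-pair concordance of response family and shift timing."""

    env_family: str
    bio_family: str
    env_shifts: list
    bio_shifts: list
    family_match: bool
    shift_match: bool
    concordant: bool
    driver: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "env_family": self.env_family,
            "bio_family": self.bio_family,
            "env_shifts": ";".join(str(s) for s in self.env_shifts),
            "bio_shifts": ";".join(str(s) for s in self.bio_shifts),
            "family_match": self.family_match,
            "shift_match": self.shift_match,
            "concordant": self.concordant,
            "driver": self.driver,
        }])


def compare_drivers(env_models: ModelComparison, env_shifts: ShiftResult,
                    bio_models: ModelComparison, bio_shifts: ShiftResult,
                    tolerance: float = 1.0) -> DriverReport:
    """Label a biological shift extrinsic or internal/unmeasured.

    Concordance requires the same best-fit family on both sides and at least
    one pair of STARS shift years within ``tolerance`` cycles of each other.
    """
    if not env_models.fits or not bio_models.fits:
        raise ValueError("both model comparisons must contain a best model")
    env_fam = env_models.best_family
    bio_fam = bio_models.best_family
    family_match = env_fam == bio_fam

    env_years = _shift_years(env_shifts)
    bio_years = _shift_years(bio_shifts)
    shift_match = any(
        abs(e - b) <= tolerance for e in env_years for b in bio_years
    )
    concordant = family_match and shift_match
    return DriverReport(
        env_family=env_fam,
        bio_family=bio_fam,
        env_shifts=env_shifts.shifts,
        bio_shifts=bio_shifts.shifts,
        family_match=family_match,
        shift_match=shift_match,
        concordant=concordant,
        driver=EXTRINSIC if concordant else INTERNAL,
    )
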