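"""Birthweight standardisation and its relationship to age at diagnosis.

Birthweight is a proxy for insulin-mediated fetal growth: a fetus already
losing beta cells secretes less insulin and grows less.  Raw birthweights are
converted to z-scores against a sex- and gestational-age-specific growth
reference (mean/SD per completed week, linearly interpolated between weeks),
then regressed on age at diabetes diagnosis — a negative intercept with a
positive slope indicates that the earliest-diagnosed infants were the
smallest at birth, i.e. that autoimmune beta-cell loss had begun in utero.

The growth reference is user-supplied data.  The package ships a synthetic
reference for examples and tests only; real analyses must load the reference
(e.g. WHO tables) appropriate to their population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "BirthRecord",
    "GrowthReference",
    "RegressionFit",
    "birthweight_z",
    "z_to_birthweight",
    "regress_z_on_age",
    "synthetic_growth_reference_path",
]

_SEXES = {"female", "male"}


@dataclass(frozen=True)
class BirthRecord:
    individual_id: str
    birthweight: float  # grams
    gestational_age: float  # completed weeks, fractional allowed
    sex: str  # 'female' | 'male'
    age_at_diagnosis: float  # weeks

    def __post_init__(self) -> None:
        if self.birthweight <= 0:
            raise ValueError(f"{self.individual_id}: birthweight must be positive")
        if self.sex not in _SEXES:
            raise ValueError(f"{self.individual_id}: sex must be 'female' or 'male'")


class GrowthReference:
    """Sex x gestational-week table of birthweight mean and SD (grams).

    Mean and SD are linearly interpolated between tabulated weeks; there is
    no extrapolation — a gestational age outside the tabulated range raises.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "gestational_week", "mean_g", "sd_g"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"growth reference missing column(s): {', '.join(sorted(missing))}")
        if (table["sd_g"] <= 0).any():
            raise ValueError("growth reference SD must be positive everywhere")
        self._by_sex: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, sub in table.groupby("sex"):
            if sex not in _SEXES:
                raise ValueError(f"unknown sex {sex!r} in growth reference")
            sub = sub.sort_values("gestational_week")
            weeks = sub["gestational_week"].to_numpy(dtype=float)
            means = sub["mean_g"].to_numpy(dtype=float)
            sds = sub["sd_g"].to_numpy(dtype=float)
            if np.any(np.diff(means) <= 0):
                warnings.warn(
                    f"growth reference mean not strictly increasing for sex={sex}",
                    stacklevel=2,
                )
            self._by_sex[str(sex)] = (weeks, means, sds)
        if set(self._by_sex) != _SEXES:
            raise ValueError("growth reference must cover both sexes")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def supported_range(self, sex: str) -> tuple[float, float]:
        weeks = self._by_sex[sex][0]
        return float(weeks[0]), float(weeks[-1])

    def mean_sd(self, sex: str, gestational_week: float) -> tuple[float, float]:
        if sex not in self._by_sex:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {sex!r}")
        weeks, means, sds = self._by_sex[sex]
        lo, hi = weeks[0], weeks[-1]
        if not (lo <= gestational_week <= hi):
            raise ValueError(
                f"gestational age {gestational_week} outside supported range [{lo:g}, {hi:g}]"
            )
        mean = float(np.interp(gestational_week, weeks, means))
        sd = float(np.interp(gestational_week, weeks, sds))
        return mean, sd


def birthweight_z(record: BirthRecord, ref: GrowthReference) -> float:
    """Birthweight z-score: (observed - reference mean) / reference SD."""
    mean, sd = ref.mean_sd(record.sex, record.gestational_age)
    return (record.birthweight - mean) / sd


def z_to_birthweight(
    z: float, sex: str, gestational_week: float, ref: GrowthReference
) -> float:
    """Invert the z-score: grams corresponding to z at (sex, week)."""
    mean, sd = ref.mean_sd(sex, gestational_week)
    return mean + z * sd


@dataclass(frozen=True)
class RegressionFit:
    slope: float  # z-score units per week of diagnosis age
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope, n-2 df
    n: int


def regress_z_on_age(ages_weeks, z_scores) -> RegressionFit:
    """Ordinary least-squares regression of birthweight z on diagnosis age.

    Requires at least three points and non-constant ages.  r-squared is
    1 - SSE/SST and the p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(ages_weeks, dtype=float)
    y = np.asarray(z_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and z-scores must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a regression fit, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: all ages equal")
    if np.all(y == y[0]):
        # zero total variance: the flat line fits perfectly and explains none
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                             p_value=1.0, n=int(x.size))
    fit = linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def synthetic_growth_reference_path() -> Path:
    """Path to the packaged synthetic growth reference (tests/examples only)."""
    return Path(__file__).parent / "data" / "growth_reference_synthetic.csv"
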