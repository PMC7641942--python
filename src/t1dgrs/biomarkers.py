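"""Islet-autoantibody positivity calls and C-peptide summaries.

Autoantibody titres (GADA, IA2A, ZnT8A, IAA) are called positive against
analyte-specific cut-offs defined as the 99th percentile of a healthy control
population, so roughly 1% of controls are expected to exceed each cut-off by
construction.  The three islet-antigen antibodies form the "any-positive"
panel; IAA is summarised separately and never enters the panel, because in
insulin-treated infants antibodies to exogenous insulin cannot be told apart
from true autoantibodies — IAA positivity is instead stratified by how long
the child had been on insulin.

C-peptide, the marker of residual beta-cell function, is reported by the
assay down to a limit of detection of 3 pmol/l; values below it are coded as
2.9 pmol/l so that censored observations sort below every detectable value
in rank-based statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import median_iqr

log = logging.getLogger(__name__)

__all__ = [
    "PANEL_ANALYTES",
    "CPEPTIDE_LOD",
    "CPEPTIDE_CODED_VALUE",
    "PanelSummary",
    "call_positive",
    "summarize_panel",
    "iaa_duration_summary",
    "code_cpeptide",
    "parse_cpeptide",
    "cpeptide_group_summary",
]

#: analytes that count towards "positive for at least one islet autoantibody"
PANEL_ANALYTES = ("GADA", "IA2A", "ZnT8A")

#: assay limit of detection for C-peptide, pmol/l
CPEPTIDE_LOD = 3.0
#: value substituted for below-LOD measurements in statistical analyses
CPEPTIDE_CODED_VALUE = 2.9

#: default insulin-treatment duration boundary (weeks) for IAA stratification,
#: i.e. "three months or less" of exposure to exogenous insulin
IAA_DURATION_BOUNDARY_WEEKS = 13.0

#: default diabetes-duration boundary (months) for C-peptide stratification
CPEPTIDE_DURATION_BOUNDARY_MONTHS = 12.0


def call_positive(titre: float, cutoff: float) -> bool:
    """True iff the titre strictly exceeds the analyte's cut-off.

    A titre exactly at the cut-off is negative: the cut-off is the control
    99th percentile, and strict comparison keeps the control false-positive
    rate at or below 1%.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if titre < 0:
        raise ValueError(f"titre must be non-negative, got {titre}")
    return titre > cutoff


@dataclass(frozen=True)
class PanelSummary:
    """Panel positivity counts for one group (GADA/IA2A/ZnT8A only)."""

    group: str
    n_measured: int
    n_any_positive: int
    n_two_positive: int
    n_three_positive: int
    per_analyte: dict[str, tuple[int, int]] = field(default_factory=dict)  # analyte -> (pos, measured)

    def __post_init__(self) -> None:
        if not (
            self.n_three_positive <= self.n_two_positive <= self.n_any_positive <= self.n_measured
        ):
            raise ValueError("panel counts must be nested: 3+ <= 2+ <= any <= measured")


def summarize_panel(
    calls: pd.DataFrame,
    analytes: tuple[str, ...] = PANEL_ANALYTES,
    group_col: str = "group",
) -> dict[str, PanelSummary]:
    """Summarise panel positivity per group from long-format calls.

    ``calls`` needs columns individual_id, ``group_col``, analyte, positive
    (boolean).  Rows for analytes outside ``analytes`` are ignored.  An
    individual measured for only a subset of the panel still counts in the
    any-positive denominator (observed-analyte denominator) and in the
    per-analyte denominators of the analytes actually measured.
    """
    required = {"individual_id", group_col, "analyte", "positive"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls missing column(s): {', '.join(sorted(missing))}")
    panel = calls[calls["analyte"].isin(analytes)]
    dup = panel.duplicated(subset=["individual_id", "analyte"])
    if dup.any():
        bad = panel.loc[dup, ["individual_id", "analyte"]].iloc[0]
        raise ValueError(
            f"duplicate call for individual {bad['individual_id']!r} analyte {bad['analyte']!r}"
        )
    out: dict[str, PanelSummary] = {}
    for group, sub in panel.groupby(group_col, sort=True):
        per_ind = sub.groupby("individual_id")["positive"].agg(["sum", "count"])
        n_measured = len(per_ind)
        n_any = int((per_ind["sum"] >= 1).sum())
        n_two = int((per_ind["sum"] >= 2).sum())
        n_three = int((per_ind["sum"] == 3).sum())
        per_analyte = {}
        for analyte in analytes:
            a = sub[sub["analyte"] == analyte]
            per_analyte[analyte] = (int(a["positive"].sum()), len(a))
        n_partial = int((per_ind["count"] < len(analytes)).sum())
        if n_partial:
            log.info(
                "group %s: %d/%d individuals measured for only a subset of the panel",
                group, n_partial, n_measured,
            )
        out[str(group)] = PanelSummary(
            group=str(group),
            n_measured=n_measured,
            n_any_positive=n_any,
            n_two_positive=n_two,
            n_three_positive=n_three,
            per_analyte=per_analyte,
        )
    return out


def iaa_duration_summary(
    calls: pd.DataFrame,
    boundary_weeks: float = IAA_DURATION_BOUNDARY_WEEKS,
    group_col: str = "group",
) -> pd.DataFrame:
    """IAA positivity per group, stratified by insulin-treatment duration.

    ``calls`` needs columns individual_id, ``group_col``, positive,
    insulin_duration_weeks.  The short stratum is inclusive on the left
    (duration <= boundary).  Individuals with missing duration are excluded
    with a logged warning.  Returns a tidy frame with columns group, stratum,
    n_positive, n, proportion.
    """
    required = {"individual_id", group_col, "positive", "insulin_duration_weeks"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls missing column(s): {', '.join(sorted(missing))}")
    has_dur = calls["insulin_duration_weeks"].notna()
    n_dropped = int((~has_dur).sum())
    if n_dropped:
        log.warning("excluding %d IAA call(s) with missing insulin duration", n_dropped)
    df = calls[has_dur].copy()
    short = f"<={boundary_weeks:g}w"
    long_ = f">{boundary_weeks:g}w"
    df["stratum"] = np.where(
        df["insulin_duration_weeks"] <= boundary_weeks, short, long_
    )
    rows = []
    for (group, stratum), sub in df.groupby([group_col, "stratum"], sort=True):
        k, n = int(sub["positive"].sum()), len(sub)
        rows.append(
            {"group": group, "stratum": stratum, "n_positive": k, "n": n, "proportion": k / n}
        )
    return pd.DataFrame(rows, columns=["group", "stratum", "n_positive", "n", "proportion"])


def code_cpeptide(raw: float | str, lod: float = CPEPTIDE_LOD) -> float:
    """Apply the limit-of-detection coding to a single C-peptide value.

    A numeric value below the LOD, or an explicit below-LOD marker such as
    the string ``"<3"``, is coded as 2.9 pmol/l; values at or above the LOD
    pass through unchanged.  Idempotent: coded values are below the LOD and
    re-code to themselves.
    """
    if isinstance(raw, str):
        token = raw.strip()
        if token.startswith("<"):
            return CPEPTIDE_CODED_VALUE
        raw = float(token)
    if raw < 0:
        raise ValueError(f"C-peptide cannot be negative, got {raw}")
    return CPEPTIDE_CODED_VALUE if raw < lod else float(raw)


def parse_cpeptide(values, lod: float = CPEPTIDE_LOD) -> np.ndarray:
    """Vectorised :func:`code_cpeptide` over a column of numbers/tokens."""
    return np.array([code_cpeptide(v, lod) for v in values], dtype=float)


def cpeptide_group_summary(
    measurements: pd.DataFrame,
    boundary_months: float = CPEPTIDE_DURATION_BOUNDARY_MONTHS,
    group_col: str = "group",
) -> pd.DataFrame:
    """Median/IQR and undetectable fraction per group x duration stratum.

    ``measurements`` needs columns ``group_col``, coded_value (already
    LOD-coded) and diabetes_duration_months.  The short stratum is inclusive
    on the left (duration <= boundary).  Undetectable means coded below the
    LOD.  Empty strata appear with n = 0 and NaN summaries.
    """
    required = {group_col, "coded_value", "diabetes_duration_months"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing column(s): {', '.join(sorted(missing))}")
    if (measurements["coded_value"] < CPEPTIDE_CODED_VALUE - 1e-12).any():
        raise ValueError("coded_value below 2.9 found: apply code_cpeptide first")
    df = measurements.copy()
    short = f"<={boundary_months:g}mo"
    long_ = f">{boundary_months:g}mo"
    df["stratum"] = np.where(
        df["diabetes_duration_months"] <= boundary_months, short, long_
    )
    rows = []
    groups = sorted(df[group_col].unique())
    for group in groups:
        for stratum in (short, long_):
            sub = df[(df[group_col] == group) & (df["stratum"] == stratum)]
            if len(sub) == 0:
                rows.append(
                    {"group": group, "stratum": stratum, "n": 0, "median": np.nan,
                     "q25": np.nan, "q75": np.nan, "undetectable_fraction": np.nan}
                )
                continue
            med, q25, q75 = median_iqr(sub["coded_value"].to_numpy())
            undet = float((sub["coded_value"] < CPEPTIDE_LOD).mean())
            rows.append(
                {"group": group, "stratum": stratum, "n": len(sub), "median": med,
                 "q25": q25, "q75": q75, "undetectable_fraction": undet}
            )
    return pd.DataFrame(rows)
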