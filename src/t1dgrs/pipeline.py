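"""End-to-end cohort analysis: score, classify, estimate excess, summarise.

Stages run in a fixed order — score genotypes, calibrate/apply the high-risk
threshold, estimate the excess of high-score individuals over the null
expectation, then summarise autoantibodies, C-peptide and birthweight per
group — and produce a machine-readable JSON report plus CSV tables and
figures.  Every proportion in the report carries its numerator and
denominator, and every p-value carries the name of the test that produced it.

Input phenotype tables may label individuals ``monogenic_NDM``, ``unknown``
or ``T1D_6_24m``; the ``unknown`` group is split into ``unknown_low_GRS`` and
``unknown_high_GRS`` by the score threshold — the split is always derived,
never supplied.  Any other group label is rejected rather than pooled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import calibration as cal
from . import clinical as cli_mod
from . import stats as st
from .grs import (
    DosageMatrix,
    WeightTable,
    classify_high_low,
    compute_grs,
    dosages_from_vcf,
    load_weight_table,
    scores_to_frame,
)

log = logging.getLogger(__name__)

__all__ = [
    "INPUT_GROUPS",
    "REPORT_GROUPS",
    "PipelineError",
    "AnalysisReport",
    "proportion_report",
    "format_excess",
    "run_pipeline",
]

INPUT_GROUPS = ("monogenic_NDM", "unknown", "T1D_6_24m")
REPORT_GROUPS = ("monogenic_NDM", "unknown_low_GRS", "unknown_high_GRS", "T1D_6_24m")


class PipelineError(ValueError):
    """Raised when pipeline inputs fail validation (exit code 2 in the CLI)."""


def proportion_report(k: int, n: int) -> str:
    """Format a count as ``"k/n (P%)"`` with P rounded half-away-from-zero."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got {k}/{n}")
    pct = math.floor(100.0 * k / n + 0.5)
    return f"{k}/{n} ({pct}%)"


def format_excess(est: cal.ExcessEstimate) -> dict[str, str]:
    """Human-readable lines for an excess estimate (arithmetic-only view)."""
    return {
        "observed_high": proportion_report(est.n_high, est.n_tested),
        "expected_high": f"{est.expected_rounded}/{est.n_tested} "
        f"(expected {100 * est.alpha:g}% if all monogenic)",
        "excess": str(est.excess),
        "excess_fraction_of_cohort": proportion_report(est.excess, est.cohort_total),
        "binomial_p": "<0.0001" if est.binomial_p < 1e-4 else f"{est.binomial_p:.4g}",
    }


@dataclass
class AnalysisReport:
    """Everything the rendered report shows, as structured data."""

    threshold: float
    threshold_source: str
    centile: float
    alpha: float
    excess: dict | None  # ExcessEstimate fields + CI, None if excess skipped
    excess_formatted: dict | None
    group_summaries: dict  # group -> {variable -> {n, median, q25, q75} or counts}
    panel: dict  # group -> PanelSummary fields
    iaa: list  # rows of iaa_duration_summary
    cpeptide: list  # rows of cpeptide_group_summary
    regression: dict | None  # RegressionFit fields for the high-GRS group
    tests: list  # [{test, comparison, groups, statistic, p, n, significant}]
    exclusions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise PipelineError(f"config {config} did not parse to a mapping")
    base = Path(config).parent
    for key in ("weights", "genotypes_vcf", "dosages_csv", "phenotypes",
                "reference_scores", "growth_reference"):
        if loaded.get(key) and not Path(loaded[key]).is_absolute():
            loaded[key] = str(base / loaded[key])
    return loaded


def _load_dosages(cfg: dict, weights: WeightTable) -> DosageMatrix:
    if cfg.get("genotypes_vcf"):
        return dosages_from_vcf(
            cfg["genotypes_vcf"], weights, strand_policy=cfg.get("strand_policy", "strict")
        )
    if cfg.get("dosages_csv"):
        df = pd.read_csv(cfg["dosages_csv"], index_col=0)
        return DosageMatrix(
            individual_ids=tuple(df.index.astype(str)),
            snp_ids=tuple(df.columns.astype(str)),
            dosages=df.to_numpy(dtype=float),
        )
    raise PipelineError("config must name either genotypes_vcf or dosages_csv")


def _resolve_threshold(cfg: dict) -> tuple[float, str, float]:
    centile_q = float(cfg.get("centile", 0.95))
    if cfg.get("threshold") is not None:
        return float(cfg["threshold"]), "fixed", centile_q
    if cfg.get("reference_scores"):
        ref = pd.read_csv(cfg["reference_scores"])
        col = "grs" if "grs" in ref.columns else ref.columns[0]
        dist = cal.ReferenceDistribution(scores=ref[col].to_numpy(dtype=float))
        return cal.centile(dist, centile_q), f"{100 * centile_q:g}th centile of reference (n={dist.n})", centile_q
    raise PipelineError("config must give either a fixed threshold or reference_scores")


def _validate_phenotypes(pheno: pd.DataFrame) -> None:
    if "individual_id" not in pheno.columns or "group" not in pheno.columns:
        raise PipelineError("phenotype table needs individual_id and group columns")
    if pheno["individual_id"].duplicated().any():
        dupes = pheno.loc[pheno["individual_id"].duplicated(), "individual_id"].tolist()
        raise PipelineError(f"duplicate individual_id(s) in phenotypes: {dupes[:5]}")
    bad = set(pheno["group"].unique()) - set(INPUT_GROUPS)
    if bad:
        raise PipelineError(
            f"unknown group label(s) {sorted(bad)}; allowed: {list(INPUT_GROUPS)}"
        )


def _antibody_calls(pheno: pd.DataFrame) -> pd.DataFrame:
    """Long-format positivity calls from per-analyte titre/cutoff columns."""
    rows = []
    for analyte in bm.PANEL_ANALYTES + ("IAA",):
        tcol, ccol = f"{analyte.lower()}_titre", f"{analyte.lower()}_cutoff"
        if tcol not in pheno.columns or ccol not in pheno.columns:
            continue
        sub = pheno[pheno[tcol].notna() & pheno[ccol].notna()]
        for _, row in sub.iterrows():
            rows.append(
                {
                    "individual_id": row["individual_id"],
                    "group": row["report_group"],
                    "analyte": analyte,
                    "positive": bm.call_positive(float(row[tcol]), float(row[ccol])),
                    "insulin_duration_weeks": row.get("insulin_duration_weeks", np.nan),
                }
            )
    return pd.DataFrame(
        rows, columns=["individual_id", "group", "analyte", "positive", "insulin_duration_weeks"]
    )


def _median_iqr_summary(values: np.ndarray) -> dict:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return {"n": 0}
    med, q25, q75 = st.median_iqr(values)
    return {"n": int(values.size), "median": med, "q25": q25, "q75": q75}


def _group_summaries(pheno: pd.DataFrame, scores: pd.DataFrame) -> dict:
    merged = pheno.merge(scores[["individual_id", "grs"]], on="individual_id", how="left")
    out = {}
    for group in REPORT_GROUPS:
        sub = merged[merged["report_group"] == group]
        if len(sub) == 0:
            continue
        summary: dict = {"n": int(len(sub))}
        summary["grs"] = _median_iqr_summary(sub["grs"].to_numpy(dtype=float))
        for var, col in [
            ("age_at_diagnosis_weeks", "age_at_diagnosis_weeks"),
            ("birthweight_z", "birthweight_z"),
        ]:
            if col in sub.columns:
                summary[var] = _median_iqr_summary(sub[col].to_numpy(dtype=float))
        if "sex" in sub.columns:
            n_female = int((sub["sex"] == "female").sum())
            summary["female_sex"] = {
                "k": n_female, "n": int(len(sub)),
                "formatted": proportion_report(n_female, len(sub)),
            }
        out[group] = summary
    return out


def _pairwise_tests(
    panel: dict, iaa: pd.DataFrame, cpep_df: pd.DataFrame, merged: pd.DataFrame
) -> list[dict]:
    """The report's standard comparisons, each tagged with its test name."""
    tests: list[dict] = []

    def add_fisher(name, g1, k1, n1, g2, k2, n2):
        if min(n1, n2) == 0:
            return
        p = st.fisher_exact((k1, n1 - k1, k2, n2 - k2))
        tests.append(
            {"test": "fisher_exact", "comparison": name, "groups": [g1, g2],
             "counts": [[k1, n1], [k2, n2]], "p": p, "significant": p < 0.05}
        )

    hi, mono, t1d = "unknown_high_GRS", "monogenic_NDM", "T1D_6_24m"
    if hi in panel and mono in panel:
        add_fisher("any_islet_autoantibody", hi, panel[hi]["n_any_positive"],
                   panel[hi]["n_measured"], mono, panel[mono]["n_any_positive"],
                   panel[mono]["n_measured"])
    if hi in panel and t1d in panel:
        add_fisher("any_islet_autoantibody", hi, panel[hi]["n_any_positive"],
                   panel[hi]["n_measured"], t1d, panel[t1d]["n_any_positive"],
                   panel[t1d]["n_measured"])
    # IAA in the short insulin-exposure stratum
    if len(iaa):
        short = iaa[iaa["stratum"].str.startswith("<=")]
        rows = {r["group"]: r for _, r in short.iterrows()}
        if hi in rows and mono in rows:
            add_fisher("IAA_short_insulin_duration", hi, int(rows[hi]["n_positive"]),
                       int(rows[hi]["n"]), mono, int(rows[mono]["n_positive"]),
                       int(rows[mono]["n"]))
    # C-peptide within the first year of diabetes
    if len(cpep_df):
        early = cpep_df[cpep_df["diabetes_duration_months"] <= bm.CPEPTIDE_DURATION_BOUNDARY_MONTHS]
        for other in (mono, "unknown_low_GRS", t1d):
            a = early.loc[early["group"] == hi, "coded_value"].to_numpy()
            b = early.loc[early["group"] == other, "coded_value"].to_numpy()
            if a.size and b.size:
                u, p = st.mann_whitney_u(a, b)
                tests.append(
                    {"test": "mann_whitney_u", "comparison": "cpeptide_first_year",
                     "groups": [hi, other], "statistic": u, "n": [int(a.size), int(b.size)],
                     "p": p, "significant": p < 0.05}
                )
    # score separation across all groups
    grs_groups = [
        merged.loc[merged["report_group"] == g, "grs"].dropna().to_numpy()
        for g in REPORT_GROUPS
    ]
    grs_groups = [g for g in grs_groups if g.size > 0]
    if len(grs_groups) >= 2:
        h, p = st.kruskal_wallis(grs_groups)
        tests.append(
            {"test": "kruskal_wallis", "comparison": "grs_across_groups",
             "groups": [g for g in REPORT_GROUPS], "statistic": h,
             "n": [int(x.size) for x in grs_groups], "p": p, "significant": p < 0.05}
        )
    return tests


def _figures(outdir: Path, merged, ref_scores, threshold, panel, cpep_df, reg_pairs, fit):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # score distribution vs reference
    fig, ax = plt.subplots(figsize=(6, 4))
    cohort_grs = merged.loc[
        merged["report_group"].isin(["unknown_low_GRS", "unknown_high_GRS"]), "grs"
    ].dropna()
    if ref_scores is not None and len(ref_scores):
        ax.hist(ref_scores, bins=40, density=True, histtype="step", color="black",
                label=f"reference (n={len(ref_scores)})")
    if len(cohort_grs):
        ax.hist(cohort_grs, bins=30, density=True, alpha=0.5, color="grey",
                label=f"cohort (n={len(cohort_grs)})")
    ax.axvline(threshold, ls="--", color="k")
    ax.set_xlabel("genetic risk score")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(outdir / "fig_grs_distribution.png", dpi=120)
    plt.close(fig)

    # antibody positivity bars
    if panel:
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = [g for g in REPORT_GROUPS if g in panel]
        width = 0.2
        keys = ["any"] + list(bm.PANEL_ANALYTES)
        for i, key in enumerate(keys):
            vals = []
            for g in groups:
                s = panel[g]
                if key == "any":
                    vals.append(s["n_any_positive"] / s["n_measured"] if s["n_measured"] else 0)
                else:
                    k, n = s["per_analyte"][key]
                    vals.append(k / n if n else 0)
            ax.bar(np.arange(len(groups)) + i * width, vals, width, label=key)
        ax.set_xticks(np.arange(len(groups)) + 1.5 * width)
        ax.set_xticklabels(groups, rotation=20, ha="right", fontsize=8)
        ax.set_ylabel("proportion positive")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "fig_antibodies.png", dpi=120)
        plt.close(fig)

    # C-peptide by group (first year of diabetes)
    if len(cpep_df):
        early = cpep_df[cpep_df["diabetes_duration_months"] <= bm.CPEPTIDE_DURATION_BOUNDARY_MONTHS]
        groups = [g for g in REPORT_GROUPS if (early["group"] == g).any()]
        if groups:
            fig, ax = plt.subplots(figsize=(6, 4))
            data = [early.loc[early["group"] == g, "coded_value"] for g in groups]
            ax.boxplot(data, tick_labels=groups)
            ax.set_yscale("log")
            ax.axhline(200, ls="--", color="grey")
            ax.set_ylabel("C-peptide (pmol/l)")
            ax.tick_params(axis="x", labelsize=7)
            fig.tight_layout()
            fig.savefig(outdir / "fig_cpeptide.png", dpi=120)
            plt.close(fig)

    # birthweight z vs age at diagnosis in the high-score group
    if reg_pairs is not None and len(reg_pairs[0]) >= 3 and fit is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        x, y = reg_pairs
        ax.scatter(x, y, s=16, facecolors="none", edgecolors="k")
        xs = np.linspace(min(x), max(x), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="k")
        ax.set_xlabel("age at diagnosis (weeks)")
        ax.set_ylabel("birthweight z-score")
        ax.set_title(f"r² = {fit.r_squared:.2f}, p = {fit.p_value:.3g}", fontsize=9)
        fig.tight_layout()
        fig.savefig(outdir / "fig_birthweight.png", dpi=120)
        plt.close(fig)


def run_pipeline(
    config: str | Path | dict,
    outdir: str | Path,
    make_figures: bool = True,
) -> AnalysisReport:
    """Run the full analysis described by a config mapping or YAML file.

    Config keys: ``weights`` (TSV), ``genotypes_vcf`` or ``dosages_csv``,
    ``phenotypes`` (CSV), ``reference_scores`` (CSV) or ``threshold`` (fixed
    value), ``centile`` (default 0.95), ``cohort_total`` (full referral
    denominator; defaults to the number of unknown-cause individuals),
    ``growth_reference`` (CSV, optional), ``strand_policy``.

    All inputs are validated before any output is written; on success the
    output directory receives ``report.json``, ``scores.csv``,
    ``group_summaries.csv`` and figures.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)

    # ---- stage 0: load + validate everything up front
    try:
        weights = load_weight_table(cfg["weights"])
    except KeyError:
        raise PipelineError("config must name a weights table") from None
    dosages = _load_dosages(cfg, weights)
    try:
        pheno = pd.read_csv(cfg["phenotypes"])
    except KeyError:
        raise PipelineError("config must name a phenotypes table") from None
    _validate_phenotypes(pheno)
    threshold, threshold_source, centile_q = _resolve_threshold(cfg)
    alpha = float(cfg.get("alpha", 1.0 - centile_q))
    growth_ref = None
    if cfg.get("growth_reference"):
        growth_ref = cli_mod.GrowthReference.from_csv(cfg["growth_reference"])
    ref_scores = None
    if cfg.get("reference_scores"):
        ref = pd.read_csv(cfg["reference_scores"])
        col = "grs" if "grs" in ref.columns else ref.columns[0]
        ref_scores = ref[col].to_numpy(dtype=float)

    exclusions: list[str] = []

    # ---- stage 1: score
    records = compute_grs(dosages, weights, missing_policy=cfg.get("missing_policy", "reduce-denominator"))
    scores = scores_to_frame(records, threshold=threshold)

    # ---- stage 2: classify unknowns into derived groups
    pheno = pheno.merge(
        scores[["individual_id", "label"]], on="individual_id", how="left"
    )
    unscored_unknown = pheno[(pheno["group"] == "unknown") & pheno["label"].isna()]
    if len(unscored_unknown):
        raise PipelineError(
            f"{len(unscored_unknown)} unknown-group individual(s) have no genotypes; "
            "cannot derive high/low classification"
        )
    pheno["report_group"] = pheno["group"]
    is_unknown = pheno["group"] == "unknown"
    pheno.loc[is_unknown, "report_group"] = np.where(
        pheno.loc[is_unknown, "label"] == "high", "unknown_high_GRS", "unknown_low_GRS"
    )

    # ---- stage 3: excess over expected among the unknowns
    excess_dict = excess_formatted = None
    n_unknown = int(is_unknown.sum())
    if n_unknown == 0:
        log.info("no unknown-cause individuals: excess stage skipped")
        exclusions.append("excess stage skipped: no unknown-cause individuals")
    else:
        n_high = int((pheno.loc[is_unknown, "label"] == "high").sum())
        cohort_total = int(cfg.get("cohort_total", n_unknown))
        est = cal.estimate_excess(n_high, n_unknown, alpha, cohort_total)
        lo, hi = cal.excess_confidence_interval(est, level=0.95)
        excess_dict = est.to_dict() | {"ci95_excess_fraction_total": [lo, hi]}
        excess_formatted = format_excess(est)

    # ---- stage 4: biomarkers
    calls = _antibody_calls(pheno)
    panel_summaries = bm.summarize_panel(calls) if len(calls) else {}
    panel = {g: dataclasses.asdict(s) for g, s in panel_summaries.items()}
    iaa_calls = calls[calls["analyte"] == "IAA"]
    iaa = (
        bm.iaa_duration_summary(iaa_calls) if len(iaa_calls) else pd.DataFrame(
            columns=["group", "stratum", "n_positive", "n", "proportion"])
    )
    if "cpeptide_pmol_l" in pheno.columns:
        has_cp = pheno["cpeptide_pmol_l"].notna()
        cpep_df = pd.DataFrame(
            {
                "individual_id": pheno.loc[has_cp, "individual_id"],
                "group": pheno.loc[has_cp, "report_group"],
                "coded_value": bm.parse_cpeptide(pheno.loc[has_cp, "cpeptide_pmol_l"]),
                "diabetes_duration_months": pheno.loc[has_cp, "diabetes_duration_months"],
            }
        )
        cpep_summary = bm.cpeptide_group_summary(cpep_df)
    else:
        cpep_df = pd.DataFrame(columns=["group", "coded_value", "diabetes_duration_months"])
        cpep_summary = pd.DataFrame()

    # ---- stage 5: clinical (birthweight z + regression in high-GRS group)
    fit = None
    reg_pairs = None
    if growth_ref is not None and {"birthweight_g", "gestational_age_weeks", "sex"} <= set(pheno.columns):
        zs = []
        for _, row in pheno.iterrows():
            try:
                rec = cli_mod.BirthRecord(
                    individual_id=str(row["individual_id"]),
                    birthweight=float(row["birthweight_g"]),
                    gestational_age=float(row["gestational_age_weeks"]),
                    sex=str(row["sex"]),
                    age_at_diagnosis=float(row.get("age_at_diagnosis_weeks", np.nan)),
                )
                zs.append(cli_mod.birthweight_z(rec, growth_ref))
            except (ValueError, TypeError):
                zs.append(np.nan)
                exclusions.append(f"birthweight z unavailable for {row['individual_id']}")
        pheno["birthweight_z"] = zs
        hi_mask = (pheno["report_group"] == "unknown_high_GRS") & pheno["birthweight_z"].notna() \
            & pheno["age_at_diagnosis_weeks"].notna()
        if hi_mask.sum() >= 3:
            x = pheno.loc[hi_mask, "age_at_diagnosis_weeks"].to_numpy(dtype=float)
            y = pheno.loc[hi_mask, "birthweight_z"].to_numpy(dtype=float)
            fit = cli_mod.regress_z_on_age(x, y)
            reg_pairs = (x, y)

    # ---- stage 6: comparison statistics + per-group summary table
    merged = pheno.merge(scores[["individual_id", "grs"]], on="individual_id", how="left")
    tests = _pairwise_tests(panel, iaa, cpep_df, merged)
    group_summaries = _group_summaries(pheno, scores)

    report = AnalysisReport(
        threshold=threshold,
        threshold_source=threshold_source,
        centile=centile_q,
        alpha=alpha,
        excess=excess_dict,
        excess_formatted=excess_formatted,
        group_summaries=group_summaries,
        panel=panel,
        iaa=iaa.to_dict(orient="records"),
        cpeptide=cpep_summary.to_dict(orient="records") if len(cpep_summary) else [],
        regression=dataclasses.asdict(fit) if fit is not None else None,
        tests=tests,
        exclusions=exclusions,
    )

    # ---- stage 7: write artefacts (only after everything computed)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"report": report.to_dict(),
               "meta": {"created": datetime.now(timezone.utc).isoformat()}}
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
    scores.to_csv(outdir / "scores.csv", index=False, float_format="%.10g")
    rows = []
    for g, s in group_summaries.items():
        for var, v in s.items():
            if isinstance(v, dict):
                rows.append({"group": g, "variable": var, **v})
    pd.DataFrame(rows).to_csv(outdir / "group_summaries.csv", index=False)
    if make_figures:
        _figures(outdir, merged, ref_scores, threshold, panel, cpep_df, reg_pairs, fit)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
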