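"""Seeded synthetic referral-cohort generator.

Emulates the data structure of a neonatal-diabetes referral series: a cohort
of infants diagnosed before 6 months of age in whom gene panel testing found
no monogenic cause, modelled as a mixture of two latent classes —

* "monogenic-like" infants (an undiscovered single-gene cause), whose
  polygenic risk scores follow the background (control) distribution; and
* "polygenic" infants with true autoimmune type 1 diabetes, whose risk-allele
  genotypes are tilted upward by the per-SNP odds ratios.

Control genotypes are drawn per SNP under Hardy–Weinberg equilibrium,
``dosage ~ Binomial(2, f)``; case genotypes use the standard logistic tilt
``P(g | case) ∝ C(2,g) f^g (1-f)^(2-g) OR^g``, which reproduces each SNP's
odds ratio exactly in expectation.  SNPs are simulated in linkage
equilibrium — real risk panels include correlated HLA variants, so simulated
score distributions are smoother than real ones (a documented limitation).

Biomarkers are class-specific: polygenic infants have high islet-autoantibody
positivity and C-peptide mostly below the assay's detection limit, and their
birthweight z-scores decline with earlier age at diagnosis.  Alongside the
mixed cohort the generator emits a control reference panel, an optional
confirmed-monogenic comparison group, and an optional group with type 1
diabetes diagnosed at 6-24 months, plus the truth labels (written separately
so the analysis pipeline never sees them).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import CPEPTIDE_LOD, PANEL_ANALYTES
from .clinical import GrowthReference, synthetic_growth_reference_path, z_to_birthweight
from .grs import DosageMatrix, WeightTable, compute_grs, load_weight_table, synthetic_weight_table_path

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "default_allele_freqs",
    "simulate_control_genotypes",
    "simulate_case_genotypes",
    "simulate_cohort",
    "exceedance_sensitivity",
    "write_vcf",
]

ANALYTES = PANEL_ANALYTES + ("IAA",)


def default_allele_freqs() -> np.ndarray:
    """Effect-allele frequencies paired with the packaged synthetic SNP panel."""
    path = Path(__file__).parent / "data" / "allele_freqs_synthetic.tsv"
    return pd.read_csv(path, sep="\t")["effect_allele_freq"].to_numpy(dtype=float)


def _default_antibody_positivity() -> dict:
    # class-conditional probability that an analyte is truly positive;
    # polygenic values reflect early-onset autoimmune diabetes, monogenic
    # values the ~1% assay false-positive floor plus exogenous-insulin IAA
    return {
        "polygenic": {"GADA": 0.27, "IA2A": 0.16, "ZnT8A": 0.12, "IAA": 0.82},
        "monogenic": {"GADA": 0.02, "IA2A": 0.04, "ZnT8A": 0.01, "IAA": 0.39},
    }


def _default_cpeptide_model() -> dict:
    # log-normal pmol/l: polygenic infants lose secretion rapidly (median
    # ~1.2 pmol/l, mostly below the 3 pmol/l detection limit); monogenic
    # infants retain measurable secretion (median ~60 pmol/l)
    return {
        "polygenic": {"log_median": np.log(1.2), "sigma": 1.2},
        "monogenic": {"log_median": np.log(60.0), "sigma": 1.3},
    }


def _default_birthweight_model() -> dict:
    # z ~ Normal(mu + beta * age_at_diagnosis_weeks, sigma); the polygenic
    # class starts lower and recovers with later diagnosis (in-utero
    # beta-cell loss), the monogenic class is uniformly growth-restricted
    return {
        "polygenic": {"mu": -2.4, "beta": 0.08, "sigma": 1.1},
        "monogenic": {"mu": -1.6, "beta": 0.02, "sigma": 1.1},
    }


def _default_age_model() -> dict:
    # age at diagnosis in (0, 26] weeks: Beta(a, b) scaled to 26 weeks;
    # monogenic causes present earlier than polygenic autoimmunity
    return {
        "polygenic": {"a": 2.5, "b": 1.6, "scale": 26.0},
        "monogenic": {"a": 1.3, "b": 2.5, "scale": 26.0},
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic referral cohort."""

    weight_table: WeightTable = field(
        default_factory=lambda: load_weight_table(synthetic_weight_table_path())
    )
    allele_freqs: np.ndarray = field(default_factory=default_allele_freqs)
    n_reference: int = 4862
    n_cohort: int = 166
    pi: float = 0.33  # true polygenic fraction of the unknown-cause cohort
    n_monogenic: int = 164  # confirmed-monogenic comparison group (0 to skip)
    n_t1d_6_24m: int = 152  # type 1 diabetes diagnosed 6-24 months (0 to skip)
    antibody_positivity: dict = field(default_factory=_default_antibody_positivity)
    titre_log10_mu: float = 0.0  # healthy log10-titre location
    titre_log10_sigma: float = 0.5
    cpeptide_model: dict = field(default_factory=_default_cpeptide_model)
    birthweight_model: dict = field(default_factory=_default_birthweight_model)
    age_model: dict = field(default_factory=_default_age_model)
    p_female: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.allele_freqs.size != self.weight_table.m:
            raise ValueError(
                f"{self.allele_freqs.size} allele frequencies for "
                f"{self.weight_table.m} SNPs"
            )
        if not np.all((self.allele_freqs > 0) & (self.allele_freqs < 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        for cls in ("polygenic", "monogenic"):
            for analyte, p in self.antibody_positivity[cls].items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"positivity[{cls}][{analyte}] = {p} outside [0, 1]")

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.array([e.odds_ratio for e in self.weight_table.entries])

    @property
    def antibody_cutoffs(self) -> dict[str, float]:
        """Per-analyte positivity cut-off: the healthy 99th percentile.

        Healthy log10 titres are Normal(mu, sigma), so the 99th percentile is
        analytic; by construction ~1% of healthy controls exceed it.
        """
        from scipy.stats import norm

        q99 = norm.ppf(0.99)
        cut = 10 ** (self.titre_log10_mu + q99 * self.titre_log10_sigma)
        return {a: cut for a in ANALYTES}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weight_table"] = [
            {"snp_id": e.snp_id, "effect_allele": e.effect_allele,
             "other_allele": e.other_allele, "odds_ratio": e.odds_ratio}
            for e in self.weight_table.entries
        ]
        d["allele_freqs"] = [float(f) for f in self.allele_freqs]
        return d


def simulate_control_genotypes(
    config: SimulationConfig, n: int, rng: np.random.Generator, prefix: str = "ctrl"
) -> DosageMatrix:
    """Hardy–Weinberg genotypes: per SNP i, dosage ~ Binomial(2, f_i)."""
    dose = rng.binomial(2, config.allele_freqs, size=(n, config.weight_table.m)).astype(float)
    ids = tuple(f"{prefix}{i + 1:05d}" for i in range(n))
    return DosageMatrix(individual_ids=ids, snp_ids=tuple(config.weight_table.snp_ids), dosages=dose)


def _case_genotype_probs(f: np.ndarray, odds_ratio: np.ndarray) -> np.ndarray:
    """Per-SNP case genotype law, shape (m, 3): P(g) ∝ C(2,g) f^g (1-f)^(2-g) OR^g."""
    g = np.arange(3)
    comb = np.array([1.0, 2.0, 1.0])
    raw = comb[None, :] * f[:, None] ** g[None, :] * (1 - f[:, None]) ** (2 - g[None, :]) \
        * odds_ratio[:, None] ** g[None, :]
    return raw / raw.sum(axis=1, keepdims=True)


def simulate_case_genotypes(
    config: SimulationConfig, n: int, rng: np.random.Generator, prefix: str = "case"
) -> DosageMatrix:
    """Odds-ratio-tilted genotypes for the polygenic (affected) class."""
    probs = _case_genotype_probs(config.allele_freqs, config.odds_ratios)
    m = config.weight_table.m
    u = rng.random(size=(n, m))
    cdf = probs.cumsum(axis=1)  # (m, 3)
    dose = (u[:, :, None] > cdf[None, :, :2]).sum(axis=2).astype(float)
    ids = tuple(f"{prefix}{i + 1:05d}" for i in range(n))
    return DosageMatrix(individual_ids=ids, snp_ids=tuple(config.weight_table.snp_ids), dosages=dose)


def exceedance_sensitivity(
    config: SimulationConfig, threshold: float, cls: str = "polygenic", n_grid: int = 1 << 17
) -> float:
    """Analytic P(score > threshold) for one latent class.

    Convolves the per-SNP dosage-weight distributions numerically on a
    uniform grid (SNPs are independent in the simulation), then sums the
    probability mass above the threshold on the allele-sum scale.
    """
    w = config.weight_table.weights
    if np.any(w < 0):
        raise ValueError("analytic sensitivity assumes non-negative weights")
    if cls == "polygenic":
        probs = _case_genotype_probs(config.allele_freqs, config.odds_ratios)
    elif cls == "monogenic":
        f = config.allele_freqs
        probs = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)
    else:
        raise ValueError(f"unknown class {cls!r}")
    total = 2 * float(w.sum())
    h = total / (n_grid - 1) if total > 0 else 1.0
    pmf = np.zeros(n_grid)
    pmf[0] = 1.0
    for i in range(config.weight_table.m):
        kernel_bins = np.rint([0.0, w[i] / h, 2 * w[i] / h]).astype(int)
        new = np.zeros_like(pmf)
        for g in range(3):
            k = kernel_bins[g]
            if k == 0:
                new += probs[i, g] * pmf
            else:
                new[k:] += probs[i, g] * pmf[: n_grid - k]
        pmf = new
    # score = allele_sum / (2m); exceed iff allele_sum > threshold * 2m
    cut = threshold * 2 * config.weight_table.m
    values = np.arange(n_grid) * h
    return float(pmf[values > cut].sum())


@dataclass
class SimulatedCohort:
    """In-memory result of a cohort simulation (files are a view of this)."""

    config: SimulationConfig
    genotypes: DosageMatrix  # unknown-cause cohort + comparison groups
    phenotypes: pd.DataFrame  # pipeline input: no truth labels
    truth: pd.DataFrame  # individual_id, latent_class
    reference_scores: np.ndarray  # control reference panel GRS

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write pipeline-ready inputs: VCF, phenotype/truth/reference CSVs, config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "phenotypes": outdir / "phenotypes.csv",
            "truth": outdir / "truth_labels.csv",
            "reference": outdir / "reference_scores.csv",
            "config": outdir / "simulation_config.yaml",
        }
        write_vcf(paths["vcf"], self.genotypes, self.config.weight_table)
        self.phenotypes.to_csv(paths["phenotypes"], index=False, float_format="%.6g")
        self.truth.to_csv(paths["truth"], index=False)
        pd.DataFrame({"grs": self.reference_scores}).to_csv(
            paths["reference"], index=False, float_format="%.10g"
        )
        cfg = self.config.to_dict()
        cfg["cpeptide_model"] = {
            k: {kk: float(vv) for kk, vv in v.items()} for k, v in cfg["cpeptide_model"].items()
        }
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return paths


def write_vcf(path: str | Path, genotypes: DosageMatrix, weights: WeightTable) -> None:
    """Write a minimal VCF v4.2 (GT only) with the effect allele as ALT.

    Dosages are unphased diploid genotypes (0/0, 0/1, 1/1; ./. when missing);
    synthetic positions are assigned deterministically from SNP order.
    """
    entry_by_id = {e.snp_id: e for e in weights.entries}
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({1 + i % 22 for i in range(len(genotypes.snp_ids))})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, snp_id in enumerate(genotypes.snp_ids):
            e = entry_by_id[snp_id]
            chrom = 1 + j % 22
            pos = 1_000_000 + 1_000 * j
            gts = "\t".join(
                gt_map.get(genotypes.dosages[i, j], "./.")
                for i in range(len(genotypes.individual_ids))
            )
            fh.write(
                f"{chrom}\t{pos}\t{snp_id}\t{e.other_allele}\t{e.effect_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"  # QUAL '.', INFO '.'
            )


def _draw_ages(model: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    ages = model["scale"] * rng.beta(model["a"], model["b"], size=n)
    return np.clip(ages, 0.15, model["scale"])  # strictly inside (0, scale]


def _draw_titres(
    cls: str, n: int, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-analyte titres: positives sit above the cut-off, negatives follow
    the healthy distribution (so ~1% incidental positives persist)."""
    cutoffs = config.antibody_cutoffs
    out = {}
    for analyte in ANALYTES:
        p_pos = config.antibody_positivity[cls][analyte]
        is_pos = rng.random(n) < p_pos
        healthy = 10 ** rng.normal(config.titre_log10_mu, config.titre_log10_sigma, size=n)
        positive = cutoffs[analyte] * np.exp(rng.exponential(1.0, size=n))
        out[analyte] = np.where(is_pos, positive, healthy)
    return out


def _simulate_class_phenotypes(
    ids, cls: str, config: SimulationConfig, rng: np.random.Generator,
    growth_ref: GrowthReference, age_override: np.ndarray | None = None,
) -> pd.DataFrame:
    n = len(ids)
    ages = _draw_ages(config.age_model[cls], n, rng) if age_override is None else age_override
    sexes = np.where(rng.random(n) < config.p_female, "female", "male")
    gest = np.clip(rng.normal(38.5, 1.8, size=n), 33.0, 42.0)
    bw_model = config.birthweight_model[cls]
    z = rng.normal(bw_model["mu"] + bw_model["beta"] * ages, bw_model["sigma"])
    birthweight = np.array(
        [z_to_birthweight(z[i], sexes[i], gest[i], growth_ref) for i in range(n)]
    )
    cp_model = config.cpeptide_model[cls]
    cpeptide = np.exp(rng.normal(cp_model["log_median"], cp_model["sigma"], size=n))
    titres = _draw_titres(cls, n, config, rng)
    cutoffs = config.antibody_cutoffs
    insulin_duration = np.exp(rng.normal(np.log(11.0), 1.1, size=n))  # weeks
    diabetes_duration = np.exp(rng.normal(np.log(8.0), 1.4, size=n))  # months
    df = pd.DataFrame(
        {
            "individual_id": list(ids),
            "age_at_diagnosis_weeks": np.round(ages, 2),
            "sex": sexes,
            "gestational_age_weeks": np.round(gest, 1),
            "birthweight_g": np.round(birthweight, 0),
            "insulin_duration_weeks": np.round(insulin_duration, 1),
            "diabetes_duration_months": np.round(diabetes_duration, 1),
        }
    )
    # LOD censoring happens at write-time: below-LOD values become "<3" tokens
    df["cpeptide_pmol_l"] = [
        "<3" if v < CPEPTIDE_LOD else f"{v:.1f}" for v in cpeptide
    ]
    for analyte in ANALYTES:
        df[f"{analyte.lower()}_titre"] = np.round(titres[analyte], 3)
        df[f"{analyte.lower()}_cutoff"] = round(cutoffs[analyte], 3)
    return df


def simulate_cohort(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedCohort:
    """Generate the full synthetic study: reference panel + referral cohort.

    The unknown-cause cohort mixes ``round(pi * n_cohort)`` polygenic
    individuals with monogenic-like individuals; comparison groups
    (confirmed monogenic, type 1 diabetes diagnosed at 6-24 months) are
    appended when their configured sizes are positive.  Truth labels are
    returned (and written) separately from the phenotype table.  A fixed seed
    gives byte-identical output files.
    """
    rng = np.random.default_rng(config.seed)
    growth_ref = GrowthReference.from_csv(synthetic_growth_reference_path())

    ref_geno = simulate_control_genotypes(config, config.n_reference, rng, prefix="ref")
    ref_scores = np.array([r.grs for r in compute_grs(ref_geno, config.weight_table)])

    n_poly = int(np.rint(config.pi * config.n_cohort))
    n_mono_like = config.n_cohort - n_poly
    blocks: list[tuple[str, str, DosageMatrix]] = []  # (group, class, genotypes)
    poly = simulate_case_genotypes(config, n_poly, rng, prefix="unk_p")
    mono = simulate_control_genotypes(config, n_mono_like, rng, prefix="unk_m")
    blocks += [("unknown", "polygenic", poly), ("unknown", "monogenic", mono)]
    if config.n_monogenic > 0:
        blocks.append(
            ("monogenic_NDM", "monogenic",
             simulate_control_genotypes(config, config.n_monogenic, rng, prefix="mono"))
        )
    if config.n_t1d_6_24m > 0:
        blocks.append(
            ("T1D_6_24m", "polygenic",
             simulate_case_genotypes(config, config.n_t1d_6_24m, rng, prefix="t1d"))
        )

    phenos, truths = [], []
    for group, cls, geno in blocks:
        age_override = None
        if group == "T1D_6_24m":
            # diagnosed at 6-24 months: uniform on 26-104 weeks
            age_override = rng.uniform(26.0, 104.0, size=len(geno.individual_ids))
        df = _simulate_class_phenotypes(
            geno.individual_ids, cls, config, rng, growth_ref, age_override
        )
        df.insert(1, "group", group)
        phenos.append(df)
        truths.append(
            pd.DataFrame({"individual_id": list(geno.individual_ids), "latent_class": cls})
        )

    all_geno = DosageMatrix(
        individual_ids=tuple(i for _, _, g in blocks for i in g.individual_ids),
        snp_ids=tuple(config.weight_table.snp_ids),
        dosages=np.vstack([g.dosages for _, _, g in blocks]),
    )
    cohort = SimulatedCohort(
        config=config,
        genotypes=all_geno,
        phenotypes=pd.concat(phenos, ignore_index=True),
        truth=pd.concat(truths, ignore_index=True),
        reference_scores=ref_scores,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
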