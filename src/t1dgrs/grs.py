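"""Genetic risk score computation from effect-allele dosages.

The score is an average log-odds per allele: each SNP's contribution is its
effect-allele dosage (0, 1 or 2) times the log10 of its published odds ratio,
and the sum is divided by the total number of alleles counted (2 x the number
of non-missing SNPs).  Dividing by alleles rather than SNPs keeps the score a
per-allele mean, so individuals genotyped at different subsets of the panel
remain on a comparable scale.

Genotypes arrive either as a tabular dosage matrix or as a VCF; VCF ingestion
resolves which VCF allele is the effect allele, optionally tolerating strand
flips at unambiguous SNPs, and never silently flipping A/T or C/G SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeightEntry",
    "WeightTable",
    "DosageMatrix",
    "ScoreRecord",
    "load_weight_table",
    "synthetic_weight_table_path",
    "dosages_from_vcf",
    "compute_grs",
    "classify_high_low",
    "scores_to_frame",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class WeightEntry:
    snp_id: str
    effect_allele: str
    other_allele: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.odds_ratio > 0 and math.isfinite(self.odds_ratio)):
            raise ValueError(f"{self.snp_id}: odds ratio must be positive and finite")

    @property
    def weight(self) -> float:
        """log10 odds ratio — the per-allele score contribution."""
        return math.log10(self.odds_ratio)

    @property
    def strand_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, where a strand flip is undetectable."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class WeightTable:
    entries: tuple[WeightEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("weight table must have at least one SNP")
        ids = [e.snp_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id(s) in weight table: {', '.join(dupes)}")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def m(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries])

    def __getitem__(self, snp_id: str) -> WeightEntry:
        for e in self.entries:
            if e.snp_id == snp_id:
                return e
        raise KeyError(snp_id)


@dataclass(frozen=True)
class DosageMatrix:
    """Effect-allele dosages, individuals x SNPs; NaN marks missing."""

    individual_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray  # float array, values in {0,1,2} or NaN

    def __post_init__(self) -> None:
        arr = np.asarray(self.dosages, dtype=float)
        n, m = len(self.individual_ids), len(self.snp_ids)
        if arr.shape != (n, m):
            raise ValueError(f"dosage shape {arr.shape} != ({n}, {m})")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp ids must be unique")
        present = arr[~np.isnan(arr)]
        if present.size and (
            np.any(present != np.rint(present)) or np.any(present < 0) or np.any(present > 2)
        ):
            raise ValueError("dosages must be integers in [0, 2] or missing")
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(self, "dosages", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=list(self.individual_ids), columns=list(self.snp_ids)
        )


@dataclass(frozen=True)
class ScoreRecord:
    individual_id: str
    grs: float
    n_snps_used: int
    missing_count: int

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_snps_used


def load_weight_table(path: str | Path) -> WeightTable:
    """Read a SNP weight table from a tab-separated file.

    Requires a header with columns snp_id, effect_allele, other_allele,
    odds_ratio; row order is preserved.  A '.' placeholder is not accepted
    for the odds ratio.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "effect_allele", "other_allele", "odds_ratio"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    entries = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw_or = getattr(row, "odds_ratio")
        try:
            or_val = float(raw_or)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} line {idx}: odds_ratio {raw_or!r} is not numeric"
            ) from None
        if not (or_val > 0):
            raise ValueError(f"{path} line {idx}: odds_ratio must be > 0, got {or_val}")
        entries.append(
            WeightEntry(
                snp_id=str(row.snp_id),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                odds_ratio=or_val,
            )
        )
    return WeightTable(entries=tuple(entries))


def synthetic_weight_table_path() -> Path:
    """Path to the packaged synthetic 30-SNP example weight table.

    The values are invented for demonstration and testing; real analyses must
    supply the weight table actually used to define their score.
    """
    return Path(__file__).parent / "data" / "snp_weights_synthetic.tsv"


def _resolve_orientation(
    ref: str, alt: str, entry: WeightEntry, strand_policy: str
) -> str:
    """Return 'alt' or 'ref' for which VCF allele is the effect allele."""
    if alt == entry.effect_allele and ref == entry.other_allele:
        return "alt"
    if ref == entry.effect_allele and alt == entry.other_allele:
        return "ref"
    if strand_policy == "flip-unambiguous":
        flipped_ref, flipped_alt = _COMPLEMENT.get(ref, "?"), _COMPLEMENT.get(alt, "?")
        flip_as_alt = flipped_alt == entry.effect_allele and flipped_ref == entry.other_allele
        flip_as_ref = flipped_ref == entry.effect_allele and flipped_alt == entry.other_allele
        if flip_as_alt or flip_as_ref:
            if entry.strand_ambiguous:
                raise ValueError(
                    f"{entry.snp_id}: strand-ambiguous "
                    f"({entry.effect_allele}/{entry.other_allele}) SNP would require a "
                    "strand flip; refusing to guess"
                )
            return "alt" if flip_as_alt else "ref"
    raise ValueError(
        f"{entry.snp_id}: VCF alleles {ref}/{alt} do not match weight-table alleles "
        f"{entry.effect_allele}/{entry.other_allele} under policy {strand_policy!r}"
    )


def dosages_from_vcf(
    vcf_path: str | Path,
    weights: WeightTable,
    strand_policy: str = "strict",
) -> DosageMatrix:
    """Extract effect-allele dosages for the weight table's SNPs from a VCF.

    Sites are matched by ID.  Only the GT field is read.  If the VCF ALT
    allele is the effect allele the dosage is the ALT count; if REF is the
    effect allele the dosage is 2 minus the ALT count.  Under the
    ``flip-unambiguous`` policy a site matching only after base complementing
    is accepted, except at strand-ambiguous (A/T, C/G) SNPs which always
    raise.  Uncalled genotypes and SNPs absent from the VCF are missing.
    """
    from cyvcf2 import VCF

    if strand_policy not in {"strict", "flip-unambiguous"}:
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    wanted = {e.snp_id: e for e in weights.entries}
    dose = np.full((len(samples), weights.m), np.nan)
    col = {sid: j for j, sid in enumerate(weights.snp_ids)}
    for variant in vcf:
        entry = wanted.get(variant.ID)
        if entry is None:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{entry.snp_id}: multiallelic site (ALT={variant.ALT}) cannot be scored"
            )
        orientation = _resolve_orientation(
            variant.REF.upper(), variant.ALT[0].upper(), entry, strand_policy
        )
        j = col[entry.snp_id]
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is phasing flag
            if any(a < 0 for a in alleles):
                continue  # uncalled -> missing
            alt_count = sum(1 for a in alleles if a == 1)
            dose[i, j] = alt_count if orientation == "alt" else 2 - alt_count
    return DosageMatrix(
        individual_ids=tuple(samples), snp_ids=tuple(weights.snp_ids), dosages=dose
    )


def compute_grs(
    dosages: DosageMatrix,
    weights: WeightTable,
    missing_policy: str = "reduce-denominator",
    max_missing: int = 0,
) -> list[ScoreRecord]:
    """Score every individual: sum of dosage x log10(OR) over 2 x SNPs used.

    Under ``reduce-denominator`` (default) a missing SNP is dropped from both
    the numerator and the denominator, keeping the score a per-allele mean.
    Under ``drop-individual`` anyone missing more than ``max_missing`` SNPs is
    omitted from the output entirely.  An individual with no genotyped SNPs
    has no defined score and raises.
    """
    if missing_policy not in {"reduce-denominator", "drop-individual"}:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    weight_by_id = {e.snp_id: e.weight for e in weights.entries}
    unknown = [s for s in dosages.snp_ids if s not in weight_by_id]
    if unknown:
        raise ValueError(f"SNP(s) in dosages absent from weight table: {', '.join(unknown)}")
    w = np.array([weight_by_id[s] for s in dosages.snp_ids])
    d = dosages.dosages
    present = ~np.isnan(d)
    n_used = present.sum(axis=1)
    m = weights.m
    numer = np.where(present, d, 0.0) @ w
    records: list[ScoreRecord] = []
    for i, ind in enumerate(dosages.individual_ids):
        used = int(n_used[i])
        missing = m - used
        if missing_policy == "drop-individual" and missing > max_missing:
            continue
        if used == 0:
            raise ValueError(f"{ind}: no non-missing SNPs, score undefined")
        records.append(
            ScoreRecord(
                individual_id=ind,
                grs=float(numer[i] / (2 * used)),
                n_snps_used=used,
                missing_count=missing,
            )
        )
    return records


def classify_high_low(
    scores: list[ScoreRecord] | dict[str, float], threshold: float
) -> list[tuple[str, str]]:
    """Label each individual 'high' if score strictly exceeds the threshold.

    The comparison is strict: a score exactly at the threshold is 'low'.
    Input order is preserved.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if isinstance(scores, dict):
        items = scores.items()
    else:
        items = ((r.individual_id, r.grs) for r in scores)
    return [(ind, "high" if g > threshold else "low") for ind, g in items]


def scores_to_frame(
    records: list[ScoreRecord], threshold: float | None = None
) -> pd.DataFrame:
    """Tabulate score records (and labels, if a threshold is given) as a DataFrame."""
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "grs": [r.grs for r in records],
            "n_snps_used": [r.n_snps_used for r in records],
            "missing_count": [r.missing_count for r in records],
        }
    )
    if threshold is not None:
        labels = classify_high_low(records, threshold)
        df["label"] = [lab for _, lab in labels]
    return df
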