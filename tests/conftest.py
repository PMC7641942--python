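from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t1dgrs.grs import WeightEntry, WeightTable, load_weight_table, synthetic_weight_table_path

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_weights():
    return load_weight_table(DATA / "toy_weights.tsv")


@pytest.fixture(scope="session")
def toy_vcf_path():
    return DATA / "toy.vcf"


@pytest.fixture(scope="session")
def toy_dosage_path():
    return DATA / "toy_dosages.tsv"


@pytest.fixture(scope="session")
def synthetic_weights():
    return load_weight_table(synthetic_weight_table_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(20201008)


def make_weight_table(odds_ratios) -> WeightTable:
    """Weight table with the given ORs and arbitrary unambiguous alleles."""
    return WeightTable(
        entries=tuple(
            WeightEntry(snp_id=f"rs{i + 1}", effect_allele="A", other_allele="G", odds_ratio=float(o))
            for i, o in enumerate(odds_ratios)
        )
    )


def per_allele_oracle(dosage_row, weights, snp_ids):
    """Independent per-allele enumeration of the score.

    Lists every allele slot of each non-missing SNP (two slots per SNP),
    gives each copy of the effect allele that SNP's log10-OR weight and every
    other slot 0, then averages over all slots.
    """
    w = {e.snp_id: e.weight for e in weights.entries}
    slots = []
    for snp_id, d in zip(snp_ids, dosage_row):
        if np.isnan(d):
            continue
        d = int(d)
        slots.extend([w[snp_id]] * d)
        slots.extend([0.0] * (2 - d))
    return sum(slots) / len(slots)
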