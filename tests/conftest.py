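import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import senseinv as si

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_inventory(rows, source_default="SRC"):
    """Inventory from (sf, lf[, source]) tuples, normalized with ids assigned."""
    records = [
        si.Record(sf=row[0], lf=row[1], source=row[2] if len(row) > 2 else source_default)
        for row in rows
    ]
    inv = si.SenseInventory(records=records)
    si.normalize_inventory(inv)
    si.assign_record_ids(inv)
    si.assign_string_ids(inv, "short_form")
    si.assign_string_ids(inv, "long_form")
    return inv


@pytest.fixture(scope="session")
def default_bundle():
    """A moderately varied 3-source fixture with ground truth (seed 1)."""
    bank = si.generate_concept_bank(60, ambiguity_rate=0.2, seed=1)
    return si.generate_inventories(bank, n_sources=3, seed=1)


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero lexical variation, zero errors: cross-source exact duplicates."""
    bank = si.generate_concept_bank(40, ambiguity_rate=0.2, seed=2)
    rates = si.VariantRates(
        sf_case=0.0, sf_periods=0.0, lf_plural=0.0, lf_genitive=0.0,
        lf_stopword=0.0, lf_token_swap=0.0, lf_misspell=0.0,
    )
    return si.generate_inventories(bank, n_sources=2, variant_rates=rates, seed=2)
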