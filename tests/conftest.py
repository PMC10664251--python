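import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrbiome.gwas_io import HarmonizedTable, SummaryStatSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_set(rows, name="trait", role="exposure", level="none"):
    """Build a SummaryStatSet from a list of dicts with sensible defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": 1e-7,
        "n": 10_000,
    }
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults)
        d["snp_id"] = f"rs{i + 1}"
        d["pos"] = 1000 + i * 100_000
        d.update(row)
        full.append(d)
    return SummaryStatSet(
        trait_name=name, records=pd.DataFrame(full), trait_role=role, taxon_level=level
    )


@pytest.fixture
def worked_table():
    """The 3-SNP worked example used for hand-checked regression oracles."""
    return HarmonizedTable.from_arrays(
        snp_id=["rs1", "rs2", "rs3"],
        beta_exp=[0.1, 0.2, 0.3],
        se_exp=[0.01, 0.01, 0.01],
        beta_out=[0.05, 0.11, 0.14],
        se_out=[0.01, 0.01, 0.02],
    )


@pytest.fixture
def noisy_table():
    """Seeded 10-SNP table with spread in exposure effects."""
    rng = np.random.default_rng(1)
    bx = rng.uniform(0.05, 0.3, 10) * rng.choice([-1, 1], 10)
    sx = rng.uniform(0.005, 0.02, 10)
    by = 0.4 * bx + rng.normal(0, 0.02, 10)
    sy = rng.uniform(0.01, 0.03, 10)
    return HarmonizedTable.from_arrays(
        snp_id=[f"rs{i}" for i in range(10)],
        beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy,
    )
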