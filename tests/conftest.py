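import numpy as np
import pandas as pd
import pytest

from ampbalance import GeneRecord


def make_gene_table(rows):
    """Build a scoped-style gene DataFrame from compact row tuples:
    (gene_id, chromosome, midpoint, cds_length, category, tajimas_d)."""
    recs = []
    for gene_id, chrom, mid, cds, cat, d in rows:
        recs.append({
            "gene_id": gene_id, "chromosome": chrom,
            "start": int(mid - cds / 2), "end": int(mid + cds / 2),
            "strand": "+", "category": cat, "cds_length": cds,
            "L_silent": max(cds // 6, 1), "S": 1,
            "pi": 0.01, "theta_w": 0.01,
            "tajimas_d": d, "n_eff": 20,
            "midpoint": float(mid),
        })
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_dataset():
    """One compact synthetic dataset shared by read-only tests."""
    from ampbalance import SimulationConfig, simulate_genome

    cfg = SimulationConfig(
        chromosome_lengths={"2L": 120_000, "3R": 120_000},
        genes_per_chromosome={"2L": 25, "3R": 25},
        amp_count=6, immune_count=5,
        cds_length_range=(300, 600),
        seed=11,
    )
    return simulate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
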