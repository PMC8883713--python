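import numpy as np
import pandas as pd
import pytest

from selsig import simdata


def make_vmap(bp, chrom="1", cm=None):
    bp = np.asarray(bp, dtype=np.int64)
    return pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(len(bp))],
        "chrom": str(chrom),
        "bp": bp,
        "cm": bp * 1e-6 if cm is None else np.asarray(cm, float),
        "allele1": "A",
        "allele2": "G",
    })


def make_samples(n, cohort=None):
    rng = np.random.default_rng(1234)
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "cohort": cohort if cohort is not None else ["unassigned"] * n,
        "breed": rng.choice(["B", "Q"], n),
        "region": rng.choice(["northeast", "northwest", "southeast"], n),
        "age": np.round(rng.uniform(2, 8, n), 2),
    })


def random_genotypes(rng, n, m, missing_rate=0.0):
    p = rng.uniform(0.1, 0.9, m)
    G = ((rng.random((n, m)) < p).astype(np.int8)
         + (rng.random((n, m)) < p).astype(np.int8))
    if missing_rate:
        G[rng.random((n, m)) < missing_rate] = -1
    return G


@pytest.fixture(scope="session")
def small_sim():
    """One modest two-cohort dataset shared across tests (read-only)."""
    cfg = simdata.SimConfig(
        n_per_cohort=30, n_chrom=2, chrom_length_bp=20_000_000,
        n_snps_per_chrom=1500, fst_divergence=0.05, roh_rate=0.5,
        roh_mean_length_bp=3_000_000, seed=42,
    )
    return simdata.simulate_cohorts(cfg)
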