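"""Shared fixtures: synthetic datasets at the study conditions the tests probe.

Everything is generated in-process from fixed seeds; nothing is loaded from
disk. Expensive cohorts are session-scoped so acceptance and unit tests
share them.
"""

import numpy as np
import pandas as pd
import pytest

from snmctkit.io_formats import MethCallTable
from snmctkit.synthetic_data import (RegionModel, SimConfig, preset_config,
                                     simulate_dataset)

SEED = 1234


@pytest.fixture(scope="session")
def tiny_result():
    return simulate_dataset(preset_config("tiny", seed=SEED))


@pytest.fixture(scope="session")
def qc_stress_result():
    return simulate_dataset(preset_config("qc_stress", seed=SEED))


@pytest.fixture(scope="session")
def trajectory_result():
    return simulate_dataset(preset_config("trajectory", seed=SEED))


@pytest.fixture(scope="session")
def rescue_result():
    return simulate_dataset(preset_config("rescue", seed=SEED))


@pytest.fixture(scope="session")
def doublet_cohort_result():
    """300 singleton + 15 union-doublet nuclei, ~30% capture of ~20k sites."""
    cfg = SimConfig(seed=SEED, n_chrom=2, chrom_len=1_000_000, chloro_len=30_000,
                    clusters=("MN",), genotypes=("WT",),
                    n_nuclei_per_cluster_per_genotype=300,
                    site_density=3.34, capture_prob=0.30, doublet_rate=0.05,
                    region_models=[])
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def shift_result():
    """-0.30 CG shift planted in one cluster (VN2) x one genotype (mutA)."""
    models = [
        RegionModel(name="cg_hypo_dmr", n=40, length=1000,
                    baseline={"CG": 0.85, "CHG": 0.35, "CHH": 0.08},
                    genotype_deltas={"CG": {"mutA": -0.30}},
                    genotype_delta_clusters=("VN2",)),
        RegionModel(name="control_regions", n=30, length=1000),
    ]
    cfg = SimConfig(seed=SEED, clusters=("MN", "MNtoVN", "VN1", "VN2", "VN4", "SN"),
                    genotypes=("WT", "mutA"),
                    n_nuclei_per_cluster_per_genotype=100,
                    region_models=models)
    return simulate_dataset(cfg)


def meth_table(records, nucleus_id="n1"):
    """Build a MethCallTable from (chrom, pos, strand, context, mc, cov) rows."""
    df = pd.DataFrame(records,
                      columns=["chrom", "pos", "strand", "context", "mc", "cov"])
    return MethCallTable(nucleus_id, df)
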