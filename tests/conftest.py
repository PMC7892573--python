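"""Shared fixtures: small seeded simulations and toy-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epidiff.methylome import MethylTable
from epidiff.simulate import SimConfig, make_genome, make_methylomes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast cohort: one 300 kb chromosome, 8 spikes per context."""
    return SimConfig(
        seed=11, n_chrom=1, chrom_len=300_000, n_genes=12,
        n_samples_per_group=(6, 7), n_spiked_dmrs_per_context=8,
        dmr_delta=0.20,  # small cohorts need the larger shift for power
        n_spiked_transitions=6, n_target_windows=0, spike_cluster_frac=0.0,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return make_genome(small_cfg)


@pytest.fixture(scope="session")
def small_methylomes(small_cfg, small_genome):
    """(table, meta, truth) for the small cohort."""
    return make_methylomes(small_cfg, small_genome)


def toy_table(records, samples=None) -> MethylTable:
    """Build a MethylTable from (chrom, pos, strand, context, meth_row, total_row)."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in records],
        columns=["chrom", "pos", "strand", "context"],
    )
    meth = np.array([r[4] for r in records])
    total = np.array([r[5] for r in records])
    if samples is None:
        samples = [f"s{i}" for i in range(meth.shape[1])]
    return MethylTable(sites, meth, total, samples)
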