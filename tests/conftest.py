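import numpy as np
import pandas as pd
import pytest

from crispra_context import (SimConfig, simulate_genome,
                             simulate_reporter_pool, simulate_counts,
                             compute_expression_scores, score_matrix,
                             normalize_median_of_ratios)


@pytest.fixture(scope="session")
def small_config():
    """Compact genome for unit tests; study-condition parameters otherwise."""
    return SimConfig(seed=11, n_chromosomes=2, chrom_length=300_000,
                     n_insertions=400)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_pool(small_genome, small_config):
    return simulate_reporter_pool(small_genome, small_config)


@pytest.fixture(scope="session")
def paired_counts(small_pool, small_config):
    """Control + VPR count tables at day 0."""
    return pd.concat([simulate_counts(small_pool, small_config, cond, 0)
                      for cond in ("control", "VPR")], ignore_index=True)


@pytest.fixture(scope="session")
def normalized_day0(paired_counts):
    """Normalized per-barcode scores for both conditions at day 0."""
    prof = compute_expression_scores(paired_counts)
    out = {}
    for cond in ("control", "VPR"):
        mat = score_matrix(prof[prof.condition == cond])
        _, norm = normalize_median_of_ratios(mat)
        out[cond] = norm.mean(axis=1)
    return out
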