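"""Synthetic-data generator: tiling, determinism, ground-truth semantics."""

import numpy as np
import pandas as pd
import pytest

from crispra_context import (SimConfig, simulate_genome,
                             simulate_reporter_pool, simulate_reads,
                             simulate_counts, simulate_sc_dataset,
                             simulate_nb_cells, default_design)
from crispra_context.config import STATES, UPSTREAM_ANCHOR, DOWNSTREAM_ANCHOR
from crispra_context.scsim import _nb_draws


def test_segmentation_tiles_chromosomes(small_genome, small_config):
    seg = small_genome.segmentation
    for chrom, size in small_genome.chrom_sizes.items():
        sub = seg[seg.chrom == chrom].sort_values("start")
        assert sub.start.iloc[0] == 0
        assert sub.end.iloc[-1] == size
        # contiguous, non-overlapping
        assert (sub.end.to_numpy()[:-1] == sub.start.to_numpy()[1:]).all()
        assert (sub.end - sub.start).sum() == size


def test_same_seed_identical_outputs(small_config):
    g1 = simulate_genome(small_config)
    g2 = simulate_genome(small_config)
    pd.testing.assert_frame_equal(g1.segmentation, g2.segmentation)
    assert g1.sequences == g2.sequences
    p1 = simulate_reporter_pool(g1, small_config)
    p2 = simulate_reporter_pool(g2, small_config)
    pd.testing.assert_frame_equal(p1.truth, p2.truth)
    c1 = simulate_counts(p1, small_config, "control", 0)
    c2 = simulate_counts(p2, small_config, "control", 0)
    pd.testing.assert_frame_equal(c1, c2)


def test_state_counts_binomial():
    """With many segments, per-state counts stay within 3 binomial sd."""
    cfg = SimConfig(seed=3, n_chromosomes=2, chrom_length=2_000_000,
                    segment_length_mean=400)
    seg = simulate_genome(cfg).segmentation
    from crispra_context.config import STATE_PROBS
    n = len(seg)
    counts = seg.state.value_counts()
    total_p = sum(STATE_PROBS.values())
    for s in STATES:
        p = STATE_PROBS[s] / total_p
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts.get(s, 0) - n * p) < 3 * sd + 1


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(segment_length_mean=10 ** 9).validate()
    with pytest.raises(ValueError):
        SimConfig(frac_silent=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(at_bias_strength=-1).validate()


def test_at_bias_direction(small_genome):
    """Insertions are AT-enriched relative to the genome under bias, and
    not under zero bias."""
    cfg0 = SimConfig(seed=7, n_chromosomes=2, chrom_length=300_000,
                     n_insertions=400, at_bias_strength=0.0)
    cfgb = SimConfig(seed=7, n_chromosomes=2, chrom_length=300_000,
                     n_insertions=400, at_bias_strength=1.5)
    genome = simulate_genome(cfg0)
    genome_at = float(np.mean(np.concatenate(
        [genome.at_field[c] for c in genome.at_field])))
    unbiased = simulate_reporter_pool(genome, cfg0).truth.local_at.mean()
    biased = simulate_reporter_pool(genome, cfgb).truth.local_at.mean()
    assert abs(unbiased - genome_at) < 0.01
    assert biased > genome_at + 0.01


def test_pool_size_and_barcode_uniqueness(small_pool, small_config):
    truth = small_pool.truth
    assert len(truth) == small_config.n_insertions
    assert truth.barcode.is_unique
    assert (truth.barcode.str.len() == small_config.barcode_length).all()


def test_silent_barcodes_have_zero_cdna(small_pool, small_config,
                                        paired_counts):
    silent = small_pool.truth.loc[small_pool.truth.silent, "barcode"]
    sub = paired_counts[paired_counts.barcode.isin(silent)
                        & (paired_counts.condition == "control")]
    assert (sub.cdna_count == 0).all()


def test_cdna_scale_linearity(small_pool, small_config):
    c1 = simulate_counts(small_pool, small_config, "control", 0)
    cfg2 = SimConfig(**{**small_config.to_dict(),
                        "cdna_depth_scale": 2 * small_config.cdna_depth_scale})
    c2 = simulate_counts(small_pool, cfg2, "control", 0)
    # gDNA untouched; mean cDNA doubles
    assert (c1.gdna_count == c2.gdna_count).all()
    m1, m2 = c1.cdna_count.mean(), c2.cdna_count.mean()
    assert m2 == pytest.approx(2 * m1, rel=0.05)


def test_low_basal_activated_more(small_pool):
    """Ground truth follows the decay law: fold activation is larger for
    weakly expressed reporters."""
    t = small_pool.truth[~small_pool.truth.silent]
    lb = np.log(t.basal_day0)
    low = t.log_fold_day0[lb < lb.quantile(0.3)]
    high = t.log_fold_day0[lb > lb.quantile(0.7)]
    assert low.mean() > high.mean()


def test_reads_reparse_to_barcode(small_pool, small_genome):
    cfg = SimConfig(seed=11, n_chromosomes=2, chrom_length=300_000,
                    n_insertions=400, malformed_read_frac=0.0,
                    ipcr_depth_mean=2.0)
    reads = simulate_reads(small_pool, small_genome, cfg)
    for enzyme, rr in reads.items():
        for rid, seq in rr[:500]:
            assert seq.startswith(UPSTREAM_ANCHOR)
            bc = seq[len(UPSTREAM_ANCHOR):len(UPSTREAM_ANCHOR) + 17]
            assert rid.split(":")[1] == bc
            assert seq[len(UPSTREAM_ANCHOR) + 17:].startswith(
                DOWNSTREAM_ANCHOR)


class TestScDataset:
    def test_count_conservation_and_truth(self):
        cfg = SimConfig(seed=9, cells_per_target=50)
        ds = simulate_sc_dataset(cfg, default_design(1, 1))
        X = np.asarray(ds.genes.X.todense())
        assert (X.sum(axis=1) == ds.obs.total_umi.to_numpy()).all()
        assert (X >= 0).all()
        # scramble/no-transfection cells are never in the active state
        ctrl = ds.obs.true_label.isin(["scramble", "no_transfection"])
        assert not ds.obs.loc[ctrl, "true_active"].any()

    def test_unknown_class_raises(self):
        cfg = SimConfig(seed=9, cells_per_target=10)
        with pytest.raises(ValueError):
            simulate_sc_dataset(cfg, {"T_bad": "E99"})

    def test_pool_ratio(self):
        cfg = SimConfig(seed=9, cells_per_target=90)
        ds = simulate_sc_dataset(cfg, default_design(1, 0))  # 10 targets
        counts = ds.obs.true_label.value_counts()
        assert counts["scramble"] == 50  # 5:90 of 900 on-target cells
        assert counts["no_transfection"] == 50


class TestNBGroundTruth:
    def test_degenerate_pi_zero_mean(self):
        cells = simulate_nb_cells({"c": -13.49}, {"c": 3.94}, {"c": 2.0},
                                  {"c": 0.0}, 50_000, 0,
                                  (np.log(10_000.0), 0.0), seed=2)
        expected = np.exp(-13.49 + np.log(10_000.0))
        assert not cells.true_active.any()
        assert cells.y.mean() == pytest.approx(expected, abs=3 * np.sqrt(
            expected * (1 + expected / 2.0) / 50_000))

    def test_nb_moments(self):
        """Simulated counts match mean exp(b0+ba*z+log N) and variance
        mu + mu^2/theta within 3 se at n = 50,000."""
        rng = np.random.default_rng(4)
        mu, theta = 5.0, 2.0
        draws = _nb_draws(rng, np.full(50_000, mu), np.full(50_000, theta))
        var = mu + mu ** 2 / theta
        se_mean = np.sqrt(var / 50_000)
        assert draws.mean() == pytest.approx(mu, abs=3 * se_mean)
        # se of the sample variance via the fourth moment
        m4 = ((draws - draws.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - var ** 2) / 50_000)
        assert draws.var() == pytest.approx(var, abs=3 * se_var)

    def test_poisson_limit(self):
        """theta -> infinity: variance/mean ratio -> 1 on 50,000 draws."""
        rng = np.random.default_rng(5)
        draws = _nb_draws(rng, np.full(50_000, 5.0), np.full(50_000, 1e9))
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)
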