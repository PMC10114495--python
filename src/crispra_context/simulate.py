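"""Reporter-pool, inverse-PCR read and amplicon count simulation.

The generator draws AT-biased insertion positions over the synthetic
genome, assigns each barcode a basal expression from its chromatin state,
a differentiation trajectory with shared per-TAD shifts, and a CRISPRa
fold activation following an exponential decay in log basal expression
plus state-specific deviations (bivalent boost, H3K9me3 damping).  From
this ground truth it emits inverse-PCR FASTQ reads per restriction enzyme
and gDNA/cDNA amplicon count tables per condition, timepoint and
replicate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (SimConfig, STATES, ENZYMES, UPSTREAM_ANCHOR,
                     DOWNSTREAM_ANCHOR)
from .genome import GenomeContext, AT_BIN

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

TIMEPOINTS = (0, 2, 5)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _stream(config_seed: int, *keys) -> np.random.Generator:
    """Independent, deterministic RNG stream keyed by strings/ints."""
    ints = [config_seed]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


@dataclass
class ReporterPool:
    """Mapped barcodes plus the generator's ground truth."""

    truth: pd.DataFrame  # one row per barcode

    def __len__(self) -> int:
        return len(self.truth)


def _random_barcodes(rng: np.random.Generator, n: int, length: int,
                     max_retries: int = 50) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            bc = "".join(
                chr(b) for b in _BASES[rng.integers(0, 4, size=length)])
            if bc not in seen:
                break
        else:
            raise RuntimeError("barcode collision after max retries")
        seen.add(bc)
        out.append(bc)
    return out


def local_at_fraction(genome: GenomeContext, chrom: str, pos: int,
                      window: int = 100) -> float:
    """Realized A/T fraction of the sequence in a window centred on pos."""
    seq = genome.sequences[chrom]
    lo = max(0, pos - window // 2)
    hi = min(len(seq), pos + window // 2)
    sub = seq[lo:hi]
    return (sub.count("A") + sub.count("T")) / max(len(sub), 1)


def _interval_lookup(df: pd.DataFrame, chrom: str, positions: np.ndarray,
                     value_col: str, default):
    """Vectorized containment lookup in sorted non-overlapping intervals."""
    sub = df[df.chrom == chrom].sort_values("start")
    starts = sub.start.to_numpy()
    ends = sub.end.to_numpy()
    values = sub[value_col].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    out = np.full(len(positions), default, dtype=object)
    ok = (idx >= 0)
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < ends[idx[ok]]
    out[inside] = values[idx[inside]]
    return out


def simulate_reporter_pool(genome: GenomeContext,
                           config: SimConfig) -> ReporterPool:
    """Draw the reporter pool and its complete ground-truth table.

    Insertion probability is proportional to ``exp(at_bias_strength * z)``
    where ``z`` is the z-score of the local AT field, reproducing the
    piggyBac preference for AT-rich regions without real sequence data.
    """
    config.validate()
    rng = _stream(config.seed, "pool")

    # sampling weights over AT-field bins, pooled across chromosomes
    chroms = list(genome.chrom_sizes)
    all_at = np.concatenate([genome.at_field[c] for c in chroms])
    mu, sd = all_at.mean(), all_at.std()
    weights, bin_chrom, bin_off = [], [], []
    for c in chroms:
        at = genome.at_field[c]
        weights.append(np.exp(config.at_bias_strength * (at - mu) / sd))
        bin_chrom.extend([c] * len(at))
        bin_off.extend(range(len(at)))
    weights = np.concatenate(weights)
    weights = weights / weights.sum()

    n = config.n_insertions
    pick = rng.choice(len(weights), size=n, p=weights)
    offsets = rng.integers(0, AT_BIN, size=n)
    rows = []
    used_pos: set[tuple[str, int]] = set()
    barcodes = _random_barcodes(rng, n, config.barcode_length)
    for i in range(n):
        chrom = bin_chrom[pick[i]]
        pos = bin_off[pick[i]] * AT_BIN + int(offsets[i])
        pos = min(pos, genome.chrom_sizes[chrom] - config.flank_length - 1)
        pos = max(pos, config.flank_length)
        while (chrom, pos) in used_pos:
            pos += 1
        used_pos.add((chrom, pos))
        rows.append((barcodes[i], chrom, pos,
                     "+" if rng.random() < 0.5 else "-"))
    truth = pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "strand"])

    # chromatin / TAD / annotation context
    states, tad_ids, annots, at_local = [], [], [], []
    for chrom, grp in truth.groupby("chrom", sort=False):
        pos = grp.pos.to_numpy()
        states.append(pd.Series(
            _interval_lookup(genome.segmentation, chrom, pos, "state", "E7"),
            index=grp.index))
        tad_ids.append(pd.Series(
            _interval_lookup(genome.tads, chrom, pos, "tad_id", ""),
            index=grp.index))
    truth["state"] = pd.concat(states).reindex(truth.index).astype(str)
    truth["tad_id"] = pd.concat(tad_ids).reindex(truth.index).astype(str)
    truth["tad_status"] = np.where(truth.tad_id != "", "intraTAD", "interTAD")
    truth["annotation"] = [
        genome.annotation_class(c, p) for c, p in zip(truth.chrom, truth.pos)]
    truth["local_at"] = [
        local_at_fraction(genome, c, p) for c, p in zip(truth.chrom, truth.pos)]

    # basal expression and differentiation dynamics
    silent = rng.random(n) < config.frac_silent
    mu_s = truth.state.map(config.basal_mu_by_state).to_numpy(float)
    sd_s = truth.state.map(config.basal_sigma_by_state).to_numpy(float)
    log_basal0 = mu_s + sd_s * rng.standard_normal(n)
    trend = config.dynamics_trend_sd * rng.standard_normal(n)

    tad_shift = {}
    for t in TIMEPOINTS[1:]:
        for tid in truth.tad_id.unique():
            if tid:
                tad_shift[(tid, t)] = \
                    config.tad_shift_sd * rng.standard_normal()
    for t in TIMEPOINTS:
        frac = t / TIMEPOINTS[-1]
        shift = np.array([tad_shift.get((tid, t), 0.0)
                          for tid in truth.tad_id])
        noise = (config.timepoint_noise_sd * rng.standard_normal(n)
                 if t > 0 else 0.0)
        logx = log_basal0 + frac * trend + shift + noise
        truth[f"basal_day{t}"] = np.where(silent, 0.0, np.exp(logx))
    truth["silent"] = silent

    # CRISPRa fold activation (natural-log scale), per stage
    A, k, C = config.decay_params
    dev = truth.state.map(config.state_deviation_by_state).to_numpy(float)
    for t in (0, TIMEPOINTS[-1]):
        basal = truth[f"basal_day{t}"].to_numpy()
        with np.errstate(divide="ignore"):
            lb = np.log(basal)
        lf = (A * np.exp(-k * lb) + C + dev
              + config.decay_noise_sd * rng.standard_normal(n))
        truth[f"log_fold_day{t}"] = np.where(silent, np.nan, lf)

    return ReporterPool(truth=truth)


def _malform(rng: np.random.Generator, barcode: str, flank: str) -> str:
    kind = rng.integers(0, 4)
    if kind == 0:  # short barcode
        return UPSTREAM_ANCHOR + barcode[:-1] + DOWNSTREAM_ANCHOR + flank
    if kind == 1:  # long barcode
        return UPSTREAM_ANCHOR + barcode + "A" + DOWNSTREAM_ANCHOR + flank
    if kind == 2:  # missing upstream anchor
        return barcode + DOWNSTREAM_ANCHOR + flank
    return UPSTREAM_ANCHOR + barcode + flank  # missing downstream anchor


def simulate_reads(pool: ReporterPool, genome: GenomeContext,
                   config: SimConfig) -> dict[str, list[tuple[str, str]]]:
    """Inverse-PCR reads per enzyme as ``[(read_id, sequence), ...]``.

    Well-formed reads are ``upstream-anchor + barcode + downstream-anchor +
    genomic flank``; the flank is the sequence immediately downstream of
    the insertion in reporter orientation.  A configurable fraction of
    reads is malformed (wrong barcode length or missing anchor).
    """
    out: dict[str, list[tuple[str, str]]] = {}
    fl = config.flank_length
    for enzyme in ENZYMES:
        rng = _stream(config.seed, "reads", enzyme)
        reads = []
        for row in pool.truth.itertuples():
            if rng.random() > config.enzyme_detect_prob:
                continue
            n_reads = rng.poisson(config.ipcr_depth_mean)
            seq = genome.sequences[row.chrom]
            if row.strand == "+":
                flank = seq[row.pos:row.pos + fl]
            else:
                flank = revcomp(seq[row.pos - fl:row.pos])
            for j in range(n_reads):
                if rng.random() < config.malformed_read_frac:
                    read = _malform(rng, row.barcode, flank)
                else:
                    read = (UPSTREAM_ANCHOR + row.barcode
                            + DOWNSTREAM_ANCHOR + flank)
                reads.append((f"{enzyme}:{row.barcode}:{j}", read))
        out[enzyme] = reads
    return out


def simulate_counts(pool: ReporterPool, config: SimConfig,
                    condition: str = "control",
                    timepoint: int = 0) -> pd.DataFrame:
    """Amplicon count table for one condition at one timepoint.

    Per replicate, gDNA counts are Poisson around ``gdna_depth_mean`` with
    a per-barcode copy-number propensity and a per-replicate library-size
    factor; cDNA counts are Poisson with mean proportional to
    gDNA x expression.  Under the "VPR" condition expression is basal x
    fold activation from the decay-model ground truth.
    """
    truth = pool.truth
    n = len(truth)
    basal = truth[f"basal_day{timepoint}"].to_numpy()
    if condition == "VPR":
        lf = truth[f"log_fold_day{timepoint}"].to_numpy()
        expression = np.where(truth.silent, 0.0, basal * np.exp(lf))
    elif condition == "control":
        expression = basal
    else:
        raise ValueError(f"unknown condition {condition!r}")

    prop_rng = _stream(config.seed, "propensity")
    propensity = np.exp(
        config.barcode_propensity_sd * prop_rng.standard_normal(n))
    # separate streams keep gDNA invariant under cDNA-model changes
    rng_g = _stream(config.seed, "counts-gdna", condition, timepoint)
    rng_c = _stream(config.seed, "counts-cdna", condition, timepoint)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        g_factor = np.exp(
            config.replicate_factor_sd * rng_g.standard_normal())
        c_factor = np.exp(
            config.replicate_factor_sd * rng_c.standard_normal())
        gdna = rng_g.poisson(config.gdna_depth_mean * g_factor * propensity)
        lam = gdna * expression * config.cdna_depth_scale * c_factor
        cdna = rng_c.poisson(np.nan_to_num(lam))
        sample_id = f"{condition}_day{timepoint}_rep{rep}"
        for i in range(n):
            rows.append((truth.barcode.iloc[i], sample_id, condition,
                         timepoint, rep, int(gdna[i]), int(cdna[i])))
    return pd.DataFrame(rows, columns=[
        "barcode", "sample_id", "condition", "timepoint", "replicate",
        "gdna_count", "cdna_count"])


def simulate_reads_and_counts(pool: ReporterPool, genome: GenomeContext,
                              config: SimConfig, condition: str = "control",
                              timepoint: int = 0):
    """Convenience wrapper returning (FASTQ reads per enzyme, count table)."""
    return (simulate_reads(pool, genome, config),
            simulate_counts(pool, config, condition, timepoint))
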