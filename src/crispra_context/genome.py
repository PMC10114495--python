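"""Synthetic genome context: state segmentation, signal tracks, TADs, genes.

The genome is a stand-in for a real reference: random nucleotide sequence
with a smoothly varying AT-content field, a chromatin-state segmentation
that tiles each chromosome, per-mark signal tracks elevated within the
states that carry the mark, TAD intervals covering a configurable fraction
of the genome, and a sparse gene annotation with exon/intron structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import SimConfig, STATES, STATE_PROBS, STATE_EMISSIONS, MARKS

AT_BIN = 100  # resolution (bp) of the AT-content field


@dataclass
class GenomeContext:
    """In-memory genome annotation bundle used throughout the pipeline."""

    chrom_sizes: dict[str, int]
    segmentation: pd.DataFrame  # chrom, start, end, state (0-based half-open)
    tracks: dict[str, pd.DataFrame]  # mark -> chrom, start, end, value
    tads: pd.DataFrame  # chrom, start, end, tad_id
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id
    exons: pd.DataFrame  # chrom, start, end, gene_id
    sequences: dict[str, str] = field(default_factory=dict)
    at_field: dict[str, np.ndarray] = field(default_factory=dict)

    def annotation_class(self, chrom: str, pos: int) -> str:
        """Classify a position as exonic, intronic or intergenic."""
        ex = self.exons
        hit = ex[(ex.chrom == chrom) & (ex.start <= pos) & (pos < ex.end)]
        if len(hit):
            return "exonic"
        g = self.genes
        hit = g[(g.chrom == chrom) & (g.start <= pos) & (pos < g.end)]
        return "intronic" if len(hit) else "intergenic"


def _tile_segments(rng: np.random.Generator, length: int,
                   mean_len: float) -> np.ndarray:
    """Segment boundaries tiling [0, length) with ~exponential lengths."""
    n_guess = int(length / mean_len * 2) + 10
    lens = np.maximum(1, rng.exponential(mean_len, size=n_guess).astype(int))
    ends = np.cumsum(lens)
    ends = ends[ends < length]
    return np.concatenate([[0], ends, [length]])


def _simulate_sequence(rng: np.random.Generator, length: int
                       ) -> tuple[str, np.ndarray]:
    """Random sequence whose local AT fraction follows a smooth field."""
    n_bins = (length + AT_BIN - 1) // AT_BIN
    noise = gaussian_filter1d(rng.standard_normal(n_bins), sigma=20.0)
    noise = (noise - noise.mean()) / noise.std()
    at = np.clip(0.59 + 0.05 * noise, 0.30, 0.90)
    p_at = np.repeat(at, AT_BIN)[:length]
    u = rng.random(length)
    v = rng.random(length)
    # A/T with prob p_at, split evenly inside each pair
    bases = np.where(u < p_at,
                     np.where(v < 0.5, ord("A"), ord("T")),
                     np.where(v < 0.5, ord("C"), ord("G")))
    seq = bases.astype(np.uint8).tobytes().decode("ascii")
    return seq, at


def simulate_genome(config: SimConfig) -> GenomeContext:
    """Generate the full genome context for a :class:`SimConfig`.

    The segmentation tiles each chromosome exactly; each mark's track is the
    state emission level (with multiplicative noise) inside segments of the
    states carrying that mark, plus a small background.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chromosomes)}
    state_p = np.array([STATE_PROBS[s] for s in STATES])
    state_p = state_p / state_p.sum()

    seg_rows, track_rows, tad_rows = [], {m: [] for m in MARKS}, []
    gene_rows, exon_rows = [], []
    sequences, at_field = {}, {}
    tad_id = 0
    gene_id = 0
    for chrom, size in chrom_sizes.items():
        seq, at = _simulate_sequence(rng, size)
        sequences[chrom] = seq
        at_field[chrom] = at

        bounds = _tile_segments(rng, size, config.segment_length_mean)
        states = rng.choice(len(STATES), size=len(bounds) - 1, p=state_p)
        for i in range(len(bounds) - 1):
            s = STATES[states[i]]
            seg_rows.append((chrom, int(bounds[i]), int(bounds[i + 1]), s))
            emit = STATE_EMISSIONS[s]
            for mark in MARKS:
                level = emit.get(mark, 0.0)
                value = level * (0.5 + rng.exponential(0.5)) \
                    + 0.05 * rng.exponential(1.0)
                track_rows[mark].append(
                    (chrom, int(bounds[i]), int(bounds[i + 1]), float(value)))

        # TADs: alternate TAD / gap so that TADs cover ~tad_fraction
        f = config.tad_fraction
        gap_mean = config.tad_length_mean * (1 - f) / max(f, 1e-9)
        pos = int(rng.exponential(gap_mean / 2))
        while pos < size:
            tlen = max(5_000, int(rng.exponential(config.tad_length_mean)))
            end = min(pos + tlen, size)
            tad_rows.append((chrom, pos, end, f"tad{tad_id}"))
            tad_id += 1
            pos = end + max(1_000, int(rng.exponential(gap_mean)))

        # genes: sequential placement with exponential gaps and lengths
        n_genes = max(1, size // config.gene_density_bp)
        gap = size / n_genes
        pos = int(rng.exponential(gap / 2))
        while pos < size - 1_000:
            glen = min(max(2_000, int(rng.exponential(20_000))), size - pos)
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene{gene_id}"
            gene_rows.append((chrom, pos, pos + glen, strand, name))
            # one exon every ~3 kb, 150 bp each, first exon at the 5' end
            for estart in range(pos, pos + glen, 3_000):
                eend = min(estart + 150, pos + glen)
                exon_rows.append((chrom, estart, eend, name))
            gene_id += 1
            pos = pos + glen + max(1_000, int(rng.exponential(gap)))

    segmentation = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "state"])
    tracks = {m: pd.DataFrame(r, columns=["chrom", "start", "end", "value"])
              for m, r in track_rows.items()}
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "tad_id"])
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])
    return GenomeContext(chrom_sizes, segmentation, tracks, tads, genes,
                         exons, sequences, at_field)
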