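"""Simulation configuration for the synthetic reporter / CRISPRa data generator.

The defaults describe a small diploid-agnostic genome segmented into ten
chromatin states, a piggyBac-style reporter pool with AT-biased insertion,
and a single-cell CRISPRa experiment with direct guide capture.  State
frequencies, silent fraction, pool ratios and the guides-per-cell
multiplicity marginals follow the reporter-assay study conditions; see
docs/methods.md for the rationale behind each default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: Chromatin-state labels.  Numbering follows the convention that E2 is the
#: active-enhancer state (H3K27ac + H3K4me1), E6 is bivalent (H3K4me3 +
#: H3K27me3), E7 is quiescent and E9 is the ZNF/repeat H3K9me3 state.
STATES = (
    "E1",  # generic enhancer
    "E2",  # active enhancer
    "E3",  # weak enhancer
    "E4",  # flanking TSS upstream
    "E5",  # flanking TSS downstream
    "E6",  # bivalent
    "E7",  # quiescent
    "E8",  # polycomb repressed
    "E9",  # ZNF genes & repeats (H3K9me3)
    "E10",  # strong transcription
)

STATE_NAMES = {
    "E1": "generic_enhancer",
    "E2": "active_enhancer",
    "E3": "weak_enhancer",
    "E4": "flank_tss_upstream",
    "E5": "flank_tss_downstream",
    "E6": "bivalent",
    "E7": "quiescent",
    "E8": "polycomb_repressed",
    "E9": "znf_repeats",
    "E10": "strong_transcription",
}

#: Histone marks carried by the synthetic signal tracks.
MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K27me3", "H3K9me3")

#: Emission levels: mean track signal of each mark inside each state.
STATE_EMISSIONS = {
    "E1": {"H3K4me1": 0.6},
    "E2": {"H3K27ac": 0.9, "H3K4me1": 0.8},
    "E3": {"H3K4me1": 0.5},
    "E4": {"H3K4me3": 0.9, "H3K27ac": 0.5},
    "E5": {"H3K4me3": 0.8, "H3K36me3": 0.4},
    "E6": {"H3K4me3": 0.8, "H3K27me3": 0.8},
    "E7": {},
    "E8": {"H3K27me3": 0.9},
    "E9": {"H3K9me3": 0.9},
    "E10": {"H3K36me3": 0.9},
}

#: Genome-fraction of each state.  Proportions mirror the per-state reporter
#: counts observed in the assay (quiescent chromatin dominates).
STATE_PROBS = {
    "E1": 0.0063,
    "E2": 0.0334,
    "E3": 0.0905,
    "E4": 0.0567,
    "E5": 0.0282,
    "E6": 0.0176,
    "E7": 0.7205,
    "E8": 0.0082,
    "E9": 0.0062,
    "E10": 0.0324,
}

ENZYMES = ("TatI", "MspI")

#: Read structure anchors flanking the 17-nt barcode in inverse-PCR reads.
UPSTREAM_ANCHOR = "ACGCTGAACTTGTGGCCGTT"
DOWNSTREAM_ANCHOR = "TGCTAGCTTGCCAAACCTAC"


def _per_state(values: dict[str, float]) -> dict[str, float]:
    missing = set(STATES) - set(values)
    if missing:
        raise ValueError(f"missing states: {sorted(missing)}")
    return dict(values)


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the study conditions: ~2,900 insertions over a
    state-segmented genome, 48.7% silent reporters, an exponential-decay
    activation law with a bivalent boost and H3K9me3 damping, and a
    single-cell layout with 5 guides per target mixed at a
    no-transfection : scramble : on-target ratio of 5:5:90.
    """

    seed: int = 0

    # genome
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_states: int = 10
    segment_length_mean: int = 2_000
    tad_fraction: float = 0.4
    tad_length_mean: int = 80_000
    gene_density_bp: int = 50_000  # one gene per this many bp on average

    # reporter pool
    n_insertions: int = 2_923
    at_bias_strength: float = 1.0
    barcode_length: int = 17
    frac_silent: float = 0.487

    # basal expression (natural-log scale of the cDNA/gDNA expression score)
    basal_mu_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": -1.5, "E2": -0.5, "E3": -2.0, "E4": 0.5, "E5": 0.3,
        "E6": -3.0, "E7": -4.0, "E8": -3.5, "E9": -3.5, "E10": -0.5,
    }))
    basal_sigma_by_state: dict = field(default_factory=lambda: _per_state(
        {s: 1.0 for s in STATES}))

    # temporal dynamics (iPSC day0 -> iNeuron day5)
    dynamics_trend_sd: float = 1.2
    tad_shift_sd: float = 0.5
    timepoint_noise_sd: float = 0.3

    # CRISPRa activation: log fold = A*exp(-k*log basal) + C + dev + noise
    decay_params: tuple = (0.15, 0.45, 0.05)
    decay_noise_sd: float = 0.35
    state_deviation_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": 0.0, "E2": 0.0, "E3": 0.0, "E4": 0.0, "E5": 0.0,
        "E6": 1.0, "E7": 0.0, "E8": 0.0, "E9": -0.5, "E10": 0.0,
    }))

    # sequencing depth for the amplicon count tables
    gdna_depth_mean: float = 200.0
    cdna_depth_scale: float = 1.0
    n_replicates: int = 4
    barcode_propensity_sd: float = 0.3  # per-barcode copy-number spread (log)
    replicate_factor_sd: float = 0.2  # per-replicate library-size spread (log)

    # inverse-PCR genotyping reads
    ipcr_depth_mean: float = 50.0
    flank_length: int = 30
    malformed_read_frac: float = 0.05
    enzyme_detect_prob: float = 0.87

    # single-cell CRISPRa experiment
    nb_beta0_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": -12.8, "E2": -12.3, "E3": -13.0, "E4": -11.5, "E5": -11.7,
        "E6": -13.5, "E7": -14.0, "E8": -13.6, "E9": -13.5, "E10": -12.5,
    }))
    nb_beta_act_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": 2.5, "E2": 3.5, "E3": 2.5, "E4": 1.5, "E5": 1.5,
        "E6": 3.9, "E7": 2.5, "E8": 3.0, "E9": 1.0, "E10": 2.0,
    }))
    nb_theta_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": 1.0, "E2": 2.0, "E3": 1.0, "E4": 2.0, "E5": 2.0,
        "E6": 0.8, "E7": 0.5, "E8": 0.5, "E9": 0.5, "E10": 2.0,
    }))
    nb_pi_by_state: dict = field(default_factory=lambda: _per_state({
        "E1": 0.6, "E2": 0.8, "E3": 0.6, "E4": 0.8, "E5": 0.8,
        "E6": 0.7, "E7": 0.4, "E8": 0.4, "E9": 0.25, "E10": 0.7,
    }))
    total_umi_lognormal: tuple = (np.log(10_000.0), 0.3)
    cells_per_target: int = 300
    pool_ratio: tuple = (5, 5, 90)  # no transfection : scramble : on-target
    guides_per_target: int = 5
    # P(0..8 guides/cell) among transfected cells; marginals chosen so that
    # the observed per-cell multiplicity reproduces ~6% zero, ~81% 1-5 and
    # ~13% >5 guides
    guide_multiplicity_probs: tuple = (
        0.061, 0.10, 0.18, 0.22, 0.18, 0.1327, 0.06, 0.04, 0.0263)
    guide_contamination: float = 0.02
    n_background_genes: int = 100
    n_mito_genes: int = 5
    mito_beta: tuple = (4.0, 60.0)  # Beta(a, b): mean ~6%, tail past 10%
    doublet_frac: float = 0.02
    guide_umi_mean: float = 100.0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be positive")
        if self.segment_length_mean < 1:
            raise ValueError("segment lengths must be >= 1 bp")
        if self.segment_length_mean >= self.chrom_length:
            raise ValueError("segment mean must be smaller than chromosomes")
        if self.n_states != len(STATES):
            raise ValueError(f"n_states must be {len(STATES)}")
        if not 0.0 <= self.frac_silent <= 1.0:
            raise ValueError("frac_silent must be a probability")
        if self.at_bias_strength < 0:
            raise ValueError("at_bias_strength must be >= 0")
        probs = np.asarray(self.guide_multiplicity_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("guide_multiplicity_probs must be a distribution")
        for s in STATES:
            if self.nb_theta_by_state[s] <= 0:
                raise ValueError("dispersions must be > 0")
            if not 0.0 <= self.nb_pi_by_state[s] <= 1.0:
                raise ValueError("pi must be a probability")

    def to_dict(self) -> dict:
        return asdict(self)
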