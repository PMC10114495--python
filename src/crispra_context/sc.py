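"""Single-cell CRISPRa processing: guide assignment, QC, activation tests.

A cell is assigned a perturbation when it carries 1-5 detected guides,
all from the 5-guide set of one target (cells with >5 guides or guides
spanning several sets are excluded; 0 guides leaves the cell
unassigned).  QC removes doublets and cells above the mitochondrial
fraction cutoff; counts are scaled to a fixed total per cell.  Per
target, activation is tested with Welch's t on normalized target-gene
expression (on-target vs scramble cells) with Bonferroni correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scanpy as scpy
from scipy import stats

from .scsim import ScDataset

MITO_MAX_DEFAULT = 0.10
NORM_TARGET = 10_000.0
MIN_CELLS_DEFAULT = 40

SIG_BANDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def significance_band(p: float) -> str:
    for cut, label in SIG_BANDS:
        if p <= cut:
            return label
    return "ns"


def assign_perturbations(dataset: ScDataset,
                         min_guide_umi: int = 1) -> pd.DataFrame:
    """Perturbation label per cell plus the guide-multiplicity summary.

    Returns a DataFrame indexed like the cells with columns
    ``perturbation`` (target, "scramble", "unassigned" or "excluded")
    and ``n_guides``, and attaches the multiplicity fractions
    (0, 1-5, >5 guides) in ``df.attrs["multiplicity"]``.
    """
    guide_target = dataset.guide_sets.set_index("guide_id")["target"]
    var_ids = list(dataset.guides.var_names)
    unknown = set(var_ids) - set(guide_target.index)
    if unknown:
        raise ValueError(f"guides not in any set: {sorted(unknown)[:5]}")
    targets_per_guide = guide_target.reindex(var_ids).to_numpy()

    X = dataset.guides.X
    present = (X >= min_guide_umi)
    present = present.toarray() if hasattr(present, "toarray") else present
    n_guides = present.sum(axis=1).astype(int)

    labels = np.empty(len(n_guides), dtype=object)
    for i in range(len(n_guides)):
        m = n_guides[i]
        if m == 0:
            labels[i] = "unassigned"
        elif m > 5:
            labels[i] = "excluded"
        else:
            sets = set(targets_per_guide[present[i]])
            labels[i] = sets.pop() if len(sets) == 1 else "excluded"
    out = pd.DataFrame({"perturbation": labels, "n_guides": n_guides},
                       index=dataset.guides.obs_names)
    n = len(out)
    out.attrs["multiplicity"] = {
        "frac_0": float((n_guides == 0).mean()),
        "frac_1_5": float(((n_guides >= 1) & (n_guides <= 5)).mean()),
        "frac_gt5": float((n_guides > 5).mean()),
        "n_cells": n,
    }
    return out


def qc_and_normalize(dataset: ScDataset, mito_max: float = MITO_MAX_DEFAULT,
                     scale: float = NORM_TARGET):
    """Filter cells (mito fraction, doublets, empty) and normalize each
    cell's counts to ``scale`` total. Returns an AnnData with raw counts
    in ``layers['counts']`` and normalized values in ``X``."""
    adata = dataset.genes.copy()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = np.ones(adata.n_obs, dtype=bool)
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} cells with zero total "
                      "UMI removed")
        keep &= totals > 0
    keep &= adata.obs["mito_frac"].to_numpy() <= mito_max
    if "doublet" in adata.obs:
        keep &= ~adata.obs["doublet"].to_numpy()
    adata = adata[keep].copy()
    adata.layers["counts"] = adata.X.copy()
    scpy.pp.normalize_total(adata, target_sum=scale)
    return adata


def activation_tests(adata, assignments: pd.DataFrame,
                     targets: list[str] | None = None,
                     min_cells: int = MIN_CELLS_DEFAULT) -> pd.DataFrame:
    """Welch's t test of on-target vs scramble normalized expression per
    target, Bonferroni-corrected over the tested targets.

    Also reports the fraction of zero raw counts in each group and the
    percentile rank of the on-target mean among the per-gene mean
    normalized expression of all genes in scramble cells.
    """
    pert = assignments.reindex(adata.obs_names)["perturbation"]
    scr_mask = (pert == "scramble").to_numpy()
    if scr_mask.sum() < 2:
        raise ValueError("need >= 2 scramble cells")
    if targets is None:
        targets = sorted(set(pert.unique())
                         - {"scramble", "unassigned", "excluded",
                            "no_transfection"})
    X = adata.X
    raw = adata.layers["counts"]
    gene_index = {g: i for i, g in enumerate(adata.var_names)}

    # per-gene mean normalized expression in scramble cells -> percentile
    scr_gene_means = np.asarray(X[scr_mask].mean(axis=0)).ravel()

    rows = []
    skipped = []
    for target in targets:
        if target not in gene_index:
            raise ValueError(f"target gene {target} absent from matrix")
        on_mask = (pert == target).to_numpy()
        if on_mask.sum() < min_cells:
            skipped.append(target)
            continue
        j = gene_index[target]
        x_on = np.asarray(X[on_mask, j].todense()).ravel() \
            if hasattr(X, "todense") else X[on_mask, j]
        x_scr = np.asarray(X[scr_mask, j].todense()).ravel() \
            if hasattr(X, "todense") else X[scr_mask, j]
        r_on = np.asarray(raw[on_mask, j].todense()).ravel() \
            if hasattr(raw, "todense") else raw[on_mask, j]
        r_scr = np.asarray(raw[scr_mask, j].todense()).ravel() \
            if hasattr(raw, "todense") else raw[scr_mask, j]
        t, p = stats.ttest_ind(x_on, x_scr, equal_var=False)
        pr = float(stats.percentileofscore(scr_gene_means, x_on.mean()))
        rows.append({
            "target": target,
            "n_cells": int(on_mask.sum()),
            "mean_on": float(x_on.mean()),
            "mean_scramble": float(x_scr.mean()),
            "welch_t": float(t),
            "p_raw": float(p),
            "zero_fraction_on": float((r_on == 0).mean() * 100),
            "zero_fraction_control": float((r_scr == 0).mean() * 100),
            "percentile_rank": pr,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out.p_raw * len(out), 1.0)
        out["significance_class"] = out.p_bonferroni.map(significance_band)
    out.attrs["skipped_low_cells"] = skipped
    return out
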