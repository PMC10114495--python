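"""Reporter expression scores, normalization, dynamics groups, safe harbors.

The expression score of a barcode in one biological replicate is
sum(cDNA counts) / sum(gDNA counts).  Barcodes with fewer than 100 total
reads in a replicate are too shallow to score.  Samples are put on a
common scale with median-of-ratios size factors (a geometric-mean
pseudo-reference, as in bulk count normalization).  Differentiation
dynamics are classified from the day5/day0 fold change: turned off
(group 1, fc < 0.5), always on (group 2, 0.5 <= fc <= 2), turned on
(group 3, fc > 2) and constitutively silent (group 4, undetectable at
either stage).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

LOW_COVERAGE_MIN = 100  # min gDNA+cDNA reads per barcode x replicate
#: display-only pseudocount for non-expressed barcodes (never used in
#: classification)
DISPLAY_PSEUDOCOUNT = 1e-5


def compute_expression_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode, per-sample expression scores from a count table.

    ``counts`` must have columns barcode, sample_id, condition, timepoint,
    replicate, gdna_count, cdna_count.  Rows of one barcode within one
    sample are summed before the ratio is taken.
    """
    if (counts.gdna_count < 0).any() or (counts.cdna_count < 0).any():
        raise ValueError("counts must be non-negative")
    agg = counts.groupby(
        ["barcode", "sample_id", "condition", "timepoint", "replicate"],
        as_index=False)[["gdna_count", "cdna_count"]].sum()
    total = agg.gdna_count + agg.cdna_count
    agg["low_coverage"] = total < LOW_COVERAGE_MIN
    with np.errstate(divide="ignore", invalid="ignore"):
        score = agg.cdna_count / agg.gdna_count
    bad = (agg.gdna_count == 0) & (agg.cdna_count > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} barcode/sample pairs have cDNA but "
                      "no gDNA; score reported as missing")
    score = score.where(~bad & (agg.gdna_count > 0))
    agg["expression_score"] = score.where(~agg.low_coverage)
    agg["detectable"] = (agg.cdna_count > 0) & ~agg.low_coverage
    return agg


def score_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pivot profiles to a barcode x sample matrix of expression scores."""
    return profiles.pivot_table(index="barcode", columns="sample_id",
                                values="expression_score", aggfunc="first")


def normalize_median_of_ratios(matrix: pd.DataFrame):
    """Median-of-ratios size factors and the normalized matrix.

    The pseudo-reference is the per-barcode geometric mean over samples,
    computed on barcodes with a positive score in every sample.  The size
    factor of a sample is the median ratio of its scores to the
    reference; normalized scores are raw scores divided by the factor.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    ok = np.all(np.isfinite(vals) & (vals > 0), axis=1)
    if not ok.any():
        raise ValueError("no barcode with a positive score in every sample")
    ref = np.exp(np.log(vals[ok]).mean(axis=1))
    factors = np.median(vals[ok] / ref[:, None], axis=0)
    normalized = matrix / factors
    return pd.Series(factors, index=matrix.columns, name="size_factor"), \
        normalized


def classify_dynamics(day0: pd.Series, day5: pd.Series,
                      gdna_present: pd.Series | None = None) -> pd.DataFrame:
    """Group barcodes by their day5/day0 normalized expression fold change.

    ``day0``/``day5`` are normalized scores indexed by barcode; NaN or 0
    means undetectable at that stage.  Barcodes undetectable at either
    stage but present in gDNA form group 4; barcodes without gDNA
    evidence are dropped with a warning.  The z-score is computed within
    groups 1-3 on the natural log of the fold change.
    """
    barcodes = day0.index.union(day5.index)
    if gdna_present is None:
        gdna_present = pd.Series(True, index=barcodes)
    d0 = day0.reindex(barcodes)
    d5 = day5.reindex(barcodes)
    detect0 = d0.notna() & (d0 > 0)
    detect5 = d5.notna() & (d5 > 0)

    drop = ~(detect0 & detect5) & ~gdna_present.reindex(barcodes).fillna(False)
    if drop.any():
        warnings.warn(f"{int(drop.sum())} barcodes lack gDNA evidence and "
                      "were dropped from dynamics classification")

    fc = (d5 / d0).where(detect0 & detect5)
    group = pd.Series(4, index=barcodes, dtype=int)
    both = detect0 & detect5
    group[both & (fc < 0.5)] = 1
    group[both & (fc >= 0.5) & (fc <= 2.0)] = 2
    group[both & (fc > 2.0)] = 3

    out = pd.DataFrame({"barcode": barcodes, "fc_day5_day0": fc.values,
                        "group": group.values}).set_index("barcode")
    out = out[~drop.values]
    out["zscore"] = np.nan
    for g in (1, 2, 3):
        sel = out.group == g
        if sel.sum() >= 2:
            logfc = np.log(out.loc[sel, "fc_day5_day0"])
            sd = logfc.std(ddof=1)
            if sd > 0:
                out.loc[sel, "zscore"] = (logfc - logfc.mean()) / sd
    return out.reset_index()


def select_safe_harbors(pool: pd.DataFrame, counts: pd.DataFrame,
                        dynamics: pd.DataFrame,
                        annotations: pd.Series) -> pd.DataFrame:
    """Nominate putative safe-harbor insertion sites.

    Filters: total gDNA >= 20 and total cDNA >= 20; inverse-PCR mapping
    read count >= 30; unambiguously mapped to a single site (pool rows
    are already unambiguous); intronic or intergenic annotation.  The
    dynamics group is reported so that constitutive (group 2) candidates
    are identifiable, but it is not a hard filter.
    """
    totals = counts.groupby("barcode")[["gdna_count", "cdna_count"]].sum()
    out = pool.merge(totals, left_on="barcode", right_index=True, how="left")
    out[["gdna_count", "cdna_count"]] = \
        out[["gdna_count", "cdna_count"]].fillna(0)
    out = out[(out.gdna_count >= 20) & (out.cdna_count >= 20)
              & (out.read_count >= 30)]
    out = out.assign(annotation=out.barcode.map(annotations))
    out = out[out.annotation.isin(["intronic", "intergenic"])]
    grp = dynamics.set_index("barcode")["group"] if len(dynamics) else {}
    out = out.assign(dynamics_group=out.barcode.map(grp))
    return out.reset_index(drop=True)
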