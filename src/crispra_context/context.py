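"""Chromatin context around reporter insertions.

Relates per-barcode expression to histone-mark signal in windows around
the insertion site, to the chromatin-state segmentation, and to TAD
architecture (within-TAD expression correlation vs randomly sampled
cross-TAD pairs, Welch's t test).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def window_signal(track: pd.DataFrame, chrom: str, position: int,
                  half_width: int, chrom_size: int | None = None) -> float:
    """Sum of a bedGraph track over [position - hw, position + hw).

    Partial interval overlap contributes value x overlap length.  The
    window is clipped to the chromosome.
    """
    if chrom_size is not None and not 0 <= position < chrom_size:
        raise ValueError(f"position {position} outside {chrom}")
    lo = max(0, position - half_width)
    hi = position + half_width
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    sub = track[track.chrom == chrom]
    starts = sub.start.to_numpy()
    ends = sub.end.to_numpy()
    values = sub.value.to_numpy()
    overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
    pos_mask = overlap > 0
    return float((values[pos_mask] * overlap[pos_mask]).sum())


def window_signals(track: pd.DataFrame, insertions: pd.DataFrame,
                   half_width: int = 5_000,
                   chrom_sizes: dict | None = None) -> pd.Series:
    """:func:`window_signal` for every insertion (columns chrom, pos)."""
    out = np.empty(len(insertions))
    for i, row in enumerate(insertions.itertuples()):
        size = chrom_sizes.get(row.chrom) if chrom_sizes else None
        out[i] = window_signal(track, row.chrom, row.pos, half_width, size)
    return pd.Series(out, index=insertions.barcode.values, name="window_sum")


def assign_state(insertions: pd.DataFrame,
                 segmentation: pd.DataFrame) -> pd.Series:
    """Chromatin-state label of the segment containing each insertion base.

    Intervals are 0-based half-open; positions falling in no interval
    (real-data gaps) get the label "unassigned".
    """
    out = pd.Series("unassigned", index=insertions.index, dtype=object)
    for chrom, grp in insertions.groupby("chrom"):
        sub = segmentation[segmentation.chrom == chrom].sort_values("start")
        if not len(sub):
            continue
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        states = sub.state.to_numpy()
        pos = grp.pos.to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(ok, states[np.clip(idx, 0, len(states) - 1)],
                        "unassigned")
        out.loc[grp.index] = vals
    out.index = insertions.barcode.values
    out.name = "state"
    return out


def quantile_bins(values: pd.Series, n_bins: int,
                  undetectable_first: bool = False) -> pd.Series:
    """Equal-size rank bins of expression values, 1-based.

    With ``undetectable_first`` (the 8-bin scheme), NaN/zero values form
    bin 1 and detectable values are split into bins 2..n_bins.  Ties are
    broken by stable input order for reproducibility.
    """
    detectable = values.notna() & (values > 0)
    bins = pd.Series(0, index=values.index, dtype=int)
    if undetectable_first:
        n_det_bins = n_bins - 1
        offset = 1
        bins[~detectable] = 1
    else:
        n_det_bins = n_bins
        offset = 0
        bins[~detectable] = 0  # dropped by caller
    det = values[detectable]
    if len(det) < n_det_bins:
        raise ValueError("fewer detectable barcodes than bins")
    order = np.argsort(det.to_numpy(), kind="stable")
    ranks = np.empty(len(det), dtype=int)
    ranks[order] = np.arange(len(det))
    bins.loc[det.index] = offset + 1 + (ranks * n_det_bins) // len(det)
    return bins


def bin_and_regress(values: pd.Series, covariate: pd.Series, n_bins: int = 8,
                    undetectable_first: bool = True) -> dict:
    """Bin barcodes by expression and regress per-bin mean covariate on
    bin index (ordinary least squares with confidence interval)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bins = quantile_bins(values, n_bins, undetectable_first)
    keep = bins > 0
    df = pd.DataFrame({"bin": bins[keep],
                       "covariate": covariate.reindex(bins.index)[keep]})
    per_bin = df.groupby("bin")["covariate"].agg(["mean", "std", "count"])
    X = sm.add_constant(per_bin.index.to_numpy(dtype=float))
    fit = sm.OLS(per_bin["mean"].to_numpy(), X).fit()
    ci = fit.conf_int()
    return {
        "bins": bins,
        "per_bin": per_bin,
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "r_squared": float(fit.rsquared),
    }


def assign_tads(insertions: pd.DataFrame, tads: pd.DataFrame) -> pd.DataFrame:
    """intraTAD/interTAD status and TAD id per insertion (half-open)."""
    tad_id = pd.Series("", index=insertions.index, dtype=object)
    for chrom, grp in insertions.groupby("chrom"):
        sub = tads[tads.chrom == chrom].sort_values("start")
        if not len(sub):
            continue
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        ids = sub.tad_id.to_numpy()
        pos = grp.pos.to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        tad_id.loc[grp.index] = np.where(
            ok, ids[np.clip(idx, 0, len(ids) - 1)], "")
    return pd.DataFrame({
        "barcode": insertions.barcode.values,
        "tad_id": tad_id.values,
        "tad_status": np.where(tad_id.values != "", "intraTAD", "interTAD"),
    })


def tad_analysis(expr: pd.DataFrame, insertions: pd.DataFrame,
                 tads: pd.DataFrame, n_random_pairs: int | None = None,
                 seed: int = 0) -> dict:
    """Within-TAD vs between-TAD correlation of expression trajectories.

    ``expr`` is a barcode x timepoint matrix (>= 2 columns).  Pearson r
    is computed for every pair of barcodes sharing a TAD (TADs with >= 2
    barcodes); an equal number of random pairs from different TADs is
    sampled with ``seed``; the two r distributions are compared with
    Welch's two-sample t test.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    status = assign_tads(insertions, tads).set_index("barcode")
    common = expr.index.intersection(status.index)
    expr = expr.loc[common]
    status = status.loc[common]

    mat = expr.to_numpy(dtype=float)
    sd = np.nanstd(mat, axis=1)
    usable = np.isfinite(mat).all(axis=1) & (sd > 0)

    by_tad: dict[str, list[int]] = {}
    for i, (bc, row) in enumerate(status.iterrows()):
        if row.tad_id and usable[i]:
            by_tad.setdefault(row.tad_id, []).append(i)

    within_pairs = [p for members in by_tad.values() if len(members) >= 2
                    for p in itertools.combinations(members, 2)]
    if not within_pairs:
        raise ValueError("no TAD with >= 2 usable barcodes")

    def _pearson(pairs):
        a = mat[[p[0] for p in pairs]]
        b = mat[[p[1] for p in pairs]]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        num = (a * b).sum(axis=1)
        den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
        return num / den

    r_within = _pearson(within_pairs)

    rng = np.random.default_rng(seed)
    n_pairs = n_random_pairs or len(within_pairs)
    intra_idx = [i for members in by_tad.values() for i in members]
    tad_of = {}
    for tid, members in by_tad.items():
        for i in members:
            tad_of[i] = tid
    between_pairs = []
    tries = 0
    while len(between_pairs) < n_pairs and tries < 100 * n_pairs:
        i, j = rng.choice(intra_idx, size=2, replace=False)
        tries += 1
        if tad_of[i] != tad_of[j]:
            between_pairs.append((i, j))
    r_between = _pearson(between_pairs)

    if np.nanstd(r_within) == 0 and np.nanstd(r_between) == 0:
        return {"tad_status": status.reset_index(), "degenerate": True,
                "r_within_mean": float(np.nanmean(r_within)),
                "r_between_mean": float(np.nanmean(r_between)),
                "t": np.nan, "p": np.nan}
    t, p = stats.ttest_ind(r_within, r_between, equal_var=False,
                           nan_policy="omit")
    return {"tad_status": status.reset_index(), "degenerate": False,
            "r_within_mean": float(np.nanmean(r_within)),
            "r_between_mean": float(np.nanmean(r_between)),
            "n_within_pairs": len(within_pairs),
            "n_between_pairs": len(between_pairs),
            "t": float(t), "p": float(p)}
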