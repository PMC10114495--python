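"""CRISPRa fold activation, exponential-decay fit and chromatin-state
deviations.

Fold activation compares the dCas9-VPR condition with the matched
scrambled-sgRNA control on a shared normalization.  The dependence of
log fold activation on log basal expression is fitted with the decay
model ``y = A exp(-k x) + C`` by nonlinear least squares.  Residuals to
the fit are ranked into six equal activation bins; per-state bin counts
are compared against the uniform expectation with binomial tests, and
per-state residual z-scores with a one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

MIN_GDNA_TOTAL = 10  # model filter: drop under-represented barcodes
TWOFOLD = 2.0


@dataclass
class DecayFit:
    A: float
    k: float
    C: float
    r_squared: float
    residuals: pd.Series = field(repr=False, default=None)


def compute_fold_activation(control: pd.DataFrame, vpr: pd.DataFrame,
                            counts: pd.DataFrame | None = None,
                            states: pd.Series | None = None) -> pd.DataFrame:
    """Per-barcode basal vs activated expression and fold activation.

    ``control``/``vpr`` carry normalized scores per barcode (columns
    barcode, normalized_score).  Model filters: total gDNA count >= 10
    (from ``counts``, if given) and basal (control cDNA) > 0.  Returns a
    table with basal, activated, fold_activation, log_basal, log_fold,
    and state when provided.
    """
    c = control.set_index("barcode")["normalized_score"]
    v = vpr.set_index("barcode")["normalized_score"]
    common = c.index.intersection(v.index)
    df = pd.DataFrame({"basal": c.loc[common], "activated": v.loc[common]})
    if counts is not None:
        gtot = counts.groupby("barcode")["gdna_count"].sum()
        df = df[gtot.reindex(df.index).fillna(0) >= MIN_GDNA_TOTAL]
    df = df[df.basal.notna() & (df.basal > 0) & df.activated.notna()
            & (df.activated > 0)]
    df["fold_activation"] = df.activated / df.basal
    df["log_basal"] = np.log(df.basal)
    with np.errstate(divide="ignore"):
        df["log_fold"] = np.log(df.fold_activation)
    if states is not None:
        df["state"] = states.reindex(df.index)
    df.index.name = "barcode"
    return df.reset_index()


def activated_fraction(table: pd.DataFrame,
                       threshold: float = TWOFOLD) -> float:
    """Fraction of barcodes activated more than ``threshold``-fold."""
    return float((table.fold_activation > threshold).mean())


def fit_exponential_decay(table: pd.DataFrame, max_iter: int = 10_000
                          ) -> DecayFit:
    """Nonlinear least squares of log fold on log basal expression.

    Model: y = A exp(-k x) + C with k >= 0.  Deterministic
    initialization A = max(y) - min(y), k = 1, C = min(y).  Flat data
    (zero y variance) degenerates to C = mean(y) with R^2 = 0.
    """
    if len(table) < 10:
        raise ValueError("need >= 10 rows to fit the decay model")
    x = table.log_basal.to_numpy(dtype=float)
    y = table.log_fold.to_numpy(dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        res = pd.Series(np.zeros(len(y)), index=table.barcode)
        return DecayFit(A=0.0, k=0.0, C=float(y.mean()), r_squared=0.0,
                        residuals=res)

    def model(x, A, k, C):
        return A * np.exp(-k * x) + C

    p0 = (float(y.max() - y.min()), 1.0, float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, maxfev=max_iter,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    A, k, C = (float(v) for v in popt)
    resid = y - model(x, A, k, C)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return DecayFit(A=A, k=k, C=C, r_squared=r2,
                    residuals=pd.Series(resid, index=table.barcode))


def rank_and_enrich(fit: DecayFit, table: pd.DataFrame, n_bins: int = 6):
    """Rank barcodes by decay-model residual into equal bins and test
    per-state enrichment against the uniform expectation.

    Bin 1 holds the most hypo-activated, bin ``n_bins`` the most
    hyper-activated reporters.  With N rows, bin sizes differ by at most
    one (the remainder goes to the lowest bins).  The expected count of
    state s in each bin is (total in s)/n_bins; each state x bin cell is
    tested with a binomial test (observed successes among the bin at the
    state's overall proportion) and corrected with Benjamini-Hochberg.
    """
    res = fit.residuals.reindex(table.barcode).to_numpy()
    order = np.argsort(res, kind="stable")
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start:start + size]] = b
        start += size
    out = table.copy()
    out["activation_bin"] = bins

    rows = []
    if "state" in out:
        state_totals = out.state.value_counts()
        for state, total in state_totals.items():
            p_state = total / n
            for b in range(1, n_bins + 1):
                in_bin = out[out.activation_bin == b]
                obs = int((in_bin.state == state).sum())
                expected = total / n_bins
                test = stats.binomtest(obs, len(in_bin), p_state)
                rows.append((state, b, obs, expected, test.pvalue))
    enrich = pd.DataFrame(rows, columns=["state", "bin", "observed",
                                         "expected", "p_raw"])
    if len(enrich):
        enrich["p_adj"] = multipletests(enrich.p_raw, method="fdr_bh")[1]
    return out, enrich


def residual_state_anova(fit: DecayFit, table: pd.DataFrame) -> dict:
    """Globally standardized residual z-scores and a one-way ANOVA of
    z across chromatin states."""
    res = fit.residuals.reindex(table.barcode)
    z = (res - res.mean()) / res.std(ddof=1)
    out = table.copy()
    out["residual_z"] = z.to_numpy()
    groups = [grp.residual_z.to_numpy()
              for _, grp in out.groupby("state") if len(grp) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 states with >= 2 barcodes")
    F, p = stats.f_oneway(*groups)
    per_state = out.groupby("state")["residual_z"].agg(
        ["mean", "std", "count"])
    return {"table": out, "per_state": per_state,
            "F": float(F), "p": float(p)}
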