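"""Two-latent-state negative-binomial regression with log-total-UMI offset.

Each cell is in an unobserved "basal" or "active" transcriptional state.
The target-gene UMI count y_i of a cell with total UMI N_i in chromatin
class c follows

    y_i ~ NB(mu_i, theta_c),   mu_i = exp(beta0_c + beta_act_c * z_i + ln N_i)

with z_i the latent active indicator, variance mu + mu^2/theta, and
P(z_i = 1) = pi_c.  Maximum-likelihood estimates come from an EM
algorithm: the E-step assigns each cell a soft active-state
responsibility, the M-step maximizes the responsibility-weighted NB
log-likelihood per class (coefficients and dispersion jointly) and
updates pi_c as the mean responsibility.  Scramble-control cells can be
anchored to the basal state (responsibility fixed at zero), which pins
the basal component and resolves label switching together with the
constraint beta_act >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import gammaln, digamma, logsumexp

BETA0_FLOOR = -30.0
_S_BOUNDS = (np.log(1e-3), np.log(1e6))


def nb_log_pmf(y, mu, theta):
    """Log NB mass with mean ``mu`` and variance ``mu + mu^2/theta``.

    Stable for counts up to ~1e6 and theta from 1e-3 to 1e6; vectorized
    over any broadcastable combination of arguments.
    """
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        if not np.allclose(y, np.round(y)):
            raise ValueError("y must be integer counts")
        y = np.round(y).astype(np.int64)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu)))


@dataclass
class NBFit:
    """Fitted per-class parameters and the EM trajectory."""

    classes: list
    beta0: dict
    beta_act: dict
    theta: dict
    pi: dict
    responsibilities: pd.Series = field(repr=False, default=None)
    loglik_trace: list = field(default_factory=list, repr=False)
    converged: bool = False
    n_iter: int = 0


def predicted_mean(fit: NBFit, class_label: str, state: str,
                   N: float) -> float:
    """Expected target-gene count: exp(beta0 + beta_act*1[active] + ln N)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if class_label not in fit.beta0:
        raise ValueError(f"unknown class {class_label}")
    act = {"basal": 0.0, "active": 1.0}[state]
    return float(np.exp(fit.beta0[class_label]
                        + fit.beta_act[class_label] * act + np.log(N)))


def class_moments(fit: NBFit, class_label: str, N: float):
    """Mixture mean and variance of counts for a class at total UMI N."""
    mu_b = predicted_mean(fit, class_label, "basal", N)
    mu_a = predicted_mean(fit, class_label, "active", N)
    th = fit.theta[class_label]
    pi = fit.pi[class_label]
    mean = (1 - pi) * mu_b + pi * mu_a
    var = ((1 - pi) * (mu_b + mu_b ** 2 / th)
           + pi * (mu_a + mu_a ** 2 / th)
           + (1 - pi) * pi * (mu_a - mu_b) ** 2)
    return mean, var


class _ClassData:
    """Per-class observations with unique-count caching.

    The gammaln/digamma terms of the NB likelihood depend on the data
    only through the (few) distinct count values, so they are evaluated
    on the unique counts and gathered, which dominates the EM runtime
    otherwise.
    """

    def __init__(self, y, logN):
        self.y = y.astype(float)
        self.logN = logN
        self.yu, self.inv = np.unique(y, return_inverse=True)

    def log_pmf(self, mu, theta):
        base = (gammaln(self.yu + theta) - gammaln(theta)
                - gammaln(self.yu + 1))[self.inv]
        return (base + theta * (np.log(theta) - np.log(theta + mu))
                + self.y * (np.log(mu) - np.log(theta + mu)))

    def dtheta(self, mu, theta):
        base = (digamma(self.yu + theta) - digamma(theta))[self.inv]
        return (base + np.log(theta) - np.log(mu + theta)
                + 1.0 - (self.y + theta) / (mu + theta))


def _neg_q(params, data: _ClassData, r, has_active):
    """Negative responsibility-weighted complete-data log-likelihood of one
    class and its gradient; params = (beta0, beta_act, log theta)."""
    b0, ba, s = params
    theta = np.exp(s)
    y, logN = data.y, data.logN
    mu_b = np.exp(np.clip(b0 + logN, -700, 700))
    w_b = 1.0 - r
    q = np.dot(w_b, data.log_pmf(mu_b, theta))
    g_b0 = np.dot(w_b, y - mu_b * (y + theta) / (mu_b + theta))
    dth = np.dot(w_b, data.dtheta(mu_b, theta))
    g_ba = 0.0
    if has_active:
        mu_a = np.exp(np.clip(b0 + ba + logN, -700, 700))
        q += np.dot(r, data.log_pmf(mu_a, theta))
        g_a = np.dot(r, y - mu_a * (y + theta) / (mu_a + theta))
        g_b0 += g_a
        g_ba = g_a
        dth += np.dot(r, data.dtheta(mu_a, theta))
    g_s = theta * dth
    return -q, -np.array([g_b0, g_ba, g_s])


def _mstep_class(data: _ClassData, r, b0, ba, s, fit_active,
                 s_bounds=_S_BOUNDS):
    res = optimize.minimize(
        _neg_q, x0=np.array([b0, ba, s]), args=(data, r, fit_active),
        jac=True, method="L-BFGS-B",
        bounds=[(BETA0_FLOOR, 30.0), (0.0, 30.0), s_bounds])
    return res.x


def _init_theta(y):
    """Method-of-moments dispersion from the raw count moments."""
    m = y.mean()
    v = y.var()
    if v > m > 0:
        return float(np.clip(m * m / (v - m), 1e-2, 1e4))
    return 10.0


def em_fit(cells: pd.DataFrame, anchor_controls: bool = True,
           tol: float = 1e-6, max_iter: int = 500,
           fix_theta: float | None = None) -> NBFit:
    """Fit the two-latent-state NB model by EM.

    Parameters
    ----------
    cells : DataFrame with columns ``cell_id``, ``class_label``, ``y``
        (target-gene UMI count), ``N`` (total UMI) and ``is_control``.
    anchor_controls : fix control cells' active responsibility at zero,
        so the controls define the basal state.
    tol : convergence tolerance on the total log-likelihood.
    max_iter : maximum EM iterations.
    fix_theta : hold the dispersion of every class at this value instead
        of estimating it (e.g. a large value for a Poisson-like fit).

    Notes
    -----
    Initialization is deterministic: responsibilities are seeded by
    thresholding y/N at the class median among non-control cells,
    pi = 0.5, and theta by the method of moments.  The mixing weight
    pi_c is the mean responsibility over non-control cells of class c.
    """
    required = {"class_label", "y", "N", "is_control"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    if (cells.N <= 0).any():
        raise ValueError("total UMI counts must be positive")
    classes = sorted(cells.class_label.unique())
    y_all = cells.y.to_numpy(dtype=np.int64)
    logN_all = np.log(cells.N.to_numpy(dtype=float))
    ctrl_all = cells.is_control.to_numpy(dtype=bool) if anchor_controls \
        else np.zeros(len(cells), dtype=bool)
    cls_all = cells.class_label.to_numpy()

    beta0, beta_act, theta, pi = {}, {}, {}, {}
    r_all = np.zeros(len(cells))
    # deterministic initialization per class
    for c in classes:
        m = cls_all == c
        if m.sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 cells")
        free = m & ~ctrl_all
        rate = y_all[m] / np.exp(logN_all[m])
        if free.any():
            med = np.median(y_all[free] / np.exp(logN_all[free]))
            r_all[m] = ((rate > med) & ~ctrl_all[m]).astype(float)
        basal_like = r_all[m] == 0
        mu0 = (y_all[m][basal_like].sum() + 0.5) \
            / np.exp(logN_all[m][basal_like]).sum()
        beta0[c] = max(np.log(mu0), BETA0_FLOOR)
        act_like = r_all[m] == 1
        if act_like.any() and y_all[m][act_like].sum() > 0:
            mu1 = y_all[m][act_like].sum() / np.exp(logN_all[m][act_like]).sum()
            beta_act[c] = max(np.log(mu1) - beta0[c], 0.1)
        else:
            beta_act[c] = 0.1
        theta[c] = fix_theta if fix_theta is not None \
            else _init_theta(y_all[m])
        pi[c] = 0.5 if free.any() else 0.0
    s_bounds = _S_BOUNDS if fix_theta is None \
        else (np.log(fix_theta), np.log(fix_theta))

    data_by_class = {c: _ClassData(y_all[cls_all == c],
                                   logN_all[cls_all == c]) for c in classes}
    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step + observed log-likelihood
        ll = 0.0
        for c in classes:
            m = cls_all == c
            data = data_by_class[c]
            y, logN = data.y, data.logN
            ctrl = ctrl_all[m]
            mu_b = np.exp(np.clip(beta0[c] + logN, -700, 700))
            mu_a = np.exp(np.clip(beta0[c] + beta_act[c] + logN, -700, 700))
            th = theta[c]
            lf_b = data.log_pmf(mu_b, th)
            lf_a = data.log_pmf(mu_a, th)
            p = np.clip(pi[c], 0.0, 1.0)
            with np.errstate(divide="ignore"):
                la = np.log(p) + lf_a
                lb = np.log1p(-p) + lf_b
            mix = logsumexp(np.vstack([la, lb]), axis=0)
            r = np.where(np.isfinite(mix), np.exp(la - np.where(
                np.isfinite(mix), mix, 1.0)), 0.0)
            r[ctrl] = 0.0
            r_all[m] = r
            ll += float(np.where(ctrl, lf_b, mix).sum())
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

        # M-step
        for c in classes:
            m = cls_all == c
            free = m & ~ctrl_all
            pi[c] = float(r_all[free].mean()) if free.any() else 0.0
            fit_active = free.any() and r_all[m].sum() > 1e-12
            b0, ba, s = _mstep_class(
                data_by_class[c], r_all[m],
                beta0[c], beta_act[c], np.log(theta[c]), fit_active,
                s_bounds)
            beta0[c], beta_act[c], theta[c] = float(b0), float(ba), \
                float(np.exp(s))
            if beta0[c] <= BETA0_FLOOR + 1e-9:
                warnings.warn(f"class {c}: beta0 at floor {BETA0_FLOOR} "
                              "(all-zero counts?)")

    resp = pd.Series(r_all, index=cells["cell_id"].values
                     if "cell_id" in cells else cells.index,
                     name="responsibility")
    return NBFit(classes=classes, beta0=beta0, beta_act=beta_act,
                 theta=theta, pi=pi, responsibilities=resp,
                 loglik_trace=trace, converged=converged, n_iter=it)


def cells_from_sc(adata, assignments: pd.DataFrame,
                  class_of_target: dict, seed: int = 0) -> pd.DataFrame:
    """Build the model's cell table from a processed single-cell dataset.

    On-target cells contribute their own target-gene count; scramble
    cells are split evenly (deterministically, by ``seed``) across the
    chromatin classes as basal-anchored controls.
    """
    pert = assignments.reindex(adata.obs_names)["perturbation"]
    raw = adata.layers["counts"] if "counts" in adata.layers else adata.X
    totals = np.asarray(raw.sum(axis=1)).ravel()
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for i, (cell, label) in enumerate(pert.items()):
        if label in class_of_target:
            j = gene_index[label]
            yv = raw[i, j]
            yv = float(yv.toarray().ravel()[0]) if hasattr(yv, "toarray") \
                else float(yv)
            rows.append((cell, class_of_target[label], int(yv),
                         int(totals[i]), False))
    classes = sorted(set(class_of_target.values()))
    scr_cells = [(i, c) for i, c in enumerate(pert) if c == "scramble"]
    rng = np.random.default_rng(seed)
    assigned = rng.permutation(len(scr_cells))
    for k, (i, _) in enumerate(scr_cells):
        c = classes[assigned[k] % len(classes)]
        # a control cell stands in for an unperturbed target of class c
        targets_c = [t for t, cc in class_of_target.items() if cc == c]
        t = targets_c[assigned[k] // len(classes) % len(targets_c)]
        j = gene_index[t]
        yv = raw[i, j]
        yv = float(yv.toarray().ravel()[0]) if hasattr(yv, "toarray") \
            else float(yv)
        rows.append((pert.index[i], c, int(yv), int(totals[i]), True))
    return pd.DataFrame(rows, columns=["cell_id", "class_label", "y", "N",
                                       "is_control"])
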