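"""Single-cell CRISPRa dataset simulation.

Each cell draws a total UMI count from a log-normal, a latent
transcriptional state (active with probability pi_c for on-target cells,
always basal for scramble / untransfected controls), and a target-gene
UMI count from a negative binomial with mean
``exp(beta0_c + beta_act_c * 1[active] + log N)`` and dispersion theta_c
(variance = mu + mu^2/theta).  Guide capture places 0-8 guides per cell
from the target's 5-guide set with configurable cross-contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import SimConfig, STATES
from .simulate import _stream


@dataclass
class ScDataset:
    """Cell-by-gene and cell-by-guide UMI matrices with metadata."""

    genes: ad.AnnData  # X: cells x genes raw UMI counts
    guides: ad.AnnData  # X: cells x guides UMI counts
    guide_sets: pd.DataFrame  # guide_id, target

    @property
    def obs(self) -> pd.DataFrame:
        return self.genes.obs


def default_design(n_per_state: int = 9, extra_bivalent: int = 6
                   ) -> dict[str, str]:
    """Target -> chromatin-class map: 9 genes per state plus extra bivalent
    genes, 96 targets in total at the defaults."""
    design = {}
    for s in STATES:
        for i in range(n_per_state):
            design[f"T_{s}_{i}"] = s
    for i in range(extra_bivalent):
        design[f"T_E6_x{i}"] = "E6"
    return design


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, theta: np.ndarray
              ) -> np.ndarray:
    """NB(mean=mu, var=mu+mu^2/theta) via the Gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_nb_cells(beta0: dict[str, float], beta_act: dict[str, float],
                      theta: dict[str, float], pi: dict[str, float],
                      n_cells_per_class: int, n_control_per_class: int,
                      total_umi_lognormal: tuple[float, float],
                      seed: int) -> pd.DataFrame:
    """Cell-level observations straight from the latent-state NB model.

    Returns a table (cell_id, class_label, y, N, is_control, true_active)
    suitable for :func:`crispra_context.nbmodel.em_fit`; used for
    parameter-recovery studies without the full experiment around it.
    """
    rng = np.random.default_rng([seed, 977])
    mu_ln, sd_ln = total_umi_lognormal
    rows = []
    for c in beta0:
        n_tot = n_cells_per_class + n_control_per_class
        N = np.maximum(1, rng.lognormal(mu_ln, sd_ln, n_tot)).astype(int)
        is_control = np.arange(n_tot) >= n_cells_per_class
        active = (rng.random(n_tot) < pi[c]) & ~is_control
        mu = np.exp(beta0[c] + beta_act[c] * active + np.log(N))
        y = _nb_draws(rng, mu, np.full(n_tot, float(theta[c])))
        for i in range(n_tot):
            rows.append((f"{c}_cell{i}", c, int(y[i]), int(N[i]),
                         bool(is_control[i]), bool(active[i])))
    return pd.DataFrame(rows, columns=[
        "cell_id", "class_label", "y", "N", "is_control", "true_active"])


def simulate_sc_dataset(config: SimConfig,
                        design: dict[str, str] | None = None) -> ScDataset:
    """Full single-cell CRISPRa experiment with ground truth in ``obs``.

    Cell pools follow the configured no-transfection : scramble :
    on-target ratio.  Per-cell gene counts conserve the realized total
    (target NB draws + mitochondrial reads + multinomial background).
    """
    config.validate()
    if design is None:
        design = default_design()
    for t, s in design.items():
        if s not in STATES:
            raise ValueError(f"target {t} has unknown class {s}")
    targets = list(design)
    rng = _stream(config.seed, "sc")

    n_on = config.cells_per_target * len(targets)
    r_nt, r_sc, r_on = config.pool_ratio
    n_scramble = int(round(n_on * r_sc / r_on))
    n_notrans = int(round(n_on * r_nt / r_on))
    labels = ([t for t in targets for _ in range(config.cells_per_target)]
              + ["scramble"] * n_scramble + ["no_transfection"] * n_notrans)
    n_cells = len(labels)
    labels = np.array(labels, dtype=object)

    mu_ln, sd_ln = config.total_umi_lognormal
    N = np.maximum(10, rng.lognormal(mu_ln, sd_ln, n_cells)).astype(int)

    # latent state and per-target counts in every cell
    t_states = np.array([design[t] for t in targets])
    b0 = np.array([config.nb_beta0_by_state[s] for s in t_states])
    bact = np.array([config.nb_beta_act_by_state[s] for s in t_states])
    th = np.array([config.nb_theta_by_state[s] for s in t_states])
    pi = np.array([config.nb_pi_by_state[s] for s in t_states])

    is_on = ~np.isin(labels, ["scramble", "no_transfection"])
    own_idx = np.array([targets.index(l) if on else -1
                        for l, on in zip(labels, is_on)])
    active = np.zeros(n_cells, dtype=bool)
    active[is_on] = rng.random(is_on.sum()) < pi[own_idx[is_on]]

    target_counts = np.zeros((n_cells, len(targets)), dtype=np.int64)
    logN = np.log(N)
    for j in range(len(targets)):
        act_j = active & (own_idx == j)
        mu = np.exp(b0[j] + bact[j] * act_j + logN)
        target_counts[:, j] = _nb_draws(rng, mu, np.full(n_cells, th[j]))

    # mitochondrial reads and multinomial background fill
    a, b = config.mito_beta
    mito_frac_true = rng.beta(a, b, n_cells)
    mito = rng.binomial(N, mito_frac_true)
    t_sum = target_counts.sum(axis=1)
    total = np.maximum(N, t_sum + mito)
    n_bg_counts = total - t_sum - mito
    bg_w = np.exp(rng.standard_normal(config.n_background_genes))
    bg_w /= bg_w.sum()
    background = rng.multinomial(n_bg_counts, bg_w)
    mito_w = np.ones(config.n_mito_genes) / config.n_mito_genes
    mito_split = rng.multinomial(mito, mito_w)

    gene_names = (targets
                  + [f"BG{i}" for i in range(config.n_background_genes)]
                  + [f"MT-{i}" for i in range(config.n_mito_genes)])
    X = np.hstack([target_counts, background, mito_split])

    # guide capture
    guide_ids = [f"{t}_g{i + 1}" for t in targets
                 for i in range(config.guides_per_target)] \
        + ["scramble_g1", "scramble_g2"]
    guide_target = [t for t in targets
                    for _ in range(config.guides_per_target)] \
        + ["scramble", "scramble"]
    guide_sets = pd.DataFrame({"guide_id": guide_ids, "target": guide_target})
    set_index: dict[str, list[int]] = {}
    for i, t in enumerate(guide_target):
        set_index.setdefault(t, []).append(i)

    mult_probs = np.asarray(config.guide_multiplicity_probs)
    n_guides_true = np.zeros(n_cells, dtype=int)
    grow, gcol, gval = [], [], []
    for i in range(n_cells):
        if labels[i] == "no_transfection":
            continue
        m = int(rng.choice(len(mult_probs), p=mult_probs))
        n_guides_true[i] = m
        if m == 0:
            continue
        own_set = set_index["scramble" if labels[i] == "scramble"
                            else labels[i]]
        chosen: list[int] = []
        pool = list(own_set)
        rng.shuffle(pool)
        for j in range(m):
            if rng.random() < config.guide_contamination or not pool:
                other = int(rng.integers(0, len(guide_ids)))
                while other in chosen:
                    other = int(rng.integers(0, len(guide_ids)))
                chosen.append(other)
            else:
                chosen.append(pool.pop())
        for g in chosen:
            grow.append(i)
            gcol.append(g)
            gval.append(1 + rng.poisson(config.guide_umi_mean))
    guide_X = sparse.coo_matrix(
        (gval, (grow, gcol)), shape=(n_cells, len(guide_ids))).tocsr()

    cell_ids = [f"cell{i}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "total_umi": X.sum(axis=1),
        "mito_frac": X[:, -config.n_mito_genes:].sum(axis=1) / X.sum(axis=1),
        "doublet": rng.random(n_cells) < config.doublet_frac,
        "true_label": labels,
        "true_active": active,
        "true_n_guides": n_guides_true,
    }, index=pd.Index(cell_ids, name="cell_id"))
    var = pd.DataFrame({
        "gene_type": (["target"] * len(targets)
                      + ["background"] * config.n_background_genes
                      + ["mito"] * config.n_mito_genes),
        "class_label": (list(t_states)
                        + [""] * (config.n_background_genes
                                  + config.n_mito_genes)),
    }, index=pd.Index(gene_names, name="gene"))
    genes = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    guides = ad.AnnData(
        X=guide_X, obs=obs[[]].copy(),
        var=pd.DataFrame(index=pd.Index(guide_ids, name="guide_id")))
    return ScDataset(genes=genes, guides=guides, guide_sets=guide_sets)
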