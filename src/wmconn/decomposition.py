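"""Per-connection decomposition of predicted group-level WM impairment.

Because the prediction is a weighted summation of connectivity values, a
patient's predicted deviation from the control mean decomposes exactly into
per-connection terms: the D-score D_{i,p} = w_i x_{i,p} - mean_c(w_i x_{i,c})
sums over selected connections i to the predicted-WMA deviation of patient p.
Z-scores standardize D by the control group's SD of weighted FC at the
connection.  Statistical machinery: permutation two-way ANOVA (diagnosis as
between-, connection as within-participant factor) for heteroscedastic Z
matrices, per-connection Kruskal-Wallis with Benjamini-Hochberg FDR, a
Kolmogorov-Smirnov comparison of selected- vs excluded-connection chi-square
values, and cluster-level summed D-scores over between-cluster connections.

Before pooling cohorts from different sites, each control group's FC is
linearly mapped onto the training cohort's per-connection distribution and
the same map is applied to that site's patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasSpec
from .model import SparseBayesianRegression


@dataclass
class AlignmentMap:
    """Per-connection linear map x' = (x - mu_src)/sigma_src * sigma_ref + mu_ref."""

    mu_src: np.ndarray
    sigma_src: np.ndarray
    mu_ref: np.ndarray
    sigma_ref: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mu_src) / self.sigma_src * self.sigma_ref + self.mu_ref

    def invert(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mu_ref) / self.sigma_ref * self.sigma_src + self.mu_src


@dataclass
class DScoreMatrix:
    """Patients x selected-connections weighted-FC deviations from controls."""

    values: np.ndarray  # (n_patients, n_support)
    feature_indices: np.ndarray  # canonical feature index per column
    diagnosis: np.ndarray | None = None  # per-patient label
    site: np.ndarray | None = None


@dataclass
class PermAnovaResult:
    F_diagnosis: float
    p_main: float
    n_perm_main: int
    F_interaction: float
    p_interaction: float
    n_perm_interaction: int
    posthoc_pairs: list[dict]
    seed: int


def align_to_reference(
    fc_controls: np.ndarray,
    fc_patients: np.ndarray,
    fc_reference: np.ndarray,
    feature_labels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, AlignmentMap]:
    """Map a site's control FC distribution onto the reference cohort's.

    The map is derived from the controls only (per-connection mean/SD) and
    applied unchanged to the site's patients, so patient deviations from
    their controls are preserved up to the per-connection scale factor.
    """
    ctl = np.asarray(fc_controls, dtype=float)
    pat = np.asarray(fc_patients, dtype=float)
    ref = np.asarray(fc_reference, dtype=float)
    if ctl.shape[1] != pat.shape[1] or ctl.shape[1] != ref.shape[1]:
        raise ValueError("feature ordering must agree across inputs")
    if ctl.shape[0] < 2:
        raise ValueError("need at least 2 control subjects")
    mu_src, sd_src = ctl.mean(axis=0), ctl.std(axis=0, ddof=1)
    if np.any(sd_src == 0):
        j = int(np.flatnonzero(sd_src == 0)[0])
        name = feature_labels[j] if feature_labels else f"feature {j}"
        raise ValueError(f"zero control SD at connection {name}")
    amap = AlignmentMap(
        mu_src=mu_src,
        sigma_src=sd_src,
        mu_ref=ref.mean(axis=0),
        sigma_ref=ref.std(axis=0, ddof=1),
    )
    return amap.apply(ctl), amap.apply(pat), amap


def d_scores(
    model: SparseBayesianRegression,
    aligned_patients: np.ndarray,
    aligned_controls: np.ndarray,
    diagnosis: np.ndarray | None = None,
    site: np.ndarray | None = None,
) -> DScoreMatrix:
    """Weighted-FC deviation of every patient from the control mean.

    D_{i,p} = w_i (x_{i,p} - mean_c x_{i,c}) over the model's selected
    connections; rows sum to the predicted-WMA deviation of the patient from
    the control mean (the intercept cancels).
    """
    pat = np.asarray(aligned_patients, dtype=float)
    ctl = np.asarray(aligned_controls, dtype=float)
    if ctl.shape[0] == 0:
        raise ValueError("empty control group")
    sup = model.support_
    w = model.coef_[sup]
    D = w * (pat[:, sup] - ctl[:, sup].mean(axis=0))
    return DScoreMatrix(
        values=D,
        feature_indices=sup.copy(),
        diagnosis=None if diagnosis is None else np.asarray(diagnosis),
        site=None if site is None else np.asarray(site),
    )


def z_scores(
    d: DScoreMatrix,
    aligned_controls: np.ndarray,
    model: SparseBayesianRegression,
) -> np.ndarray:
    """D-scores standardized by the control SD of weighted FC per connection."""
    ctl = np.asarray(aligned_controls, dtype=float)
    sup = d.feature_indices
    sd = np.abs(model.coef_[sup]) * ctl[:, sup].std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero control SD of weighted FC at support column {j}")
    return d.values / sd


# ----------------------------------------------------------------------
# two-way mixed-design ANOVA with permutation p-values


def _mixed_anova_F(Z: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """F statistics (main effect of group, group x connection interaction)
    for a design with group between-participants and connection
    within-participants.  Classical sums of squares with group-size weights
    (exact for the balanced-by-design synthetic layout; the permutation null
    calibrates the unbalanced case)."""
    N, C = Z.shape
    GM = Z.mean()
    subj_mean = Z.mean(axis=1)
    n_g = np.bincount(codes, minlength=k).astype(float)
    group_mean = np.bincount(codes, weights=subj_mean, minlength=k) / n_g
    ss_diag = C * float(n_g @ (group_mean - GM) ** 2)
    ss_subj = C * float(np.sum((subj_mean - group_mean[codes]) ** 2))
    F_main = (ss_diag / (k - 1)) / (ss_subj / (N - k)) if ss_subj > 0 else np.inf

    conn_mean = Z.mean(axis=0)
    cell = np.zeros((k, C))
    np.add.at(cell, codes, Z)
    cell /= n_g[:, None]
    inter = cell - group_mean[:, None] - conn_mean[None, :] + GM
    ss_inter = float(n_g @ np.sum(inter**2, axis=1))
    resid = Z - subj_mean[:, None] - cell[codes] + group_mean[codes][:, None]
    ss_err = float(np.sum(resid**2))
    df_i = (k - 1) * (C - 1)
    df_e = (N - k) * (C - 1)
    F_inter = (ss_inter / df_i) / (ss_err / df_e) if ss_err > 0 else np.inf
    return F_main, F_inter


def _main_effect_F_batch(
    subj_mean: np.ndarray, codes: np.ndarray, k: int, C: int, perm_idx: np.ndarray
) -> np.ndarray:
    """Vectorized main-effect F over row-permutations (perm_idx: (P, N))."""
    N = subj_mean.shape[0]
    GM = subj_mean.mean()
    n_g = np.bincount(codes, minlength=k).astype(float)
    G = np.zeros((N, k))
    G[np.arange(N), codes] = 1.0
    S = subj_mean[perm_idx]  # (P, N)
    group_mean = (S @ G) / n_g  # (P, k)
    ss_total = C * float(np.sum((subj_mean - GM) ** 2))
    ss_diag = C * np.sum(n_g * (group_mean - GM) ** 2, axis=1)
    ss_subj = ss_total - ss_diag
    ss_subj = np.clip(ss_subj, 1e-300, None)
    return (ss_diag / (k - 1)) / (ss_subj / (N - k))


def perm_two_way_anova(
    Z: np.ndarray,
    diagnosis_labels: np.ndarray,
    n_perm_main: int = 10_000,
    n_perm_inter: int = 100_000,
    seed: int = 0,
    posthoc: bool = True,
    interaction_shuffle: str = "within_subject",
) -> PermAnovaResult:
    """Permutation two-way ANOVA of the Z-score matrix.

    Main effect of diagnosis: diagnosis labels are shuffled across subjects
    (rows move intact, respecting the within-participant connection factor).
    Interaction: diagnosis labels are shuffled and, in the default
    ``within_subject`` scheme, connection labels are additionally permuted
    independently within each subject (``global`` permutes one connection
    relabelling shared by all subjects instead).  p = (1 + #{F_null >=
    F_obs}) / (1 + n_perm).  Post-hoc pairwise tests shuffle labels within
    each diagnosis pair.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(diagnosis_labels)
    if Z.ndim != 2 or Z.shape[0] != labels.shape[0]:
        raise ValueError("Z must be subjects x connections, one label per row")
    if min(n_perm_main, n_perm_inter) < 100:
        raise ValueError("n_perm must be >= 100")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.shape[0]
    if k < 2 or Z.shape[1] < 2:
        raise ValueError("need >= 2 diagnoses and >= 2 connections")
    N, C = Z.shape
    rng = np.random.default_rng(seed)

    F_main_obs, F_inter_obs = _mixed_anova_F(Z, codes, k)

    subj_mean = Z.mean(axis=1)
    from itertools import permutations as _perms
    from math import factorial as _fact

    if N <= 8 and _fact(N) <= n_perm_main:
        # exhaustive null of the main effect (identity included)
        perm_idx = np.array(list(_perms(range(N))))
        F_null_main = _main_effect_F_batch(subj_mean, codes, k, C, perm_idx)
        p_main = float(np.mean(F_null_main >= F_main_obs - 1e-12))
    else:
        perm_idx = np.argsort(rng.random((n_perm_main, N)), axis=1)
        F_null_main = _main_effect_F_batch(subj_mean, codes, k, C, perm_idx)
        p_main = (1 + int(np.sum(F_null_main >= F_main_obs - 1e-12))) / (
            1 + n_perm_main
        )

    count_inter = 0
    for _ in range(n_perm_inter):
        idx = rng.permutation(N)
        Zp = Z[idx]
        if interaction_shuffle == "within_subject":
            Zp = rng.permuted(Zp, axis=1)
        elif interaction_shuffle == "global":
            Zp = Zp[:, rng.permutation(C)]
        else:
            raise ValueError(f"unknown interaction_shuffle {interaction_shuffle!r}")
        _, Fi = _mixed_anova_F(Zp, codes, k)
        count_inter += Fi >= F_inter_obs - 1e-12
    p_inter = (1 + count_inter) / (1 + n_perm_inter)

    pairs = []
    if posthoc:
        for i, j in combinations(range(k), 2):
            sel = (codes == i) | (codes == j)
            Zij = Z[sel]
            cij = (codes[sel] == j).astype(int)
            F_obs_ij, _ = _mixed_anova_F(Zij, cij, 2)
            sm = Zij.mean(axis=1)
            pidx = np.argsort(rng.random((n_perm_main, Zij.shape[0])), axis=1)
            F_null = _main_effect_F_batch(sm, cij, 2, C, pidx)
            p_ij = (1 + int(np.sum(F_null >= F_obs_ij - 1e-12))) / (1 + n_perm_main)
            pairs.append(
                {
                    "group1": str(uniq[i]),
                    "group2": str(uniq[j]),
                    "F": float(F_obs_ij),
                    "p_perm": float(p_ij),
                }
            )
    return PermAnovaResult(
        F_diagnosis=float(F_main_obs),
        p_main=float(p_main),
        n_perm_main=n_perm_main,
        F_interaction=float(F_inter_obs),
        p_interaction=float(p_inter),
        n_perm_interaction=n_perm_inter,
        posthoc_pairs=pairs,
        seed=seed,
    )


def kw_per_connection_fdr(
    Z: np.ndarray, diagnosis_labels: np.ndarray, q: float = 0.05
) -> dict:
    """Tie-corrected Kruskal-Wallis per connection, BH-FDR at level ``q``."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(diagnosis_labels)
    uniq = np.unique(labels)
    if uniq.shape[0] < 2:
        raise ValueError("need at least 2 diagnoses")
    H = np.empty(Z.shape[1])
    p = np.empty(Z.shape[1])
    for j in range(Z.shape[1]):
        groups = [Z[labels == u, j] for u in uniq]
        col = Z[:, j]
        if np.all(col == col[0]):
            warnings.warn(f"connection column {j} is all-tied; H=0, p=1", stacklevel=2)
            H[j], p[j] = 0.0, 1.0
            continue
        H[j], p[j] = sst.kruskal(*groups)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return {
        "chi_square": H,
        "p": p,
        "p_fdr": p_adj,
        "significant": reject,
        "q": q,
    }


def ks_model_vs_other_connections(
    chisq_model: np.ndarray, chisq_other: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test on Kruskal-Wallis chi-square values of the model's
    selected connections vs all excluded connections."""
    a = np.asarray(chisq_model, dtype=float)
    b = np.asarray(chisq_other, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sst.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def cluster_summed_dscores(d: DScoreMatrix, atlas: AtlasSpec) -> "pd.DataFrame":
    """Summed mean D-scores per (cluster, diagnosis) over between-cluster
    connections touching the cluster.

    Only connections whose two endpoint networks lie in different clusters
    are counted (within-network features are inherently within-cluster); a
    bridging connection contributes its diagnosis-mean D to both endpoint
    clusters.  Clusters touched by no selected bridging connection are
    absent from the output.
    """
    import pandas as pd

    if d.diagnosis is None:
        raise ValueError("DScoreMatrix carries no diagnosis labels")
    diags = np.unique(d.diagnosis)
    rows: dict[tuple[str, str], float] = {}
    for col, feat in enumerate(d.feature_indices):
        kind, i, j = atlas.feature_of_index(int(feat))
        if kind == "within":
            continue
        ci, cj = atlas.cluster_of[i], atlas.cluster_of[j]
        if ci == cj:
            continue
        for diag in diags:
            mean_d = float(d.values[d.diagnosis == diag, col].mean())
            for cluster in (ci, cj):
                rows[(cluster, str(diag))] = rows.get((cluster, str(diag)), 0.0) + mean_d
    if not rows:
        return pd.DataFrame(columns=["cluster", "diagnosis", "summed_d"])
    return pd.DataFrame(
        [
            {"cluster": c, "diagnosis": g, "summed_d": v}
            for (c, g), v in sorted(rows.items())
        ]
    )
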