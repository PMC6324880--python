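"""Confound-controlled evaluation of model predictions on independent cohorts.

Partial correlations (Pearson or Spearman) with permutation p-values whose
null preserves the subject-to-confound links: only the predicted scores are
shuffled, confounds stay attached to their subjects.  Group-level machinery:
pooled-variance t-tests with Bonferroni correction, Hedges g with 95% CI,
one-way ANOVA with Holm-corrected post-hoc pairs and a Bartlett
homoscedasticity report, containment of effect sizes in externally supplied
meta-analytic confidence intervals, and a bootstrap comparison of two
dependent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import factorial

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


@dataclass
class PartialCorrResult:
    rho: float
    method: str
    confound_names: list[str]
    n: int
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class GroupComparison:
    label: str
    n1: int
    n2: int
    t: float
    df: int
    p: float
    p_adjusted: float
    adjust_method: str
    hedges_g: float
    g_ci_low: float
    g_ci_high: float


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def _confound_matrix(confounds, n: int) -> np.ndarray:
    if confounds is None or (hasattr(confounds, "size") and confounds.size == 0):
        C = np.ones((n, 1))
    else:
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        C = np.column_stack([np.ones(n), conf])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("confound matrix (with intercept) is rank deficient")
    return C


def partial_correlation(
    a: np.ndarray,
    b: np.ndarray,
    confounds: np.ndarray | None = None,
    method: str = "pearson",
) -> float:
    """Correlation of ``a`` and ``b`` after regressing out the confounds.

    Pearson: correlate the residuals of each variable regressed on the
    confounds (plus intercept).  Spearman: rank-transform every variable
    first, then proceed as Pearson.  With no confounds this reduces to the
    plain (rank) correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    n = a.shape[0]
    if method == "spearman":
        a = sst.rankdata(a)
        b = sst.rankdata(b)
        if confounds is not None and np.asarray(confounds).size:
            conf = np.asarray(confounds, dtype=float)
            if conf.ndim == 1:
                conf = conf[:, None]
            confounds = np.column_stack([sst.rankdata(c) for c in conf.T])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    C = _confound_matrix(confounds, n)
    ra = _residualize(a, C)
    rb = _residualize(b, C)
    # a variable fully explained by the confounds has a null residual: its
    # partial correlation with anything is 0 (up to numerical noise)
    for v, rv in ((a, ra), (b, rb)):
        scale = np.linalg.norm(v - v.mean())
        if np.linalg.norm(rv) <= 1e-8 * max(scale, 1e-300):
            if scale == 0.0:
                raise ValueError("constant variable after residualization")
            return 0.0
    denom = np.sqrt(float(ra @ ra) * float(rb @ rb))
    return float(np.clip(ra @ rb / denom, -1.0, 1.0))


def permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    confounds: np.ndarray | None = None,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PartialCorrResult:
    """Two-sided permutation p-value for the partial correlation.

    Only ``a`` (the predicted score) is shuffled; ``b`` and the confounds
    keep their subject labels, preserving the confound structure under the
    null.  For sampled permutations p = (1 + #{|rho_null| >= |rho_obs|}) /
    (1 + n_perm); when n! <= n_perm the null is enumerated exhaustively and
    p = #{|rho_null| >= |rho_obs|} / n! (the identity permutation makes p
    strictly positive).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant input variable; permutation test undefined")
    rho_obs = partial_correlation(a, b, confounds, method)
    names = (
        []
        if confounds is None
        else [f"c{i}" for i in range(np.atleast_2d(np.asarray(confounds).T).shape[0])]
    )

    exhaustive = n <= 20 and factorial(n) <= n_perm
    rng = np.random.default_rng(seed)
    if exhaustive:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            rho = partial_correlation(a[list(perm)], b, confounds, method)
            count += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        p = count / total
    else:
        # Vectorized: with projection M onto the confound complement,
        # rho(a_perm) = a_perm . (M b) / (||M a_perm|| ||M b||), and
        # ||M a_perm||^2 = ||a_perm||^2 - a_perm . (H a_perm).
        av, bv, conf = a, b, confounds
        if method == "spearman":
            av, bv = sst.rankdata(av), sst.rankdata(bv)
            if conf is not None and np.asarray(conf).size:
                cm = np.asarray(conf, dtype=float)
                if cm.ndim == 1:
                    cm = cm[:, None]
                conf = np.column_stack([sst.rankdata(c) for c in cm.T])
        C = _confound_matrix(conf, n)
        H = C @ np.linalg.pinv(C)
        rb = bv - H @ bv
        rb_norm = np.linalg.norm(rb)
        A = rng.permuted(np.broadcast_to(av, (n_perm, n)).copy(), axis=1)
        num = A @ rb
        norms2 = np.einsum("ij,ij->i", A, A) - np.einsum("ij,ij->i", A, A @ H)
        rho_null = num / (np.sqrt(np.clip(norms2, 1e-300, None)) * rb_norm)
        count = int(np.sum(np.abs(rho_null) >= abs(rho_obs) - 1e-12))
        p = (1 + count) / (1 + n_perm)
    return PartialCorrResult(
        rho=rho_obs,
        method=method,
        confound_names=names,
        n=n,
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def hedges_g(
    group1: np.ndarray, group2: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Bias-corrected standardized mean difference (group1 - group2).

    g = J * (m1 - m2) / s_pooled with J = 1 - 3 / (4(n1+n2) - 9); the 95% CI
    uses the large-sample variance (n1+n2)/(n1 n2) + g^2 / (2(n1+n2-2)).
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    d = (x1.mean() - x2.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = float(J * d)
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2 - 2)))
    return g, (g - 1.96 * se, g + 1.96 * se)


def group_ttests_bonferroni(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    n_comparisons: int | None = None,
) -> list[GroupComparison]:
    """Two-tailed pooled-variance t-test per diagnosis vs its own controls.

    ``groups`` maps label -> (patients, matched_controls); p-values are
    Bonferroni-adjusted over ``n_comparisons`` (default: number of groups),
    p_adj = min(1, p * n_comparisons).
    """
    if n_comparisons is None:
        n_comparisons = len(groups)
    out = []
    for label, (pat, ctl) in groups.items():
        pat = np.asarray(pat, dtype=float)
        ctl = np.asarray(ctl, dtype=float)
        if pat.shape[0] < 2 or ctl.shape[0] < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
        t, p = sst.ttest_ind(pat, ctl, equal_var=True)
        if np.isnan(t):  # identical constant groups
            t, p = 0.0, 1.0
        g, (lo, hi) = hedges_g(pat, ctl)
        out.append(
            GroupComparison(
                label=label,
                n1=pat.shape[0],
                n2=ctl.shape[0],
                t=float(t),
                df=pat.shape[0] + ctl.shape[0] - 2,
                p=float(p),
                p_adjusted=bonferroni_adjust(float(p), n_comparisons),
                adjust_method="bonferroni",
                hedges_g=g,
                g_ci_low=lo,
                g_ci_high=hi,
            )
        )
    return out


def bonferroni_adjust(p: float, n_comparisons: int) -> float:
    """p_adjusted = min(1, p * n_comparisons)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(min(1.0, p * n_comparisons))


def anova_oneway_holm(
    values: np.ndarray, labels: np.ndarray, posthoc: bool = True
) -> dict:
    """One-way ANOVA over diagnosis groups with Holm-corrected post-hoc pairs.

    Returns the F statistic and p-value, a Bartlett homoscedasticity report
    (informational, not gating), and — unless ``posthoc=False`` —
    pooled-variance pairwise t-tests with Holm step-down adjusted p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [str(u) for u in np.unique(labels)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    groups = [values[labels == u] for u in np.unique(labels)]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    F, p = sst.f_oneway(*groups)
    bart_stat, bart_p = sst.bartlett(*groups)
    posthoc_rows: list[dict] = []
    if posthoc:
        pairs = list(combinations(range(len(groups)), 2))
        raw = []
        trows = []
        for i, j in pairs:
            t, pij = sst.ttest_ind(groups[i], groups[j], equal_var=True)
            raw.append(float(pij))
            trows.append((names[i], names[j], float(t)))
        _, p_adj, *_ = multipletests(raw, method="holm")
        posthoc_rows = [
            {
                "group1": a,
                "group2": b,
                "t": t,
                "p": praw,
                "p_holm": float(padj),
            }
            for (a, b, t), praw, padj in zip(trows, raw, p_adj)
        ]
    return {
        "F": float(F),
        "df_between": len(groups) - 1,
        "df_within": values.shape[0] - len(groups),
        "p": float(p),
        "bartlett_stat": float(bart_stat),
        "bartlett_p": float(bart_p),
        "posthoc": posthoc_rows,
    }


def ci_containment(
    g_estimates: dict[str, float],
    meta_intervals: dict[str, dict[str, tuple[float, float]]],
) -> dict[str, dict[str, bool]]:
    """Is each diagnosis' effect size inside each meta-analytic 95% CI?

    ``meta_intervals`` maps diagnosis -> measure -> (low, high); intervals
    are closed, so boundary values count as contained.
    """
    out: dict[str, dict[str, bool]] = {}
    for diag, g in g_estimates.items():
        out[diag] = {}
        for measure, (lo, hi) in meta_intervals.get(diag, {}).items():
            if lo > hi:
                raise ValueError(
                    f"inverted interval for {diag}/{measure}: ({lo}, {hi})"
                )
            out[diag][measure] = bool(lo <= g <= hi)
    return out


def compare_dependent_correlations(
    a1: np.ndarray,
    a2: np.ndarray,
    b: np.ndarray,
    confounds: np.ndarray | None = None,
    method: str = "spearman",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Bootstrap test for a difference between two dependent partial
    correlations rho(a1, b) and rho(a2, b) sharing the variable ``b``.

    Subjects are resampled with replacement; the two-sided p-value is the
    percentile position of zero in the bootstrap distribution of the
    difference.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (a1.shape == a2.shape == b.shape):
        raise ValueError("a1, a2 and b must share the same subjects")
    n = b.shape[0]
    conf = None if confounds is None else np.asarray(confounds, dtype=float)
    rho1 = partial_correlation(a1, b, conf, method)
    rho2 = partial_correlation(a2, b, conf, method)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ck = None if conf is None else conf[idx]
        try:
            diffs[k] = partial_correlation(
                a1[idx], b[idx], ck, method
            ) - partial_correlation(a2[idx], b[idx], ck, method)
        except ValueError:  # degenerate resample
            diffs[k] = 0.0
    p = 2.0 * min(np.mean(diffs <= 0.0), np.mean(diffs >= 0.0))
    return {
        "rho1": rho1,
        "rho2": rho2,
        "diff": rho1 - rho2,
        "p_boot": float(min(1.0, max(p, 1.0 / n_boot))),
        "n_boot": n_boot,
        "seed": seed,
    }
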