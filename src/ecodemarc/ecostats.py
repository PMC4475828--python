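"""Ecological distinctness and interchangeability statistics.

Four tools: canonical correspondence analysis (CCA) of the variant x
sample table against temperature and depth; a permutation test for
nonrandom (clumped) placement of a PE's variants in ordination space;
the G-test of distribution heterogeneity on sequence counts; and
binomial-GLM trend tests for perturbation responses -- heterogeneity of
PE trajectories (distinctness) and stability of within-PE composition
(interchangeability).

CCA follows the ter Braak formulation: the chi-square standardized
abundance matrix is projected onto the row-mass-weighted span of the
standardized predictors and eigen-decomposed. Scores are reported in
species-conditional scaling ("scaling 2"), the convention under which
variant scores are fed to the cluster test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

UP, DOWN, FLAT = "up", "down", "none"


# ---------------------------------------------------------------------------
# CCA


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray           # constrained axes, non-increasing
    variant_scores: pd.DataFrame      # species scores, scaling 2
    site_scores: pd.DataFrame         # LC site scores
    total_inertia: float
    constrained_inertia: float
    predictor_fractions: dict[str, float]


def _cca_core(Y: np.ndarray, X: np.ndarray):
    """Return (eigenvalues, U, V_scaled, total_inertia) for counts Y
    (sites x species) constrained by standardized predictors X."""
    yt = Y.sum()
    P = Y / yt
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("empty row or column in abundance table")
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total = float((Qbar**2).sum())
    # weighted standardization of predictors
    mean = r @ X
    Xc = X - mean
    sd = np.sqrt(r @ (Xc**2))
    if (sd < 1e-12).any():
        raise ValueError("degenerate constraint: constant predictor")
    Xs = Xc / sd
    Xw = np.sqrt(r)[:, None] * Xs
    # projection of Qbar onto span(Xw)
    B, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    Yhat = Xw @ B
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(X.shape[1], int((S > 1e-12).sum()))
    S, U, Vt = S[:k], U[:, :k], Vt[:k]
    eig = S**2
    # scaling 2: species scores scaled by singular values
    V = (Vt.T / np.sqrt(c)[:, None]) * S
    Usites = U / np.sqrt(r)[:, None]
    return eig, Usites, V, total


def cca(abundance: pd.DataFrame, env: pd.DataFrame) -> OrdinationResult:
    """Canonical correspondence analysis of a variant x sample count table
    against environmental predictors (samples x predictors).

    Per-predictor explained fractions are marginal: the constrained
    inertia of a single-predictor CCA over the total inertia.
    """
    samples = list(abundance.columns)
    if list(env.index) != samples:
        env = env.loc[samples]
    Y = abundance.to_numpy(dtype=float).T  # sites x species
    X = env.to_numpy(dtype=float)
    eig, U, V, total = _cca_core(Y, X)
    constrained = float(eig.sum())
    fractions = {}
    for j, name in enumerate(env.columns):
        e_j, *_ , tot_j = _cca_core(Y, X[:, [j]])
        fractions[name] = float(e_j.sum()) / tot_j
    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    return OrdinationResult(
        eigenvalues=eig,
        variant_scores=pd.DataFrame(V, index=abundance.index, columns=axes),
        site_scores=pd.DataFrame(U, index=samples, columns=axes),
        total_inertia=total,
        constrained_inertia=constrained,
        predictor_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# ordination cluster permutation test


@dataclass
class ClusterTestResult:
    group: str
    statistic: float          # mean squared distance to group centroid
    p_value: float | None
    n_permutations: int
    seed: int | None
    testable: bool = True


def ordtest_cluster(scores: pd.DataFrame, members: Sequence[str],
                    n_perm: int = 999, seed: int = 0,
                    group_label: str = "PE") -> ClusterTestResult:
    """Permutation test for clumped placement of a group in ordination space.

    Statistic: mean squared Euclidean distance of the group's points to
    their centroid. Null: size-preserving random relabeling among all
    points. p = (1 + #{perm stat <= observed}) / (n_perm + 1).
    Groups with fewer than 2 members are not testable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = list(members)
    if len(members) < 2:
        return ClusterTestResult(group_label, np.nan, None, n_perm, seed,
                                 testable=False)
    pts = scores.to_numpy(dtype=float)
    idx = [scores.index.get_loc(m) for m in members]
    obs = _centroid_spread(pts[idx])
    rng = np.random.default_rng(seed)
    k, n = len(idx), pts.shape[0]
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    sub = pts[perm_idx]                       # n_perm x k x d
    cent = sub.mean(axis=1, keepdims=True)
    perm_stats = ((sub - cent) ** 2).sum(axis=2).mean(axis=1)
    p = (1 + int((perm_stats <= obs).sum())) / (n_perm + 1)
    return ClusterTestResult(group_label, float(obs), p, n_perm, seed)


def _centroid_spread(points: np.ndarray) -> float:
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# G-test


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float


def g_test(counts) -> GTestResult:
    """Log-likelihood-ratio test of independence on a contingency table.

    G = 2 sum O ln(O/E) over cells with O > 0; df = (r-1)(c-1); p from
    the chi-square approximation. Zero rows/columns are dropped with a
    warning.
    """
    O = np.asarray(counts, dtype=float)
    if O.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    keep_r = O.sum(axis=1) > 0
    keep_c = O.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero rows/columns from contingency table")
        O = O[keep_r][:, keep_c]
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2 after "
                         "dropping empty rows/columns")
    n = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    g = float(2.0 * special.xlogy(O, O / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return GTestResult(g=g, df=df, p_value=float(stats.chi2.sf(g, df)))


# ---------------------------------------------------------------------------
# perturbation trend tests (binomial GLM; ANCOVA alternate mode)


@dataclass
class TrendTestResult:
    interaction_p: float              # heterogeneity of slopes: distinctness
    interaction_df: int
    slopes: pd.DataFrame              # per PE: slope, p, direction
    method: str


@dataclass
class HomogeneityResult:
    components: pd.DataFrame          # per component: slope, p
    worst_p: float                    # min component p (anti-conservative)


def _binomial_glm(successes, totals, X):
    import statsmodels.api as sm

    endog = np.column_stack([successes, np.asarray(totals) - successes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        return model.fit()


def perturbation_trend(counts: pd.DataFrame,
                       times: Sequence[float] | None = None,
                       method: str = "glm",
                       alpha: float = 0.05) -> TrendTestResult:
    """Test whether PEs changed their relative frequencies separately
    over time (ecological distinctness under perturbation).

    ``counts`` is PE x timepoint; column totals are the per-timepoint
    sequence totals. The default models the counts with a binomial-family
    generalization of linear regression in its multinomial log-linear
    (surrogate Poisson) form: counts ~ PE + timepoint + PE x linear-time,
    with the per-timepoint totals conditioned out by the timepoint
    factor. Heterogeneity of the PE trends is tested by the deviance
    difference of dropping the interaction block, against chi-square with
    (n_pe - 1) df. Per-PE slopes come from marginal binomial GLMs of the
    PE's share on time and get direction labels (up/down/none at
    ``alpha``). method="ancova" instead fits OLS on arcsine-sqrt
    proportions and F-tests the interaction.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    if times is None:
        times = [float(t) for t in counts.columns]
    times = np.asarray(times, dtype=float)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    pes = list(counts.index)
    n_pe = len(pes)
    n_t = len(times)
    # long format: one row per (pe, timepoint)
    y = counts.to_numpy(dtype=float).ravel()
    tot = np.tile(totals, n_pe)
    t_long = np.tile(times, n_pe)
    pe_idx = np.repeat(np.arange(n_pe), n_t)
    pe_dummies = np.eye(n_pe)[pe_idx]          # cell-means coding
    X_full = np.column_stack([pe_dummies, pe_dummies * t_long[:, None]])
    X_red = np.column_stack([pe_dummies, t_long])
    if method == "glm":
        import statsmodels.api as sm

        tp_dummies = np.eye(n_t)[np.tile(np.arange(n_t), n_pe)][:, 1:]
        inter = (pe_dummies * t_long[:, None])[:, 1:]   # drop reference PE
        Z_red = np.column_stack([pe_dummies, tp_dummies])
        Z_full = np.column_stack([Z_red, inter])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(y, Z_full, family=sm.families.Poisson()).fit()
            red = sm.GLM(y, Z_red, family=sm.families.Poisson()).fit()
        dev_diff = red.deviance - full.deviance
        df = n_pe - 1
        p_int = float(stats.chi2.sf(dev_diff, df))
        slope_rows = []
        for i, pe in enumerate(pes):
            fit = _binomial_glm(counts.loc[pe].to_numpy(dtype=float), totals,
                                np.column_stack([np.ones_like(times), times]))
            slope = fit.params[1]
            p = fit.pvalues[1]
            slope_rows.append((pe, slope, p, _direction(slope, p, alpha)))
    elif method == "ancova":
        import statsmodels.api as sm

        props = np.clip(y / tot, 0, 1)
        z = np.arcsin(np.sqrt(props))
        full = sm.OLS(z, X_full).fit()
        red = sm.OLS(z, X_red).fit()
        ftest = full.compare_f_test(red)
        p_int, df = float(ftest[0:2][1]), int(ftest[2])
        slope_rows = []
        for i, pe in enumerate(pes):
            zi = np.arcsin(np.sqrt(np.clip(
                counts.loc[pe].to_numpy(dtype=float) / totals, 0, 1)))
            fit = sm.OLS(zi, np.column_stack([np.ones_like(times),
                                              times])).fit()
            slope, p = fit.params[1], fit.pvalues[1]
            slope_rows.append((pe, slope, p, _direction(slope, p, alpha)))
    else:
        raise ValueError(f"unknown method {method!r}")
    slopes = pd.DataFrame(slope_rows,
                          columns=["pe", "slope", "p", "direction"]
                          ).set_index("pe")
    return TrendTestResult(interaction_p=p_int, interaction_df=df,
                           slopes=slopes, method=method)


def _direction(slope: float, p: float, alpha: float) -> str:
    if p >= alpha:
        return FLAT
    return UP if slope > 0 else DOWN


def within_pe_homogeneity(hfs_counts: pd.DataFrame,
                          lfs_counts: pd.Series | None = None,
                          times: Sequence[float] | None = None
                          ) -> HomogeneityResult:
    """Test whether the composition inside one PE shifted over time.

    For each HFS, a binomial GLM of its share of the PE total on time;
    if LFS counts are given, also the LFS:HFS ratio on time. Flat slopes
    (large p) indicate ecological interchangeability of the variants.
    """
    if hfs_counts.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    if times is None:
        times = [float(t) for t in hfs_counts.columns]
    times = np.asarray(times, dtype=float)
    hfs_total = hfs_counts.sum(axis=0).to_numpy(dtype=float)
    pe_total = hfs_total.copy()
    if lfs_counts is not None:
        pe_total = pe_total + lfs_counts.to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(times), times])
    rows = []
    for h in hfs_counts.index:
        fit = _binomial_glm(hfs_counts.loc[h].to_numpy(dtype=float),
                            pe_total, X)
        rows.append((f"HFS:{h}", fit.params[1], fit.pvalues[1]))
    if lfs_counts is not None:
        fit = _binomial_glm(lfs_counts.to_numpy(dtype=float), pe_total, X)
        rows.append(("LFS-share", fit.params[1], fit.pvalues[1]))
    comp = pd.DataFrame(rows, columns=["component", "slope", "p"]
                        ).set_index("component")
    return HomogeneityResult(components=comp, worst_p=float(comp["p"].min()))


def plot_ordination(result: OrdinationResult,
                    highlight: dict[str, Sequence[str]] | None = None,
                    path: str | None = None):
    """Scatter the variant scores on the first two constrained axes,
    color-highlighting each listed PE's variants against a grey
    background cloud; writes SVG when ``path`` is given."""
    import matplotlib
    matplotlib.use("svg", force=False)
    import matplotlib.pyplot as plt

    scores = result.variant_scores
    axes = list(scores.columns[:2])
    if len(axes) < 2:
        raise ValueError("need at least two constrained axes to plot")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(scores[axes[0]], scores[axes[1]], s=12, c="0.7",
               label="_background")
    for i, (pe, members) in enumerate(sorted((highlight or {}).items())):
        sub = scores.loc[[m for m in members if m in scores.index]]
        ax.scatter(sub[axes[0]], sub[axes[1]], s=30,
                   c=f"C{i % 10}", label=pe)
    ax.set_xlabel(f"{axes[0]} ({result.eigenvalues[0]:.3f})")
    ax.set_ylabel(f"{axes[1]} ({result.eigenvalues[1]:.3f})")
    if highlight:
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig
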