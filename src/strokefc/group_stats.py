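"""Group-level univariate statistics.

The core is a mixed-design (split-plot) ANOVA with one between-subject
factor (group) and one within-subject factor (condition: rest, L1, L2),
applied per edge or per node. Effect sums of squares are Type III
(cell-means / sum-to-zero contrasts, appropriate for the unbalanced
44-vs-100 design); the group effect is tested against the
subject-within-group stratum and the condition and interaction effects
against the condition×subject-within-group stratum. No sphericity
correction is applied by default; a Greenhouse–Geisser option is exposed.
Multiplicity is handled by Benjamini–Hochberg FDR separately per effect.

SDSA — the standard deviation of a node's time series — is computed on the
unstandardized signals, upstream of the unit-variance scaling used for
network estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import node_columns


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass
class MixedAnovaResult:
    F_group: float
    F_condition: float
    F_interaction: float
    df_group: tuple[int, int]
    df_condition: tuple[int, int]
    df_interaction: tuple[int, int]
    p_group: float
    p_condition: float
    p_interaction: float
    degenerate: bool = False


def _sum_code(idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n_levels − 1 columns."""
    X = np.zeros((idx.size, n_levels - 1))
    for lev in range(n_levels - 1):
        X[idx == lev, lev] = 1.0
    X[idx == n_levels - 1, :] = -1.0
    return X


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    fitted_norm2 = ((Q.T @ Y) ** 2).sum(axis=0)
    return (Y**2).sum(axis=0) - fitted_norm2


def mixed_anova_many(Y: np.ndarray, group_labels, gg: bool = False) -> dict[str, np.ndarray]:
    """Split-plot ANOVA for many response variables at once.

    ``Y`` has shape (N subjects, C conditions, E variables); every subject
    contributes all conditions (no imputation — missing cells must be
    rejected upstream). Returns arrays of F statistics, p-values and the
    degrees of freedom shared by all variables.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    N, C, E = Y.shape
    if np.isnan(Y).any():
        raise ValueError("missing cells are not allowed")
    groups = np.asarray(group_labels)
    if groups.shape[0] != N:
        raise ValueError("one group label per subject required")
    glabels, gidx = np.unique(groups, return_inverse=True)
    G = glabels.size
    if G < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(gidx)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    if C < 2:
        raise ValueError("need at least 2 conditions")

    # observation-level design, subject-major ordering
    g_obs = np.repeat(gidx, C)
    c_obs = np.tile(np.arange(C), N)
    ones = np.ones((N * C, 1))
    Xg = _sum_code(g_obs, G)
    Xc = _sum_code(c_obs, C)
    Xi = np.concatenate(
        [Xg[:, [a]] * Xc[:, [b]] for a in range(G - 1) for b in range(C - 1)], axis=1
    )
    Yf = Y.reshape(N * C, E)

    sse_full = _sse(np.hstack([ones, Xg, Xc, Xi]), Yf)
    ss_group = _sse(np.hstack([ones, Xc, Xi]), Yf) - sse_full
    ss_cond = _sse(np.hstack([ones, Xg, Xi]), Yf) - sse_full
    ss_inter = _sse(np.hstack([ones, Xg, Xc]), Yf) - sse_full

    # error strata
    m = Y.mean(axis=1)                                   # N x E subject means
    gmean = np.stack([m[gidx == g].mean(axis=0) for g in range(G)])   # G x E
    ss_subj = C * ((m - gmean[gidx]) ** 2).sum(axis=0)
    df_subj = N - G
    cellmean = np.stack(
        [Y[gidx == g].mean(axis=0) for g in range(G)]
    )                                                     # G x C x E
    fitted = m[:, None, :] + cellmean[gidx] - gmean[gidx][:, None, :]
    ss_resid = ((Y - fitted) ** 2).sum(axis=(0, 1))
    df_resid = (N - G) * (C - 1)

    df_g, df_c, df_i = G - 1, C - 1, (G - 1) * (C - 1)
    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    scale = np.maximum((Yf**2).sum(axis=0), 1.0)
    degenerate = (ms_subj <= 1e-12 * scale) | (ms_resid <= 1e-12 * scale)

    def f_and_p(ss, df1, ms_err):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(degenerate, 0.0, (ss / df1) / np.where(ms_err > 0, ms_err, np.nan))
        F = np.where(np.isfinite(F), F, 0.0)
        F = np.maximum(F, 0.0)
        return F, np.where(degenerate, 1.0, stats.f.sf(F, df1, df_subj if ms_err is ms_subj else df_resid))

    F_group, p_group = f_and_p(ss_group, df_g, ms_subj)
    F_cond, p_cond = f_and_p(ss_cond, df_c, ms_resid)
    F_inter, p_inter = f_and_p(ss_inter, df_i, ms_resid)

    if gg:
        # Greenhouse–Geisser epsilon from the pooled double-centered
        # within-subject covariance, applied to the within-stratum tests
        W = Y - cellmean[gidx]                                  # N x C x E
        H = np.eye(C) - np.ones((C, C)) / C
        p_cond = p_cond.copy()
        p_inter = p_inter.copy()
        for e in range(E):
            Sc = np.cov(W[:, :, e], rowvar=False, ddof=1)
            Sdc = H @ Sc @ H
            tr = np.trace(Sdc)
            tr2 = np.trace(Sdc @ Sdc)
            eps = 1.0 / (C - 1) if tr2 <= 0 else float(np.clip(tr**2 / ((C - 1) * tr2), 1.0 / (C - 1), 1.0))
            if not degenerate[e]:
                p_cond[e] = stats.f.sf(F_cond[e], eps * df_c, eps * df_resid)
                p_inter[e] = stats.f.sf(F_inter[e], eps * df_i, eps * df_resid)

    return {
        "F_group": F_group, "p_group": p_group, "df_group": (df_g, df_subj),
        "F_condition": F_cond, "p_condition": p_cond, "df_condition": (df_c, df_resid),
        "F_interaction": F_inter, "p_interaction": p_inter, "df_interaction": (df_i, df_resid),
        "degenerate": degenerate,
    }


def mixed_anova(values: np.ndarray, group_labels, gg: bool = False) -> MixedAnovaResult:
    """Split-plot ANOVA for a single variable (subjects × conditions)."""
    res = mixed_anova_many(np.asarray(values, dtype=float)[:, :, None], group_labels, gg=gg)
    return MixedAnovaResult(
        F_group=float(res["F_group"][0]),
        F_condition=float(res["F_condition"][0]),
        F_interaction=float(res["F_interaction"][0]),
        df_group=res["df_group"],
        df_condition=res["df_condition"],
        df_interaction=res["df_interaction"],
        p_group=float(res["p_group"][0]),
        p_condition=float(res["p_condition"][0]),
        p_interaction=float(res["p_interaction"][0]),
        degenerate=bool(res["degenerate"][0]),
    )


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _stats_table(Y, group_labels, names, q, name_col):
    res = mixed_anova_many(Y, group_labels)
    out = pd.DataFrame({name_col: names})
    for eff in ("group", "condition", "interaction"):
        F = res[f"F_{eff}"]
        p = res[f"p_{eff}"]
        df1, df2 = res[f"df_{eff}"]
        out[f"F_{eff}"] = F
        out[f"df1_{eff}"] = df1
        out[f"df2_{eff}"] = df2
        out[f"p_{eff}"] = p
        out[f"sig_{eff}"] = p < 0.05
        out[f"fdr_{eff}"] = fdr_bh(p, q=q)
    out["degenerate"] = res["degenerate"]
    return out


def _pivot_complete(table: pd.DataFrame, value_cols, conditions=None) -> tuple[np.ndarray, np.ndarray, list]:
    conds = sorted(table["condition"].unique()) if conditions is None else list(conditions)
    subs = table["subject_id"].unique()
    wide = table.set_index(["subject_id", "condition"]).sort_index()
    Y = np.empty((len(subs), len(conds), len(value_cols)))
    groups = []
    for si, s in enumerate(subs):
        for ci, c in enumerate(conds):
            try:
                row = wide.loc[(s, c)]
            except KeyError:
                raise ValueError(f"subject {s} is missing condition {c}") from None
            Y[si, ci] = row[value_cols].to_numpy(dtype=float)
        groups.append(wide.loc[(s, conds[0])]["group"])
    return Y, np.asarray(groups), list(subs)


def edgewise_anova(edge_table: pd.DataFrame, q: float = 0.05, conditions=None) -> pd.DataFrame:
    """Per-edge split-plot ANOVA with BH-FDR applied separately per effect."""
    edge_cols = [c for c in edge_table.columns if c.startswith("edge_")]
    if not edge_cols:
        raise ValueError("no edge_* columns in the table")
    Y, groups, _ = _pivot_complete(edge_table, edge_cols, conditions)
    return _stats_table(Y, groups, edge_cols, q, "edge")


def compute_sdsa(ts: np.ndarray) -> np.ndarray:
    """SDSA: sample SD (denominator T−1) of each node's raw time series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need a T x K matrix with T >= 2")
    return ts.std(axis=0, ddof=1)


def sdsa_table(cohort) -> pd.DataFrame:
    """Per subject × condition × node SDSA for a whole cohort."""
    cols = node_columns(cohort.n_nodes)
    groups = cohort.groups_of()
    rows = []
    for (sid, cond), ts in cohort.series.items():
        rows.append({"subject_id": sid, "group": groups[sid], "condition": cond,
                     **dict(zip(cols, compute_sdsa(ts)))})
    return pd.DataFrame(rows)


def nodewise_sdsa_anova(sdsa: pd.DataFrame, q: float = 0.05, conditions=None) -> pd.DataFrame:
    """Per-node split-plot ANOVA of SDSA with BH-FDR per effect."""
    cols = [c for c in sdsa.columns if c.startswith("node_")]
    if not cols:
        raise ValueError("no node_* columns in the table")
    Y, groups, _ = _pivot_complete(sdsa, cols, conditions)
    return _stats_table(Y, groups, cols, q, "node")


def welch_t_from_summary(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from (mean, sd, n) summaries.

    Returns (t, Welch–Satterthwaite df, two-sided p). Zero variance in
    both groups with equal means gives t = 0 by convention.
    """
    a = a if isinstance(a, GroupSummary) else GroupSummary(*a)
    b = b if isinstance(b, GroupSummary) else GroupSummary(*b)
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance with unequal means")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
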