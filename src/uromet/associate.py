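"""Univariate GA-association screening and related descriptive analyses.

* per-feature Spearman screen (descriptive, raw P < 0.05 by default;
  Benjamini-Hochberg available behind a flag) with a volcano beta from an
  OLS fit of log2 abundance on GA;
* PCA of the significant features with GA-correlated axis selection;
* coefficient of variation per GA bin, stratified by delivery outcome;
* one-sided Fisher-exact over-representation of supplied pathway sets;
* overlap of stratified model panels with the full-cohort panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_screen",
    "pca_ga_axes",
    "cv_by_ga_bin",
    "pathway_ora",
    "model_overlap",
    "DEFAULT_GA_BINS",
]

#: GA-bin edges in weeks for the variability analysis
DEFAULT_GA_BINS = (8.0, 11.0, 14.0, 17.0, 19.0)


def spearman_screen(
    X, y, alpha: float = 0.05, correct: str | None = None
) -> pd.DataFrame:
    """Per-feature Spearman association with GA plus a log2 volcano beta.

    ``X`` is samples x features (positive abundances), ``y`` GA in weeks.
    Returns a DataFrame indexed by feature with columns ``rho``, ``p``,
    ``beta`` (log2 change per week from OLS) and ``significant``.
    ``correct='bh'`` applies Benjamini-Hochberg before thresholding.
    """
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    y = np.asarray(y, dtype=float)
    if len(Xf) != len(y):
        raise ValueError("X and y length mismatch")
    vals = Xf.to_numpy(float)
    n_feat = vals.shape[1]
    rho = np.empty(n_feat)
    p = np.empty(n_feat)
    ry = stats.rankdata(y)
    log2X = np.log2(vals)
    ga_c = y - y.mean()
    denom = float((ga_c**2).sum())
    beta = (ga_c @ (log2X - log2X.mean(axis=0))) / denom
    for j in range(n_feat):
        col = vals[:, j]
        if np.ptp(col) == 0:
            rho[j], p[j] = 0.0, 1.0
            logger.info("feature %r is constant; rho set to 0", Xf.columns[j])
            continue
        rho[j], p[j] = stats.spearmanr(ry, col)
    p_for_mask = p.copy()
    if correct == "bh":
        from statsmodels.stats.multitest import multipletests

        p_for_mask = multipletests(p, method="fdr_bh")[1]
    elif correct is not None:
        raise ValueError(f"unknown correction {correct!r}")
    return pd.DataFrame(
        {"rho": rho, "p": p, "beta": beta, "significant": p_for_mask < alpha},
        index=Xf.columns,
    )


def pca_ga_axes(
    X_sig, y, n_components: int = 10
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """PCA of the significant-feature matrix with GA-driven axis choice.

    Features are standardized (mean 0, SD 1); the two components whose
    scores correlate most strongly (|Spearman rho|) with GA are selected.
    Returns (scores, per-PC rho, [chosen PC names]).
    """
    Xf = X_sig if isinstance(X_sig, pd.DataFrame) else pd.DataFrame(np.asarray(X_sig, float))
    y = np.asarray(y, dtype=float)
    if Xf.shape[1] < 2:
        raise ValueError("need at least 2 features for PCA")
    if len(Xf) < 3:
        raise ValueError("need at least 3 samples for PCA")
    vals = Xf.to_numpy(float)
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (vals - vals.mean(axis=0)) / sd
    k = max(1, min(n_components, Z.shape[0] - 1, Z.shape[1]))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    names = [f"PC{i + 1}" for i in range(k)]
    rhos = []
    for i in range(k):
        if np.ptp(scores[:, i]) == 0:
            rhos.append(0.0)
        else:
            rhos.append(float(stats.spearmanr(scores[:, i], y)[0]))
    rho_s = pd.Series(rhos, index=names, name="rho_ga")
    chosen = list(rho_s.abs().sort_values(ascending=False).index[:2])
    scores_df = pd.DataFrame(scores, index=Xf.index, columns=names)
    scores_df.attrs["explained_variance"] = pca.explained_variance_
    return scores_df, rho_s, chosen


def cv_by_ga_bin(
    X_top, y, bins: tuple[float, ...] = DEFAULT_GA_BINS, groups=None
) -> dict[str, pd.DataFrame]:
    """Coefficient of variation (SD/mean of raw abundances) per GA bin.

    Computed per feature, separately per group (e.g. term vs preterm); a
    group's empty or zero-mean bin yields NaN. Returns
    {group: DataFrame features x bins}.
    """
    Xf = X_top if isinstance(X_top, pd.DataFrame) else pd.DataFrame(np.asarray(X_top, float))
    y = np.asarray(y, dtype=float)
    edges = np.asarray(bins, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    if groups is None:
        groups = pd.Series(["all"] * len(Xf), index=Xf.index)
    else:
        groups = pd.Series(np.asarray(groups), index=Xf.index)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(groups.unique()):
        rows = groups == g
        yg = y[rows.to_numpy()]
        Xg = Xf.loc[rows.to_numpy()].to_numpy(float)
        cv = np.full((Xf.shape[1], len(labels)), np.nan)
        for b in range(len(labels)):
            hi_inclusive = b == len(labels) - 1
            in_bin = (yg >= edges[b]) & ((yg <= edges[b + 1]) if hi_inclusive else (yg < edges[b + 1]))
            if in_bin.sum() < 2:
                logger.info("group %r bin %s has <2 samples; CV undefined", g, labels[b])
                continue
            block = Xg[in_bin]
            mean = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                c = sd / mean
            cv[:, b] = np.where(mean > 0, c, np.nan)
        out[str(g)] = pd.DataFrame(cv, index=Xf.columns, columns=labels)
    return out


def pathway_ora(
    significant_ids, background_ids, pathways: dict[str, set], alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of pathway sets.

    For each pathway the 2x2 table (in/out pathway x significant/not) over
    the background universe is tested for enrichment (alternative='greater').
    """
    background = set(background_ids)
    if not background:
        raise ValueError("background set is empty")
    significant = set(significant_ids)
    if not significant <= background:
        raise ValueError("significant ids must be a subset of the background")
    rows = []
    for pid, members in sorted(pathways.items()):
        in_path = set(members) & background
        hits = len(in_path & significant)
        table = [
            [hits, len(in_path) - hits],
            [len(significant) - hits, len(background) - len(in_path) - len(significant) + hits],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {"pathway": pid, "n_pathway": len(in_path), "n_hits": hits,
             "p": float(p), "significant": p <= alpha}
        )
    return pd.DataFrame(rows).set_index("pathway")


def model_overlap(selected_full, selected_a, selected_b) -> dict:
    """Overlap of stratified panels with the full-cohort panel + Venn sizes.

    Overlap percentages follow |group ∩ full| / |group|; an empty group
    yields NaN. Venn partition keys are 'full_only', 'a_only', 'b_only',
    'full_a', 'full_b', 'a_b', 'full_a_b'.
    """
    full, a, b = set(selected_full), set(selected_a), set(selected_b)

    def pct(group: set) -> float:
        return float("nan") if not group else 100.0 * len(group & full) / len(group)

    venn = {
        "full_only": len(full - a - b),
        "a_only": len(a - full - b),
        "b_only": len(b - full - a),
        "full_a": len((full & a) - b),
        "full_b": len((full & b) - a),
        "a_b": len((a & b) - full),
        "full_a_b": len(full & a & b),
    }
    return {"overlap_a_pct": pct(a), "overlap_b_pct": pct(b), "venn": venn}
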