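"""TR-metabolite association networks and tissue-signature statistics.

Associations are pairwise Spearman correlations between inferred TR
activities and Z-scored metabolite abundances across cell lines. Network
links are thresholded at an |R| cutoff controlling the false discovery rate,
obtained by pooling correlations from label-resampled null data sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ActivityMatrix, AssociationMatrix, FdrThreshold, ZMatrix


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm."""
    r = stats.rankdata(X, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    norm[norm == 0] = np.nan
    return r / norm


def spearman_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman R and two-sided p between rows of X and rows of Y.

    Ties get average ranks; p-values use the t approximation on n-2 degrees
    of freedom. Rows that are constant yield NaN (pair undefined).
    """
    n = X.shape[1]
    if Y.shape[1] != n:
        raise ValueError("X and Y must share the sample axis")
    R = _rank_standardize(X) @ _rank_standardize(Y).T
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(R), 1.0)] = 0.0
    p[np.isnan(R)] = np.nan
    return R, p


def correlate(activity: ActivityMatrix | pd.DataFrame, z: ZMatrix | pd.DataFrame) -> AssociationMatrix:
    """Spearman correlation of every TR against every metabolite.

    Computed over the cell lines shared by the two tables (>= 5 required).
    Missing metabolite values are treated as zero — they mark abundances at
    background level. Constant rows give NaN entries (pair undefined).
    """
    act = activity.activity if isinstance(activity, ActivityMatrix) else activity
    zm = z.z if isinstance(z, ZMatrix) else z
    shared = act.columns.intersection(zm.columns)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared cell lines, got {len(shared)}")
    X = act[shared].to_numpy(dtype=float)
    Y = zm[shared].fillna(0.0).to_numpy(dtype=float)
    R, p = spearman_matrix(X, Y)
    return AssociationMatrix(
        R=pd.DataFrame(R, index=act.index, columns=zm.index),
        p=pd.DataFrame(p, index=act.index, columns=zm.index),
        n_obs=len(shared),
    )


def bootstrap_fdr(
    activity: ActivityMatrix | pd.DataFrame,
    z: ZMatrix | pd.DataFrame,
    n_resamples: int = 100,
    fdr: float = 0.001,
    seed: int = 0,
) -> FdrThreshold:
    """|R| cutoff controlling the association-network FDR.

    Per resample the cell-line labels of the metabolome table are resampled
    with replacement — independently of the activity table, which breaks the
    pairing and produces a null. All pairwise |R| values are pooled over
    resamples and the threshold is the (1 - fdr) quantile of the pooled null
    (the smallest correlation exceeding the (1-fdr) fraction of lowest null
    correlations).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    act = activity.activity if isinstance(activity, ActivityMatrix) else activity
    zm = z.z if isinstance(z, ZMatrix) else z
    shared = act.columns.intersection(zm.columns)
    X = act[shared].to_numpy(dtype=float)
    Y = zm[shared].fillna(0.0).to_numpy(dtype=float)
    n = len(shared)
    rng = np.random.default_rng(seed)

    Xr = _rank_standardize(X)
    pooled = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        Yr = _rank_standardize(Y[:, idx])
        R = Xr @ Yr.T
        pooled.append(np.abs(R[np.isfinite(R)]))
    null = np.concatenate(pooled)
    threshold = float(np.quantile(null, 1.0 - fdr)) if fdr < 1 else 0.0
    return FdrThreshold(threshold=min(threshold, 1.0), fdr=fdr, n_resamples=n_resamples)


def association_links(assoc: AssociationMatrix, threshold: FdrThreshold | float) -> pd.DataFrame:
    """Long-format network links passing the |R| cutoff."""
    cut = threshold.threshold if isinstance(threshold, FdrThreshold) else float(threshold)
    long = assoc.R.stack().rename("R").reset_index()
    long.columns = ["tr", "metabolite", "R"]
    long["p"] = assoc.p.stack().to_numpy()
    long["pass_fdr"] = long["R"].abs() >= cut
    return long


def augmented_network(
    activity: pd.DataFrame,
    expression: pd.DataFrame,
    enzyme_genes: list[str],
    r_threshold: float = 0.5,
) -> pd.DataFrame:
    """TR-enzyme edges from activity/expression co-variation on a compendium.

    An edge (TR, enzyme) is drawn iff |Spearman R| between the TR's activity
    profile and the enzyme's transcript profile exceeds ``r_threshold``
    (default 0.5), expanding the curated network to enzymes a TR regulates
    directly or indirectly.
    """
    shared = activity.columns.intersection(expression.columns)
    enz = [g for g in enzyme_genes if g in expression.index]
    X = activity[shared].to_numpy(dtype=float)
    Y = expression.loc[enz, shared].to_numpy(dtype=float)
    R, _ = spearman_matrix(X, Y)
    rows = []
    trs = list(activity.index)
    for i, tr in enumerate(trs):
        for j, g in enumerate(enz):
            if np.isfinite(R[i, j]) and abs(R[i, j]) > r_threshold:
                rows.append((tr, g, R[i, j]))
    return pd.DataFrame(rows, columns=["tr", "enzyme", "R"])


def tissue_anova(z: ZMatrix | pd.DataFrame, tissue: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of each metabolite's abundance across tissue groups.

    Requires >= 2 tissues with >= 2 lines each; degenerate metabolites
    (constant within every group) are flagged and skipped. Storey q-values
    are appended.
    """
    from .enrich import storey_q

    zm = z.z if isinstance(z, ZMatrix) else z
    shared = zm.columns.intersection(tissue.index)
    groups = tissue.loc[shared]
    sizes = groups.value_counts()
    valid_tissues = sizes.index[sizes >= 2]
    if len(valid_tissues) < 2:
        raise ValueError("need >= 2 tissues with >= 2 lines each")
    cols_by_tissue = [shared[(groups == t).to_numpy()] for t in valid_tissues]

    out = []
    for ion in zm.index:
        vals = [zm.loc[ion, c].dropna().to_numpy() for c in cols_by_tissue]
        vals = [v for v in vals if len(v) >= 2]
        if len(vals) < 2 or all(np.ptp(v) == 0 for v in vals):
            out.append((ion, np.nan, np.nan, True))
            continue
        f, p = stats.f_oneway(*vals)
        out.append((ion, float(f), float(p), False))
    df = pd.DataFrame(out, columns=["metabolite", "F", "p", "degenerate"]).set_index("metabolite")
    mask = df["p"].notna()
    q = pd.Series(np.nan, index=df.index)
    if mask.sum():
        q[mask] = storey_q(df.loc[mask, "p"].to_numpy())
    df["q"] = q
    return df


def tissue_similarity_roc(
    profiles: pd.DataFrame,
    tissue: pd.Series,
    method: str = "spearman",
) -> float:
    """AUC for same-tissue line pairs being more similar than cross-tissue.

    All unordered pairs of cell lines are scored by the correlation of their
    molecular profiles (columns of ``profiles``); the positive class is
    "same tissue". Returns the area under the ROC curve.
    """
    from sklearn.metrics import roc_auc_score

    shared = profiles.columns.intersection(tissue.index)
    X = profiles[shared].fillna(0.0).to_numpy(dtype=float)
    if method == "spearman":
        Xs = _rank_standardize(X.T)
    elif method == "pearson":
        Xc = X.T - X.T.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Xc, axis=1, keepdims=True)
        norm[norm == 0] = np.nan
        Xs = Xc / norm
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    S = Xs @ Xs.T
    labels = tissue.loc[shared].to_numpy()
    iu = np.triu_indices(len(shared), k=1)
    scores = S[iu]
    y = (labels[iu[0]] == labels[iu[1]]).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both same-tissue and cross-tissue pairs")
    return float(roc_auc_score(y, scores))
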