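"""Dot-product scores linking TR-metabolite signatures to phenotypes.

All scores share one functional form: the inner product of a TR's metabolite
signature with a metabolite-indexed observation vector, normalized by the L1
norm of the signature,

    S_TR = (C_TR . x) / ||C_TR||_1,

where C_TR holds Spearman R x (-log10 p) per metabolite. The observation x
is a flux-correlation vector (glycolytic-flux scoring), a patient's log2
fold-changes (in-vivo TR inference), or siRNA-knockdown fold-changes (TR
ranking). Significance comes from shuffling the metabolite order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import spearman_matrix
from .enrich import hypergeom_p, storey_q
from .types import AssociationMatrix


# ---------------------------------------------------------------------------
# glycolytic flux
# ---------------------------------------------------------------------------

def metabolite_flux_correlation(
    z: pd.DataFrame, uptake: pd.Series, secretion: pd.Series
) -> pd.Series:
    """Mean Spearman correlation of each metabolite with glucose uptake and
    lactate secretion over shared cell lines (>= 5 required)."""
    shared = z.columns.intersection(uptake.index).intersection(secretion.index)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared cell lines, got {len(shared)}")
    for name, v in (("uptake", uptake), ("secretion", secretion)):
        if v[shared].nunique() <= 1:
            raise ValueError(f"constant {name} vector")
    X = z[shared].fillna(0.0).to_numpy(dtype=float)
    F = np.vstack([uptake[shared].to_numpy(), secretion[shared].to_numpy()])
    R, _ = spearman_matrix(X, F)
    return pd.Series(R.mean(axis=1), index=z.index, name="flux_correlation")


def tr_flux_score(assoc: AssociationMatrix | pd.DataFrame, flux_corr: pd.Series) -> pd.Series:
    """Per-TR association with glycolytic flux.

    ``score_TR = sum_m R_TR,m flux_corr_m / sum_m |R_TR,m|`` over the shared
    metabolite space; undefined pairs contribute zero. TRs whose correlation
    row is all zero are returned NaN.
    """
    R = assoc.R if isinstance(assoc, AssociationMatrix) else assoc
    shared = R.columns.intersection(flux_corr.index)
    Rm = R[shared].fillna(0.0).to_numpy(dtype=float)
    f = flux_corr[shared].fillna(0.0).to_numpy(dtype=float)
    denom = np.abs(Rm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (Rm @ f) / denom
    score[denom == 0] = np.nan
    return pd.Series(score, index=R.index, name="flux_score")


def pathway_tr_score(
    tr_scores: pd.Series,
    pathway_trs: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean TR flux-association score per pathway with permutation p / q.

    For each pathway the mean score over its TRs (those with enzyme targets
    in the pathway) is compared with means of equal-size TR sets drawn at
    random; the two-sided permutation p is the fraction of null means at
    least as extreme around the global mean. Pathways with no mapped TR
    raise a KeyError.
    """
    scores = tr_scores.dropna()
    rng = np.random.default_rng(seed)
    vals = scores.to_numpy()
    rows = []
    for pw, trs in pathway_trs.items():
        members = [t for t in trs if t in scores.index]
        if not members:
            raise KeyError(f"pathway {pw!r} has no mapped TR with a score")
        obs = float(scores[members].mean())
        k = len(members)
        null = vals[rng.integers(0, len(vals), size=(n_perm, k))].mean(axis=1)
        center = vals.mean()
        p = float(np.mean(np.abs(null - center) >= abs(obs - center)))
        p = max(p, 1.0 / n_perm)
        rows.append((pw, k, obs, p))
    df = pd.DataFrame(rows, columns=["pathway", "n_trs", "mean_score", "p"]).set_index("pathway")
    df["q"] = storey_q(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# in-vivo TR inference from patient fold-changes
# ---------------------------------------------------------------------------

@dataclass
class InvivoResult:
    """Per-(TR, patient) scores and per-TR medians for one cohort."""

    S: pd.DataFrame        # TRs x patients
    p: pd.DataFrame        # permutation p per (TR, patient)
    q: pd.DataFrame        # Storey q per patient (column-wise)
    median_S: pd.Series
    median_q: pd.Series
    metabolites_used: list[str]


def filter_cohort_metabolites(fc: pd.DataFrame, max_missing: int = 10) -> pd.DataFrame:
    """Drop metabolites with more than ``max_missing`` missing patient values."""
    keep = fc.isna().sum(axis=1) <= max_missing
    return fc.loc[keep]


def invivo_tr_score(
    ctr: pd.DataFrame,
    fc: pd.DataFrame,
    n_perm: int = 10_000,
    max_missing: int = 10,
    seed: int = 0,
) -> InvivoResult:
    """Score TRs for mediating in-vivo metabolic changes.

    ``S_TR^p = (C_TR . FC^p) / ||C_TR||_1`` over the metabolites shared by
    the signature matrix and the (missingness-filtered) fold-change table;
    remaining missing values count as zero change. The one-sided permutation
    p is the fraction of metabolite-order shuffles with a score >= the
    observed one (no pseudocount, as the permutation definition states, so
    p can be 0). Storey q-values are computed per patient across TRs, and
    per-TR medians across patients are reported.
    """
    fc = filter_cohort_metabolites(fc, max_missing=max_missing)
    # canonical metabolite order makes the Monte-Carlo p invariant to how
    # the caller happened to order the shared metabolites
    shared = ctr.columns.intersection(fc.index).sort_values()
    if len(shared) < 2:
        raise ValueError("fewer than 2 overlapping metabolites after filtering")
    C = ctr[shared].to_numpy(dtype=float)
    F = fc.loc[shared].fillna(0.0).to_numpy(dtype=float)  # mets x patients
    denom = np.abs(C).sum(axis=1, keepdims=True)
    denom[denom == 0] = np.nan
    S = (C @ F) / denom

    rng = np.random.default_rng(seed)
    n_m = len(shared)
    count_ge = np.zeros_like(S)
    for _ in range(n_perm):
        perm = rng.permutation(n_m)
        S_null = (C[:, perm] @ F) / denom
        count_ge += S_null >= S
    p = count_ge / n_perm

    q = np.full_like(p, np.nan)
    for j in range(p.shape[1]):
        q[:, j] = storey_q(p[:, j])

    trs, patients = ctr.index, fc.columns
    Sd = pd.DataFrame(S, index=trs, columns=patients)
    pd_ = pd.DataFrame(p, index=trs, columns=patients)
    qd = pd.DataFrame(q, index=trs, columns=patients)
    return InvivoResult(
        S=Sd, p=pd_, q=qd,
        median_S=Sd.median(axis=1).rename("median_S"),
        median_q=qd.median(axis=1).rename("median_q"),
        metabolites_used=list(shared),
    )


# ---------------------------------------------------------------------------
# knockdown ranking
# ---------------------------------------------------------------------------

def knockdown_rank(
    ctr: pd.DataFrame,
    fc: pd.DataFrame,
    p_per_conc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Rank TRs by overlap with knockdown metabolite fold-changes.

    ``fc`` holds metabolite fold-changes per siRNA concentration (>= 2
    columns). Each concentration gets the L1-normalized dot-product score
    per TR; TRs are ranked by the median score over concentrations. If
    per-concentration metabolite p-values are given, the combined per-
    metabolite significance (product over concentrations) is returned too.

    Returns ``(scores-with-median, combined_p or None)`` with rows sorted by
    ascending median score (the knocked-down TR moves metabolites against
    its signature, so it ranks toward the most negative scores).
    """
    if fc.shape[1] < 2:
        raise ValueError("need >= 2 siRNA concentrations")
    shared = ctr.columns.intersection(fc.index)
    C = ctr[shared].to_numpy(dtype=float)
    denom = np.abs(C).sum(axis=1)
    denom[denom == 0] = np.nan
    scores = pd.DataFrame(
        (C @ fc.loc[shared].fillna(0.0).to_numpy()) / denom[:, None],
        index=ctr.index, columns=fc.columns,
    )
    scores["median_score"] = scores.median(axis=1)
    scores = scores.sort_values("median_score")
    combined = None
    if p_per_conc is not None:
        combined = p_per_conc.prod(axis=1).rename("combined_p")
    return scores, combined


# ---------------------------------------------------------------------------
# drug sensitivity regression
# ---------------------------------------------------------------------------

@dataclass
class DrugAssociation:
    """Per-(TR, drug) activity effect in the tissue-adjusted drug model."""

    tr: str
    drug: str
    lam: float                  # TR-activity effect on sensitivity
    p: float
    beta_tissue: dict[str, float]
    significant: bool = False


def drug_tr_regression(
    sensitivity: pd.DataFrame,
    activity: pd.DataFrame,
    tissue: pd.Series,
    alpha: float = 0.05,
    log_transform: bool = False,
    min_lines_per_tissue: int = 2,
) -> pd.DataFrame:
    """Regress each drug's sensitivity on each TR's activity plus tissue.

    Model per (TR, drug): ``sensitivity = lambda activity_TR + sum_t beta_t
    1[tissue_t]`` (tissue indicators take the intercept's role). The
    activity-effect p-value is a two-sided t-test on lambda; significance
    uses the Bonferroni threshold alpha / (n_TR x n_drug). GI50-style raw
    concentrations should be passed through ``log_transform``. Tissues with
    fewer than ``min_lines_per_tissue`` lines are pooled into "other".
    """
    shared = sensitivity.columns.intersection(activity.columns).intersection(tissue.index)
    Y = sensitivity[shared].to_numpy(dtype=float).T  # lines x drugs
    if log_transform:
        Y = np.log10(Y)
    groups = tissue.loc[shared].copy()
    sizes = groups.value_counts()
    small = sizes.index[sizes < min_lines_per_tissue]
    if len(small):
        import warnings
        warnings.warn(f"pooling tissues with <{min_lines_per_tissue} lines into 'other': {list(small)}")
        groups[groups.isin(small)] = "other"
    T = pd.get_dummies(groups).to_numpy(dtype=float)  # lines x tissues
    tissue_names = list(pd.get_dummies(groups).columns)

    n_tests = activity.shape[0] * sensitivity.shape[0]
    bonf = alpha / n_tests
    rows = []
    for tr in activity.index:
        a = activity.loc[tr, shared].to_numpy(dtype=float)
        X = np.column_stack([a, T])
        pinv = np.linalg.pinv(X)
        coef = pinv @ Y  # (1 + n_tissues) x drugs
        resid = Y - X @ coef
        dof = X.shape[0] - np.linalg.matrix_rank(X)
        sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
        var_lam = (pinv[0] ** 2).sum() * sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = coef[0] / np.sqrt(var_lam)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), max(dof, 1))
        for j, drug in enumerate(sensitivity.index):
            rows.append({
                "tr": tr, "drug": drug, "lambda": coef[0, j], "p": pvals[j],
                **{f"beta_{t}": coef[1 + ti, j] for ti, t in enumerate(tissue_names)},
                "significant": pvals[j] <= bonf,
            })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = bonf
    return out


def moa_cluster_enrichment(
    results: pd.DataFrame,
    tr_clusters: pd.Series,
    moa: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of significant TR-drug pairs per (cluster, MoA).

    Each (TR cluster, mechanism-of-action) cell tests, by upper-tail
    hypergeometric, whether significant pairs concentrate in that cell
    relative to all tested pairs. Returned matrix holds p-values; the
    Bonferroni threshold across cells is stored in ``attrs``.
    """
    df = results.copy()
    df["cluster"] = df["tr"].map(tr_clusters)
    df["moa"] = df["drug"].map(moa)
    df = df.dropna(subset=["cluster", "moa"])
    N = len(df)
    K_total = int(df["significant"].sum())
    clusters = sorted(df["cluster"].unique())
    moas = sorted(df["moa"].unique())
    P = pd.DataFrame(1.0, index=clusters, columns=moas)
    for c in clusters:
        for m in moas:
            cell = df[(df["cluster"] == c) & (df["moa"] == m)]
            if len(cell) == 0:
                continue
            k = int(cell["significant"].sum())
            P.loc[c, m] = hypergeom_p(k, N, K_total, len(cell))
    P.attrs["bonferroni_threshold"] = alpha / (len(clusters) * len(moas))
    return P
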