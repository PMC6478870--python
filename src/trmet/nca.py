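"""TR-activity inference by topology-constrained matrix decomposition.

A transcriptional regulator's activity — the latent signal it imprints on its
target genes — is estimated from expression by network component analysis:
the expression matrix E (genes x samples) is decomposed as ``E ~ A . P``
where the loading matrix A is restricted to the support of a curated signed
TR -> target network and P holds the per-sample activities. The solver is
alternating least squares with per-gene sign constraints on the loadings.

Two devices make the estimates robust to network incompleteness and growth
confounding, mirroring the bootstrapped estimation scheme:

* a growth pseudo-TR targeting all genes absorbs the pleiotropic, rank-one
  effect of proliferation on expression;
* each TR is re-estimated in many random subnetworks (the focal TR plus k
  randomly drawn others and their targets), and the reported activity is the
  median over all estimates.

Activities are relative: each TR row is reported up to sign and scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ActivityMatrix

GROWTH_TR = "__growth__"

# support encoding: +1 activating edge, -1 repressing, 2 present/unconstrained
UNCONSTRAINED = 2


def network_targets(network: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Map TR -> {target gene -> mode} from a (tr, target, mode) frame."""
    out: dict[str, dict[str, str]] = {}
    for tr, gene, mode in network[["tr", "target", "mode"]].itertuples(index=False):
        out.setdefault(tr, {})[gene] = mode
    return out


@dataclass
class Subnetwork:
    """One bootstrap subnetwork: focal TR, sampled TRs, signed support."""

    focal: str
    trs: list[str]           # real TRs (focal + sampled)
    support: pd.DataFrame    # genes x (trs + growth pseudo-TR), encoded signs

    @property
    def genes(self) -> pd.Index:
        return self.support.index


def build_support(
    targets: dict[str, dict[str, str]],
    trs: list[str],
    include_growth: bool = True,
) -> pd.DataFrame:
    """Signed support matrix over the union of the TRs' target genes."""
    genes = sorted({g for tr in trs for g in targets.get(tr, {})})
    cols = list(trs) + ([GROWTH_TR] if include_growth else [])
    S = pd.DataFrame(0, index=genes, columns=cols, dtype=int)
    code = {"activation": 1, "repression": -1, "unknown": UNCONSTRAINED}
    for tr in trs:
        for gene, mode in targets.get(tr, {}).items():
            S.at[gene, tr] = code.get(mode, UNCONSTRAINED)
    if include_growth:
        S[GROWTH_TR] = UNCONSTRAINED
    return S


def sample_subnetwork(
    network: pd.DataFrame,
    focal: str,
    k: int = 48,
    seed: int | np.random.Generator = 0,
    include_growth: bool = True,
) -> Subnetwork:
    """Draw the focal TR plus ``k`` others uniformly without replacement.

    With the default k = 48 the subnetwork holds 50 TR columns: 49 real TRs
    plus the growth pseudo-TR connected to every gene.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = network_targets(network)
    if focal not in targets:
        raise ValueError(f"focal TR {focal!r} not in network")
    others = [t for t in targets if t != focal]
    if k > len(others):
        raise ValueError(f"k={k} exceeds the {len(others)} available non-focal TRs")
    chosen = list(rng.choice(np.array(others, dtype=object), size=k, replace=False)) if k else []
    trs = [focal] + sorted(chosen)
    support = build_support(targets, trs, include_growth=include_growth)
    return Subnetwork(focal=focal, trs=trs, support=support)


@dataclass
class NcaFit:
    """Result of one constrained ALS decomposition."""

    A: pd.DataFrame          # genes x TRs loadings (support-restricted)
    P: pd.DataFrame          # TRs x samples activities
    objective: list[float] = field(default_factory=list)
    converged: bool = True


def _pattern_groups(S: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group genes by the size of their TR support pattern.

    Returns a list of ``(gene_idx (n,), cols (n, m), signs (n, m))`` per
    distinct pattern size m, enabling batched per-gene least squares.
    """
    n_genes = S.shape[0]
    by_size: dict[int, list[int]] = {}
    for gi in range(n_genes):
        m = int((S[gi] != 0).sum())
        if m:
            by_size.setdefault(m, []).append(gi)
    groups = []
    for m, genes in sorted(by_size.items()):
        idx = np.array(genes)
        cols = np.vstack([np.flatnonzero(S[g]) for g in genes])
        signs = S[idx[:, None], cols]
        groups.append((idx, cols, signs))
    return groups


def _solve_A(
    E: np.ndarray,
    P: np.ndarray,
    S: np.ndarray,
    enforce_signs: bool,
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """A-step: per-gene restricted least squares, batched by pattern size.

    All genes with m regulating TRs are solved in one batched normal-equation
    solve. Sign constraints (activation loading >= 0, repression <= 0) are
    applied by an active-set pass: any violating loading is zeroed and the
    remaining ones re-fitted (rarely triggered, per-gene loop).
    """
    n_genes, n_tr = S.shape
    A = np.zeros((n_genes, n_tr))
    G = P @ P.T                      # TR x TR Gram matrix
    R = P @ E.T                      # TR x genes cross products
    jitter = 1e-12 * np.trace(G) / max(len(G), 1)

    for idx, cols, signs in groups:
        n, m = cols.shape
        Gs = G[cols[:, :, None], cols[:, None, :]]            # n x m x m
        Gs = Gs + jitter * np.eye(m)[None, :, :]
        rhs = R[cols, idx[:, None]]                           # n x m
        coef = np.linalg.solve(Gs, rhs[:, :, None])[:, :, 0]  # n x m
        if enforce_signs:
            constrained = signs != UNCONSTRAINED
            viol = constrained & (coef * signs < 0)
            for i in np.flatnonzero(viol.any(axis=1)):
                active = ~viol[i]
                c = np.zeros(m)
                for _ in range(m):
                    sub = np.linalg.solve(
                        Gs[i][np.ix_(active, active)], rhs[i][active]
                    )
                    c[:] = 0.0
                    c[active] = sub
                    new_viol = constrained[i] & (c * signs[i] < 0) & active
                    if not new_viol.any():
                        break
                    active &= ~new_viol
                coef[i] = c
        A[idx[:, None], cols] = coef
    return A


def run_nca(
    expression: pd.DataFrame,
    support: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 100,
    enforce_signs: bool = True,
    decorrelate_growth: bool = True,
    seed: int | np.random.Generator = 0,
) -> NcaFit:
    """Alternating least squares for ``E ~ A . P`` under a signed support.

    Convergence is declared when the relative change of the squared-error
    objective falls below ``tol``; non-convergence returns the best iterate
    with a warning flag (``converged = False``). The objective trace is
    non-increasing by construction of the alternating updates.

    Because the growth pseudo-TR targets every gene, each real TR's activity
    is identified only up to adding multiples of the growth activity (the
    unconstrained growth loadings absorb any such shift exactly). With
    ``decorrelate_growth`` the returned representative is the gauge choice
    with each TR row orthogonal to the growth row — an exact transformation
    that leaves ``A . P`` and all support constraints untouched.
    """
    missing = support.index.difference(expression.index)
    if len(missing):
        raise ValueError(f"expression lacks {len(missing)} support genes (e.g. {list(missing[:3])})")
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    empty_cols = support.columns[(support == 0).all(axis=0)]
    if len(empty_cols):
        warnings.warn(f"support columns with no targets are structurally unidentifiable: {list(empty_cols)}")

    E = expression.loc[support.index].to_numpy(dtype=float)
    S = support.to_numpy()
    groups = _pattern_groups(S)
    A0 = np.where(S == UNCONSTRAINED, 1.0, S.astype(float))
    P, *_ = np.linalg.lstsq(A0, E, rcond=None)

    objective: list[float] = []
    converged = False
    for _ in range(max_iter):
        A = _solve_A(E, P, S, enforce_signs, groups)
        P, *_ = np.linalg.lstsq(A, E, rcond=None)
        # fix the per-TR scale gauge (product A.P is invariant)
        norms = np.max(np.abs(P), axis=1)
        norms[norms == 0] = 1.0
        P = P / norms[:, None]
        A = A * norms[None, :]
        obj = float(((E - A @ P) ** 2).sum())
        if objective and objective[-1] > 0 and (objective[-1] - obj) / objective[-1] < tol:
            objective.append(obj)
            converged = True
            break
        objective.append(obj)
    if not converged:
        warnings.warn("ALS did not converge within max_iter; returning best iterate")

    if decorrelate_growth and GROWTH_TR in support.columns:
        gi = support.columns.get_loc(GROWTH_TR)
        g = P[gi]
        denom = float(g @ g)
        if denom > 0:
            c = (P @ g) / denom
            c[gi] = 0.0
            P = P - np.outer(c, g)
            A[:, gi] = A[:, gi] + A @ c

    return NcaFit(
        A=pd.DataFrame(A, index=support.index, columns=support.columns),
        P=pd.DataFrame(P, index=support.columns, columns=expression.columns),
        objective=objective,
        converged=converged,
    )


def _align_signs(E: np.ndarray, fit_A: np.ndarray, P: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-TR orientation: activity sign chosen so the edge-sign-weighted
    covariance between the TR's activity and its targets' expression is
    positive (prior edge signs where known, fitted loading signs otherwise)."""
    Ec = E - E.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    C = Ec @ Pc.T  # genes x TRs
    W = np.where(S == UNCONSTRAINED, np.sign(fit_A), S.astype(float))
    scores = (W * C * (S != 0)).sum(axis=0)
    s = np.sign(scores)
    s[s == 0] = 1.0
    return s


def bootstrap_activities(
    expression: pd.DataFrame,
    network: pd.DataFrame,
    subnetworks_per_tr: int = 10,
    k: int = 48,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 60,
    enforce_signs: bool = True,
    include_growth: bool = True,
    normalize: str = "subnetwork",
) -> ActivityMatrix:
    """The bootstrapped activity estimate: median over subnetwork fits.

    Every TR's activity is collected from every subnetwork that contains it
    (not only the ones it seeded), so with 728 TRs, 10 subnetworks each and
    k = 48 a TR is sampled in about 490 subnetworks on average. Per
    subnetwork each TR row is sign-aligned and normalized by its maximum
    absolute value (``normalize="global"`` instead scales each TR once by
    its global maximum before summarizing); the growth pseudo-TR's estimates
    are discarded. Reported per (TR, line): median, SD and estimate count.
    """
    if normalize not in ("subnetwork", "global"):
        raise ValueError("normalize must be 'subnetwork' or 'global'")
    targets = network_targets(network)
    genes_avail = set(expression.index)
    usable, missing_trs = [], []
    for tr, tgt in targets.items():
        (usable if any(g in genes_avail for g in tgt) else missing_trs).append(tr)
    usable = sorted(usable)
    if missing_trs:
        warnings.warn(f"{len(missing_trs)} TRs have no targets in the expression matrix and are reported missing")
    network_use = network[network["tr"].isin(usable) & network["target"].isin(genes_avail)]
    targets = network_targets(network_use)

    lines = expression.columns
    estimates: dict[str, list[np.ndarray]] = {tr: [] for tr in usable}
    for fi, focal in enumerate(usable):
        rng = np.random.default_rng([seed, fi])
        for _ in range(subnetworks_per_tr):
            sub = sample_subnetwork(network_use, focal, k=k, seed=rng, include_growth=include_growth)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = run_nca(expression, sub.support, tol=tol, max_iter=max_iter,
                              enforce_signs=enforce_signs)
            E = expression.loc[sub.support.index].to_numpy()
            S = sub.support.to_numpy()
            P = fit.P.to_numpy()
            s = _align_signs(E, fit.A.to_numpy(), P, S)
            P = P * s[:, None]
            if normalize == "subnetwork":
                m = np.max(np.abs(P), axis=1)
                m[m == 0] = 1.0
                P = P / m[:, None]
            for ti, tr in enumerate(sub.support.columns):
                if tr == GROWTH_TR:
                    continue
                estimates[tr].append(P[ti])

    act = np.full((len(usable) + len(missing_trs), len(lines)), np.nan)
    spread = np.full_like(act, np.nan)
    counts = np.zeros(len(usable) + len(missing_trs), dtype=int)
    all_trs = usable + sorted(missing_trs)
    for i, tr in enumerate(all_trs):
        rows = estimates.get(tr, [])
        counts[i] = len(rows)
        if rows:
            M = np.vstack(rows)
            if normalize == "global":
                m = np.max(np.abs(M))
                if m > 0:
                    M = M / m
            act[i] = np.median(M, axis=0)
            spread[i] = M.std(axis=0)

    return ActivityMatrix(
        activity=pd.DataFrame(act, index=all_trs, columns=lines),
        spread=pd.DataFrame(spread, index=all_trs, columns=lines),
        n_estimates=pd.Series(counts, index=all_trs, name="n_estimates"),
    )


def expected_subnetwork_coverage(n_trs: int = 728, subnetworks_per_tr: int = 10, k: int = 48) -> float:
    """Expected number of subnetworks containing a fixed TR.

    Each TR seeds ``subnetworks_per_tr`` subnetworks, and appears in another
    TR's subnetwork with probability k / (n_trs - 1):
    ``subnetworks_per_tr * (1 + k)`` exactly (490 under the defaults).
    """
    return subnetworks_per_tr + (n_trs - 1) * subnetworks_per_tr * k / (n_trs - 1)


def simulate_subnetwork_coverage(
    n_trs: int = 728, subnetworks_per_tr: int = 10, k: int = 48, seed: int = 0
) -> pd.Series:
    """Monte-Carlo appearance counts per TR under the full sampling scheme."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_trs, dtype=int)
    for focal in range(n_trs):
        for _ in range(subnetworks_per_tr):
            others = rng.choice(n_trs - 1, size=k, replace=False)
            others = np.where(others >= focal, others + 1, others)
            counts[focal] += 1
            counts[others] += 1
    return pd.Series(counts, index=[f"TR{i + 1}" for i in range(n_trs)], name="subnetworks")
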