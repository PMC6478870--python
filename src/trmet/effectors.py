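"""Ensemble nonlinear models predicting effectors of TR activity.

A TR's activity is modeled as a function of its own protein abundance
modulated by candidate metabolite and/or kinase effectors:

    activity = a + b . protein . f(met; K_m) . f(kin; K_k)

with saturable activation ``f(x; K) = x / (K + x)`` or inhibition
``f(x; K) = K / (K + x)``. The linear parameters (a, b) are profiled out by
least squares at every evaluation, so the nonlinear search runs only over
the binding constants (log K), from a small multi-start grid. A candidate
effector is called when adding it improves the mean squared error over the
protein-only baseline by more than the (1 - fdr) quantile of a null
distribution built from activity rows with permuted cell-line labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

MODES = ("activation", "inhibition")
_LOGK_GRID = np.linspace(-3.0, 3.0, 7)  # coarse search grid in log10 K


@dataclass(frozen=True)
class EffectorModelSpec:
    """One candidate model: a TR with a metabolite and/or kinase modulator."""

    tr: str
    metabolite: Optional[str] = None
    met_mode: Optional[str] = None
    kinase: Optional[str] = None
    kin_mode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.metabolite is None and self.kinase is None:
            raise ValueError("a model spec needs at least one modulator")
        for mode, present in ((self.met_mode, self.metabolite), (self.kin_mode, self.kinase)):
            if present is not None and mode not in MODES:
                raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    @property
    def kind(self) -> str:
        if self.metabolite and self.kinase:
            return "metabolite+kinase"
        return "metabolite" if self.metabolite else "kinase"


@dataclass
class EffectorResult:
    """Fit summary for one candidate model."""

    spec: EffectorModelSpec
    params: dict[str, float] = field(default_factory=dict)
    mse: float = np.nan
    mse_baseline: float = np.nan
    fitted: bool = True
    passes: bool = False

    @property
    def delta_mse(self) -> float:
        return self.mse_baseline - self.mse


def enumerate_models(
    trs: Sequence[str], metabolites: Sequence[str], kinases: Sequence[str]
) -> list[EffectorModelSpec]:
    """All candidate specs: per TR, 2M metabolite-only + 2K kinase-only +
    4MK combined models, in deterministic order."""
    specs = []
    for tr in trs:
        for m in metabolites:
            for mm in MODES:
                specs.append(EffectorModelSpec(tr=tr, metabolite=m, met_mode=mm))
        for k in kinases:
            for km in MODES:
                specs.append(EffectorModelSpec(tr=tr, kinase=k, kin_mode=km))
        for m, k in itertools.product(metabolites, kinases):
            for mm, km in itertools.product(MODES, MODES):
                specs.append(EffectorModelSpec(tr=tr, metabolite=m, met_mode=mm, kinase=k, kin_mode=km))
    return specs


def saturable(x: np.ndarray, K: float, mode: str) -> np.ndarray:
    """Saturable modulation term, safe at extreme K."""
    if mode == "activation":
        return x / (K + x)
    if mode == "inhibition":
        return K / (K + x)
    raise ValueError(f"unknown mode {mode!r}")


def _profiled_sse(y: np.ndarray, regressor: np.ndarray) -> tuple[float, float, float]:
    """SSE of ``y ~ a + b r`` with (a, b) solved in closed form."""
    r = regressor
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom <= 1e-30 or not np.isfinite(denom):
        a = float(y.mean())
        return float(((y - a) ** 2).sum()), a, 0.0
    b = float(rc @ (y - y.mean())) / denom
    a = float(y.mean() - b * r.mean())
    sse = float(((y - a - b * r) ** 2).sum())
    return sse, a, b


def fit_effector_model(
    activity: np.ndarray,
    protein: np.ndarray,
    spec: EffectorModelSpec,
    metabolite: Optional[np.ndarray] = None,
    kinase: Optional[np.ndarray] = None,
    logk_bounds: tuple[float, float] = (-4.0, 4.0),
) -> EffectorResult:
    """Fit one candidate model by variable projection.

    Modulator abundances must be positive and are rescaled to unit median
    internally. Only the binding constants are optimized (Nelder-Mead from a
    small log K multi-start grid); (a, b) are solved analytically at each
    objective evaluation. ``mse_baseline`` is the protein-only model
    ``a + b . protein``. An optimizer failure marks the result unfit.
    """
    y = np.asarray(activity, dtype=float)
    if len(y) < 8:
        raise ValueError("need >= 8 shared cell lines")
    prot = np.asarray(protein, dtype=float)
    prot = prot / np.median(prot)

    mods: list[tuple[np.ndarray, str]] = []
    if spec.metabolite is not None:
        if metabolite is None:
            raise ValueError("spec has a metabolite but no profile was given")
        m = np.asarray(metabolite, dtype=float)
        med = np.median(m)
        mods.append((m / (med if med > 0 else 1.0), spec.met_mode))
    if spec.kinase is not None:
        if kinase is None:
            raise ValueError("spec has a kinase but no profile was given")
        kv = np.asarray(kinase, dtype=float)
        med = np.median(kv)
        mods.append((kv / (med if med > 0 else 1.0), spec.kin_mode))
    for x, _ in mods:
        if (x < 0).any():
            raise ValueError("modulator abundances must be nonnegative")

    sse_base, a0, b0 = _profiled_sse(y, prot)
    n = len(y)

    def objective(logk: np.ndarray) -> float:
        lk = np.clip(logk, *logk_bounds)
        r = prot.copy()
        for (x, mode), l in zip(mods, lk):
            r = r * saturable(x, 10.0 ** l, mode)
        return _profiled_sse(y, r)[0]

    # coarse grid over log K, then one local refinement from the best cell
    d = len(mods)
    try:
        grid = [np.array(c) for c in itertools.product(_LOGK_GRID, repeat=d)]
        vals = np.array([objective(g) for g in grid])
        start = grid[int(np.argmin(vals))]
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 80 * d})
        best_x, best_f = (res.x, res.fun) if res.fun <= vals.min() else (start, vals.min())
    except Exception:
        return EffectorResult(spec=spec, mse_baseline=sse_base / n, fitted=False)
    if not np.isfinite(best_f):
        return EffectorResult(spec=spec, mse_baseline=sse_base / n, fitted=False)

    lk = np.clip(best_x, *logk_bounds)
    r = prot.copy()
    for (x, mode), l in zip(mods, lk):
        r = r * saturable(x, 10.0 ** l, mode)
    sse, a, b = _profiled_sse(y, r)
    params = {"a": a, "b": b}
    keys = []
    if spec.metabolite is not None:
        keys.append("K_met")
    if spec.kinase is not None:
        keys.append("K_kin")
    for key, l in zip(keys, lk):
        params[key] = 10.0 ** l
    return EffectorResult(spec=spec, params=params, mse=sse / n, mse_baseline=sse_base / n)


def _profiles(spec, proteome, z_positive):
    met = z_positive.loc[spec.metabolite].to_numpy() if spec.metabolite else None
    kin = proteome.loc[spec.kinase].to_numpy() if spec.kinase else None
    return met, kin


def ensemble_scan(
    activity: pd.DataFrame,
    proteome: pd.DataFrame,
    metabolite_levels: pd.DataFrame,
    specs: Sequence[EffectorModelSpec],
    fdr: float = 0.001,
    n_null: int = 20,
    seed: int = 0,
) -> list[EffectorResult]:
    """Fit every candidate model and call passing interactions at an FDR.

    ``metabolite_levels`` must be positive abundances (e.g. exponentiated
    Z-scores or per-cell slopes rescaled to unit median). The null Delta-MSE
    distribution pools, over ``n_null`` permutations, refits of every spec
    against activity rows with permuted cell-line labels; a spec passes iff
    its Delta-MSE exceeds the (1 - fdr) null quantile. A pooled null smaller
    than 1/fdr values cannot resolve the requested quantile and is an error.
    """
    if n_null * len(specs) < 1.0 / fdr:
        raise ValueError(
            f"null pool of {n_null} x {len(specs)} values cannot resolve the {1 - fdr:.4f} quantile"
        )
    lines = activity.columns.intersection(proteome.columns).intersection(metabolite_levels.columns)
    if len(lines) < 8:
        raise ValueError("need >= 8 shared cell lines")
    act = activity[lines]
    prot = proteome[lines]
    mets = metabolite_levels[lines]

    rng = np.random.default_rng(seed)
    results: list[EffectorResult] = []
    null_deltas: list[float] = []
    perms = [rng.permutation(len(lines)) for _ in range(n_null)]
    for spec in specs:
        if spec.tr not in act.index or spec.tr not in prot.index:
            continue
        y = act.loc[spec.tr].to_numpy()
        pr = prot.loc[spec.tr].to_numpy()
        met, kin = _profiles(spec, prot, mets)
        res = fit_effector_model(y, pr, spec, metabolite=met, kinase=kin)
        results.append(res)
        for perm in perms:
            nres = fit_effector_model(y[perm], pr, spec, metabolite=met, kinase=kin)
            if nres.fitted:
                null_deltas.append(nres.delta_mse)

    null = np.array(null_deltas)
    cutoff = float(np.quantile(null, 1.0 - fdr))
    for r in results:
        if r.fitted and np.isfinite(r.delta_mse):
            r.passes = r.delta_mse > cutoff
    return results


def results_frame(results: Sequence[EffectorResult]) -> pd.DataFrame:
    """Long-format summary of an ensemble scan."""
    rows = []
    for r in results:
        rows.append({
            "tr": r.spec.tr, "metabolite": r.spec.metabolite, "met_mode": r.spec.met_mode,
            "kinase": r.spec.kinase, "kin_mode": r.spec.kin_mode, "kind": r.spec.kind,
            "mse": r.mse, "mse_baseline": r.mse_baseline, "delta_mse": r.delta_mse,
            "fitted": r.fitted, "passes": r.passes,
        })
    return pd.DataFrame(rows)


def kinase_degree_compare(degrees_a: Sequence[int], degrees_b: Sequence[int]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on per-node kinase-degree samples.

    Used to compare how many kinases interact with TRs versus with metabolic
    enzymes. Returns ``(statistic, p)``.
    """
    a, b = np.asarray(degrees_a, float), np.asarray(degrees_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both degree samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
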