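"""Normalization of raw ion intensities into comparable per-cell abundances.

The normalization proceeds in four steps:

1. plate correction — a two-factor log-linear model over pooled quality
   control extracts estimates one multiplicative scaling factor gamma_p per
   plate (``log I_{i,j,p} = log gamma_p + log M_{i,j}``);
2. cell-number regression — for every ion one multiple regression over all
   cell lines relates intensity to extracted cell number, giving a slope
   alpha per (ion, line) plus one shared background intercept beta;
3. ion filtering and cell-volume correction — only ions with a significant
   linear cell-number dependency are kept, and a consensus per-line volume
   factor (from ions tracking the first principal component of the alpha
   matrix) removes cell-size differences;
4. Z-scoring across cell lines (population SD).

Extracted cell number comes from well confluence divided by the line's
characteristic cell area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import WELL_AREA_UM2
from .types import AbundanceMatrix, IntensityTable, IonAnnotation, PlateFactors, ZMatrix

PROTON_MASS = 1.007276  # amu, mass removed on deprotonation

_ATOMIC = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}
# phenylhydrazone derivatization of alpha-keto acids: +C6H8N2 -H2O
PHENYLHYDRAZONE_SHIFT = (
    6 * _ATOMIC["C"] + 8 * _ATOMIC["H"] + 2 * _ATOMIC["N"]
    - (2 * _ATOMIC["H"] + _ATOMIC["O"])
)


def cells_from_confluence(confluence: float, cell_area: float, well_area: float = WELL_AREA_UM2) -> float:
    """Extracted cell number from confluence (%) and characteristic cell area.

    ``count = (confluence / 100) * well_area / cell_area``; both areas in the
    same unit (um^2 by default).
    """
    if not 0 <= confluence <= 100:
        raise ValueError(f"confluence must lie in [0, 100], got {confluence}")
    if cell_area <= 0 or well_area <= 0:
        raise ValueError("areas must be positive")
    return (confluence / 100.0) * well_area / cell_area


# ---------------------------------------------------------------------------
# plate factors
# ---------------------------------------------------------------------------

def _components(pairs: pd.DataFrame) -> pd.Series:
    """Connected components of the plate / pooled-composition design graph."""
    import networkx as nx

    g = nx.Graph()
    for plate, pool in pairs.itertuples(index=False):
        g.add_edge(("plate", plate), ("pool", pool))
    labels = {}
    for c, comp in enumerate(nx.connected_components(g)):
        for kind, name in comp:
            if kind == "plate":
                labels[name] = c
    return pd.Series(labels, name="component")


def estimate_plate_factors(table: IntensityTable, tol: float = 1e-12, max_iter: int = 500) -> tuple[PlateFactors, IntensityTable]:
    """Fit per-plate scaling factors from pooled samples and correct the table.

    Least-squares fit of the two-factor log-linear model (plate effect +
    pooled-composition-by-ion effect) over all pooled wells, by alternating
    projections (exact at convergence; one pass for balanced designs). The
    gauge fixes ``prod(gamma_p) = 1`` within each connected component of the
    plate/pool design; plates in different components are only comparable up
    to an arbitrary factor, which the component labels make explicit.

    Returns the factors and a corrected table with every sample's intensities
    divided by its plate's gamma.
    """
    pooled = table.subset("pooled")
    if pooled.intensity.shape[1] == 0:
        raise ValueError("no pooled samples in table")
    if (pooled.intensity.to_numpy() <= 0).any():
        raise ValueError("pooled intensities must be positive")

    meta = pooled.sample_meta
    plates = meta["plate"].astype(str)
    pools = meta["pool_id"].astype(str)
    n_plates_sharing = (
        pd.DataFrame({"plate": plates, "pool": pools}).drop_duplicates().groupby("pool")["plate"].nunique()
    )
    if (n_plates_sharing < 2).all():
        raise ValueError("no pooled composition is shared by >= 2 plates; plate factors unidentifiable")

    logI = np.log(pooled.intensity.to_numpy())  # ions x pooled wells
    plate_codes, plate_ids = pd.factorize(plates)
    pool_codes, pool_ids = pd.factorize(pools)
    n_p, n_j = len(plate_ids), len(pool_ids)
    n_ions, n_wells = logI.shape

    g = np.zeros(n_p)
    m = np.zeros((n_ions, n_j))
    plate_counts = np.bincount(plate_codes, minlength=n_p).astype(float) * n_ions
    pool_counts = np.bincount(pool_codes, minlength=n_j).astype(float)
    for _ in range(max_iter):
        resid = logI - g[None, plate_codes]
        sums = np.zeros((n_ions, n_j))
        np.add.at(sums.T, pool_codes, resid.T)
        m = sums / pool_counts[None, :]
        resid_p = (logI - m[:, pool_codes]).sum(axis=0)
        g_new = np.bincount(plate_codes, weights=resid_p, minlength=n_p) / plate_counts
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new

    comp = _components(pd.DataFrame({"plate": plates.to_numpy(), "pool": pools.to_numpy()}).drop_duplicates())
    comp = comp.reindex(plate_ids)
    # gauge: zero-mean log gamma within each component
    for c in comp.unique():
        mask = (comp == c).to_numpy()
        g[mask] -= g[mask].mean()

    gamma = pd.Series(np.exp(g), index=pd.Index(plate_ids, name="plate"), name="gamma")
    all_plates = table.sample_meta["plate"].astype(str)
    missing = set(all_plates.unique()) - set(gamma.index)
    if missing:
        raise ValueError(f"plates without pooled samples cannot be corrected: {sorted(missing)}")

    divisor = gamma.reindex(all_plates).to_numpy()
    corrected = table.intensity / divisor[None, :]
    factors = PlateFactors(gamma=gamma, component=comp.astype(int))
    return factors, IntensityTable(corrected, table.sample_meta.copy())


# ---------------------------------------------------------------------------
# per-cell abundance regression
# ---------------------------------------------------------------------------

def fit_cell_regression(table: IntensityTable, counts: pd.Series) -> AbundanceMatrix:
    """Per-ion multiple regression of intensity on extracted cell number.

    The design is block diagonal: one slope alpha per cell line (nonzero only
    on that line's samples) and one intercept beta shared by all samples. All
    ions share the design, so a single pseudo-inverse yields every fit; the
    estimates are invariant to sample ordering. Lines whose samples do not
    span at least two distinct cell counts (or have fewer than three samples)
    are rank deficient and flagged missing (NaN alpha).
    """
    cells = table.subset("cell")
    samples = cells.samples.intersection(counts.index)
    if len(samples) < len(cells.samples):
        raise ValueError("counts missing for some cell samples")
    meta = cells.sample_meta.loc[samples]
    y = cells.intensity[samples].to_numpy().T  # samples x ions

    line_codes, lines = pd.factorize(meta["cell_line"], sort=True)
    n_s, n_lines = len(samples), len(lines)
    n = counts.reindex(samples).to_numpy()

    ok_lines = np.ones(n_lines, dtype=bool)
    for i in range(n_lines):
        vals = n[line_codes == i]
        if len(vals) < 3 or len(np.unique(vals)) < 2:
            ok_lines[i] = False

    keep = ok_lines[line_codes]
    y_fit = y[keep]
    codes_fit = line_codes[keep]
    n_fit = n[keep]
    fit_lines = np.flatnonzero(ok_lines)
    remap = {old: new for new, old in enumerate(fit_lines)}
    codes_fit = np.array([remap[c] for c in codes_fit])
    k = len(fit_lines)

    X = np.zeros((len(y_fit), k + 1))
    X[np.arange(len(y_fit)), codes_fit] = n_fit
    X[:, -1] = 1.0

    pinv = np.linalg.pinv(X)
    coef = pinv @ y_fit  # (k+1) x ions
    resid = y_fit - X @ coef
    dof = len(y_fit) - (k + 1)
    if dof <= 0:
        raise ValueError("not enough samples for regression")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    var_diag = (pinv ** 2).sum(axis=1)  # diag of (X'X)^-1
    se = np.sqrt(np.outer(var_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals[se == 0] = 0.0  # exact fit: slope indistinguishable from certain

    ions = cells.intensity.index
    alpha = np.full((len(ions), n_lines), np.nan)
    alpha_se = np.full_like(alpha, np.nan)
    alpha_p = np.full_like(alpha, np.nan)
    alpha[:, fit_lines] = coef[:-1].T
    alpha_se[:, fit_lines] = se[:-1].T
    alpha_p[:, fit_lines] = pvals[:-1].T

    return AbundanceMatrix(
        alpha=pd.DataFrame(alpha, index=ions, columns=lines),
        alpha_se=pd.DataFrame(alpha_se, index=ions, columns=lines),
        alpha_p=pd.DataFrame(alpha_p, index=ions, columns=lines),
        beta=pd.Series(coef[-1], index=ions, name="beta"),
    )


def filter_ions(
    ab: AbundanceMatrix,
    alpha_level: float = 0.05,
    fraction_of_lines: float = 0.8,
    nominal_level: float = 0.05,
    n_ions_tested: int | None = None,
) -> pd.Series:
    """Retain ions with a robust linear cell-number dependency.

    The Bonferroni threshold is ``alpha_level / (n_lines * n_ions_tested)``
    (3.4e-7 at 54 lines and 2723 ions). An ion is retained iff its regression
    p-value passes that threshold in at least one line AND a nominal
    ``p < nominal_level`` in more than ``fraction_of_lines`` of lines.
    """
    p = ab.alpha_p
    n_lines = p.shape[1]
    n_tested = n_ions_tested if n_ions_tested is not None else p.shape[0]
    threshold = alpha_level / (n_lines * n_tested)
    any_bonf = (p <= threshold).any(axis=1)
    frac_nominal = (p < nominal_level).mean(axis=1)
    retained = any_bonf & (frac_nominal > fraction_of_lines)
    ab.retained = retained.rename("retained")
    return ab.retained


def bonferroni_threshold(n_lines: int, n_ions: int, alpha: float = 0.05) -> float:
    """The per-test threshold alpha / (n_lines * n_ions)."""
    return alpha / (n_lines * n_ions)


# ---------------------------------------------------------------------------
# volume correction and Z-scoring
# ---------------------------------------------------------------------------

def volume_correct(
    ab: AbundanceMatrix,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    standardize_pca: bool = True,
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Remove cell-volume differences with a consensus per-line factor.

    PCA on the retained alpha matrix (cell lines as observations) gives PC1
    scores that track cell volume. Ions are standardized before PCA by
    default: raw per-cell slopes span orders of magnitude between ions, and
    without standardization PC1 follows the few most abundant ions instead of
    the volume factor shared by all of them (``standardize_pca=False`` gives
    the center-only variant). Ions whose alpha row correlates with PC1
    (Pearson r > ``r_threshold``, p < ``p_threshold``) are volume reporters;
    each selected row is rescaled to unit mean and the per-line consensus
    factor is their mean. All alpha columns are divided by the factor.

    Returns ``(corrected alpha, volume factors, selected ion index)``.
    """
    from sklearn.decomposition import PCA

    if ab.retained is None:
        raise ValueError("run filter_ions before volume correction")
    alpha = ab.alpha.loc[ab.retained].dropna(axis=0, how="any")
    if alpha.shape[0] < 3:
        raise ValueError("need >= 3 retained ions for volume correction")

    X = alpha.to_numpy().T  # lines x ions
    if standardize_pca:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    pc1 = PCA(n_components=1).fit_transform(X - X.mean(axis=0)).ravel()

    # orient PC1 so that volume reporters correlate positively
    r = np.array([stats.pearsonr(alpha.iloc[i].to_numpy(), pc1)[0] for i in range(alpha.shape[0])])
    if np.nansum(r) < 0:
        pc1 = -pc1
        r = -r
    n = len(pc1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    selected = alpha.index[(r > r_threshold) & (p < p_threshold)]
    if len(selected) == 0:
        raise ValueError(
            f"no ion passed volume-reporter selection (r > {r_threshold}, p < {p_threshold}); "
            "check the retained alpha matrix for a volume component"
        )

    rows = ab.alpha.loc[selected]
    unit = rows.div(rows.mean(axis=1), axis=0)
    factor = unit.mean(axis=0).rename("volume_factor")
    corrected = ab.alpha.div(factor, axis=1)
    return corrected, factor, selected


def zscore(alpha_corrected: pd.DataFrame, volume_factor: pd.Series | None = None) -> ZMatrix:
    """Z-score each ion across cell lines with the population (1/n) SD.

    Missing values propagate as missing (treated as zero downstream). Ions
    with zero variance across lines are flagged and left NaN.
    """
    a = alpha_corrected.to_numpy(dtype=float)
    mean = np.nanmean(a, axis=1, keepdims=True)
    sd = np.sqrt(np.nanmean((a - mean) ** 2, axis=1, keepdims=True))
    # constant within float precision counts as constant
    scale = np.nanmax(np.abs(a), axis=1)
    const = (sd.ravel() <= 1e-10 * np.where(scale > 0, scale, 1.0)) | ~np.isfinite(sd.ravel())
    flagged = alpha_corrected.index[const]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (a - mean) / sd
    z[const, :] = np.nan
    vf = volume_factor if volume_factor is not None else pd.Series(1.0, index=alpha_corrected.columns)
    return ZMatrix(
        z=pd.DataFrame(z, index=alpha_corrected.index, columns=alpha_corrected.columns),
        volume_factor=vf,
        flagged_constant=flagged,
    )


def quantify(
    table: IntensityTable,
    counts: pd.Series,
    r_threshold: float = 0.8,
    alpha_level: float = 0.05,
) -> tuple[AbundanceMatrix, ZMatrix, PlateFactors]:
    """Full normalization: plate factors, regression, filter, volume, Z-score."""
    factors, corrected = estimate_plate_factors(table)
    ab = fit_cell_regression(corrected, counts)
    filter_ions(ab, alpha_level=alpha_level)
    alpha_corr, vf, _ = volume_correct(ab, r_threshold=r_threshold)
    zm = zscore(alpha_corr.loc[ab.retained], vf)
    return ab, zm, factors


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_ions(
    mz: pd.Series,
    reference: pd.DataFrame,
    tolerance: float = 0.003,
) -> list[IonAnnotation]:
    """Match measured m/z values against a reference compound list.

    A candidate matches iff ``|mz - (M - 1.007276)| <= tolerance`` where M is
    the neutral monoisotopic mass (deprotonation as the prevalent ionization
    mode). Compounds flagged ``is_alpha_keto`` are additionally tested as
    their phenylhydrazone derivatives (+C6H8N2 -H2O, +90.05818 amu). All
    matches within tolerance are reported.

    ``reference`` columns: compound_id, formula, monoisotopic_mass,
    is_alpha_keto (bool).
    """
    required = {"compound_id", "formula", "monoisotopic_mass"}
    if not required <= set(reference.columns):
        raise ValueError(f"reference must have columns {sorted(required)}")
    is_keto = reference["is_alpha_keto"].astype(bool) if "is_alpha_keto" in reference else pd.Series(False, index=reference.index)

    targets = []  # (target mz, compound row, adduct)
    for row, keto in zip(reference.itertuples(index=False), is_keto):
        m = row.monoisotopic_mass
        targets.append((m - PROTON_MASS, row, "[M-H]-"))
        if keto:
            targets.append((m + PHENYLHYDRAZONE_SHIFT - PROTON_MASS, row, "[M+PH-H]-"))

    out: list[IonAnnotation] = []
    for ion_id, value in mz.items():
        for target, row, adduct in targets:
            err = value - target
            if abs(err) <= tolerance:
                out.append(IonAnnotation(
                    ion_id=str(ion_id), mz=float(value),
                    compound_id=row.compound_id, formula=row.formula,
                    adduct=adduct, mass_error=float(err),
                ))
    return out
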