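"""Shared in-memory containers passed between pipeline stages.

All matrices are pandas DataFrames with ion / TR / metabolite ids on the rows
and sample or cell-line ids on the columns, so every stage can align on labels
rather than positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("cell", "pooled", "blank")


@dataclass
class IntensityTable:
    """Raw or plate-corrected ion intensities with per-sample metadata.

    ``intensity``: ions x samples, nonnegative.
    ``sample_meta``: indexed by sample id with columns ``sample_type``
    ("cell" | "pooled" | "blank"), ``cell_line`` (empty for pooled/blank),
    ``plate``, ``pool_id`` (pooled-composition key, empty for cell samples),
    ``timepoint``, ``replicate`` and ``confluence`` (%).
    """

    intensity: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensity.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.intensity.columns]
        if self.sample_meta["plate"].isna().any():
            raise ValueError("every sample must carry a plate id")
        bad = ~self.sample_meta["sample_type"].isin(SAMPLE_TYPES)
        if bad.any():
            raise ValueError(
                f"unknown sample_type values: {self.sample_meta['sample_type'][bad].unique()}"
            )
        cellful = self.sample_meta["sample_type"] != "cell"
        if self.sample_meta.loc[cellful, "cell_line"].notna().any():
            raise ValueError("pooled/blank samples must not carry a cell line")

    @property
    def ions(self) -> pd.Index:
        return self.intensity.index

    @property
    def samples(self) -> pd.Index:
        return self.intensity.columns

    def subset(self, sample_type: str) -> "IntensityTable":
        keep = self.sample_meta.index[self.sample_meta["sample_type"] == sample_type]
        return IntensityTable(self.intensity[keep], self.sample_meta.loc[keep].copy())


@dataclass
class PlateFactors:
    """Per-plate multiplicative scaling factors gamma_p.

    Gauge: the product of gamma over the plates of each connected
    plate/pooled-composition component equals 1 (the global scale of the
    intensities is not identifiable).
    """

    gamma: pd.Series
    component: pd.Series  # connected-component label per plate

    def __post_init__(self) -> None:
        if (self.gamma <= 0).any():
            raise ValueError("plate factors must be positive")


@dataclass
class AbundanceMatrix:
    """Per-cell abundance slopes from the intensity-vs-cell-number regression.

    ``alpha``: ions x cell lines; ``alpha_se`` and ``alpha_p`` match its shape.
    ``beta`` is the per-ion shared background intercept. ``retained`` marks
    ions passing the significance filter (set by :func:`trmet.quantify.filter_ions`).
    """

    alpha: pd.DataFrame
    alpha_se: pd.DataFrame
    alpha_p: pd.DataFrame
    beta: pd.Series
    retained: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        for name in ("alpha_se", "alpha_p"):
            m = getattr(self, name)
            if m.shape != self.alpha.shape:
                raise ValueError(f"{name} shape does not match alpha")
        if (self.alpha_se.to_numpy() < -1e-12).any():
            raise ValueError("standard errors must be nonnegative")
        p = self.alpha_p.to_numpy()
        with np.errstate(invalid="ignore"):
            if ((p < -1e-12) | (p > 1 + 1e-12)).any():
                raise ValueError("p-values must lie in [0, 1]")


@dataclass
class ZMatrix:
    """Z-scored, volume-corrected metabolite abundances (ions x cell lines)."""

    z: pd.DataFrame
    volume_factor: pd.Series
    flagged_constant: pd.Index = field(default_factory=lambda: pd.Index([]))


@dataclass
class IonAnnotation:
    """One candidate compound match for a measured ion m/z."""

    ion_id: str
    mz: float
    compound_id: str
    formula: str
    adduct: str  # "[M-H]-" or "[M+PH-H]-" (phenylhydrazone, alpha-keto acids)
    mass_error: float


@dataclass
class ActivityMatrix:
    """TR activities per cell line, summarized over bootstrap subnetworks."""

    activity: pd.DataFrame  # TRs x cell lines, median over estimates
    spread: pd.DataFrame    # matching SD
    n_estimates: pd.Series  # per-TR count of collected estimates

    def __post_init__(self) -> None:
        if self.spread.shape != self.activity.shape:
            raise ValueError("spread shape does not match activity")


@dataclass
class AssociationMatrix:
    """Spearman correlations between TR activities and metabolite levels."""

    R: pd.DataFrame  # TRs x metabolites
    p: pd.DataFrame
    n_obs: int

    def __post_init__(self) -> None:
        r = self.R.to_numpy()
        with np.errstate(invalid="ignore"):
            if (np.abs(r) > 1 + 1e-9).any():
                raise ValueError("correlations must lie in [-1, 1]")

    def ctr_vectors(self) -> pd.DataFrame:
        """Per-TR signature vectors C_TR = R * (-log10 p), metabolites on columns.

        Undefined pairs (NaN R or p) contribute 0.
        """
        with np.errstate(divide="ignore"):
            logp = -np.log10(self.p.to_numpy())
        logp[~np.isfinite(logp)] = 0.0
        c = self.R.to_numpy() * logp
        c = np.nan_to_num(c, nan=0.0)
        return pd.DataFrame(c, index=self.R.index, columns=self.R.columns)


@dataclass
class FdrThreshold:
    """|R| cutoff controlling the association-network FDR at a nominal level."""

    threshold: float
    fdr: float
    n_resamples: int

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
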