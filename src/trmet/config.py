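"""Configuration objects for the synthetic study and the pipeline driver.

The synthetic study emulates a 96-well metabolic-profiling screen across a
panel of adherent cancer cell lines: lines are grown in batches, sampled in
triplicate at five daily time points, and ion intensities scale linearly with
the number of extracted cells on top of a per-plate instrument factor and a
constant background. Defaults mirror that study design (54 lines from 8
tissues, 15 metabolome samples per line, 12 pooled-extract wells per plate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

WELL_AREA_UM2 = 0.32e8  # growth area of a 96-well plate well (0.32 cm^2)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Counts must all be >= 1 and ``noise_cv`` >= 0. The same seed and config
    reproduce bit-identical tables.
    """

    n_cell_lines: int = 54
    n_tissues: int = 8
    n_ions: int = 500
    n_true_metabolites: int = 300
    n_genes: int = 1200
    n_trs: int = 100
    n_kinases: int = 20
    replicates_per_timepoint: int = 3
    n_timepoints: int = 5
    lines_per_batch: int = 5
    pooled_samples_per_plate: int = 12
    blanks_per_plate: int = 3
    noise_cv: float = 0.10
    seed: int = 0

    # secondary knobs of the generative model (all with units noted)
    expression_noise_sd: float = 0.10      # additive SD on expression, signal SD ~1
    growth_confounder_strength: float = 2.0  # SD of the rank-one growth term
    bio_variation_sd: float = 0.40         # per-(ion, line) log-abundance SD
    tissue_effect_sd: float = 0.60         # log-abundance SD of planted tissue shifts
    coupling_strength: float = 1.0         # log-abundance shift per unit TR activity
    n_volume_ions: int = 60                # ions reporting purely on cell volume
    n_coupled_trs: int = 10                # TRs with planted metabolite coupling
    mets_per_coupled_tr: int = 8
    targets_per_tr_min: int = 12
    targets_per_tr_max: int = 24
    plate_factor_sd: float = 0.25          # log-SD of per-plate scaling factors

    def __post_init__(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_tissues": self.n_tissues,
            "n_ions": self.n_ions,
            "n_true_metabolites": self.n_true_metabolites,
            "n_genes": self.n_genes,
            "n_trs": self.n_trs,
            "n_kinases": self.n_kinases,
            "replicates_per_timepoint": self.replicates_per_timepoint,
            "n_timepoints": self.n_timepoints,
            "lines_per_batch": self.lines_per_batch,
            "pooled_samples_per_plate": self.pooled_samples_per_plate,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_true_metabolites > self.n_ions:
            raise ValueError("n_true_metabolites cannot exceed n_ions")
        if self.targets_per_tr_min > self.targets_per_tr_max:
            raise ValueError("targets_per_tr_min > targets_per_tr_max")

    @property
    def samples_per_line(self) -> int:
        return self.replicates_per_timepoint * self.n_timepoints

    @property
    def n_batches(self) -> int:
        return -(-self.n_cell_lines // self.lines_per_batch)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """Stage parameters for the end-to-end pipeline driver.

    Defaults are the values used throughout the analyses: 0.003 amu annotation
    tolerance, Pearson r > 0.8 volume-ion selection, |Spearman R| > 0.5 for the
    augmented TR-gene network, 100 association-bootstrap resamples, 10,000
    permutations for permutation tests, FDR 0.1 %, and the >10-missing-values
    metabolite filter for patient cohorts.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "trmet_out"

    mz_tolerance_amu: float = 0.003
    bonferroni_alpha: float = 0.05
    volume_r_threshold: float = 0.8
    augmented_r_threshold: float = 0.5
    assoc_n_resamples: int = 100
    assoc_fdr: float = 0.001
    subnetworks_per_tr: int = 10
    nca_k: int = 48
    nca_tol: float = 1e-6
    nca_max_iter: int = 60
    n_permutations: int = 10_000
    n_random_graphs: int = 10_000
    cohort_max_missing: int = 10
    cohort_n_patients: int = 20
    effector_fdr: float = 0.001
    effector_n_null: int = 20
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
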