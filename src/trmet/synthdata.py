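"""Seeded synthetic study generator.

Emulates the statistical structure of a large-scale adherent-cell metabolic
profiling screen and the omics layers integrated with it:

* logistic growth monitored as well confluence, triplicate wells at five
  daily time points (15 metabolome samples per line);
* ion intensities linear in extracted cell number, on top of a per-plate
  instrument scaling factor and a cell-independent background, with
  multiplicative log-normal noise;
* a signed TR -> target-gene network generating expression as
  activity-weighted sums plus a rank-one growth confounder;
* a toy bipartite metabolite/reaction network with enzyme -> reaction
  mapping, in which selected TRs have enzyme targets and the metabolites
  around those reactions are coupled to the TR's activity;
* patient cohorts with one planted perturbed TR, siRNA knockdown
  fold-changes, and proteome/drug panels with planted metabolite/kinase
  effectors of TR activity.

All randomness flows from ``SimulationConfig.seed``; identical seed and
config give bit-identical tables. Each generator stage draws from its own
child stream so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, WELL_AREA_UM2
from .types import IntensityTable

CELL_HEIGHT_UM = 12.0  # adherent cell height treated as constant across lines

# child-stream tags so each stage has an independent, reproducible stream
_STREAM = {
    "truth": 1,
    "growth": 2,
    "intensity": 3,
    "expression": 4,
    "cohort": 5,
    "proteome": 6,
    "knockdown": 7,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stage]])


@dataclass
class GroundTruth:
    """True parameters behind one synthetic study."""

    tissue: pd.Series              # per-line tissue label
    cell_area: pd.Series           # per-line characteristic cell area (um^2)
    cell_volume: pd.Series         # per-line cell volume (um^3)
    doubling_time: pd.Series       # per-line doubling time (h)
    alpha_true: pd.DataFrame       # ions x lines per-cell intensity slopes
    beta_true: pd.Series           # per-ion background intensity
    plate_factor_true: pd.Series   # per-plate gamma_p, product 1 per batch
    tr_activity_true: pd.DataFrame  # TRs x lines
    regulatory_edges: list[tuple[str, str, str]]  # (TR, gene, mode)
    reaction_table: pd.DataFrame   # reaction_id, gene_ids, substrates, products
    coupled_metabolites: dict[str, list[str]]  # TR -> coupled metabolite ions
    tissue_metabolites: list[str]  # ions with a planted tissue effect
    volume_ions: list[str]         # ions reporting purely on cell volume
    planted_effectors: list[tuple[str, str, str, str, str]]  # (TR, met, kin, met_mode, kin_mode)
    perturbed_tr: str
    plate_batch: pd.Series         # plate id -> batch id

    def __post_init__(self) -> None:
        prods = self.plate_factor_true.groupby(self.plate_batch).prod()
        if not np.allclose(prods.to_numpy(), 1.0):
            raise ValueError("plate factors must multiply to 1 within each batch")
        if (self.alpha_true.to_numpy() < 0).any():
            raise ValueError("alpha_true must be nonnegative")
        mets = set(self.alpha_true.index)
        trs = set(self.tr_activity_true.index)
        for tr, met, kin, _, _ in self.planted_effectors:
            if tr not in trs or met not in mets:
                raise ValueError(f"planted effector references unknown entity: {(tr, met, kin)}")
        if self.perturbed_tr not in trs:
            raise ValueError(f"unknown perturbed TR {self.perturbed_tr!r}")


def _line_ids(config: SimulationConfig) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(config.n_cell_lines)]


def _ion_ids(config: SimulationConfig) -> list[str]:
    return [f"ion{i + 1:04d}" for i in range(config.n_ions)]


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(config.n_genes)]


def _tr_ids(config: SimulationConfig) -> list[str]:
    return [f"TR{i + 1:03d}" for i in range(config.n_trs)]


def _kinase_ids(config: SimulationConfig) -> list[str]:
    return [f"K{i + 1:02d}" for i in range(config.n_kinases)]


def _batches(config: SimulationConfig) -> list[list[str]]:
    lines = _line_ids(config)
    step = config.lines_per_batch
    return [lines[i:i + step] for i in range(0, len(lines), step)]


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the latent parameters of one synthetic study."""
    rng = _rng(config, "truth")
    lines = _line_ids(config)
    ions = _ion_ids(config)
    genes = _gene_ids(config)
    trs = _tr_ids(config)
    kinases = _kinase_ids(config)

    tissue = pd.Series(
        [f"tissue{(i * config.n_tissues) // config.n_cell_lines + 1}" for i in range(config.n_cell_lines)],
        index=lines, name="tissue",
    )
    cell_area = pd.Series(rng.uniform(1200.0, 3600.0, config.n_cell_lines), index=lines, name="cell_area")
    cell_volume = (cell_area * CELL_HEIGHT_UM).rename("cell_volume")
    doubling_time = pd.Series(rng.uniform(18.0, 45.0, config.n_cell_lines), index=lines, name="doubling_time")

    # per-plate scaling factors, product fixed to 1 within each batch
    batches = _batches(config)
    plate_ids, batch_of_plate, log_gamma = [], [], []
    for b in range(len(batches)):
        lg = rng.normal(0.0, config.plate_factor_sd, config.n_timepoints)
        lg -= lg.mean()
        for t in range(config.n_timepoints):
            plate_ids.append(f"P{b + 1:02d}T{t + 1}")
            batch_of_plate.append(f"batch{b + 1:02d}")
            log_gamma.append(lg[t])
    plate_factor = pd.Series(np.exp(log_gamma), index=plate_ids, name="gamma")
    plate_batch = pd.Series(batch_of_plate, index=plate_ids, name="batch")

    # TR activities (iid across TRs and lines; relative scale is arbitrary).
    # Rows are drawn orthogonal to the growth-rate direction: the growth
    # program is carried by the rank-one confounder, and with a dense growth
    # pseudo-TR in the inference only the growth-orthogonal component of an
    # activity is identifiable, so the latent regulatory signals are defined
    # net of proliferation.
    act = rng.standard_normal((config.n_trs, config.n_cell_lines))
    rate = 1.0 / doubling_time.to_numpy()
    w = (rate - rate.mean()) / np.linalg.norm(rate - rate.mean())
    act = act - np.outer(act @ w, w)
    tr_activity = pd.DataFrame(act, index=trs, columns=lines)

    # toy bipartite metabolic network: a metabolite chain closed into a ring,
    # one enzyme gene per reaction, occasional extra substrate
    n_met = config.n_true_metabolites
    met_ids = ions[:n_met]
    n_rxn = min(n_met, config.n_genes)
    rows = []
    for r in range(n_rxn):
        subs = [met_ids[r]]
        if rng.random() < 0.3:
            subs.append(met_ids[int(rng.integers(n_met))])
        prods = [met_ids[(r + 1) % n_met]]
        rows.append({
            "reaction_id": f"R{r + 1:04d}",
            "gene_ids": genes[r],
            "substrates": ";".join(sorted(set(subs))),
            "products": ";".join(prods),
        })
    reaction_table = pd.DataFrame(rows)

    # planted TR-metabolite couplings: each coupled TR targets the enzymes of
    # a window of consecutive reactions; metabolites of that window track the
    # TR's activity in their per-cell abundance
    window = max(config.mets_per_coupled_tr - 1, 1)
    stride = max(n_rxn // max(config.n_coupled_trs, 1), window + 1)
    coupled: dict[str, list[str]] = {}
    tr_enzyme_targets: dict[str, list[str]] = {}
    for j in range(min(config.n_coupled_trs, config.n_trs)):
        tr = trs[j]
        start = (j * stride) % max(n_rxn - window, 1)
        rxns = list(range(start, min(start + window, n_rxn)))
        tr_enzyme_targets[tr] = [genes[r] for r in rxns]
        mets = sorted({met_ids[r] for r in rxns} | {met_ids[(r + 1) % n_met] for r in rxns})
        coupled[tr] = mets[:config.mets_per_coupled_tr]

    # signed regulatory edges: enzyme targets for coupled TRs plus random fill
    edges: list[tuple[str, str, str]] = []
    for tr in trs:
        n_targets = int(rng.integers(config.targets_per_tr_min, config.targets_per_tr_max + 1))
        targets = list(tr_enzyme_targets.get(tr, []))
        pool = [g for g in genes if g not in targets]
        extra = rng.choice(len(pool), size=max(n_targets - len(targets), 0), replace=False)
        targets.extend(pool[i] for i in sorted(extra))
        for g in targets:
            mode = "activation" if rng.random() < 0.7 else "repression"
            edges.append((tr, g, mode))

    # per-cell abundance slopes: ion scale x relative cell volume x biology
    rel_volume = (cell_volume / cell_volume.mean()).to_numpy()
    ion_scale = np.exp(rng.normal(np.log(10.0), 1.0, config.n_ions))
    log_bio = rng.normal(0.0, config.bio_variation_sd, (n_met, config.n_cell_lines))
    met_index = {m: i for i, m in enumerate(met_ids)}
    for tr, mets in coupled.items():
        act = tr_activity.loc[tr].to_numpy()
        for m in mets:
            log_bio[met_index[m]] += config.coupling_strength * act

    # planted tissue effects on a slice of non-coupled metabolites
    coupled_set = {m for ms in coupled.values() for m in ms}
    free_mets = [m for m in met_ids if m not in coupled_set]
    tissue_mets = free_mets[:min(40, len(free_mets) // 3)]
    tissue_codes = tissue.astype("category").cat.codes.to_numpy()
    for m in tissue_mets:
        shifts = rng.normal(0.0, config.tissue_effect_sd, config.n_tissues)
        log_bio[met_index[m]] += shifts[tissue_codes]

    # volume-reporter ions: purely proportional to cell volume (no biology)
    vol_ions = free_mets[-config.n_volume_ions:] if config.n_volume_ions else []
    for m in vol_ions:
        log_bio[met_index[m]] = 0.0

    alpha = np.zeros((config.n_ions, config.n_cell_lines))
    alpha[:n_met] = ion_scale[:n_met, None] * rel_volume[None, :] * np.exp(log_bio)
    alpha_true = pd.DataFrame(alpha, index=ions, columns=lines)
    beta_true = pd.Series(np.exp(rng.normal(np.log(500.0), 0.5, config.n_ions)), index=ions, name="beta")

    # planted effectors: TRs outside the coupled block, paired with free
    # metabolites and kinases, covering activating and inhibiting modes
    effector_trs = trs[config.n_coupled_trs:config.n_coupled_trs + 3] or trs[:3]
    modes = [("activation", "activation"), ("activation", "inhibition"), ("inhibition", "activation")]
    planted = []
    step = max(len(free_mets) // (len(effector_trs) + 1), 1)
    used: set[str] = set()
    for i, tr in enumerate(effector_trs):
        met = free_mets[(5 + step * i) % len(free_mets)]
        while met in used:
            met = free_mets[(free_mets.index(met) + 1) % len(free_mets)]
        used.add(met)
        kin = kinases[i % config.n_kinases]
        planted.append((tr, met, kin) + modes[i % len(modes)])

    return GroundTruth(
        tissue=tissue,
        cell_area=cell_area,
        cell_volume=cell_volume,
        doubling_time=doubling_time,
        alpha_true=alpha_true,
        beta_true=beta_true,
        plate_factor_true=plate_factor,
        tr_activity_true=tr_activity,
        regulatory_edges=edges,
        reaction_table=reaction_table,
        coupled_metabolites=coupled,
        tissue_metabolites=tissue_mets,
        volume_ions=list(vol_ions),
        planted_effectors=planted,
        perturbed_tr=trs[0],
        plate_batch=plate_batch,
    )


# ---------------------------------------------------------------------------
# growth and sampling design
# ---------------------------------------------------------------------------

def simulate_growth(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate confluence curves and the metabolome sampling design.

    Returns ``(confluence, counts, sample_meta)``: a long table of per-well
    confluence at each sampled time point, extracted cell counts per cell
    sample, and the full per-sample metadata (cell, pooled and blank wells).
    Extracted cell number is confluence/100 x well area / characteristic
    cell area. Each line yields ``replicates_per_timepoint x n_timepoints``
    metabolome samples (15 under defaults).
    """
    rng = _rng(config, "growth")
    batches = _batches(config)
    hours = 24.0 * np.arange(config.n_timepoints)

    meta_rows = []
    conf_rows = []
    for b, batch_lines in enumerate(batches):
        batch_id = f"batch{b + 1:02d}"
        for t in range(config.n_timepoints):
            plate = f"P{b + 1:02d}T{t + 1}"
            for line in batch_lines:
                c0 = rng.uniform(4.0, 8.0)
                r = np.log(2.0) / truth.doubling_time[line]
                conf_t = 100.0 / (1.0 + (100.0 / c0 - 1.0) * np.exp(-r * hours[t]))
                for rep in range(1, config.replicates_per_timepoint + 1):
                    conf = float(np.clip(conf_t * (1.0 + 0.03 * rng.standard_normal()), 0.0, 100.0))
                    sid = f"{line}_t{t + 1}_r{rep}"
                    meta_rows.append((sid, "cell", line, plate, "", t + 1, rep, conf))
                    conf_rows.append((sid, line, t + 1, rep, conf))
            for j in range(1, config.pooled_samples_per_plate + 1):
                sid = f"{plate}_pool{j:02d}"
                meta_rows.append((sid, "pooled", None, plate, batch_id, t + 1, j, np.nan))
            for j in range(1, config.blanks_per_plate + 1):
                sid = f"{plate}_blank{j}"
                meta_rows.append((sid, "blank", None, plate, "", t + 1, j, np.nan))

    sample_meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "sample_type", "cell_line", "plate", "pool_id", "timepoint", "replicate", "confluence"],
    ).set_index("sample")
    confluence = pd.DataFrame(conf_rows, columns=["sample", "cell_line", "timepoint", "replicate", "confluence"])

    cells = sample_meta.loc[sample_meta["sample_type"] == "cell"]
    area = truth.cell_area.reindex(cells["cell_line"]).to_numpy()
    counts = pd.Series(
        (cells["confluence"].to_numpy() / 100.0) * WELL_AREA_UM2 / area,
        index=cells.index, name="cells",
    )
    return confluence, counts, sample_meta


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def simulate_intensities(
    truth: GroundTruth,
    counts: pd.Series,
    sample_meta: pd.DataFrame,
    config: SimulationConfig,
    pooled_reference_cells: float = 1.5e4,
) -> IntensityTable:
    """Generate the raw ion-intensity table for the designed samples.

    Cell wells emit ``gamma_p * (alpha_true . N + beta_true)``; pooled wells
    share one pooled composition per batch across that batch's plates (the
    batch mean of cell compositions at a reference cell number); blanks emit
    ``gamma_p * beta_true``. All intensities carry multiplicative log-normal
    noise with coefficient of variation ``noise_cv``.
    """
    if (counts < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (truth.alpha_true.to_numpy() < 0).any():
        raise ValueError("alpha_true must be nonnegative")
    rng = _rng(config, "intensity")
    alpha = truth.alpha_true.to_numpy()
    beta = truth.beta_true.to_numpy()
    gamma = truth.plate_factor_true

    # pooled composition per batch (pre-noise, identical across the batch's plates)
    line_idx = {l: i for i, l in enumerate(truth.alpha_true.columns)}
    pooled_comp = {}
    for batch_id, batch_lines in zip(
        sorted(truth.plate_batch.unique()), _batches(config)
    ):
        cols = [line_idx[l] for l in batch_lines]
        pooled_comp[batch_id] = alpha[:, cols].mean(axis=1) * pooled_reference_cells + beta

    n_ions = alpha.shape[0]
    out = np.empty((n_ions, len(sample_meta)))
    stypes = sample_meta["sample_type"].to_numpy()
    plates = sample_meta["plate"].to_numpy()
    for k, sid in enumerate(sample_meta.index):
        g = gamma[plates[k]]
        if stypes[k] == "cell":
            mean = g * (alpha[:, line_idx[sample_meta.at[sid, "cell_line"]]] * counts[sid] + beta)
        elif stypes[k] == "pooled":
            mean = g * pooled_comp[sample_meta.at[sid, "pool_id"]]
        else:
            mean = g * beta
        out[:, k] = mean

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, out.shape))
        out = out * noise

    intensity = pd.DataFrame(out, index=truth.alpha_true.index, columns=sample_meta.index)
    return IntensityTable(intensity, sample_meta.copy())


# ---------------------------------------------------------------------------
# regulatory system and expression
# ---------------------------------------------------------------------------

def regulatory_network_frame(truth: GroundTruth) -> pd.DataFrame:
    """The ground-truth regulatory network as a (tr, target, mode) frame."""
    return pd.DataFrame(truth.regulatory_edges, columns=["tr", "target", "mode"])


def simulate_tr_system(
    config: SimulationConfig,
    truth: GroundTruth,
    include_growth_confounder: bool = True,
    noise_sd: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate expression from the signed network and true TR activities.

    ``E = A . P + g w^T + noise`` where A respects the edge signs of the
    regulatory network, P is the true activity matrix, and ``g w^T`` is a
    rank-one confounder with w proportional to the standardized growth rate
    (1 / doubling time). Returns ``(network, expression)``.
    """
    rng = _rng(config, "expression")
    genes = _gene_ids(config)
    trs = _tr_ids(config)
    lines = list(truth.tr_activity_true.columns)
    gidx = {g: i for i, g in enumerate(genes)}
    tidx = {t: i for i, t in enumerate(trs)}

    A = np.zeros((config.n_genes, config.n_trs))
    for tr, gene, mode in truth.regulatory_edges:
        sign = 1.0 if mode == "activation" else -1.0
        A[gidx[gene], tidx[tr]] = sign * rng.uniform(0.5, 1.5)

    E = A @ truth.tr_activity_true.to_numpy()
    if include_growth_confounder and config.growth_confounder_strength > 0:
        rate = 1.0 / truth.doubling_time.to_numpy()
        w = (rate - rate.mean()) / rate.std()
        g = rng.standard_normal(config.n_genes)
        E = E + config.growth_confounder_strength * np.outer(g, w)
    sd = config.expression_noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        E = E + rng.normal(0.0, sd, E.shape)

    network = regulatory_network_frame(truth)
    expression = pd.DataFrame(E, index=genes, columns=lines)
    return network, expression


# ---------------------------------------------------------------------------
# patient cohorts and knockdown
# ---------------------------------------------------------------------------

def simulate_cohort(
    ctr: pd.DataFrame,
    config: SimulationConfig,
    perturbed_tr: str,
    n_patients: int = 20,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.02,
    n_dropout_metabolites: int = 12,
) -> pd.DataFrame:
    """Patient log2 fold-changes driven by one perturbed TR's signature.

    ``ctr`` is the TR x metabolite signature matrix (R x -log10 p) derived
    in vitro. Per patient, FC = effect_size x C_perturbed + noise. A fraction
    of entries is missing completely at random, and ``n_dropout_metabolites``
    metabolites are mostly missing to exercise the >10-missing filter.
    """
    if perturbed_tr not in ctr.index:
        raise ValueError(f"unknown perturbed TR {perturbed_tr!r}")
    rng = _rng(config, "cohort")
    c = ctr.loc[perturbed_tr].to_numpy()
    mets = list(ctr.columns)
    patients = [f"patient{i + 1:02d}" for i in range(n_patients)]
    fc = effect_size * c[:, None] + rng.normal(0.0, noise_sd, (len(mets), n_patients))
    fc = pd.DataFrame(fc, index=mets, columns=patients)

    if missing_fraction > 0:
        mask = rng.random(fc.shape) < missing_fraction
        fc = fc.mask(mask)
    if n_dropout_metabolites > 0:
        drop = rng.choice(len(mets), size=min(n_dropout_metabolites, len(mets)), replace=False)
        heavy = rng.random((len(drop), n_patients)) < 0.8
        block = fc.iloc[drop].mask(heavy)
        fc.iloc[drop] = block
    return fc


def simulate_knockdown(
    ctr: pd.DataFrame,
    config: SimulationConfig,
    knocked_tr: str,
    concentrations: Sequence[str] = ("10nM", "25nM", "50nM"),
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite fold-changes and p-values after silencing one TR.

    Knocking a TR down moves metabolites against its association signature;
    higher siRNA concentration gives a stronger effect. Returns ``(fc, p)``,
    metabolites x concentrations.
    """
    if knocked_tr not in ctr.index:
        raise ValueError(f"unknown TR {knocked_tr!r}")
    rng = _rng(config, "knockdown")
    from scipy.stats import norm

    c = ctr.loc[knocked_tr].to_numpy()
    scales = np.linspace(0.6, 1.0, len(concentrations))
    fc = np.empty((len(c), len(concentrations)))
    for j, s in enumerate(scales):
        fc[:, j] = -effect_size * s * c + rng.normal(0.0, noise_sd, len(c))
    p = 2.0 * norm.sf(np.abs(fc) / noise_sd)
    cols = list(concentrations)
    return (
        pd.DataFrame(fc, index=ctr.columns, columns=cols),
        pd.DataFrame(p, index=ctr.columns, columns=cols),
    )


# ---------------------------------------------------------------------------
# proteome, modeled activity, drug panel
# ---------------------------------------------------------------------------

@dataclass
class ProteomeTable:
    """Protein abundances for TRs and kinases (rows) across cell lines."""

    abundance: pd.DataFrame
    protein_type: pd.Series  # "TR" | "kinase"


@dataclass
class DrugPanel:
    """GI50-style drug sensitivities with mechanism-of-action labels."""

    sensitivity: pd.DataFrame  # drugs x lines (log GI50 scale)
    moa: pd.Series             # per-drug mechanism of action
    lambda_true: pd.DataFrame  # drugs x TRs planted activity effects
    tr_clusters: pd.Series     # per-TR functional cluster label


def saturable(x: np.ndarray, K: float, mode: str) -> np.ndarray:
    """Saturable modulation: activation x/(K+x) or inhibition K/(K+x)."""
    if mode == "activation":
        return x / (K + x)
    if mode == "inhibition":
        return K / (K + x)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_proteome_drugs(
    config: SimulationConfig,
    truth: GroundTruth,
    n_drugs: int = 30,
    n_moa: int = 6,
    activity_noise_sd: Optional[float] = None,
    drug_noise_sd: float = 0.3,
    lambda_effect: float = 1.5,
) -> tuple[ProteomeTable, pd.DataFrame, DrugPanel]:
    """Proteome, effector-modeled TR activity, and a drug panel.

    For each planted (TR, metabolite, kinase) effector the TR's activity row
    follows ``a + b . protein . f(met) . f(kinase)`` with saturable
    activation/inhibition terms; all other TRs keep their ground-truth
    activity. Drug sensitivity is ``lambda . activity_TR + sum_t beta_t
    tissue_t + noise``; drugs of the first mechanism-of-action class target
    TRs of the first functional cluster.
    """
    rng = _rng(config, "proteome")
    lines = list(truth.tr_activity_true.columns)
    trs = list(truth.tr_activity_true.index)
    kinases = _kinase_ids(config)

    prot = np.exp(rng.normal(0.0, 0.5, (len(trs) + len(kinases), len(lines))))
    abundance = pd.DataFrame(prot, index=trs + kinases, columns=lines)
    abundance = abundance.div(abundance.median(axis=1), axis=0)  # unit median
    ptype = pd.Series(["TR"] * len(trs) + ["kinase"] * len(kinases), index=trs + kinases)

    # metabolite levels on a positive scale with unit median
    met_level = truth.alpha_true.div(truth.alpha_true.median(axis=1).replace(0, 1.0), axis=0)

    sd = config.noise_cv if activity_noise_sd is None else activity_noise_sd
    activity = truth.tr_activity_true.copy()
    for tr, met, kin, met_mode, kin_mode in truth.planted_effectors:
        f_m = saturable(met_level.loc[met].to_numpy(), 1.0, met_mode)
        f_k = saturable(abundance.loc[kin].to_numpy(), 1.0, kin_mode)
        base = abundance.loc[tr].to_numpy() * f_m * f_k
        signal = (base - base.mean()) / base.std()
        activity.loc[tr] = 0.2 + signal + rng.normal(0.0, sd, len(lines))

    # drug panel
    drugs = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    moa = pd.Series([f"moa{i % n_moa + 1}" for i in range(n_drugs)], index=drugs, name="moa")
    cluster = pd.Series([f"c{i // 5 + 1}" for i in range(len(trs))], index=trs, name="cluster")
    lam = pd.DataFrame(0.0, index=drugs, columns=trs)
    target_cluster = cluster[cluster == "c1"].index
    for i, d in enumerate(moa[moa == "moa1"].index):
        tr = target_cluster[i % len(target_cluster)]
        lam.loc[d, tr] = lambda_effect

    tissues = sorted(truth.tissue.unique())
    beta_t = {t: rng.normal(0.0, 0.5) for t in tissues}
    tissue_term = np.array([beta_t[truth.tissue[l]] for l in lines])
    sens = lam.to_numpy() @ activity.loc[trs].to_numpy() + tissue_term[None, :]
    sens = sens + rng.normal(0.0, drug_noise_sd, sens.shape)
    sensitivity = pd.DataFrame(sens, index=drugs, columns=lines)

    panel = DrugPanel(sensitivity=sensitivity, moa=moa, lambda_true=lam, tr_clusters=cluster)
    return ProteomeTable(abundance, ptype), activity, panel


# ---------------------------------------------------------------------------
# convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one synthetic study produces, keyed by stage."""

    config: SimulationConfig
    truth: GroundTruth
    confluence: pd.DataFrame
    counts: pd.Series
    intensities: IntensityTable
    network: pd.DataFrame
    expression: pd.DataFrame


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage under one config and bundle the outputs."""
    truth = make_ground_truth(config)
    confluence, counts, sample_meta = simulate_growth(config, truth)
    intensities = simulate_intensities(truth, counts, sample_meta, config)
    network, expression = simulate_tr_system(config, truth)
    return SyntheticStudy(
        config=config,
        truth=truth,
        confluence=confluence,
        counts=counts,
        intensities=intensities,
        network=network,
        expression=expression,
    )
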