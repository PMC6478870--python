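"""Build the TR-metabolite association network at a bootstrap-calibrated FDR.

Couples the quantified metabolome with TR activities, computes all pairwise
Spearman correlations, and sets the |R| cutoff so that the expected
fraction of false network links is 0.1% (pooled null from resampling the
metabolome's cell-line labels with replacement).
"""

from trmet import assoc, quantify, synthdata
from trmet.config import SimulationConfig

cfg = SimulationConfig(
    n_cell_lines=20, n_tissues=4, n_ions=120, n_true_metabolites=80,
    n_genes=300, n_trs=30, n_kinases=6, n_coupled_trs=5, n_volume_ions=15,
    seed=3,
)
study = synthdata.simulate_study(cfg)
_, zm, _ = quantify.quantify(study.intensities, study.counts)

am = assoc.correlate(study.truth.tr_activity_true, zm)
thr = assoc.bootstrap_fdr(study.truth.tr_activity_true, zm,
                          n_resamples=100, fdr=0.001, seed=0)
links = assoc.association_links(am, thr)
print(f"{am.R.shape[0]} TRs x {am.R.shape[1]} metabolites; "
      f"|R| threshold {thr.threshold:.3f} at 0.1% FDR")
print(f"{int(links['pass_fdr'].sum())} links pass the threshold")

hits = total = 0
for tr, mets in study.truth.coupled_metabolites.items():
    for m in mets:
        if m in am.R.columns:
            total += 1
            hits += int(abs(am.R.loc[tr, m]) >= thr.threshold)
print(f"planted TR-metabolite couplings recovered above threshold: {hits}/{total}")
print("each link is a TR whose inferred activity co-varies with a "
      "metabolite's per-cell abundance across the panel")
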