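"""End-to-end synthetic run: simulate, search, FDR-filter, quantify.

Generates a synthetic glycoproteome under the two-condition (siCon vs
siFut8), two-replicate TMT6 design with a 0.05 knockdown of
core-fucosylated forms, simulates noisy MS/MS spectra, searches them
against the proteome at 6/20 ppm with target-decoy FDR control, and
prints the recovered site-level siFut8/siCon ratios.
"""

import numpy as np

from fucoquant.quant import quantify_reporters
from fucoquant.search import SearchConfig, build_candidate_index, fdr_filter, search_spectra
from fucoquant.simulate import (
    NoiseModel,
    StudyDesign,
    make_synthetic_proteome,
    simulate_ground_truth,
    simulate_spectra,
)

proteome = make_synthetic_proteome(n_proteins=25, length=240, sites_per_protein=2, seed=1)
design = StudyDesign(n_proteins=25, knockdown_ratio=0.05, seed=1)
truth = simulate_ground_truth(design, proteome)
spectra, sidecar = simulate_spectra(truth, NoiseModel(), seed=2)
print(f"simulated {len(spectra)} spectra "
      f"({sum(sidecar.core_fucosylated)} core-fucosylated glycopeptides)")

config = SearchConfig()
index = build_candidate_index(proteome, config)
print(f"candidate index: {len(index)} entries ({index.n_targets} targets)")

psms = search_spectra(spectra, index, config)
accepted = fdr_filter(psms, q=config.fdr_q)
print(f"identified {len(psms)} spectra, {len(accepted)} accepted at q <= 1%")

records = quantify_reporters(accepted, spectra)
core_sites = {
    (r.protein_id, int(r.glyco_site_protein))
    for r in sidecar.itertuples() if r.core_fucosylated
}
core = [r for r in records if (r.protein_id, r.site) in core_sites]
other = [r for r in records if (r.protein_id, r.site) not in core_sites]
print(f"\nquantified {len(records)} glycosylation sites")
print(f"  core-fucosylated : median ratio rep1 = "
      f"{np.median([r.ratio_rep1 for r in core]):.3f}  (simulated 0.05)")
print(f"  non-fucosylated  : median ratio rep1 = "
      f"{np.median([r.ratio_rep1 for r in other]):.3f}  (expected ~1)")
print("\nA recovered median near 0.05 for core-fucosylated sites, with")
print("non-fucosylated remnants near 1, reproduces the knockdown signature")
print("the ranking stage selects on.")
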