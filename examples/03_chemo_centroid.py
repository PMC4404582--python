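"""Prospective chemosensitivity prediction with a cell-line centroid.

Selects drug-sensitive cell lines (log IC50 < -1 for taxane and/or
anthracycline), averages their expression over the signature's genes into
a centroid, then classifies neoadjuvant patients by Spearman correlation
with the centroid (sensitive iff rho > 0.35). Predictions are scored
against pathologic response (pCR vs residual disease) and against distant
relapse-free survival of the two predicted groups.
"""

import numpy as np

from sigscreen import SimulationConfig, simulate_cellline_panel, simulate_neoadjuvant_cohort
from sigscreen.chemo import (
    build_centroid,
    classify_cohort_by_centroid,
    km_by_prediction,
    response_metrics,
    select_sensitive_cell_lines,
)

cfg = SimulationConfig(n_genes=2000, n_samples=200, program_size=50, seed=31)
panel, truth = simulate_cellline_panel(cfg, n_lines=20, sens_fraction=0.65, seed=31)
lines = select_sensitive_cell_lines(panel, list(panel.drugs))
centroid = build_centroid(panel, lines, truth.planted_signature())
print(f"{len(lines)} of {len(panel.line_ids)} cell lines are drug-sensitive (log IC50 < -1)")

cohort, _ = simulate_neoadjuvant_cohort(cfg, n_patients=150, seed=32)
pred = classify_cohort_by_centroid(cohort, centroid)
n_sens = int((pred.labels == "sensitive").sum())
print(f"cohort of {cohort.n_samples}: {n_sens} predicted sensitive (rho > 0.35)")

metrics = response_metrics(pred, cohort.clinical, "pCR/RD")
base_rd = 100 * (cohort.clinical["pcr"] == "RD").mean()
print(
    f"pCR/RD endpoint: PPV {metrics.ppv:.1f}% vs RD base rate {base_rd:.1f}% "
    f"(sensitivity {metrics.sensitivity:.1f}%, specificity {metrics.specificity:.1f}%)"
)

km = km_by_prediction(
    pred, cohort.clinical["time"].to_numpy(), cohort.clinical["event"].to_numpy(int)
)
print(f"DRFS log-rank between predicted groups: chi2 = {km.chi2:.1f}, P = {km.p:.2e}")
print(
    "PPV above the residual-disease base rate means a patient called\n"
    "treatment-insensitive is enriched for RD beyond chance; the log-rank P\n"
    "shows the predicted groups also separate in long-term outcome."
)
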