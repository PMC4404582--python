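"""Screen a signature collection against survival cohorts.

Builds three synthetic breast-cancer-like cohorts carrying a planted
hazard program, plus one with no survival signal, then screens the
planted signature, two partial-overlap candidates and two signal-free
controls: each signature stratifies every cohort by Spearman/average-
linkage clustering and is scored by the log-rank test.
"""

from sigscreen import (
    SimulationConfig,
    rank_signatures_by_rate,
    run_screen,
    simulate_registry,
    simulate_signature_collection,
)

cfg = SimulationConfig(n_genes=2000, n_samples=150, program_size=50, seed=11)
registry, truth = simulate_registry(cfg, n_signal=3, n_null=1)
signatures = [truth.planted_signature()] + simulate_signature_collection(
    truth,
    registry.datasets[0].gene_ids,
    n_overlapping=2,
    n_random=0,
    overlap_fraction=0.6,
    length=50,
    seed=12,
) + simulate_signature_collection(
    truth,
    registry.datasets[0].gene_ids,
    n_overlapping=2,
    n_random=0,
    overlap_fraction=0.0,
    length=50,
    seed=13,
    overlap_prefix="CONTROL",
)

matrix = run_screen(signatures, registry)
ranking = rank_signatures_by_rate(matrix, cutoff=50.0)

print(f"{'signature':<18}{'significant rate':>18}  candidate")
for sig_id in ranking.order:
    mark = "yes" if sig_id in ranking.candidates else ""
    print(f"{sig_id:<18}{ranking.rates[sig_id]:>16.0f}%  {mark}")

cell = matrix.cell("PLANTED_PROGRAM", registry.ids[0])
print(
    f"\nPlanted program on {registry.ids[0]}: log-rank P = {cell.logrank_p:.2e}, "
    f"HR = {cell.hr:.2f} ({cell.hr_ci[0]:.2f}-{cell.hr_ci[1]:.2f}), c-index = {cell.c_index:.2f}"
)
print(
    "The rate is the share of cohorts (incl. the no-signal one) where the\n"
    "signature's two-group split separates survival at P < 0.05; candidates\n"
    "must exceed 50%. Signal-free controls should sit near the 5% false-\n"
    "positive level and never qualify."
)
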