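"""Random-signature permutation QC: adjusted P, N/A rate, differential index.

Builds a small registry containing sound cohorts, one contaminated with
flat dead-array samples (fails the >5% N/A bar) and one whose survival is
confounded with a global expression factor (random signatures succeed, so
the differential index collapses below 9 points). Length-matched random
signatures drawn from each cohort's own gene universe form the null.
"""

from sigscreen import (
    NullCache,
    SimulationConfig,
    adjusted_p,
    rank_signatures_by_rate,
    run_screen,
    simulate_registry,
    simulate_signature_collection,
    validate_datasets,
)

cfg = SimulationConfig(n_genes=2000, n_samples=140, program_size=50, seed=21)
registry, truth = simulate_registry(
    cfg, n_signal=4, n_null=0, n_degraded=1, n_confounded=1
)
signatures = [truth.planted_signature()] + simulate_signature_collection(
    truth, registry.datasets[0].gene_ids, 3, 20, 0.8, 50, seed=22
)

matrix = run_screen(signatures, registry, with_cox=False, with_cindex=False)
ranking = rank_signatures_by_rate(matrix)
cache = NullCache(master_seed=21, n_perm=200)
nulls = {ds.id: [cache.get(ds, 50)] for ds in registry}
report = validate_datasets(matrix, nulls, ranking.candidates)

print(f"{'dataset':<14}{'N/A rate':>9}{'DI (pts)':>10}  verdict")
for qc in report.per_dataset:
    print(
        f"{qc.dataset_id:<14}{qc.na_rate:>8.1%}{qc.differential_index:>10.1f}  {qc.verdict}"
    )

ds = registry.get(report.validated[0])
null = cache.get(ds, 50)
observed = matrix.cell("PLANTED_PROGRAM", ds.id).logrank_p
print(
    f"\nOn {ds.id}: observed log-rank P = {observed:.2e}; "
    f"{null.n_perm} length-matched random signatures give adjusted P = "
    f"{adjusted_p(observed, null):.3f}"
)
print(
    "A validated dataset keeps its N/A rate at or below 5% and shows a\n"
    "differential index of at least 9 points: candidate signatures must beat\n"
    "random gene sets of the same length, not just the log-rank null."
)
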