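"""End-to-end pipeline: screen -> permutation QC -> adjusted ranking -> chemo evaluation.

`run_pipeline` drives preloaded objects; `run_full_pipeline` is the
path-based wrapper the CLI uses; `make_demo` materialises a fully
synthetic workspace (signal + null survival datasets, a signature
collection with planted candidates, a cell-line panel and a neoadjuvant
cohort) and runs the whole pipeline on it. Every artifact is a pure
function of (inputs, config): no timestamps or environment state are
written, so reruns under the same master seed are bitwise identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import chemo as chemo_mod
from .chemo import CellLinePanel
from .io import (
    DatasetRegistry,
    ExpressionDataset,
    GeneSignature,
    read_registry,
    read_signature_collection,
    write_registry,
    write_signature_collection,
)
from .permutation import (
    AdjustedRanking,
    NullCache,
    QCReport,
    rank_by_adjusted_median_p,
    validate_datasets,
)
from .screen import RankResult, ScreenMatrix, rank_signatures_by_rate, run_screen
from .simulate import (
    SimulationConfig,
    simulate_cellline_panel,
    simulate_neoadjuvant_cohort,
    simulate_registry,
    simulate_signature_collection,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; every protocol threshold is explicit."""

    alpha: float = 0.05
    n_perm: int = 1000
    na_cut: float = 0.05
    di_cut: float = 9.0
    rate_cutoff: float = 50.0
    correlation_threshold: float = 0.35
    ic50_cutoff: float = -1.0
    drfs_horizon: float = 3.0
    label_mode: str = "by_direction"
    min_coverage: float = 0.5
    seed: int = 0
    drugs: tuple[str, ...] = ("taxane", "anthracycline")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not 0 <= self.na_cut <= 1:
            raise ValueError("na_cut must lie in [0, 1]")
        if not 0 <= self.rate_cutoff <= 100:
            raise ValueError("rate_cutoff is a percentage")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    screen: ScreenMatrix
    ranking: RankResult
    qc: QCReport | None
    adjusted: AdjustedRanking | None
    chemo: dict[str, object] = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    signatures: Sequence[GeneSignature],
    registry: DatasetRegistry,
    cfg: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
    panel: CellLinePanel | None = None,
    neoadjuvant: Sequence[ExpressionDataset] = (),
    chemo_signature_id: str | None = None,
) -> PipelineResult:
    """Execute screen -> QC -> adjusted ranking (-> chemo) and write artifacts.

    The chemo stage runs when a cell-line panel and at least one
    neoadjuvant cohort are supplied; the evaluated signature defaults to
    the top adjusted-ranked candidate.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    sig_by_id = {s.id: s for s in signatures}

    stage = "screen"
    try:
        screen = run_screen(
            signatures,
            registry,
            alpha=cfg.alpha,
            label_mode=cfg.label_mode,
            min_coverage=cfg.min_coverage,
        )
        ranking = rank_signatures_by_rate(screen, cutoff=cfg.rate_cutoff)
        if out is not None:
            _write_tsv(screen.to_long_frame(), out / "screen_long.tsv", artifacts, "screen_long")
            _write_tsv(
                screen.to_p_matrix().rename_axis("signature_id").reset_index(),
                out / "p_matrix.tsv",
                artifacts,
                "p_matrix",
            )
            rank_frame = pd.DataFrame(
                {
                    "signature_id": list(ranking.order),
                    "significant_rate_pct": [ranking.rates[s] for s in ranking.order],
                    "candidate": [s in ranking.candidates for s in ranking.order],
                }
            )
            _write_tsv(rank_frame, out / "ranking.tsv", artifacts, "ranking")

        stage = "permutation_qc"
        qc = adjusted = None
        if ranking.candidates:
            cache = NullCache(master_seed=cfg.seed, n_perm=cfg.n_perm)
            lengths = sorted({len(sig_by_id[s]) for s in ranking.candidates})
            for ds in registry:
                for length in lengths:
                    cache.get(ds, length)
            nulls_by_dataset = {d: cache.nulls_for_dataset(d) for d in registry.ids}
            qc = validate_datasets(
                screen,
                nulls_by_dataset,
                ranking.candidates,
                alpha=cfg.alpha,
                na_cut=cfg.na_cut,
                di_cut=cfg.di_cut,
            )
            if out is not None:
                _write_tsv(qc.to_frame(), out / "qc_report.tsv", artifacts, "qc_report")
            stage = "adjusted_ranking"
            if qc.validated:
                adjusted = rank_by_adjusted_median_p(
                    screen,
                    sig_by_id,
                    ranking.candidates,
                    qc.validated,
                    cache,
                    registry,
                    alpha=cfg.alpha,
                )
                if out is not None:
                    _write_tsv(
                        adjusted.to_frame(), out / "adjusted_ranking.tsv", artifacts, "adjusted"
                    )
        else:
            logger.info("no candidate signatures above the %.0f%% cutoff", cfg.rate_cutoff)

        stage = "chemo"
        chemo_results: dict[str, object] = {}
        if panel is not None and neoadjuvant:
            target_id = chemo_signature_id
            if target_id is None:
                if adjusted is not None and adjusted.top:
                    target_id = adjusted.top[0]
                elif ranking.candidates:
                    target_id = ranking.candidates[0]
            if target_id is None:
                logger.info("chemo stage skipped: no candidate signature to evaluate")
            else:
                chemo_results = _chemo_stage(
                    sig_by_id[target_id], panel, neoadjuvant, cfg, out, artifacts
                )
        result = PipelineResult(
            screen=screen, ranking=ranking, qc=qc, adjusted=adjusted,
            chemo=chemo_results, artifacts=artifacts,
        )
        if out is not None:
            manifest = {
                "config": asdict(cfg),
                "n_signatures": len(signatures),
                "datasets": list(registry.ids),
                "candidates": list(ranking.candidates),
                "validated_datasets": list(qc.validated) if qc else [],
                "artifacts": {k: p.name for k, p in artifacts.items()},
            }
            (out / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
            artifacts["manifest"] = out / "run_manifest.yaml"
        return result
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _chemo_stage(
    sig: GeneSignature,
    panel: CellLinePanel,
    cohorts: Sequence[ExpressionDataset],
    cfg: RunConfig,
    out: Path | None,
    artifacts: dict[str, Path],
) -> dict[str, object]:
    lines = chemo_mod.select_sensitive_cell_lines(
        panel, cfg.drugs, cutoff=cfg.ic50_cutoff
    )
    centroid = chemo_mod.build_centroid(panel, lines, sig, drug_tag="+".join(cfg.drugs))
    results: dict[str, object] = {"centroid": centroid, "sensitive_lines": lines}
    metric_rows = []
    for ds in cohorts:
        preds = {
            "centroid": chemo_mod.classify_cohort_by_centroid(
                ds, centroid, threshold=cfg.correlation_threshold
            ),
            "clustering": chemo_mod.classify_by_clustering(ds, sig, label_mode=cfg.label_mode),
        }
        per_cohort: dict[str, object] = {}
        for method, pred in preds.items():
            per_cohort[method] = pred
            for endpoint in ("pCR/RD", "RCB", "DRFS3y"):
                try:
                    m = chemo_mod.response_metrics(
                        pred, ds.clinical, endpoint, horizon=cfg.drfs_horizon
                    )
                except (KeyError, ValueError) as exc:
                    logger.info("%s/%s/%s: metrics unavailable (%s)", ds.id, method, endpoint, exc)
                    continue
                metric_rows.append(
                    {
                        "cohort": ds.id,
                        "signature_id": sig.id,
                        "method": method,
                        "endpoint": endpoint,
                        **{k: getattr(m, k) for k in ("tp", "fp", "tn", "fn", "ppv", "npv",
                                                      "sensitivity", "specificity",
                                                      "n_evaluable", "n_indeterminate")},
                    }
                )
            km = chemo_mod.km_by_prediction(
                pred, ds.clinical["time"].to_numpy(float), ds.clinical["event"].to_numpy(int)
            )
            per_cohort[f"{method}_km"] = km
        results[ds.id] = per_cohort
        if out is not None:
            pred_frame = pd.DataFrame(
                {
                    "patient_id": list(preds["centroid"].labels.index),
                    "centroid_label": preds["centroid"].labels.to_numpy(),
                    "rho": preds["centroid"].rho.to_numpy(),
                    "clustering_label": preds["clustering"].labels.to_numpy(),
                }
            )
            _write_tsv(
                pred_frame, out / f"predictions_{ds.id}.tsv", artifacts, f"predictions_{ds.id}"
            )
    results["metrics"] = pd.DataFrame(metric_rows)
    if out is not None and metric_rows:
        _write_tsv(results["metrics"], out / "response_metrics.tsv", artifacts, "response_metrics")
    return results


def _write_tsv(frame: pd.DataFrame, path: Path, artifacts: dict[str, Path], key: str) -> None:
    frame.to_csv(path, sep="\t", index=False)
    artifacts[key] = path


def run_full_pipeline(
    registry_manifest: str | Path,
    signatures_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig = RunConfig(),
) -> PipelineResult:
    """Path-based pipeline entry point (no chemo stage; see run_pipeline for that)."""
    registry = read_registry(registry_manifest)
    signatures = read_signature_collection(signatures_path)
    return run_pipeline(signatures, registry, cfg=cfg, out_dir=out_dir)


@dataclass(frozen=True)
class DemoScale:
    """Problem sizes of the self-contained demo workspace."""

    n_genes: int = 2000
    n_samples: int = 120
    program_size: int = 40
    n_signal: int = 6
    n_degraded: int = 1
    n_null: int = 2
    n_overlapping: int = 4
    n_random: int = 5
    overlap_fraction: float = 0.8
    n_perm: int = 150
    n_lines: int = 20
    sens_fraction: float = 0.65
    n_patients: int = 120


def make_demo(
    out_dir: str | Path, seed: int = 0, scale: DemoScale = DemoScale()
) -> PipelineResult:
    """Build a synthetic workspace and run the full pipeline on it.

    The miniature mirrors the study layout: a registry of signal datasets
    carrying the planted hazard program plus matched null datasets, a
    signature collection mixing the planted program, planted-overlap
    candidates and random signatures, a drug-sensitivity cell-line panel
    and a neoadjuvant cohort. Inputs are written under ``inputs/`` so the
    same run is reproducible from files alone.
    """
    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimulationConfig(
        n_genes=scale.n_genes,
        n_samples=scale.n_samples,
        program_size=scale.program_size,
        seed=seed,
    )
    registry, truth = simulate_registry(
        sim_cfg, scale.n_signal, scale.n_null, n_degraded=scale.n_degraded, base_seed=seed
    )
    signatures = [truth.planted_signature()] + simulate_signature_collection(
        truth,
        universe=registry.datasets[0].gene_ids,
        n_overlapping=scale.n_overlapping,
        n_random=scale.n_random,
        overlap_fraction=scale.overlap_fraction,
        length=scale.program_size,
        seed=seed + 1000,
    )
    write_registry(registry, inputs)
    write_signature_collection(signatures, inputs / "signatures.gmt")
    panel, _ = simulate_cellline_panel(
        sim_cfg, n_lines=scale.n_lines, sens_fraction=scale.sens_fraction, seed=seed + 2000
    )
    neoadj, _ = simulate_neoadjuvant_cohort(
        sim_cfg, n_patients=scale.n_patients, seed=seed + 3000
    )
    run_cfg = RunConfig(n_perm=scale.n_perm, seed=seed)
    return run_pipeline(
        signatures,
        registry,
        cfg=run_cfg,
        out_dir=out,
        panel=panel,
        neoadjuvant=[neoadj],
        chemo_signature_id="PLANTED_PROGRAM",
    )
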