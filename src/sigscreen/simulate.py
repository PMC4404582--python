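"""Synthetic cohorts with planted prognostic structure.

The generator emulates the statistical skeleton the screening pipeline
assumes: a latent "hazard program" whose summarized expression acts
multiplicatively on the hazard of relapse. Each sample carries a
continuous program activation a_i = mutation_effect * mutant_i +
N(0, activation_sd^2), where mutant_i is a binary TP53-like mutation;
each program gene responds to the activation with a signed unit loading
(a fraction of the program up, the rest down, mirroring the mixed up/down
composition of published prognostic signatures) plus independent
measurement noise; all remaining genes are pure noise. The signed
loadings give sample profiles over the program the bipolar correlation
structure real signature data shows (program-high and program-low samples
anti-correlate), which is what the Spearman-distance clustering bifurcates
on. Survival is exponential (proportional hazards exactly true in the
realized program score) with uniform administrative censoring.

On top of the survival cohorts the module generates cell-line panels whose
log(IC50) tracks program expression (drug-sensitive lines look
mutant-like), neoadjuvant cohorts in which the probability of pathologic
complete response and distant relapse-free survival both depend on the
program score, and signature collections with controlled overlap with the
planted program.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chemo import CellLinePanel
from .io import DatasetRegistry, ExpressionDataset, GeneSignature


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    beta is the log-hazard increment per unit program score; with the
    default up_fraction the mutant-vs-wild-type score gap is
    mutation_effect * (2 * up_fraction - 1), so beta=1, mutation_effect=2
    gives mutants roughly a 3-fold hazard. mutation_rate defaults to the
    ~30% TP53-mutation prevalence seen in breast tumor cohorts;
    up_fraction defaults to 0.78 (39 of 50 genes up-shifted).
    """

    n_genes: int = 10_000
    n_samples: int = 200
    program_size: int = 50
    beta: float = 1.0
    mutation_rate: float = 0.3
    mutation_effect: float = 2.0
    up_fraction: float = 0.78
    activation_sd: float = 1.0
    baseline_hazard: float = 0.1
    censor_horizon: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.program_size > self.n_genes:
            raise ValueError("program_size exceeds n_genes")
        if self.program_size < 1 or self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must lie in [0, 1]")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0 or self.censor_horizon <= 0:
            raise ValueError("noise_sd, baseline_hazard and censor_horizon must be positive")
        if self.activation_sd < 0:
            raise ValueError("activation_sd must be non-negative")

    def null(self) -> "SimulationConfig":
        """The matched no-signal configuration (no hazard effect, no expression shift)."""
        return replace(self, beta=0.0, mutation_effect=0.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside a simulated cohort."""

    program_genes: tuple[str, ...]
    directions: dict[str, str]
    program_score: np.ndarray
    mutant: np.ndarray
    beta: float

    def planted_signature(self, sig_id: str = "PLANTED_PROGRAM") -> GeneSignature:
        """The planted program as a directed GeneSignature."""
        return GeneSignature(
            id=sig_id,
            genes=self.program_genes,
            description="planted hazard program",
            directions=dict(self.directions),
            phenotype_tag="TP53-like status",
        )


def _gene_ids(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def _program_layout(cfg: SimulationConfig) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Program gene ids, signed unit loadings, and up/down directions.

    The program occupies the first ``program_size`` gene ids: datasets
    generated under dimension-compatible configs share the planted program,
    which multi-dataset screens require.
    """
    genes = _gene_ids(cfg.n_genes)
    program = genes[: cfg.program_size]
    n_up = round(cfg.up_fraction * cfg.program_size)
    loading = np.full(cfg.program_size, -1.0)
    loading[:n_up] = 1.0
    directions = {g: ("up" if i < n_up else "down") for i, g in enumerate(program)}
    return genes, loading, directions


def _expression(
    cfg: SimulationConfig, rng: np.random.Generator, mutant: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray, SyntheticTruth]:
    genes, loading, directions = _program_layout(cfg)
    n = len(mutant)
    activation = cfg.mutation_effect * mutant + rng.normal(0.0, cfg.activation_sd, size=n)
    X = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    X[: cfg.program_size] += np.outer(loading, activation)
    score = X[: cfg.program_size].mean(axis=0)
    truth = SyntheticTruth(
        program_genes=tuple(genes[: cfg.program_size]),
        directions=directions,
        program_score=score,
        mutant=mutant.astype(int),
        beta=cfg.beta,
    )
    return pd.DataFrame(X, index=genes), score, truth


def _survival(
    cfg: SimulationConfig, rng: np.random.Generator, log_hazard: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    rate = cfg.baseline_hazard * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(1e-6, cfg.censor_horizon, size=len(log_hazard))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event


def simulate_survival_dataset(
    cfg: SimulationConfig,
    dataset_id: str = "SYNTH",
    seed: int | None = None,
    endpoint: str = "RFS",
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """One expression + survival cohort with the planted hazard program.

    Mutation status is Bernoulli(mutation_rate); program-gene expression is
    noise plus the signed mutation shift; survival is exponential with rate
    baseline_hazard * exp(beta * program_score), censored uniformly on
    (0, censor_horizon).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mutant = (rng.random(cfg.n_samples) < cfg.mutation_rate).astype(int)
    matrix, score, truth = _expression(cfg, rng, mutant)
    time, event = _survival(cfg, rng, cfg.beta * score)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    matrix.columns = samples
    clinical = pd.DataFrame(
        {"time": time, "event": event, "tp53_mutant": mutant}, index=pd.Index(samples, name="sample")
    )
    ds = ExpressionDataset(id=dataset_id, matrix=matrix, clinical=clinical, endpoint=endpoint)
    return ds, truth


def simulate_confounded_dataset(
    cfg: SimulationConfig,
    loading_sd: float = 0.7,
    gamma: float = 1.0,
    dataset_id: str = "CONFOUNDED",
    seed: int | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """A dataset whose survival is driven by a global expression factor.

    A per-sample latent factor q (think array quality or a dominant
    proliferation axis) loads with gene-specific weights on *every* gene
    and multiplies the hazard by exp(gamma * q); the planted program
    carries no signal. Any gene subset then clusters samples by q and
    "predicts" survival, so random signatures succeed at a high rate —
    the poorly-performing-dataset phenotype the differential-index filter
    is designed to reject (candidate and random rates are both high and
    nearly equal, leaving DI near zero).
    """
    null_cfg = cfg.null()
    used_seed = null_cfg.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    mutant = (rng.random(null_cfg.n_samples) < null_cfg.mutation_rate).astype(int)
    matrix, _, truth = _expression(null_cfg, rng, mutant)
    q = rng.normal(0.0, 1.0, size=null_cfg.n_samples)
    loadings = rng.normal(0.0, loading_sd, size=null_cfg.n_genes)
    matrix.iloc[:, :] = matrix.to_numpy() + np.outer(loadings, q)
    time, event = _survival(null_cfg, rng, gamma * q)
    samples = [f"S{i:04d}" for i in range(null_cfg.n_samples)]
    matrix.columns = samples
    clinical = pd.DataFrame(
        {"time": time, "event": event, "tp53_mutant": mutant},
        index=pd.Index(samples, name="sample"),
    )
    ds = ExpressionDataset(id=dataset_id, matrix=matrix, clinical=clinical, endpoint="RFS")
    return ds, truth


def simulate_degraded_dataset(
    cfg: SimulationConfig,
    n_dead: int = 10,
    dataset_id: str = "DEGRADED",
    seed: int | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """A no-signal dataset contaminated with flat "dead-array" samples.

    ``n_dead`` randomly chosen samples get an exactly constant expression
    profile, the stylized signature of a failed hybridization. Rank
    correlation is undefined against a flat profile, so every signature's
    stratification on such a dataset records N/A (constant_expression) —
    the dataset-level failure mode the N/A-rate QC filter exists to catch.
    """
    null_cfg = cfg.null()
    if n_dead < 1 or n_dead >= null_cfg.n_samples:
        raise ValueError("n_dead must be in [1, n_samples)")
    used_seed = null_cfg.seed if seed is None else seed
    ds, truth = simulate_survival_dataset(null_cfg, dataset_id=dataset_id, seed=used_seed)
    rng = np.random.default_rng(used_seed + 7)
    dead = rng.choice(ds.n_samples, size=n_dead, replace=False)
    X = ds.matrix.to_numpy()
    X[:, dead] = 0.0
    ds.matrix.iloc[:, :] = X
    return ds, truth


def simulate_registry(
    cfg: SimulationConfig,
    n_signal: int,
    n_null: int,
    n_degraded: int = 0,
    n_confounded: int = 0,
    base_seed: int | None = None,
    id_prefix: str = "DS",
    n_dead: int = 10,
) -> tuple[DatasetRegistry, SyntheticTruth]:
    """A registry of signal datasets plus matched bad datasets.

    Layout mirrors the screening study: datasets that carry the planted
    hazard program ("SIG"), dead-array-contaminated datasets that should
    fail the N/A filter ("DEG"), survival-confounded datasets on which
    random signatures succeed and which the differential-index filter
    should reject ("CONF"), and plain no-signal datasets ("NULL").
    Per-dataset seeds stream from ``base_seed + index`` (default:
    ``cfg.seed``), so removing one entry never perturbs the others. The
    returned truth is the shared program layout.
    """
    base = cfg.seed if base_seed is None else base_seed
    datasets: list[ExpressionDataset] = []
    truth: SyntheticTruth | None = None
    kinds = (
        ["SIG"] * n_signal + ["DEG"] * n_degraded + ["CONF"] * n_confounded + ["NULL"] * n_null
    )
    for k, kind in enumerate(kinds):
        ds_seed = base + k
        ds_id = f"{id_prefix}{k:02d}_{kind}"
        if kind == "SIG":
            ds, t = simulate_survival_dataset(cfg, dataset_id=ds_id, seed=ds_seed)
        elif kind == "DEG":
            ds, t = simulate_degraded_dataset(cfg, n_dead=n_dead, dataset_id=ds_id, seed=ds_seed)
        elif kind == "CONF":
            ds, t = simulate_confounded_dataset(cfg, dataset_id=ds_id, seed=ds_seed)
        else:
            ds, t = simulate_survival_dataset(cfg.null(), dataset_id=ds_id, seed=ds_seed)
        datasets.append(ds)
        if truth is None:
            truth = t
    assert truth is not None
    return DatasetRegistry(datasets=datasets), truth


def simulate_cellline_panel(
    cfg: SimulationConfig,
    n_lines: int = 20,
    sens_fraction: float = 0.65,
    drugs: Sequence[str] = ("taxane", "anthracycline"),
    seed: int | None = None,
) -> tuple[CellLinePanel, SyntheticTruth]:
    """A cell-line panel whose drug-sensitive lines look program-activated.

    ``round(sens_fraction * n_lines)`` lines are sensitive: log(IC50) drawn
    from Uniform(-3, -1.01) for one randomly chosen drug (the remaining
    drugs resistant-range), and program-gene expression shifted as in
    mutant tumors. Resistant lines draw log(IC50) from Uniform(-0.99, 2)
    for every drug. The defaults yield the 13-of-20 sensitive layout.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 cell lines")
    if not 0.0 < sens_fraction < 1.0:
        raise ValueError("sens_fraction must lie strictly between 0 and 1")
    if not drugs:
        raise ValueError("need at least one drug")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_sens = round(sens_fraction * n_lines)
    sensitive = np.zeros(n_lines, dtype=int)
    sensitive[:n_sens] = 1
    matrix, score, truth = _expression(cfg, rng, sensitive)
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    matrix.columns = lines
    ic50 = rng.uniform(-0.99, 2.0, size=(n_lines, len(drugs)))
    for i in range(n_sens):
        drug_idx = rng.integers(len(drugs))
        ic50[i, drug_idx] = rng.uniform(-3.0, -1.01)
    log_ic50 = pd.DataFrame(ic50, index=lines, columns=list(drugs))
    her2 = pd.Series("neg", index=lines, name="her2_status")
    panel = CellLinePanel(expression=matrix, log_ic50=log_ic50, her2_status=her2)
    return panel, truth


def simulate_neoadjuvant_cohort(
    cfg: SimulationConfig,
    n_patients: int = 150,
    pcr_intercept: float = -1.8,
    pcr_slope: float = 1.5,
    pcr_hazard_ratio: float = 0.3,
    dataset_id: str = "NEOADJ",
    seed: int | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """A neoadjuvant cohort: pCR probability and DRFS both driven by the program.

    P(pCR) = logistic(pcr_intercept + pcr_slope * program_score); the DRFS
    hazard is baseline_hazard * exp(beta * score), multiplied by
    ``pcr_hazard_ratio`` for responders (pCR is protective). RCB class is 0
    or I for pCR patients and II or III otherwise. The default intercept is
    calibrated so the cohort pCR rate sits near the 25-30% seen in
    taxane/anthracycline neoadjuvant trials at the default slope.
    """
    if n_patients < 20:
        raise ValueError("neoadjuvant cohort needs at least 20 patients")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mutant = (rng.random(n_patients) < cfg.mutation_rate).astype(int)
    cohort_cfg = replace(cfg, n_samples=n_patients)
    matrix, score, truth = _expression(cohort_cfg, rng, mutant)
    p_pcr = 1.0 / (1.0 + np.exp(-(pcr_intercept + pcr_slope * score)))
    pcr = (rng.random(n_patients) < p_pcr).astype(int)
    rcb = np.where(
        pcr == 1,
        rng.choice(["0", "I"], size=n_patients),
        rng.choice(["II", "III"], size=n_patients),
    )
    log_hazard = cfg.beta * score + np.log(pcr_hazard_ratio) * pcr
    time, event = _survival(cfg, rng, log_hazard)
    samples = [f"P{i:04d}" for i in range(n_patients)]
    matrix.columns = samples
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "pcr": np.where(pcr == 1, "pCR", "RD"),
            "rcb": rcb,
            "tp53_mutant": mutant,
        },
        index=pd.Index(samples, name="sample"),
    )
    ds = ExpressionDataset(id=dataset_id, matrix=matrix, clinical=clinical, endpoint="DRFS")
    return ds, truth


def simulate_signature_collection(
    truth: SyntheticTruth,
    universe: Sequence[str],
    n_overlapping: int,
    n_random: int,
    overlap_fraction: float,
    length: int,
    seed: int = 0,
    overlap_prefix: str = "PLANTED",
    random_prefix: str = "RANDOM",
) -> list[GeneSignature]:
    """Planted-overlap candidate signatures plus uniform random signatures.

    Each overlapping signature draws ``round(overlap_fraction * length)``
    genes from the planted program (carrying their true directions) and the
    rest from the non-program pool; random signatures are uniform draws
    from the whole universe.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    universe = list(universe)
    if length > len(universe):
        raise ValueError("signature length exceeds gene universe")
    program = [g for g in truth.program_genes if g in set(universe)]
    pool = [g for g in universe if g not in set(truth.program_genes)]
    k = round(overlap_fraction * length)
    if k > len(program):
        raise ValueError("requested program overlap exceeds planted program size")
    if length - k > len(pool):
        raise ValueError("noise pool too small for requested signature length")
    rng = np.random.default_rng(seed)
    signatures: list[GeneSignature] = []
    for i in range(n_overlapping):
        from_program = list(rng.choice(program, size=k, replace=False)) if k else []
        from_pool = list(rng.choice(pool, size=length - k, replace=False))
        genes = tuple(from_program + from_pool)
        directions = {g: truth.directions[g] for g in from_program}
        signatures.append(
            GeneSignature(
                id=f"{overlap_prefix}{i:02d}",
                genes=genes,
                description=f"planted-overlap signature (overlap={overlap_fraction:g})",
                directions=directions or None,
            )
        )
    for i in range(n_random):
        genes = tuple(rng.choice(universe, size=length, replace=False))
        signatures.append(
            GeneSignature(id=f"{random_prefix}{i:02d}", genes=genes, description="random signature")
        )
    return signatures


def logistic(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def expected_pcr_rate(
    cfg: SimulationConfig, pcr_intercept: float, pcr_slope: float
) -> float:
    """Population pCR rate implied by the generator, by Gauss-Hermite quadrature.

    The program score is Gaussian within each mutation stratum with mean
    mean_loading * mutation_effect * mutant and variance
    mean_loading^2 * activation_sd^2 + noise_sd^2 / program_size, where
    mean_loading = 2 * up_fraction - 1; the rate is the mutation-rate
    mixture of the two strata's expected logistic values.
    """
    mean_loading = 2.0 * cfg.up_fraction - 1.0
    sd = math.sqrt(
        mean_loading**2 * cfg.activation_sd**2 + cfg.noise_sd**2 / cfg.program_size
    )
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def stratum(mu: float) -> float:
        return float(weights @ logistic(pcr_intercept + pcr_slope * (mu + sd * nodes)))

    mu_mut = mean_loading * cfg.mutation_effect
    return float(
        (1 - cfg.mutation_rate) * stratum(0.0) + cfg.mutation_rate * stratum(mu_mut)
    )
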