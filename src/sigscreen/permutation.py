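"""Random-signature permutation nulls, adjusted P values, and dataset QC.

For each (dataset, signature length) the null is the log-rank P
distribution of length-matched random gene sets drawn from that dataset's
own gene universe (1,000 per signature by default), run through the same
stratify -> log-rank machinery as real signatures. Null stratification
failures are recorded and count as non-significant and non-smaller.

Three quantities build on the null:

* the permutation-adjusted P of a candidate: the fraction of its
  length-matched random signatures achieving a strictly smaller log-rank P
  (raw count divided by the full null size, no smoothing);
* the differential index (DI) of a dataset: mean percent-significant of
  the candidate signatures minus mean percent-significant of the random
  signatures, in percentage points — a dataset-level QC statistic;
* dataset validation: reject datasets whose N/A rate over all tested
  signatures exceeds 5%, then those with DI below 9 points; the remainder
  are the validated test datasets over which candidates are re-ranked by
  their median adjusted P.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DatasetRegistry, ExpressionDataset, GeneSignature, map_signature_to_dataset
from .screen import ScreenMatrix
from .stratify import stratify_two_groups
from .survival import logrank_two_groups

#: Default thresholds from the screening protocol.
DEFAULT_N_PERM = 1000
NA_CUT = 0.05
DI_CUT = 9.0


def generate_random_signature(
    universe: Sequence[str], length: int, seed: int | np.random.Generator, sig_id: str | None = None
) -> GeneSignature:
    """A uniform without-replacement gene sample from a dataset's universe."""
    universe = list(universe)
    if length > len(universe):
        raise ValueError("random signature length exceeds gene universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = tuple(rng.choice(universe, size=length, replace=False))
    return GeneSignature(
        id=sig_id or f"RAND_L{length}", genes=genes, description="length-matched random signature"
    )


@dataclass(frozen=True)
class RandomSignatureNull:
    """Null log-rank P distribution for one (dataset, length); NaN marks failures."""

    dataset_id: str
    length: int
    p_values: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.p_values) != self.n_perm:
            raise ValueError("null must record one entry (P or failure) per permutation")

    @property
    def successes(self) -> np.ndarray:
        return self.p_values[~np.isnan(self.p_values)]

    @property
    def n_failures(self) -> int:
        return int(np.isnan(self.p_values).sum())

    def significant_fraction(self, alpha: float = 0.05) -> float:
        """Fraction of the full null (failures included) with P < alpha."""
        return float((self.successes < alpha).sum() / self.n_perm)


def _null_seed(master_seed: int, dataset_id: str, length: int) -> int:
    """Stable per-(dataset, length) sub-seed below 2**31."""
    h = zlib.crc32(f"{dataset_id}:{length}".encode())
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


def build_null(
    ds: ExpressionDataset,
    length: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> RandomSignatureNull:
    """Run n_perm length-matched random signatures through stratify + log-rank."""
    rng = np.random.default_rng(seed)
    times = ds.clinical["time"].to_numpy(float)
    events = ds.clinical["event"].to_numpy(int)
    ps = np.full(n_perm, np.nan)
    for i in range(n_perm):
        sig = generate_random_signature(ds.gene_ids, length, rng, sig_id=f"RAND{i:05d}")
        mapped = map_signature_to_dataset(sig, ds)
        ga = stratify_two_groups(ds, mapped)
        if ga.status != "ok" or events.sum() == 0:
            continue
        _, p = logrank_two_groups(times, events, (ga.labels == "group1").to_numpy())
        ps[i] = p
    return RandomSignatureNull(
        dataset_id=ds.id, length=length, p_values=ps, n_perm=n_perm, seed=seed
    )


class NullCache:
    """Cache of nulls keyed by (dataset_id, length, n_perm); one build per key.

    Sub-seeds derive deterministically from the master seed and the key, so
    equal-length candidates on the same dataset share a bitwise-identical
    null vector.
    """

    def __init__(self, master_seed: int = 0, n_perm: int = DEFAULT_N_PERM):
        self.master_seed = master_seed
        self.n_perm = n_perm
        self._store: dict[tuple[str, int, int], RandomSignatureNull] = {}

    def get(self, ds: ExpressionDataset, length: int) -> RandomSignatureNull:
        key = (ds.id, length, self.n_perm)
        if key not in self._store:
            self._store[key] = build_null(
                ds, length, n_perm=self.n_perm, seed=_null_seed(self.master_seed, ds.id, length)
            )
        return self._store[key]

    def nulls_for_dataset(self, dataset_id: str) -> list[RandomSignatureNull]:
        return [null for (d, _, _), null in sorted(self._store.items()) if d == dataset_id]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (d, length, n_perm), null in sorted(self._store.items()):
            path = directory / f"null_{d}_L{length}_n{n_perm}_s{null.seed}.tsv"
            pd.DataFrame({"p": null.p_values}).to_csv(
                path, sep="\t", index=False, float_format="%.17g"
            )

    def load(self, path: str | Path, dataset_id: str, length: int) -> RandomSignatureNull:
        ps = pd.read_csv(path, sep="\t", float_precision="round_trip")["p"].to_numpy(float)
        null = RandomSignatureNull(
            dataset_id=dataset_id, length=length, p_values=ps, n_perm=len(ps), seed=-1
        )
        self._store[(dataset_id, length, len(ps))] = null
        return null


def adjusted_p(observed_p: float, null: RandomSignatureNull, smooth: bool = False) -> float:
    """Fraction of the null with a strictly smaller P (failures never smaller).

    ``smooth=True`` applies the usual (count+1)/(n_perm+1) permutation
    correction; the default divides the raw count by the full null size.
    """
    if not 0.0 <= observed_p <= 1.0:
        raise ValueError("observed P outside [0, 1]")
    if null.n_perm == 0:
        raise ValueError("empty null")
    count = int((null.successes < observed_p).sum())
    if smooth:
        return (count + 1) / (null.n_perm + 1)
    return count / null.n_perm


def na_rate(matrix: ScreenMatrix, dataset_id: str) -> float:
    """Fraction of tested signatures that failed (N/A) on the dataset."""
    if dataset_id not in matrix.dataset_ids:
        raise KeyError(dataset_id)
    n_na = sum(1 for s in matrix.signature_ids if matrix.cells[(s, dataset_id)].status == "NA")
    return n_na / len(matrix.signature_ids)


def differential_index(candidate_rates: Sequence[float], random_rates: Sequence[float]) -> float:
    """mean(candidate) - mean(random), in percentage points."""
    if len(candidate_rates) == 0 or len(random_rates) == 0:
        raise ValueError("differential index needs non-empty rate lists")
    return float(np.mean(candidate_rates) - np.mean(random_rates))


@dataclass(frozen=True)
class DatasetQC:
    """Per-dataset QC summary feeding the validation verdict."""

    dataset_id: str
    na_rate: float
    mean_rate_top: float
    mean_rate_random: float
    differential_index: float
    verdict: str  # pass | fail_na | fail_di

    def __post_init__(self) -> None:
        if not -100.0 <= self.differential_index <= 100.0:
            raise ValueError("differential index outside [-100, 100]")


@dataclass(frozen=True)
class QCReport:
    per_dataset: tuple[DatasetQC, ...]
    validated: tuple[str, ...]
    rejected: Mapping[str, str]  # dataset -> reason

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([qc.__dict__ for qc in self.per_dataset])


def dataset_qc(
    matrix: ScreenMatrix,
    dataset_id: str,
    nulls: Sequence[RandomSignatureNull],
    candidates: Sequence[str],
    alpha: float = 0.05,
    na_cut: float = NA_CUT,
    di_cut: float = DI_CUT,
) -> DatasetQC:
    """QC one dataset: N/A rate over all signatures, DI from candidates vs nulls."""
    if not nulls:
        raise ValueError(f"no null available for dataset {dataset_id!r}")
    if not candidates:
        raise ValueError("dataset QC needs a non-empty candidate set")
    na = na_rate(matrix, dataset_id)
    cand_rates = [
        100.0 if (c := matrix.cells[(s, dataset_id)]).status == "ok" and c.logrank_p < alpha else 0.0
        for s in candidates
    ]
    pooled = np.concatenate([null.p_values for null in nulls])
    n_total = len(pooled)
    rand_rate = 100.0 * float((pooled[~np.isnan(pooled)] < alpha).sum()) / n_total
    di = differential_index(cand_rates, [rand_rate])
    if na > na_cut:
        verdict = "fail_na"
    elif di < di_cut:
        verdict = "fail_di"
    else:
        verdict = "pass"
    return DatasetQC(
        dataset_id=dataset_id,
        na_rate=na,
        mean_rate_top=float(np.mean(cand_rates)),
        mean_rate_random=rand_rate,
        differential_index=di,
        verdict=verdict,
    )


def validate_datasets(
    matrix: ScreenMatrix,
    nulls_by_dataset: Mapping[str, Sequence[RandomSignatureNull]],
    candidates: Sequence[str],
    alpha: float = 0.05,
    na_cut: float = NA_CUT,
    di_cut: float = DI_CUT,
) -> QCReport:
    """Partition datasets into validated and rejected (fail_na before fail_di).

    A dataset is rejected when its N/A rate strictly exceeds ``na_cut``,
    otherwise when its differential index falls below ``di_cut`` (DI equal
    to the cut passes).
    """
    per_dataset = []
    validated, rejected = [], {}
    for d in matrix.dataset_ids:
        if d not in nulls_by_dataset or not nulls_by_dataset[d]:
            raise ValueError(f"missing null for dataset {d!r}")
        qc = dataset_qc(
            matrix, d, nulls_by_dataset[d], candidates, alpha=alpha, na_cut=na_cut, di_cut=di_cut
        )
        per_dataset.append(qc)
        if qc.verdict == "pass":
            validated.append(d)
        else:
            rejected[d] = qc.verdict
    return QCReport(
        per_dataset=tuple(per_dataset), validated=tuple(validated), rejected=rejected
    )


@dataclass(frozen=True)
class AdjustedCell:
    signature_id: str
    dataset_id: str
    observed_p: float | None
    adjusted_p: float


@dataclass(frozen=True)
class AdjustedRanking:
    """Candidates ordered by median permutation-adjusted P over validated datasets."""

    cells: tuple[AdjustedCell, ...]
    median_adjusted_p: Mapping[str, float]
    adjusted_significant_rate: Mapping[str, float]  # % of validated datasets with adj P < alpha
    order: tuple[str, ...]
    top: tuple[str, ...]  # median adjusted P < alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signature_id": list(self.order),
                "median_adjusted_p": [self.median_adjusted_p[s] for s in self.order],
                "adjusted_significant_rate_pct": [
                    self.adjusted_significant_rate[s] for s in self.order
                ],
            }
        )


def rank_by_adjusted_median_p(
    matrix: ScreenMatrix,
    signatures: Mapping[str, GeneSignature],
    candidates: Sequence[str],
    validated: Sequence[str],
    cache: NullCache,
    registry: DatasetRegistry,
    alpha: float = 0.05,
) -> AdjustedRanking:
    """Adjusted-P ranking of candidate signatures over the validated datasets.

    Each candidate's observed log-rank P on each validated dataset is
    adjusted against the length-matched null of that dataset; an N/A
    observation is the worst case (adjusted P 1). Candidates are sorted by
    ascending median adjusted P; the top set has median below alpha.
    """
    if not validated:
        raise ValueError("no validated datasets")
    cells: list[AdjustedCell] = []
    medians: dict[str, float] = {}
    rates: dict[str, float] = {}
    for s in candidates:
        sig = signatures[s]
        adj: list[float] = []
        for d in validated:
            cell = matrix.cells[(s, d)]
            if cell.status != "ok":
                a, obs = 1.0, None
            else:
                null = cache.get(registry.get(d), len(sig))
                obs = cell.logrank_p
                a = adjusted_p(obs, null)
            adj.append(a)
            cells.append(AdjustedCell(signature_id=s, dataset_id=d, observed_p=obs, adjusted_p=a))
        medians[s] = float(np.median(adj))
        rates[s] = 100.0 * sum(1 for a in adj if a < alpha) / len(adj)
    order = tuple(sorted(candidates, key=lambda s: (medians[s], -rates[s], s)))
    top = tuple(s for s in order if medians[s] < alpha)
    return AdjustedRanking(
        cells=tuple(cells),
        median_adjusted_p=medians,
        adjusted_significant_rate=rates,
        order=order,
        top=top,
    )
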