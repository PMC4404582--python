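"""Two-group sample stratification by unsupervised hierarchical clustering.

Samples are clustered on the signature's mapped genes with average linkage
on a Spearman-correlation distance (1 - rho between sample profiles) and
split at the dendrogram's first bifurcation, i.e. cut into exactly two
clusters. A stratification can fail (N/A) for three reasons: the signature
maps to fewer than half its genes (``low_coverage``), the split leaves one
group too small to test (``degenerate_group``), or a sample profile is
constant over the mapped genes so rank correlation is undefined
(``constant_expression``). N/A is a per-signature outcome; a dataset with
fewer than 10 samples is unusable outright and raises.

The module also hosts the mutation-enrichment clustering used on tumor
panels: Euclidean/complete two-cluster cut followed by a Fisher exact test
of cluster membership against mutation status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import ExpressionDataset, GeneSignature, MappedSignature

logger = logging.getLogger(__name__)

NAReason = Literal["low_coverage", "degenerate_group", "constant_expression"]

#: Default N/A thresholds (config-exposed through the stratify call).
MIN_COVERAGE = 0.5
MIN_GROUP_ABS = 5
MIN_GROUP_FRAC = 0.05
MIN_DATASET_SAMPLES = 10


@dataclass
class GroupAssignment:
    """Result of a two-group stratification attempt."""

    dataset_id: str
    signature_id: str
    status: Literal["ok", "NA"]
    labels: pd.Series | None = None  # sample -> {"group1", "group2"}
    na_reason: NAReason | None = None
    risk_labels: dict[str, str] | None = None  # group -> {"high_risk", "low_risk"}
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.labels is None:
                raise ValueError("ok assignment must label every sample")
            arr = self.labels.to_numpy()
            n1 = int((arr == "group1").sum())
            if n1 == 0 or n1 == len(arr):
                raise ValueError("ok assignment needs two non-empty groups")
            if n1 + int((arr == "group2").sum()) != len(arr):
                raise ValueError("ok assignment must label every sample")
        elif self.na_reason is None:
            raise ValueError("NA assignment must carry a reason")

    def group_samples(self, group: str) -> list[str]:
        assert self.labels is not None
        return list(self.labels.index[self.labels == group])

    def high_risk_mask(self) -> np.ndarray:
        """Boolean per-sample mask of the high-risk group (risk labels required)."""
        if self.risk_labels is None or self.labels is None:
            raise ValueError("risk labels not assigned")
        high = [g for g, r in self.risk_labels.items() if r == "high_risk"]
        return self.labels.isin(high).to_numpy()


def _spearman_distance(X: np.ndarray) -> np.ndarray:
    """1 - Spearman rho between sample columns, average-rank ties."""
    ranks = rankdata(X, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks.T)
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _cut_two(Z: np.ndarray) -> np.ndarray:
    """First bifurcation of an agglomerative tree == maxclust-2 cut."""
    return fcluster(Z, 2, criterion="maxclust")


def stratify_two_groups(
    ds: ExpressionDataset,
    mapped: MappedSignature,
    min_coverage: float = MIN_COVERAGE,
    min_group_abs: int = MIN_GROUP_ABS,
    min_group_frac: float = MIN_GROUP_FRAC,
) -> GroupAssignment:
    """Split samples at the first bifurcation of Spearman/average-linkage clustering."""
    n = ds.n_samples
    if n < MIN_DATASET_SAMPLES:
        raise ValueError(f"dataset {ds.id!r} has {n} samples; need >= {MIN_DATASET_SAMPLES}")
    na = lambda reason: GroupAssignment(  # noqa: E731
        dataset_id=ds.id, signature_id=mapped.signature_id, status="NA", na_reason=reason
    )
    if mapped.coverage < min_coverage:
        return na("low_coverage")
    index = ds._upper_index()
    rows = [index[g.upper()] for g in mapped.mapped_genes]
    X = ds._values()[rows]
    if X.shape[0] < 2 or np.any(np.ptp(X, axis=0) == 0):
        return na("constant_expression")
    D = _spearman_distance(X)
    Z = linkage(squareform(D, checks=False), method="average")
    cluster = _cut_two(Z)
    sizes = np.bincount(cluster)[1:]
    floor = max(min_group_abs, min_group_frac * n)
    if len(sizes) < 2 or sizes.min() < floor:
        return na("degenerate_group")
    labels = pd.Series(
        np.where(cluster == 1, "group1", "group2"), index=list(ds.sample_ids), name="group"
    )
    return GroupAssignment(
        dataset_id=ds.id, signature_id=mapped.signature_id, status="ok", labels=labels
    )


def assign_risk_labels(
    ga: GroupAssignment,
    ds: ExpressionDataset,
    mapped: MappedSignature,
    mode: Literal["by_direction", "by_outcome"] = "by_direction",
    signature: GeneSignature | None = None,
) -> GroupAssignment:
    """Attach high/low-risk labels to an ok stratification.

    ``by_direction``: high risk is the group with the higher mean
    expression over the signature's up-direction genes (all mapped genes
    when no directions are available) — usable prospectively.
    ``by_outcome``: high risk is the group with the higher Nelson-Aalen
    cumulative hazard at the median follow-up time — retrospective, for
    evaluation only. Ties under by_outcome (or by_direction with explicit
    up genes) break toward group1 with a logged flag; a tie on the
    undirected fallback is unresolvable and flips the assignment to N/A.
    """
    if ga.status != "ok":
        raise ValueError("risk labels require an ok stratification")
    assert ga.labels is not None
    if mode == "by_direction":
        up = [g for g in mapped.mapped_genes if signature and (signature.directions or {}).get(g) == "up"]
        used_fallback = not up
        genes = up or list(mapped.mapped_genes)
        sub = ds.matrix.loc[genes]
        means = {
            g: float(sub.loc[:, ga.group_samples(g)].to_numpy().mean()) for g in ("group1", "group2")
        }
        if means["group1"] == means["group2"]:
            if used_fallback:
                return replace(ga, status="NA", na_reason="degenerate_group", labels=None)
            logger.warning("risk-label tie on up-gene means; breaking toward group1")
            return replace(
                ga, risk_labels={"group1": "high_risk", "group2": "low_risk"}, tie_flag=True
            )
        high = max(means, key=means.get)  # type: ignore[arg-type]
    elif mode == "by_outcome":
        times = ds.clinical["time"].to_numpy(float)
        median_follow = float(np.median(times))
        hazards = {}
        for g in ("group1", "group2"):
            samples = ga.group_samples(g)
            sub = ds.clinical.loc[samples]
            naf = NelsonAalenFitter()
            naf.fit(sub["time"].to_numpy(float), sub["event"].to_numpy(int))
            hazards[g] = float(naf.cumulative_hazard_at_times([median_follow]).iloc[0])
        if hazards["group1"] == hazards["group2"]:
            logger.warning("risk-label tie on cumulative hazard; breaking toward group1")
            return replace(
                ga, risk_labels={"group1": "high_risk", "group2": "low_risk"}, tie_flag=True
            )
        high = max(hazards, key=hazards.get)  # type: ignore[arg-type]
    else:
        raise ValueError(f"unknown risk-label mode {mode!r}")
    low = "group2" if high == "group1" else "group1"
    return replace(ga, risk_labels={high: "high_risk", low: "low_risk"})


@dataclass(frozen=True)
class MutationEnrichment:
    """Two-cluster mutation enrichment on an expression block."""

    cluster_labels: np.ndarray
    mutant_fraction: tuple[float, float]  # (cluster 1, cluster 2)
    table: np.ndarray  # 2x2 cluster x mutation counts
    p: float


def mutation_cluster_enrichment(expr: pd.DataFrame, mutation) -> MutationEnrichment:
    """Euclidean/complete two-cluster cut, Fisher-tested against mutation status.

    ``expr`` is a genes x samples block (typically restricted to a
    signature); ``mutation`` is a per-sample 0/1 vector. Requires at least
    two mutant and two wild-type samples.
    """
    mutation = np.asarray(mutation, dtype=int)
    if expr.shape[1] != len(mutation):
        raise ValueError("mutation vector length must match sample count")
    if mutation.sum() < 2 or (1 - mutation).sum() < 2:
        raise ValueError("need >= 2 mutant and >= 2 wild-type samples")
    D = pdist(expr.to_numpy(float).T, metric="euclidean")
    Z = linkage(D, method="complete")
    cluster = _cut_two(Z)
    table = np.array(
        [
            [(mutation[cluster == c] == 1).sum(), (mutation[cluster == c] == 0).sum()]
            for c in (1, 2)
        ]
    )
    fractions = tuple(row[0] / row.sum() if row.sum() else np.nan for row in table)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return MutationEnrichment(
        cluster_labels=cluster, mutant_fraction=fractions, table=table, p=float(p)
    )
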