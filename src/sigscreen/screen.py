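"""The signature x dataset survival screen and significant-rate ranking.

Every (signature, dataset) pair is mapped, stratified, and — when the
stratification succeeds — tested: two-group log-rank, univariate Cox
hazard ratio for the high-risk group, and Harrell's c-index. Failed
stratifications propagate as N/A cells; in the significant-rate a failed
stratification counts as a failed prediction (the cell stays in the
denominator). Signatures are ranked by their percentage of datasets with
log-rank P below alpha, and candidates are those strictly above the rate
cutoff (default: significant in more than half the datasets).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DatasetRegistry, ExpressionDataset, GeneSignature, map_signature_to_dataset
from .stratify import assign_risk_labels, stratify_two_groups
from .survival import concordance_index, cox_univariate, logrank_two_groups

logger = logging.getLogger(__name__)

SubsetFilter = Callable[[pd.DataFrame], "pd.Series[bool]"]


@dataclass(frozen=True)
class ScreenCell:
    """One signature x dataset result."""

    signature_id: str
    dataset_id: str
    status: Literal["ok", "NA"]
    na_reason: str | None = None
    logrank_p: float | None = None
    chi2: float | None = None
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None
    hr_p: float | None = None
    c_index: float | None = None

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.logrank_p is not None):
            raise ValueError("status=ok iff a log-rank P is present")
        if self.hr is not None and self.hr_ci is not None:
            if not (self.hr_ci[0] <= self.hr <= self.hr_ci[1]):
                raise ValueError("HR outside its confidence interval")


@dataclass
class ScreenMatrix:
    """Complete grid of screen cells with the significance threshold used."""

    signature_ids: tuple[str, ...]
    dataset_ids: tuple[str, ...]
    cells: dict[tuple[str, str], ScreenCell] = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for s in self.signature_ids:
            for d in self.dataset_ids:
                if (s, d) not in self.cells:
                    raise ValueError(f"incomplete screen grid: missing cell {(s, d)}")

    def cell(self, signature_id: str, dataset_id: str) -> ScreenCell:
        return self.cells[(signature_id, dataset_id)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.signature_ids:
            for d in self.dataset_ids:
                c = self.cells[(s, d)]
                rows.append(
                    {
                        "signature_id": s,
                        "dataset_id": d,
                        "status": c.status,
                        "na_reason": c.na_reason or "",
                        "p": c.logrank_p,
                        "chi2": c.chi2,
                        "hr": c.hr,
                        "ci_low": c.hr_ci[0] if c.hr_ci else None,
                        "ci_high": c.hr_ci[1] if c.hr_ci else None,
                        "c_index": c.c_index,
                    }
                )
        return pd.DataFrame(rows)

    def to_p_matrix(self) -> pd.DataFrame:
        """Wide signature x dataset matrix of log-rank P (NaN for N/A cells)."""
        data = {
            d: [self.cells[(s, d)].logrank_p for s in self.signature_ids]
            for d in self.dataset_ids
        }
        return pd.DataFrame(data, index=list(self.signature_ids), dtype=float)


def scheduled_tests(signatures: Sequence[GeneSignature], registry: DatasetRegistry) -> int:
    """Number of log-rank tests a screen will schedule (|signatures| x |datasets|)."""
    return len(signatures) * len(registry)


def _screen_one(
    sig: GeneSignature,
    ds: ExpressionDataset,
    label_mode: str,
    with_cox: bool,
    with_cindex: bool,
    min_coverage: float,
) -> ScreenCell:
    mapped = map_signature_to_dataset(sig, ds)
    ga = stratify_two_groups(ds, mapped, min_coverage=min_coverage)
    if ga.status == "ok":
        ga = assign_risk_labels(ga, ds, mapped, mode=label_mode, signature=sig)
    if ga.status != "ok":
        return ScreenCell(
            signature_id=sig.id, dataset_id=ds.id, status="NA", na_reason=ga.na_reason
        )
    times = ds.clinical["time"].to_numpy(float)
    events = ds.clinical["event"].to_numpy(int)
    if events.sum() == 0:
        return ScreenCell(
            signature_id=sig.id, dataset_id=ds.id, status="NA", na_reason="degenerate_group"
        )
    high = ga.high_risk_mask()
    chi2, p = logrank_two_groups(times, events, high)
    hr = hr_ci = hr_p = None
    if with_cox and events[high].sum() > 0 and events[~high].sum() > 0:
        fit = cox_univariate(high.astype(int), times, events)
        if fit.converged:
            hr, hr_ci, hr_p = fit.hr, (fit.ci_low, fit.ci_high), fit.p
    cidx = None
    if with_cindex:
        try:
            cidx = concordance_index(high.astype(float), times, events)
        except ValueError:
            cidx = None
    return ScreenCell(
        signature_id=sig.id,
        dataset_id=ds.id,
        status="ok",
        logrank_p=p,
        chi2=chi2,
        hr=hr,
        hr_ci=hr_ci,
        hr_p=hr_p,
        c_index=cidx,
    )


def run_screen(
    signatures: Sequence[GeneSignature],
    registry: DatasetRegistry,
    subset_filter: SubsetFilter | Mapping[str, object] | None = None,
    alpha: float = 0.05,
    label_mode: str = "by_direction",
    with_cox: bool = True,
    with_cindex: bool = True,
    min_coverage: float = 0.5,
) -> ScreenMatrix:
    """Screen every signature against every dataset.

    ``subset_filter`` restricts each dataset's samples before
    stratification: either a callable on the clinical table returning a
    boolean mask, or a column->value mapping (equality on every entry,
    e.g. ``{"ER": "neg"}``). A dataset whose subset is too small to
    stratify yields N/A cells for all signatures.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    cells: dict[tuple[str, str], ScreenCell] = {}
    for ds in registry:
        sub = _apply_subset(ds, subset_filter)
        for sig in signatures:
            if sub is None:
                cells[(sig.id, ds.id)] = ScreenCell(
                    signature_id=sig.id, dataset_id=ds.id, status="NA", na_reason="degenerate_group"
                )
                continue
            cells[(sig.id, ds.id)] = _screen_one(
                sig, sub, label_mode, with_cox, with_cindex, min_coverage
            )
    return ScreenMatrix(
        signature_ids=tuple(s.id for s in signatures),
        dataset_ids=registry.ids,
        cells=cells,
        alpha=alpha,
    )


def _apply_subset(
    ds: ExpressionDataset, subset_filter: SubsetFilter | Mapping[str, object] | None
) -> ExpressionDataset | None:
    if subset_filter is None:
        return ds
    if callable(subset_filter):
        mask = np.asarray(subset_filter(ds.clinical), dtype=bool)
    else:
        mask = np.ones(ds.n_samples, dtype=bool)
        for col, val in subset_filter.items():
            if col not in ds.clinical.columns:
                logger.info("dataset %s lacks covariate %r; subset empty", ds.id, col)
                return None
            mask &= (ds.clinical[col] == val).to_numpy()
    samples = [s for s, keep in zip(ds.sample_ids, mask) if keep]
    if len(samples) < 10:
        logger.info("dataset %s: subset of %d samples too small to screen", ds.id, len(samples))
        return None
    return ds.subset_samples(samples)


def significant_rate(
    matrix: ScreenMatrix,
    signature_id: str,
    alpha: float | None = None,
    include_na: bool = True,
) -> float:
    """Percentage of datasets on which the signature's log-rank P < alpha.

    By default N/A cells count in the denominator: a failed stratification
    is a failed prediction. ``include_na=False`` restricts the denominator
    to testable cells instead. Returns the unrounded percentage; use
    ``round_half_up`` for table-style integer reporting.
    """
    if signature_id not in matrix.signature_ids:
        raise KeyError(signature_id)
    a = matrix.alpha if alpha is None else alpha
    cells = [matrix.cells[(signature_id, d)] for d in matrix.dataset_ids]
    if not include_na:
        cells = [c for c in cells if c.status == "ok"]
        if not cells:
            return 0.0
    hits = sum(1 for c in cells if c.status == "ok" and c.logrank_p < a)
    return 100.0 * hits / len(cells)


def round_half_up(x: float) -> int:
    """Round-half-up to an integer (reporting convention for rate tables)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RankResult:
    """Significant-rate ranking of all screened signatures."""

    rates: Mapping[str, float]  # unrounded percentages
    order: tuple[str, ...]  # descending by rate, ties by median P then id
    candidates: tuple[str, ...]  # strictly above the cutoff
    cutoff: float


def _median_p(matrix: ScreenMatrix, signature_id: str) -> float:
    ps = [
        c.logrank_p
        for d in matrix.dataset_ids
        if (c := matrix.cells[(signature_id, d)]).status == "ok"
    ]
    return float(np.median(ps)) if ps else float("inf")


def rank_signatures_by_rate(matrix: ScreenMatrix, cutoff: float = 50.0) -> RankResult:
    """Rank signatures by significant-rate; candidates exceed the cutoff strictly."""
    rates = {s: significant_rate(matrix, s) for s in matrix.signature_ids}
    order = tuple(
        sorted(rates, key=lambda s: (-rates[s], _median_p(matrix, s), s))
    )
    candidates = tuple(s for s in order if rates[s] > cutoff)
    return RankResult(rates=rates, order=order, candidates=candidates, cutoff=cutoff)
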