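"""Neoadjuvant chemotherapy response prediction and its evaluation.

Two predictors are implemented. The retrospective one reuses the
unsupervised two-group stratification: the high-risk cluster is called
treatment-insensitive. The prospective one is a nearest-centroid
classifier: the centroid is the per-gene mean expression of a signature
over drug-sensitive cell lines (log(IC50) < -1 for at least one of the
named drugs), and a patient is called sensitive when the Spearman
correlation between their profile and the centroid exceeds 0.35 (strict).

Predictions are scored against pathologic response (pCR vs RD, or RCB 0/I
vs II/III) and against distant relapse-free survival dichotomized at a
3-year horizon, by PPV / NPV / sensitivity / specificity with "predicted
insensitive" as the positive call and non-response as the positive
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, GeneSignature, map_signature_to_dataset
from .stratify import assign_risk_labels, stratify_two_groups
from .survival import km_curve, logrank_two_groups

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.35
IC50_CUTOFF = -1.0
DRFS_HORIZON_YEARS = 3.0
MIN_SHARED_GENES = 5


@dataclass
class CellLinePanel:
    """Expression and per-drug log(IC50) for a cell-line panel."""

    expression: pd.DataFrame  # genes x lines
    log_ic50: pd.DataFrame  # lines x drugs
    her2_status: pd.Series | None = None  # line -> {"pos", "neg"}

    def __post_init__(self) -> None:
        if self.log_ic50.shape[1] == 0:
            raise ValueError("panel needs at least one drug")
        if self.log_ic50.index.duplicated().any():
            raise ValueError("duplicate cell-line ids")
        if not self.expression.columns.equals(self.log_ic50.index):
            if set(self.expression.columns) != set(self.log_ic50.index):
                raise ValueError("expression columns and IC50 rows disagree")
            self.log_ic50 = self.log_ic50.loc[self.expression.columns]

    @property
    def line_ids(self) -> tuple[str, ...]:
        return tuple(self.expression.columns)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.log_ic50.columns)


@dataclass(frozen=True)
class DrugSensitivityCentroid:
    """Per-gene mean expression over the selected drug-sensitive lines."""

    signature_id: str
    values: pd.Series  # gene -> mean expression
    n_lines_used: int
    drug_tag: str

    def __post_init__(self) -> None:
        if self.n_lines_used < 2:
            raise ValueError("centroid needs at least 2 cell lines")


@dataclass
class ResponsePrediction:
    """Per-patient sensitive/insensitive calls from one prediction method."""

    method: Literal["clustering", "centroid"]
    labels: pd.Series  # patient -> {"sensitive", "insensitive"}
    rho: pd.Series | None = None  # centroid mode only

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"sensitive", "insensitive"}
        if bad:
            raise ValueError(f"invalid prediction labels {sorted(bad)}")
        if self.method == "centroid" and self.rho is None:
            raise ValueError("centroid predictions must record rho")


def dichotomize_drfs(
    time: float, event: int, horizon: float = DRFS_HORIZON_YEARS
) -> Literal["early_event", "survivor", "indeterminate"]:
    """Classify one patient's DRFS at the horizon.

    An event at or before the horizon is an early event; follow-up beyond
    the horizon (with or without a later event) is a survivor; censoring
    before the horizon is indeterminate and excluded from horizon metrics.
    """
    if time <= 0:
        raise ValueError("time must be positive")
    if event == 1 and time <= horizon:
        return "early_event"
    if time > horizon:
        return "survivor"
    return "indeterminate"


def select_sensitive_cell_lines(
    panel: CellLinePanel,
    drugs: Sequence[str],
    cutoff: float = IC50_CUTOFF,
    her2_negative_only: bool = True,
) -> list[str]:
    """Lines with log(IC50) strictly below the cutoff for at least one named drug."""
    missing = [d for d in drugs if d not in panel.log_ic50.columns]
    if missing:
        raise KeyError(f"panel lacks drugs {missing}")
    if not drugs:
        raise ValueError("need at least one drug")
    mask = (panel.log_ic50[list(drugs)] < cutoff).any(axis=1)
    if her2_negative_only and panel.her2_status is not None:
        mask &= panel.her2_status.reindex(panel.log_ic50.index) == "neg"
    selected = list(panel.log_ic50.index[mask])
    if not selected:
        raise ValueError("no sensitive cell lines; centroid impossible")
    return selected


def build_centroid(
    panel: CellLinePanel, line_ids: Sequence[str], sig: GeneSignature, drug_tag: str = ""
) -> DrugSensitivityCentroid:
    """Per-gene mean over the selected lines, restricted to signature genes in the panel."""
    if len(line_ids) < 2:
        raise ValueError("centroid needs at least 2 cell lines")
    by_upper = {g.upper(): g for g in panel.expression.index}
    present = [by_upper[g.upper()] for g in sig.genes if g.upper() in by_upper]
    dropped = len(sig.genes) - len(present)
    if dropped:
        logger.warning(
            "centroid for %s: %d signature genes absent from the panel", sig.id, dropped
        )
    if len(present) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(present)} signature genes in panel; need >= {MIN_SHARED_GENES}"
        )
    values = panel.expression.loc[present, list(line_ids)].mean(axis=1)
    return DrugSensitivityCentroid(
        signature_id=sig.id, values=values, n_lines_used=len(line_ids), drug_tag=drug_tag
    )


def classify_by_centroid(
    profile: pd.Series,
    centroid: DrugSensitivityCentroid,
    threshold: float = CORRELATION_THRESHOLD,
) -> tuple[str, float]:
    """One patient: Spearman rho against the centroid; sensitive iff rho > threshold."""
    by_upper = {g.upper(): g for g in profile.index}
    shared = [g for g in centroid.values.index if g.upper() in by_upper]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(f"only {len(shared)} shared genes; need >= {MIN_SHARED_GENES}")
    x = profile[[by_upper[g.upper()] for g in shared]].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("constant patient profile; Spearman correlation undefined")
    rho = float(stats.spearmanr(x, centroid.values[shared].to_numpy(float)).statistic)
    label = "sensitive" if rho > threshold else "insensitive"
    return label, rho


def classify_cohort_by_centroid(
    ds: ExpressionDataset,
    centroid: DrugSensitivityCentroid,
    threshold: float = CORRELATION_THRESHOLD,
    zscore: bool = False,
) -> ResponsePrediction:
    """Centroid classification of every patient in a cohort.

    ``zscore=True`` standardizes each gene across the cohort before
    correlating (off by default; rank correlation already absorbs
    monotone platform effects).
    """
    matrix = ds.matrix
    if zscore:
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1).replace(0.0, 1.0)
        matrix = matrix.sub(mu, axis=0).div(sd, axis=0)
    labels, rhos = {}, {}
    for s in ds.sample_ids:
        label, rho = classify_by_centroid(matrix[s], centroid, threshold=threshold)
        labels[s], rhos[s] = label, rho
    return ResponsePrediction(
        method="centroid",
        labels=pd.Series(labels, name="label"),
        rho=pd.Series(rhos, name="rho"),
    )


def classify_by_clustering(
    ds: ExpressionDataset, sig: GeneSignature, label_mode: str = "by_direction"
) -> ResponsePrediction:
    """Retrospective prediction: high-risk cluster -> treatment-insensitive."""
    mapped = map_signature_to_dataset(sig, ds)
    ga = stratify_two_groups(ds, mapped)
    if ga.status != "ok":
        raise ValueError(f"stratification failed ({ga.na_reason}); no prediction possible")
    ga = assign_risk_labels(ga, ds, mapped, mode=label_mode, signature=sig)
    if ga.status != "ok":
        raise ValueError(f"risk labeling failed ({ga.na_reason}); no prediction possible")
    high = ga.high_risk_mask()
    labels = pd.Series(
        np.where(high, "insensitive", "sensitive"), index=list(ds.sample_ids), name="label"
    )
    return ResponsePrediction(method="clustering", labels=labels)


@dataclass(frozen=True)
class ResponseMetrics:
    """Confusion counts and predictive values (positive call = predicted insensitive)."""

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    endpoint: str
    n_evaluable: int
    n_indeterminate: int = 0

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.tn + self.fn != self.n_evaluable:
            raise ValueError("confusion counts do not reconcile with n_evaluable")


def _condition_positive(
    clinical: pd.DataFrame, endpoint: str, horizon: float
) -> tuple[pd.Series, pd.Series]:
    """(condition-positive mask, evaluable mask) for the requested endpoint."""
    if endpoint == "pCR/RD":
        if "pcr" not in clinical.columns:
            raise KeyError("clinical table lacks a 'pcr' column")
        evaluable = clinical["pcr"].isin(["pCR", "RD"])
        positive = clinical["pcr"] == "RD"
    elif endpoint == "RCB":
        if "rcb" not in clinical.columns:
            raise KeyError("clinical table lacks an 'rcb' column")
        evaluable = clinical["rcb"].isin(["0", "I", "II", "III"])
        positive = clinical["rcb"].isin(["II", "III"])
    elif endpoint == "DRFS3y":
        status = pd.Series(
            [
                dichotomize_drfs(t, e, horizon)
                for t, e in zip(clinical["time"], clinical["event"])
            ],
            index=clinical.index,
        )
        evaluable = status != "indeterminate"
        positive = status == "early_event"
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return positive, evaluable


def response_metrics(
    pred: ResponsePrediction,
    clinical: pd.DataFrame,
    endpoint: Literal["pCR/RD", "RCB", "DRFS3y"],
    horizon: float = DRFS_HORIZON_YEARS,
) -> ResponseMetrics:
    """PPV/NPV/sensitivity/specificity of a prediction against an observed endpoint.

    Positive prediction is "insensitive"; condition positive is RD, RCB
    II/III, or an early DRFS event depending on the endpoint. Patients
    censored before the DRFS horizon are excluded (counted as
    indeterminate).
    """
    clinical = clinical.loc[pred.labels.index]
    positive, evaluable = _condition_positive(clinical, endpoint, horizon)
    n_indet = int((~evaluable).sum())
    labels = pred.labels[evaluable]
    positive = positive[evaluable]
    pred_pos = labels == "insensitive"
    if pred_pos.sum() == 0:
        raise ValueError("no predicted-insensitive patients; PPV undefined")
    if (~pred_pos).sum() == 0:
        raise ValueError("no predicted-sensitive patients; NPV undefined")
    tp = int((pred_pos & positive).sum())
    fp = int((pred_pos & ~positive).sum())
    tn = int((~pred_pos & ~positive).sum())
    fn = int((~pred_pos & positive).sum())
    return ResponseMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        ppv=100.0 * tp / (tp + fp),
        npv=100.0 * tn / (tn + fn),
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        endpoint=endpoint,
        n_evaluable=int(evaluable.sum()),
        n_indeterminate=n_indet,
    )


@dataclass(frozen=True)
class PredictionSurvival:
    """KM step curves per predicted group plus their log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    chi2: float
    p: float


def km_by_prediction(pred: ResponsePrediction, times, events) -> PredictionSurvival:
    """Compare survival between predicted-sensitive and predicted-insensitive patients."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = pred.labels.to_numpy()
    curves = {}
    for lab in ("sensitive", "insensitive"):
        mask = labels == lab
        if mask.sum() == 0:
            raise ValueError(f"no patients predicted {lab}")
        curves[lab] = km_curve(times[mask], events[mask])
    chi2, p = logrank_two_groups(times, events, labels)
    return PredictionSurvival(curves=curves, chi2=chi2, p=p)
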