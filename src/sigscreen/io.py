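"""Domain types and readers/writers for signature collections and expression datasets.

Signature collections use GMT-style text (one gene set per line:
``id<TAB>description<TAB>gene1<TAB>gene2...``) with an optional direction
dialect: a gene token may carry a ``|up`` or ``|down`` suffix. Expression
data is a genes x samples TSV; the clinical table is a per-sample TSV with
at least ``time`` and ``event`` columns. A registry manifest (YAML) lists
the datasets a screen runs over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Recognised survival endpoint labels.
ENDPOINTS = ("RFS", "DFS", "DRFS", "DMFS", "OS", "DSS")

#: Divisors that convert clinical time columns to years.
TIME_UNITS = {"days": 365.25, "months": 12.0, "years": 1.0}

_DIRECTIONS = ("up", "down", "unknown")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally with per-gene up/down directions."""

    id: str
    genes: tuple[str, ...]
    description: str = ""
    directions: Mapping[str, str] | None = None
    phenotype_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.id!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.id!r} has duplicate gene symbols")
        if self.directions is not None:
            extra = set(self.directions) - set(self.genes)
            if extra:
                raise ValueError(
                    f"signature {self.id!r}: directions for non-member genes {sorted(extra)}"
                )
            bad = set(self.directions.values()) - set(_DIRECTIONS)
            if bad:
                raise ValueError(f"signature {self.id!r}: invalid directions {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def up_genes(self) -> tuple[str, ...]:
        if not self.directions:
            return ()
        return tuple(g for g in self.genes if self.directions.get(g) == "up")


@dataclass
class ExpressionDataset:
    """A genes x samples log-expression matrix plus per-sample clinical data.

    ``clinical`` is indexed by sample id (same order as the matrix columns)
    and must contain ``time`` (years, > 0) and ``event`` (0/1); any further
    columns are treated as covariates (ER, HER2, grade, pcr, rcb,
    tp53_mutant, ...).
    """

    id: str
    matrix: pd.DataFrame
    clinical: pd.DataFrame
    endpoint: str

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"dataset {self.id!r}: duplicate gene ids {dups[:5]}")
        if not self.matrix.columns.equals(self.clinical.index):
            if set(self.matrix.columns) != set(self.clinical.index):
                raise ValueError(f"dataset {self.id!r}: matrix samples != clinical samples")
            self.clinical = self.clinical.loc[self.matrix.columns]
        times = self.clinical["time"].to_numpy(float)
        if not np.all(times > 0):
            raise ValueError(f"dataset {self.id!r}: survival times must be strictly positive")
        events = self.clinical["event"].to_numpy()
        if not np.isin(events, (0, 1)).all():
            raise ValueError(f"dataset {self.id!r}: event indicator must be 0/1")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    def _upper_index(self) -> dict[str, int]:
        """Cached uppercase gene symbol -> row position (mapping hot path)."""
        cached = getattr(self, "_upper_index_cache", None)
        if cached is None:
            cached = {g.upper(): i for i, g in enumerate(self.matrix.index)}
            object.__setattr__(self, "_upper_index_cache", cached)
        return cached

    def _values(self) -> "np.ndarray":
        """Cached expression ndarray (screen/permutation hot path)."""
        cached = getattr(self, "_values_cache", None)
        if cached is None:
            cached = self.matrix.to_numpy(dtype=float)
            object.__setattr__(self, "_values_cache", cached)
        return cached

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, sample_ids: Sequence[str], suffix: str = "subset") -> "ExpressionDataset":
        """Restrict to a sample subset (e.g. an ER-negative slice)."""
        ids = list(sample_ids)
        return ExpressionDataset(
            id=f"{self.id}[{suffix}]",
            matrix=self.matrix.loc[:, ids],
            clinical=self.clinical.loc[ids],
            endpoint=self.endpoint,
        )


@dataclass(frozen=True)
class MappedSignature:
    """A signature resolved against one dataset's gene universe."""

    signature_id: str
    dataset_id: str
    mapped_genes: tuple[str, ...]
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0, 1]")


@dataclass
class DatasetRegistry:
    """Ordered collection of datasets; QC verdicts are attached after permutation QC."""

    datasets: list[ExpressionDataset] = field(default_factory=list)
    qc: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ds.id for ds in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset ids in registry")

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ds.id for ds in self.datasets)

    def get(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.id == dataset_id:
                return ds
        raise KeyError(dataset_id)


# ---------------------------------------------------------------------------
# Signature collections (GMT dialect)
# ---------------------------------------------------------------------------

def read_signature_collection(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT-style file into GeneSignature records.

    Duplicate genes within a line are collapsed (first occurrence wins) with
    a logged warning; duplicate signature ids or gene-less lines are errors.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()]
    signatures: list[GeneSignature] = []
    seen_ids: set[str] = set()
    any_content = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        any_content = True
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected id, description and >= 1 gene")
        sig_id, description = fields[0], fields[1]
        if sig_id in seen_ids:
            raise ValueError(f"{path}:{lineno}: duplicate signature id {sig_id!r}")
        seen_ids.add(sig_id)
        genes: list[str] = []
        directions: dict[str, str] = {}
        for token in fields[2:]:
            token = token.strip()
            if not token:
                continue
            if "|" in token:
                gene, _, direction = token.partition("|")
                if direction not in ("up", "down"):
                    raise ValueError(
                        f"{path}:{lineno}: bad direction {direction!r} for gene {gene!r}"
                    )
            else:
                gene, direction = token, None
            if gene in genes:
                logger.warning(
                    "%s:%d: duplicate gene %r in signature %r collapsed", path, lineno, gene, sig_id
                )
                continue
            genes.append(gene)
            if direction is not None:
                directions[gene] = direction
        if not genes:
            raise ValueError(f"{path}:{lineno}: signature {sig_id!r} lists no genes")
        signatures.append(
            GeneSignature(
                id=sig_id,
                description=description,
                genes=tuple(genes),
                directions=directions or None,
            )
        )
    if not any_content:
        raise ValueError(f"{path}: empty signature file")
    return signatures


def write_signature_collection(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Write signatures in the same GMT dialect ``read_signature_collection`` accepts."""
    path = Path(path)
    rows = []
    for sig in signatures:
        tokens = []
        for g in sig.genes:
            d = (sig.directions or {}).get(g)
            tokens.append(f"{g}|{d}" if d in ("up", "down") else g)
        rows.append("\t".join([sig.id, sig.description, *tokens]))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Expression datasets
# ---------------------------------------------------------------------------

def read_expression_dataset(
    expr_path: str | Path,
    clinical_path: str | Path,
    endpoint: str,
    dataset_id: str | None = None,
    time_unit: str = "years",
) -> ExpressionDataset:
    """Read a genes x samples TSV plus a per-sample clinical TSV.

    Samples are inner-joined (order from the expression file); duplicate
    gene rows are collapsed by per-gene maximum; times are converted to
    years according to ``time_unit``.
    """
    expr_path, clinical_path = Path(expr_path), Path(clinical_path)
    if time_unit not in TIME_UNITS:
        raise ValueError(f"time_unit must be one of {sorted(TIME_UNITS)}")
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    bad = expr.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        gene = bad.index[bad.isna().any(axis=1)][0]
        sample = bad.columns[bad.isna().any(axis=0)][0]
        raise ValueError(
            f"{expr_path}: non-numeric expression value at gene {gene!r}, sample {sample!r}"
        )
    expr = bad.astype(float)
    if expr.index.duplicated().any():
        n_dup = int(expr.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by maximum", expr_path, n_dup)
        expr = expr.groupby(level=0, sort=False).max()
    clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
    clinical.index = clinical.index.astype(str)
    expr.columns = expr.columns.astype(str)
    shared = [s for s in expr.columns if s in set(clinical.index)]
    if not shared:
        raise ValueError(f"no overlapping samples between {expr_path} and {clinical_path}")
    expr = expr.loc[:, shared]
    clinical = clinical.loc[shared].copy()
    if "time" not in clinical.columns or "event" not in clinical.columns:
        raise ValueError(f"{clinical_path}: clinical table needs 'time' and 'event' columns")
    clinical["time"] = clinical["time"].astype(float) / TIME_UNITS[time_unit]
    if (clinical["time"] <= 0).any():
        raise ValueError(f"{clinical_path}: survival times must be strictly positive")
    clinical["event"] = clinical["event"].astype(int)
    return ExpressionDataset(
        id=dataset_id or expr_path.stem,
        matrix=expr,
        clinical=clinical,
        endpoint=endpoint,
    )


def write_expression_dataset(
    ds: ExpressionDataset, expr_path: str | Path, clinical_path: str | Path
) -> None:
    ds.matrix.to_csv(expr_path, sep="\t", index_label="gene")
    ds.clinical.to_csv(clinical_path, sep="\t", index_label="sample")


def map_signature_to_dataset(sig: GeneSignature, ds: ExpressionDataset) -> MappedSignature:
    """Resolve a signature against a dataset's gene universe.

    Matching is exact and case-insensitive; ``mapped_genes`` are reported
    in dataset order under the dataset's spelling. Zero coverage is a valid
    result (downstream stratification records it as N/A).
    """
    index = ds._upper_index()
    positions = sorted(index[u] for g in sig.genes if (u := g.upper()) in index)
    mapped = tuple(ds.matrix.index[i] for i in positions)
    return MappedSignature(
        signature_id=sig.id,
        dataset_id=ds.id,
        mapped_genes=mapped,
        coverage=len(mapped) / len(sig.genes),
    )


# ---------------------------------------------------------------------------
# Registry manifests
# ---------------------------------------------------------------------------

def read_registry(manifest_path: str | Path) -> DatasetRegistry:
    """Load a YAML manifest: a list of {id, expr_path, clinical_path, endpoint, time_unit}."""
    manifest_path = Path(manifest_path)
    entries = yaml.safe_load(manifest_path.read_text())
    if not entries:
        raise ValueError(f"{manifest_path}: empty registry manifest")
    datasets = []
    for entry in entries:
        root = manifest_path.parent
        datasets.append(
            read_expression_dataset(
                expr_path=root / entry["expr_path"],
                clinical_path=root / entry["clinical_path"],
                endpoint=entry["endpoint"],
                dataset_id=entry["id"],
                time_unit=entry.get("time_unit", "years"),
            )
        )
    return DatasetRegistry(datasets=datasets)


def write_registry(
    registry: DatasetRegistry, directory: str | Path, manifest_name: str = "registry.yaml"
) -> Path:
    """Materialise every dataset as TSV pairs plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in registry:
        expr_name, clin_name = f"{ds.id}_expr.tsv", f"{ds.id}_clinical.tsv"
        write_expression_dataset(ds, directory / expr_name, directory / clin_name)
        entries.append(
            {
                "id": ds.id,
                "expr_path": expr_name,
                "clinical_path": clin_name,
                "endpoint": ds.endpoint,
                "time_unit": "years",
            }
        )
    manifest = directory / manifest_name
    manifest.write_text(yaml.safe_dump(entries, sort_keys=False))
    return manifest
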