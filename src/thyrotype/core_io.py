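"""Readers/writers for the pipeline's file formats plus run configuration and seeded RNG.

The pipeline's universal substrate is a dense, non-negative gene-by-sample
expression matrix on the RPKM scale (reads per kilobase per million mapped
reads).  All file formats are plain text: TSV for matrices and metadata, GMT
for gene sets, YAML for run configuration.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("thyrotype")

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "RunConfig",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "log2_transform",
    "rng_for",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


@dataclass
class ExpressionMatrix:
    """Dense non-negative gene-by-sample expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with one column per sample id.
        Values must be finite and >= 0 (RPKM scale, or log2(RPKM+1) after
        :func:`log2_transform`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite")
        if (values < 0).any():
            raise FormatError("expression values must be non-negative")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes].copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)].copy())


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT semantics): unique set names, non-empty lists."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if not deduped:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = deduped
        self.descriptions[name] = description


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Named parameters of every pipeline stage, serializable to YAML.

    Every stochastic operation draws from a child generator derived from
    (seed, operation-name) via :func:`rng_for`, so stages are independently
    reproducible and the whole run is reproducible from ``seed`` alone.
    """

    seed: int = 0
    # subtyping
    nmf_rank: int = 6
    nmf_restarts: int = 50
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    exemplar_count: int = 50
    marker_permutations: int = 100
    marker_alpha: float = 0.05
    rf_trees: int = 200
    ntp_permutations: int = 1000
    # filtering
    low_expr_threshold: float = 1.0
    cv_threshold: float = 0.8
    log2_pseudocount: float = 1.0
    # network
    mi_bins: int = 0  # 0 -> ceil(sqrt(n)) capped at 10
    dpi_tolerance: float = 0.0
    mi_null_permutations: int = 100
    mi_alpha: float = 0.05
    top_hubs: int = 10
    gsea_permutations: int = 1000
    # scoring
    ssgsea_tau: float = 0.25
    # trajectory
    trajectory_centroids: int = 0  # 0 -> ceil(n/10)
    beam_spline_df: int = 3
    # diagnosis
    cv_folds: tuple[int, ...] = (4, 6, 8, 10)
    test_fraction: float = 0.2

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["cv_folds"] = list(self.cv_folds)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "cv_folds" in payload:
            payload["cv_folds"] = tuple(payload["cv_folds"])
        return cls(**payload)


def rng_for(seed: int, op_name: str) -> np.random.Generator:
    """Child generator for one named operation.

    Derived from ``(seed, crc32(op_name))`` so each stage sees an independent,
    reproducible stream regardless of the order stages run in.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(op_name.encode())]))


# ---------------------------------------------------------------------------
# Expression matrix TSV


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (header = sample ids, first column = gene symbols).

    Duplicate gene rows are collapsed by per-sample maximum (the common
    convention when several transcripts map to one symbol) and logged.
    Negative values and duplicate sample ids are format errors.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = sample_ids
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if not np.all(np.isfinite(df.to_numpy())):
        raise FormatError(f"{path}: non-finite expression value")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression value")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by per-sample max", path, n_dup)
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample metadata TSV

SAMPLE_COLUMNS = ["sample_id", "tissue", "histology", "pair_id"]


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV.

    Required columns: sample_id, tissue (nodule/adjacent), histology
    (PTC/BTN), pair_id.  Optional: braf_mutant, subtype, clinicopathologic
    booleans.  sample_id must be unique; each pair_id links at most one
    nodule and one adjacent sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample-table columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    bad_tissue = set(df["tissue"]) - {"nodule", "adjacent"}
    if bad_tissue:
        raise FormatError(f"{path}: unknown tissue values {sorted(bad_tissue)}")
    counts = df.groupby(["pair_id", "tissue"]).size()
    if (counts > 1).any():
        raise FormatError(f"{path}: a pair_id links more than one nodule or adjacent sample")
    return df.set_index("sample_id", drop=False)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: name, description, genes...

    Within-set duplicates are removed preserving first occurrence; duplicate
    set names and lines with fewer than three fields are format errors.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            collection.add(name, genes, description)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *collection[name]]) + "\n")


# ---------------------------------------------------------------------------
# Transforms


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + pseudocount); shape- and order-preserving."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return ExpressionMatrix(np.log2(m.data + pseudocount))
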