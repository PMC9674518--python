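"""Post-filters for candidate fusion and somatic-mutation calls.

Both filters are deterministic row-wise rules with literal boundary
semantics: "at least" means >=, "less than" means strictly <.  Getting these
boundaries wrong silently changes downstream results, so each rule is applied
in a fixed order and the first failed rule becomes the row's rejection
reason.

Fusion rules (applied in order):
  1. split_reads >= 5
  2. spanning_pairs >= 2
  3. both partner genes measured in the expression matrix
  4. neither partner has max RPKM across all samples < 1 ("low expression")
  5. not a read-through: not (same chromosome and gene-pair distance < 10 kb)

Mutation rules (applied in order):
  1. tumor depth >= 10 and normal depth >= 10 ("insufficient coverage")
  2. tumor VAF >= 0.05
  3. normal VAF < 0.01
  4. tumor alt reads >= 5
  5. not a dbSNP-135 site

VAF is alt reads / depth; zero depth makes the VAF undefined and the row is
rejected for insufficient coverage.  dbSNP membership arrives as a boolean
column — no database lookup happens here.  The distance rule uses the
distance between the nearest gene boundaries as supplied by the caller; the
coverage threshold is read as applying to both tumor and normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "FusionCandidate",
    "MutationCandidate",
    "filter_fusions",
    "filter_mutations",
    "fusions_from_frame",
    "mutations_from_frame",
]

MIN_SPLIT_READS = 5
MIN_SPANNING_PAIRS = 2
MIN_PARTNER_RPKM = 1.0
READTHROUGH_DISTANCE_BP = 10_000
MIN_DEPTH = 10
MIN_TUMOR_VAF = 0.05
MAX_NORMAL_VAF = 0.01
MIN_TUMOR_ALT_READS = 5


@dataclass(frozen=True)
class FusionCandidate:
    gene_a: str
    gene_b: str
    split_reads: int
    spanning_pairs: int
    same_chromosome: bool = False
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.spanning_pairs < 0 or self.distance_bp < 0:
            raise ValueError("fusion read counts and distance must be >= 0")


@dataclass(frozen=True)
class MutationCandidate:
    gene: str
    position: int
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    dbsnp135: bool = False

    def __post_init__(self) -> None:
        if min(self.tumor_depth, self.normal_depth) < 0:
            raise ValueError("depths must be >= 0")
        if self.tumor_alt > self.tumor_depth or self.normal_alt > self.normal_depth:
            raise ValueError("alt reads cannot exceed depth")


def _fusion_reason(c: FusionCandidate, max_rpkm: dict[str, float]) -> str:
    if c.split_reads < MIN_SPLIT_READS:
        return "low split reads"
    if c.spanning_pairs < MIN_SPANNING_PAIRS:
        return "low spanning pairs"
    if c.gene_a not in max_rpkm or c.gene_b not in max_rpkm:
        return "unexpressed partner"
    if max_rpkm[c.gene_a] < MIN_PARTNER_RPKM or max_rpkm[c.gene_b] < MIN_PARTNER_RPKM:
        return "low expression"
    if c.same_chromosome and c.distance_bp < READTHROUGH_DISTANCE_BP:
        return "read-through"
    return ""


def filter_fusions(
    candidates: list[FusionCandidate], expression: ExpressionMatrix
) -> tuple[list[FusionCandidate], list[str]]:
    """Apply the fusion post-filter rules.

    Returns the kept candidates and, aligned with the *input* order, the
    per-row rejection reason (empty string = kept).  A partner gene missing
    from the expression matrix is a rejection, not an error.
    """
    max_rpkm = expression.data.max(axis=1).to_dict()
    reasons = [_fusion_reason(c, max_rpkm) for c in candidates]
    kept = [c for c, r in zip(candidates, reasons) if not r]
    return kept, reasons


def _mutation_reason(c: MutationCandidate) -> str:
    if c.tumor_depth < MIN_DEPTH or c.normal_depth < MIN_DEPTH:
        return "insufficient coverage"
    if c.tumor_alt / c.tumor_depth < MIN_TUMOR_VAF:
        return "low tumor VAF"
    if c.normal_alt / c.normal_depth >= MAX_NORMAL_VAF:
        return "high normal VAF"
    if c.tumor_alt < MIN_TUMOR_ALT_READS:
        return "low tumor alt reads"
    if c.dbsnp135:
        return "dbSNP135 site"
    return ""


def filter_mutations(
    candidates: list[MutationCandidate],
) -> tuple[list[MutationCandidate], list[str]]:
    """Apply the somatic-mutation post-filter rules (see module docstring)."""
    reasons = [_mutation_reason(c) for c in candidates]
    kept = [c for c, r in zip(candidates, reasons) if not r]
    return kept, reasons


# ---------------------------------------------------------------------------
# TSV adapters


def fusions_from_frame(df: pd.DataFrame) -> list[FusionCandidate]:
    """Build candidates from a TSV-derived frame (synthetic_data column names)."""
    return [
        FusionCandidate(
            gene_a=str(r.gene_a),
            gene_b=str(r.gene_b),
            split_reads=int(r.split_reads),
            spanning_pairs=int(r.spanning_pairs),
            same_chromosome=bool(r.same_chromosome),
            distance_bp=int(r.distance_bp),
        )
        for r in df.itertuples(index=False)
    ]


def mutations_from_frame(df: pd.DataFrame) -> list[MutationCandidate]:
    return [
        MutationCandidate(
            gene=str(r.gene),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            tumor_depth=int(r.tumor_depth),
            tumor_alt=int(r.tumor_alt),
            normal_depth=int(r.normal_depth),
            normal_alt=int(r.normal_alt),
            dbsnp135=bool(r.dbsnp135),
        )
        for r in df.itertuples(index=False)
    ]
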