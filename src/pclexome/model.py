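"""Domain types for the pPCL exome pipeline.

Coordinate conventions follow the file formats each type mirrors: variants
are 1-based (VCF), copy-number segments and gene models are 0-based
half-open (BED).  :func:`variant_overlaps_interval` is the single place
where the two conventions meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

VARIANT_CLASSES = ("snv", "insertion", "deletion")
CONSEQUENCES = (
    "missense",
    "nonsense",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "noncoding",
)
#: coding consequences that alter the protein ("non-silent")
NON_SILENT = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site"}
)

_DNA = frozenset("ACGT")


def _check_dna(s: str, what: str) -> None:
    if not s or not set(s) <= _DNA:
        raise ValueError(f"{what} must be a non-empty uppercase ACGT string, got {s!r}")


@dataclass
class VariantRecord:
    """One called variant in one sample — the atom of the filter cascade.

    Annotation flags (polymorphism-database membership, COSMIC/ClinVar,
    damaging prediction) are precomputed inputs, never live lookups.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    variant_class: str
    consequence: str
    gene: str | None = None
    context3: str | None = None
    in_polymorphism_db: bool = False
    in_cosmic: bool = False
    cosmic_confirmed_somatic: bool = False
    in_clinvar: bool = False
    damaging: bool = False

    def __post_init__(self) -> None:
        _check_dna(self.ref, "ref")
        _check_dna(self.alt, "alt")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.total_depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if is_snv != (self.variant_class == "snv"):
            raise ValueError(
                "variant_class=snv iff ref and alt are single bases "
                f"(got {self.ref}>{self.alt}, class {self.variant_class})"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.context3 is not None:
            if len(self.context3) != 3 or not set(self.context3) <= _DNA:
                raise ValueError(f"context3 must be a 3-mer, got {self.context3!r}")
            if self.variant_class == "snv" and self.context3[1] != self.ref:
                raise ValueError(
                    f"context3 {self.context3} not centered on ref base {self.ref}"
                )
        if self.cosmic_confirmed_somatic and not self.in_cosmic:
            raise ValueError("cosmic_confirmed_somatic requires in_cosmic")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact genomic identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth else 0.0

    @property
    def non_silent(self) -> bool:
        return self.consequence in NON_SILENT


@dataclass
class SampleMeta:
    sample_id: str
    role: str  # tumor | control
    matched_control_id: str | None = None
    translocation_group: str | None = None
    purity: float = 0.9

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "control"):
            raise ValueError(f"role must be tumor or control, got {self.role!r}")
        if self.role == "control" and self.matched_control_id is not None:
            raise ValueError("control samples cannot themselves have a matched control")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")


@dataclass
class GeneModel:
    gene: str
    transcript: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.transcript}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CNSegment:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ExpressionMatrix:
    """log2 expression, genes x samples, with per-sample class labels."""

    values: pd.DataFrame  # index=genes, columns=samples
    sample_labels: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene rows in expression matrix: {dups}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def variant_overlaps_interval(pos: int, start: int, end: int) -> bool:
    """Does a 1-based variant position fall in a 0-based half-open interval?

    The variant base occupies half-open coordinate ``pos - 1``, so a variant
    at ``pos = start + 1`` overlaps and one at ``pos = end + 1`` does not.
    """
    return start <= pos - 1 < end


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of overlap between two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
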