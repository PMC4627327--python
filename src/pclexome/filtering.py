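"""The somatic filter cascade.

Raw per-sample calls are reduced to coding somatic non-silent variants in
a fixed stage order: read-depth floor, non-silent consequence selection,
polymorphism-database filter (with COSMIC/ClinVar rescue), control
subtraction (matched control in paired mode, the control pool in unpaired
mode), and — in paired mode only — sub-clonal labeling by an exact
binomial test against the clonal expectation.

Unpaired mode cannot prove somatic status: identical variants recurring in
two or more unpaired samples that sit in the polymorphism databases and in
COSMIC without confirmed somatic status are flagged as possible residual
germline (`germline_risk_flag`).  The carry-over audit quantifies how much
private germline background survives unpaired-mode filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom

from .model import VariantRecord

STAGES = ("depth", "non_silent", "polymorphism", "control_subtraction", "subclonal_label")


@dataclass
class CascadeParams:
    min_depth: int = 10
    min_control_depth: int = 10
    alpha: float = 0.05
    ccf_threshold: float = 0.5


@dataclass
class FilterFunnel:
    """Per-stage surviving/removed counts; counts never increase."""

    n_input: int
    stages: list[str] = field(default_factory=list)
    survivors: list[int] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)

    def add(self, stage: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise ValueError(f"stage {stage}: survivors increased")
        self.stages.append(stage)
        self.survivors.append(n_after)
        self.removed.append(n_before - n_after)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "survivors": self.survivors, "removed": self.removed}
        )


@dataclass
class SomaticCall:
    record: VariantRecord
    clonality: str  # clonal | subclonal
    mode: str  # paired | unpaired
    germline_risk_flag: bool = False
    ccf: float | None = None

    def __post_init__(self) -> None:
        if self.clonality not in ("clonal", "subclonal"):
            raise ValueError(f"bad clonality {self.clonality!r}")
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.clonality == "subclonal" and self.mode != "paired":
            raise ValueError("subclonal labels exist only in paired mode")
        if self.germline_risk_flag and self.mode != "unpaired":
            raise ValueError("germline_risk_flag applies only to unpaired calls")


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Left-normalize an indel representation for exact matching.

    Trims shared trailing bases, then shared leading bases (advancing the
    position), always keeping at least one base on each allele.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def _nkey(r: VariantRecord) -> tuple[str, int, str, str]:
    return normalize_key(r.chrom, r.pos, r.ref, r.alt)


# ------------------------------------------------------------------ stages


def depth_filter(records: Iterable[VariantRecord], min_depth: int = 10) -> list[VariantRecord]:
    """Keep records with total depth at or above the floor (inclusive)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return [r for r in records if r.total_depth >= min_depth]


def select_non_silent(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep coding protein-altering consequences, incl. splice sites."""
    return [r for r in records if r.non_silent]


def polymorphism_filter(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop known polymorphisms unless rescued by COSMIC or ClinVar."""
    return [
        r
        for r in records
        if not (r.in_polymorphism_db and not r.in_cosmic and not r.in_clinvar)
    ]


def subtract_controls(
    tumor_records: Iterable[VariantRecord],
    control_records: Sequence[VariantRecord],
    min_control_depth: int = 10,
) -> list[VariantRecord]:
    """Remove tumor variants called in any control at adequate depth.

    Matching is exact on (chrom, pos, ref, alt) after indel
    left-normalization; a control call below ``min_control_depth`` carries
    no veto power.
    """
    if not control_records:
        raise ValueError("no controls supplied")
    veto = {
        _nkey(c) for c in control_records if c.total_depth >= min_control_depth
    }
    return [r for r in tumor_records if _nkey(r) not in veto]


def label_subclonal(
    somatic_records: Iterable[VariantRecord],
    purity: float,
    alpha: float = 0.05,
    ccf_threshold: float = 0.5,
) -> list[SomaticCall]:
    """Split paired-mode somatic calls into clonal and sub-clonal.

    A variant is sub-clonal when a one-sided exact binomial test rejects
    alt_depth ~ Binomial(total_depth, 0.5 x purity) low at level ``alpha``
    AND its cancer-cell-fraction estimate 2 x VAF / purity (diploid
    assumption) is below ``ccf_threshold``.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    p0 = 0.5 * purity
    calls = []
    for r in somatic_records:
        ccf = 2.0 * r.vaf / purity
        p_low = float(binom.cdf(r.alt_depth, r.total_depth, p0))
        clonality = "subclonal" if (p_low < alpha and ccf < ccf_threshold) else "clonal"
        calls.append(SomaticCall(r, clonality, "paired", ccf=ccf))
    return calls


# ----------------------------------------------------------------- cascade


def run_cascade(
    tumor_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    mode: str,
    purity: float = 0.9,
    params: CascadeParams | None = None,
    allow_no_controls: bool = False,
) -> tuple[list[SomaticCall], FilterFunnel]:
    """Apply the full filter cascade to one tumor sample.

    ``control_records`` is the matched control in paired mode and the
    pooled controls in unpaired mode.  ``allow_no_controls`` turns an
    empty control set into a pass-through subtraction stage (unpaired
    runs without any normals) instead of an error.
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"mode must be paired or unpaired, got {mode!r}")
    params = params or CascadeParams()
    funnel = FilterFunnel(n_input=len(tumor_records))
    n = len(tumor_records)

    records = depth_filter(tumor_records, params.min_depth)
    funnel.add("depth", n, len(records))
    n = len(records)

    records = select_non_silent(records)
    funnel.add("non_silent", n, len(records))
    n = len(records)

    records = polymorphism_filter(records)
    funnel.add("polymorphism", n, len(records))
    n = len(records)

    if control_records or not allow_no_controls:
        records = subtract_controls(records, control_records, params.min_control_depth)
    funnel.add("control_subtraction", n, len(records))
    n = len(records)

    if mode == "paired":
        calls = label_subclonal(records, purity, params.alpha, params.ccf_threshold)
    else:
        calls = [SomaticCall(r, "clonal", "unpaired") for r in records]
    funnel.add("subclonal_label", n, len(calls))
    return calls, funnel


def spectrum_input(
    tumor_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    params: CascadeParams | None = None,
) -> list[VariantRecord]:
    """The variant set feeding mutation spectra: germline-filtered but
    keeping silent SNVs (spectra count synonymous substitutions too)."""
    params = params or CascadeParams()
    records = depth_filter(tumor_records, params.min_depth)
    records = polymorphism_filter(records)
    if not control_records:
        return records
    return subtract_controls(records, control_records, params.min_control_depth)


def carryover_audit(
    variants: Mapping[str, Sequence[VariantRecord]],
    metadata: Sequence,
    params: CascadeParams | None = None,
) -> pd.DataFrame:
    """Quantify private germline carry-over in unpaired-mode filtering.

    Each paired tumor is run in paired mode (its matched control) and in
    unpaired mode (the pool of the OTHER samples' controls); variants
    unique to the unpaired run are potential residual germline.
    """
    params = params or CascadeParams()
    paired = [m for m in metadata if m.role == "tumor" and m.matched_control_id]
    if not paired:
        raise ValueError("carry-over audit needs at least one paired sample")
    control_ids = [m.sample_id for m in metadata if m.role == "control"]
    rows = []
    for m in paired:
        matched = variants[m.matched_control_id]
        others = [
            r for cid in control_ids if cid != m.matched_control_id for r in variants[cid]
        ]
        paired_calls, _ = run_cascade(variants[m.sample_id], matched, "paired", m.purity, params)
        # a single-control cohort leaves the "other controls" pool empty
        unpaired_calls, _ = run_cascade(
            variants[m.sample_id], others, "unpaired", m.purity, params,
            allow_no_controls=True,
        )
        pk = {_nkey(c.record) for c in paired_calls}
        uk = {_nkey(c.record) for c in unpaired_calls}
        extra = uk - pk
        rows.append(
            {
                "sample_id": m.sample_id,
                "n_paired": len(pk),
                "n_unpaired": len(uk),
                "n_extra": len(extra),
                "extra_fraction": len(extra) / len(uk) if uk else 0.0,
            }
        )
    return pd.DataFrame(rows)


def flag_unconfirmed_recurrent(calls: Iterable[SomaticCall]) -> list[SomaticCall]:
    """Flag identical variants recurring in >=2 unpaired samples whose
    COSMIC entry does not confirm somatic status (possible residual
    germline).  Returns the same call objects, flags set in place."""
    calls = list(calls)
    by_key: dict[tuple, set[str]] = {}
    for c in calls:
        if c.mode == "unpaired":
            by_key.setdefault(_nkey(c.record), set()).add(c.record.sample_id)
    for c in calls:
        if c.mode != "unpaired":
            continue
        r = c.record
        if (
            len(by_key.get(_nkey(r), ())) >= 2
            and r.in_polymorphism_db
            and r.in_cosmic
            and not r.cosmic_confirmed_somatic
        ):
            c.germline_risk_flag = True
    return calls
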