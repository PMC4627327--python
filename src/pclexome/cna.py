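"""Copy-number integration: gene CN state, two-hit calls, burden summary.

Segments (consumed, never re-segmented here) are projected onto the
largest transcript of each gene.  A gene's copy number is that of the
overlapping segment with the greatest overlap length; any overlapping
CN=0 segment marks the gene homozygously deleted regardless (a focal
deletion inside a gene still destroys it).  Biallelic ("two-hit")
inactivation is a homozygous deletion, or a non-silent somatic mutation
combined with hemizygous loss of the other allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .model import CNSegment, GeneModel, interval_overlap
from .filtering import SomaticCall

CN_CLASSES = ("homozygous_del", "hemizygous_del", "neutral", "gain", "amplification")


def cn_class(copy_number: int, baseline: int = 2) -> str:
    """Map an integer copy number to its class relative to the ploidy
    baseline (2 for diploid; 4 shifts every threshold by +2, e.g. for a
    basally tetraploid sample)."""
    adjusted = copy_number - (baseline - 2)
    if adjusted <= 0:
        return "homozygous_del"
    if adjusted == 1:
        return "hemizygous_del"
    if adjusted == 2:
        return "neutral"
    if adjusted in (3, 4):
        return "gain"
    return "amplification"


@dataclass
class GeneCNState:
    sample_id: str
    gene: str
    copy_number: int
    cn_class: str
    mixed_flag: bool = False

    def __post_init__(self) -> None:
        if self.cn_class not in CN_CLASSES:
            raise ValueError(f"bad cn_class {self.cn_class!r}")


@dataclass
class TwoHitEvent:
    sample_id: str
    gene: str
    mechanism: str  # homozygous_deletion | mutation_plus_loss
    variant: object | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("homozygous_deletion", "mutation_plus_loss"):
            raise ValueError(f"bad mechanism {self.mechanism!r}")
        if self.mechanism == "mutation_plus_loss" and self.variant is None:
            raise ValueError("mutation_plus_loss requires a supporting variant")


def largest_transcript(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Pick one model per gene: the largest span, ties broken by the
    lexicographically smallest transcript id."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene)
        if (
            cur is None
            or m.span > cur.span
            or (m.span == cur.span and m.transcript < cur.transcript)
        ):
            best[m.gene] = m
    return best


def assign_gene_cn(
    segments: Sequence[CNSegment],
    gene_models: Sequence[GeneModel],
    diploid_baseline: int = 2,
    baselines: Mapping[str, int] | None = None,
) -> list[GeneCNState]:
    """Per sample x gene copy-number state from segment overlaps.

    Genes with no overlapping segment are neutral at the sample's
    baseline.  ``baselines`` overrides the baseline per sample (e.g. a
    tetraploid outlier).
    """
    baselines = baselines or {}
    chosen = largest_transcript(gene_models)
    by_sample: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)

    states = []
    for sample_id in sorted(by_sample):
        base = int(baselines.get(sample_id, diploid_baseline))
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in by_sample[sample_id]:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for gene in sorted(chosen):
            gm = chosen[gene]
            overlaps = [
                (interval_overlap(gm.start, gm.end, s.start, s.end), s)
                for s in by_chrom.get(gm.chrom, [])
            ]
            overlaps = [(o, s) for o, s in overlaps if o > 0]
            if not overlaps:
                states.append(GeneCNState(sample_id, gene, base, "neutral", False))
                continue
            # greatest overlap wins; deterministic tie-break on coordinates
            overlaps.sort(key=lambda t: (-t[0], t[1].start, t[1].end, t[1].copy_number))
            cn = overlaps[0][1].copy_number
            distinct = {s.copy_number for _, s in overlaps}
            klass = cn_class(cn, base)
            if any(s.copy_number == 0 for _, s in overlaps):
                klass = "homozygous_del"
            states.append(GeneCNState(sample_id, gene, cn, klass, len(distinct) > 1))
    return states


def call_two_hits(
    gene_cn_states: Sequence[GeneCNState],
    somatic_calls: Sequence[SomaticCall],
) -> list[TwoHitEvent]:
    """Biallelic inactivation events: homozygous deletions, and non-silent
    mutations on a hemizygous-deletion background.

    Two mutations in one gene without copy loss are NOT two-hit (phase
    unknown); use :func:`multi_mutated_genes` for that report.
    """
    calls_by = {}
    for c in somatic_calls:
        if c.record.gene is not None and c.record.non_silent:
            calls_by.setdefault((c.record.sample_id, c.record.gene), []).append(c)
    events = []
    for st in gene_cn_states:
        if st.cn_class == "homozygous_del":
            events.append(TwoHitEvent(st.sample_id, st.gene, "homozygous_deletion"))
        elif st.cn_class == "hemizygous_del":
            hits = calls_by.get((st.sample_id, st.gene))
            if hits:
                events.append(
                    TwoHitEvent(st.sample_id, st.gene, "mutation_plus_loss", hits[0])
                )
    return events


def multi_mutated_genes(somatic_calls: Sequence[SomaticCall]) -> pd.DataFrame:
    """Sample x gene pairs carrying >=2 non-silent somatic calls."""
    counts: dict[tuple[str, str], int] = {}
    for c in somatic_calls:
        if c.record.gene is not None and c.record.non_silent:
            key = (c.record.sample_id, c.record.gene)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"sample_id": s, "gene": g, "n_calls": n}
        for (s, g), n in sorted(counts.items())
        if n >= 2
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene", "n_calls"])


def burden_summary(
    somatic_calls: Sequence[SomaticCall],
    segments: Sequence[CNSegment],
    diploid_baseline: int = 2,
    baselines: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample alteration burden: somatic calls + altered segments."""
    baselines = baselines or {}
    samples = sorted(
        {c.record.sample_id for c in somatic_calls} | {s.sample_id for s in segments}
    )
    rows = []
    for sid in samples:
        n_var = sum(1 for c in somatic_calls if c.record.sample_id == sid)
        base = int(baselines.get(sid, diploid_baseline))
        n_cna = sum(
            1 for s in segments if s.sample_id == sid and s.copy_number != base
        )
        rows.append(
            {"sample_id": sid, "n_variants": n_var, "n_cna": n_cna, "total": n_var + n_cna}
        )
    return pd.DataFrame(rows)


def gene_cn_table(states: Sequence[GeneCNState]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "gene": s.gene,
                "copy_number": s.copy_number,
                "cn_class": s.cn_class,
                "mixed_flag": s.mixed_flag,
            }
            for s in states
        ],
        columns=["sample_id", "gene", "copy_number", "cn_class", "mixed_flag"],
    )


def two_hit_table(events: Sequence[TwoHitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "gene": e.gene,
                "mechanism": e.mechanism,
                "variant": (
                    None
                    if e.variant is None
                    else "{}:{}:{}>{}".format(*e.variant.record.key)
                ),
            }
            for e in events
        ],
        columns=["sample_id", "gene", "mechanism", "variant"],
    )
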