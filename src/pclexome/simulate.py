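"""Synthetic tumor-cohort generator with a full ground-truth channel.

Emulates the study design the pipeline targets: a dozen tumor exomes of
which a subset have matched normals, sequenced at ~40x; shared and private
germline polymorphisms (a small fraction absent from polymorphism
databases); clonal and sub-clonal somatic SNVs/indels whose trinucleotide
contexts are drawn from a two-signature mixture (aging-like NpCpG C>T and
APOBEC-like TpCpN C>T/C>G); copy-number segments including planted
hemizygous losses over mutated genes and homozygous deletions; and a
translocation-group-structured expression matrix with planted
differentially expressed genes.

The genome is a toy model (24 named chromosomes, ~500 genes with 1-3
transcripts each); read-level simulation is out of scope.  Every emitted
variant carries exactly one truth label, so each downstream stage can be
scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CNSegment, ExpressionMatrix, GeneModel, GeneSet, SampleMeta, VariantRecord
from .signatures import CONTEXT_LABELS, make_signature_profiles, revcomp
from . import io as pio

CHROMOSOMES = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X", "Y"])
CHROM_LENGTH = 5_000_000

LABEL_GERMLINE = "germline"
LABEL_CLONAL = "somatic_clonal"
LABEL_SUBCLONAL = "somatic_subclonal"

_GROUP_POOL = (
    ["t(14;16)"] * 4 + ["t(11;14)"] * 4 + ["t(4;14)"] * 2 + ["t(14;20)"] * 2
)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the target cohort: 12 tumors, 5 with matched normals,
    mean depth 42x, ~150 clonal non-silent somatic events per sample plus
    ~20 sub-clonal events in paired samples, 7% of somatic events indels.
    """

    n_tumors: int = 12
    n_paired: int = 5
    mean_depth: int = 42
    n_germline_per_sample: int = 1500
    n_somatic_clonal: int = 150
    n_somatic_subclonal: int = 20
    subclonal_ccf: float = 0.2
    signature_weights: dict[str, tuple[float, float]] | None = None
    indel_fraction: float = 0.07
    seed: int = 0
    # germline structure
    shared_germline_fraction: float = 0.5
    db_absent_fraction: float = 0.02
    purity: float = 0.9
    # silent somatic events (feed the spectrum, removed by the cascade)
    n_somatic_silent: int = 30
    # planted events
    n_twohit_mutloss_per_sample: int = 6
    n_homdel_total: int = 3
    n_cna_per_sample: int = 20
    n_recurrent_flagged: int = 2
    # expression
    n_genes: int = 500
    n_expr_background: int = 24
    n_de_genes: int = 40
    de_effect: float = 1.5
    n_group_genes: int = 60
    group_effect: float = 2.0
    n_variable_noise_genes: int = 150
    variable_noise_sd: float = 1.0
    expr_noise_sd: float = 0.35
    signature_concentration: float = 0.97

    def __post_init__(self) -> None:
        if self.n_paired > self.n_tumors:
            raise ValueError("n_paired cannot exceed n_tumors")
        for name in (
            "n_tumors", "n_paired", "mean_depth", "n_germline_per_sample",
            "n_somatic_clonal", "n_somatic_subclonal", "n_somatic_silent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.signature_weights is not None:
            for sid, (wa, wb) in self.signature_weights.items():
                if wa < 0 or wb < 0 or abs(wa + wb - 1.0) > 1e-9:
                    raise ValueError(f"signature weights of {sid} must be >=0 and sum to 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth against which every pipeline stage is scored."""

    variants: pd.DataFrame  # one row per emitted tumor variant
    signature_weights: dict[str, tuple[float, float]]
    two_hit: pd.DataFrame  # sample_id, gene, mechanism
    de_genes: pd.DataFrame  # gene, direction, effect
    group_genes: list[str]
    enriched_set: str
    recurrent_flagged_keys: list[tuple[str, int, str, str]]


@dataclass
class Cohort:
    """Everything one synthetic run emits, in memory."""

    config: SimConfig
    metadata: list[SampleMeta]
    variants: dict[str, list[VariantRecord]]  # tumors and controls
    segments: list[CNSegment]
    gene_models: list[GeneModel]
    gene_sets: list[GeneSet]
    expression: ExpressionMatrix
    truth: SyntheticTruth

    @property
    def tumors(self) -> list[SampleMeta]:
        return [m for m in self.metadata if m.role == "tumor"]

    @property
    def controls(self) -> dict[str, list[VariantRecord]]:
        return {
            m.sample_id: self.variants[m.sample_id]
            for m in self.metadata
            if m.role == "control"
        }


# ------------------------------------------------------------------ pieces


def _make_gene_models(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    models = []
    per_chrom = -(-config.n_genes // len(CHROMOSOMES))
    g = 0
    for chrom in CHROMOSOMES:
        cursor = 50_000
        for _ in range(per_chrom):
            if g >= config.n_genes:
                break
            span = int(rng.integers(10_000, 50_000))
            start = cursor + int(rng.integers(5_000, 20_000))
            end = start + span
            gene = f"GENE{g:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gene, "T1", chrom, start, end, strand))
            for t in range(int(rng.integers(0, 3))):
                sub_start = start + int(rng.integers(0, span // 4 + 1))
                sub_end = end - int(rng.integers(1, span // 4 + 1))
                if sub_end - sub_start < 100:
                    sub_end = sub_start + 100
                models.append(GeneModel(gene, f"T{t + 2}", chrom, sub_start, sub_end, strand))
            cursor = end
            g += 1
    return models


def _context_to_alleles(label: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """Turn a 96-class label into (ref, alt, context3) on a random strand."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    ctx = five + ref + three
    if rng.random() < 0.5:  # emit on the purine strand half the time
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return comp[ref], comp[alt], revcomp(ctx)
    return ref, alt, ctx


def _draw_indel(rng: np.random.Generator) -> tuple[str, str, str]:
    bases = "ACGT"
    b1 = bases[rng.integers(4)]
    b2 = bases[rng.integers(4)]
    if rng.random() < 0.5:
        return b1, b1 + b2, "insertion"
    return b1 + b2, b1, "deletion"


class _PositionAllocator:
    """Hands out unused (chrom, pos) pairs, optionally inside a gene."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def in_gene(self, gene: GeneModel) -> int:
        for _ in range(1000):
            pos = int(self.rng.integers(gene.start + 2, gene.end))  # 1-based, inside
            if (gene.chrom, pos) not in self.used:
                self.used.add((gene.chrom, pos))
                return pos
        raise RuntimeError(f"could not place a variant in {gene.gene}")

    def anywhere(self) -> tuple[str, int]:
        for _ in range(1000):
            chrom = CHROMOSOMES[self.rng.integers(len(CHROMOSOMES))]
            pos = int(self.rng.integers(2, CHROM_LENGTH))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("position space exhausted")


def _default_signature_weights(metadata: list[SampleMeta]) -> dict[str, tuple[float, float]]:
    """Group-linked defaults: t(14;16) tumors are APOBEC-driven, one
    t(11;14) tumor is purely aging-driven, the rest are admixtures."""
    weights = {}
    first_t1114 = True
    for m in metadata:
        if m.role != "tumor":
            continue
        if m.translocation_group == "t(14;16)":
            weights[m.sample_id] = (0.1, 0.9)
        elif m.translocation_group == "t(11;14)" and first_t1114:
            weights[m.sample_id] = (0.9, 0.1)
            first_t1114 = False
        else:
            weights[m.sample_id] = (0.6, 0.4)
    return weights


# ------------------------------------------------------------------- main


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    profiles = make_signature_profiles(config.signature_concentration)
    prof = {c: profiles[c].to_numpy() for c in profiles.columns}

    gene_models = _make_gene_models(config, rng)
    largest = {}
    for m in gene_models:
        if m.gene not in largest or m.span > largest[m.gene].span:
            largest[m.gene] = m
    gene_list = sorted(largest)

    # --- metadata
    metadata: list[SampleMeta] = []
    for i in range(config.n_tumors):
        group = _GROUP_POOL[i % len(_GROUP_POOL)]
        ctrl = f"CTRL-{i + 1:03d}" if i < config.n_paired else None
        metadata.append(
            SampleMeta(f"PCL-{i + 1:03d}", "tumor", ctrl, group, config.purity)
        )
    for i in range(config.n_paired):
        metadata.append(SampleMeta(f"CTRL-{i + 1:03d}", "control"))
    tumors = [m for m in metadata if m.role == "tumor"]

    weights = config.signature_weights or _default_signature_weights(metadata)

    alloc = _PositionAllocator(rng)
    depth = lambda: max(1, int(rng.poisson(config.mean_depth)))  # noqa: E731

    # --- germline site pool (shared across individuals)
    pool_size = max(1, int(config.n_germline_per_sample * config.shared_germline_fraction / 0.6))
    pool_sites = [_make_germline_site(config, rng, alloc, largest, gene_list) for _ in range(pool_size)]

    truth_rows = []
    variants: dict[str, list[VariantRecord]] = {m.sample_id: [] for m in metadata}

    for idx, tumor in enumerate(tumors):
        ctrl_id = tumor.matched_control_id
        # shared germline
        n_shared = int(rng.binomial(pool_size, 0.6))
        n_shared = min(n_shared, config.n_germline_per_sample)
        shared_idx = rng.choice(pool_size, size=n_shared, replace=False)
        sites = [pool_sites[j] for j in shared_idx]
        shared_flags = [True] * n_shared
        # private germline tops up to the exact per-sample total
        for _ in range(config.n_germline_per_sample - n_shared):
            sites.append(_make_germline_site(config, rng, alloc, largest, gene_list))
            shared_flags.append(False)
        for site, shared in zip(sites, shared_flags):
            hom = rng.random() < 1 / 3
            p = 1.0 if hom else 0.5
            rec = _site_to_record(tumor.sample_id, site, depth(), p, rng)
            variants[tumor.sample_id].append(rec)
            truth_rows.append(
                _truth_row(rec, LABEL_GERMLINE, "flat", private=not shared)
            )
            if ctrl_id is not None:
                variants[ctrl_id].append(_site_to_record(ctrl_id, site, depth(), p, rng))

    # --- planted two-hit genes (distinct chromosomes within each sample)
    two_hit_rows = []
    planted_segments: list[CNSegment] = []
    homdel_assignments = []
    enriched_genes: set[str] = set()
    mutated_gene_pool: list[str] = []

    all_gene_idx = rng.permutation(len(gene_list))
    gene_cursor = 0

    def next_gene_on_new_chrom(used_chroms: set[str]) -> GeneModel:
        nonlocal gene_cursor
        for _ in range(len(gene_list)):
            gene = gene_list[all_gene_idx[gene_cursor % len(gene_list)]]
            gene_cursor += 1
            gm = largest[gene]
            if gm.chrom not in used_chroms:
                used_chroms.add(gm.chrom)
                return gm
        raise RuntimeError("ran out of chromosomes for planted events")

    # cohort-wide homozygous deletions
    for j in range(config.n_homdel_total):
        t = tumors[int(rng.integers(len(tumors)))]
        homdel_assignments.append((t.sample_id, j))

    planted_chroms: dict[str, set[str]] = {t.sample_id: set() for t in tumors}
    for sid, _ in homdel_assignments:
        gm = next_gene_on_new_chrom(planted_chroms[sid])
        planted_segments.append(
            CNSegment(sid, gm.chrom, max(0, gm.start - 5000), gm.end + 5000, 0)
        )
        two_hit_rows.append({"sample_id": sid, "gene": gm.gene, "mechanism": "homozygous_deletion"})

    twohit_mut_plan: dict[str, list[GeneModel]] = {}
    for t in tumors:
        plan = []
        for _ in range(config.n_twohit_mutloss_per_sample):
            gm = next_gene_on_new_chrom(planted_chroms[t.sample_id])
            plan.append(gm)
            planted_segments.append(
                CNSegment(t.sample_id, gm.chrom, max(0, gm.start - 5000), gm.end + 5000, 1)
            )
            two_hit_rows.append(
                {"sample_id": t.sample_id, "gene": gm.gene, "mechanism": "mutation_plus_loss"}
            )
        twohit_mut_plan[t.sample_id] = plan

    # --- enriched pathway gene set (damaging-boosted)
    enriched_genes = set(
        gene_list[i] for i in rng.choice(len(gene_list), size=25, replace=False)
    )

    # --- somatic variants
    for tumor in tumors:
        wa, wb = weights[tumor.sample_id]
        p_clonal = 0.5 * config.purity
        planted = twohit_mut_plan[tumor.sample_id]
        for k in range(config.n_somatic_clonal):
            if k < len(planted):
                gm = planted[k]
                force_snv, force_clean = True, True
            else:
                gm = largest[gene_list[int(rng.integers(len(gene_list)))]]
                force_snv = force_clean = False
            rec, signature = _make_somatic_record(
                tumor.sample_id, gm, alloc, rng, config, prof, (wa, wb),
                depth(), p_clonal, silent=False, force_snv=force_snv,
                force_clean=force_clean, enriched=gm.gene in enriched_genes,
            )
            variants[tumor.sample_id].append(rec)
            truth_rows.append(_truth_row(rec, LABEL_CLONAL, signature))
            mutated_gene_pool.append(gm.gene)
        for _ in range(config.n_somatic_silent):
            gm = largest[gene_list[int(rng.integers(len(gene_list)))]]
            rec, signature = _make_somatic_record(
                tumor.sample_id, gm, alloc, rng, config, prof, (wa, wb),
                depth(), p_clonal, silent=True,
            )
            variants[tumor.sample_id].append(rec)
            truth_rows.append(_truth_row(rec, LABEL_CLONAL, signature))
        if tumor.matched_control_id is not None:
            p_sub = 0.5 * config.purity * config.subclonal_ccf
            for _ in range(config.n_somatic_subclonal):
                gm = largest[gene_list[int(rng.integers(len(gene_list)))]]
                rec, signature = _make_somatic_record(
                    tumor.sample_id, gm, alloc, rng, config, prof, (wa, wb),
                    depth(), p_sub, silent=False,
                    enriched=gm.gene in enriched_genes,
                )
                variants[tumor.sample_id].append(rec)
                truth_rows.append(_truth_row(rec, LABEL_SUBCLONAL, signature))
                mutated_gene_pool.append(gm.gene)

    # --- recurrent residual-germline variants shared by unpaired tumors
    recurrent_keys = []
    unpaired = [t for t in tumors if t.matched_control_id is None]
    if len(unpaired) >= 2:
        for _ in range(config.n_recurrent_flagged):
            gm = largest[gene_list[int(rng.integers(len(gene_list)))]]
            pos = alloc.in_gene(gm)
            label = CONTEXT_LABELS[int(rng.integers(96))]
            ref, alt, ctx = _context_to_alleles(label, rng)
            pair = rng.choice(len(unpaired), size=2, replace=False)
            recurrent_keys.append((gm.chrom, pos, ref, alt))
            for j in pair:
                t = unpaired[j]
                d = depth()
                rec = VariantRecord(
                    sample_id=t.sample_id, chrom=gm.chrom, pos=pos, ref=ref, alt=alt,
                    total_depth=d, alt_depth=max(1, int(rng.binomial(d, 0.5))),
                    variant_class="snv", consequence="missense", gene=gm.gene,
                    context3=ctx, in_polymorphism_db=True, in_cosmic=True,
                    cosmic_confirmed_somatic=False, in_clinvar=False, damaging=False,
                )
                variants[t.sample_id].append(rec)
                truth_rows.append(_truth_row(rec, LABEL_GERMLINE, "flat", private=True))

    # --- copy-number segments (fill to n_cna_per_sample on unused chroms)
    segments = list(planted_segments)
    for t in tumors:
        used = set(planted_chroms[t.sample_id])
        free = [c for c in CHROMOSOMES if c not in used]
        order = rng.permutation(len(free))
        n_fill = max(0, config.n_cna_per_sample - sum(1 for s in planted_segments if s.sample_id == t.sample_id))
        for j in range(min(n_fill, len(free))):
            chrom = free[order[j]]
            start = int(rng.integers(0, CHROM_LENGTH - 200_000))
            end = start + int(rng.integers(50_000, 200_000))
            cn = int(rng.choice([1, 1, 3, 3, 4]))
            segments.append(CNSegment(t.sample_id, chrom, start, end, cn))

    # --- gene sets
    gene_sets = [GeneSet("planted_enriched", frozenset(enriched_genes), "synthetic")]
    for j in range(3):
        members = frozenset(
            gene_list[i] for i in rng.choice(len(gene_list), size=30, replace=False)
        )
        gene_sets.append(GeneSet(f"random_set_{j + 1}", members, "synthetic"))

    # --- expression matrix with planted group structure and DE genes
    expression, de_df, group_genes = _make_expression(
        config, rng, gene_list, sorted(set(mutated_gene_pool)), metadata
    )

    truth = SyntheticTruth(
        variants=pd.DataFrame(truth_rows),
        signature_weights=weights,
        two_hit=pd.DataFrame(two_hit_rows),
        de_genes=de_df,
        group_genes=group_genes,
        enriched_set="planted_enriched",
        recurrent_flagged_keys=recurrent_keys,
    )
    return Cohort(config, metadata, variants, segments, gene_models, gene_sets, expression, truth)


def _make_germline_site(config, rng, alloc, largest, gene_list) -> dict:
    r = rng.random()
    if r < 0.5:
        consequence, gene, in_gene = "noncoding", None, False
    elif r < 0.7:
        consequence, gene, in_gene = "synonymous", gene_list[int(rng.integers(len(gene_list)))], True
    else:
        consequence, gene, in_gene = "missense", gene_list[int(rng.integers(len(gene_list)))], True
    if in_gene:
        gm = largest[gene]
        chrom, pos = gm.chrom, alloc.in_gene(gm)
    else:
        chrom, pos = alloc.anywhere()
    if rng.random() < config.indel_fraction:
        ref, alt, vclass = _draw_indel(rng)
        ctx = None
        if consequence == "missense":
            consequence = "frameshift" if (len(ref) - len(alt)) % 3 else "inframe_indel"
    else:
        label = CONTEXT_LABELS[int(rng.integers(96))]
        ref, alt, ctx = _context_to_alleles(label, rng)
        vclass = "snv"
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "variant_class": vclass, "consequence": consequence, "gene": gene,
        "context3": ctx, "db": rng.random() >= config.db_absent_fraction,
    }


def _site_to_record(sample_id, site, total_depth, p, rng) -> VariantRecord:
    alt_depth = max(1, int(rng.binomial(total_depth, p)))
    alt_depth = min(alt_depth, total_depth)
    return VariantRecord(
        sample_id=sample_id, chrom=site["chrom"], pos=site["pos"],
        ref=site["ref"], alt=site["alt"], total_depth=total_depth,
        alt_depth=alt_depth, variant_class=site["variant_class"],
        consequence=site["consequence"], gene=site["gene"],
        context3=site["context3"], in_polymorphism_db=site["db"],
    )


def _make_somatic_record(
    sample_id, gm, alloc, rng, config, prof, w, total_depth, p,
    silent=False, force_snv=False, force_clean=False, enriched=False,
):
    pos = alloc.in_gene(gm)
    is_indel = (not force_snv) and (not silent) and rng.random() < config.indel_fraction
    if is_indel:
        ref, alt, vclass = _draw_indel(rng)
        ctx, signature = None, "flat"
        consequence = "frameshift" if rng.random() < 0.8 else "inframe_indel"
        damaging = consequence == "frameshift"
    else:
        wa, wb = w
        signature = "aging" if rng.random() < wa else "apobec"
        label = CONTEXT_LABELS[int(rng.choice(96, p=prof[signature]))]
        ref, alt, ctx = _context_to_alleles(label, rng)
        vclass = "snv"
        if silent:
            consequence = "synonymous" if rng.random() < 0.7 else "noncoding"
            damaging = False
        else:
            r = rng.random()
            consequence = "missense" if r < 0.88 else ("nonsense" if r < 0.95 else "splice_site")
            if consequence == "nonsense":
                damaging = True
            else:
                damaging = rng.random() < (0.8 if enriched else 0.25)
    if force_clean:
        db = cosmic = confirmed = clinvar = False
    else:
        db = rng.random() < 0.01
        cosmic = rng.random() < 0.05
        confirmed = cosmic and rng.random() < 0.6
        clinvar = False
    alt_depth = min(max(1, int(rng.binomial(total_depth, p))), total_depth)
    rec = VariantRecord(
        sample_id=sample_id, chrom=gm.chrom, pos=pos, ref=ref, alt=alt,
        total_depth=total_depth, alt_depth=alt_depth, variant_class=vclass,
        consequence=consequence, gene=None if consequence == "noncoding" else gm.gene,
        context3=ctx, in_polymorphism_db=db, in_cosmic=cosmic,
        cosmic_confirmed_somatic=confirmed, in_clinvar=clinvar, damaging=damaging,
    )
    return rec, signature


def _truth_row(rec: VariantRecord, label: str, signature: str, private: bool = False) -> dict:
    return {
        "sample_id": rec.sample_id, "chrom": rec.chrom, "pos": rec.pos,
        "ref": rec.ref, "alt": rec.alt, "label": label, "signature": signature,
        "consequence": rec.consequence, "gene": rec.gene,
        "in_polymorphism_db": rec.in_polymorphism_db, "private": private,
    }


def _make_expression(config, rng, gene_list, mutated_genes, metadata):
    tumor_ids = [m.sample_id for m in metadata if m.role == "tumor"]
    mm_ids = [f"MM-{i + 1:03d}" for i in range(config.n_expr_background)]
    samples = tumor_ids + mm_ids
    groups = {m.sample_id: m.translocation_group for m in metadata if m.role == "tumor"}
    for i, sid in enumerate(mm_ids):
        groups[sid] = _GROUP_POOL[i % len(_GROUP_POOL)]

    baseline = rng.normal(8.0, 1.5, size=len(gene_list))
    values = baseline[:, None] + rng.normal(0.0, config.expr_noise_sd, size=(len(gene_list), len(samples)))
    df = pd.DataFrame(values, index=gene_list, columns=samples)

    pool = [g for g in mutated_genes if g in set(gene_list)] or list(gene_list)
    order = rng.permutation(len(pool))
    n_group = min(config.n_group_genes, len(pool))
    group_genes = [pool[i] for i in order[:n_group]]
    rest = [pool[i] for i in order[n_group:]]
    n_de = min(config.n_de_genes, len(rest))
    de_genes = rest[:n_de]

    # a tier of strongly variable but unstructured genes, so variability
    # selection is a real filter rather than a pass-through
    taken = set(group_genes) | set(de_genes)
    free = [g for g in gene_list if g not in taken]
    free_order = rng.permutation(len(free))
    noisy = [free[i] for i in free_order[: config.n_variable_noise_genes]]
    for gene in noisy:
        df.loc[gene] += rng.normal(0.0, config.variable_noise_sd, size=len(samples))

    group_names = sorted({g for g in groups.values() if g})
    for gene in group_genes:
        offsets = {grp: rng.normal(0.0, config.group_effect) for grp in group_names}
        for sid in samples:
            grp = groups.get(sid)
            if grp:
                df.loc[gene, sid] += offsets[grp]

    de_rows = []
    for j, gene in enumerate(de_genes):
        direction = "up" if j % 2 == 0 else "down"
        delta = config.de_effect if direction == "up" else -config.de_effect
        df.loc[gene, tumor_ids] += delta
        de_rows.append({"gene": gene, "direction": direction, "effect": delta})

    labels = {
        sid: {
            "disease_class": "pPCL" if sid in tumor_ids else "MM",
            "translocation_group": groups.get(sid),
        }
        for sid in samples
    }
    matrix = ExpressionMatrix(df.round(4), labels)
    return matrix, pd.DataFrame(de_rows), group_genes


def simulate_expression_matrix(
    n_genes: int, n_a: int, n_b: int, n_de: int, effect: float = 1.5,
    noise_sd: float = 1.0, seed: int = 0,
):
    """Standalone two-class expression simulator for differential-expression
    scoring: class A samples get +/-``effect`` (log2) on ``n_de`` planted
    genes.  Returns (ExpressionMatrix, truth DataFrame)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    baseline = rng.normal(8.0, 1.5, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_a + n_b))
    df = pd.DataFrame(values, index=genes, columns=samples)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    rows = []
    for j, gi in enumerate(de_idx):
        direction = "up" if j % 2 == 0 else "down"
        delta = effect if direction == "up" else -effect
        df.iloc[gi, :n_a] += delta
        rows.append({"gene": genes[gi], "direction": direction, "effect": delta})
    labels = {s: {"disease_class": "A" if s.startswith("A") else "B"} for s in samples}
    return ExpressionMatrix(df, labels), pd.DataFrame(rows)


# ------------------------------------------------------------------- files


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Emit every external format plus the truth channel (truth.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "segments": outdir / "segments.bed",
        "genes": outdir / "genes.bed",
        "gene_sets": outdir / "pathways.gmt",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    all_records = [r for sid in sorted(cohort.variants) for r in cohort.variants[sid]]
    pio.write_variants(all_records, paths["variants"])
    pio.write_segments(cohort.segments, paths["segments"])
    pio.write_gene_models(cohort.gene_models, paths["genes"])
    pio.write_gene_sets(cohort.gene_sets, paths["gene_sets"])
    pio.write_expression(cohort.expression, paths["expression"])
    pio.write_sample_metadata(cohort.metadata, paths["metadata"])
    cohort.truth.variants.to_csv(paths["truth"], sep="\t", index=False)
    return paths
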