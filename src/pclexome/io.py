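"""Readers and writers for every external format the pipeline touches.

Variants travel as VCF 4.x (annotation flags in INFO, depths in FORMAT) or
as a flat TSV; copy-number segments and gene models are BED-like 0-based
half-open; gene sets are GMT; expression and sample metadata are TSV.
Every reader/writer pair round-trips field-for-field.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd
import pysam

from .model import (
    CNSegment,
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    SampleMeta,
    VariantRecord,
)

MISSING = "."

_VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "consequence",
    "gene",
    "context3",
    "total_depth",
    "alt_depth",
    "in_polymorphism_db",
    "in_cosmic",
    "cosmic_confirmed_somatic",
    "in_clinvar",
    "damaging",
]
_BOOL_COLUMNS = [
    "in_polymorphism_db",
    "in_cosmic",
    "cosmic_confirmed_somatic",
    "in_clinvar",
    "damaging",
]

_VCF_INFO = [
    ("POLYDB", 0, "Flag", "Present in dbSNP/1000G/ESP polymorphism databases"),
    ("COSMIC", 0, "Flag", "Present in COSMIC"),
    ("COSMIC_SOM", 0, "Flag", "Confirmed somatic in COSMIC"),
    ("CLINVAR", 0, "Flag", "Present in ClinVar"),
    ("DMG", 0, "Flag", "Predicted damaging"),
    ("GENE", 1, "String", "Gene symbol"),
    ("CSQ", 1, "String", "Coding consequence"),
    ("CTX", 1, "String", "Trinucleotide reference context"),
]


# ---------------------------------------------------------------- variants


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variant records from a TSV or VCF file.

    Multi-allelic VCF sites are split into one record per sample x allele;
    coordinates stay 1-based.
    """
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variants(
    records: Iterable[VariantRecord], path: str | Path, dialect: str = "tsv"
) -> None:
    records = list(records)
    if dialect == "tsv":
        _write_variants_tsv(records, path)
    elif dialect == "vcf":
        _write_variants_vcf(records, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_VARIANT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    VariantRecord(
                        sample_id=row["sample_id"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        variant_class=row["variant_class"],
                        consequence=row["consequence"],
                        gene=None if row["gene"] == MISSING else row["gene"],
                        context3=None if row["context3"] == MISSING else row["context3"],
                        total_depth=int(row["total_depth"]),
                        alt_depth=int(row["alt_depth"]),
                        **{c: row[c] == "1" for c in _BOOL_COLUMNS},
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


def _write_variants_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.variant_class,
                    r.consequence,
                    r.gene if r.gene is not None else MISSING,
                    r.context3 if r.context3 is not None else MISSING,
                    r.total_depth,
                    r.alt_depth,
                ]
                + ["1" if getattr(r, c) else "0" for c in _BOOL_COLUMNS]
            )


def _infer_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    return "insertion" if len(alt) > len(ref) else "deletion"


def _read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for site in vf:
            info = dict(site.info)  # only keys present on the record
            alts = site.alts or ()
            for sample in samples:
                fmt = site.samples[sample]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                if dp is None or ad is None:
                    raise ValueError(
                        f"{path}: {site.chrom}:{site.pos} sample {sample}: "
                        "missing DP/AD depth fields"
                    )
                for i, alt in enumerate(alts):
                    records.append(
                        VariantRecord(
                            sample_id=sample,
                            chrom=site.chrom,
                            pos=site.pos,
                            ref=site.ref,
                            alt=alt,
                            variant_class=_infer_class(site.ref, alt),
                            consequence=info.get("CSQ", "noncoding"),
                            gene=info.get("GENE"),
                            context3=info.get("CTX"),
                            total_depth=int(dp),
                            alt_depth=int(ad[i + 1]),
                            in_polymorphism_db="POLYDB" in info,
                            in_cosmic="COSMIC" in info,
                            cosmic_confirmed_somatic="COSMIC_SOM" in info,
                            in_clinvar="CLINVAR" in info,
                            damaging="DMG" in info,
                        )
                    )
    return records


def _write_variants_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(
            "VCF dialect writes one sample per file; use the TSV dialect "
            f"for multi-sample tables (got samples {sorted(samples)})"
        )
    header = pysam.VariantHeader()
    for chrom in sorted({r.chrom for r in records}):
        length = max(r.pos for r in records if r.chrom == chrom) + 1000
        header.contigs.add(chrom, length=length)
    for name, number, typ, desc in _VCF_INFO:
        header.info.add(name, number, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    sample = next(iter(samples)) if samples else "SAMPLE"
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            site = vf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            site.info["CSQ"] = r.consequence
            if r.gene is not None:
                site.info["GENE"] = r.gene
            if r.context3 is not None:
                site.info["CTX"] = r.context3
            for flag, attr in [
                ("POLYDB", "in_polymorphism_db"),
                ("COSMIC", "in_cosmic"),
                ("COSMIC_SOM", "cosmic_confirmed_somatic"),
                ("CLINVAR", "in_clinvar"),
                ("DMG", "damaging"),
            ]:
                if getattr(r, attr):
                    site.info[flag] = True
            fmt = site.samples[sample]
            fmt["GT"] = (0, 1)
            fmt["DP"] = r.total_depth
            fmt["AD"] = (r.total_depth - r.alt_depth, r.alt_depth)
            vf.write(site)


# ------------------------------------------------------ segments and genes


def read_segments(path: str | Path, sample_id: str | None = None) -> list[CNSegment]:
    """Read copy-number segments from a BED-like file.

    Accepts 4 columns (chrom, start, end, CN — requires ``sample_id``) or
    5 columns (…, sample).  Overlapping segments of one sample on one
    chromosome are rejected.
    """
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 BED columns")
            sid = fields[4] if len(fields) >= 5 else sample_id
            if sid is None:
                raise ValueError(
                    f"{path}: line {lineno}: 4-column BED requires sample_id argument"
                )
            try:
                segments.append(
                    CNSegment(sid, fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    _check_segment_overlaps(segments, path)
    return segments


def _check_segment_overlaps(segments: Sequence[CNSegment], path) -> None:
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    offenders = []
    for (sid, chrom), segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                offenders.append(f"{sid} {chrom}:{a.start}-{a.end} vs {b.start}-{b.end}")
    if offenders:
        raise ValueError(f"{path}: overlapping same-sample segments: {offenders}")


def write_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\t{s.sample_id}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 with name field ``gene|transcript``.

    All transcripts are retained; largest-transcript selection happens in
    the copy-number integration step.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns")
            if "|" not in fields[3]:
                raise ValueError(
                    f"{path}: line {lineno}: name field must be 'gene|transcript'"
                )
            gene, transcript = fields[3].split("|", 1)
            models.append(
                GeneModel(gene, transcript, fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene}|{m.transcript}\t0\t{m.strand}\n"
            )


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, source, genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs name, source, >=1 gene")
            sets.append(GeneSet(fields[0], frozenset(fields[2:]), fields[1]))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source] + sorted(s.genes)) + "\n")


# ----------------------------------------------------- expression/metadata


def read_expression(
    path: str | Path, metadata: Sequence[SampleMeta] | None = None
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = {}
    if metadata is not None:
        labels = {
            m.sample_id: {"translocation_group": m.translocation_group, "role": m.role}
            for m in metadata
        }
    return ExpressionMatrix(df, labels)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                role=row["role"],
                matched_control_id=(
                    None
                    if pd.isna(row["matched_control_id"]) or row["matched_control_id"] == MISSING
                    else row["matched_control_id"]
                ),
                translocation_group=(
                    None
                    if pd.isna(row["translocation_group"]) or row["translocation_group"] == MISSING
                    else row["translocation_group"]
                ),
                purity=float(row["purity"]),
            )
        )
    return metas


def write_sample_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "role": m.role,
            "matched_control_id": m.matched_control_id or MISSING,
            "translocation_group": m.translocation_group or MISSING,
            "purity": m.purity,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
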