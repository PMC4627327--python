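"""End-to-end orchestration: filtering -> signatures -> CN integration ->
recurrence/enrichment -> expression, from one config, with a manifest.

Every stage writes a TSV into the output directory; ``manifest.json``
records the package version, seed, parameter values and a SHA-256 hash of
every output file, so identical config + seed reproduces an identical
bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .model import SampleMeta
from .filtering import (
    CascadeParams,
    carryover_audit,
    flag_unconfirmed_recurrent,
    run_cascade,
    spectrum_input,
)
from .signatures import (
    build_spectrum,
    cohort_signature_report,
    decompose,
    make_signature_profiles,
    read_signature_matrix,
)
from .cna import (
    assign_gene_cn,
    burden_summary,
    call_two_hits,
    gene_cn_table,
    multi_mutated_genes,
    two_hit_table,
)
from .enrichment import enrich_gene_sets, gene_recurrence, load_spurious_genes, recurrence_table
from .expression import (
    bhi,
    differential_expression,
    group_association,
    hcluster,
    replication_probability,
    select_variable_genes,
)

log = logging.getLogger("pclexome")


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run (YAML-loadable)."""

    variants: str
    metadata: str
    outdir: str
    segments: str | None = None
    genes: str | None = None
    gene_sets: str | None = None
    expression: str | None = None
    signature_matrix: str | None = None
    # stage parameters
    min_depth: int = 10
    min_control_depth: int = 10
    alpha: float = 0.05
    ccf_threshold: float = 0.5
    distinct_threshold: float = 0.7
    fold: float = 2.0
    k: int = 4
    B_enrich: int = 100_000
    B_assoc: int = 10_000
    B_replication: int = 1000
    seed: int = 7
    baselines: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cascade_params(self) -> CascadeParams:
        return CascadeParams(self.min_depth, self.min_control_depth, self.alpha, self.ccf_threshold)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns the output-file map."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    log.info("pclexome %s starting; seed=%d", __version__, config.seed)

    metadata = pio.read_sample_metadata(config.metadata)
    all_records = pio.read_variants(config.variants, "tsv")
    by_sample: dict[str, list] = {}
    for r in all_records:
        by_sample.setdefault(r.sample_id, []).append(r)
    for m in metadata:
        by_sample.setdefault(m.sample_id, [])

    outputs: dict[str, Path] = {}
    params = config.cascade_params()
    tumors = [m for m in metadata if m.role == "tumor"]
    controls = {m.sample_id: by_sample[m.sample_id] for m in metadata if m.role == "control"}
    pooled = [r for recs in controls.values() for r in recs]

    # ---- filtering
    all_calls, funnels = [], []
    for m in tumors:
        stage_t = time.time()
        if m.matched_control_id is not None:
            if m.matched_control_id not in controls:
                raise ValueError(
                    f"filtering [{m.sample_id}]: matched control "
                    f"{m.matched_control_id} has no variants"
                )
            calls, funnel = run_cascade(
                by_sample[m.sample_id], controls[m.matched_control_id],
                "paired", m.purity, params,
            )
        elif pooled:
            calls, funnel = run_cascade(by_sample[m.sample_id], pooled, "unpaired", m.purity, params)
        else:
            log.warning(
                "filtering [%s]: no controls available; skipping control subtraction",
                m.sample_id,
            )
            calls, funnel = run_cascade(
                by_sample[m.sample_id], [], "unpaired", m.purity, params,
                allow_no_controls=True,
            )
        all_calls.extend(calls)
        f = funnel.to_frame()
        f.insert(0, "sample_id", m.sample_id)
        funnels.append(f)
        log.info("filtering [%s]: %d calls (%.2fs)", m.sample_id, len(calls), time.time() - stage_t)
    all_calls = flag_unconfirmed_recurrent(all_calls)
    outputs["funnel"] = _write(pd.concat(funnels, ignore_index=True), outdir / "funnel.tsv")
    outputs["calls"] = _write(_calls_frame(all_calls), outdir / "calls.tsv")

    paired = [m for m in tumors if m.matched_control_id]
    if paired and pooled:
        outputs["carryover"] = _write(
            carryover_audit(by_sample, metadata, params), outdir / "carryover.tsv"
        )

    # ---- mutational signatures
    if config.signature_matrix:
        signature_matrix = read_signature_matrix(config.signature_matrix)
    else:
        signature_matrix = make_signature_profiles()
    spectra, exposures = [], []
    for m in tumors:
        ctrl = (
            controls[m.matched_control_id]
            if m.matched_control_id is not None and m.matched_control_id in controls
            else pooled
        )
        recs = spectrum_input(by_sample[m.sample_id], ctrl, params)
        spectrum = build_spectrum(recs, m.sample_id)
        spectra.append(spectrum)
        if spectrum.counts96.sum() > 0:
            exposures.append(decompose(spectrum, signature_matrix, config.distinct_threshold))
    outputs["signatures"] = _write(
        cohort_signature_report(spectra, exposures, metadata), outdir / "signatures.tsv"
    )
    log.info("signatures: %d samples decomposed", len(exposures))

    # ---- copy-number integration
    if config.segments and config.genes:
        segments = pio.read_segments(config.segments)
        gene_models = pio.read_gene_models(config.genes)
        states = assign_gene_cn(segments, gene_models, baselines=config.baselines)
        events = call_two_hits(states, all_calls)
        outputs["gene_cn"] = _write(gene_cn_table(states), outdir / "gene_cn.tsv")
        outputs["two_hits"] = _write(two_hit_table(events), outdir / "two_hits.tsv")
        outputs["multi_mutated"] = _write(multi_mutated_genes(all_calls), outdir / "multi_mutated.tsv")
        outputs["burden"] = _write(
            burden_summary(all_calls, segments, baselines=config.baselines), outdir / "burden.tsv"
        )
        log.info("cna integration: %d two-hit events", len(events))

    # ---- recurrence and enrichment
    spurious = load_spurious_genes()
    recs = gene_recurrence(all_calls, spurious)
    outputs["recurrence"] = _write(recurrence_table(recs), outdir / "recurrence.tsv")
    if config.gene_sets:
        gene_sets = pio.read_gene_sets(config.gene_sets)
        outputs["enrichment"] = _write(
            enrich_gene_sets(all_calls, gene_sets, config.B_enrich, config.seed, spurious),
            outdir / "enrichment.tsv",
        )
        log.info("enrichment: %d gene sets tested", len(gene_sets))

    # ---- expression integration
    if config.expression:
        matrix = pio.read_expression(config.expression, metadata)
        mutated = sorted(
            {c.record.gene for c in all_calls if c.record.gene is not None}
            & set(matrix.genes)
        )
        variable = select_variable_genes(matrix, config.fold)
        focal = sorted(set(mutated) & set(variable))
        groups = {
            s: (matrix.sample_labels.get(s) or {}).get("translocation_group")
            for s in matrix.samples
        }
        expr_rows = {"n_mutated": len(mutated), "n_variable": len(variable), "n_focal": len(focal)}
        if len(focal) >= 2:
            result = hcluster(matrix, focal, config.k)
            assoc = group_association(result.labels, groups, config.B_assoc, config.seed)
            outputs["clusters"] = _write(
                pd.DataFrame(
                    {"sample_id": list(result.labels), "cluster": list(result.labels.values())}
                ),
                outdir / "clusters.tsv",
            )
            outputs["association"] = _write(
                pd.DataFrame(
                    [{"group": g, "p": p} for g, p in assoc.items()]
                ),
                outdir / "association.tsv",
            )
            expr_rows["bhi"] = bhi(result.labels, groups)
            if len(variable) > len(focal):
                expr_rows["replication_p"] = replication_probability(
                    matrix, variable, focal, config.k, config.B_replication, config.seed, groups
                )
        classes = {
            s: (matrix.sample_labels.get(s) or {}).get("disease_class") for s in matrix.samples
        }
        class_a = [s for s, c in classes.items() if c == "pPCL"]
        class_b = [s for s, c in classes.items() if c == "MM"]
        if len(class_a) >= 3 and len(class_b) >= 3 and mutated:
            sub = pio.read_expression(config.expression, metadata)
            sub.values = sub.values.loc[mutated]
            deg = differential_expression(sub, class_a, class_b)
            outputs["deg"] = _write(deg.reset_index(), outdir / "deg.tsv")
            expr_rows["n_deg"] = int(deg["significant"].sum())
        outputs["expression_summary"] = _write(
            pd.DataFrame([expr_rows]), outdir / "expression_summary.tsv"
        )
        log.info("expression: %s", expr_rows)

    # ---- manifest
    manifest = {
        "package": "pclexome",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (dict,)) or v
        },
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
        "runtime_seconds": round(time.time() - t0, 2),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    outputs["manifest"] = manifest_path
    log.info("done in %.1fs; %d outputs", time.time() - t0, len(outputs))
    return outputs


def _calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        r = c.record
        rows.append(
            {
                "sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos,
                "ref": r.ref, "alt": r.alt, "gene": r.gene,
                "variant_class": r.variant_class, "consequence": r.consequence,
                "vaf": round(r.vaf, 4), "clonality": c.clonality, "mode": c.mode,
                "germline_risk_flag": c.germline_risk_flag,
                "damaging": r.damaging,
            }
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(stream)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
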