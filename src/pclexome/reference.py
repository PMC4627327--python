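"""Published per-sample somatic-variant counts for the reference cohort.

A transcription of the printed per-sample counts of a 12-tumor pPCL
whole-exome series (somatic and somatic sub-clonal non-synonymous SNVs
and indels) plus the cohort-level class decomposition (1,831 non-syn
SNVs, 90 indels, 7 splice-site variants).  These are inputs for summary
arithmetic, not outputs of this package's pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_cohort_counts() -> pd.DataFrame:
    """Per-sample counts table, one row per tumor."""
    with resources.files("pclexome").joinpath("data", "cohort_variant_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_class_totals() -> pd.DataFrame:
    """Cohort-level counts by variant class."""
    with resources.files("pclexome").joinpath("data", "cohort_class_totals.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_count_summary() -> dict:
    """Summary arithmetic over the reference counts.

    Means are over the clonal ("somatic") columns; totals include
    sub-clonal calls; the class decomposition sums non-syn SNVs, indels
    and splice-site variants cohort-wide.
    """
    counts = load_reference_cohort_counts()
    classes = load_reference_class_totals()
    i_max = counts["total"].idxmax()
    i_min = counts["total"].idxmin()
    return {
        "n_samples": int(len(counts)),
        "mean_somatic_snv": float(counts["somatic_snv"].mean()),
        "mean_somatic_indel": float(counts["somatic_indel"].mean()),
        "max_total": int(counts.loc[i_max, "total"]),
        "max_total_sample": str(counts.loc[i_max, "sample_id"]),
        "min_total": int(counts.loc[i_min, "total"]),
        "min_total_sample": str(counts.loc[i_min, "sample_id"]),
        "class_total": int(classes["count"].sum()),
        "mean_total_variants": float(counts["total"].mean()),
    }
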