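"""Gene recurrence and pathway enrichment for damaging variants.

Recurrence counts de-duplicate identical flagged variants (possible
residual germline recurring across unpaired samples count once, so their
genes are not over-scored) and mark genes on a user-replaceable
"spurious" list — genes frequently mutated in cancer surveys for reasons
unrelated to tumor biology (gene size, late replication) — which are
retained in the table but excluded from enrichment.

Pathway enrichment is a one-sided Fisher exact test on the 2x2 table
{damaging, non-damaging} x {in-set, out-of-set} over variant calls, with
the tail probability computed by direct hypergeometric summation, plus a
resampling null: draw the same number of calls without replacement and
compare the damaging fraction.  Multiplicity is handled by
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GeneSet
from .filtering import SomaticCall, normalize_key


@dataclass
class GeneRecurrence:
    gene: str
    n_samples: int
    n_variants: int
    n_snv: int
    n_indel: int
    dedup_applied: bool = False
    spurious_flag: bool = False


@dataclass
class EnrichmentResult:
    name: str
    a: int  # damaging, in set
    b: int  # non-damaging, in set
    c: int  # damaging, out of set
    d: int  # non-damaging, out of set
    odds_ratio: float | None
    p_fisher: float
    p_resample: float | None = None
    q_value: float | None = None


def load_spurious_genes() -> frozenset[str]:
    """The packaged spurious-gene list (editable text, one symbol/line)."""
    text = resources.files("pclexome").joinpath("data", "spurious_genes.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def gene_recurrence(
    calls: Sequence[SomaticCall],
    spurious_list: Iterable[str] = (),
    dedup: bool = True,
) -> list[GeneRecurrence]:
    """Per-gene recurrence across the cohort.

    A variant identity shared by several samples with
    ``germline_risk_flag`` contributes once (not k times) to its gene's
    variant count when ``dedup`` is on.
    """
    spurious = set(spurious_list)
    by_gene: dict[str, list[SomaticCall]] = {}
    for c in calls:
        if c.record.gene is not None:
            by_gene.setdefault(c.record.gene, []).append(c)
    out = []
    for gene in sorted(by_gene):
        gcalls = by_gene[gene]
        samples = {c.record.sample_id for c in gcalls}
        n_variants = n_snv = n_indel = 0
        dedup_applied = False
        seen_flagged: set[tuple] = set()
        for c in gcalls:
            key = normalize_key(*c.record.key)
            if dedup and c.germline_risk_flag:
                if key in seen_flagged:
                    dedup_applied = True
                    continue
                seen_flagged.add(key)
            n_variants += 1
            if c.record.variant_class == "snv":
                n_snv += 1
            else:
                n_indel += 1
        out.append(
            GeneRecurrence(
                gene, len(samples), n_variants, n_snv, n_indel,
                dedup_applied, gene in spurious,
            )
        )
    return out


def recurrence_table(recs: Sequence[GeneRecurrence]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in recs])
    if not df.empty:
        df = df.sort_values(["n_samples", "n_variants", "gene"], ascending=[False, False, True])
    return df.reset_index(drop=True)


# ------------------------------------------------------------- Fisher test


def hypergeom_tail(a: int, row1: int, col1: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeom(n, col1, row1), by direct summation.

    ``row1`` items are drawn from ``n`` of which ``col1`` are marked; the
    tail sums the point probabilities from ``a`` upward in log space.
    """
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if a > hi:
        return 0.0

    def logpmf(k: int) -> float:
        return (
            _lchoose(col1, k)
            + _lchoose(n - col1, row1 - k)
            - _lchoose(n, row1)
        )

    total = sum(math.exp(logpmf(k)) for k in range(max(a, lo), hi + 1))
    return min(1.0, total)


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_damaging(
    calls: Sequence[SomaticCall],
    gene_set: GeneSet,
    spurious: Iterable[str] = (),
) -> EnrichmentResult:
    """One-sided Fisher exact test for damaging-variant enrichment in a
    gene set, over all non-silent calls in genes (spurious excluded)."""
    spurious = set(spurious)
    usable = [
        c
        for c in calls
        if c.record.gene is not None
        and c.record.non_silent
        and c.record.gene not in spurious
    ]
    in_set = [c for c in usable if c.record.gene in gene_set.genes]
    out_set = [c for c in usable if c.record.gene not in gene_set.genes]
    a = sum(1 for c in in_set if c.record.damaging)
    b = len(in_set) - a
    c_ = sum(1 for c in out_set if c.record.damaging)
    d = len(out_set) - c_
    n = a + b + c_ + d
    row1, col1 = a + b, a + c_
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        p = 1.0
        odds = None
    else:
        p = hypergeom_tail(a, row1, col1, n)
        odds = (a * d) / (b * c_) if b and c_ else None
    return EnrichmentResult(gene_set.name, a, b, c_, d, odds, p)


def resample_damaging(
    calls: Sequence[SomaticCall],
    gene_set: GeneSet,
    B: int = 100_000,
    seed: int = 0,
    spurious: Iterable[str] = (),
) -> float:
    """Resampling null for the damaging fraction in a gene set.

    Draws B subsets of m calls (m = calls in the set) without replacement
    from all usable calls and returns the add-one probability of seeing a
    damaging fraction at least as large as observed.  The damaging count
    of such a draw is Hypergeometric(n, d, m), which is sampled directly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    spurious = set(spurious)
    usable = [
        c
        for c in calls
        if c.record.gene is not None
        and c.record.non_silent
        and c.record.gene not in spurious
    ]
    in_set = [c for c in usable if c.record.gene in gene_set.genes]
    m = len(in_set)
    if m == 0:
        raise ValueError("empty pathway intersection")
    n = len(usable)
    d = sum(1 for c in usable if c.record.damaging)
    k_obs = sum(1 for c in in_set if c.record.damaging)
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(d, n - d, m, size=B)
    return float((1 + int((draws >= k_obs).sum())) / (B + 1))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich_gene_sets(
    calls: Sequence[SomaticCall],
    gene_sets: Sequence[GeneSet],
    B: int = 100_000,
    seed: int = 0,
    spurious: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fisher + resampling enrichment over a gene-set catalog, BH-adjusted."""
    spurious = load_spurious_genes() if spurious is None else set(spurious)
    results = []
    for i, gs in enumerate(gene_sets):
        res = fisher_damaging(calls, gs, spurious)
        try:
            res.p_resample = resample_damaging(calls, gs, B, seed + i, spurious)
        except ValueError:
            res.p_resample = None
        results.append(res)
    qs = bh_adjust([r.p_fisher for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return pd.DataFrame(
        [
            {
                "set": r.name, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio, "p_fisher": r.p_fisher,
                "p_resample": r.p_resample, "q_value": r.q_value,
            }
            for r in results
        ]
    )
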