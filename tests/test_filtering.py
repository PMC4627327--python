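"""Filter cascade: stage contracts, oracles, truth-channel recovery."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from pclexome.filtering import (
    CascadeParams,
    SomaticCall,
    carryover_audit,
    depth_filter,
    flag_unconfirmed_recurrent,
    label_subclonal,
    normalize_key,
    polymorphism_filter,
    run_cascade,
    select_non_silent,
    subtract_controls,
)
from pclexome.model import NON_SILENT, VariantRecord

from conftest import run_all_cascades
from test_io import random_records


def mk(pos=100, depth=40, alt=18, cons="missense", db=False, cosmic=False,
       clinvar=False, confirmed=False, sample="T1", ref="C", altb="T", chrom="chr1"):
    vclass = "snv" if len(ref) == len(altb) == 1 else (
        "insertion" if len(altb) > len(ref) else "deletion"
    )
    return VariantRecord(
        sample, chrom, pos, ref, altb, depth, alt, vclass,
        cons if vclass == "snv" or cons in ("frameshift", "inframe_indel", "noncoding") else "frameshift",
        gene="G1", in_polymorphism_db=db, in_cosmic=cosmic,
        cosmic_confirmed_somatic=confirmed, in_clinvar=clinvar,
    )


def test_depth_boundary_inclusive():
    records = [mk(depth=9, alt=4), mk(pos=101, depth=10, alt=4)]
    out = depth_filter(records, 10)
    assert [r.total_depth for r in out] == [10]
    assert depth_filter(records, 1) == records


def test_depth_filter_matches_brute_force(rng):
    records = random_records(rng, 300)
    assert depth_filter(records, 25) == [r for r in records if r.total_depth >= 25]


@pytest.mark.parametrize(
    "cons,kept",
    [
        ("missense", True), ("nonsense", True), ("frameshift", True),
        ("inframe_indel", True), ("splice_site", True),
        ("synonymous", False), ("noncoding", False),
    ],
)
def test_non_silent_selection(cons, kept):
    out = select_non_silent([mk(cons=cons)])
    assert bool(out) == kept
    assert select_non_silent([]) == []


@pytest.mark.parametrize(
    "db,cosmic,clinvar,kept",
    [
        (True, True, False, True),    # COSMIC rescue
        (True, False, True, True),    # ClinVar rescue
        (True, False, False, False),  # plain polymorphism: discarded
        (False, False, False, True),  # not in databases: kept
        (False, True, True, True),
    ],
)
def test_polymorphism_filter_rescue_rules(db, cosmic, clinvar, kept):
    out = polymorphism_filter([mk(db=db, cosmic=cosmic, clinvar=clinvar)])
    assert bool(out) == kept


def test_subtract_controls_basics():
    tumor = [mk(pos=100), mk(pos=200)]
    control = [mk(pos=100, sample="C1")]
    assert [r.pos for r in subtract_controls(tumor, control)] == [200]
    # a control call below the depth floor cannot veto
    weak = [mk(pos=100, depth=9, alt=4, sample="C1")]
    assert subtract_controls(tumor, weak) == tumor
    with pytest.raises(ValueError, match="no controls"):
        subtract_controls(tumor, [])


def test_subtract_controls_matches_set_difference_oracle(rng):
    tumor = random_records(rng, 500, "T1")
    control = random_records(rng, 250, "C1") + [
        VariantRecord("C1", r.chrom, r.pos, r.ref, r.alt, 50, 20, r.variant_class, r.consequence)
        for r in tumor[::3]
    ]
    got = subtract_controls(tumor, control, 10)
    veto = {
        normalize_key(c.chrom, c.pos, c.ref, c.alt)
        for c in control if c.total_depth >= 10
    }
    expected = [
        r for r in tumor if normalize_key(r.chrom, r.pos, r.ref, r.alt) not in veto
    ]
    assert got == expected


def test_indel_left_normalization_matches():
    # ATG>A at 100 is the same deletion as xATGy trailing-context forms
    assert normalize_key("chr1", 100, "ATG", "A") == normalize_key("chr1", 100, "ATGC", "AC")
    assert normalize_key("chr1", 100, "CAT", "CT") == ("chr1", 100, "CA", "C")
    tumor = [mk(pos=100, ref="ATGC", altb="AC", cons="frameshift")]
    control = [mk(pos=100, ref="ATG", altb="A", cons="frameshift", sample="C1")]
    assert subtract_controls(tumor, control) == []


def test_subclonal_labeling_boundaries():
    # VAF at the clonal expectation stays clonal
    clonal = mk(depth=40, alt=20)
    # deep sub-clone: exact binomial lower tail below alpha, ccf ~ 0.17
    sub = mk(pos=101, depth=40, alt=3)
    calls = label_subclonal([clonal, sub], purity=0.9)
    assert [c.clonality for c in calls] == ["clonal", "subclonal"]
    # independent tail computation by direct summation
    p0 = 0.45
    tail = sum(binom.pmf(k, 40, p0) for k in range(0, 4))
    assert tail < 0.05
    assert calls[1].ccf == pytest.approx(2 * (3 / 40) / 0.9)
    with pytest.raises(ValueError, match="purity"):
        label_subclonal([clonal], purity=0.0)


def test_subclonal_type_one_error_bounded(rng):
    purity = 0.9
    n = 800
    depths = np.maximum(1, rng.poisson(42, n))
    alts = np.maximum(1, rng.binomial(depths, 0.5 * purity))
    records = [
        mk(pos=100 + i, depth=int(d), alt=int(min(a, d))) for i, (d, a) in enumerate(zip(depths, alts))
    ]
    calls = label_subclonal(records, purity, alpha=0.05)
    frac = np.mean([c.clonality == "subclonal" for c in calls])
    assert frac <= 2 * 0.05


def test_cascade_empty_input():
    calls, funnel = run_cascade([], [mk(sample="C1")], "unpaired")
    assert calls == []
    assert funnel.survivors == [0] * 5 and funnel.removed == [0] * 5


def test_funnel_monotone_and_conserving(rng):
    tumor = random_records(rng, 400, "T1")
    control = random_records(rng, 100, "C1")
    _, funnel = run_cascade(tumor, control, "unpaired")
    counts = [funnel.n_input] + funnel.survivors
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    for k in range(len(funnel.stages)):
        assert funnel.removed[k] + funnel.survivors[k] == counts[k]


def test_independent_predicate_stages_commute(rng):
    records = random_records(rng, 300)
    stages = {
        "depth": lambda rs: depth_filter(rs, 10),
        "non_silent": select_non_silent,
        "polymorphism": polymorphism_filter,
    }
    baseline = None
    for order in itertools.permutations(stages):
        out = records
        for name in order:
            out = stages[name](out)
        keys = {r.key for r in out}
        baseline = keys if baseline is None else baseline
        assert keys == baseline


def test_paired_output_subset_of_unpaired(small_cohort):
    params = CascadeParams()
    pooled_others = lambda m: [  # noqa: E731
        r
        for cid, recs in small_cohort.controls.items()
        if cid != m.matched_control_id
        for r in recs
    ]
    for m in small_cohort.tumors:
        if not m.matched_control_id:
            continue
        paired, _ = run_cascade(
            small_cohort.variants[m.sample_id],
            small_cohort.variants[m.matched_control_id],
            "paired", m.purity, params,
        )
        unpaired, _ = run_cascade(
            small_cohort.variants[m.sample_id], pooled_others(m), "unpaired", m.purity, params
        )
        assert {c.record.key for c in paired} <= {c.record.key for c in unpaired}


def test_no_database_present_germline_leaks_in_paired_mode(small_cohort):
    truth = small_cohort.truth.variants
    results = run_all_cascades(small_cohort)
    for m in small_cohort.tumors:
        if not m.matched_control_id:
            continue
        calls, _ = results[m.sample_id]
        gl = truth[
            (truth.sample_id == m.sample_id)
            & (truth.label == "germline")
            & truth.in_polymorphism_db
        ]
        germline_keys = {(r.chrom, r.pos, r.ref, r.alt) for _, r in gl.iterrows()}
        assert not any(c.record.key in germline_keys for c in calls)


def test_carryover_audit_truth_oracle(small_cohort):
    params = CascadeParams()
    audit = carryover_audit(small_cohort.variants, small_cohort.metadata, params)
    assert (audit.n_unpaired == audit.n_paired + audit.n_extra).all()
    truth = small_cohort.truth.variants
    meta = {m.sample_id: m for m in small_cohort.metadata}
    for _, row in audit.iterrows():
        recs = {
            (r.chrom, r.pos): r for r in small_cohort.variants[row.sample_id]
        }
        other_controls = {
            r.key
            for cid, rs in small_cohort.controls.items()
            if cid != meta[row.sample_id].matched_control_id
            for r in rs
            if r.total_depth >= params.min_control_depth
        }
        # carried over: database-absent germline not covered by the other
        # controls (shared or private), surviving depth + consequence filters
        gl = truth[
            (truth.sample_id == row.sample_id)
            & (truth.label == "germline")
            & ~truth.in_polymorphism_db
            & truth.consequence.isin(NON_SILENT)
        ]
        expected = sum(
            1
            for _, t in gl.iterrows()
            if recs[(t.chrom, t.pos)].total_depth >= params.min_depth
            and (t.chrom, t.pos, t.ref, t.alt) not in other_controls
        )
        assert row.n_extra == expected


def test_carryover_zero_when_all_germline_in_databases():
    from conftest import small_config
    from pclexome.simulate import simulate_cohort

    cohort = simulate_cohort(small_config(23, db_absent_fraction=0.0))
    audit = carryover_audit(cohort.variants, cohort.metadata)
    assert (audit.extra_fraction == 0).all()


def test_flag_unconfirmed_recurrent_rules():
    shared = dict(pos=500, db=True, cosmic=True)
    calls = [
        SomaticCall(mk(sample="T1", **shared), "clonal", "unpaired"),
        SomaticCall(mk(sample="T2", **shared), "clonal", "unpaired"),
        SomaticCall(mk(sample="T3", pos=600, db=True, cosmic=True), "clonal", "unpaired"),
    ]
    flagged = flag_unconfirmed_recurrent(calls)
    assert [c.germline_risk_flag for c in flagged] == [True, True, False]
    # confirmed-somatic recurrent variants stay unflagged
    confirmed = dict(pos=500, db=True, cosmic=True, confirmed=True)
    calls = [
        SomaticCall(mk(sample="T1", **confirmed), "clonal", "unpaired"),
        SomaticCall(mk(sample="T2", **confirmed), "clonal", "unpaired"),
    ]
    assert not any(c.germline_risk_flag for c in flag_unconfirmed_recurrent(calls))


def test_somatic_clonal_recall_on_synthetic_truth(small_cohort):
    truth = small_cohort.truth.variants
    results = run_all_cascades(small_cohort)
    call_keys = {
        (c.record.sample_id,) + c.record.key
        for calls, _ in results.values()
        for c in calls
    }
    ns = truth[(truth.label == "somatic_clonal") & truth.consequence.isin(NON_SILENT)]
    hits = [
        (r.sample_id, r.chrom, r.pos, r.ref, r.alt) in call_keys for _, r in ns.iterrows()
    ]
    assert np.mean(hits) >= 0.95
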