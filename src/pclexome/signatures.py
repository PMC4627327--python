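"""Trinucleotide mutation spectra and signature attribution.

Somatic SNVs are classified into the 96 pyrimidine-strand trinucleotide
classes (6 substitutions x 4 five-prime x 4 three-prime flanks, in the
conventional order: substitutions alphabetical C>A..T>G, flanks A,C,G,T).
Per-sample spectra are decomposed onto a signature matrix by non-negative
least squares; samples are attributed to a single dominant process when
one exposure crosses ``distinct_threshold``, otherwise called an
admixture.

Two built-in signature profiles model the processes seen in plasma-cell
dyscrasias: an aging-like profile (C>T transitions at NpCpG sites, from
spontaneous deamination of 5-methylcytosine) and an APOBEC-like profile
(C>T and C>G at TpCpN sites, from APOBEC cytidine-deaminase activity).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .model import VariantRecord

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 context labels, "A[C>A]A"-style, in conventional order
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}

#: the four aging-signature contexts: C>T at NpCpG
AGING_CONTEXTS = frozenset(f"{five}[C>T]G" for five in BASES)
#: the eight APOBEC-signature contexts: C>T and C>G at TpCpN
APOBEC_CONTEXTS = frozenset(
    f"T[{sub}]{three}" for sub in ("C>T", "C>G") for three in BASES
)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def collapse_to_pyrimidine(ref: str, alt: str, context3: str) -> tuple[str, str, str]:
    """Map a substitution to its pyrimidine-strand class.

    Purine-reference calls (A, G) are reverse-complemented so every class
    has a C or T reference.  Returns (substitution, 5' base, 3' base).
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"ref/alt must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(f"context3 {context3!r} not centered on ref {ref!r}")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context3 = revcomp(context3)
    return f"{ref}>{alt}", context3[0], context3[2]


def context_label(ref: str, alt: str, context3: str) -> str:
    sub, five, three = collapse_to_pyrimidine(ref, alt, context3)
    return f"{five}[{sub}]{three}"


@dataclass
class MutSpectrum:
    """Per-sample 96-context counts plus the 6-class substitution summary."""

    sample_id: str
    counts96: np.ndarray  # length 96, conventional order
    n_no_context: int = 0

    def __post_init__(self) -> None:
        self.counts96 = np.asarray(self.counts96, dtype=int)
        if self.counts96.shape != (96,) or (self.counts96 < 0).any():
            raise ValueError("counts96 must be 96 non-negative integers")
        if self.n_no_context < 0:
            raise ValueError("n_no_context must be >= 0")

    @property
    def counts6(self) -> dict[str, int]:
        by_class = self.counts96.reshape(6, 16).sum(axis=1)
        return dict(zip(SUBSTITUTIONS, by_class.tolist()))

    @property
    def n_snv(self) -> int:
        return int(self.counts96.sum()) + self.n_no_context

    @property
    def transition_fraction(self) -> float:
        c6 = self.counts6
        total = int(self.counts96.sum())
        return (c6["C>T"] + c6["T>C"]) / total if total else 0.0


@dataclass
class ExposureResult:
    sample_id: str
    exposures: dict[str, float]
    residual_norm: float
    attribution: str

    def __post_init__(self) -> None:
        vals = np.array(list(self.exposures.values()))
        if (vals < -1e-12).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("exposures must be non-negative and sum to 1")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


def build_spectrum(calls: Iterable, sample_id: str | None = None) -> MutSpectrum:
    """Count SNVs into the 96 contexts; indels are ignored.

    Accepts VariantRecords or objects exposing a ``.record`` attribute
    (somatic calls).  SNVs with no resolvable context are tallied in
    ``n_no_context`` rather than dropped silently.
    """
    counts = np.zeros(96, dtype=int)
    n_no_context = 0
    sid = sample_id
    for call in calls:
        rec: VariantRecord = getattr(call, "record", call)
        if sid is None:
            sid = rec.sample_id
        if rec.variant_class != "snv":
            continue
        if rec.context3 is None:
            n_no_context += 1
            continue
        counts[_CONTEXT_INDEX[context_label(rec.ref, rec.alt, rec.context3)]] += 1
    return MutSpectrum(sid or "", counts, n_no_context)


def make_signature_profiles(concentration: float = 0.97) -> pd.DataFrame:
    """Build the two built-in 96-context signature profiles.

    ``concentration`` is the probability mass placed on the signature's
    characteristic contexts (spread uniformly within them); the remainder
    is uniform over the other contexts.  Columns sum to 1.
    """
    if not 0.0 < concentration <= 1.0:
        raise ValueError("concentration must be in (0,1]")
    profiles = pd.DataFrame(0.0, index=list(CONTEXT_LABELS), columns=["aging", "apobec"])
    for col, contexts in [("aging", AGING_CONTEXTS), ("apobec", APOBEC_CONTEXTS)]:
        inside = profiles.index.isin(contexts)
        profiles.loc[inside, col] = concentration / inside.sum()
        profiles.loc[~inside, col] = (1.0 - concentration) / (~inside).sum()
    return profiles


def decompose(
    spectrum: MutSpectrum,
    signature_matrix: pd.DataFrame,
    distinct_threshold: float = 0.7,
) -> ExposureResult:
    """Non-negative least-squares decomposition of a normalized spectrum.

    Solves min ||p - M e||_2 subject to e >= 0, where p is the spectrum
    normalized to sum 1 and M the 96 x K signature matrix; exposures are
    renormalized to sum 1.
    """
    total = spectrum.counts96.sum()
    if total == 0:
        raise ValueError("empty spectrum")
    M = signature_matrix.loc[list(CONTEXT_LABELS)].to_numpy(dtype=float)
    p = spectrum.counts96 / total
    e, _ = nnls(M, p)
    residual = float(np.linalg.norm(p - M @ e))
    if e.sum() == 0:
        raise ValueError("decomposition collapsed to zero exposure")
    e = e / e.sum()
    exposures = dict(zip(signature_matrix.columns, e.tolist()))
    top = max(exposures, key=exposures.get)
    attribution = f"distinct_{top}" if exposures[top] >= distinct_threshold else "admixture"
    return ExposureResult(spectrum.sample_id, exposures, residual, attribution)


def cohort_signature_report(
    spectra: Sequence[MutSpectrum],
    exposures: Sequence[ExposureResult],
    metadata: Sequence | None = None,
) -> pd.DataFrame:
    """Per-sample signature summary plus a pooled cohort row."""
    groups = {}
    if metadata is not None:
        groups = {m.sample_id: m.translocation_group for m in metadata}
    exp_by_sample = {e.sample_id: e for e in exposures}
    rows = []
    signature_names = list(exposures[0].exposures) if exposures else []
    for spec in spectra:
        exp = exp_by_sample.get(spec.sample_id)
        row = {
            "sample_id": spec.sample_id,
            "n_snv": spec.n_snv,
            "n_no_context": spec.n_no_context,
            "transition_fraction": spec.transition_fraction,
            "attribution": exp.attribution if exp else None,
            "translocation_group": groups.get(spec.sample_id),
        }
        for name in signature_names:
            row[f"exposure_{name}"] = exp.exposures[name] if exp else None
        rows.append(row)
    pooled = MutSpectrum(
        "cohort",
        np.sum([s.counts96 for s in spectra], axis=0),
        sum(s.n_no_context for s in spectra),
    )
    rows.append(
        {
            "sample_id": "cohort",
            "n_snv": pooled.n_snv,
            "n_no_context": pooled.n_no_context,
            "transition_fraction": pooled.transition_fraction,
            "attribution": None,
            "translocation_group": None,
        }
    )
    return pd.DataFrame(rows)


def write_signature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="context")


def read_signature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="context")
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix missing contexts: {sorted(missing)[:5]}...")
    return df.loc[list(CONTEXT_LABELS)]
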