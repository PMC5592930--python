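"""Variant classification, filtering, and per-kilobase density accounting.

Classes follow the small-variant taxonomy used for draft-genome diversity
surveys: SNV (1 bp substitution), MNV (length-preserving multi-base
substitution), insertion/deletion (one allele empty after trimming shared
context), and replacement (both alleles non-empty but of unequal length,
e.g. AAA→CC).  Alleles are canonicalized by trimming the longest shared
suffix and then the longest shared prefix, preserving VCF left-anchoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

CLASSES = ("SNV", "MNV", "insertion", "deletion", "replacement")


class MonomorphicRecordError(ValueError):
    """ref == alt after trimming shared context."""


@dataclass(frozen=True)
class VariantRecord:
    scaffold: str
    pos: int  # 1-based, as on disk
    ref: str
    alt: str
    depth: int
    prob: float
    fwd_support: int | None = None
    rev_support: int | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def trim_alleles(ref: str, alt: str) -> tuple[str, str]:
    """Trim the longest shared suffix, then the longest shared prefix."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    return ref, alt


def classify_variant(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair into SNV/MNV/insertion/deletion/replacement."""
    r, a = trim_alleles(ref.upper(), alt.upper())
    if not r and not a:
        raise MonomorphicRecordError(f"{ref}->{alt} is monomorphic after trimming")
    if not r:
        return "insertion"
    if not a:
        return "deletion"
    if len(r) == len(a):
        return "SNV" if len(r) == 1 else "MNV"
    return "replacement"


def filter_variants(
    records: Sequence[VariantRecord],
    min_depth: int = 4,
    min_prob: float = 0.95,
    require_both_strands: bool = True,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the survey's coverage/probability/strand filters (all inclusive).

    A record survives iff depth >= min_depth, prob >= min_prob, and — when
    strand support fields are present and the strand rule is enabled — both
    orientations carry at least one supporting read.  Records without strand
    fields are not rejected by the strand rule (dialects vary); set
    ``require_both_strands=False`` to disable the rule entirely.  Returns the
    survivors plus per-rule rejection tallies (a record failing several rules
    increments each).
    """
    kept: list[VariantRecord] = []
    tallies = {"coverage": 0, "probability": 0, "strand": 0}
    for rec in records:
        ok = True
        if rec.depth < min_depth:
            tallies["coverage"] += 1
            ok = False
        if rec.prob < min_prob:
            tallies["probability"] += 1
            ok = False
        if (
            require_both_strands
            and rec.fwd_support is not None
            and rec.rev_support is not None
            and not (rec.fwd_support > 0 and rec.rev_support > 0)
        ):
            tallies["strand"] += 1
            ok = False
        if ok:
            kept.append(rec)
    return kept, tallies


@dataclass(frozen=True)
class DensityReport:
    counts: dict[str, int]
    total: int
    callable_bp: int
    density_per_kb: float
    relative_change_percent: float | None = None


def density_report(
    records: Iterable[VariantRecord],
    callable_bp: int,
    reference_density: float | None = None,
) -> DensityReport:
    """Per-class counts and variants-per-kilobase over the callable span.

    ``relative_change_percent`` (one decimal) compares against a supplied
    reference density (per kb).
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    counts: Counter[str] = Counter()
    for rec in records:
        counts[classify_variant(rec.ref, rec.alt)] += 1
    total = sum(counts.values())
    density = 1000.0 * total / callable_bp
    change = None
    if reference_density is not None:
        change = round(100.0 * (density - reference_density) / reference_density, 1)
    return DensityReport(
        counts={c: counts.get(c, 0) for c in CLASSES},
        total=total,
        callable_bp=callable_bp,
        density_per_kb=density,
        relative_change_percent=change,
    )


def relative_change_percent(density: float, reference: float) -> float:
    return round(100.0 * (density - reference) / reference, 1)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path,
    prob_field: str = "PR",
    depth_field: str = "DP",
    strand_fields: tuple[str, str] = ("SF", "SR"),
) -> list[VariantRecord]:
    """Read biallelic records from a VCF 4.x file (gz-transparent).

    The caller probability is read from INFO ``prob_field``; when absent it
    is derived from the first sample's genotype quality (prob = 1 − 10^(−GQ/10)).
    Depth comes from INFO ``depth_field``; per-orientation support from the
    INFO ``strand_fields`` when present.
    """
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            info = rec.info
            depth = int(_scalar(info.get(depth_field, 0)))
            prob = info.get(prob_field)
            if prob is None and rec.samples:
                gq = next(iter(rec.samples.values())).get("GQ")
                prob = 1.0 - 10 ** (-gq / 10.0) if gq is not None else 0.0
            fwd = info.get(strand_fields[0])
            rev = info.get(strand_fields[1])
            out.append(
                VariantRecord(
                    scaffold=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    depth=depth,
                    prob=float(_scalar(prob)),
                    fwd_support=None if fwd is None else int(_scalar(fwd)),
                    rev_support=None if rev is None else int(_scalar(rev)),
                )
            )
    return out


def _scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value
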