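"""Assembly survey statistics and k-mer-spectrum genome-size estimation.

The survey statistics are the quantities customarily reported for a draft
assembly: total and ungapped span, N50, largest scaffold, GC content of the
non-N fraction, and the number of largest scaffolds needed to capture 90% of
the span.  Genome size is estimated from the k-mer multiplicity spectrum of a
read set: total k-mer instances beyond the error region divided by the depth
of the main coverage mode.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import GenomeSequence, _open_text, revcomp


class EmptyAssemblyError(ValueError):
    pass


class GenomeSizeError(ValueError):
    """K-mer histogram carries no coverage mode separable from errors."""


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    ungapped_bp: int
    n_scaffolds: int
    n50: int
    largest: int
    gc_percent: float
    scaffolds_to_90: int

    @property
    def gap_bp(self) -> int:
        return self.total_bp - self.ungapped_bp


def assembly_summary(
    seqs: Iterable[GenomeSequence], min_len: int = 1000
) -> AssemblyStats:
    """Survey statistics over scaffolds of length >= min_len.

    N50 is the length of the scaffold at which the descending cumulative
    length first reaches half the total; scaffolds_to_90 is the minimum count
    of largest scaffolds whose cumulative length reaches 90% of the total.
    GC is computed over A/C/G/T only (N excluded from the denominator).
    """
    kept = [s for s in seqs if len(s) >= min_len]
    if not kept:
        raise EmptyAssemblyError(f"no scaffold of length >= {min_len}")
    lengths = np.array(sorted((len(s) for s in kept), reverse=True), dtype=np.int64)
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[int(np.searchsorted(cum, total / 2, side="left"))])
    to90 = int(np.searchsorted(cum, 0.90 * total, side="left")) + 1
    gc = at = n_bases = 0
    for s in kept:
        gc += s.seq.count("G") + s.seq.count("C")
        at += s.seq.count("A") + s.seq.count("T")
        n_bases += s.seq.count("N")
    gc_percent = 100.0 * gc / (gc + at) if (gc + at) else 0.0
    return AssemblyStats(
        total_bp=total,
        ungapped_bp=total - n_bases,
        n_scaffolds=len(kept),
        n50=n50,
        largest=int(lengths[0]),
        gc_percent=gc_percent,
        scaffolds_to_90=to90,
    )


# ---------------------------------------------------------------------------
# K-mer spectrum
# ---------------------------------------------------------------------------


@dataclass
class KmerHistogram:
    """Multiplicity spectrum: multiplicity -> number of distinct canonical k-mers."""

    k: int
    counts: dict[int, int]

    def total_instances(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (multiplicity, count) arrays from m=1 to the max multiplicity."""
        mmax = max(self.counts)
        counts = np.zeros(mmax + 1, dtype=np.int64)
        for m, c in self.counts.items():
            counts[m] = c
        return np.arange(mmax + 1), counts


def _iter_read_strings(reads: Sequence[str] | str | Path) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        path = Path(reads)
        stem = path.name.removesuffix(".gz")
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq).upper()
    else:
        for r in reads:
            yield r.upper()


def kmer_histogram(reads: Sequence[str] | str | Path, k: int = 21) -> KmerHistogram:
    """Exact canonical k-mer multiplicity spectrum of a read set.

    Canonical form is the lexicographic minimum of a k-mer and its reverse
    complement; k must be odd so no k-mer is its own reverse complement.
    K-mers containing N are skipped.  Counting is exact and in-memory
    (intended for survey-scale inputs, not production-scale read sets).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form ill-defined for palindromes)")
    if not (11 <= k <= 31):
        raise ValueError("k must lie in [11, 31]")
    kmer_counts: Counter[str] = Counter()
    any_read = False
    for seq in _iter_read_strings(reads):
        any_read = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            kmer_counts[min(kmer, rc)] += 1
    if not any_read:
        raise ValueError("no reads provided")
    spectrum: Counter[int] = Counter(kmer_counts.values())
    return KmerHistogram(k=k, counts=dict(spectrum))


@dataclass(frozen=True)
class GenomeSizeEstimate:
    size_bp: float
    error_cutoff: int
    peak_depth: int
    peak_depth_refined: float
    k: int


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Estimate genome size from a k-mer spectrum.

    The error cutoff is the first local minimum of the (lightly smoothed)
    spectrum scanning upward from multiplicity 1; the peak depth is the
    modal multiplicity beyond the cutoff; the size is the total number of
    k-mer instances beyond the cutoff divided by the peak depth.
    """
    if not hist.counts:
        raise GenomeSizeError("empty k-mer histogram")
    m, counts = hist.as_arrays()
    # 3-bin moving average for extremum robustness at desk-scale counts
    smooth = counts.astype(float)
    if len(smooth) >= 4:
        smooth[1:] = np.convolve(counts[1:], np.ones(3) / 3, mode="same")

    mmax = len(counts) - 1
    if mmax < 2:
        raise GenomeSizeError("spectrum too narrow to separate errors from coverage")
    if not np.any(counts[2:] > counts[1:-1]):
        raise GenomeSizeError(
            "monotonically decreasing spectrum: no coverage mode beyond the error "
            "region; deeper coverage needed"
        )
    # coverage mode: modal multiplicity beyond the m=1 error spike, located on
    # a smoothed spectrum with the spike itself excluded
    no_err = counts.astype(float)
    no_err[1] = 0.0
    smooth_peak = no_err.copy()
    if len(no_err) >= 4:
        smooth_peak[1:] = np.convolve(no_err[1:], np.ones(3) / 3, mode="same")
    peak = 2 + int(np.argmax(smooth_peak[2:]))
    # smoothing flattens single-bin spikes; re-anchor the mode on raw counts
    lo, hi = max(2, peak - 1), min(mmax, peak + 1)
    peak = lo + int(np.argmax(counts[lo : hi + 1]))
    if counts[peak] == 0:
        raise GenomeSizeError("no coverage mode beyond the error region")
    # error cutoff: deepest point of the valley between the error spike and
    # the coverage mode (first local minimum scanning m=1 upward; the last
    # index attaining the minimum is used so flat zero valleys hug the mode)
    valley = smooth[1:peak]
    vmin = valley.min()
    cutoff = 1 + int(np.nonzero(valley == vmin)[0][-1])
    # everything below the mode is zero => no error peak at all
    if counts[1 : cutoff + 1].sum() == 0:
        cutoff = 0
    if cutoff > 0 and smooth[cutoff] >= smooth[peak]:
        raise GenomeSizeError(
            "monotonically decreasing spectrum: no coverage mode beyond the error "
            "region; deeper coverage needed"
        )
    # the true coverage peak rarely falls on an integer multiplicity: refine
    # it as the count-weighted centroid of the raw spectrum within ±25% of
    # the mode (equivariant under uniform rescaling of multiplicities)
    w_lo = max(cutoff + 1, int(math.ceil(0.75 * peak)))
    w_hi = min(mmax, int(math.floor(1.25 * peak)))
    weights = counts[w_lo : w_hi + 1].astype(float)
    refined = float(peak)
    if weights.sum() > 0:
        refined = float(np.average(m[w_lo : w_hi + 1], weights=weights))
    instances = int((m[cutoff + 1 :] * counts[cutoff + 1 :]).sum())
    return GenomeSizeEstimate(
        size_bp=instances / refined,
        error_cutoff=cutoff,
        peak_depth=peak,
        peak_depth_refined=refined,
        k=hist.k,
    )
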