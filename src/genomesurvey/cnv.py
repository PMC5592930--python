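"""Read-depth segmental duplication/deletion calling and companion screens.

The caller marks each usable window whose GC-corrected depth exceeds the
duplication cutoff (mean + 3 SD) or falls below the deletion cutoff
(mean − 2 SD), then slides a seven-window frame: every frame with at least
six marked windows seeds a call, overlapping or adjacent seed frames merge,
and the merged span is trimmed to its outermost marked windows.

Companion screens: deletion windows intersecting repeat masks or assembly
gaps are removed (with the 6-of-7 rule re-applied), candidate heterozygous
deletions are separated from homozygous ones by a corrected-depth floor,
everted (reverse-then-forward) read pairs are clustered into tandem
duplication candidates, and duplication calls from two assemblies are
reciprocally mapped to partition them into shared and assembly-private sets.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .depthmodel import DepthCalibration, DepthWindow
from .seqio import GenomeSequence, GenomicInterval, IntervalSet, revcomp

log = logging.getLogger(__name__)

RULE_FRAME = 7  # consecutive windows examined
RULE_MIN_MARKED = 6  # marked windows required inside a frame


@dataclass
class CNVSegment:
    """A called duplication/deletion with its founding windows."""

    scaffold: str
    start: int
    end: int
    type: str  # "duplication" | "deletion"
    n_windows: int
    mean_corrected_depth: float
    zygosity: str = "not_applicable"
    genes: list[str] = field(default_factory=list)
    provenance: str = "wssd"
    # all windows in the trimmed span plus their mark flags, kept so that
    # deletion filtering can unmark and re-evaluate
    windows: list[DepthWindow] = field(default_factory=list, repr=False)
    marks: list[bool] = field(default_factory=list, repr=False)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.start, self.end, self.type)


@dataclass(frozen=True)
class ReadPairRecord:
    """A mapped mate pair, normalized so pos1 <= pos2."""

    scaffold: str
    pos1: int
    pos2: int
    orient1: str  # "forward" | "reverse"
    orient2: str
    insert: int

    def __post_init__(self) -> None:
        if self.pos1 > self.pos2:
            p1, p2 = self.pos2, self.pos1
            o1, o2 = self.orient2, self.orient1
            object.__setattr__(self, "pos1", p1)
            object.__setattr__(self, "pos2", p2)
            object.__setattr__(self, "orient1", o1)
            object.__setattr__(self, "orient2", o2)

    @property
    def everted(self) -> bool:
        """Reverse mate upstream of the forward mate: tandem-junction signature."""
        return self.orient1 == "reverse" and self.orient2 == "forward"


@dataclass(frozen=True)
class MappingHit:
    query: str
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    aligned_len: int


# ---------------------------------------------------------------------------
# WSSD calling
# ---------------------------------------------------------------------------


def _mark_windows(
    windows: Sequence[DepthWindow], calib: DepthCalibration, kind: str
) -> np.ndarray:
    marks = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows):
        if not w.usable() or w.corrected_depth is None:
            continue  # flagged windows count as unmarked
        if kind == "duplication":
            marks[i] = w.corrected_depth > calib.dup_cutoff
        else:
            marks[i] = w.corrected_depth < calib.del_cutoff
    return marks


def _segments_from_marks(
    windows: Sequence[DepthWindow], marks: np.ndarray, kind: str
) -> list["CNVSegment"]:
    """Apply the 6-of-7 frame rule to a per-scaffold, ordered window run."""
    n = len(windows)
    if n < RULE_FRAME:
        return []
    covered = np.zeros(n, dtype=bool)
    counts = np.convolve(marks.astype(int), np.ones(RULE_FRAME, dtype=int), "valid")
    for i in np.nonzero(counts >= RULE_MIN_MARKED)[0]:
        covered[i : i + RULE_FRAME] = True
    segments: list[CNVSegment] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        idx = [k for k in range(i, j) if marks[k]]
        if idx:
            first, last = idx[0], idx[-1]
            span = list(windows[first : last + 1])
            span_marks = [bool(marks[k]) for k in range(first, last + 1)]
            marked = [w for w, m in zip(span, span_marks) if m]
            segments.append(
                CNVSegment(
                    scaffold=windows[0].scaffold,
                    start=span[0].start,
                    end=span[-1].end,
                    type=kind,
                    n_windows=len(marked),
                    mean_corrected_depth=float(
                        np.mean([w.corrected_depth for w in marked])
                    ),
                    windows=span,
                    marks=span_marks,
                )
            )
        i = j
    return segments


def call_wssd(
    windows: Sequence[DepthWindow], calib: DepthCalibration
) -> list[CNVSegment]:
    """Call duplication and deletion segments with the 6-of-7 window rule.

    Flagged windows (gap-dominated or partial) neither carry marks nor may be
    spanned by a call: each scaffold's window run is split at flagged windows
    and the frame rule is applied within the unflagged stretches, so no call
    ever overlaps a flagged window.
    """
    by_scaffold: dict[str, list[DepthWindow]] = defaultdict(list)
    for w in windows:
        run = by_scaffold[w.scaffold]
        if run and w.start < run[-1].start:
            raise ValueError(f"windows of scaffold {w.scaffold} are not ordered")
        run.append(w)
    segments: list[CNVSegment] = []
    for scaf in sorted(by_scaffold):
        for run in _unflagged_stretches(by_scaffold[scaf]):
            for kind in ("duplication", "deletion"):
                marks = _mark_windows(run, calib, kind)
                segments.extend(_segments_from_marks(run, marks, kind))
    segments.sort(key=lambda s: (s.scaffold, s.start, s.type))
    return segments


def _unflagged_stretches(run: Sequence[DepthWindow]) -> list[list[DepthWindow]]:
    out: list[list[DepthWindow]] = []
    cur: list[DepthWindow] = []
    for w in run:
        if w.usable():
            cur.append(w)
        elif cur:
            out.append(cur)
            cur = []
    if cur:
        out.append(cur)
    return out


def filter_deletions(
    segments: Iterable[CNVSegment],
    repeat_mask: IntervalSet,
    gaps: IntervalSet,
) -> list[CNVSegment]:
    """Drop deletion evidence from repeat-masked or gapped windows.

    Windows of deletion segments overlapping (>= 1 bp) the repeat mask or an
    assembly gap are unmarked; each segment is then re-derived by re-applying
    the 6-of-7 rule to the surviving marks, so every surviving deletion still
    satisfies the calling rule.  Duplication segments pass through untouched.
    """
    out: list[CNVSegment] = []
    for seg in segments:
        if seg.type != "deletion":
            out.append(seg)
            continue
        marks = np.array(seg.marks, dtype=bool)
        for i, w in enumerate(seg.windows):
            if marks[i] and (
                repeat_mask.overlaps(w.scaffold, w.start, w.end)
                or gaps.overlaps(w.scaffold, w.start, w.end)
            ):
                marks[i] = False
        out.extend(_segments_from_marks(seg.windows, marks, "deletion"))
    out.sort(key=lambda s: (s.scaffold, s.start, s.type))
    return out


def classify_zygosity(segment: CNVSegment, floor: float = 5.0) -> str:
    """Heterozygous if no founding window drops below the corrected-depth floor.

    A deletion with every window's corrected depth >= ``floor`` retains one
    haplotype's worth of coverage (heterozygous); any window below the floor
    indicates loss of both copies (homozygous).
    """
    if segment.type != "deletion":
        raise ValueError("zygosity classification applies to deletion segments only")
    marked = [w for w, m in zip(segment.windows, segment.marks) if m]
    hom = any(
        w.corrected_depth is not None and w.corrected_depth < floor for w in marked
    )
    segment.zygosity = "homozygous" if hom else "heterozygous"
    return segment.zygosity


def annotate_genes(
    segments: Sequence[CNVSegment], genes: IntervalSet
) -> tuple[list[CNVSegment], dict[str, int]]:
    """Attach overlapping gene labels (>= 1 bp) and summarize the counts."""
    unique: set[str] = set()
    with_genes = 0
    for seg in segments:
        hits = genes.overlapping(seg.scaffold, seg.start, seg.end)
        seg.genes = sorted({h.label for h in hits})
        if seg.genes:
            with_genes += 1
            unique.update(seg.genes)
    return list(segments), {
        "segments_with_genes": with_genes,
        "unique_genes": len(unique),
    }


# ---------------------------------------------------------------------------
# Everted-pair tandem duplication screen
# ---------------------------------------------------------------------------


def call_everted_tandem(
    pairs: Iterable[ReadPairRecord],
    min_support: int = 3,
    max_cluster_gap: int | None = None,
) -> list[CNVSegment]:
    """Cluster everted pairs into tandem-duplication candidate segments.

    Everted pairs (reverse mate upstream of its forward partner) are the
    junction signature of reads from a tandem-duplicated haplotype mapped
    onto the single-copy reference.  Pairs whose spans mutually overlap or
    lie within ``max_cluster_gap`` (default: one median insert size) cluster
    together; clusters with >= ``min_support`` pairs become candidates
    spanning the union of member spans.
    """
    everted = [p for p in pairs if p.everted]
    if not everted:
        return []
    if max_cluster_gap is None:
        max_cluster_gap = int(np.median([p.insert for p in everted]))
    by_scaffold: dict[str, list[ReadPairRecord]] = defaultdict(list)
    for p in everted:
        by_scaffold[p.scaffold].append(p)
    candidates: list[CNVSegment] = []
    for scaf in sorted(by_scaffold):
        members = sorted(by_scaffold[scaf], key=lambda p: (p.pos1, p.pos2))
        cluster: list[ReadPairRecord] = []
        cluster_end = -1
        for p in members + [None]:  # sentinel flush
            if p is not None and (not cluster or p.pos1 <= cluster_end + max_cluster_gap):
                cluster.append(p)
                cluster_end = max(cluster_end, p.pos2)
                continue
            if len(cluster) >= min_support:
                start = min(q.pos1 for q in cluster)
                end = max(q.pos2 for q in cluster)
                candidates.append(
                    CNVSegment(
                        scaffold=scaf,
                        start=start,
                        end=end,
                        type="duplication",
                        n_windows=len(cluster),
                        mean_corrected_depth=float("nan"),
                        provenance="everted_pair",
                    )
                )
            if p is not None:
                cluster = [p]
                cluster_end = p.pos2
    return candidates


def read_pair_table(path) -> list[ReadPairRecord]:
    """Read the pair-record TSV dialect: scaffold, pos1, orient1, pos2, orient2."""
    out: list[ReadPairRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            scaf, pos1, o1, pos2, o2 = line.rstrip("\n").split("\t")[:5]
            p1, p2 = int(pos1), int(pos2)
            out.append(
                ReadPairRecord(scaf, p1, p2, o1, o2, insert=abs(p2 - p1))
            )
    return out


# ---------------------------------------------------------------------------
# Seed-and-extend mapping and shared-duplication comparison
# ---------------------------------------------------------------------------


def _seed_index(assembly: Sequence[GenomeSequence], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for scaf in assembly:
        seq = scaf.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append((scaf.name, i))
    return dict(index)


def _extend_ungapped(
    query: str, target: str, q_anchor: int, t_anchor: int, k: int, min_identity: float
) -> tuple[int, int, int, int]:
    """Extend an exact k-mer anchor in both directions without gaps.

    Extension past a mismatch continues only while overall identity stays at
    or above ``min_identity``.  Returns (q_start, q_end, t_start, t_end).
    """
    matches = k
    length = k
    # right
    qi, ti = q_anchor + k, t_anchor + k
    q_end, t_end = qi, ti
    m, L = matches, length
    while qi < len(query) and ti < len(target):
        m += query[qi] == target[ti]
        L += 1
        if m / L < min_identity:
            break
        qi += 1
        ti += 1
        if query[qi - 1] == target[ti - 1]:
            q_end, t_end = qi, ti
            matches, length = m, L
    # left
    qi, ti = q_anchor, t_anchor
    q_start, t_start = qi, ti
    m, L = matches, length
    while qi > 0 and ti > 0:
        m += query[qi - 1] == target[ti - 1]
        L += 1
        if m / L < min_identity:
            break
        qi -= 1
        ti -= 1
        if query[qi] == target[ti]:
            q_start, t_start = qi, ti
            matches, length = m, L
    return q_start, q_end, t_start, t_end


def map_region(
    query: str,
    target: Sequence[GenomeSequence],
    query_id: str = "query",
    seed_k: int = 15,
    min_identity: float = 0.8,
    min_aligned_fraction: float = 0.5,
    seed_stride: int | None = None,
    index: dict | None = None,
) -> list[MappingHit]:
    """Map a query sequence onto an assembly by exact seeding and ungapped extension.

    Exact ``seed_k``-mers of the query (both strands) are looked up in the
    target, each anchor is extended without gaps while identity stays at or
    above ``min_identity``, overlapping hits keep the best identity, and hits
    shorter than ``min_aligned_fraction`` of the query are discarded.
    """
    if len(query) < seed_k:
        raise ValueError(f"query shorter than seed_k={seed_k}")
    if index is None:
        index = _seed_index(target, seed_k)
    targets = {t.name: t.seq for t in target}
    stride = seed_stride or seed_k
    raw_hits: list[MappingHit] = []
    for strand, qseq in (("+", query.upper()), ("-", revcomp(query.upper()))):
        seen_anchors: set[tuple[str, int]] = set()
        for q in range(0, len(qseq) - seed_k + 1, stride):
            kmer = qseq[q : q + seed_k]
            if "N" in kmer:
                continue
            for scaf, t in index.get(kmer, ()):
                diag = (scaf, t - q)
                if diag in seen_anchors:
                    continue
                seen_anchors.add(diag)
                qs, qe, ts, te = _extend_ungapped(
                    qseq, targets[scaf], q, t, seed_k, min_identity
                )
                matches = sum(
                    1 for a, b in zip(qseq[qs:qe], targets[scaf][ts:te]) if a == b
                )
                raw_hits.append(
                    MappingHit(
                        query=query_id,
                        scaffold=scaf,
                        start=ts,
                        end=te,
                        strand=strand,
                        identity=matches / (qe - qs),
                        aligned_len=qe - qs,
                    )
                )
    merged = _merge_hits(raw_hits)
    min_len = min_aligned_fraction * len(query)
    return [h for h in merged if h.aligned_len >= min_len]


def _merge_hits(hits: list[MappingHit]) -> list[MappingHit]:
    """Collapse target-overlapping hits, keeping the best identity/longest."""
    hits = sorted(
        hits, key=lambda h: (h.scaffold, h.start, -h.aligned_len, -h.identity)
    )
    out: list[MappingHit] = []
    for h in hits:
        if out and out[-1].scaffold == h.scaffold and h.start < out[-1].end:
            best = out[-1]
            if (h.aligned_len, h.identity) > (best.aligned_len, best.identity):
                out[-1] = h
        else:
            out.append(h)
    return out


def shared_duplications(
    segments_a: Sequence[CNVSegment],
    assembly_a: Sequence[GenomeSequence],
    segments_b: Sequence[CNVSegment],
    assembly_b: Sequence[GenomeSequence],
    seed_k: int = 15,
    min_identity: float = 0.8,
    min_aligned_fraction: float = 0.5,
) -> dict[str, list[CNVSegment]]:
    """Partition duplication calls of two assemblies into shared/private sets.

    A segment of A is shared iff its sequence maps into B overlapping
    (>= 1 bp) a segment of B, and that B segment reciprocally maps back into
    A overlapping a segment of A.  Returns {"shared_a", "shared_b", "a_only",
    "b_only"} (shared segments listed once per side).
    """
    seq_a = {s.name: s.seq for s in assembly_a}
    seq_b = {s.name: s.seq for s in assembly_b}
    index_a = _seed_index(assembly_a, seed_k)
    index_b = _seed_index(assembly_b, seed_k)

    def overlapped(seg, seqs, target_assembly, target_index, target_segments) -> set[int]:
        """Indices of target segments overlapped by this segment's mapping hits."""
        query = seqs[seg.scaffold][seg.start : seg.end]
        if len(query) < seed_k:
            return set()
        hits = map_region(
            query,
            target_assembly,
            query_id=f"{seg.scaffold}:{seg.start}-{seg.end}",
            seed_k=seed_k,
            min_identity=min_identity,
            min_aligned_fraction=min_aligned_fraction,
            index=target_index,
        )
        found: set[int] = set()
        for h in hits:
            for j, t in enumerate(target_segments):
                if t.scaffold == h.scaffold and t.start < h.end and h.start < t.end:
                    found.add(j)
        return found

    a_over = [
        overlapped(s, seq_a, assembly_b, index_b, segments_b) for s in segments_a
    ]
    b_over = [
        overlapped(s, seq_b, assembly_a, index_a, segments_a) for s in segments_b
    ]
    # shared requires reciprocity: an overlapped opposite segment must itself
    # map back onto a call of the first assembly
    a_shared = [any(b_over[j] for j in over) for over in a_over]
    b_shared = [any(a_over[i] for i in over) for over in b_over]
    return {
        "shared_a": [s for s, ok in zip(segments_a, a_shared) if ok],
        "shared_b": [s for s, ok in zip(segments_b, b_shared) if ok],
        "a_only": [s for s, ok in zip(segments_a, a_shared) if not ok],
        "b_only": [s for s, ok in zip(segments_b, b_shared) if not ok],
    }
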