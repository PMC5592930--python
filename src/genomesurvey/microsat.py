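"""Imperfect microsatellite discovery and density reporting.

Tandem repeats of unit size 2–10 are found by seeding on two exact adjacent
copies of a primitive motif and extending in both directions without gaps,
phase-anchored at the seed.  Extension tolerates mismatches (including up to
a configurable number of successive Ns, each counted as a mismatch) as long
as a bounded look-ahead finds an exact in-phase unit ahead; the final locus
is trimmed to the farthest in-phase match that keeps the running perfection
at or above the configured minimum.  Perfection is the percentage of locus
positions matching the ideal repetition of the unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import GenomeSequence

# unit-block extension scoring: a block keeps the walk alive while >= 75% of
# its positions match; the trimmed boundary maximizes (matches − 2·mismatches),
# so flanking sequence (~25% chance matches) cannot pull the boundary outward
_GOOD_BLOCK_FRAC = 0.75
_MISMATCH_PENALTY = 2.0


@dataclass(frozen=True)
class MicrosatParams:
    unit_min: int = 2
    unit_max: int = 10
    max_successive_n: int = 2
    perfection_min: float = 80.0
    perfection_max: float = 100.0
    min_length: int = 12
    recursion_depth: int = 5  # look-ahead probes (unit lengths) past a mismatch

    def __post_init__(self) -> None:
        if not (1 <= self.unit_min <= self.unit_max):
            raise ValueError("need 1 <= unit_min <= unit_max")
        if not (0 < self.perfection_min <= self.perfection_max <= 100):
            raise ValueError("need 0 < perfection_min <= perfection_max <= 100")


@dataclass(frozen=True)
class MicrosatelliteHit:
    scaffold: str
    start: int
    end: int
    unit: str  # canonical (lexicographically least) rotation of the observed motif
    copies: float
    perfection: float
    n_count: int

    @property
    def unit_size(self) -> int:
        return len(self.unit)

    def __len__(self) -> int:
        return self.end - self.start


def canonical_rotation(motif: str) -> str:
    """Lexicographically least rotation of a motif (score-equivalent phases)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number power of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def locus_perfection(seq: str, start: int, end: int, motif: str, phase_origin: int) -> float:
    """Percent of positions matching the perfect repeat of ``motif`` anchored at
    ``phase_origin`` (ungapped)."""
    u = len(motif)
    matches = sum(
        1 for p in range(start, end) if seq[p] == motif[(p - phase_origin) % u]
    )
    return 100.0 * matches / (end - start)


def _extend(
    seq: str, anchor: int, motif: str, params: MicrosatParams
) -> tuple[int, int]:
    """Bidirectional unit-block extension from a two-copy seed at ``anchor``.

    The sequence on each side of the seed is consumed in whole unit-length
    blocks.  A block is "good" when >= 75% of its positions match the
    in-phase perfect repeat; walking stops after ``recursion_depth``
    consecutive bad blocks (the look-ahead failed to restore matching) or
    when an N run exceeds the tolerance.  Each side is then trimmed to the
    farthest block whose boundary block is at least half matched, whose
    outermost three blocks average >= 60% matches (rejects chance matches in
    flanking sequence), and that keeps the whole-locus perfection at or
    above the configured minimum.  Returns the (start, end) of the locus.
    """
    u = len(motif)
    L = len(seq)
    R = max(1, params.recursion_depth)

    def in_phase(p: int) -> bool:
        c = seq[p]
        return c != "N" and c == motif[(p - anchor) % u]

    seed_lo, seed_hi = anchor, anchor + 2 * u  # two exact copies by construction

    def walk(step: int) -> list[int]:
        """Per-block match counts moving away from the seed."""
        counts: list[int] = []
        bad_streak = 0
        run_n = 0
        k = 0
        while True:
            if step > 0:
                lo = seed_hi + k * u
                hi = lo + u
            else:
                hi = seed_lo - k * u
                lo = hi - u
            if lo < 0 or hi > L:
                break
            block = seq[lo:hi] if step > 0 else seq[lo:hi][::-1]
            n_violation = False
            for c in block:
                if c == "N":
                    run_n += 1
                    if run_n > params.max_successive_n:
                        n_violation = True
                        break
                else:
                    run_n = 0
            if n_violation:
                break
            m = sum(in_phase(p) for p in range(lo, hi))
            counts.append(m)
            if m / u >= _GOOD_BLOCK_FRAC:
                bad_streak = 0
            else:
                bad_streak += 1
                if bad_streak >= R:
                    break
            k += 1
        return counts

    right = walk(+1)
    left = walk(-1)

    base_matches = 2 * u
    need = params.perfection_min / 100.0

    def best_blocks(counts: list[int], other_m: int, other_blocks: int) -> int:
        cums = []
        cum = 0
        for m in counts:
            cum += m
            cums.append(cum)
        best, best_score = 0, 0.0
        for nb in range(1, len(counts) + 1):
            score = cums[nb - 1] - _MISMATCH_PENALTY * (nb * u - cums[nb - 1])
            if score < best_score:
                continue
            total_m = base_matches + other_m + cums[nb - 1]
            total_l = (2 + other_blocks + nb) * u
            if total_m / total_l >= need:
                best, best_score = nb, score
        return best

    # iterate so each side sees the other's final contribution
    r = best_blocks(right, 0, 0)
    l = best_blocks(left, sum(right[:r]), r)
    r = best_blocks(right, sum(left[:l]), l)

    return seed_lo - l * u, seed_hi + r * u


def find_microsatellites(
    seq: GenomeSequence, params: MicrosatParams | None = None
) -> list[MicrosatelliteHit]:
    """Find maximal, non-nested imperfect tandem repeats in one scaffold.

    When hits of different unit sizes cover the same span the hit with the
    higher perfection wins, ties broken in favour of the smaller unit.
    """
    params = params or MicrosatParams()
    s = seq.seq
    L = len(s)
    raw: list[MicrosatelliteHit] = []
    seen: set[tuple[int, int, int]] = set()
    for u in range(max(2, params.unit_min), params.unit_max + 1):
        i = 0
        limit = L - 2 * u
        while i <= limit:
            motif = s[i : i + u]
            if "N" in motif or not is_primitive(motif) or s[i + u : i + 2 * u] != motif:
                i += 1
                continue
            # every seed is tried: a seed whose motif absorbed a substitution
            # anchors a weaker extension, and a later clean seed must be able
            # to supersede it (resolution keeps the best span)
            start, end = _extend(s, i, motif, params)
            key = (start, end, u)
            if key not in seen:
                seen.add(key)
                perfection = locus_perfection(s, start, end, motif, i)
                if (
                    end - start >= params.min_length
                    and params.perfection_min <= perfection <= params.perfection_max
                ):
                    raw.append(
                        MicrosatelliteHit(
                            scaffold=seq.name,
                            start=start,
                            end=end,
                            unit=canonical_rotation(motif),
                            copies=(end - start) / u,
                            perfection=perfection,
                            n_count=s[start:end].count("N"),
                        )
                    )
            i += 1
    raw = _merge_fragments(s, raw, params)
    return _resolve_nesting(raw)


def _max_n_run(segment: str) -> int:
    run = best = 0
    for c in segment:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


def _merge_fragments(
    seq: str, hits: list[MicrosatelliteHit], params: MicrosatParams
) -> list[MicrosatelliteHit]:
    """Join same-unit hits split by a dense error patch.

    Two hits of the same unit size whose gap is at most ``recursion_depth``
    units merge when some rotation of the left hit's unit keeps the merged
    span's perfection above the minimum; an out-of-phase pair (an indel-like
    slip) fails this test and stays split.  Grouping is by unit size rather
    than motif because a substitution inside one fragment's seed yields a
    slightly different observed motif for the same underlying repeat."""
    from collections import defaultdict

    by_size: dict[tuple[str, int], list[MicrosatelliteHit]] = defaultdict(list)
    for h in hits:
        by_size[(h.scaffold, h.unit_size)].append(h)
    out: list[MicrosatelliteHit] = []
    for (scaffold, u), group in by_size.items():
        group.sort(key=lambda h: (h.start, h.end))
        cur = group[0]
        for h in group[1:]:
            if cur.start <= h.start and h.end <= cur.end:
                if h.perfection > cur.perfection and len(h) == len(cur):
                    cur = h
                continue  # contained duplicate from another seed
            merged = None
            if h.start - cur.end <= params.recursion_depth * u and h.end > cur.end:
                span = seq[cur.start : h.end]
                if _max_n_run(span) <= params.max_successive_n:
                    best_unit, best = cur.unit, -1.0
                    for unit in (cur.unit, h.unit):
                        for r in range(u):
                            rot = unit[r:] + unit[:r]
                            p = locus_perfection(seq, cur.start, h.end, rot, cur.start)
                            if p > best:
                                best_unit, best = rot, p
                    if best >= params.perfection_min:
                        merged = MicrosatelliteHit(
                            scaffold=scaffold,
                            start=cur.start,
                            end=h.end,
                            unit=canonical_rotation(best_unit),
                            copies=(h.end - cur.start) / u,
                            perfection=best,
                            n_count=span.count("N"),
                        )
            if merged is not None:
                cur = merged
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return out


def _resolve_nesting(hits: list[MicrosatelliteHit]) -> list[MicrosatelliteHit]:
    """Keep maximal non-nested hits.

    Hits of different unit sizes covering essentially the same span (>= 90%
    reciprocal overlap) compete first: the smaller unit wins unless the
    larger unit's perfection is more than 3 points higher, since interior
    mismatches of a short-unit repeat can always be absorbed into a longer
    motif.  Among the survivors, priority is span length, then perfection,
    then smaller unit.
    """
    drop: set[int] = set()
    by_scaffold: dict[str, list[int]] = {}
    for idx, h in enumerate(hits):
        by_scaffold.setdefault(h.scaffold, []).append(idx)
    for idxs in by_scaffold.values():
        for ii, i in enumerate(idxs):
            a = hits[i]
            for j in idxs[ii + 1 :]:
                b = hits[j]
                if a.unit_size == b.unit_size:
                    continue
                ov = min(a.end, b.end) - max(a.start, b.start)
                if ov <= 0 or ov < 0.9 * len(a) or ov < 0.9 * len(b):
                    continue
                small, big = (a, b) if a.unit_size < b.unit_size else (b, a)
                if small.perfection >= big.perfection - 3.0:
                    drop.add(i if big is a else j)
                else:
                    drop.add(i if small is a else j)
    hits = [h for idx, h in enumerate(hits) if idx not in drop]
    order = sorted(
        hits,
        key=lambda h: (-len(h), -h.perfection, h.unit_size, h.start),
    )
    kept: list[MicrosatelliteHit] = []
    for h in order:
        nested = False
        for k in kept:
            if k.scaffold != h.scaffold:
                continue
            inside = k.start <= h.start and h.end <= k.end
            contains = h.start <= k.start and k.end <= h.end
            if inside or (contains and (k.perfection, -k.unit_size) >= (h.perfection, -h.unit_size)):
                nested = True
                break
        if not nested:
            kept = [
                k
                for k in kept
                if not (
                    k.scaffold == h.scaffold and h.start <= k.start and k.end <= h.end
                )
            ]
            kept.append(h)
    kept.sort(key=lambda h: (h.scaffold, h.start, h.end))
    return kept


def find_microsatellites_all(
    seqs: Iterable[GenomeSequence], params: MicrosatParams | None = None
) -> list[MicrosatelliteHit]:
    out: list[MicrosatelliteHit] = []
    for s in seqs:
        out.extend(find_microsatellites(s, params))
    return out


@dataclass(frozen=True)
class MicrosatReport:
    counts_by_unit_size: dict[int, int]
    total: int
    ungapped_bp: int
    spacing_bp: int | None  # mean bp of ungapped sequence per microsatellite

    @property
    def density_defined(self) -> bool:
        return self.spacing_bp is not None


def microsat_report(
    hits: Sequence[MicrosatelliteHit], ungapped_bp: int
) -> MicrosatReport:
    """Per-unit-size tallies plus the mean ungapped spacing between hits."""
    if ungapped_bp <= 0:
        raise ValueError("ungapped_bp must be positive")
    counts = Counter(h.unit_size for h in hits)
    total = sum(counts.values())
    spacing = round(ungapped_bp / total) if total else None
    return MicrosatReport(
        counts_by_unit_size={u: counts.get(u, 0) for u in sorted(counts)},
        total=total,
        ungapped_bp=ungapped_bp,
        spacing_bp=spacing,
    )
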