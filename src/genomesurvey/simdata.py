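"""Synthetic genomes, depth, read pairs, and variants with a truth ledger.

The generator emulates the statistical structure the survey analyses assume:
multi-scaffold assemblies with N-gap runs, GC-heterogeneous background,
planted interspersed and tandem duplications (copy number relative to the
diploid baseline), heterozygous/homozygous deletions, imperfect
microsatellites, masked repeats, gene intervals, and Poisson window depth
modulated by a smooth multiplicative GC bias.  Every simulator is a pure
function of its configuration (seed mandatory), and every planted feature is
recorded in a machine-readable :class:`SimulationTruth` ledger so that each
pipeline stage can be scored against known truth.

Depth is simulated at window granularity (the read-depth caller operates on
windows, so per-read placement adds cost without test power); the read-pair
simulator computes everted-pair coordinates analytically from the planted
tandem-duplication intervals rather than by running an aligner.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnv import ReadPairRecord
from .depthmodel import DEPTH_TABLE_HEADER, make_windows
from .seqio import GenomeSequence, GenomicInterval, IntervalSet, write_bed, write_fasta
from .variants import VariantRecord, filter_variants

EVENT_KINDS = {
    "duplication",
    "deletion",
    "tandem_duplication",
    "microsatellite",
    "gap",
    "repeat_mask",
    "gene",
}

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEvent:
    kind: str
    scaffold: str
    start: int
    end: int
    copy_number: float | None = None  # duplications (diploid baseline = 2)
    zygosity: str | None = None  # deletions: heterozygous | homozygous
    unit: str | None = None  # microsatellites
    perfection: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ConfigError(f"invalid event interval {self.start}-{self.end}")

    @property
    def copy_factor(self) -> float:
        """Expected depth multiplier relative to the diploid baseline."""
        if self.kind in {"duplication", "tandem_duplication"}:
            cn = self.copy_number if self.copy_number is not None else 4.0
            return cn / 2.0
        if self.kind == "deletion":
            return 0.0 if self.zygosity == "homozygous" else 0.5
        if self.kind == "gap":
            return 0.0
        return 1.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults emulate the survey's sequencing regime: 2×125 bp paired reads,
    deep coverage, ~42% GC background, and a smooth linear GC bias
    f(gc) = 0.5 + gc (identity-free unless slope/intercept are reset).
    """

    seed: int
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    gc_profile: tuple[float, ...] = (0.38, 0.42, 0.46)  # cycled per region
    gc_region_bp: int = 50_000
    window_width: int = 500
    window_depth_lambda: float = 100.0  # mean per-bp depth, diploid baseline
    depth_cv: float = 0.05  # Gamma overdispersion of the window rate
    gc_bias_intercept: float = 0.5
    gc_bias_slope: float = 1.0
    events: list[PlantedEvent] = field(default_factory=list)
    allow_overlap: bool = False
    variant_rate: float = 0.0025  # per ungapped bp
    variant_class_mix: tuple[float, float, float, float] = (0.884, 0.020, 0.093, 0.003)
    variant_depth_mean: float = 30.0
    variant_high_conf_fraction: float = 0.9
    read_length: int = 125
    insert_mean: int = 500
    insert_sd: int = 50

    def gc_bias(self, gc: float) -> float:
        return self.gc_bias_intercept + self.gc_bias_slope * gc

    def validate(self) -> None:
        by_scaffold: dict[str, list[PlantedEvent]] = {}
        names = {f"scaffold_{i+1}" for i in range(self.n_scaffolds)}
        for ev in self.events:
            if ev.scaffold not in names:
                raise ConfigError(f"event on unknown scaffold {ev.scaffold!r}")
            if ev.end > self.scaffold_length:
                raise ConfigError(f"event {ev} extends past scaffold end")
            by_scaffold.setdefault(ev.scaffold, []).append(ev)
        if not self.allow_overlap:
            # annotation-only events (genes, masked repeats) may overlap others
            material = {"duplication", "deletion", "tandem_duplication", "microsatellite", "gap"}
            for evs in by_scaffold.values():
                evs = sorted(
                    (e for e in evs if e.kind in material), key=lambda e: e.start
                )
                for a, b in zip(evs, evs[1:]):
                    if b.start < a.end:
                        raise ConfigError(
                            f"overlapping events {a} / {b}; set allow_overlap=True"
                        )


@dataclass
class SimulationTruth:
    """Ledger of every planted feature, with realized coordinates."""

    events: list[PlantedEvent]
    scaffold_lengths: dict[str, int]
    window_width: int
    expected_variant_counts: dict[str, int] = field(default_factory=dict)

    def of_kind(self, *kinds: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.kind in kinds]

    def copy_factor(self, scaffold: str, start: int, end: int) -> float:
        """bp-weighted expected depth multiplier over an interval."""
        total = end - start
        weighted = float(total)  # baseline factor 1
        for ev in self.events:
            if ev.scaffold != scaffold:
                continue
            ov = min(end, ev.end) - max(start, ev.start)
            if ov > 0:
                weighted += ov * (ev.copy_factor - 1.0)
        return weighted / total

    def to_json(self, path: str | Path) -> None:
        doc = {
            "events": [asdict(e) for e in self.events],
            "scaffold_lengths": self.scaffold_lengths,
            "window_width": self.window_width,
            "expected_variant_counts": self.expected_variant_counts,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            events=[PlantedEvent(**e) for e in doc["events"]],
            scaffold_lengths=doc["scaffold_lengths"],
            window_width=doc["window_width"],
            expected_variant_counts=doc.get("expected_variant_counts", {}),
        )


@dataclass
class GenomeSimulation:
    assembly: list[GenomeSequence]
    repeats: IntervalSet
    gaps: IntervalSet
    genes: IntervalSet
    truth: SimulationTruth

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": outdir / "assembly.fasta",
            "repeats": outdir / "repeats.bed",
            "gaps": outdir / "gaps.bed",
            "genes": outdir / "genes.gff3",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.assembly, paths["assembly"])
        write_bed(self.repeats, paths["repeats"])
        write_bed(self.gaps, paths["gaps"])
        _write_gff3(self.genes, paths["genes"])
        self.truth.to_json(paths["truth"])
        return paths


def _write_gff3(genes: IntervalSet, path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for iv in genes:
            fh.write(
                f"{iv.scaffold}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={iv.label}\n"
            )


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _degrade_repeat(
    rng: np.random.Generator, motif: str, length: int, perfection: float
) -> str:
    """A perfect tandem repeat with substitutions bringing it to ``perfection``.

    Substitutions fall in the interior (the first and last unit stay intact)
    so that the locus boundary is well defined, and at least one exact
    adjacent double copy of the motif is preserved so the locus remains
    seedable; substituted bases always differ from the perfect base.
    """
    u = len(motif)
    perfect = (motif * (length // u + 2))[:length]
    n_sub = int(round(length * (1.0 - perfection / 100.0)))
    if n_sub == 0:
        return perfect
    interior = np.arange(u, max(u + 1, length - u))
    n_sub = min(n_sub, len(interior))
    alphabet = "ACGT"
    for _ in range(200):
        positions = interior[rng.choice(len(interior), size=n_sub, replace=False)]
        flags = np.ones(length, dtype=bool)
        flags[positions] = False
        # verify an intact double copy survives at some phase-0 offset
        ok = any(
            flags[s : s + 2 * u].all()
            for s in range(0, length - 2 * u + 1, u)
        )
        if ok:
            break
    out = list(perfect)
    for p in positions:
        choices = [c for c in alphabet if c != perfect[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_genome(config: SimulationConfig) -> GenomeSimulation:
    """Draw the background assembly and plant every configured feature."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    assembly: list[GenomeSequence] = []
    realized: list[PlantedEvent] = []
    repeats, gaps, genes = IntervalSet(), IntervalSet(), IntervalSet()
    for i in range(config.n_scaffolds):
        name = f"scaffold_{i+1}"
        codes = np.empty(config.scaffold_length, dtype=np.int64)
        pos = 0
        region = 0
        while pos < config.scaffold_length:
            gc = config.gc_profile[region % len(config.gc_profile)]
            L = min(config.gc_region_bp, config.scaffold_length - pos)
            codes[pos : pos + L] = _background(rng, L, gc)
            pos += L
            region += 1
        seq = np.array(list("ACGT"))[codes]
        for ev in [e for e in config.events if e.scaffold == name]:
            span = ev.end - ev.start
            if ev.kind == "gap":
                seq[ev.start : ev.end] = "N"
                gaps.add(GenomicInterval(name, ev.start, ev.end, "gap"))
            elif ev.kind == "microsatellite":
                locus = _degrade_repeat(
                    rng, ev.unit, span, ev.perfection if ev.perfection else 100.0
                )
                seq[ev.start : ev.end] = list(locus)
                # break the repeat phase in the flanking unit on each side so
                # the ledger's boundaries are true boundaries
                u = len(ev.unit)
                for p in range(max(0, ev.start - u), ev.start):
                    expected = ev.unit[(p - ev.start) % u]
                    if seq[p] == expected:
                        choices = [c for c in "ACGT" if c != expected]
                        seq[p] = choices[rng.integers(3)]
                for p in range(ev.end, min(len(seq), ev.end + u)):
                    expected = ev.unit[(p - ev.start) % u]
                    if seq[p] == expected:
                        choices = [c for c in "ACGT" if c != expected]
                        seq[p] = choices[rng.integers(3)]
            elif ev.kind == "repeat_mask":
                repeats.add(GenomicInterval(name, ev.start, ev.end, ev.label or "repeat"))
            elif ev.kind == "gene":
                genes.add(
                    GenomicInterval(name, ev.start, ev.end, ev.label or f"gene_{len(genes)+1}")
                )
            realized.append(ev)
        assembly.append(GenomeSequence(name, "".join(seq)))
    truth = SimulationTruth(
        events=realized,
        scaffold_lengths={s.name: len(s) for s in assembly},
        window_width=config.window_width,
    )
    return GenomeSimulation(
        assembly=assembly, repeats=repeats, gaps=gaps, genes=genes, truth=truth
    )


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------


def simulate_depth(
    assembly: Sequence[GenomeSequence],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Windowed depth table under Poisson counts, copy-number track, and GC bias.

    Window counts are Poisson with rate λ·width·(copy factor)·f(GC), with a
    small Gamma jitter on the rate (CV = ``depth_cv``) reproducing the
    overdispersion of real sequencing depth.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    windows = make_windows(assembly, config.window_width)
    rows = []
    shape = None
    if config.depth_cv > 0:
        shape = 1.0 / config.depth_cv**2
    for w in windows:
        # gap events carry factor 0, so N runs already suppress the rate
        factor = truth.copy_factor(w.scaffold, w.start, w.end)
        lam = (
            config.window_depth_lambda
            * w.width
            * factor
            * config.gc_bias(w.gc_fraction)
        )
        if shape is not None and lam > 0:
            lam *= rng.gamma(shape, 1.0 / shape)
        count = rng.poisson(lam) if lam > 0 else 0
        rows.append((w.scaffold, w.start, w.end, count / w.width))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "depth"])


def write_depth_table_df(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(DEPTH_TABLE_HEADER + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------


def simulate_read_pairs(
    truth: SimulationTruth,
    config: SimulationConfig,
    n_pairs: int = 50_000,
) -> list[ReadPairRecord]:
    """Concordant pairs plus analytically placed everted junction pairs.

    For each planted tandem duplication, reads spanning the donor junction
    (end of copy 1 → start of copy 2) are mapped back onto the single-copy
    reference, where the downstream mate lands upstream in everted
    orientation.  The expected junction-pair count equals the physical
    coverage of the junction point.
    """
    rng = np.random.default_rng(config.seed + 2)
    total_len = sum(truth.scaffold_lengths.values())
    scaffolds = sorted(truth.scaffold_lengths)
    weights = np.array([truth.scaffold_lengths[s] for s in scaffolds], dtype=float)
    weights /= weights.sum()
    rl, im, isd = config.read_length, config.insert_mean, config.insert_sd
    pairs: list[ReadPairRecord] = []
    for _ in range(n_pairs):
        scaf = scaffolds[rng.choice(len(scaffolds), p=weights)]
        L = truth.scaffold_lengths[scaf]
        insert = max(2 * rl, int(round(rng.normal(im, isd))) if isd > 0 else im)
        pos1 = int(rng.integers(0, max(1, L - insert)))
        pos2 = pos1 + insert - rl
        pairs.append(ReadPairRecord(scaf, pos1, pos2, "forward", "reverse", insert))
    inner = im - 2 * rl
    for ev in truth.of_kind("tandem_duplication"):
        span = ev.end - ev.start
        if span <= im:
            continue  # junction pairs indistinguishable from concordant noise
        expected = n_pairs * inner / total_len
        n_junction = int(rng.poisson(expected))
        for _ in range(n_junction):
            insert = max(2 * rl + 1, int(round(rng.normal(im, isd))) if isd > 0 else im)
            # donor coordinates: junction at ev.end; left mate fully in copy 1,
            # right mate fully in copy 2
            lo, hi = ev.end - insert + rl, ev.end - rl
            if hi <= lo:
                continue
            d1 = int(rng.integers(lo, hi))
            r1 = d1  # forward mate, reference coords (copy 1 == reference)
            r2 = d1 + insert - rl - span  # reverse mate mapped into copy 1
            if r2 < 0:
                continue
            pairs.append(
                ReadPairRecord(
                    ev.scaffold, r2, r1, "reverse", "forward", insert=r1 + rl - r2
                )
            )
    return pairs


def write_pair_table(pairs: Iterable[ReadPairRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("#scaffold\tpos1\torient1\tpos2\torient2\n")
        for p in pairs:
            fh.write(f"{p.scaffold}\t{p.pos1}\t{p.orient1}\t{p.pos2}\t{p.orient2}\n")


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

_ALPHABET = "ACGT"


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [c for c in _ALPHABET if c != base]
    return choices[rng.integers(3)]


def simulate_variants(
    assembly: Sequence[GenomeSequence],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> list[VariantRecord]:
    """Plant unambiguous SNV/MNV/indel/replacement records at the configured mix.

    Depth is Poisson around ``variant_depth_mean``; a configured fraction of
    records receives probability >= 0.95, the rest lower; strand support
    splits the depth binomially.  The expected post-filter counts are recorded
    in the truth ledger.
    """
    if config.variant_rate <= 0:
        raise ConfigError("variant_rate must be > 0")
    rng = np.random.default_rng(config.seed + 3)
    mix = np.array(config.variant_class_mix, dtype=float)
    mix = mix / mix.sum()
    records: list[VariantRecord] = []
    planted_classes: dict[str, int] = {}
    for scaf in assembly:
        seq = scaf.seq
        n = rng.poisson(config.variant_rate * scaf.ungapped_length)
        # draw candidate positions away from scaffold ends and N runs
        positions = np.sort(rng.choice(len(seq) - 12, size=min(n, len(seq) // 20), replace=False)) + 1
        for pos in positions:
            window = seq[pos : pos + 8]
            if "N" in window:
                continue
            cls = ("SNV", "MNV", "indel", "replacement")[rng.choice(4, p=mix)]
            ref, alt = _make_alleles(rng, seq, int(pos), cls)
            realized_cls = cls if cls != "indel" else (
                "insertion" if len(alt) > len(ref) else "deletion"
            )
            planted_classes[realized_cls] = planted_classes.get(realized_cls, 0) + 1
            depth = int(rng.poisson(config.variant_depth_mean))
            if rng.random() < config.variant_high_conf_fraction:
                prob = float(rng.uniform(0.95, 1.0))
            else:
                prob = float(rng.uniform(0.5, 0.95))
            fwd = int(rng.binomial(depth, 0.5)) if depth else 0
            records.append(
                VariantRecord(
                    scaffold=scaf.name,
                    pos=int(pos) + 1,
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    prob=prob,
                    fwd_support=fwd,
                    rev_support=depth - fwd,
                )
            )
    kept, _ = filter_variants(records)
    truth.expected_variant_counts = {
        "planted": len(records),
        "expected_kept": len(kept),
        **planted_classes,
    }
    return records


def _make_alleles(
    rng: np.random.Generator, seq: str, pos: int, cls: str
) -> tuple[str, str]:
    if cls == "SNV":
        ref = seq[pos]
        return ref, _other_base(rng, ref)
    if cls == "MNV":
        k = int(rng.integers(2, 4))
        ref = seq[pos : pos + k]
        alt = "".join(_other_base(rng, c) for c in ref)
        return ref, alt
    if cls == "indel":
        if rng.random() < 0.5:  # insertion
            ref = seq[pos]
            ins = "".join(_ALPHABET[rng.integers(4)] for _ in range(int(rng.integers(1, 6))))
            return ref, ref + ins
        d = int(rng.integers(1, 6))
        return seq[pos : pos + 1 + d], seq[pos]
    # replacement: unequal lengths, ends guaranteed to differ -> no trimming
    a = int(rng.integers(2, 4))
    b = a + 1 if rng.random() < 0.5 else max(1, a - 1)
    ref = seq[pos : pos + a]
    if b == 1:
        choices = [c for c in _ALPHABET if c != ref[0] and c != ref[-1]]
        return ref, choices[rng.integers(len(choices))]
    alt = [_other_base(rng, ref[0])]
    alt += [_ALPHABET[rng.integers(4)] for _ in range(b - 2)]
    alt.append(_other_base(rng, ref[-1]))
    return ref, "".join(alt)


def recovery_config(seed: int, scaffold_length: int = 2_500_000) -> SimulationConfig:
    """The standard two-scaffold, twenty-event recovery benchmark (~5 Mb).

    Ten events per scaffold: interspersed duplications at copy number 3–6, a
    tandem duplication, heterozygous and homozygous deletions (all spanning
    at least eight windows), plus assembly gaps, masked repeats, and gene
    intervals as annotation fodder.
    """
    events: list[PlantedEvent] = []
    for scaf in ("scaffold_1", "scaffold_2"):
        anchor = 150_000
        step = 220_000

        def at(i: int, span: int) -> tuple[int, int]:
            start = anchor + i * step
            return start, start + span

        specs = [
            ("duplication", 5_000, {"copy_number": 3}),
            ("duplication", 8_000, {"copy_number": 4}),
            ("duplication", 4_000, {"copy_number": 6}),
            ("tandem_duplication", 6_000, {"copy_number": 4}),
            ("deletion", 5_000, {"zygosity": "heterozygous"}),
            ("deletion", 7_000, {"zygosity": "heterozygous"}),
            ("deletion", 4_000, {"zygosity": "homozygous"}),
            ("deletion", 6_000, {"zygosity": "homozygous"}),
            ("duplication", 10_000, {"copy_number": 3}),
            ("deletion", 5_000, {"zygosity": "heterozygous"}),
        ]
        for i, (kind, span, kw) in enumerate(specs):
            start, end = at(i, span)
            events.append(PlantedEvent(kind, scaf, start, end, **kw))
        # annotation fodder: a gap, a masked repeat, and genes (one on a dup)
        g0 = anchor + len(specs) * step
        events.append(PlantedEvent("gap", scaf, g0, g0 + 2_000))
        events.append(PlantedEvent("repeat_mask", scaf, g0 + 10_000, g0 + 12_000))
        events.append(
            PlantedEvent("gene", scaf, at(0, 5_000)[0] + 1_000, at(0, 5_000)[0] + 3_000,
                         label=f"{scaf}_gene1")
        )
        events.append(
            PlantedEvent("gene", scaf, g0 + 20_000, g0 + 22_000, label=f"{scaf}_gene2")
        )
    return SimulationConfig(seed=seed, scaffold_length=scaffold_length, events=events)


def score_cnv_recovery(
    truth: SimulationTruth,
    segments,
    n_windows: int,
    min_reciprocal: float = 0.5,
) -> dict[str, float]:
    """Sensitivity over qualifying planted events and false segments per 10k
    neutral windows.

    An event qualifies if it spans >= 6 windows and is a duplication at copy
    number >= 3 or a deletion (one or zero remaining copies).  A call counts
    as a recovery when its type matches and the reciprocal overlap is at
    least ``min_reciprocal``.  A call overlapping no planted event of its
    type is a false segment.
    """
    width = truth.window_width
    qualifying = []
    for ev in truth.of_kind("duplication", "tandem_duplication", "deletion"):
        if ev.end - ev.start < 6 * width:
            continue
        if ev.kind == "deletion" or (ev.copy_number or 4) >= 3:
            qualifying.append(ev)
    ev_type = {
        "duplication": "duplication",
        "tandem_duplication": "duplication",
        "deletion": "deletion",
    }
    recovered = 0
    for ev in qualifying:
        hit = False
        for seg in segments:
            if seg.scaffold != ev.scaffold or seg.type != ev_type[ev.kind]:
                continue
            ov = min(seg.end, ev.end) - max(seg.start, ev.start)
            if ov <= 0:
                continue
            if ov >= min_reciprocal * (ev.end - ev.start) and ov >= min_reciprocal * (
                seg.end - seg.start
            ):
                hit = True
                break
        recovered += hit
    false_segments = 0
    for seg in segments:
        touches = any(
            seg.scaffold == ev.scaffold
            and seg.type == ev_type[ev.kind]
            and min(seg.end, ev.end) > max(seg.start, ev.start)
            for ev in truth.of_kind("duplication", "tandem_duplication", "deletion")
        )
        false_segments += not touches
    event_windows = sum(
        (ev.end - ev.start) // width
        for ev in truth.of_kind("duplication", "tandem_duplication", "deletion", "gap")
    )
    neutral_windows = max(1, n_windows - event_windows)
    return {
        "n_qualifying": len(qualifying),
        "sensitivity": recovered / len(qualifying) if qualifying else float("nan"),
        "false_segments": false_segments,
        "false_per_10k_neutral_windows": 1e4 * false_segments / neutral_windows,
    }


def _random_primitive_motif(rng: np.random.Generator, unit_size: int) -> str:
    while True:
        motif = "".join(_ALPHABET[rng.integers(4)] for _ in range(unit_size))
        from .microsat import is_primitive

        if is_primitive(motif):
            return motif


def microsat_config(
    seed: int, n_loci: int = 50, scaffold_length: int = 100_000
) -> SimulationConfig:
    """One scaffold with ``n_loci`` planted imperfect microsatellites.

    Unit sizes cycle over 2–10, perfection is drawn uniformly in [80, 100],
    and locus lengths span 15–40 whole units (minimum 36 bp), spaced evenly
    so loci never interact.
    """
    rng = np.random.default_rng(seed + 5)
    slot = scaffold_length // n_loci
    events: list[PlantedEvent] = []
    for i in range(n_loci):
        u = 2 + i % 9
        motif = _random_primitive_motif(rng, u)
        n_units = int(rng.integers(15, 41))
        length = max(36, u * n_units)
        length = min(length, slot - 200)
        length -= length % u  # whole-unit loci
        start = i * slot + 100
        perfection = float(rng.uniform(80.0, 100.0))
        events.append(
            PlantedEvent(
                "microsatellite",
                "scaffold_1",
                start,
                start + length,
                unit=motif,
                perfection=perfection,
            )
        )
    return SimulationConfig(
        seed=seed, n_scaffolds=1, scaffold_length=scaffold_length, events=events
    )


def score_microsat_recovery(truth: SimulationTruth, hits, min_reciprocal: float = 0.9):
    """Fraction of planted loci recovered with the correct unit size and
    >= ``min_reciprocal`` reciprocal span overlap."""
    planted = truth.of_kind("microsatellite")
    recovered = 0
    for ev in planted:
        ok = False
        for h in hits:
            if h.scaffold != ev.scaffold or len(h.unit) != len(ev.unit):
                continue
            ov = min(h.end, ev.end) - max(h.start, ev.start)
            if ov <= 0:
                continue
            if ov >= min_reciprocal * (ev.end - ev.start) and ov >= min_reciprocal * (
                h.end - h.start
            ):
                ok = True
                break
        recovered += ok
    return {
        "n_planted": len(planted),
        "recovered": recovered,
        "recovery_fraction": recovered / len(planted) if planted else float("nan"),
    }


def shared_duplication_pair(seed: int, scaffold_length: int = 120_000):
    """Two independent assemblies sharing exactly one duplicated region.

    Assembly A and assembly B have unrelated backgrounds except for one
    4 kb region copied from A into B; each also carries one private
    duplication call over background found nowhere in the other assembly.
    Returns (assembly_a, segments_a, assembly_b, segments_b) with the shared
    call listed first on each side.
    """
    from .cnv import CNVSegment

    cfg_a = SimulationConfig(seed=seed, n_scaffolds=1, scaffold_length=scaffold_length)
    cfg_b = SimulationConfig(seed=seed + 101, n_scaffolds=1, scaffold_length=scaffold_length)
    sim_a = simulate_genome(cfg_a)
    sim_b = simulate_genome(cfg_b)
    a = sim_a.assembly[0]
    b = sim_b.assembly[0]
    shared = a.seq[30_000:34_000]
    b = GenomeSequence(b.name, b.seq[:60_000] + shared + b.seq[64_000:])

    def dup(scaf: str, start: int, end: int) -> CNVSegment:
        return CNVSegment(scaf, start, end, "duplication", 8, float("nan"))

    segments_a = [dup(a.name, 30_000, 34_000), dup(a.name, 70_000, 74_000)]
    segments_b = [dup(b.name, 60_000, 64_000), dup(b.name, 20_000, 24_000)]
    return [a], segments_a, [b], segments_b


def simulate_reads(
    assembly: Sequence[GenomeSequence],
    config: SimulationConfig,
    coverage: float = 30.0,
    read_length: int | None = None,
) -> list[str]:
    """Error-free single-end reads at the requested coverage (for k-mer surveys)."""
    rng = np.random.default_rng(config.seed + 4)
    rl = read_length or config.read_length
    reads: list[str] = []
    for scaf in assembly:
        n_reads = int(round(coverage * len(scaf) / rl))
        starts = rng.integers(0, len(scaf) - rl + 1, size=n_reads)
        reads.extend(scaf.seq[s : s + rl] for s in sorted(starts))
    return reads


def write_vcf(
    records: Sequence[VariantRecord],
    assembly: Sequence[GenomeSequence],
    path: str | Path,
) -> None:
    """Write records as VCF 4.2 with INFO DP/PR/ADF/ADR."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for s in assembly:
            fh.write(f"##contig=<ID={s.name},length={len(s)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=PR,Number=1,Type=Float,Description="Variant probability">\n')
        fh.write('##INFO=<ID=SF,Number=1,Type=Integer,Description="Forward strand support">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Reverse strand support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.scaffold, r.pos)):
            info = f"DP={r.depth};PR={r.prob:.4f}"
            if r.fwd_support is not None:
                info += f";SF={r.fwd_support};SR={r.rev_support}"
            fh.write(
                f"{r.scaffold}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n"
            )
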