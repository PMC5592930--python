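# Methods

This note documents the models and procedures implemented in `genomesurvey`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Read-depth CNV model

The depth model assumes reads sample the genome approximately uniformly
after conditioning on local GC content, so that per-window depth is
proportional to the underlying copy number. Windows are nonoverlapping and
fixed-width (default 500 bp, `make_windows(width=...)`, minimum 50 bp); the
trailing partial window of each scaffold is kept but flagged and never
enters statistics or calls. Raw depth is mean per-bp coverage — from BAM,
the aligned bases of primary, non-duplicate reads with MAPQ ≥ 0 by default
(multi-mapping evidence is deliberately retained, since duplications attract
it), or a plain windowed TSV taken as-is.

**GC correction.** Windows are binned by GC fraction of their non-N bases
(bin width 0.01). A window's corrected depth is raw × (global mean)/(bin
mean); bins holding fewer than 50 usable windows fall back to a factor of 1.
Windows with more than 50% N are excluded from the bin statistics and
flagged. This is the minimal multiplicative model: it removes any smooth
bias that is a function of GC alone and by construction makes every
well-occupied bin's mean equal the global mean, while redistributing rather
than inflating depth (global mean preserved; tested to 1%).

**Calibration.** Global mean and SD come from a Gaussian least-squares fit
to the corrected-depth histogram (bin width max(1, range/200)), restricted
to bins within ±50% of the modal bin. The mode-centred restriction keeps
duplicated and deleted tails — which are exactly what the caller is looking
for — from biasing the fit; a 5% contaminating mode at 3× depth moves the
fitted mean by well under one SD. If the optimizer fails or the data are
degenerate, the calibration falls back to median and 1.4826·MAD with a
logged warning. Cutoffs are mean + 3 SD (duplication) and mean − 2 SD
(deletion); both multipliers are configurable.

**Calling.** Per scaffold and per call type, windows beyond the cutoff are
marked, a seven-window frame slides across the run, and every frame with at
least six marks seeds a call. Overlapping or adjacent seed frames merge;
the merged span trims to its outermost marked window; `n_windows` counts
marked windows. Two details are deliberate choices the rule itself does not
fix: (i) trimming to the outermost marked window avoids padding calls with
sub-threshold windows; (ii) flagged windows (gap-dominated or partial) not
only carry no marks but split the window run, so no call ever spans a
flagged window — gap-dominated depth is meaningless and a call bridging it
would be unsupported. Deletion filtering removes marks from windows
overlapping repeat masks or assembly gaps and re-applies the 6-of-7 rule, so
every surviving deletion still satisfies the calling rule (a testable
invariant). Zygosity: a deletion is heterozygous when no constituent marked
window has corrected depth below 5 (one retained haplotype keeps depth near
half the mean), homozygous otherwise; the floor is configurable.

## Everted-pair tandem screen

On a single-copy reference, a mate pair drawn across the junction of a
tandem duplication maps with the reverse mate upstream of the forward mate
(everted orientation). `call_everted_tandem` selects everted pairs,
clusters pairs whose spans overlap or lie within one (median) insert size,
and emits clusters with ≥ 3 supporting pairs as candidates spanning the
union of member spans. The support threshold and cluster gap are
parameters; 3 is the smallest count that cannot arise from a single
mischarted fragment and its optical duplicates.

## Reciprocal mapping and shared duplications

`map_region` is an exact-seed (k = 15), both-strand, ungapped-extension
mapper: extension past a mismatch continues only while overall identity
stays ≥ 0.8, overlapping hits keep the best, and hits shorter than half the
query are dropped. It is intended for the multi-kilobase, high-identity
queries of the shared-duplication comparison, not as a general aligner. A
duplication of assembly A is *shared* iff one of its mapping hits into B
overlaps (≥ 1 bp) a B call and that B call in turn maps back overlapping an
A call — the two-way condition makes the partition symmetric under swapping
the assemblies.

## Survey statistics and genome size

N50 uses the ≥ convention (the scaffold whose addition first reaches half
the total); scaffolds-to-90% is the minimum count of largest scaffolds
reaching 90% of the span; GC excludes N from the denominator; scaffolds
below 1 kb are excluded by default. K-mer counting is exact, in-memory, and
canonical (lexicographic minimum of k-mer and reverse complement; k must be
odd; default k = 21, a standard survey length). The genome-size estimator
smooths the spectrum with a 3-bin moving average, finds the coverage mode
beyond the m = 1 error spike, places the error cutoff at the deepest point
of the valley between spike and mode, and divides the k-mer instances beyond
the cutoff by the peak depth. The peak is refined as the count-weighted
centroid of the raw spectrum within ±25% of the mode: the true k-mer
coverage is rarely an integer, and the centroid — unlike parabolic
interpolation — is exactly equivariant when every multiplicity is scaled
(duplicating all reads changes the estimate by < 2%, tested). A spectrum
with no mode beyond the error region raises an error advising deeper
coverage.

## Microsatellite finder

Loci are seeded on two exact adjacent copies of a primitive motif (unit
2–10) and extended bidirectionally in unit-length blocks, phase-anchored at
the seed. A block keeps the walk alive while ≥ 75% of its positions match
the in-phase perfect repeat; the walk stops after `recursion_depth` (= 5)
consecutive failing blocks — the bounded look-ahead that must "restore
matching" — or when an N run exceeds 2. Each side is then trimmed to the
block boundary maximizing the score (matches − 2·mismatches) subject to
whole-locus perfection ≥ 80%: with ~25% chance matches in flanking
sequence the score decays there, so the boundary cannot drift outward,
while interior error patches are absorbed. Every seed is tried (a seed
whose motif captured a substitution anchors a weaker extension, and a
cleaner seed must be able to supersede it); fragments of the same unit size
split by a dense error patch merge when some rotation of the motif keeps the
joined span above minimum perfection, and out-of-phase pairs (indel-like
slips) stay split. Extension is ungapped throughout — perfection is
defined against the ideal repeat under a fixed phase. Nested hits resolve
to the maximal span; hits of different unit sizes covering essentially the
same span (≥ 90% reciprocal overlap) prefer the smaller unit unless the
larger unit is more than 3 points more perfect, because interior mismatches
of a short-unit repeat can always be re-encoded into a longer motif.
Mononucleotide runs are out of scope (unit ≥ 2); the default minimum locus
length is 12 bp and affects absolute counts, not the finder's properties.
The density report divides ungapped length by the hit count and rounds to
the nearest integer (mean spacing in bp).

## Variant classes, filters, density

Alleles are canonicalized by trimming the longest shared suffix, then the
longest shared prefix (suffix first preserves VCF left-anchoring). Equal
trimmed lengths give SNV (1 bp) or MNV; an emptied allele gives
insertion/deletion; unequal non-empty lengths give a replacement. All
filter thresholds are inclusive: depth ≥ 4, probability ≥ 0.95, and ≥ 1
supporting read on each strand when per-strand fields are present (records
without strand fields are not rejected by that rule, since VCF dialects
vary; strict behaviour is a flag). Density is 1000 × records / callable bp,
with callable bp supplied by the caller — typically the ungapped length of
the scaffolds analysed — and an optional relative change against a
reference density, reported to one decimal.

## Synthetic-data generator

The generator is the package's study-conditions oracle. It emulates: a
multi-scaffold assembly whose background GC follows a piecewise profile
(defaults 38/42/46% over 50 kb regions, bird-like); N-gap runs; planted
duplications (copy number ≥ 3), tandem duplications, heterozygous (factor
0.5) and homozygous (factor 0) deletions; imperfect microsatellites;
repeat-mask and gene intervals; window depth that is Poisson at
λ·width·(copy factor)·f(GC) with a smooth linear bias f(gc) = 0.5 + gc by
default and a small Gamma jitter on the rate (CV 5%) — pure Poisson window
totals at deep coverage would have sub-1% spread, which no real library
achieves, and the jitter restores the overdispersion the Gaussian
calibration stage exists to measure. The default depth λ = 100 per bp
reflects the deep short-read coverage regime these surveys run at; reads
are 2×125 bp with 500 ± 50 bp inserts.

Everted-pair coordinates are computed analytically from the planted tandem
interval (junction at the end of the first copy; the downstream mate maps
one duplication-length upstream), keeping the generator aligner-free and
deterministic. Variant planting constructs each class so that
classification is unambiguous (e.g. MNV alleles differ at every position;
replacement alleles differ at both ends), which is what lets a recovery
test demand exact class counts. Microsatellite degradation places
substitutions in the locus interior, leaves the first and last unit intact,
and re-draws any flanking base that happens to continue the repeat phase —
so the ledger's start/end are true boundaries and recovery can be scored by
span overlap. Every simulator is a pure function of (config, seed):
repeated runs are byte-identical, and every planted feature appears in the
JSON truth ledger.

**What passing these benchmarks does not show.** The generator omits
sequencing error in reads, base qualities, mappability structure, real
repeat families, alignment artefacts, and reference bias; depth is drawn at
window granularity rather than placed read by read. Recovery of planted
events under these conditions demonstrates the correctness of the
algorithms' logic and calibration, not their performance on real libraries,
where mapping ambiguity and unmodelled bias dominate the error budget.

## Problem sizes

The standard benchmarks are sized for interactive runs: the CNV benchmark
uses two 2.5 Mb scaffolds (10,000 windows, 20 events), the microsatellite
benchmark 50 loci on 100 kb, the genome-size benchmark 30× reads from
100 kb, and the calibration/correction benchmarks 10,000 windows. These
sizes put the stochastic tolerances tested (2–5%) several standard errors
away from their thresholds.

## Known limitations

- The exact k-mer counter is dictionary-based and intended for survey-scale
  inputs, not production read sets.
- `map_region` is ungapped; an indel inside a duplicated region splits its
  hit, which can demote a genuinely shared duplication to private when the
  surviving fragments fall below half the query length.
- The microsatellite finder does not model indel slippage within a locus
  (an out-of-phase continuation is reported as a second locus rather than a
  gapped one).
- Window depth from BAM requires consistent scaffold naming between the
  assembly and the alignments; no lift-over is attempted.
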