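"""Assembly survey statistics and k-mer genome-size estimation.

Builds a small multi-scaffold assembly with a gap, reports the Table-style
survey numbers (N50, ungapped span, GC, scaffolds capturing 90% of the
assembly), then estimates genome size from the k-mer spectrum of simulated
30x error-free reads.
"""

from genomesurvey import simdata, stats

config = simdata.SimulationConfig(
    seed=3,
    n_scaffolds=4,
    scaffold_length=100_000,
    events=[simdata.PlantedEvent("gap", "scaffold_2", 40_000, 42_000)],
)
sim = simdata.simulate_genome(config)

summary = stats.assembly_summary(sim.assembly, min_len=1_000)
print("assembly survey:")
print(f"  total span      {summary.total_bp:,} bp")
print(f"  ungapped span   {summary.ungapped_bp:,} bp  (gaps {summary.gap_bp:,} bp)")
print(f"  scaffolds       {summary.n_scaffolds}   N50 {summary.n50:,} bp   "
      f"largest {summary.largest:,} bp")
print(f"  GC content      {summary.gc_percent:.2f} %  (non-N bases)")
print(f"  scaffolds to 90%  {summary.scaffolds_to_90}")

reads = simdata.simulate_reads(sim.assembly, config, coverage=30.0)
hist = stats.kmer_histogram(reads, k=21)
est = stats.estimate_genome_size(hist)
true_size = summary.total_bp
print("\nk-mer genome size (k=21, 30x error-free reads):")
print(f"  error cutoff at multiplicity {est.error_cutoff}, "
      f"coverage mode at {est.peak_depth} (refined {est.peak_depth_refined:.2f})")
print(f"  estimate {est.size_bp:,.0f} bp vs true {true_size:,} bp "
      f"({100 * abs(est.size_bp - true_size) / true_size:.2f} % error)")
# The estimate is total k-mer instances beyond the error cutoff divided by
# the k-mer coverage at the spectrum's main mode.
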