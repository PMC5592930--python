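import numpy as np
import pytest

from genomesurvey import simdata
from genomesurvey.microsat import locus_perfection
from genomesurvey.simdata import (
    ConfigError,
    PlantedEvent,
    SimulationConfig,
    SimulationTruth,
    simulate_depth,
    simulate_genome,
    simulate_read_pairs,
    simulate_variants,
)
from genomesurvey.variants import classify_variant, filter_variants


class TestSimulateGenome:
    def test_flat_gc_profile_realized(self):
        cfg = SimulationConfig(
            seed=7, n_scaffolds=1, scaffold_length=100_000, gc_profile=(0.5,)
        )
        sim = simulate_genome(cfg)
        seq = sim.assembly[0].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_deterministic_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_scaffolds=1, scaffold_length=20_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_genome(cfg).write_outputs(d1)
        simulate_genome(cfg).write_outputs(d2)
        for name in ("assembly.fasta", "repeats.bed", "gaps.bed", "genes.gff3", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_planted_microsat_perfection_near_target(self):
        ev = PlantedEvent(
            "microsatellite", "scaffold_1", 5_000, 5_050, unit="AC", perfection=90.0
        )
        cfg = SimulationConfig(
            seed=7, n_scaffolds=1, scaffold_length=20_000, events=[ev]
        )
        sim = simulate_genome(cfg)
        realized = locus_perfection(sim.assembly[0].seq, 5_000, 5_050, "AC", 5_000)
        assert 88.0 <= realized <= 92.0

    def test_gap_written_as_n_run(self):
        ev = PlantedEvent("gap", "scaffold_1", 1_000, 1_200)
        cfg = SimulationConfig(seed=7, n_scaffolds=1, scaffold_length=5_000, events=[ev])
        sim = simulate_genome(cfg)
        assert sim.assembly[0].seq[1_000:1_200] == "N" * 200
        assert [(g.start, g.end) for g in sim.gaps] == [(1_000, 1_200)]

    def test_overlapping_material_events_rejected(self):
        events = [
            PlantedEvent("duplication", "scaffold_1", 1_000, 3_000, copy_number=3),
            PlantedEvent("deletion", "scaffold_1", 2_000, 4_000, zygosity="homozygous"),
        ]
        cfg = SimulationConfig(seed=7, n_scaffolds=1, scaffold_length=10_000, events=events)
        with pytest.raises(ConfigError, match="overlap"):
            simulate_genome(cfg)

    def test_truth_ledger_roundtrip(self, tmp_path):
        cfg = simdata.recovery_config(seed=3, scaffold_length=2_500_000)
        truth = SimulationTruth(
            events=cfg.events,
            scaffold_lengths={"scaffold_1": 2_500_000, "scaffold_2": 2_500_000},
            window_width=500,
            expected_variant_counts={"planted": 5},
        )
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SimulationTruth.from_json(p)
        assert back == truth


class TestSimulateDepth:
    def test_neutral_background_mean(self):
        cfg = SimulationConfig(
            seed=5,
            n_scaffolds=1,
            scaffold_length=2_500_000,
            window_depth_lambda=100.0,
            gc_bias_intercept=1.0,
            gc_bias_slope=0.0,
        )
        sim = simulate_genome(cfg)
        df = simulate_depth(sim.assembly, sim.truth, cfg)
        assert abs(df["depth"].mean() - 100.0) / 100.0 < 0.02

    def test_homozygous_deletion_windows_are_zero(self):
        ev = PlantedEvent("deletion", "scaffold_1", 10_000, 15_000, zygosity="homozygous")
        cfg = SimulationConfig(seed=5, n_scaffolds=1, scaffold_length=50_000, events=[ev])
        sim = simulate_genome(cfg)
        df = simulate_depth(sim.assembly, sim.truth, cfg)
        inside = df[(df.start >= 10_000) & (df.end <= 15_000)]
        assert (inside["depth"] == 0.0).all()

    def test_copy_number_four_doubles_depth(self):
        ev = PlantedEvent("duplication", "scaffold_1", 50_000, 100_000, copy_number=4)
        cfg = SimulationConfig(
            seed=5,
            n_scaffolds=1,
            scaffold_length=500_000,
            events=[ev],
            gc_bias_intercept=1.0,
            gc_bias_slope=0.0,
        )
        sim = simulate_genome(cfg)
        df = simulate_depth(sim.assembly, sim.truth, cfg)
        inside = df[(df.start >= 50_000) & (df.end <= 100_000)]["depth"].mean()
        outside = df[(df.end <= 50_000) | (df.start >= 100_000)]["depth"].mean()
        assert abs(inside / outside - 2.0) < 0.05

    def test_copy_factor_track(self):
        ev = PlantedEvent("duplication", "scaffold_1", 1_000, 2_000, copy_number=3)
        truth = SimulationTruth([ev], {"scaffold_1": 10_000}, 500)
        assert truth.copy_factor("scaffold_1", 1_000, 1_500) == pytest.approx(1.5)
        assert truth.copy_factor("scaffold_1", 0, 500) == 1.0
        # half-overlap blends the factors by bp
        assert truth.copy_factor("scaffold_1", 750, 1_250) == pytest.approx(1.25)


class TestSimulateReadPairs:
    def test_no_tandem_events_no_everted_pairs(self):
        cfg = SimulationConfig(seed=5, n_scaffolds=1, scaffold_length=50_000)
        sim = simulate_genome(cfg)
        pairs = simulate_read_pairs(sim.truth, cfg, n_pairs=2_000)
        assert sum(p.everted for p in pairs) == 0

    def test_junction_pairs_are_everted_and_local(self):
        ev = PlantedEvent("tandem_duplication", "scaffold_1", 50_000, 56_000, copy_number=4)
        cfg = SimulationConfig(seed=5, n_scaffolds=1, scaffold_length=200_000, events=[ev])
        sim = simulate_genome(cfg)
        pairs = simulate_read_pairs(sim.truth, cfg, n_pairs=20_000)
        everted = [p for p in pairs if p.everted]
        assert len(everted) >= 3
        for p in everted:
            assert 50_000 - 1_000 <= p.pos1 and p.pos2 <= 56_000 + 1_000

    def test_zero_insert_sd_degenerate(self):
        cfg = SimulationConfig(
            seed=5, n_scaffolds=1, scaffold_length=50_000, insert_sd=0
        )
        sim = simulate_genome(cfg)
        pairs = simulate_read_pairs(sim.truth, cfg, n_pairs=500)
        spans = {p.pos2 + cfg.read_length - p.pos1 for p in pairs}
        assert spans == {cfg.insert_mean}


class TestSimulateVariants:
    def test_poisson_count_scale(self):
        cfg = SimulationConfig(
            seed=5, n_scaffolds=1, scaffold_length=100_000, variant_rate=0.001
        )
        sim = simulate_genome(cfg)
        records = simulate_variants(sim.assembly, sim.truth, cfg)
        assert 80 <= len(records) <= 120

    def test_all_low_probability_records_filtered(self):
        cfg = SimulationConfig(seed=5, n_scaffolds=1, scaffold_length=50_000)
        sim = simulate_genome(cfg)
        records = simulate_variants(sim.assembly, sim.truth, cfg)
        lowered = [
            simdata.VariantRecord(
                r.scaffold, r.pos, r.ref, r.alt, r.depth, 0.5, r.fwd_support, r.rev_support
            )
            for r in records
        ]
        kept, _ = filter_variants(lowered)
        assert kept == []

    def test_classifier_recovers_planted_class_counts(self):
        cfg = SimulationConfig(
            seed=5,
            n_scaffolds=1,
            scaffold_length=400_000,
            variant_rate=0.0025,
            variant_class_mix=(0.70, 0.10, 0.15, 0.05),
        )
        sim = simulate_genome(cfg)
        records = simulate_variants(sim.assembly, sim.truth, cfg)
        got: dict[str, int] = {}
        for r in records:
            c = classify_variant(r.ref, r.alt)
            got[c] = got.get(c, 0) + 1
        expected = {
            k: v
            for k, v in sim.truth.expected_variant_counts.items()
            if k not in ("planted", "expected_kept")
        }
        assert got == expected
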