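"""The generator's planted truth must be exact and its sampling unbiased."""

import numpy as np
import pytest

from satkit.io import write_fasta, write_fastq
from satkit.synthetic_data import (
    ChipSimSpec,
    GenomeSpec,
    QualityModel,
    SatelliteFamilySpec,
    build_genome,
    make_monomer,
    simulate_chip,
    simulate_reads,
)


class TestMakeMonomer:
    def test_pure_at(self):
        assert set(make_monomer(4, 1.0, seed=0)) <= {"A", "T"}

    def test_pure_gc(self):
        assert set(make_monomer(50, 0.0, seed=0)) <= {"C", "G"}

    def test_realized_at_fraction(self):
        mono = make_monomer(1000, 0.75, seed=1)
        at = (mono.count("A") + mono.count("T")) / 1000
        assert abs(at - 0.75) <= 0.05

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            make_monomer(0, 0.5, 1)

    def test_deterministic(self):
        assert make_monomer(200, 0.6, seed=7) == make_monomer(200, 0.6, seed=7)


class TestBuildGenome:
    def test_single_family_fills_genome(self):
        spec = GenomeSpec(
            1000, [SatelliteFamilySpec("f", 100, target_fraction=1.0)], seed=0
        )
        genome, truth = build_genome(spec)
        assert len(genome["genome"]) == 1000
        assert truth.families["f"].fraction == 1.0

    def test_fraction_within_one_monomer(self):
        spec = GenomeSpec(
            100_000, [SatelliteFamilySpec("f", 191, target_fraction=0.10)], seed=1
        )
        _, truth = build_genome(spec)
        assert abs(truth.families["f"].fraction - 0.10) <= 191 / 100_000

    def test_two_families_disjoint(self):
        spec = GenomeSpec(
            50_000,
            [
                SatelliteFamilySpec("a", 100, target_fraction=0.2),
                SatelliteFamilySpec("b", 50, target_fraction=0.3),
            ],
            seed=2,
        )
        _, truth = build_genome(spec)
        spans = [s for ft in truth.families.values() for s in ft.arrays]
        (a0, a1), (b0, b1) = spans
        assert a1 <= b0 or b1 <= a0
        assert sum(ft.fraction for ft in truth.families.values()) <= 1.0

    def test_truth_fractions_recomputable_exactly(self):
        spec = GenomeSpec(
            30_000,
            [
                SatelliteFamilySpec("a", 191, target_fraction=0.1),
                SatelliteFamilySpec("b", 58, target_fraction=0.05),
            ],
            seed=3,
        )
        _, truth = build_genome(spec)
        recomputed = truth.recompute_fractions()
        for name, ft in truth.families.items():
            assert recomputed[name] == ft.fraction

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(
                1000,
                [
                    SatelliteFamilySpec("a", 100, target_fraction=0.7),
                    SatelliteFamilySpec("b", 100, target_fraction=0.7),
                ],
            )


class TestSimulateReads:
    @pytest.fixture()
    def small_genome(self):
        return build_genome(
            GenomeSpec(20_000, [SatelliteFamilySpec("f", 100, target_fraction=0.2)], seed=5)
        )

    def test_error_free_reads_are_substrings(self, small_genome):
        genome, _ = small_genome
        seq = genome["genome"]
        from satkit._seq import revcomp

        for read in simulate_reads(genome, 10, 80, error_rate=0.0, seed=6):
            assert read.seq in seq or revcomp(read.seq) in seq

    def test_zero_reads(self, small_genome):
        genome, _ = small_genome
        assert simulate_reads(genome, 0, 80, seed=1) == []

    def test_negative_reads_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            simulate_reads(genome, -1, 80)

    def test_read_count_conserved(self, small_genome):
        genome, _ = small_genome
        assert len(simulate_reads(genome, 137, 101, seed=2)) == 137

    def test_start_positions_binomial(self):
        # fraction of reads starting inside the planted arrays should track
        # the genomic fraction within 3 binomial standard deviations
        genome, truth = build_genome(
            GenomeSpec(200_000, [SatelliteFamilySpec("f", 191, target_fraction=0.10)], seed=7)
        )
        n = 50_000
        reads = simulate_reads(genome, n, 101, error_rate=0.0, seed=8)
        (s0, e0) = truth.families["f"].arrays[0]
        hits = sum(
            1 for r in reads if s0 <= int(r.id.split("|pos=")[1].split("|")[0]) < e0
        )
        # starts are uniform over genome_length - read_length + 1 positions
        p = (e0 - s0) / (200_000 - 101 + 1)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) <= 3 * sd


class TestSimulateChip:
    @pytest.fixture()
    def setup(self):
        genome, truth = build_genome(
            GenomeSpec(
                50_000,
                [
                    SatelliteFamilySpec("a", 100, target_fraction=0.10),
                    SatelliteFamilySpec("b", 50, target_fraction=0.05),
                ],
                seed=9,
            )
        )
        return genome, truth

    def test_factor_one_matches_genomic_fraction(self, setup):
        genome, truth = setup
        spec = ChipSimSpec({"a": 1.0, "b": 1.0}, n_chip=20_000, n_input=20_000, seed=10)
        chip, inp = simulate_chip(truth, spec, genome)
        (s0, e0) = truth.families["a"].arrays[0]

        def frac(reads):
            n = sum(
                1 for r in reads if s0 <= int(r.id.split("|pos=")[1].split("|")[0]) < e0
            )
            return n / len(reads)

        ratio = frac(chip) / frac(inp)
        assert abs(ratio - 1.0) < 0.15

    def test_empty_chip_pool(self, setup):
        genome, truth = setup
        spec = ChipSimSpec({"a": 5.0}, n_chip=0, n_input=100, seed=1)
        chip, inp = simulate_chip(truth, spec, genome)
        assert chip == [] and len(inp) == 100

    def test_negative_factor_rejected(self, setup):
        genome, truth = setup
        with pytest.raises(ValueError):
            ChipSimSpec({"a": -1.0}, n_chip=10, n_input=10)

    def test_unknown_family_rejected(self, setup):
        genome, truth = setup
        spec = ChipSimSpec({"nope": 2.0}, n_chip=10, n_input=10)
        with pytest.raises(ValueError):
            simulate_chip(truth, spec, genome)


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        def render():
            genome, truth = build_genome(
                GenomeSpec(
                    10_000, [SatelliteFamilySpec("f", 60, target_fraction=0.1)], seed=11
                )
            )
            reads = simulate_reads(genome, 500, 101, seed=12)
            chip, inp = simulate_chip(
                truth, ChipSimSpec({"f": 10.0}, 300, 300, seed=13), genome
            )
            fa, fq = tmp_path / "g.fa", tmp_path / "r.fq"
            write_fasta(fa, genome)
            write_fastq(fq, reads + chip + inp)
            return fa.read_bytes(), fq.read_bytes()

        assert render() == render()

    def test_low_quality_tail_model(self):
        qm = QualityModel(q=30, tail_q=2, tail_length=10, tail_fraction=1.0)
        quals = qm.sample(5, 50, np.random.default_rng(0))
        assert (quals[:, :40] == 30).all() and (quals[:, 40:] == 2).all()
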