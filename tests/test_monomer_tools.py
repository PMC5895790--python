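"""Tandem-organization validation: period, subrepeats, primers, in-silico PCR."""

import numpy as np
import pytest

from conftest import random_seq
from satkit._seq import revcomp
from satkit.monomer_tools import (
    NoValidPrimerError,
    PrimerPair,
    design_outward_primers,
    detect_subrepeats,
    estimate_period,
    in_silico_pcr,
    percent_identity,
    wallace_tm,
)
from satkit.synthetic_data import mutate_copy


class TestEstimatePeriod:
    def test_clean_pentamer_tandem(self):
        est = estimate_period("ACGTT" * 20)
        assert est.period == 5 and est.confidence == 1.0

    def test_homopolymer_period_one(self):
        assert estimate_period("A" * 60).period == 1

    def test_diverged_array_recovers_monomer_length(self, rng):
        mono = random_seq(rng, 191)
        array = "".join(mutate_copy(mono, 0.05, rng) for _ in range(50))
        est = estimate_period(array, min_period=50, max_period=500)
        assert est.period == 191
        assert est.confidence == pytest.approx(0.90, abs=0.03)

    def test_never_a_multiple_of_the_true_period(self, rng):
        mono = random_seq(rng, 37)
        assert estimate_period(mono * 30).period == 37

    def test_rotation_invariant_on_clean_tandem(self, rng):
        mono = random_seq(rng, 53)
        array = mono * 20
        periods = {
            estimate_period(array[k:] + array[:k]).period for k in (0, 7, 29, 52)
        }
        assert periods == {53}

    def test_no_qualifying_lag_returns_none(self, rng):
        assert estimate_period(random_seq(rng, 400), min_period=5) is None

    def test_infeasible_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_period("ACGT", min_period=10)


class TestDetectSubrepeats:
    def test_random_monomer_has_none(self, rng):
        assert detect_subrepeats(random_seq(rng, 1000), min_len=20) == []

    def test_duplicated_half_detected(self, rng):
        half = random_seq(rng, 500)
        hits = detect_subrepeats(half + half, min_len=20)
        assert any(period == 500 and span == (0, 1000) for period, span in hits)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_subrepeats(random_seq(rng, 30), min_len=20)


class TestDesignOutwardPrimers:
    def test_geometry_on_mixed_composition(self, rng):
        mono = random_seq(rng, 1000)
        pair = design_outward_primers(mono)
        assert pair.reverse[1] <= pair.forward[0]
        assert 18 <= len(pair.forward_seq) <= 25
        assert 18 <= len(pair.reverse_seq) <= 25
        assert mono[pair.forward[0] : pair.forward[1]] == pair.forward_seq
        assert revcomp(mono[pair.reverse[0] : pair.reverse[1]]) == pair.reverse_seq

    def test_infeasible_geometry_rejected(self, rng):
        with pytest.raises(NoValidPrimerError):
            design_outward_primers(random_seq(rng, 30))

    def test_at_rich_input_relaxes_gc_with_warning(self, rng):
        mono = "".join(rng.choice(list("AT" * 4 + "GC"), size=600))  # ~80 % AT
        with pytest.warns(UserWarning, match="relaxed"):
            pair = design_outward_primers(mono)
        assert pair.warnings

    def test_wallace_rule(self):
        assert wallace_tm("AATTGGCC") == 2 * 4 + 4 * 4


class TestInSilicoPcr:
    @pytest.fixture()
    def monomer_and_pair(self, rng):
        mono = random_seq(rng, 1000)
        pair = PrimerPair(
            forward=(900, 920),
            reverse=(130, 150),
            forward_seq=mono[900:920],
            reverse_seq=revcomp(mono[130:150]),
        )
        return mono, pair

    def test_single_monomer_yields_no_product(self, monomer_and_pair):
        mono, pair = monomer_and_pair
        assert in_silico_pcr(mono, pair) == []

    def test_dimer_junction_product_length(self, monomer_and_pair):
        # product spans (1000 - 900) bases of copy one plus 150 of copy two
        mono, pair = monomer_and_pair
        assert in_silico_pcr(mono * 2, pair) == [250]

    def test_trimer_yields_two_products(self, monomer_and_pair):
        mono, pair = monomer_and_pair
        assert in_silico_pcr(mono * 3, pair) == [250, 250]

    @pytest.mark.parametrize("n_copies", [2, 5, 9])
    def test_n_minus_one_product_law(self, rng, n_copies):
        mono = random_seq(rng, 400)
        pair = design_outward_primers(mono)
        products = in_silico_pcr(mono * n_copies, pair)
        assert len(products) == n_copies - 1
        assert len(set(products)) == 1

    def test_reversed_template_orientation_found(self, monomer_and_pair):
        mono, pair = monomer_and_pair
        assert in_silico_pcr(revcomp(mono * 2), pair) == [250]

    def test_short_primer_rejected(self, monomer_and_pair):
        mono, _ = monomer_and_pair
        bad = PrimerPair((0, 10), (20, 30), mono[:10], revcomp(mono[20:30]))
        with pytest.raises(ValueError):
            in_silico_pcr(mono, bad)


class TestPercentIdentity:
    def test_identical(self, rng):
        seq = random_seq(rng, 250)
        assert percent_identity(seq, seq) == 100.0

    def test_single_substitution(self, rng):
        seq = random_seq(rng, 100)
        other = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        assert percent_identity(seq, other) == pytest.approx(99.0)

    def test_symmetric(self, rng):
        a, b = random_seq(rng, 120), random_seq(rng, 110)
        assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_simulated_clone_in_published_band(self, rng):
        consensus = random_seq(rng, 963)
        clone = mutate_copy(consensus, 0.05, rng)
        assert 92.0 <= percent_identity(consensus, clone) <= 99.0
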