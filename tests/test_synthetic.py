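"""Synthetic promoter / tRNA generation and its ground truth."""

import math

import numpy as np
import pytest
from scipy import stats

from promdpp.cpe_scan import (
    CORE_LESS,
    classify_promoter,
    find_element_matches,
    iupac_match,
    scan_cpes,
)
from promdpp.synthetic import (
    SynthConfig,
    expected_species_fractions,
    generate_background,
    generate_promoter_set,
    generate_trna_set,
    measure_accidental_rates,
    plant_element,
    promoter_set_to_inputs,
)


class TestBackground:
    def test_gc_zero_is_AT_only(self):
        seq = generate_background(500, 0.0, np.random.default_rng(0))
        assert set(seq) <= {"A", "T"}

    def test_gc_one_is_GC_only(self):
        seq = generate_background(500, 1.0, np.random.default_rng(0))
        assert set(seq) <= {"G", "C"}

    def test_gc_half_concentrates_within_3_sigma(self):
        # binomial concentration: |f_GC - 0.5| < 3*sqrt(0.25/1e5)
        n = 10**5
        seq = generate_background(n, 0.5, np.random.default_rng(1))
        f = (seq.count("G") + seq.count("C")) / n
        assert abs(f - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_background(10, 1.5, np.random.default_rng(0))


class TestPlantElement:
    def test_plant_matches_consensus_at_start(self):
        rng = np.random.default_rng(2)
        seq = plant_element("A" * 40, "TATAWAWR", 10, rng)
        assert iupac_match(seq[10:18], "TATAWAWR")
        assert seq[:10] == "A" * 10 and seq[18:] == "A" * 22

    def test_degenerate_positions_vary_across_seeds(self):
        outs = {plant_element("A" * 20, "GGTTCGANNCC", 3,
                              np.random.default_rng(s))[10:12]
                for s in range(40)}
        assert len(outs) > 1  # the two N positions take several values

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            plant_element("A" * 10, "TATAWAWR", 5, np.random.default_rng(0))


class TestGeneratePromoterSet:
    def test_pure_coreless_mix(self, defs):
        cfg = SynthConfig(n=100, seed=3, species_mix={CORE_LESS: 1.0})
        _, truth = generate_promoter_set(cfg, defs)
        assert truth.species == [CORE_LESS] * 100
        assert all(not e for e in truth.elements)

    def test_planted_shifts_within_jitter(self, defs):
        cfg = SynthConfig(n=200, seed=4, species_mix={"TATA+Inr": 1.0},
                          jitter=(-5, 5))
        _, truth = generate_promoter_set(cfg, defs)
        for plants in truth.elements:
            assert {p.name for p in plants} == {"TATA", "Inr"}
            assert all(-5 <= p.shift <= 5 for p in plants)

    def test_same_seed_byte_identical(self, defs):
        cfg = SynthConfig(n=50, seed=5)
        a, _ = generate_promoter_set(cfg, defs)
        b, _ = generate_promoter_set(cfg, defs)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_prefix_stable_when_n_grows(self, defs):
        small, t_small = generate_promoter_set(SynthConfig(n=30, seed=6), defs)
        large, t_large = generate_promoter_set(SynthConfig(n=60, seed=6), defs)
        assert [r.seq for r in small] == [r.seq for r in large[:30]]
        assert t_small.species == t_large.species[:30]

    def test_unknown_species_label_rejected(self, defs):
        cfg = SynthConfig(n=5, seed=0, species_mix={"NoSuchElement": 1.0})
        with pytest.raises(ValueError, match="unknown element"):
            generate_promoter_set(cfg, defs)

    def test_planted_elements_recovered_from_scan(self, defs):
        """Scan + classify recovers planted truth on an Inr-only mix."""
        cfg = SynthConfig(n=500, seed=7, species_mix={"Inr": 1.0})
        records, truth = generate_promoter_set(cfg, defs)
        by_name = {d.name: d for d in defs}
        for r, plants in zip(records, truth.elements):
            (plant,) = plants
            matches = find_element_matches(r, by_name["Inr"])
            assert any(h.shift == plant.shift for h in matches)

    def test_recovered_shift_distribution_uniform(self, defs):
        """Chi-square goodness of fit of planted shifts to uniform[-5,5]."""
        cfg = SynthConfig(n=2000, seed=8, species_mix={"TATA": 1.0})
        _, truth = generate_promoter_set(cfg, defs)
        shifts = [p.shift for plants in truth.elements for p in plants]
        observed = [shifts.count(s) for s in range(-5, 6)]
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_roundtrip_through_genome_and_tss_table(self, defs):
        from promdpp.genome_io import extract_promoters

        cfg = SynthConfig(n=20, seed=9)
        records, _ = generate_promoter_set(cfg, defs)
        genome, tss = promoter_set_to_inputs(records)
        out, summary = extract_promoters(genome, tss, cfg.anchor,
                                         cfg.length - cfg.anchor - 1)
        assert summary.skipped == 0
        assert [p.seq for p in out] == [r.seq for r in records]


class TestExpectedSpeciesFractions:
    def test_zero_rates_reproduce_the_mix(self, defs):
        mix = {CORE_LESS: 0.5, "Inr": 0.3, "TATA+Inr": 0.2}
        rates = {d.name: 0.0 for d in defs}
        assert expected_species_fractions(mix, rates, defs) == pytest.approx(mix)

    def test_fractions_sum_to_one(self, defs):
        mix = {CORE_LESS: 0.55, "Inr": 0.30, "TATA+Inr": 0.15}
        rates = {d.name: 0.1 for d in defs}
        out = expected_species_fractions(mix, rates, defs)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_single_element_rate_moves_mass_correctly(self, defs):
        # only Inr can occur accidentally: core-less -> Inr with prob q
        q = 0.2
        rates = {d.name: (q if d.name == "Inr" else 0.0) for d in defs}
        out = expected_species_fractions({CORE_LESS: 1.0}, rates, defs)
        assert out[CORE_LESS] == pytest.approx(1 - q)
        assert out["Inr"] == pytest.approx(q)

    def test_measured_rates_are_probabilities(self, defs):
        rates = measure_accidental_rates(defs, n=300, seed=10)
        assert set(rates) == {d.name for d in defs}
        assert all(0.0 <= v <= 1.0 for v in rates.values())


class TestSyntheticTRNA:
    def test_annotations_satisfy_anchor_ordering(self):
        _, anns = generate_trna_set(10, seed=11)
        assert len(anns) == 10  # constructor enforces tss <= mature5 < disc

    def test_determinism(self):
        g1, a1 = generate_trna_set(5, seed=12)
        g2, a2 = generate_trna_set(5, seed=12)
        assert g1 == g2 and a1 == a2

    def test_both_strands_occur(self):
        _, anns = generate_trna_set(40, seed=13)
        assert {a.strand for a in anns} == {"+", "-"}


def test_species_classification_matches_truth_up_to_accidentals(defs):
    """On a low-degeneracy world the scan labels equal the planted labels."""
    cfg = SynthConfig(n=300, seed=14, species_mix={CORE_LESS: 0.5, "TATA": 0.5},
                      gc=1.0)  # GC background cannot contain TATAWAWR by accident
    records, truth = generate_promoter_set(cfg, defs)
    labels = [classify_promoter(scan_cpes(r, defs).hits) for r in records]
    for lbl, true_lbl in zip(labels, truth.species):
        if true_lbl == "TATA":
            assert "TATA" in lbl.split("+")
        else:
            assert "TATA" not in lbl.split("+")
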