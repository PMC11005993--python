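"""IUPAC matching, positional CPE scanning, species classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promdpp.cpe_scan import (
    CORE_LESS,
    CPEDefinition,
    CPEHit,
    classify_promoter,
    find_element_matches,
    iupac_match,
    load_element_definitions,
    scan_cpes,
    tabulate_species,
    top_species,
)
from promdpp.genome_io import PromoterRecord

from conftest import random_seq


class TestIupacMatch:
    @pytest.mark.parametrize(
        "window, consensus, expected",
        [
            ("TATAAAAG", "TATAWAWR", True),
            ("GGTTCGATACC", "GGTTCGANNCC", True),  # B-box consensus
            ("TANAAAAG", "TATAWAWR", False),  # N in the subject never matches
            ("TGGCGAAGTGG", "TGGCNNAGTGG", True),  # A-box consensus
            ("TGGCGAAGTGG", "TRGYNNARBGG", True),  # alternative A-box consensus
            ("TATAAAAC", "TATAWAWR", False),
        ],
    )
    def test_examples(self, window, consensus, expected):
        assert iupac_match(window, consensus) is expected

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            iupac_match("TATA", "TATAWAWR")

    def test_case_insensitive_subject(self):
        assert iupac_match("tataaaag", "TATAWAWR")


def _promoter(planted: dict[int, str], length=101, anchor=60, fill="C") -> PromoterRecord:
    """Promoter of `fill` bases with strings planted at TSS-relative starts."""
    seq = list(fill * length)
    for start, s in planted.items():
        seq[anchor + start : anchor + start + len(s)] = list(s)
    return PromoterRecord(gene_id="p", seq="".join(seq), anchor=anchor)


TOY = CPEDefinition(name="TATA", consensus="TATAAA", canonical_start=-30)


class TestScanCpes:
    def test_hit_within_tolerance_reports_shift(self):
        res = scan_cpes(_promoter({-28: "TATAAA"}), [TOY])
        assert res.hits == [CPEHit(element="TATA", start=-28, shift=2)]

    def test_shift_six_is_not_a_hit(self):
        res = scan_cpes(_promoter({-36: "TATAAA"}), [TOY])
        assert res.hits == [] and res.all_matches["TATA"] == []

    def test_minimal_abs_shift_wins(self):
        # non-overlapping matches at -31 (|shift|=1) and -25 (|shift|=5)
        res = scan_cpes(_promoter({-31: "TATAAA", -25: "TATAAA"}), [TOY])
        assert res.hits[0].start == -31 and res.hits[0].shift == -1

    def test_equal_abs_shift_upstream_wins(self):
        # "ACACAC" at -31 matches ACAC at shifts -1 and +1 but not 0
        toy = CPEDefinition(name="X", consensus="ACAC", canonical_start=-30)
        res = scan_cpes(_promoter({-31: "ACACAC"}), [toy])
        assert {h.shift for h in res.all_matches["X"]} == {-1, 1}
        assert res.hits[0].shift == -1

    def test_all_matches_lists_every_in_window_occurrence(self):
        res = scan_cpes(_promoter({-33: "TATATATAAA"}), [TOY])
        starts = {h.start for h in res.all_matches["TATA"]}
        assert -29 in starts  # TATAAA at -29 from the tail of the plant

    def test_window_outside_promoter_is_unevaluable(self):
        short = PromoterRecord(gene_id="p", seq="C" * 20, anchor=10)
        res = scan_cpes(short, [TOY])
        assert res.unevaluable == ["TATA"] and not res.evaluable
        assert find_element_matches(short, TOY) is None

    def test_scan_is_sense_strand_only(self):
        from promdpp.genome_io import reverse_complement

        p = _promoter({-30: "TATAAA"})
        rc = PromoterRecord(gene_id="p", seq=reverse_complement(p.seq),
                            anchor=len(p.seq) - 1 - p.anchor)
        assert scan_cpes(p, [TOY]).hits and not scan_cpes(rc, [TOY]).hits


class TestClassifyPromoter:
    def test_empty_is_core_less(self):
        assert classify_promoter([]) == CORE_LESS

    def test_singleton(self):
        assert classify_promoter([CPEHit("Inr", -3, 0)]) == "Inr"

    def test_ordered_by_canonical_start(self):
        hits = [CPEHit("Inr", -3, 0), CPEHit("TATA", -29, 2)]
        assert classify_promoter(hits) == "TATA+Inr"

    def test_shift_not_part_of_label(self):
        a = [CPEHit("TATA", -31, 0)]
        b = [CPEHit("TATA", -26, 5)]
        assert classify_promoter(a) == classify_promoter(b) == "TATA"

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(perm=st.permutations(list(range(4))))
    def test_permutation_invariant(self, perm):
        hits = [CPEHit("TATA", -31, 0), CPEHit("Inr", -3, 0),
                CPEHit("BREu", -38, 0), CPEHit("DPE", 27, 0)]
        shuffled = [hits[i] for i in perm]
        assert classify_promoter(shuffled) == classify_promoter(hits)


class TestTabulateSpecies:
    def test_fifty_fifty(self):
        t = tabulate_species([("g", CORE_LESS), ("g", CORE_LESS),
                              ("g", "Inr"), ("g", "Inr")])
        assert sorted(t["percent"]) == [50.0, 50.0]

    def test_groups_tabulated_independently(self):
        labels = [("a", "Inr")] * 3 + [("a", CORE_LESS)] + [("b", "TATA")] * 2
        t = tabulate_species(labels)
        sums = t.groupby("group")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_top5_view_has_five_rows_when_six_species(self):
        labels = [("g", f"sp{i}") for i in range(6) for _ in range(6 - i)]
        t = tabulate_species(labels)
        assert len(t) == 6 and len(top_species(t, 5)) == 5
        # highest-percentage species first
        assert top_species(t, 5).iloc[0]["species"] == "sp0"

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_percent_sums_to_100_per_group(self, seed):
        rng = np.random.default_rng(seed)
        labels = [
            (f"g{rng.integers(3)}", f"sp{rng.integers(5)}")
            for _ in range(int(rng.integers(1, 50)))
        ]
        t = tabulate_species(labels)
        for _, s in t.groupby("group")["percent"].sum().items():
            assert abs(s - 100.0) < 1e-9


class TestDefaultDefinitions:
    def test_packaged_set_names_and_tolerance(self, defs):
        by_name = {d.name: d for d in defs}
        assert set(by_name) == {"TATA", "Inr", "BREu", "BREd", "DPE"}
        assert all(d.max_shift == 5 for d in defs)
        assert by_name["TATA"].canonical_start == -31  # covers the -27 site
        assert by_name["Inr"].consensus[3] == "A"  # A at the TSS (position 0)
        assert by_name["Inr"].canonical_start == -3

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "e.yaml"
        path.write_text(
            "elements:\n"
            "  - {name: X, consensus: TATA, canonical_start: -30}\n"
            "  - {name: X, consensus: GGGG, canonical_start: 0}\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_element_definitions(path)


def test_scan_on_random_background_matches_rescan_of_same_promoter(defs):
    """Scanning is deterministic and pure (no state between promoters)."""
    rng = np.random.default_rng(7)
    p = PromoterRecord(gene_id="p", seq=random_seq(rng, 151), anchor=100)
    first = scan_cpes(p, defs)
    second = scan_cpes(p, defs)
    assert first.hits == second.hits and first.all_matches == second.all_matches
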