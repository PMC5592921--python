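"""Off-target search: seed index, full-sequence scan, naive-scan oracle, mapping."""

import numpy as np
import pytest

from asirna.offtarget import (
    OffTargetHit,
    build_seed_index,
    full_offtargets,
    map_guides,
    seed_of,
    seed_offtargets,
)
from asirna.sequence import enumerate_candidates, reverse_complement
from asirna.synthetic import PlantSpec, gen_allele_pair, gen_genome_with_planted_sites

GUIDE = "UAGCGAUCGAUCGAUCGAU"


def naive_seed_scan(guide, targets, mode):
    """Position-by-position oracle for the indexed seed search."""
    site = reverse_complement(seed_of(guide, mode))
    k = len(site)
    hits = []
    for rec_id, seq in targets.items():
        s = seq.upper().replace("T", "U")
        for i in range(len(s) - k + 1):
            if s[i : i + k] == site:
                hits.append((rec_id, i + 1))
    return sorted(hits)


def naive_full_scan(guide, targets, max_mismatch):
    """Hamming-distance oracle comparing the guide to each window's complement."""
    hits = []
    for rec_id, seq in targets.items():
        s = seq.upper().replace("T", "U")
        for i in range(len(s) - 19 + 1):
            window = s[i : i + 19]
            if set(window) - set("ACGU"):
                continue
            d = sum(a != b for a, b in zip(guide, reverse_complement(window)))
            if d <= max_mismatch:
                hits.append((rec_id, i + 1, d))
    return sorted(hits)


def random_targets(rng, n_records=3, lo=200, hi=2000):
    return {
        f"r{i}": "".join(rng.choice(list("ACGU"), size=rng.integers(lo, hi)))
        for i in range(n_records)
    }


def test_seed_substrings():
    assert seed_of(GUIDE, "seed6") == "AGCGAU"
    assert seed_of(GUIDE, "seed7") == "AGCGAUC"


def test_seed7_extends_seed6():
    assert seed_of(GUIDE, "seed7")[:6] == seed_of(GUIDE, "seed6")


def test_seed_of_rejects_bad_input():
    with pytest.raises(ValueError):
        seed_of("ACGU", "seed6")
    with pytest.raises(ValueError):
        seed_of(GUIDE, "seed8")


class TestSeedIndex:
    def test_single_kmer_record(self):
        index = build_seed_index({"x": "AAAAAA"}, 6)
        assert index == {"AAAAAA": [("x", 1)]}

    def test_short_record_contributes_nothing(self):
        assert build_seed_index({"x": "ACG"}, 6) == {}

    def test_ambiguous_bases_skipped(self):
        index = build_seed_index({"x": "ACGNACGUACGU"}, 6)
        assert all("N" not in k for k in index)

    def test_occurrence_counts_match_naive_scan(self, rng):
        targets = random_targets(rng, n_records=2, lo=300, hi=600)
        index = build_seed_index(targets, 6)
        for kmer, occs in list(index.items())[:50]:
            count = sum(
                seq[i : i + 6] == kmer
                for seq in targets.values()
                for i in range(len(seq) - 5)
            )
            assert count == len(occs)

    def test_empty_fasta_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_seed_index({}, 6)


class TestSeedSearch:
    def test_planted_sites_recovered_exactly(self):
        plants = [PlantSpec(50, "seed6"), PlantSpec(300, "seed6"), PlantSpec(700, "seed6")]
        genome, truth = gen_genome_with_planted_sites(1500, GUIDE, plants, seed=4)
        hits = seed_offtargets(GUIDE, build_seed_index(genome, 6), "seed6")
        assert [h.start for h in hits] == truth["start"].tolist()

    def test_absent_seed_gives_empty_list(self):
        genome, _ = gen_genome_with_planted_sites(800, GUIDE, [], seed=5)
        hits = seed_offtargets(GUIDE, build_seed_index(genome, 6), "seed6")
        assert hits == []

    def test_seed7_hits_subset_of_seed6(self, rng):
        targets = random_targets(rng)
        h6 = {(h.sequence_id, h.start) for h in
              seed_offtargets(GUIDE, build_seed_index(targets, 6), "seed6")}
        h7 = {(h.sequence_id, h.start - 1) for h in
              seed_offtargets(GUIDE, build_seed_index(targets, 7), "seed7")}
        # a seed7 site at s implies a seed6 site at s+1 (guide position 2 is
        # one base further from the window 3' end)
        assert h7 <= h6

    def test_index_mode_mismatch_rejected(self, rng):
        index = build_seed_index(random_targets(rng, 1), 6)
        with pytest.raises(ValueError, match="does not match"):
            seed_offtargets(GUIDE, index, "seed7")


class TestFullSearch:
    def test_zero_mismatch_equals_exact_match(self):
        genome, truth = gen_genome_with_planted_sites(
            2000, GUIDE, [PlantSpec(800, "full_d0")], seed=6
        )
        hits = full_offtargets(GUIDE, genome, 0)
        assert [(h.start, h.mismatches) for h in hits] == [(801, 0)]
        assert hits[0].site == reverse_complement(GUIDE)

    def test_planted_d2_found_at_2_not_1(self):
        genome, _ = gen_genome_with_planted_sites(
            2000, GUIDE, [PlantSpec(900, "full_d2")], seed=7
        )
        assert [h.start for h in full_offtargets(GUIDE, genome, 2)] == [901]
        assert full_offtargets(GUIDE, genome, 1) == []

    def test_monotone_in_mismatch_budget(self, rng):
        targets = random_targets(rng, 2)
        prev = set()
        for d in range(4):
            cur = {(h.sequence_id, h.start) for h in full_offtargets(GUIDE, targets, d)}
            assert prev <= cur
            prev = cur

    def test_reported_distance_independently_verified(self):
        plants = [PlantSpec(100, "full_d1"), PlantSpec(500, "full_d3")]
        genome, _ = gen_genome_with_planted_sites(1200, GUIDE, plants, seed=8)
        for h in full_offtargets(GUIDE, genome, 3):
            site = genome[h.sequence_id][h.start - 1 : h.start - 1 + 19]
            d = sum(a != b for a, b in zip(GUIDE, reverse_complement(site)))
            assert d == h.mismatches <= 3

    def test_ceiling_enforced_but_overridable(self, rng):
        targets = random_targets(rng, 1)
        with pytest.raises(ValueError, match="ceiling"):
            full_offtargets(GUIDE, targets, 4)
        full_offtargets(GUIDE, targets, 4, allow_above_ceiling=True)

    def test_ambiguous_bases_never_match(self):
        site = reverse_complement(GUIDE)
        genome = {"x": "ACGU" * 10 + site[:9] + "N" + site[10:] + "ACGU" * 10}
        assert full_offtargets(GUIDE, genome, 3) == []


def test_oracle_equivalence_on_random_genomes(rng):
    """Indexed/vectorized searches equal the naive scanners on random genomes."""
    for trial in range(6):
        targets = random_targets(rng, n_records=2, lo=500, hi=3000)
        for mode, k in (("seed6", 6), ("seed7", 7)):
            hits = seed_offtargets(GUIDE, build_seed_index(targets, k), mode)
            assert [(h.sequence_id, h.start) for h in hits] == naive_seed_scan(
                GUIDE, targets, mode
            )
        for d in (0, 2, 3):
            hits = full_offtargets(GUIDE, targets, d)
            assert [
                (h.sequence_id, h.start, h.mismatches) for h in hits
            ] == naive_full_scan(GUIDE, targets, d)


class TestMapGuides:
    def test_designed_guide_maps_back_to_its_window(self):
        pair, _ = gen_allele_pair(60, seed=9)
        cands = enumerate_candidates(pair)
        for c in cands[:5]:
            rows = map_guides([c.guide], pair.mutant_seq)
            starts = [r["start"] for r in rows if r["mapped"]]
            assert c.target_window_start + 1 in starts

    def test_unmapped_guide_flagged(self):
        rows = map_guides({"g": GUIDE}, "A" * 100)
        assert rows == [{"guide_id": "g", "guide": GUIDE, "start": None, "mapped": False}]

    def test_duplicate_site_gives_two_rows(self):
        gene = "ACGU" * 5 + reverse_complement(GUIDE) + "UUUU" + reverse_complement(GUIDE)
        rows = map_guides({"g": GUIDE}, gene)
        assert [r["start"] for r in rows] == [21, 44]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            map_guides({}, "ACGU")
        with pytest.raises(ValueError):
            map_guides({"g": GUIDE}, "")


def test_hit_ordering_deterministic(rng):
    targets = random_targets(rng, 3)
    a = full_offtargets(GUIDE, targets, 3)
    b = full_offtargets(GUIDE, targets, 3)
    assert a == b
    keys = [(h.sequence_id, h.start, h.mismatches) for h in a]
    assert keys == sorted(keys)


def test_hit_start_must_be_positive():
    with pytest.raises(ValueError):
        OffTargetHit("x", 0, "seed6", 0, "AAAAAA")
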