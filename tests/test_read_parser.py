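"""Greedy scanner semantics: eligibility, ordering, caps, oracle equivalence."""

import random

import pytest

from _oracles import scan_brute
from conftest import clean_filler
from tagmux import (
    Config,
    FileWindow,
    FragmentSet,
    ParseState,
    TagRecord,
    build_index,
    eligible,
    parse_fragment_set,
    resolve_candidates,
)
from tagmux.fixtures import GeneratorSpec, generate, plant_substitutions


def _frag(*seqs):
    return FragmentSet(
        headers=[f"r/{i+1}" for i in range(len(seqs))],
        sequences=list(seqs),
        qualities=["I" * len(s) for s in seqs],
    )


class TestEligibility:
    def test_location_constrains_hit_start(self, demo_cfg):
        tag = demo_cfg.tags[0]  # grp_A, location 0:0:5
        state = ParseState(active_groups=set(demo_cfg.groups))
        assert eligible(tag, state, file_index=0, position=3)
        assert not eligible(tag, state, file_index=0, position=6)
        assert not eligible(tag, state, file_index=1, position=3)

    def test_group_cap_blocks_further_finds(self, demo_cfg):
        tag = demo_cfg.tags[0]
        state = ParseState(active_groups=set(demo_cfg.groups), group_counts={"grp_A": 1})
        assert not eligible(tag, state, 0, 3)

    def test_unconstrained_tag_is_always_eligible(self):
        tag = TagRecord("T1", "g", "ACGT")
        state = ParseState(active_groups={"g"})
        for pos in (0, 7, 100):
            assert eligible(tag, state, 1, pos)


class TestResolution:
    def test_exact_match_dominates_one_error(self):
        tags = [TagRecord("t1", "g", "AAAA", distance=1), TagRecord("t2", "g", "AAAT", distance=1)]
        idx = build_index(tags)
        state = ParseState(active_groups={"g"})
        best = resolve_candidates(idx.table["AAAT"], state, 0, 0)
        assert best.tag.tag_id == "t2" and best.total_errors == 0

    def test_equal_error_tie_goes_to_earlier_config_row(self):
        # AATT is 1 substitution from both AATA (row 0) and AATG (row 1)
        tags = [TagRecord("t1", "g", "AATA", distance=1), TagRecord("t2", "g", "AATG", distance=1)]
        idx = build_index(tags)
        state = ParseState(active_groups={"g"})
        best = resolve_candidates(idx.table["AATT"], state, 0, 0)
        assert best.tag.tag_id == "t1"

    def test_no_eligible_candidate_returns_none(self, demo_cfg, demo_index):
        state = ParseState(active_groups=set())  # nothing searchable
        seq = demo_cfg.tags[0].sequence
        assert resolve_candidates(demo_index.table[seq], state, 0, 0) is None


class TestParseFragmentSet:
    def test_structured_read_yields_ordered_combination(self, demo_cfg, demo_index):
        a2 = demo_cfg.tag_by_id("Barcode_A2").sequence
        b1 = demo_cfg.tag_by_id("Barcode_B1").sequence
        filler1 = clean_filler(demo_index, 4, random.Random(11), a2[-5:])
        tail = clean_filler(demo_index, 20, random.Random(12), b1[-5:])
        r1 = a2 + filler1 + b1 + tail
        result = parse_fragment_set(_frag(r1, "ACGT" * 10), demo_index, demo_cfg)
        assert result.combination == ("Barcode_A2", "Barcode_B1")
        assert [(h.start, h.end) for h in result.hits] == [(0, 6), (10, 16)]
        assert result.assigned

    def test_empty_sequence_is_unassigned(self, demo_cfg, demo_index):
        result = parse_fragment_set(_frag("", ""), demo_index, demo_cfg)
        assert result.hits == [] and not result.assigned

    @pytest.mark.parametrize("n_subs,found", [(0, True), (1, True), (2, False)])
    def test_error_tolerance_boundary(self, demo_cfg, demo_index, n_subs, found):
        rng = random.Random(100 + n_subs)
        a1 = demo_cfg.tag_by_id("Barcode_A1").sequence
        variant = plant_substitutions(a1, n_subs, rng)
        tail = clean_filler(demo_index, 24, rng, variant[-5:])
        result = parse_fragment_set(_frag(variant + tail), demo_index, demo_cfg)
        assert ("Barcode_A1" in result.combination) == found

    def test_group_cap_one_counts_single_hit(self):
        # two tags of one group, cap 1, both present exactly: one hit only
        tags = (
            TagRecord("X", "g", "AAAATT", max_finds_group=1),
            TagRecord("Y", "g", "GGGGCC", max_finds_group=1),
        )
        cfg = Config(tags=tags)
        idx = build_index(cfg.tags)
        result = parse_fragment_set(_frag("AAAATTCACACAGGGGCC"), idx, cfg)
        assert result.combination == ("X",)

    def test_max_finds_caps_repeats_of_same_tag(self):
        cfg = Config(tags=(TagRecord("X", "g", "AAAATT", max_finds=2),))
        idx = build_index(cfg.tags)
        result = parse_fragment_set(_frag("AAAATT" * 4), idx, cfg)
        assert result.combination == ("X", "X")

    def test_next_replaces_searchable_groups(self):
        tags = (
            TagRecord("X", "g1", "AAAATT", next_groups=("g2",)),
            TagRecord("Y", "g2", "GGGGCC"),
        )
        cfg = Config(tags=tags)
        idx = build_index(cfg.tags)
        # second occurrence of X is skipped: only g2 is searchable after X
        result = parse_fragment_set(_frag("AAAATT" + "AAAATT" + "GGGGCC"), idx, cfg)
        assert result.combination == ("X", "Y")

    def test_min_finds_requirement_gates_assignment(self):
        tags = (
            TagRecord("X", "g", "AAAATT"),
            TagRecord("Y", "h", "GGGGCC", min_finds=1),
        )
        cfg = Config(tags=tags)
        idx = build_index(cfg.tags)
        result = parse_fragment_set(_frag("AAAATTCACACA"), idx, cfg)
        assert result.combination == ("X",) and not result.assigned

    def test_keep_groups_requirement(self, demo_cfg, demo_index):
        a2 = demo_cfg.tag_by_id("Barcode_A2").sequence
        tail = clean_filler(demo_index, 24, random.Random(5), a2[-5:])
        frag = _frag(a2 + tail)
        only_a = parse_fragment_set(frag, demo_index, demo_cfg)
        assert only_a.assigned  # no keep requirement
        gated = parse_fragment_set(
            frag, demo_index, demo_cfg, keep_groups={"grp_A", "grp_B"}
        )
        assert not gated.assigned

    def test_hits_disjoint_and_sorted(self, demo_cfg, demo_index):
        sim = generate(GeneratorSpec(config=demo_cfg, n_records=30, seed=42, error_rate=0.6))
        for frag in sim.fragments:
            result = parse_fragment_set(frag, demo_index, demo_cfg)
            by_file = {}
            for h in result.hits:
                by_file.setdefault(h.file_index, []).append(h)
            for hits in by_file.values():
                assert hits == sorted(hits, key=lambda h: h.start)
                for a, b in zip(hits, hits[1:]):
                    assert a.end <= b.start


def _random_two_tag_config(rng: random.Random) -> Config:
    def seq(n):
        return "".join(rng.choice("ACGT") for _ in range(n))

    groups = ["g1", "g2"] if rng.random() < 0.5 else ["g1", "g1"]
    tags = []
    for k in range(2):
        s = seq(rng.choice([5, 6]))
        loc = None
        if rng.random() < 0.4:
            start = rng.randint(0, 4)
            loc = FileWindow(0, start, start + rng.randint(3, 20))
        tags.append(
            TagRecord(
                tag_id=f"t{k}",
                group=groups[k],
                sequence=s,
                distance=rng.randint(0, 1),
                location=loc,
                next_groups=("g2",) if (k == 0 and rng.random() < 0.3 and "g2" in groups) else None,
                max_finds=rng.choice([None, 1, 2]),
                max_finds_group=rng.choice([None, 1]),
            )
        )
    return Config(tags=tuple(tags))


class TestOracleEquivalence:
    def test_matches_brute_force_window_scanner(self):
        """Greedy dictionary scanner equals direct-Hamming brute force on
        random 30-bp reads under random small substitution-only configs."""
        rng = random.Random(2024)
        for trial in range(60):
            cfg = _random_two_tag_config(rng)
            idx = build_index(cfg.tags)
            for _ in range(5):
                read = "".join(rng.choice("ACGT") for _ in range(30))
                got = parse_fragment_set(_frag(read), idx, cfg)
                expected = scan_brute([read], cfg)
                assert [
                    (h.tag_id, h.file_index, h.start, h.end, h.substitutions)
                    for h in got.hits
                ] == expected, (cfg, read)
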