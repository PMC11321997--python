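"""Mutant designers: edit-log round trips, placement rules, conservation."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from aroscan import (
    Interval,
    ProteinRecord,
    annotate_omega,
    apply_edits,
    aro_lite,
    aro_perfect,
    aro_perfect_is,
    aro_plus,
    find_stickers,
    scramble,
    shift_pattern,
    tile,
)

from conftest import random_sequence


def spacers_of(seq):
    return find_stickers(ProteinRecord("tmp", seq)).spacers


def region_of(rec):
    return Interval(rec.id, 1, len(rec.sequence))


@pytest.fixture()
def random_parent(rng):
    def make(length=80, p_aro=0.15):
        return ProteinRecord("wt", random_sequence(rng, length, p_aro))
    return make


DESIGNERS = [
    ("arolite", lambda p, r: aro_lite(p, r, "S")),
    ("aroperfect", lambda p, r: aro_perfect(p, r)),
    ("is10", lambda p, r: aro_perfect_is(p, r, 10)),
    ("aroplus", lambda p, r: aro_plus(p, r, max_spacer=15)),
    ("scramble", lambda p, r: scramble(p, r, seed=5)),
]


class TestEditLogContracts:
    @pytest.mark.parametrize("name, designer", DESIGNERS)
    def test_edit_log_reproduces_variant_and_length_conserved(
        self, name, designer, random_parent
    ):
        for _ in range(20):
            parent = random_parent()
            variant = designer(parent, region_of(parent))
            assert len(variant.sequence) == len(parent.sequence)
            assert apply_edits(parent.sequence, variant.edits) == variant.sequence

    @pytest.mark.parametrize(
        "name, designer",
        [d for d in DESIGNERS if d[0] in ("aroperfect", "scramble")],
    )
    def test_permutation_designs_conserve_composition(self, name, designer, random_parent):
        for _ in range(20):
            parent = random_parent()
            variant = designer(parent, region_of(parent))
            assert Counter(variant.sequence) == Counter(parent.sequence)

    def test_edits_confined_to_region(self, random_parent):
        parent = random_parent(length=100)
        region = Interval("wt", 21, 70)
        variant = aro_lite(parent, region, "A")
        assert all(21 <= pos <= 70 for pos, _, _ in variant.edits)
        assert variant.sequence[:20] == parent.sequence[:20]
        assert variant.sequence[70:] == parent.sequence[70:]


class TestAroLite:
    def test_replaces_every_aromatic(self):
        parent = ProteinRecord("wt", "GFGYG")
        v = aro_lite(parent, region_of(parent), "S")
        assert v.sequence == "GSGSG"
        assert len(v.edits) == 2

    def test_aromatic_free_region_is_identity_with_warning(self, caplog):
        parent = ProteinRecord("wt", "GGGGG")
        with caplog.at_level("WARNING"):
            v = aro_lite(parent, region_of(parent), "A")
        assert v.sequence == parent.sequence and v.edits == ()
        assert "identity" in caplog.text

    def test_invalid_replacement_rejected(self):
        parent = ProteinRecord("wt", "GFG")
        with pytest.raises(ValueError):
            aro_lite(parent, region_of(parent), "Y")

    def test_omega_after_undefined_and_flagged(self):
        parent = ProteinRecord("wt", "GGFGGYGGWGGFGG")
        v = aro_lite(parent, region_of(parent), "A")
        v = annotate_omega(v, parent, n_shuffles=50, seed=0)
        assert v.omega_before is not None
        assert v.omega_after is None
        assert "omega_after_undefined" in v.params


class TestAroPerfect:
    def test_forced_placement_example(self):
        parent = ProteinRecord("wt", "FFGGGGGG")
        v = aro_perfect(parent, region_of(parent))
        assert v.sequence == "GFGGGFGG"

    def test_output_spacers_differ_pairwise_by_at_most_one(self, random_parent):
        for _ in range(200):
            parent = random_parent(length=int(np.random.default_rng().integers(20, 120)))
            if find_stickers(parent).n_aro < 2:
                continue
            v = aro_perfect(parent, region_of(parent))
            sp = spacers_of(v.sequence)
            if len(sp) >= 2:
                assert max(sp) - min(sp) <= 1, (parent.sequence, v.sequence)

    def test_multiset_conserved(self, random_parent):
        parent = random_parent()
        v = aro_perfect(parent, region_of(parent))
        assert Counter(v.sequence) == Counter(parent.sequence)

    def test_needs_two_aromatics(self):
        parent = ProteinRecord("wt", "GFGGG")
        with pytest.raises(ValueError, match="at least 2"):
            aro_perfect(parent, region_of(parent))


class TestAroPerfectIS:
    def test_two_slot_example(self):
        parent = ProteinRecord("wt", "G" * 31)
        v = aro_perfect_is(parent, region_of(parent), 15)
        pos = [i + 1 for i, c in enumerate(v.sequence) if c in "FYW"]
        assert pos == [8, 24]
        assert all(c == "Y" for c in (v.sequence[7], v.sequence[23]))
        assert spacers_of(v.sequence) == (15,)

    def test_smaller_k_gives_more_aromatics(self):
        parent = ProteinRecord("wt", "G" * 31)
        n15 = find_stickers(ProteinRecord("x", aro_perfect_is(parent, region_of(parent), 15).sequence)).n_aro
        n10 = find_stickers(ProteinRecord("x", aro_perfect_is(parent, region_of(parent), 10).sequence)).n_aro
        assert n10 > n15

    def test_interior_spacers_exactly_k(self, random_parent):
        for k in (5, 10, 15):
            for _ in range(30):
                parent = random_parent(length=90)
                v = aro_perfect_is(parent, region_of(parent), k)
                assert all(s == k for s in spacers_of(v.sequence))

    def test_native_letters_fill_slots_in_order(self):
        parent = ProteinRecord("wt", "WGFGG" + "G" * 28)
        v = aro_perfect_is(parent, region_of(parent), 10)
        letters = [c for c in v.sequence if c in "FYW"]
        assert letters[:2] == ["W", "F"] and set(letters[2:]) <= {"Y"}

    def test_surplus_natives_become_alanine(self):
        parent = ProteinRecord("wt", "FYFYFYFYFYFY" + "G" * 10)  # 12 natives, few slots
        v = aro_perfect_is(parent, region_of(parent), 10)
        assert v.params["n_surplus"] == v.params["n_native"] - v.params["n_slots"] > 0
        assert "A" in v.sequence

    def test_too_short_region_rejected(self):
        parent = ProteinRecord("wt", "GGGG")
        with pytest.raises(ValueError):
            aro_perfect_is(parent, region_of(parent), 15)


class TestAroPlus:
    def test_minimal_split_arithmetic(self):
        parent = ProteinRecord("wt", "F" + "G" * 35 + "F")
        v = aro_plus(parent, region_of(parent), max_spacer=15)
        assert v.params["n_subs"] == 2
        assert spacers_of(v.sequence) == (11, 11, 11)

    def test_short_spacers_identity(self):
        parent = ProteinRecord("wt", ("F" + "G" * 10) * 4)
        v = aro_plus(parent, region_of(parent), max_spacer=15)
        assert v.sequence == parent.sequence and v.edits == ()

    def test_only_tyrosine_introduced_on_non_aromatics(self, random_parent):
        for _ in range(30):
            parent = random_parent(length=120, p_aro=0.04)
            v = aro_plus(parent, region_of(parent))
            for pos, frm, to in v.edits:
                assert to == "Y" and frm not in "FYW"

    def test_never_removes_native_stickers(self, random_parent):
        for _ in range(30):
            parent = random_parent(length=120, p_aro=0.05)
            before = find_stickers(parent).positions
            v = aro_plus(parent, region_of(parent))
            after = find_stickers(ProteinRecord("x", v.sequence)).positions
            assert set(before) <= set(after)

    def test_resulting_spacers_within_cutoff(self, random_parent):
        for _ in range(30):
            parent = random_parent(length=150, p_aro=0.03)
            v = aro_plus(parent, region_of(parent), max_spacer=15)
            assert all(s <= 15 for s in spacers_of(v.sequence))

    def test_max_subs_cap(self):
        parent = ProteinRecord("wt", "F" + "G" * 70 + "F")
        v = aro_plus(parent, region_of(parent), max_spacer=10, max_subs=1)
        assert v.params["n_subs"] == 1


class TestShiftPattern:
    def test_single_swap_example(self):
        parent = ProteinRecord("wt", "GGFGG")
        assert shift_pattern(parent, region_of(parent), -2).sequence == "FGGGG"

    def test_zero_offset_identity(self):
        parent = ProteinRecord("wt", "GGFGGYG")
        assert shift_pattern(parent, region_of(parent), 0).sequence == parent.sequence

    def test_round_trip(self, random_parent):
        for offset in (-2, -1, 1, 2):
            for _ in range(20):
                parent = random_parent(length=60, p_aro=0.1)
                prof = find_stickers(parent)
                if prof.n_aro == 0:
                    continue
                if not all(1 <= p + offset <= 60 for p in prof.positions):
                    continue
                fwd = shift_pattern(parent, region_of(parent), offset)
                back = shift_pattern(
                    ProteinRecord("wt", fwd.sequence), region_of(parent), -offset
                )
                assert back.sequence == parent.sequence

    def test_out_of_region_target_lists_offenders(self):
        parent = ProteinRecord("wt", "FGGGG")
        with pytest.raises(ValueError, match=r"\[1\]"):
            shift_pattern(parent, region_of(parent), -2)

    def test_composition_conserved(self, random_parent):
        parent = ProteinRecord("wt", "GGGFGGYGGWGGG")
        v = shift_pattern(parent, region_of(parent), 2)
        assert Counter(v.sequence) == Counter(parent.sequence)


class TestScramble:
    def test_seeded_determinism(self):
        parent = ProteinRecord("wt", "GGFGGYGGWGGFGGGG")
        region = region_of(parent)
        assert scramble(parent, region, 7).sequence == scramble(parent, region, 7).sequence

    def test_uniform_over_position_sets(self):
        """2,000 seeds on a 20-mer with 3 stickers: the first-sticker
        position is distributed as exact enumeration predicts (chi-square
        on a coarsened partition)."""
        parent = ProteinRecord("wt", "FYW" + "G" * 17)
        region = region_of(parent)
        L, n = 20, 3
        sets = list(itertools.combinations(range(1, L + 1), n))
        # coarsen: partition by min position bucket (1-5, 6-10, 11-15, 16-18)
        def bucket(first):
            return min((first - 1) // 5, 3)
        expected = Counter(bucket(s[0]) for s in sets)
        observed = Counter()
        for seed in range(2000):
            v = scramble(parent, region, seed)
            first = next(i + 1 for i, c in enumerate(v.sequence) if c in "FYW")
            observed[bucket(first)] += 1
        exp = np.array([expected[b] / len(sets) * 2000 for b in range(4)])
        obs = np.array([observed[b] for b in range(4)])
        assert chisquare(obs, exp).pvalue > 1e-3

    def test_letter_order_preserved(self):
        parent = ProteinRecord("wt", "FGYGWGGGGG")
        v = scramble(parent, region_of(parent), 3)
        assert [c for c in v.sequence if c in "FYW"] == ["F", "Y", "W"]

    def test_needs_a_sticker(self):
        parent = ProteinRecord("wt", "GGGG")
        with pytest.raises(ValueError):
            scramble(parent, region_of(parent), 0)


class TestTile:
    def test_exact_fit(self):
        parent = ProteinRecord("wt", "G" * 100)
        tiles = tile(parent, region_of(parent))
        assert [(t.region.start, t.region.end) for t in tiles] == [
            (1, 40), (21, 60), (41, 80), (61, 100)
        ]

    def test_tail_dropped_with_warning(self, caplog):
        parent = ProteinRecord("wt", "G" * 110)
        with caplog.at_level("WARNING"):
            tiles = tile(parent, region_of(parent))
        assert len(tiles) == 4
        assert "tail dropped" in caplog.text

    def test_consecutive_overlap_is_exact(self, random_parent):
        parent = random_parent(length=140)
        tiles = tile(parent, region_of(parent))
        for a, b in zip(tiles, tiles[1:]):
            assert a.region.end - b.region.start + 1 == 20
            assert a.sequence[-20:] == b.sequence[:20]

    def test_tile_count_formula(self):
        for L in range(40, 200, 7):
            parent = ProteinRecord("wt", "G" * L)
            assert len(tile(parent, region_of(parent))) == (L - 40) // 20 + 1

    def test_region_shorter_than_tile_rejected(self):
        parent = ProteinRecord("wt", "G" * 30)
        with pytest.raises(ValueError):
            tile(parent, region_of(parent))


class TestOmegaEffects:
    def test_aro_perfect_rarely_increases_omega(self, rng):
        """Uniform redistribution lowers omega for most parents whose native
        spacers vary (median over 200 synthetic parents decreases)."""
        deltas = []
        for _ in range(200):
            parent = ProteinRecord("wt", random_sequence(rng, 100, p_aro=0.1))
            prof = find_stickers(parent)
            if prof.n_aro < 3 or np.var(prof.spacers) == 0:
                continue
            from aroscan import omega_for_record
            before = omega_for_record(parent, n_shuffles=0)
            v = aro_perfect(parent, region_of(parent))
            after = omega_for_record(
                ProteinRecord("x", v.sequence), n_shuffles=0,
                blob_size=before.blob_size,
            )
            deltas.append(after.omega - before.omega)
        assert np.median(deltas) < 0
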