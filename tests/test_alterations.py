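"""Alteration rulesets: dispatch, worked examples, and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainnoise import (
    AlterationKind,
    alter_f4,
    alter_f8,
    classify_pair_f4,
    classify_pair_f8,
    cut_f8,
    flip_f4,
    flip_f8,
    pull_f8,
    push_f8,
    remove_f4,
    remove_f8,
    rotate_f8,
    wrap_f4,
    wrap_f8,
)
from chainnoise.alter_f8 import WrongRuleError
from chainnoise.chain_core import CodeType, symbol_displacement


def vec_sum(symbols, code_type):
    dx = dy = 0
    for s in symbols:
        sx, sy = symbol_displacement(s, code_type)
        dx, dy = dx + sx, dy + sy
    return (dx, dy)


def all_f8_options(c1, c2):
    """Every concrete replacement reachable for an F8 pair."""
    kind = classify_pair_f8(c1, c2)
    if kind is AlterationKind.REMOVE:
        return [remove_f8()]
    if kind is AlterationKind.PUSH:
        return [push_f8(c1, "A"), push_f8(c1, "B")]
    if kind is AlterationKind.WRAP:
        return [wrap_f8(c1, "A"), wrap_f8(c1, "B")]
    if kind is AlterationKind.FLIP:
        return [flip_f8(c1, c2)]
    if kind is AlterationKind.PULL:
        return [pull_f8(c1, c2)]
    if kind is AlterationKind.FLIP_OR_CUT:
        return [flip_f8(c1, c2), cut_f8(c1, c2)]
    return [rotate_f8(c1, c2), cut_f8(c1, c2)]


def all_f4_options(c1, c2):
    kind = classify_pair_f4(c1, c2)
    if kind is AlterationKind.WRAP:
        return [wrap_f4(c1, "A"), wrap_f4(c1, "B")]
    if kind is AlterationKind.REMOVE:
        return [remove_f4()]
    return [flip_f4(c1, c2)]


class TestF8Dispatch:
    @pytest.mark.parametrize("pair,kind", [
        ((3, 7), AlterationKind.REMOVE),
        ((0, 0), AlterationKind.PUSH),
        ((1, 1), AlterationKind.WRAP),
        ((2, 3), AlterationKind.FLIP),
        ((3, 5), AlterationKind.PULL),
        ((4, 2), AlterationKind.FLIP_OR_CUT),
        ((4, 1), AlterationKind.ROTATE_OR_CUT),
    ])
    def test_classification(self, pair, kind):
        assert classify_pair_f8(*pair) is kind

    def test_partition_exactly_one_branch(self):
        """The seven dispatch conditions tile all 64 ordered pairs."""
        for c1 in range(8):
            for c2 in range(8):
                d, matches = abs(c1 - c2), []
                if d == 4:
                    matches.append("REMOVE")
                if c1 == c2 and c1 % 2 == 0:
                    matches.append("PUSH")
                if c1 == c2 and c1 % 2 == 1:
                    matches.append("WRAP")
                if d in (1, 7):
                    matches.append("FLIP")
                if d in (2, 6) and c1 % 2 == 1:
                    matches.append("PULL")
                if d in (2, 6) and c1 % 2 == 0:
                    matches.append("FLIP_OR_CUT")
                if d in (3, 5):
                    matches.append("ROTATE_OR_CUT")
                assert matches == [classify_pair_f8(c1, c2).value]

    def test_out_of_alphabet(self):
        with pytest.raises(WrongRuleError):
            classify_pair_f8(8, 0)


class TestF8Rules:
    """Worked examples (paired with the demo path) and independent arithmetic."""

    def test_remove_is_empty(self):
        assert remove_f8().replacement == ()

    @pytest.mark.parametrize("c,branch,expected", [
        (0, "A", (1, 7)), (2, "A", (3, 1)), (6, "B", (5, 7)),
    ])
    def test_push(self, c, branch, expected):
        assert push_f8(c, branch).replacement == expected

    def test_push_rejects_odd(self):
        with pytest.raises(WrongRuleError):
            push_f8(3)

    @pytest.mark.parametrize("c,branch,expected", [
        (1, "B", (0, 1, 2)), (5, "A", (6, 5, 4)), (7, "B", (6, 7, 0)),
    ])
    def test_wrap(self, c, branch, expected):
        assert wrap_f8(c, branch).replacement == expected

    def test_flip_transposes_and_is_involution(self):
        assert flip_f8(2, 3).replacement == (3, 2)
        assert flip_f8(0, 7).replacement == (7, 0)
        for c1 in range(8):
            for c2 in range(8):
                assert flip_f8(*flip_f8(c1, c2).replacement).replacement == (c1, c2)

    @pytest.mark.parametrize("pair,expected", [
        ((3, 5), (4, 4)), ((7, 1), (0, 0)), ((1, 3), (2, 2)),
    ])
    def test_pull(self, pair, expected):
        assert pull_f8(*pair).replacement == expected

    @pytest.mark.parametrize("pair,expected", [
        ((4, 2), (3,)), ((0, 3), (2,)), ((1, 6), (0,)),
    ])
    def test_cut(self, pair, expected):
        assert cut_f8(*pair).replacement == expected

    @pytest.mark.parametrize("pair,expected", [
        ((4, 1), (3, 0)), ((2, 5), (3, 6)), ((3, 6), (2, 5)),
    ])
    def test_rotate(self, pair, expected):
        assert rotate_f8(*pair).replacement == expected


class TestF8Conservation:
    def test_displacement_conserved_every_branch(self):
        """Replacements carry the pair's net step, keeping loops closed."""
        for c1 in range(8):
            for c2 in range(8):
                want = vec_sum((c1, c2), CodeType.F8)
                for res in all_f8_options(c1, c2):
                    assert vec_sum(res.replacement, CodeType.F8) == want, (c1, c2, res)

    def test_alphabet_closure_and_length_deltas(self):
        deltas = set()
        for c1 in range(8):
            for c2 in range(8):
                for res in all_f8_options(c1, c2):
                    assert all(0 <= s <= 7 for s in res.replacement)
                    deltas.add(len(res.replacement) - 2)
        assert deltas == {-2, -1, 0, +1}


class TestF4Rules:
    @pytest.mark.parametrize("pair,kind", [
        ((0, 0), AlterationKind.WRAP),
        ((1, 3), AlterationKind.REMOVE),
        ((0, 1), AlterationKind.FLIP),
    ])
    def test_classification(self, pair, kind):
        assert classify_pair_f4(*pair) is kind

    def test_partition(self):
        for c1 in range(4):
            for c2 in range(4):
                if c1 == c2:
                    want = AlterationKind.WRAP
                elif abs(c1 - c2) == 2:
                    want = AlterationKind.REMOVE
                else:
                    want = AlterationKind.FLIP
                assert classify_pair_f4(c1, c2) is want

    @pytest.mark.parametrize("c,branch,expected", [
        (0, "B", (3, 0, 0, 1)), (1, "A", (2, 1, 1, 0)), (2, "B", (1, 2, 2, 3)),
    ])
    def test_wrap(self, c, branch, expected):
        assert wrap_f4(c, branch).replacement == expected

    def test_remove_and_flip(self):
        assert remove_f4().replacement == ()
        assert flip_f4(3, 0).replacement == (0, 3)
        assert flip_f4(*flip_f4(0, 1).replacement).replacement == (0, 1)

    def test_displacement_and_length_deltas(self):
        deltas = set()
        for c1 in range(4):
            for c2 in range(4):
                want = vec_sum((c1, c2), CodeType.F4)
                for res in all_f4_options(c1, c2):
                    assert vec_sum(res.replacement, CodeType.F4) == want
                    assert all(0 <= s <= 3 for s in res.replacement)
                    deltas.add(len(res.replacement) - 2)
        assert deltas == {-2, 0, +2}


class TestRandomisedDispatch:
    def test_remove_is_forced(self):
        rng = np.random.default_rng(0)
        assert alter_f8(3, 7, rng).kind is AlterationKind.REMOVE
        assert alter_f4(1, 3, rng).kind is AlterationKind.REMOVE

    def test_composite_resolution_is_balanced(self):
        """FLIP/CUT composite resolves close to 50/50 over many draws."""
        rng = np.random.default_rng(42)
        kinds = [alter_f8(4, 2, rng).kind for _ in range(1000)]
        n_flip = sum(k is AlterationKind.FLIP for k in kinds)
        assert set(kinds) == {AlterationKind.FLIP, AlterationKind.CUT}
        assert 400 < n_flip < 600

    def test_wrap_pair_yields_only_wrap_variants(self):
        rng = np.random.default_rng(7)
        results = {alter_f8(1, 1, rng).replacement for _ in range(100)}
        assert results == {(2, 1, 0), (0, 1, 2)}
        results4 = {alter_f4(0, 0, rng).replacement for _ in range(100)}
        assert results4 == {(1, 0, 0, 3), (3, 0, 0, 1)}

    @given(st.integers(0, 7), st.integers(0, 7), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=200)
    def test_alter_f8_always_conserves(self, c1, c2, seed):
        res = alter_f8(c1, c2, np.random.default_rng(seed))
        assert vec_sum(res.replacement, CodeType.F8) == vec_sum((c1, c2), CodeType.F8)
        assert not res.kind.is_composite
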