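"""Binary encoding, the isolated/"010" statistic, fractions and chi-square."""

import itertools

import numpy as np
import pytest

from finray.adjacency import (
    BinarySequence,
    ContingencyTable,
    DegenerateTableError,
    UndefinedStatisticError,
    bystander_fraction,
    chi_square_test,
    count_isolated,
    encode_binary,
    neighbor_association_rate,
    regeneration_fraction,
)
from finray.records import RayRecord, ValidationError

from conftest import make_dataset, make_fin


def seq(values, blocks=None):
    blocks = blocks or [(0, len(values))]
    return BinarySequence(np.array(values), tuple(blocks))


def scan_oracle(values):
    """Independent literal scan: a 1 is isolated iff no existing neighbor is 1."""
    iso = 0
    for i, v in enumerate(values):
        if v != 1:
            continue
        left = values[i - 1] if i > 0 else 0
        right = values[i + 1] if i < len(values) - 1 else 0
        if left == 0 and right == 0:
            iso += 1
    return iso, sum(values)


# ---------------------------------------------------------------------------
# encoding


def test_encode_single_block():
    rays = make_fin([("none", False), ("none", True), ("none", False)]).rays
    s = encode_binary(rays, "regen_7dpi")
    assert list(s.values) == [0, 1, 0]
    assert s.blocks == ((0, 3),)


def test_encode_two_fins_pooled_blocks():
    a = make_fin([("none", True), ("none", False)], fish="f1").rays
    b = make_fin([("none", False), ("none", True)], fish="f2").rays
    s = encode_binary(a + b, "regen_7dpi")
    assert s.blocks == ((0, 2), (2, 2))
    assert s.block_one_counts() == [(2, 1), (2, 1)]


def test_encode_preserves_multiset_counts():
    rays = [
        RayRecord("f1", "c", i + 1, regen_7dpi=(i < 142)) for i in range(551)
    ]
    s = encode_binary(rays, "regen_7dpi")
    assert s.ones_count == 142 and len(s) - s.ones_count == 409


def test_block_invariants_enforced():
    with pytest.raises(ValidationError):
        BinarySequence(np.array([0, 1]), ((0, 1),))  # lengths do not cover


# ---------------------------------------------------------------------------
# isolated counting


@pytest.mark.parametrize(
    "values, expected",
    [
        ([0, 1, 0], (1, 1)),
        ([1, 1], (0, 2)),
        ([1], (1, 1)),
        ([0, 1, 0, 1, 1, 0, 1], (2, 4)),  # positions 2 and 7 isolated
    ],
)
def test_count_isolated_examples(values, expected):
    assert count_isolated(seq(values)) == expected


def test_count_isolated_matches_scan_oracle_exhaustively():
    """Exhaustive oracle equivalence on every binary sequence of length <= 12."""
    for L in range(1, 13):
        for bits in itertools.product((0, 1), repeat=L):
            assert count_isolated(seq(list(bits)), respect_blocks=False) == scan_oracle(
                list(bits)
            )


def test_blocks_can_only_gain_isolation():
    """A boundary 1 may become isolated when fins are respected, never the
    reverse: isolated(respect) >= isolated(pooled) on any block split."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        L = int(rng.integers(2, 16))
        values = rng.integers(0, 2, size=L).tolist()
        cut = int(rng.integers(1, L))
        s = seq(values, blocks=[(0, cut), (cut, L - cut)])
        with_blocks, _ = count_isolated(s, respect_blocks=True)
        pooled, _ = count_isolated(s, respect_blocks=False)
        assert with_blocks >= pooled


def test_respect_blocks_splits_adjacent_pair():
    s = seq([0, 1, 1, 0], blocks=[(0, 2), (2, 2)])
    assert count_isolated(s, respect_blocks=True) == (2, 2)
    assert count_isolated(s, respect_blocks=False) == (0, 2)


# ---------------------------------------------------------------------------
# bystander fraction


@pytest.mark.parametrize(
    "values, expected", [([1, 1, 0, 0], 1.0), ([0, 1, 0], 0.0)]
)
def test_bystander_fraction_examples(values, expected):
    assert bystander_fraction(seq(values)) == expected


def test_bystander_fraction_is_complement_of_isolated_freq():
    rng = np.random.default_rng(1)
    for _ in range(100):
        values = rng.integers(0, 2, size=int(rng.integers(1, 30))).tolist()
        if sum(values) == 0:
            continue
        s = seq(values)
        iso, ones = count_isolated(s)
        assert bystander_fraction(s) + iso / ones == pytest.approx(1.0)


def test_bystander_fraction_undefined_without_ones():
    with pytest.raises(UndefinedStatisticError):
        bystander_fraction(seq([0, 0, 0]))


# ---------------------------------------------------------------------------
# neighbor association and fractions


def test_escaper_with_regenerating_neighbors():
    ds = make_dataset(make_fin([("none", True), "escaper", ("none", True)]))
    assert neighbor_association_rate(ds, "escaper") == 1.0


def test_association_zero_when_nothing_regenerates():
    ds = make_dataset(make_fin([("none", False), "re_amputation", ("none", False)]))
    assert neighbor_association_rate(ds, "re_amputation") == 0.0


def test_association_undefined_without_focal_rays():
    ds = make_dataset(make_fin(["none", "none"]))
    with pytest.raises(UndefinedStatisticError):
        neighbor_association_rate(ds, "skin_wound")


def test_regeneration_fraction_values():
    rays = [RayRecord("f", "c", i + 1, regen_7dpi=(i < 62)) for i in range(84)]
    assert regeneration_fraction(rays, "regen_7dpi") == pytest.approx(62 / 84)
    rays551 = [RayRecord("f", "c", i + 1, regen_7dpi=(i < 142)) for i in range(551)]
    assert regeneration_fraction(rays551, "regen_7dpi") == pytest.approx(142 / 551)
    assert regeneration_fraction(
        [RayRecord("f", "c", 1)], "regen_7dpi"
    ) == 0.0


def test_regeneration_fraction_empty_subset():
    with pytest.raises(UndefinedStatisticError):
        regeneration_fraction([], "regen_7dpi")


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_balanced_table_is_null():
    res = chi_square_test(ContingencyTable.from_counts(10, 10, 10, 10))
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed_statistic():
    # [[3,1],[1,3]]: all expected counts are 2, Pearson sum = 4 * (1/2) = 2
    res = chi_square_test(ContingencyTable.from_counts(3, 1, 1, 3))
    assert res.statistic == pytest.approx(2.0)
    assert res.df == 1


def test_chi_square_invariant_under_transpose_and_row_swap():
    t = ContingencyTable.from_counts(12, 5, 3, 20)
    base = chi_square_test(t).statistic
    assert chi_square_test(ContingencyTable(t.counts.T)).statistic == pytest.approx(base)
    assert chi_square_test(ContingencyTable(t.counts[::-1])).statistic == pytest.approx(base)


def test_chi_square_degenerate_margin():
    with pytest.raises(DegenerateTableError):
        chi_square_test(ContingencyTable.from_counts(0, 0, 5, 5))


def test_yates_correction_shrinks_statistic():
    t = ContingencyTable.from_counts(12, 5, 3, 20)
    assert chi_square_test(t, "yates").statistic < chi_square_test(t).statistic
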