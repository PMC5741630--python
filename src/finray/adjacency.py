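"""Binary encoding of regeneration calls and adjacency statistics.

A regenerating ray is coded 1, a non-regenerating ray 0.  A 1 is an
*isolated regenerator* ("010") when every existing neighbor is 0; a 1
with at least one regenerating neighbor is a *bystander*.  The isolated
frequency is isolated ones / total ones, and the bystander fraction its
complement.

End convention: a 1 at a sequence or fin-block end has a single existing
neighbor and is isolated iff that neighbor is 0 — no phantom zeros, no
wraparound.  Block boundaries can be respected (fins treated as separate
runs) or ignored (one pooled list); a boundary 1 can only gain isolation
when blocks are respected, never lose it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .records import Dataset, RayRecord, ValidationError, ray_outcome

__all__ = [
    "BinarySequence",
    "ContingencyTable",
    "ChiSquareResult",
    "UndefinedStatisticError",
    "DegenerateTableError",
    "encode_binary",
    "count_isolated",
    "bystander_fraction",
    "neighbor_association_rate",
    "regeneration_fraction",
    "chi_square_test",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. no ones)."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


@dataclass
class BinarySequence:
    """A 0/1 sequence with the fin-block structure that produced it."""

    values: np.ndarray
    blocks: tuple[tuple[int, int], ...]
    mode: str = "pooled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("values must be 0 or 1")
        self.blocks = tuple((int(s), int(l)) for s, l in self.blocks)
        pos = 0
        for start, length in self.blocks:
            if start != pos or length < 1:
                raise ValidationError(
                    f"blocks must be ordered, disjoint and contiguous; got {self.blocks}"
                )
            pos += length
        if pos != len(self.values):
            raise ValidationError("block lengths must sum to the sequence length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def ones_count(self) -> int:
        return int(self.values.sum())

    def block_one_counts(self) -> list[tuple[int, int]]:
        """Per block: (length, number of ones) — the stratified-null layout."""
        return [
            (length, int(self.values[start : start + length].sum()))
            for start, length in self.blocks
        ]


def encode_binary(
    rays: Sequence[RayRecord], outcome_field: str, mode: str = "pooled"
) -> BinarySequence:
    """Encode an ordered ray subset as 0/1 with fin boundaries recorded.

    Consecutive rays sharing (fish_id, fin_id) form one block; blocks are
    concatenated in input order.  The rays need not be a full fin —
    eligibility filtering leaves gaps, and consecutive survivors of the
    same fin are treated as one run.
    """
    values = [1 if ray_outcome(r, outcome_field) else 0 for r in rays]
    blocks: list[tuple[int, int]] = []
    prev_key: tuple[str, str] | None = None
    for i, r in enumerate(rays):
        k = (r.fish_id, r.fin_id)
        if k != prev_key:
            blocks.append((i, 1))
            prev_key = k
        else:
            start, length = blocks[-1]
            blocks[-1] = (start, length + 1)
    return BinarySequence(np.array(values, dtype=np.int8), tuple(blocks), mode=mode)


def _isolated_in_run(arr: np.ndarray) -> int:
    left = np.concatenate(([0], arr[:-1]))
    right = np.concatenate((arr[1:], [0]))
    return int(((arr == 1) & (left == 0) & (right == 0)).sum())


def count_isolated(seq: BinarySequence, respect_blocks: bool = True) -> tuple[int, int]:
    """Count ones whose every existing neighbor is 0.

    Returns ``(isolated_count, ones_count)``; the isolated frequency is
    their ratio (undefined when there are no ones).
    """
    v = seq.values
    ones = int(v.sum())
    if respect_blocks and seq.blocks:
        isolated = sum(
            _isolated_in_run(v[s : s + l]) for s, l in seq.blocks
        )
    else:
        isolated = _isolated_in_run(v)
    return isolated, ones


def bystander_fraction(seq: BinarySequence, respect_blocks: bool = True) -> float:
    """Fraction of regenerating rays that have a regenerating neighbor."""
    isolated, ones = count_isolated(seq, respect_blocks=respect_blocks)
    if ones == 0:
        raise UndefinedStatisticError(
            "bystander fraction undefined: no regenerating rays"
        )
    return 1.0 - isolated / ones


def neighbor_association_rate(
    dataset: Dataset, focal_category: str, outcome_field: str = "regen_7dpi"
) -> float:
    """Fraction of focal rays with >=1 regenerating immediate neighbor.

    ``focal_category`` is ``"escaper"`` (the flag) or an injury class.
    Used as the control comparing escaper-adjacent with injury-adjacent
    bystander induction.
    """
    n_focal = 0
    n_assoc = 0
    for fin in dataset.fins:
        for i, ray in enumerate(fin.rays):
            if focal_category == "escaper":
                is_focal = ray.escaper
            else:
                is_focal = ray.injury == focal_category
            if not is_focal:
                continue
            n_focal += 1
            if any(ray_outcome(nb, outcome_field) for nb in fin.neighbors(i)):
                n_assoc += 1
    if n_focal == 0:
        raise UndefinedStatisticError(
            f"no rays in focal category {focal_category!r}"
        )
    return n_assoc / n_focal


def regeneration_fraction(rays: Iterable[RayRecord], outcome_field: str) -> float:
    """(# rays with the outcome true) / (# rays)."""
    rays = list(rays)
    if not rays:
        raise UndefinedStatisticError("regeneration fraction undefined on empty subset")
    return sum(ray_outcome(r, outcome_field) for r in rays) / len(rays)


@dataclass
class ContingencyTable:
    """2x2 counts: rows = treatment groups, columns = regenerating / not."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValidationError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("at least one count must be positive")

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int) -> "ContingencyTable":
        """Row-major: [[a, b], [c, d]]."""
        return cls(np.array([[a, b], [c, d]]))

    @classmethod
    def from_fractions(
        cls, k1: int, n1: int, k2: int, n2: int
    ) -> "ContingencyTable":
        """Build from per-group successes and totals."""
        return cls(np.array([[k1, n1 - k1], [k2, n2 - k2]]))


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def chi_square_test(
    table: ContingencyTable, correction: str = "none"
) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table (``correction="yates"`` optional)."""
    if correction not in ("none", "yates"):
        raise ValueError(f"correction must be 'none' or 'yates', got {correction!r}")
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "chi-square undefined: table has a zero row or column margin"
        )
    stat, p, df, _ = stats.chi2_contingency(c, correction=(correction == "yates"))
    return ChiSquareResult(float(stat), int(df), float(p))
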