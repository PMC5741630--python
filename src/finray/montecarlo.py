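"""Monte Carlo permutation null for the isolated-regenerator frequency.

The question: are regenerating non-injured rays spatially clustered, or
placed as if at random?  Under the null, the observed multiset of ones
and zeros is re-arranged uniformly at random; for each arrangement the
isolated ("010") frequency — isolated ones / total ones — is recorded.
Clustering shows up as an observed isolated frequency *below* the null,
so with r = number of iterations whose null frequency is strictly lower
than the observed one and N iterations in total, the one-sided p-value is

    P = (r + 1) / (N + 1).

Ties (null frequency exactly equal to the observed) are not counted in r
but are reported separately.  Two null modes are offered: ``pooled``
shuffles the whole list as one run (ignoring fin boundaries), and
``stratified`` shuffles independently within each fin block, preserving
per-block one-counts.  ``expected_isolated`` gives the exact closed-form
null expectation for the pooled arrangement and serves as an analytic
cross-check on the permutation engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import json
from typing import Sequence

import numpy as np

from .adjacency import UndefinedStatisticError, count_isolated, encode_binary
from .eligibility import EligibilityConfig, eligible_noninjured
from .records import Dataset

__all__ = [
    "MCResult",
    "shuffle_null",
    "expected_isolated",
    "mc_pvalue",
    "run_bystander_test",
]

_BATCH = 2048  # iterations materialized at once; fixed so runs are bit-reproducible


@dataclass(eq=False)
class MCResult:
    """Observed isolated frequency, its permutation null, and the p-value."""

    observed_freq: float
    null_freqs: np.ndarray
    n_iterations: int
    r: int
    ties: int
    p_value: float
    seed: int | None = None
    mode: str = "pooled"

    @property
    def N(self) -> int:
        return self.n_iterations

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_freqs))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_freqs, ddof=1)) if self.n_iterations > 1 else 0.0

    @property
    def bystander_fraction(self) -> float:
        return 1.0 - self.observed_freq

    def to_json_dict(self) -> dict:
        return {
            "observed_isolated_freq": self.observed_freq,
            "N": self.n_iterations,
            "r": self.r,
            "ties": self.ties,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
            "mode": self.mode,
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(doc + "\n", encoding="utf-8")
        return doc

    def summary(self) -> str:
        lines = [
            "Monte Carlo permutation test of isolated-regenerator frequency",
            f"  null mode                 : {self.mode}",
            f"  iterations (N)            : {self.n_iterations}",
            f"  observed isolated freq    : {self.observed_freq:.4f}",
            f"  implied bystander fraction: {self.bystander_fraction:.4f}",
            f"  null mean (s.d.)          : {self.null_mean:.4f} ({self.null_sd:.4f})",
            f"  r (null < observed)       : {self.r}   ties: {self.ties}",
            f"  p = (r+1)/(N+1)           : {self.p_value:.6g}",
        ]
        return "\n".join(lines)


def _isolated_counts_matrix(S: np.ndarray) -> np.ndarray:
    """Isolated-one counts per row of a boolean matrix of arrangements."""
    P = np.zeros((S.shape[0], S.shape[1] + 2), dtype=bool)
    P[:, 1:-1] = S
    neighbor = P[:, :-2] | P[:, 2:]
    return (S & ~neighbor).sum(axis=1)


def _random_isolated_counts(
    rng: np.random.Generator, n_ones: int, length: int, iterations: int
) -> np.ndarray:
    """Isolated counts of uniform arrangements of ``n_ones`` ones in ``length``."""
    out = np.empty(iterations, dtype=np.int64)
    done = 0
    while done < iterations:
        b = min(_BATCH, iterations - done)
        u = rng.random((b, length))
        # positions of the n_ones smallest uniforms are a uniform subset
        idx = np.argpartition(u, n_ones - 1, axis=1)[:, :n_ones]
        S = np.zeros((b, length), dtype=bool)
        S[np.arange(b)[:, None], idx] = True
        out[done : done + b] = _isolated_counts_matrix(S)
        done += b
    return out


def shuffle_null(
    n_ones: int,
    n_zeros: int,
    iterations: int,
    seed: int | None = None,
    blocks: Sequence[tuple[int, int]] | None = None,
    mode: str = "pooled",
) -> np.ndarray:
    """Null distribution of the isolated frequency under random arrangement.

    Parameters
    ----------
    n_ones, n_zeros
        Multiset composition of the list being shuffled.
    blocks
        For ``mode="stratified"``: sequence of ``(length, ones)`` pairs,
        one per fin block; lengths must sum to ``n_ones + n_zeros`` and
        ones to ``n_ones``.  Ignored when pooled.
    mode
        ``"pooled"`` shuffles one flat list; ``"stratified"`` shuffles
        independently within each block and counts isolation within
        blocks.

    Returns the isolated frequency of each of ``iterations`` arrangements.
    """
    if n_ones < 1:
        raise UndefinedStatisticError("need at least one regenerating ray (n_ones >= 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode not in ("pooled", "stratified"):
        raise ValueError(f"mode must be 'pooled' or 'stratified', got {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "pooled":
        counts = _random_isolated_counts(rng, n_ones, n_ones + n_zeros, iterations)
        return counts / n_ones
    if blocks is None:
        raise ValueError("stratified mode requires per-block (length, ones) pairs")
    blocks = [(int(l), int(o)) for l, o in blocks]
    if sum(l for l, _ in blocks) != n_ones + n_zeros:
        raise ValueError("block lengths must sum to n_ones + n_zeros")
    if sum(o for _, o in blocks) != n_ones:
        raise ValueError("block one-counts must sum to n_ones")
    total = np.zeros(iterations, dtype=np.int64)
    for length, ones in blocks:
        if ones == 0:
            continue
        total += _random_isolated_counts(rng, ones, length, iterations)
    return total / n_ones


def expected_isolated(n_ones: int, n_zeros: int) -> float:
    """Exact expected isolated frequency under uniform pooled arrangement.

    By exchangeability the probability that an *end* position holds an
    isolated 1 is n1*n0 / (n*(n-1)); an *interior* position contributes
    n1*n0*(n0-1) / (n*(n-1)*(n-2)) — the two neighbors are drawn without
    replacement from the remaining symbols.  Summing over positions and
    dividing by n1 gives the expected frequency.
    """
    if n_ones < 1:
        raise UndefinedStatisticError("n_ones must be >= 1")
    if n_zeros < 0:
        raise ValueError("n_zeros must be >= 0")
    n1, n0 = n_ones, n_zeros
    n = n1 + n0
    if n == 1:
        return 1.0  # a lone 1 has no neighbors and is isolated by convention
    expected_count = 2 * Fraction(n1 * n0, n * (n - 1))
    if n >= 3:
        expected_count += (n - 2) * Fraction(
            n1 * n0 * (n0 - 1), n * (n - 1) * (n - 2)
        )
    return float(expected_count / n1)


def mc_pvalue(
    observed_freq: float,
    null_freqs: Sequence[float] | np.ndarray,
    seed: int | None = None,
    mode: str = "pooled",
) -> MCResult:
    """Assemble an :class:`MCResult` with P = (r+1)/(N+1).

    ``r`` counts null frequencies *strictly* lower than the observed one;
    ties are tallied separately and do not enter r.
    """
    null = np.asarray(null_freqs, dtype=float)
    if null.size == 0:
        raise ValueError("null_freqs must be non-empty")
    r = int((null < observed_freq).sum())
    ties = int((null == observed_freq).sum())
    N = int(null.size)
    return MCResult(
        observed_freq=float(observed_freq),
        null_freqs=null,
        n_iterations=N,
        r=r,
        ties=ties,
        p_value=(r + 1) / (N + 1),
        seed=seed,
        mode=mode,
    )


def run_bystander_test(
    dataset: Dataset,
    config: EligibilityConfig | None = None,
    outcome_field: str = "regen_7dpi",
    iterations: int = 10_000,
    seed: int | None = None,
    mode: str = "pooled",
    observed_respect_blocks: bool = True,
) -> MCResult:
    """End-to-end test: filter, encode, observe, build the null, report.

    The observed isolated frequency is computed on the eligible
    non-injured rays with fin boundaries respected by default (a boundary
    ray has one neighbor); the null re-arranges the same one/zero counts
    either pooled — the flat-list procedure — or stratified within fins.
    """
    rays = eligible_noninjured(dataset, config)
    if not rays:
        raise UndefinedStatisticError("no eligible non-injured rays in dataset")
    seq = encode_binary(rays, outcome_field, mode="pooled")
    isolated, ones = count_isolated(seq, respect_blocks=observed_respect_blocks)
    if ones == 0:
        raise UndefinedStatisticError("no regenerating rays among the eligible set")
    observed = isolated / ones
    null = shuffle_null(
        n_ones=ones,
        n_zeros=len(seq) - ones,
        iterations=iterations,
        seed=seed,
        blocks=[(l, o) for l, o in seq.block_one_counts()] if mode == "stratified" else None,
        mode=mode,
    )
    return mc_pvalue(observed, null, seed=seed, mode=mode)
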