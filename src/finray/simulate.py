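"""Synthetic ray-score datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
ordered fins of rays, sparse experimental injuries (one or two per fish,
never adjacent to each other when avoidable), injury-induced and
spontaneous regeneration, escapers, and nearest-neighbor contagion — a
ray next to a regenerating ray converting with probability
``p_bystander`` over a fixed number of synchronous passes.  It is a
purely statistical stand-in for locally spreading wound signals; there is
no mechanistic signaling model and no induction beyond immediate
neighbors.

Every simulated ray carries a ground-truth label (spontaneous,
injury_induced, bystander, escaper, silent) so each pipeline stage can be
tested against what the generator actually did.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjacency import UndefinedStatisticError
from .eligibility import EligibilityConfig
from .records import Dataset, FinSeries, RayRecord, ValidationError, INJURY_CATEGORIES

__all__ = ["SimParams", "SimTruth", "simulate_dataset", "sweep_power", "LABELS"]

LABELS = ("spontaneous", "injury_induced", "bystander", "escaper", "silent")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the contagion model.

    Defaults emulate the study conditions: 61 fish with one re-injury
    each, 18 rays per fin, a 74% induction rate on injured rays, and a
    spontaneous rate / contagion strength calibrated so the eligible
    non-injured regeneration frequency lands near 0.258 with a high
    bystander share (see docs/methods.md for the calibration).
    """

    n_fish: int = 61
    rays_per_fin: int = 18
    p_spont: float = 0.11
    p_injured_regen: float = 0.74
    p_bystander: float = 0.80
    spread_rounds: int = 1
    p_escaper: float = 0.03
    injuries_per_fish: int = 1
    injury_type: str = "epidermal_wound"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_spont", "p_injured_regen", "p_bystander", "p_escaper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_fish < 0 or self.rays_per_fin < 1:
            raise ValidationError("n_fish must be >= 0 and rays_per_fin >= 1")
        if self.injuries_per_fish not in (0, 1, 2):
            raise ValidationError("injuries_per_fish must be 0, 1 or 2")
        if self.injuries_per_fish > self.rays_per_fin:
            raise ValidationError("injuries_per_fish cannot exceed rays_per_fin")
        if self.spread_rounds < 0:
            raise ValidationError("spread_rounds must be >= 0")
        if self.injury_type not in INJURY_CATEGORIES or self.injury_type == "none":
            raise ValidationError(f"injury_type must be an injury class, got {self.injury_type!r}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(doc, encoding="utf-8")
        return doc

    @classmethod
    def from_yaml(cls, src: str | Path) -> "SimParams":
        text = Path(src).read_text(encoding="utf-8") if Path(str(src)).exists() else str(src)
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class SimTruth:
    """Per-ray generative labels keyed by (fish_id, fin_id, ray_index)."""

    labels: dict = field(default_factory=dict)

    def label_of(self, ray: RayRecord) -> str:
        return self.labels[ray.key]

    def counts(self) -> dict:
        out = {lab: 0 for lab in LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fish_id": f, "fin_id": n, "ray_index": i, "label": lab}
            for (f, n, i), lab in self.labels.items()
        ]
        return pd.DataFrame(rows, columns=["fish_id", "fin_id", "ray_index", "label"])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (str(r.fish_id), str(r.fin_id), int(r.ray_index)): str(r.label)
                for r in df.itertuples()
            }
        )


def _place_injuries(rng: np.random.Generator, K: int, n_inj: int) -> list[int]:
    """Uniformly random injury positions, mutually non-adjacent when possible."""
    positions: list[int] = []
    available = list(range(K))
    for _ in range(n_inj):
        if available:
            pos = int(rng.choice(available))
        else:  # no non-adjacent slot left; fall back to any uninjured position
            remaining = [i for i in range(K) if i not in positions]
            if not remaining:
                break
            pos = int(rng.choice(remaining))
        positions.append(pos)
        available = [i for i in available if abs(i - pos) > 1]
    return sorted(positions)


def simulate_dataset(params: SimParams) -> tuple[Dataset, SimTruth]:
    """Draw one dataset (one fin per fish) plus its ground-truth labels.

    Per fin: injuries are placed first; seed regenerators are drawn —
    injured rays with ``p_injured_regen``, uninjured rays spontaneously
    with ``p_spont`` or, failing that, as escapers with ``p_escaper``
    (escapers grow from day 0 and act as contagion sources); then
    ``spread_rounds`` synchronous contagion passes convert silent rays
    with at least one regenerating neighbor with probability
    ``p_bystander``.  ``regen_3dpi`` records the seed state, ``regen_7dpi``
    the state after spreading.
    """
    rng = np.random.default_rng(params.seed)
    fins: list[FinSeries] = []
    labels: dict = {}
    K = params.rays_per_fin
    for f in range(params.n_fish):
        fish_id = f"fish{f + 1:03d}"
        fin_id = "caudal"
        injured_pos = set(_place_injuries(rng, K, params.injuries_per_fish))
        label = ["silent"] * K
        regen = np.zeros(K, dtype=bool)
        for i in range(K):
            if i in injured_pos:
                if rng.random() < params.p_injured_regen:
                    regen[i] = True
                    label[i] = "injury_induced"
            else:
                if rng.random() < params.p_spont:
                    regen[i] = True
                    label[i] = "spontaneous"
                elif rng.random() < params.p_escaper:
                    regen[i] = True
                    label[i] = "escaper"
        regen_3dpi = regen.copy()
        for _ in range(params.spread_rounds):
            snapshot = regen.copy()
            for i in range(K):
                if snapshot[i]:
                    continue
                has_source = (i > 0 and snapshot[i - 1]) or (
                    i < K - 1 and snapshot[i + 1]
                )
                if has_source and rng.random() < params.p_bystander:
                    regen[i] = True
                    label[i] = "bystander"
        rays = []
        for i in range(K):
            rays.append(
                RayRecord(
                    fish_id=fish_id,
                    fin_id=fin_id,
                    ray_index=i + 1,
                    injury=params.injury_type if i in injured_pos else "none",
                    escaper=(label[i] == "escaper"),
                    inadvertent_injury=False,
                    regen_3dpi=bool(regen_3dpi[i]),
                    regen_7dpi=bool(regen[i]),
                )
            )
            labels[(fish_id, fin_id, i + 1)] = label[i]
        fins.append(FinSeries(fish_id, fin_id, rays))
    return Dataset(fins=fins, label="simulated"), SimTruth(labels)


def sweep_power(
    params_grid: list[SimParams],
    replicates: int,
    alpha: float = 0.05,
    iterations: int = 2000,
    outcome_field: str = "regen_7dpi",
    config: EligibilityConfig | None = None,
    mode: str = "pooled",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the permutation test over a parameter grid.

    Each replicate simulates a fresh dataset (child seeds spawned from
    ``base_seed``) and runs the full pipeline; a replicate on which the
    statistic is undefined (no eligible regenerating ray) counts as a
    non-rejection and is tallied in ``n_undefined``.
    """
    from .montecarlo import run_bystander_test

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(params_grid) * replicates)
    rows = []
    for j, params in enumerate(params_grid):
        rejections = 0
        undefined = 0
        for rep in range(replicates):
            child = children[j * replicates + rep]
            sim_seed = int(child.generate_state(2)[0] % (2**31))
            test_seed = int(child.generate_state(2)[1] % (2**31))
            dataset, _ = simulate_dataset(replace(params, seed=sim_seed))
            try:
                result = run_bystander_test(
                    dataset,
                    config=config,
                    outcome_field=outcome_field,
                    iterations=iterations,
                    seed=test_seed,
                    mode=mode,
                )
            except UndefinedStatisticError:
                undefined += 1
                continue
            if result.p_value <= alpha:
                rejections += 1
        rows.append(
            {
                "p_spont": params.p_spont,
                "p_bystander": params.p_bystander,
                "spread_rounds": params.spread_rounds,
                "n_fish": params.n_fish,
                "injuries_per_fish": params.injuries_per_fish,
                "replicates": replicates,
                "n_undefined": undefined,
                "rejections": rejections,
                "rejection_rate": rejections / replicates,
            }
        )
    return pd.DataFrame(rows)
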