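"""Exclusion rules defining which rays enter each analysis.

Two eligible sets matter downstream:

* the *non-injured analysis set* — non-injured, non-escaper rays with no
  immediate neighbor that is an escaper or carries an excluded injury
  class.  This is the set over which spontaneous/bystander regeneration
  frequencies and the permutation test are computed, and it is how
  bystander growth next to experimentally injured rays is kept from
  contaminating the "spontaneous" signal;
* the *bystander-quantification set* — the same, minus rays with
  inadvertent epidermis/bone damage and (configurably) minus rays that
  themselves grew next to another regenerating ray.

"Directly adjacent" always means a ray_index difference of exactly 1
within the same fin; boundary rays have a single neighbor and there is no
wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .records import (
    Dataset,
    FinSeries,
    RayRecord,
    ValidationError,
    copy_with,
    ray_outcome,
)

__all__ = [
    "EligibilityConfig",
    "ADJACENCY_CATEGORIES",
    "flag_escapers",
    "eligible_noninjured",
    "eligible_bystander_analysis",
]

#: Categories a neighbor can be excluded for. ``escaper`` refers to the
#: escaper flag; the rest are injury classes.
ADJACENCY_CATEGORIES = frozenset(
    {"escaper", "re_amputation", "epidermal_wound", "skin_wound"}
)

_DEFAULT_ADJACENT = frozenset({"escaper", "re_amputation", "epidermal_wound"})


@dataclass(frozen=True)
class EligibilityConfig:
    """Which exclusion rules apply.  Defaults reproduce the study rules:
    escapers excluded, rays adjacent to escapers / re-amputated /
    epidermally wounded rays excluded, inadvertently injured rays excluded
    from the bystander quantification, and — under the literal reading of
    the scoring protocol — rays that grew next to another regenerating ray
    excluded from that quantification as well (set
    ``exclude_bystander_growers=False`` for the alternative reading)."""

    exclude_escapers: bool = True
    exclude_adjacent_to: frozenset = _DEFAULT_ADJACENT
    exclude_inadvertent_injury: bool = True
    exclude_bystander_growers: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclude_adjacent_to", frozenset(self.exclude_adjacent_to))
        bad = self.exclude_adjacent_to - ADJACENCY_CATEGORIES
        if bad:
            raise ValidationError(f"unknown adjacency categories: {sorted(bad)}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            {
                "exclude_escapers": self.exclude_escapers,
                "exclude_adjacent_to": sorted(self.exclude_adjacent_to),
                "exclude_inadvertent_injury": self.exclude_inadvertent_injury,
                "exclude_bystander_growers": self.exclude_bystander_growers,
            },
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(doc, encoding="utf-8")
        return doc

    @classmethod
    def from_yaml(cls, src: str | Path) -> "EligibilityConfig":
        text = Path(src).read_text(encoding="utf-8") if Path(str(src)).exists() else str(src)
        data = yaml.safe_load(text) or {}
        if "exclude_adjacent_to" in data:
            data["exclude_adjacent_to"] = frozenset(data["exclude_adjacent_to"])
        return cls(**data)


def flag_escapers(dataset: Dataset, regen_field_at_relief: str) -> Dataset:
    """Re-derive the escaper flag from a growth call at blockade relief.

    Escapers are exactly the *uninjured* rays whose named boolean field is
    true — rays that visibly grew when transgene expression subsided and
    hence were never fully blocked.  Injured rays are never flagged.
    """
    fins = []
    for fin in dataset.fins:
        rays = [
            copy_with(
                r,
                escaper=(r.injury == "none" and ray_outcome(r, regen_field_at_relief)),
            )
            for r in fin.rays
        ]
        fins.append(FinSeries(fin.fish_id, fin.fin_id, rays))
    return Dataset(fins=fins, label=dataset.label)


def _neighbor_excluded(nb: RayRecord, categories: frozenset) -> bool:
    if nb.escaper and "escaper" in categories:
        return True
    return nb.injury != "none" and nb.injury in categories


def eligible_noninjured(
    dataset: Dataset, config: EligibilityConfig | None = None
) -> list[RayRecord]:
    """Rays entering the analysis of non-injured regeneration.

    Returns records in (fish, fin, ray_index) order so the result can be
    binary-encoded directly.
    """
    config = config or EligibilityConfig()
    out: list[RayRecord] = []
    for fin in dataset.fins:
        for i, ray in enumerate(fin.rays):
            if ray.injury != "none":
                continue
            if config.exclude_escapers and ray.escaper:
                continue
            if any(
                _neighbor_excluded(nb, config.exclude_adjacent_to)
                for nb in fin.neighbors(i)
            ):
                continue
            out.append(ray)
    return out


def eligible_bystander_analysis(
    dataset: Dataset,
    config: EligibilityConfig | None = None,
    outcome_field: str = "regen_7dpi",
) -> list[RayRecord]:
    """Rays entering the bystander quantification.

    Starts from the non-injured analysis rules and additionally drops rays
    with inadvertent epidermis/bone damage and, when
    ``exclude_bystander_growers`` is set, rays that regenerated with at
    least one regenerating immediate neighbor (i.e. growth not in
    isolation).
    """
    config = config or EligibilityConfig()
    base = {id(r) for r in eligible_noninjured(dataset, config)}
    out: list[RayRecord] = []
    for fin in dataset.fins:
        for i, ray in enumerate(fin.rays):
            if id(ray) not in base:
                continue
            if config.exclude_inadvertent_injury and ray.inadvertent_injury:
                continue
            if config.exclude_bystander_growers and ray_outcome(ray, outcome_field):
                if any(ray_outcome(nb, outcome_field) for nb in fin.neighbors(i)):
                    continue
            out.append(ray)
    return out
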