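"""Model/results front end for the bystander-regeneration analysis.

:class:`BystanderRegenerationTest` is constructed from a scored dataset
(or a table file / dataframe); :meth:`~BystanderRegenerationTest.fit`
runs the full pipeline — eligibility filtering, binary encoding, the
observed isolated-regenerator frequency, the Monte Carlo permutation
null — plus the descriptive layer: per-group regeneration fractions and
2x2 chi-square comparisons of each injured group against the eligible
non-injured rays.  The returned :class:`BystanderRegenerationResults`
carries the estimates and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .adjacency import (
    ContingencyTable,
    DegenerateTableError,
    chi_square_test,
    encode_binary,
)
from .eligibility import EligibilityConfig, eligible_noninjured
from .montecarlo import MCResult, expected_isolated, run_bystander_test
from .records import Dataset, read_ray_table

__all__ = ["BystanderRegenerationTest", "BystanderRegenerationResults"]

REPORT_SCHEMA_VERSION = 1


class BystanderRegenerationTest:
    """Spatial-clustering test of regeneration calls on ordered fin rays.

    Parameters
    ----------
    dataset
        A validated :class:`~finray.records.Dataset`.
    eligibility
        Exclusion rules; defaults to the study rules.
    outcome
        Which regeneration call to analyze (``regen_3dpi`` or
        ``regen_7dpi``).
    """

    def __init__(
        self,
        dataset: Dataset,
        eligibility: EligibilityConfig | None = None,
        outcome: str = "regen_7dpi",
    ):
        self.dataset = dataset
        self.eligibility = eligibility or EligibilityConfig()
        self.outcome = outcome

    @classmethod
    def from_table(
        cls, path: str | Path, dialect: str = "tsv", **kwargs
    ) -> "BystanderRegenerationTest":
        return cls(read_ray_table(path, dialect=dialect), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label: str = "", **kwargs
    ) -> "BystanderRegenerationTest":
        return cls(Dataset.from_dataframe(df, label=label), **kwargs)

    def fit(
        self,
        iterations: int = 10_000,
        seed: int | None = None,
        null_mode: str = "pooled",
        observed_respect_blocks: bool = True,
    ) -> "BystanderRegenerationResults":
        mc = run_bystander_test(
            self.dataset,
            config=self.eligibility,
            outcome_field=self.outcome,
            iterations=iterations,
            seed=seed,
            mode=null_mode,
            observed_respect_blocks=observed_respect_blocks,
        )
        eligible = eligible_noninjured(self.dataset, self.eligibility)
        seq = encode_binary(eligible, self.outcome)
        groups = self._group_fractions(eligible)
        comparisons = self._comparisons(groups)
        return BystanderRegenerationResults(
            model=self,
            mc=mc,
            n_eligible=len(eligible),
            n_regenerating=seq.ones_count,
            expected_isolated_null=expected_isolated(
                seq.ones_count, len(seq) - seq.ones_count
            )
            if seq.ones_count
            else float("nan"),
            group_fractions=groups,
            comparisons=comparisons,
        )

    def _group_fractions(self, eligible) -> dict:
        """Regeneration fraction per analysis group (k/n pairs)."""
        out = {}
        k = sum(1 for r in eligible if getattr(r, self.outcome))
        out["non_injured_eligible"] = {"k": k, "n": len(eligible)}
        for cat in ("re_amputation", "epidermal_wound", "skin_wound"):
            rays = [r for r in self.dataset.iter_rays() if r.injury == cat]
            if rays:
                kk = sum(1 for r in rays if getattr(r, self.outcome))
                out[cat] = {"k": kk, "n": len(rays)}
        return out

    def _comparisons(self, groups: dict) -> list[dict]:
        base = groups["non_injured_eligible"]
        out = []
        for cat, g in groups.items():
            if cat == "non_injured_eligible":
                continue
            table = ContingencyTable.from_fractions(g["k"], g["n"], base["k"], base["n"])
            entry = {"group": cat, "vs": "non_injured_eligible",
                     "table": table.counts.tolist()}
            try:
                res = chi_square_test(table)
                entry.update(statistic=res.statistic, df=res.df, p_value=res.p_value)
            except DegenerateTableError as exc:
                entry.update(statistic=None, df=None, p_value=None, note=str(exc))
            out.append(entry)
        return out


class BystanderRegenerationResults:
    """Estimates, null distribution and diagnostics from a fitted test."""

    def __init__(
        self,
        model: BystanderRegenerationTest,
        mc: MCResult,
        n_eligible: int,
        n_regenerating: int,
        expected_isolated_null: float,
        group_fractions: dict,
        comparisons: list[dict],
    ):
        self.model = model
        self.mc = mc
        self.n_eligible = n_eligible
        self.n_regenerating = n_regenerating
        self.expected_isolated_null = expected_isolated_null
        self.group_fractions = group_fractions
        self.comparisons = comparisons

    # -- convenience accessors -------------------------------------------
    @property
    def p_value(self) -> float:
        return self.mc.p_value

    @property
    def observed_isolated_freq(self) -> float:
        return self.mc.observed_freq

    @property
    def bystander_fraction(self) -> float:
        return self.mc.bystander_fraction

    @property
    def null_mean(self) -> float:
        return self.mc.null_mean

    @property
    def null_sd(self) -> float:
        return self.mc.null_sd

    @property
    def marginal_regen_fraction(self) -> float:
        return self.n_regenerating / self.n_eligible if self.n_eligible else float("nan")

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "label": self.model.dataset.label,
            "outcome": self.model.outcome,
            "eligibility": {
                "exclude_escapers": self.model.eligibility.exclude_escapers,
                "exclude_adjacent_to": sorted(self.model.eligibility.exclude_adjacent_to),
                "exclude_inadvertent_injury": self.model.eligibility.exclude_inadvertent_injury,
                "exclude_bystander_growers": self.model.eligibility.exclude_bystander_growers,
            },
            "n_eligible": self.n_eligible,
            "n_regenerating": self.n_regenerating,
            "marginal_regen_fraction": self.marginal_regen_fraction,
            "expected_isolated_null": self.expected_isolated_null,
            "group_fractions": {
                k: {**v, "fraction": v["k"] / v["n"]}
                for k, v in self.group_fractions.items()
            },
            "comparisons": self.comparisons,
            "monte_carlo": self.mc.to_json_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(doc + "\n", encoding="utf-8")
        return doc

    def summary(self) -> str:
        lines = [
            "Bystander regeneration analysis",
            "=" * 64,
            f"dataset label        : {self.model.dataset.label or '(unlabeled)'}",
            f"outcome field        : {self.model.outcome}",
            f"eligible non-injured : {self.n_eligible} rays, "
            f"{self.n_regenerating} regenerating "
            f"(fraction {self.marginal_regen_fraction:.4f})",
            "",
            "Group regeneration fractions",
            "-" * 64,
        ]
        for name, g in self.group_fractions.items():
            lines.append(
                f"  {name:24s} {g['k']:4d}/{g['n']:<4d} = {g['k'] / g['n']:.3f}"
            )
        if self.comparisons:
            lines += ["", "Chi-square comparisons vs eligible non-injured rays", "-" * 64]
            for c in self.comparisons:
                if c.get("p_value") is None:
                    lines.append(f"  {c['group']:24s} degenerate table, no test")
                else:
                    lines.append(
                        f"  {c['group']:24s} chi2 = {c['statistic']:8.3f}  "
                        f"df = {c['df']}  p = {c['p_value']:.3g}"
                    )
        lines += [
            "",
            self.mc.summary(),
            f"  closed-form null mean     : {self.expected_isolated_null:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BystanderRegenerationResults p={self.p_value:.4g} "
            f"bystander={self.bystander_fraction:.3f} n={self.n_eligible}>"
        )


def input_digest(path: str | Path) -> str:
    """SHA-256 hex digest of an input file, for run provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
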