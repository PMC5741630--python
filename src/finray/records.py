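"""Ray-level data model and tabular I/O for fin regeneration score tables.

A scored experiment is a collection of fins; each fin is an ordered series
of rays (lepidotrichia), the anatomical unit of scoring.  Adjacency — the
substrate of every bystander statistic in this package — is defined only
between consecutive ray positions within the same fin, never across fins
or fish.

Tables are UTF-8 TSV (default) or CSV with a header row naming at least
the core columns below.  Booleans are serialized as ``0``/``1`` and the
injury class as one of the lower-case category names, which keeps tables
locale-proof.  Unknown extra columns survive a read/write round trip but
are ignored by the analysis code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "INJURY_CATEGORIES",
    "CORE_COLUMNS",
    "RayRecord",
    "FinSeries",
    "Dataset",
    "RayTableError",
    "ValidationError",
    "UnknownFieldError",
    "read_ray_table",
    "write_ray_table",
    "ray_outcome",
]

#: Injury classes a ray can carry. ``none`` marks a non-injured ray;
#: the other three are the experimental re-injury regimes.
INJURY_CATEGORIES = ("none", "re_amputation", "epidermal_wound", "skin_wound")

#: Canonical column order for serialized tables.
CORE_COLUMNS = (
    "fish_id",
    "fin_id",
    "ray_index",
    "injury",
    "escaper",
    "inadvertent_injury",
    "regen_3dpi",
    "regen_7dpi",
)

_BOOL_FIELDS = ("escaper", "inadvertent_injury", "regen_3dpi", "regen_7dpi")


class ValidationError(ValueError):
    """A record, fin or dataset violates a structural invariant."""


class RayTableError(ValueError):
    """A tabular file could not be parsed into a valid dataset."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class UnknownFieldError(KeyError):
    """A named outcome field exists neither as a core column nor an extra."""


@dataclass
class RayRecord:
    """One scored fin ray.

    ``escaper`` marks an uninjured ray that resumed growth despite the
    regeneration blockade; by definition an escaper has ``injury == "none"``.
    ``inadvertent_injury`` flags rays whose epidermis or bone was damaged
    accidentally during handling.  ``regen_3dpi``/``regen_7dpi`` are the
    regeneration calls at 3 and 7 days post-injury.
    """

    fish_id: str
    fin_id: str
    ray_index: int
    injury: str = "none"
    escaper: bool = False
    inadvertent_injury: bool = False
    regen_3dpi: bool = False
    regen_7dpi: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injury not in INJURY_CATEGORIES:
            raise ValidationError(
                f"unknown injury category {self.injury!r}; "
                f"expected one of {INJURY_CATEGORIES}"
            )
        if not isinstance(self.ray_index, int) or self.ray_index < 1:
            raise ValidationError(
                f"ray_index must be a positive integer, got {self.ray_index!r}"
            )
        if self.escaper and self.injury != "none":
            raise ValidationError(
                f"ray ({self.fish_id}, {self.fin_id}, {self.ray_index}): "
                "an escaper must be a non-injured ray"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.fish_id, self.fin_id, self.ray_index)


def ray_outcome(record: RayRecord, field_name: str) -> bool:
    """Boolean value of a named field on a record (core bool or extra column)."""
    if field_name in _BOOL_FIELDS:
        return bool(getattr(record, field_name))
    if field_name in record.extras:
        return _parse_bool(str(record.extras[field_name]))
    raise UnknownFieldError(field_name)


@dataclass
class FinSeries:
    """The ordered rays of one fin of one fish — the unit of adjacency.

    Rays are kept sorted by ``ray_index``, which must run 1..K with no
    gaps; a gap would make "directly adjacent" ambiguous.
    """

    fish_id: str
    fin_id: str
    rays: list[RayRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rays = sorted(self.rays, key=lambda r: r.ray_index)
        indices = [r.ray_index for r in self.rays]
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError(
                f"fin ({self.fish_id}, {self.fin_id}): ray_index values "
                f"{indices} are not contiguous 1..{len(indices)}"
            )
        for r in self.rays:
            if (r.fish_id, r.fin_id) != (self.fish_id, self.fin_id):
                raise ValidationError(
                    f"fin ({self.fish_id}, {self.fin_id}) contains a ray "
                    f"keyed {r.key}"
                )

    def __len__(self) -> int:
        return len(self.rays)

    def neighbors(self, i: int) -> list[RayRecord]:
        """Existing immediate neighbors of the ray at list position *i*."""
        out = []
        if i > 0:
            out.append(self.rays[i - 1])
        if i < len(self.rays) - 1:
            out.append(self.rays[i + 1])
        return out


@dataclass
class Dataset:
    """A collection of fins plus a free-text experiment label."""

    fins: list[FinSeries] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for fin in self.fins:
            k = (fin.fish_id, fin.fin_id)
            if k in seen:
                raise ValidationError(f"duplicate fin {k}")
            seen.add(k)

    def iter_rays(self) -> Iterator[RayRecord]:
        for fin in self.fins:
            yield from fin.rays

    @property
    def n_rays(self) -> int:
        return sum(len(f) for f in self.fins)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to one row per ray (core columns first, extras after)."""
        rows = []
        for r in self.iter_rays():
            d = {c: getattr(r, c) for c in CORE_COLUMNS}
            d.update(r.extras)
            rows.append(d)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Dataset":
        """Build a validated dataset from a per-ray dataframe."""
        missing = set(CORE_COLUMNS) - set(df.columns)
        if missing:
            raise RayTableError(f"missing column(s): {sorted(missing)}")
        extra_cols = [c for c in df.columns if c not in CORE_COLUMNS]
        groups: dict[tuple[str, str], list[RayRecord]] = {}
        for _, row in df.iterrows():
            rec = RayRecord(
                fish_id=str(row["fish_id"]),
                fin_id=str(row["fin_id"]),
                ray_index=int(row["ray_index"]),
                injury=str(row["injury"]),
                escaper=_coerce_bool(row["escaper"]),
                inadvertent_injury=_coerce_bool(row["inadvertent_injury"]),
                regen_3dpi=_coerce_bool(row["regen_3dpi"]),
                regen_7dpi=_coerce_bool(row["regen_7dpi"]),
                extras={c: row[c] for c in extra_cols},
            )
            groups.setdefault((rec.fish_id, rec.fin_id), []).append(rec)
        fins = [FinSeries(f, n, rays) for (f, n), rays in groups.items()]
        return cls(fins=fins, label=label)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("1", "true"):
        return True
    if t in ("0", "false"):
        return False
    raise ValueError(f"cannot parse boolean value {text!r}")


def _coerce_bool(value) -> bool:
    if isinstance(value, (bool,)) or str(type(value)).startswith("<class 'numpy.bool"):
        return bool(value)
    if isinstance(value, (int,)) and value in (0, 1):
        return bool(value)
    return _parse_bool(str(value))


def _delimiter(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")


def read_ray_table(path: str | Path, dialect: str = "tsv") -> Dataset:
    """Read and validate a ray-score table.

    Rows belonging to the same ``(fish_id, fin_id)`` are collected into a
    :class:`FinSeries` and normalized by ``ray_index``; parse problems are
    reported with the 1-based file row number.
    """
    path = Path(path)
    delim = _delimiter(dialect)
    groups: dict[tuple[str, str], list[RayRecord]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise RayTableError("empty file: no header row")
        missing = set(CORE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise RayTableError(f"missing column(s): {sorted(missing)}")
        extra_cols = [c for c in reader.fieldnames if c not in CORE_COLUMNS]
        for rownum, row in enumerate(reader, start=2):
            try:
                rec = RayRecord(
                    fish_id=row["fish_id"],
                    fin_id=row["fin_id"],
                    ray_index=int(row["ray_index"]),
                    injury=row["injury"],
                    escaper=_parse_bool(row["escaper"]),
                    inadvertent_injury=_parse_bool(row["inadvertent_injury"]),
                    regen_3dpi=_parse_bool(row["regen_3dpi"]),
                    regen_7dpi=_parse_bool(row["regen_7dpi"]),
                    extras={c: row[c] for c in extra_cols},
                )
            except (ValueError, ValidationError, TypeError) as exc:
                raise RayTableError(str(exc), row=rownum) from exc
            groups.setdefault((rec.fish_id, rec.fin_id), []).append(rec)
    fins = []
    for (fish, fin), rays in groups.items():
        try:
            fins.append(FinSeries(fish, fin, rays))
        except ValidationError as exc:
            raise RayTableError(str(exc)) from exc
    return Dataset(fins=fins, label=path.stem)


def write_ray_table(dataset: Dataset, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a dataset under a fixed field order; deterministic byte-for-byte.

    Extra columns are the sorted union over all rays; rays missing an extra
    get an empty cell (and round-trip back as the empty string).
    """
    path = Path(path)
    delim = _delimiter(dialect)
    extra_cols = sorted({k for r in dataset.iter_rays() for k in r.extras})
    columns = list(CORE_COLUMNS) + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(columns)
        for fin in dataset.fins:
            for r in fin.rays:
                cells = [
                    r.fish_id,
                    r.fin_id,
                    str(r.ray_index),
                    r.injury,
                ] + ["1" if getattr(r, b) else "0" for b in _BOOL_FIELDS]
                cells += [str(r.extras.get(c, "")) for c in extra_cols]
                writer.writerow(cells)
    return path


def copy_with(record: RayRecord, **changes) -> RayRecord:
    """Validated functional update of a record (extras copied, not shared)."""
    if "extras" not in changes:
        changes["extras"] = dict(record.extras)
    return replace(record, **changes)
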