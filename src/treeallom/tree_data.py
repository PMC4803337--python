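"""Domain types and data handling for destructively sampled trees.

A sampled tree carries three predictors — diameter at breast height ``D``
(cm), total height ``H`` (m) and crown radius ``CR`` (m) — and the oven-dry
biomass (kg) of four components: trunk, branch, leaf and root.  Total
biomass is always the derived sum of the four components, never an input
column.  Trees belong to one of three stand-development classes: young
(age <= 5 yr), middle-aged (<= 15 yr) and mature (> 15 yr).

Root biomass by field convention excludes fine roots below 2 mm diameter;
this is a data definition, not something the code enforces.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Component",
    "BIOMASS_COMPONENTS",
    "TreeRecord",
    "FieldSegment",
    "FieldSample",
    "GroupSummary",
    "ValidationError",
    "assign_age_group",
    "compute_dry_weight",
    "total_biomass",
    "allocation_proportions",
    "crown_radius_from_widths",
    "read_trees",
    "write_trees",
    "summarize_group",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class AgeGroup(enum.IntEnum):
    """Stand-development class; ordered young < middle < mature."""

    YOUNG = 0
    MIDDLE = 1
    MATURE = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "AgeGroup":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown age-group label {label!r}; expected one of "
                f"{[g.label for g in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class Component(enum.Enum):
    """Biomass component; TOTAL is derived, never stored as an input."""

    TRUNK = "trunk"
    BRANCH = "branch"
    LEAF = "leaf"
    ROOT = "root"
    TOTAL = "total"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "Component":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown component {label!r}") from None


#: The four measured components, in canonical order.
BIOMASS_COMPONENTS: tuple[Component, ...] = (
    Component.TRUNK,
    Component.BRANCH,
    Component.LEAF,
    Component.ROOT,
)


def assign_age_group(age_years: float, *, strict: bool = False) -> AgeGroup:
    """Map an age in years to its stand-development class.

    The class definitions are age <= 5 -> young, 6 < age <= 15 -> middle,
    age > 15 -> mature, which leave (5, 6] formally unassigned; by default
    that interval is folded into the middle class (extending its upper
    interval downward) so every positive age classifies.  ``strict=True``
    restores the literal intervals and rejects ages in (5, 6).
    """
    if not math.isfinite(age_years) or age_years <= 0:
        raise ValidationError(f"age must be a positive number, got {age_years!r}")
    if age_years <= 5:
        return AgeGroup.YOUNG
    if strict and age_years < 6:
        raise ValidationError(
            f"age {age_years} falls in the unassigned interval (5, 6) "
            "under strict class definitions"
        )
    if age_years <= 15:
        return AgeGroup.MIDDLE
    return AgeGroup.MATURE


def crown_radius_from_widths(width1_m: float, width2_m: float) -> float:
    """Crown radius from two perpendicular crown-width measurements.

    Field protocol measures the crown width in two directions at right
    angles and averages them; the radius is half that mean width.  This
    conversion is opt-in: when a data file already carries a crown radius
    column it is taken verbatim.
    """
    if width1_m <= 0 or width2_m <= 0:
        raise ValidationError("crown widths must be positive")
    return 0.5 * (width1_m + width2_m) / 2.0


@dataclass(frozen=True)
class TreeRecord:
    """One destructively sampled tree.

    Predictors must be strictly positive and every component biomass must
    be strictly positive so that log transforms are defined.  If both
    ``age_years`` and ``group`` are supplied they must agree; if only the
    age is supplied the group is derived from it.
    """

    tree_id: str
    D: float
    H: float
    CR: float
    w_trunk: float
    w_branch: float
    w_leaf: float
    w_root: float
    age_years: float | None = None
    group: AgeGroup | None = None

    def __post_init__(self) -> None:
        for name in ("D", "H", "CR"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")
        for name in ("w_trunk", "w_branch", "w_leaf", "w_root"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{name} must be strictly positive (log-transform must be "
                    f"defined), got {v!r}"
                )
        if self.age_years is None and self.group is None:
            raise ValidationError("one of age_years or group is required")
        if self.age_years is not None:
            derived = assign_age_group(self.age_years)
            if self.group is None:
                object.__setattr__(self, "group", derived)
            elif self.group is not derived:
                raise ValidationError(
                    f"group {self.group.label!r} inconsistent with age "
                    f"{self.age_years} (implies {derived.label!r})"
                )

    def biomass(self, component: Component) -> float:
        if component is Component.TOTAL:
            return total_biomass(self)
        return getattr(self, f"w_{component.value}")

    @property
    def total(self) -> float:
        return total_biomass(self)


def total_biomass(record: TreeRecord) -> float:
    """Total dry biomass: the exact sum of the four component biomasses."""
    return record.w_trunk + record.w_branch + record.w_leaf + record.w_root


def allocation_proportions(record: TreeRecord) -> dict[Component, float]:
    """Per-component share of total biomass; shares sum to 1 exactly."""
    tot = total_biomass(record)
    return {c: record.biomass(c) / tot for c in BIOMASS_COMPONENTS}


@dataclass(frozen=True)
class FieldSegment:
    """One weighed segment of a component with its fresh/dry subsamples."""

    fresh_weight_kg: float
    subsample_pairs: tuple[tuple[float, float], ...]  # (fresh g, dry g)

    def __post_init__(self) -> None:
        if self.fresh_weight_kg <= 0:
            raise ValidationError("segment fresh weight must be positive")
        if len(self.subsample_pairs) == 0:
            raise ValidationError("segment has no subsample pairs")
        for fresh, dry in self.subsample_pairs:
            if fresh <= 0 or dry <= 0:
                raise ValidationError("subsample weights must be positive")
            if dry > fresh:
                raise ValidationError(
                    f"subsample dry weight {dry} exceeds fresh weight {fresh}"
                )

    @property
    def mean_dry_ratio(self) -> float:
        return float(np.mean([d / f for f, d in self.subsample_pairs]))


@dataclass(frozen=True)
class FieldSample:
    """Fresh-weight field measurements for one component of one tree."""

    component: Component
    segments: tuple[FieldSegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValidationError("field sample has no segments")
        if self.component is Component.TRUNK:
            typical = len(self.segments) == 3 and all(
                len(s.subsample_pairs) == 3 for s in self.segments
            )
            if not typical:
                warnings.warn(
                    "trunk samples typically use 3 segments with 3 subsample "
                    "pairs each",
                    stacklevel=2,
                )


def compute_dry_weight(sample: FieldSample) -> float:
    """Component dry weight from fresh weights and subsample dry ratios.

    Each segment's fresh weight is scaled by the mean dry/fresh ratio of
    its subsamples; segment contributions are summed.
    """
    return sum(
        seg.fresh_weight_kg * seg.mean_dry_ratio for seg in sample.segments
    )


# ---------------------------------------------------------------------------
# CSV input/output

#: Default CSV column names (long self-describing names with units).
DEFAULT_COLUMNS: dict[str, str] = {
    "tree_id": "tree_id",
    "age_years": "age_years",
    "group": "group",
    "D": "dbh_cm",
    "H": "height_m",
    "CR": "crown_radius_m",
    "w_trunk": "w_trunk_kg",
    "w_branch": "w_branch_kg",
    "w_leaf": "w_leaf_kg",
    "w_root": "w_root_kg",
}

_REQUIRED_FIELDS = ("D", "H", "CR", "w_trunk", "w_branch", "w_leaf", "w_root")


def read_trees(
    path, column_map: Mapping[str, str] | None = None
) -> list[TreeRecord]:
    """Read and validate tree records from a CSV file.

    ``column_map`` maps field names (keys of :data:`DEFAULT_COLUMNS`) to the
    header names actually used in the file.  At least one of the age and
    group columns must be present.  Any row violating a record invariant is
    reported with its (zero-based) data row index; a file with bad rows is
    rejected as a whole.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [cols[f] for f in ("tree_id", *_REQUIRED_FIELDS) if cols[f] not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    has_age = cols["age_years"] in df.columns
    has_group = cols["group"] in df.columns
    if not (has_age or has_group):
        raise ValidationError(
            f"need at least one of columns {cols['age_years']!r} / {cols['group']!r}"
        )

    records: list[TreeRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            kwargs = {"tree_id": str(row[cols["tree_id"]])}
            for f in _REQUIRED_FIELDS:
                raw = row[cols[f]]
                val = float(raw)
                if math.isnan(val):
                    raise ValidationError(f"{cols[f]} is not numeric: {raw!r}")
                kwargs[f] = val
            if has_age and not pd.isna(row[cols["age_years"]]):
                kwargs["age_years"] = float(row[cols["age_years"]])
            if has_group and not pd.isna(row[cols["group"]]):
                kwargs["group"] = AgeGroup.from_label(row[cols["group"]])
            records.append(TreeRecord(**kwargs))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(
            "invalid rows in " + str(path) + ":\n  " + "\n  ".join(errors)
        )
    return records


def write_trees(records: Sequence[TreeRecord], path) -> None:
    """Write records to CSV using the default column names (UTF-8, '.')."""
    rows = []
    for r in records:
        rows.append(
            {
                DEFAULT_COLUMNS["tree_id"]: r.tree_id,
                DEFAULT_COLUMNS["age_years"]: r.age_years,
                DEFAULT_COLUMNS["group"]: r.group.label,
                DEFAULT_COLUMNS["D"]: r.D,
                DEFAULT_COLUMNS["H"]: r.H,
                DEFAULT_COLUMNS["CR"]: r.CR,
                DEFAULT_COLUMNS["w_trunk"]: r.w_trunk,
                DEFAULT_COLUMNS["w_branch"]: r.w_branch,
                DEFAULT_COLUMNS["w_leaf"]: r.w_leaf,
                DEFAULT_COLUMNS["w_root"]: r.w_root,
            }
        )
    # repr-precision floats so read_trees round-trips values bit-identically
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8",
                              float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Group summaries

_SUMMARY_VARS = ("D", "H", "CR", "w_trunk", "w_branch", "w_leaf", "w_root")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SD/max/min of predictors and component biomasses.

    SDs use the n-1 (sample) divisor.
    """

    group: AgeGroup
    n: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T[["mean", "sd", "max", "min"]]


def summarize_group(
    records: Iterable[TreeRecord], group: AgeGroup
) -> GroupSummary:
    """Summary statistics of one age group (requires >= 2 trees)."""
    rows = [r for r in records if r.group is group]
    if len(rows) < 2:
        raise ValidationError(
            f"group {group.label!r} has {len(rows)} record(s); "
            "need at least 2 for a sample SD"
        )
    stats: dict[str, dict[str, float]] = {}
    for var in _SUMMARY_VARS:
        x = np.array([getattr(r, var) for r in rows], dtype=float)
        stats[var] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "max": float(x.max()),
            "min": float(x.min()),
        }
    return GroupSummary(group=group, n=len(rows), stats=stats)
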