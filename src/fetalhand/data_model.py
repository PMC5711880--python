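"""Core domain types, CSV readers/writers, packaged count fixture, summaries.

The canonical unit for movement time (MT) is the millisecond; time to peak
velocity (TPV) is a percentage of MT in the open interval (0, 100).  CSV
inputs may declare MT in seconds through the ``mt_s`` column name and are
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from fetalhand.errors import FormatError, ValidationError

GESTATIONAL_WEEKS = (14, 18, 22)
TARGETS = ("eye", "mouth", "wall")
HANDS = ("right", "left")
GROUPS = ("right", "left")

#: Number of hand x target x week conditions.
N_CONDITIONS = len(HANDS) * len(TARGETS) * len(GESTATIONAL_WEEKS)

#: Cohort roster sizes that accompany the packaged count fixture.
FIXTURE_GROUP_SIZES = {"right": 25, "left": 4}


class Handedness:
    """String constants for postnatal handedness (parent-assigned at age 9)."""

    RIGHT = "right"
    LEFT = "left"


class Target:
    """String constants for movement endpoints."""

    EYE = "eye"
    MOUTH = "mouth"
    WALL = "wall"


@dataclass(frozen=True)
class FetusInfo:
    """One fetus with its postnatal handedness label."""

    fetus_id: str
    handedness: str

    def __post_init__(self):
        if self.handedness not in GROUPS:
            raise ValidationError(f"invalid handedness {self.handedness!r}")


@dataclass(frozen=True)
class MovementRecord:
    """One observed arm movement with its kinematic metrics and labels.

    Attributes
    ----------
    fetus_id : str
        Identifier resolving to a :class:`FetusInfo` in the cohort roster.
    gw : int
        Gestational week; one of 14, 18, 22.
    target : str
        Movement endpoint; one of ``eye``, ``mouth``, ``wall``.
    hand : str
        Moving hand; ``right`` or ``left``.
    mt : float
        Movement time in milliseconds, strictly positive.
    tpv : float
        Time to peak velocity as a percentage of MT, in (0, 100).
    """

    fetus_id: str
    gw: int
    target: str
    hand: str
    mt: float
    tpv: float

    def __post_init__(self):
        problems = record_problems(self.gw, self.target, self.hand, self.mt, self.tpv)
        if problems:
            raise ValidationError(f"invalid record for {self.fetus_id!r}: " + "; ".join(problems))


def record_problems(gw, target, hand, mt, tpv) -> list[str]:
    """Return human-readable invariant violations for one record's fields."""
    problems = []
    if gw not in GESTATIONAL_WEEKS:
        problems.append(f"gw={gw!r} not in {GESTATIONAL_WEEKS}")
    if target not in TARGETS:
        problems.append(f"target={target!r} not in {TARGETS}")
    if hand not in HANDS:
        problems.append(f"hand={hand!r} not in {HANDS}")
    if not (mt > 0):
        problems.append(f"mt={mt!r} must be > 0")
    if not (0 < tpv < 100):
        problems.append(f"tpv={tpv!r} must be in (0, 100)")
    return problems


@dataclass
class Cohort:
    """Roster of fetuses plus all their movement records."""

    fetuses: list[FetusInfo]
    records: list[MovementRecord]

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.fetuses:
            raise ValidationError("empty cohort: at least one fetus is required")
        ids = [f.fetus_id for f in self.fetuses]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate fetus_id in roster")
        known = set(ids)
        orphans = sorted({r.fetus_id for r in self.records} - known)
        if orphans:
            raise ValidationError(f"records reference unknown fetus_id(s): {orphans}")

    @property
    def handedness_map(self) -> dict[str, str]:
        return {f.fetus_id: f.handedness for f in self.fetuses}

    def group_ids(self, handedness: str) -> list[str]:
        return [f.fetus_id for f in self.fetuses if f.handedness == handedness]

    def to_frame(self) -> pd.DataFrame:
        """Records as a tidy DataFrame with the roster handedness joined in."""
        hmap = self.handedness_map
        return pd.DataFrame(
            {
                "fetus_id": [r.fetus_id for r in self.records],
                "handedness": [hmap[r.fetus_id] for r in self.records],
                "gw": [r.gw for r in self.records],
                "target": [r.target for r in self.records],
                "hand": [r.hand for r in self.records],
                "mt": [r.mt for r in self.records],
                "tpv": [r.tpv for r in self.records],
            }
        )


@dataclass
class CountsTable:
    """Movement counts per (handedness group x gestational week x hand).

    ``counts[(group, gw, hand)]`` is a non-negative integer; column totals
    (per group and week, summed over hands) are exposed via
    :meth:`column_total`.
    """

    counts: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def cell(self, group: str, gw: int, hand: str) -> int:
        return int(self.counts.get((group, gw, hand), 0))

    def column_total(self, group: str, gw: int) -> int:
        return sum(self.cell(group, gw, h) for h in HANDS)

    def group_total(self, group: str) -> int:
        return sum(self.column_total(group, gw) for gw in GESTATIONAL_WEEKS)

    def grand_total(self) -> int:
        return sum(self.group_total(g) for g in GROUPS)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "gw": gw, "hand": h, "count": self.cell(g, gw, h)}
            for g in GROUPS
            for gw in GESTATIONAL_WEEKS
            for h in HANDS
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_COLUMNS = ("fetus_id", "handedness", "gw", "target", "hand", "tpv_pct")


def read_cohort(path) -> Cohort:
    """Read a movement CSV into a validated :class:`Cohort`.

    Expected columns: ``fetus_id, handedness, gw, target, hand, mt_ms, tpv_pct``.
    A ``mt_s`` column may be used instead of ``mt_ms``; values are then
    converted from seconds to milliseconds on read.

    Raises
    ------
    FormatError
        Missing columns or an empty file.
    ValidationError
        Rows violating the record invariants, with 0-based row indices.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if "mt_ms" in df.columns:
        mt = df["mt_ms"].astype(float)
    elif "mt_s" in df.columns:
        mt = df["mt_s"].astype(float) * 1000.0
    else:
        missing.append("mt_ms (or mt_s)")
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty cohort (no data rows)")

    bad_rows: list[int] = []
    messages: list[str] = []
    records: list[MovementRecord] = []
    roster: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        fid = str(row.fetus_id)
        handed = str(row.handedness)
        problems = record_problems(
            int(row.gw), str(row.target), str(row.hand), float(mt.iloc[i]), float(row.tpv_pct)
        )
        if handed not in GROUPS:
            problems.append(f"handedness={handed!r} not in {GROUPS}")
        elif roster.get(fid, handed) != handed:
            problems.append(f"fetus {fid!r} has conflicting handedness labels")
        if problems:
            bad_rows.append(i)
            messages.append(f"row {i}: " + "; ".join(problems))
            continue
        roster.setdefault(fid, handed)
        records.append(
            MovementRecord(fid, int(row.gw), str(row.target), str(row.hand),
                           float(mt.iloc[i]), float(row.tpv_pct))
        )
    if bad_rows:
        raise ValidationError("invalid rows:\n" + "\n".join(messages), rows=bad_rows)

    fetuses = [FetusInfo(fid, handed) for fid, handed in roster.items()]
    return Cohort(fetuses=fetuses, records=records)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV such that :func:`read_cohort` round-trips it exactly.

    Fetuses without records cannot be represented in the one-movement-per-row
    format and raise :class:`ValidationError` (lossless round-trip contract).
    """
    cohort.validate()
    with_records = {r.fetus_id for r in cohort.records}
    silent = [f.fetus_id for f in cohort.fetuses if f.fetus_id not in with_records]
    if silent:
        raise ValidationError(
            f"cohort has fetuses without records, not representable in CSV: {silent}"
        )
    df = cohort.to_frame().rename(columns={"mt": "mt_ms", "tpv": "tpv_pct"})
    # %.17g round-trips every float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def table2_fixture() -> CountsTable:
    """The packaged per-(group x week x hand) movement-count fixture."""
    src = resources.files("fetalhand").joinpath("data/table2_counts.csv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p)
    counts = {
        (str(r.group), int(r.gw), str(r.hand)): int(r.count)
        for r in df.itertuples(index=False)
    }
    return CountsTable(counts=counts)


# ---------------------------------------------------------------------------
# Summaries


def counts_table(cohort: Cohort) -> CountsTable:
    """Tally movements per (handedness group x gestational week x hand)."""
    hmap = cohort.handedness_map
    counts: dict[tuple[str, int, str], int] = {}
    for r in cohort.records:
        key = (hmap[r.fetus_id], r.gw, r.hand)
        counts[key] = counts.get(key, 0) + 1
    return CountsTable(counts=counts)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group movement-count means derived from a :class:`CountsTable`."""

    n_right: int
    n_left: int
    total: dict[str, int]
    mean_per_condition: dict[str, float]
    mean_per_fetus: dict[str, float]
    pct_right: float


def group_movement_summary(counts: CountsTable, n_right: int, n_left: int) -> GroupSummary:
    """Group totals, per-condition means (total / 18) and per-fetus means.

    ``n_right`` / ``n_left`` are the roster sizes of the two handedness
    groups (they are not recoverable from the counts alone).
    """
    if n_right <= 0 or n_left <= 0:
        raise ValidationError("group sizes must be positive")
    sizes = {"right": n_right, "left": n_left}
    total = {g: counts.group_total(g) for g in GROUPS}
    return GroupSummary(
        n_right=n_right,
        n_left=n_left,
        total=total,
        mean_per_condition={g: total[g] / N_CONDITIONS for g in GROUPS},
        mean_per_fetus={g: total[g] / sizes[g] for g in GROUPS},
        pct_right=100.0 * n_right / (n_right + n_left),
    )


def iter_conditions(with_hand: bool = True) -> Iterable[tuple]:
    """Yield (gw, target[, hand]) condition keys in canonical order."""
    for gw in GESTATIONAL_WEEKS:
        for target in TARGETS:
            if with_hand:
                for hand in HANDS:
                    yield gw, target, hand
            else:
                yield gw, target
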