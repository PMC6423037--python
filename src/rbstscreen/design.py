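"""Longitudinal study design: dose schedule, sampling days, cycles, plates.

The experiment this package targets follows a small dairy herd (3 control
and 6 treated cows) over eight months.  Treated animals receive repeated
subcutaneous doses of recombinant bovine somatotropin (rbST) on a 14-day
cycle, with one deliberate 28-day gap inserted mid-study to probe washout.
Milk yield is recorded daily; milk somatic cells are sampled on a fixed set
of study days for transcriptomic profiling.  Study day 0 is the day of the
first dose; the conditioning (pre-dose) period carries negative days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "StudyDesign",
    "DoseSchedule",
    "PlateLayout",
    "PlateReport",
    "DEFAULT_SAMPLING_DAYS",
    "build_dose_schedule",
    "days_since_last_dose",
    "recording_span",
    "assign_cycle",
    "validate_plate",
]

#: Default milk-sampling days (36 study days, day 0 = first dose).
#: Three conditioning-period days, dense coverage of the first two dose
#: cycles where transcriptional responses are sharpest, then roughly
#: weekly-to-biweekly sampling through treatment and follow-up.
DEFAULT_SAMPLING_DAYS: tuple[int, ...] = (
    -18, -11, -4,
    1, 2, 3, 4, 7, 9, 11, 14,
    15, 16, 18, 21, 23, 25, 28,
    35, 42, 49, 56, 63, 70, 77, 84, 91, 98,
    112, 126, 140, 154, 168, 182, 196, 219,
)


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the longitudinal dosing/sampling experiment.

    Defaults reproduce the reference design: 12 doses of 500 mg rbST at
    14-day intervals with a 28-day gap between doses 5 and 6, an 18-day
    conditioning period and 54 days of post-treatment follow-up, for a
    240-day daily milk-recording window.
    """

    n_control: int = 3
    n_treated: int = 6
    first_dose_day: int = 0
    dose_interval_days: int = 14
    gap_after_dose: int | None = 5
    gap_days: int = 28
    n_doses: int = 12
    conditioning_days: int = 18
    followup_days: int = 54
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    dose_amount_mg: float = 500.0
    #: Optional explicit cycle edges (list of last-day-of-cycle study days);
    #: when None, uniform ``dose_interval_days`` bins are used.
    cycle_edges: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.dose_interval_days < 1:
            raise ValueError("dose_interval_days must be >= 1")
        if self.gap_after_dose is not None and self.gap_days < self.dose_interval_days:
            raise ValueError("gap_days must be >= dose_interval_days")
        days = tuple(self.sampling_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        object.__setattr__(self, "sampling_days", days)

    @property
    def n_animals(self) -> int:
        return self.n_control + self.n_treated

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["sampling_days"] = list(self.sampling_days)
        if self.cycle_edges is not None:
            d["cycle_edges"] = list(self.cycle_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        if "sampling_days" in d:
            d["sampling_days"] = tuple(d["sampling_days"])
        if d.get("cycle_edges") is not None:
            d["cycle_edges"] = tuple(d["cycle_edges"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyDesign":
        """Load a design from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered study days on which doses are administered."""

    dose_days: tuple[int, ...]

    def __post_init__(self) -> None:
        days = tuple(self.dose_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose_days must be strictly increasing")
        object.__setattr__(self, "dose_days", days)

    def __len__(self) -> int:
        return len(self.dose_days)

    def to_csv(self, path: str | Path) -> None:
        lines = ["dose_index,day"]
        lines += [f"{i + 1},{d}" for i, d in enumerate(self.dose_days)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class PlateLayout:
    """A high-throughput qPCR plate layout (assays x replicates x samples)."""

    n_assays: int = 18
    n_replicates: int = 3
    n_samples: int = 56
    capacity: int = 3072

    def __post_init__(self) -> None:
        for name in ("n_assays", "n_replicates", "n_samples", "capacity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class PlateReport:
    valid: bool
    total_reactions: int
    capacity: int

    @property
    def message(self) -> str:
        rel = "<=" if self.valid else ">"
        return f"{self.total_reactions} reactions {rel} capacity {self.capacity}"


def build_dose_schedule(design: StudyDesign) -> DoseSchedule:
    """Enumerate dose days from the design's interval/gap structure.

    Dose ``k`` (1-based) falls ``(k-1)`` intervals after the first dose,
    except that the interval following dose ``gap_after_dose`` is replaced
    by ``gap_days``.
    """
    days = []
    day = design.first_dose_day
    for k in range(1, design.n_doses + 1):
        days.append(day)
        if design.gap_after_dose is not None and k == design.gap_after_dose:
            day += design.gap_days
        else:
            day += design.dose_interval_days
    return DoseSchedule(tuple(days))


def days_since_last_dose(
    schedule: DoseSchedule, day: float, *, pre_administration: bool = False
) -> float | None:
    """Days elapsed since the most recent dose at ``day``.

    Returns ``None`` before the first dose.  On a dose day the default
    (post-administration) semantics return 0; with
    ``pre_administration=True`` the dose given that day is ignored, which
    is the right reading when a sample is drawn before the injection.
    """
    if pre_administration:
        past = [d for d in schedule.dose_days if d < day]
    else:
        past = [d for d in schedule.dose_days if d <= day]
    if not past:
        return None
    return day - past[-1]


def recording_span(design: StudyDesign, schedule: DoseSchedule) -> int:
    """Total daily-recording window in days: conditioning + treatment + follow-up."""
    return (
        design.conditioning_days
        + schedule.dose_days[-1]
        - design.first_dose_day
        + design.followup_days
    )


def _cycle_upper_edges(design: StudyDesign, schedule: DoseSchedule) -> list[int]:
    if design.cycle_edges is not None:
        return list(design.cycle_edges)
    last = recording_span(design, schedule) - design.conditioning_days
    w = design.dose_interval_days
    edges = [0]
    e = w
    while e < last + w:
        edges.append(e)
        e += w
    return edges


def assign_cycle(day: float, design: StudyDesign, schedule: DoseSchedule | None = None) -> int:
    """Map a study day to its dose cycle.

    Cycle 0 is the conditioning window (``-conditioning_days..0``); cycle
    ``n >= 1`` covers days ``w*(n-1)+1 .. w*n`` for interval width ``w``
    (uniform bins by default; ``design.cycle_edges`` overrides).
    """
    if schedule is None:
        schedule = build_dose_schedule(design)
    edges = _cycle_upper_edges(design, schedule)
    lo = -design.conditioning_days
    hi = edges[-1]
    if day < lo or day > hi:
        raise ValueError(f"day {day} outside recording window [{lo}, {hi}]")
    for i, e in enumerate(edges):
        if day <= e:
            return i
    return len(edges) - 1  # pragma: no cover


def validate_plate(layout: PlateLayout) -> PlateReport:
    """Check whether a plate layout fits in the plate's reaction capacity."""
    total = layout.n_assays * layout.n_replicates * layout.n_samples
    return PlateReport(valid=total <= layout.capacity, total_reactions=total,
                       capacity=layout.capacity)
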