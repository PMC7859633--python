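"""Pressure-mat footfall parsing and spatiotemporal gait parameters.

The data unit is a *run*: one pass of a pig over the pressure mat,
recorded as footfall events (hoof, contact time, lift time, forward
position, lateral position, relative pressure).  A run qualifies as
"good" with at least 12 footfalls in total and at least three complete
contact-to-contact cycles for every limb.

Per limb, a cycle is the interval between successive contacts of the same
hoof; stride length is the forward distance between those contacts;
stance is contact-to-lift, and the swing share of the stride is
``100 * (cycle - stance) / cycle``.  Run velocity is first-to-last
contact displacement over elapsed time (the mat records no continuous
trajectory), and cadence is 60 over the mean limb cycle time, i.e.
strides per minute.

Pre-stroke sessions are aggregated as the mean of day means over three
collection days; post-stroke performance is the mean over exactly five
good runs.  Post values are normalized per animal to its pre-stroke
value, ``100 * (post - pre) / pre``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HOOVES",
    "FootfallEvent",
    "GaitRun",
    "GaitParameters",
    "parse_footfalls",
    "runs_from_frame",
    "write_footfalls",
    "is_good_run",
    "run_parameters",
    "aggregate_parameters",
    "percent_change",
    "gait_changes",
]

HOOVES = ("LF", "RF", "LH", "RH")

CSV_COLUMNS = ["run_id", "hoof", "contact_time_s", "lift_time_s", "x_cm", "y_cm", "pressure_au"]

MIN_FOOTFALLS = 12
MIN_CYCLES = 3


@dataclass(frozen=True)
class FootfallEvent:
    run_id: str
    hoof: str
    contact_time: float  # s
    lift_time: float  # s
    x: float  # forward position, cm
    y: float  # lateral position, cm
    pressure: float  # arbitrary units


@dataclass
class GaitRun:
    run_id: str
    events: list[FootfallEvent]

    def by_hoof(self, hoof: str) -> list[FootfallEvent]:
        return [e for e in self.events if e.hoof == hoof]


@dataclass
class GaitParameters:
    """Whole-run and per-limb spatiotemporal parameters."""

    velocity: float  # cm/s
    cadence: float  # strides/min
    cycle_time: dict[str, float] = field(default_factory=dict)  # s per limb
    swing_percent: dict[str, float] = field(default_factory=dict)  # % of stride
    stride_length: dict[str, float] = field(default_factory=dict)  # cm per limb
    mean_pressure: dict[str, float] = field(default_factory=dict)  # a.u. per limb

    def as_flat(self) -> dict[str, float]:
        """Flatten to ``{parameter or parameter_LIMB: value}``."""
        flat = {"velocity": self.velocity, "cadence": self.cadence}
        for name, limbs in (
            ("cycle_time", self.cycle_time),
            ("swing_percent", self.swing_percent),
            ("stride_length", self.stride_length),
            ("mean_pressure", self.mean_pressure),
        ):
            for hoof in HOOVES:
                flat[f"{name}_{hoof}"] = limbs[hoof]
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, float]) -> "GaitParameters":
        return cls(
            velocity=flat["velocity"],
            cadence=flat["cadence"],
            cycle_time={h: flat[f"cycle_time_{h}"] for h in HOOVES},
            swing_percent={h: flat[f"swing_percent_{h}"] for h in HOOVES},
            stride_length={h: flat[f"stride_length_{h}"] for h in HOOVES},
            mean_pressure={h: flat[f"mean_pressure_{h}"] for h in HOOVES},
        )


def parse_footfalls(path: str | Path) -> list[GaitRun]:
    """Parse a footfall CSV into runs sorted by contact time.

    Required header: ``run_id,hoof,contact_time_s,lift_time_s,x_cm,y_cm,
    pressure_au``.  Malformed rows raise with their (1-based data) row
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such footfall file: {path}")
    return runs_from_frame(pd.read_csv(path), origin=str(path))


def runs_from_frame(df: pd.DataFrame, origin: str = "<frame>") -> list[GaitRun]:
    """Validate an in-memory footfall table and group it into runs."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"footfall table {origin} is missing column(s): {', '.join(missing)}")
    runs: dict[str, list[FootfallEvent]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        hoof = str(row.hoof)
        if hoof not in HOOVES:
            raise ValueError(f"row {i}: unknown hoof code {hoof!r} (expected one of {HOOVES})")
        contact, lift = float(row.contact_time_s), float(row.lift_time_s)
        if lift <= contact:
            raise ValueError(f"row {i}: lift_time {lift} not after contact_time {contact}")
        pressure = float(row.pressure_au)
        if pressure < 0:
            raise ValueError(f"row {i}: negative pressure {pressure}")
        runs.setdefault(str(row.run_id), []).append(
            FootfallEvent(
                run_id=str(row.run_id),
                hoof=hoof,
                contact_time=contact,
                lift_time=lift,
                x=float(row.x_cm),
                y=float(row.y_cm),
                pressure=pressure,
            )
        )
    return [
        GaitRun(run_id=rid, events=sorted(evts, key=lambda e: e.contact_time))
        for rid, evts in runs.items()
    ]


def write_footfalls(runs: list[GaitRun], path: str | Path) -> None:
    rows = [
        {
            "run_id": e.run_id,
            "hoof": e.hoof,
            "contact_time_s": e.contact_time,
            "lift_time_s": e.lift_time,
            "x_cm": e.x,
            "y_cm": e.y,
            "pressure_au": e.pressure,
        }
        for run in runs
        for e in run.events
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def is_good_run(run: GaitRun) -> tuple[bool, str]:
    """Apply the good-run rule; always returns a verdict with a reason."""
    if len(run.events) < MIN_FOOTFALLS:
        return False, (
            f"fewer than {MIN_FOOTFALLS} consecutive footfalls ({len(run.events)})"
        )
    for hoof in HOOVES:
        contacts = run.by_hoof(hoof)
        cycles = len(contacts) - 1
        if cycles < MIN_CYCLES:
            return False, (
                f"fewer than {MIN_CYCLES} complete gait cycles for {hoof} ({max(cycles, 0)})"
            )
    return True, "accepted"


def run_parameters(run: GaitRun) -> GaitParameters:
    """Extract spatiotemporal parameters from an accepted run.

    The forward axis is x; runs in either direction are normalized so the
    net displacement is positive.
    """
    if not run.events:
        raise ValueError("run has no events")
    events = sorted(run.events, key=lambda e: e.contact_time)
    sign = 1.0 if events[-1].x - events[0].x >= 0 else -1.0

    cycle_time: dict[str, float] = {}
    swing: dict[str, float] = {}
    stride: dict[str, float] = {}
    pressure: dict[str, float] = {}
    for hoof in HOOVES:
        contacts = run.by_hoof(hoof)
        if len(contacts) < 2:
            raise ValueError(f"fewer than 2 contacts for limb {hoof}")
        contacts = sorted(contacts, key=lambda e: e.contact_time)
        times = np.array([e.contact_time for e in contacts])
        xs = sign * np.array([e.x for e in contacts])
        ct = float(np.diff(times).mean())
        if ct <= 0:
            raise ValueError(f"non-positive cycle time for limb {hoof}")
        stance = float(np.mean([e.lift_time - e.contact_time for e in contacts]))
        cycle_time[hoof] = ct
        stride[hoof] = float(np.diff(xs).mean())
        swing[hoof] = 100.0 * (ct - stance) / ct
        pressure[hoof] = float(np.mean([e.pressure for e in contacts]))

    elapsed = events[-1].contact_time - events[0].contact_time
    if elapsed <= 0:
        raise ValueError("run has zero elapsed time between first and last contact")
    velocity = sign * (events[-1].x - events[0].x) / elapsed
    cadence = 60.0 / float(np.mean([cycle_time[h] for h in HOOVES]))
    return GaitParameters(
        velocity=velocity,
        cadence=cadence,
        cycle_time=cycle_time,
        swing_percent=swing,
        stride_length=stride,
        mean_pressure=pressure,
    )


def _mean_parameters(items: list[GaitParameters]) -> GaitParameters:
    flats = [p.as_flat() for p in items]
    return GaitParameters.from_flat(
        {k: float(np.mean([f[k] for f in flats])) for k in flats[0]}
    )


def aggregate_parameters(
    runs: list[tuple[object, GaitParameters]], phase: str
) -> GaitParameters:
    """Aggregate per-run parameters for a collection phase.

    ``runs`` pairs a day identifier with the run's parameters.  The
    pre-stroke aggregate is the mean of per-day means over three distinct
    collection days (equal day weights); the post-stroke aggregate is the
    mean over exactly five runs.
    """
    if phase == "pre":
        by_day: dict[object, list[GaitParameters]] = {}
        for day, params in runs:
            by_day.setdefault(day, []).append(params)
        if len(by_day) != 3:
            raise ValueError(
                f"pre-stroke aggregation needs runs on 3 distinct days, got {len(by_day)}"
            )
        day_means = [_mean_parameters(v) for _, v in sorted(by_day.items(), key=lambda kv: str(kv[0]))]
        return _mean_parameters(day_means)
    if phase == "post":
        if len(runs) != 5:
            raise ValueError(f"post-stroke aggregation needs exactly 5 runs, got {len(runs)}")
        return _mean_parameters([p for _, p in runs])
    raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")


def percent_change(post: float, pre: float) -> float:
    """Percent change of a post value relative to its pre value."""
    if pre == 0:
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


def gait_changes(post: GaitParameters, pre: GaitParameters) -> dict[str, float]:
    """Per-parameter (and per-limb) percent change, post relative to pre."""
    pre_flat, post_flat = pre.as_flat(), post.as_flat()
    return {k: percent_change(post_flat[k], pre_flat[k]) for k in pre_flat}
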