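"""Detection of complete transmembrane crossing events.

The counting region is a bounded cylinder: two z-planes (the boundary
glutamate rings at the ends of the transmembrane pore) and a radial gate.
Each ion is tracked through three zones — above the top ring, inside, below
the bottom ring. A top-to-bottom (TB) event is one continuous passage
top → inside → bottom without a radial escape while inside; bottom-to-top
(BT) is the mirror image. Only complete traversals count: an ion already
inside the region at the first frame contributes no event for that
residency, and a residency still open at the last frame is discarded.

Event start/end times are, by default, linearly interpolated between the
frames bracketing each ring crossing (switchable to frame-snapped times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import ChannelGeometry, IonTrace, TrajectoryBundle

__all__ = [
    "CrossingEvent",
    "EventLedger",
    "CoarseSamplingWarning",
    "detect_crossings",
    "waiting_times",
    "event_durations",
]

TB = +1  # top-to-bottom (extracellular -> intracellular)
BT = -1


class CoarseSamplingWarning(UserWarning):
    """An ion jumped across the whole region between consecutive frames."""


@dataclass
class CrossingEvent:
    """One complete traversal of the counting region."""

    ion_id: str
    species: str
    direction: int  # +1 TB, -1 BT
    t_start: float  # ns, entry-ring crossing
    t_end: float  # ns, exit-ring crossing
    pathway: str = "axial"  # entry-leg label; see pathways_profiles
    segment: str = "1"

    def __post_init__(self) -> None:
        if self.direction not in (TB, BT):
            raise ValueError("direction must be +1 (TB) or -1 (BT)")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventLedger:
    """Time-ordered crossing events for one analysed stretch of trajectory."""

    events: list[CrossingEvent]
    dt: float  # ns analysed per segment
    segment: str = "1"

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t_start)

    def __len__(self) -> int:
        return len(self.events)

    def counts(self) -> dict[tuple[str, int], int]:
        """Tally of events by (species, direction)."""
        out: dict[tuple[str, int], int] = {}
        for ev in self.events:
            key = (ev.species, ev.direction)
            out[key] = out.get(key, 0) + 1
        return out

    def count(self, species: str, direction: int) -> int:
        return self.counts().get((species, direction), 0)

    def select(self, species: str | None = None, direction: int | None = None):
        return [
            ev
            for ev in self.events
            if (species is None or ev.species == species)
            and (direction is None or ev.direction == direction)
        ]


def _interp_time(t0, t1, z0, z1, zc):
    return t0 + (zc - z0) / (z1 - z0) * (t1 - t0)


def _detect_one(
    trace: IonTrace,
    geometry: ChannelGeometry,
    interpolate: bool,
    segment: str,
) -> list[CrossingEvent]:
    z = trace.z
    t = trace.times
    n = len(t)
    if n < 2:
        return []
    if geometry.time_varying and geometry.z_top_series is not None:
        z_top = geometry.z_top_series
        z_bot = geometry.z_bottom_series
        if len(z_top) != n:
            raise ValueError("time-varying geometry series length does not match trace")
    else:
        z_top = np.full(n, geometry.z_top)
        z_bot = np.full(n, geometry.z_bottom)

    zone = np.zeros(n, dtype=np.int8)  # +1 above top, 0 inside, -1 below bottom
    zone[z > z_top] = 1
    zone[z < z_bot] = -1
    r_out = trace.radial_distance(geometry.center_xy) > geometry.cylinder_radius

    # indices where anything relevant changes
    change = np.flatnonzero(
        (zone[1:] != zone[:-1]) | ((zone[1:] == 0) & (r_out[1:] != r_out[:-1]))
    ) + 1

    events: list[CrossingEvent] = []
    # side: +1 = last outside the region on top, -1 = bottom, 0 = unknown
    # pending: (entry side, t_start) while the ion is inside
    if zone[0] == 0 and not r_out[0]:
        side, inside, pending = 0, True, None  # starts inside: residency void
    else:
        side = zone[0] if zone[0] != 0 else (1 if abs(z[0] - z_top[0]) < abs(z[0] - z_bot[0]) else -1)
        inside, pending = False, None

    for k in change:
        zk = zone[k]
        if inside:
            if zk == 0:
                if r_out[k]:  # radial escape: reset to the entry side
                    if pending is not None:
                        side = pending[0]
                    elif side == 0:
                        side = 1 if abs(z[k] - z_top[k]) < abs(z[k] - z_bot[k]) else -1
                    inside, pending = False, None
                continue
            # crossed a ring
            if pending is not None:
                entry_side, t_start = pending
                if zk == -entry_side:  # completed traversal
                    zc = z_bot[k] if zk == -1 else z_top[k]
                    t_end = (
                        _interp_time(t[k - 1], t[k], z[k - 1], z[k], zc)
                        if interpolate
                        else t[k]
                    )
                    events.append(
                        CrossingEvent(
                            ion_id=trace.ion_id,
                            species=trace.species,
                            direction=TB if entry_side == 1 else BT,
                            t_start=t_start,
                            t_end=max(t_end, np.nextafter(t_start, np.inf)),
                            segment=segment,
                        )
                    )
                # else: backed out through the entry ring — no event
            side = zk
            inside, pending = False, None
        else:
            if zk == 0:
                if r_out[k]:
                    continue  # skimming the corner outside the radial gate
                inside = True
                if side == 0:
                    pending = None  # unknown origin: residency cannot count
                elif zone[k - 1] == side and not (zone[k - 1] == 0):
                    zc = z_top[k] if side == 1 else z_bot[k]
                    t_start = (
                        _interp_time(t[k - 1], t[k], z[k - 1], z[k], zc)
                        if interpolate
                        else t[k]
                    )
                    pending = (side, t_start)
                else:
                    # re-entry through the side wall after a radial reset:
                    # treated as re-entering from the remembered side
                    pending = (side, t[k])
            elif zk == -side and side != 0 and zone[k - 1] == side:
                # jumped clean across the region in one frame step
                warnings.warn(
                    f"ion {trace.ion_id!r} skipped the counting region between "
                    f"frames {k - 1} and {k}; frame interval too coarse",
                    CoarseSamplingWarning,
                    stacklevel=2,
                )
                if interpolate:
                    zc_in = z_top[k] if side == 1 else z_bot[k]
                    zc_out = z_bot[k] if side == 1 else z_top[k]
                    t_start = _interp_time(t[k - 1], t[k], z[k - 1], z[k], zc_in)
                    t_end = _interp_time(t[k - 1], t[k], z[k - 1], z[k], zc_out)
                else:
                    t_start, t_end = t[k - 1], t[k]
                events.append(
                    CrossingEvent(
                        ion_id=trace.ion_id,
                        species=trace.species,
                        direction=TB if side == 1 else BT,
                        t_start=t_start,
                        t_end=max(t_end, np.nextafter(t_start, np.inf)),
                        segment=segment,
                    )
                )
                side = zk
            else:
                side = zk
    # any residency still open at the last frame is discarded (incomplete)
    return events


def detect_crossings(
    bundle: TrajectoryBundle, *, interpolate: bool = True, segment: str | None = None
) -> EventLedger:
    """Run the three-zone state machine over every trace in a bundle."""
    if bundle.geometry is None:
        raise ValueError("bundle has no channel geometry")
    seg = segment if segment is not None else bundle.metadata.segment
    events: list[CrossingEvent] = []
    for trace in bundle.traces:
        events.extend(_detect_one(trace, bundle.geometry, interpolate, seg))
    return EventLedger(events=events, dt=bundle.metadata.duration, segment=seg)


def waiting_times(
    ledger: EventLedger, direction: int, species: str = "K+"
) -> np.ndarray:
    """Intervals between the start times of consecutive same-direction events.

    Computed within each segment only — no interval ever spans a segment
    boundary — then pooled. Fewer than two events in a segment contribute
    nothing; an empty result is not an error.
    """
    out: list[np.ndarray] = []
    by_seg: dict[str, list[float]] = {}
    for ev in ledger.select(species=species, direction=direction):
        by_seg.setdefault(ev.segment, []).append(ev.t_start)
    for starts in by_seg.values():
        if len(starts) >= 2:
            out.append(np.diff(np.sort(starts)))
    return np.concatenate(out) if out else np.empty(0)


def event_durations(
    ledger: EventLedger, direction: int | None = None, species: str | None = None
) -> np.ndarray:
    """t_end − t_start per event (ns), optionally filtered."""
    return np.asarray(
        [ev.duration for ev in ledger.select(species=species, direction=direction)]
    )
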