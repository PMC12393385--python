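"""Synthetic ion trajectories with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not the physics that produces it: event start times per direction
follow a configurable renewal process (single Poisson or lag+conduction
double-Poisson), transit durations are log-normal, a small fraction of
top-entering ions approach the pore sideways through the extracellular
wall, and non-permeant bulk ions random-walk in the reservoirs on either
side of the membrane at the nominal bulk concentration. Every permeation
event is recorded in a GroundTruth ledger so detector output can be checked
exactly.

Default parameters are the study conditions of the receptor system this
package was written around: 200-ns segments sampled every 10 ps at −102 mV,
top-to-bottom K+ entries from a double-Poisson process with mean lag 1 ns
and mean conduction interval 3.62 ns (bottom-to-top: 1.53 ns and 8.14 ns),
1.24-ns mean transit duration, 0.6% lateral entries, 150 mM bulk KCl.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (
    ChannelGeometry,
    IonTrace,
    SystemMetadata,
    TrajectoryBundle,
)
from .event_detection import BT, TB, CrossingEvent
from .permeation_stats import (
    DoublePoissonModel,
    PoissonModel,
    lognormal_params_for_mean,
    sample_waiting_times,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SegmentCounts",
    "generate_run",
    "sample_waiting_times",
    "table1_fixture",
]

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

_DIR_NAME = {TB: "TB", BT: "BT"}


def _default_entry_models() -> dict:
    return {
        ("K+", TB): DoublePoissonModel(lam_lag=1.0, lam_cond=1.0 / 3.62),
        ("K+", BT): DoublePoissonModel(lam_lag=1.0 / 1.53, lam_cond=1.0 / 8.14),
        # chloride events are rare at this voltage: ~0-1 per 200-ns segment
        ("Cl-", TB): PoissonModel(lam=0.0005),
        ("Cl-", BT): PoissonModel(lam=0.0025),
    }


def _default_geometry() -> ChannelGeometry:
    return ChannelGeometry(z_top=18.0, z_bottom=-18.0, cylinder_radius=17.3)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic run.

    entry_models maps (species, direction) to a waiting-time model for the
    renewal process of event start times in that direction; transit
    durations are log-normal with arithmetic mean ``transit_mean`` ns and
    log-sd ``transit_sigma`` (default: solved so that 99% of durations
    exceed three frame intervals). Durations below ``min_transit`` (default
    five frame intervals) are resampled so every generated event is
    resolvable at the frame spacing.
    """

    duration: float = 200.0  # ns
    frame_interval: float = 10.0  # ps
    geometry: ChannelGeometry = field(default_factory=_default_geometry)
    entry_models: dict = field(default_factory=_default_entry_models)
    transit_mean: float = 1.24  # ns
    transit_sigma: float | None = None
    min_transit: float | None = None  # ns; default 5 frame intervals
    lateral_fraction: float = 0.006
    jitter: float = 1.0  # Å per frame, in-plane
    bulk_step: float = 2.0  # Å per frame per axis, reservoir random walk
    box: tuple[float, float, float] = (50.0, 50.0, 160.0)
    bulk_concentration: float = 150.0  # mM
    n_bulk: int | None = None  # per species; default from concentration
    membrane_voltage: float = -102.0  # mV
    approach_ns: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.lateral_fraction <= 1.0:
            raise ValueError("lateral_fraction must lie in [0, 1]")
        for model in self.entry_models.values():
            if isinstance(model, PoissonModel) and model.lam < 0:
                raise ValueError("entry rates must be nonnegative")
        dt_ns = self.frame_interval / 1000.0
        if self.transit_sigma is None:
            # solve exp(mu + s^2/2) = mean with P(X < 3 frames) = 1%
            floor = 3.0 * dt_ns
            z99 = 2.3263478740408408  # standard-normal 99% quantile
            b = 2.0 * z99
            c = 2.0 * (np.log(floor) - np.log(self.transit_mean))
            s = (-b + np.sqrt(b * b - 4.0 * c)) / 2.0
            self.transit_sigma = float(s)
        if self.min_transit is None:
            self.min_transit = 5.0 * dt_ns
        if self.transit_mean >= self.duration:
            raise ValueError("infeasible spec: mean transit exceeds run duration")
        if 2.0 * self.geometry.cylinder_radius > min(self.box[0], self.box[1]):
            raise ValueError("infeasible spec: box narrower than the counting cylinder")
        if self.geometry.z_top + 45.0 >= self.box[2] / 2.0 - 4.0:
            raise ValueError("infeasible spec: box too short for the top reservoir")

    @property
    def frame_times(self) -> np.ndarray:
        dt_ns = self.frame_interval / 1000.0
        n = int(np.floor(self.duration / dt_ns + 1e-9)) + 1
        return np.arange(n) * dt_ns

    def default_bulk_count(self) -> int:
        vol_l = self.box[0] * self.box[1] * self.box[2] * 1e-27  # Å^3 -> L
        return int(round(self.bulk_concentration * 1e-3 * AVOGADRO * vol_l))


@dataclass
class GroundTruth:
    """True permeation events and the rate models that generated them."""

    events: list[CrossingEvent]
    entry_models: dict

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t_start)

    def counts(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for ev in self.events:
            key = (ev.species, ev.direction)
            out[key] = out.get(key, 0) + 1
        return out


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free random walk into [lo, hi] by reflection."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _reservoir_walk(rng, n, start_xy, start_z, z_lo, z_hi, box, step):
    """Random walk confined to a reservoir slab, reflected at walls."""
    if n <= 0:
        return np.empty((0, 3))
    steps = rng.normal(0.0, step, size=(n, 3))
    xyz = np.cumsum(steps, axis=0)
    x = _reflect(start_xy[0] + xyz[:, 0], -box[0] / 2.0 + 1.0, box[0] / 2.0 - 1.0)
    y = _reflect(start_xy[1] + xyz[:, 1], -box[1] / 2.0 + 1.0, box[1] / 2.0 - 1.0)
    z = _reflect(start_z + xyz[:, 2], z_lo, z_hi)
    return np.column_stack([x, y, z])


def _jittered_radial_walk(rng, n, r_max, start_xy, jitter):
    """In-plane jitter that never leaves radius r_max (radial reflection)."""
    if n <= 0:
        return np.empty((0, 2))
    steps = rng.normal(0.0, jitter, size=(n, 2))
    out = np.empty((n, 2))
    pos = np.asarray(start_xy, dtype=float)
    for i in range(n):
        cand = pos + steps[i]
        r = np.hypot(cand[0], cand[1])
        if r > r_max:
            cand *= (2.0 * r_max - r) / r  # radial reflection
        pos = cand
        out[i] = pos
    return out


def _permeant_trace(
    spec: SyntheticSpec, rng, ion_id, species, direction, t_start, t_dur, lateral
) -> IonTrace:
    """Build one full-length trace realizing a single permeation event."""
    times = spec.frame_times
    geo = spec.geometry
    box = spec.box
    z_top, z_bot = geo.z_top, geo.z_bottom
    if direction == TB:
        entry_z, exit_z = z_top, z_bot
        res_lo, res_hi = z_top + 45.0, box[2] / 2.0 - 2.0
        out_lo, out_hi = -box[2] / 2.0 + 2.0, z_bot - 6.0
        post_sign = -1.0
    else:
        entry_z, exit_z = z_bot, z_top
        res_lo, res_hi = -box[2] / 2.0 + 2.0, z_bot - 45.0
        out_lo, out_hi = z_top + 6.0, box[2] / 2.0 - 2.0
        post_sign = +1.0

    t_end = t_start + t_dur
    t_a = max(t_start - spec.approach_ns, 0.0)
    post_ns = 1.0
    r_inner = 0.55 * geo.cylinder_radius

    n = len(times)
    pos = np.empty((n, 3))
    pre = times < t_a
    approach = (~pre) & (times < t_start)
    inside = (times >= t_start) & (times < t_end + 1e-12)
    after = times >= t_end + 1e-12
    post = after & (times < t_end + post_ns)
    far = after & ~post

    # --- approach leg geometry
    if lateral:
        # sideways through the extracellular wall: radial cut-in at fixed
        # z inside the ECD window, then a short axial descent to the ring
        z_lat = z_top + 10.0
        r_far = geo.cylinder_radius + min(6.0, box[0] / 2.0 - geo.cylinder_radius - 2.0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        u = np.clip((times[approach] - t_a) / max(t_start - t_a, 1e-9), 0.0, 1.0)
        cut = u < 0.6  # radial phase
        r_of_u = np.where(cut, r_far + (4.0 - r_far) * (u / 0.6), 4.0)
        z_of_u = np.where(cut, z_lat, z_lat + (entry_z - z_lat) * ((u - 0.6) / 0.4))
        # keep strictly on the entry side of the ring until t_start
        z_of_u = entry_z + np.maximum(z_of_u - entry_z, 0.015) if direction == TB else z_of_u
        pos[approach, 0] = r_of_u * np.cos(theta)
        pos[approach, 1] = r_of_u * np.sin(theta)
        pos[approach, 2] = z_of_u
        res_start_z = z_lat
        res_lo_eff, res_hi_eff = z_lat - 2.0, z_lat + 2.0
        res_xy = (r_far * np.cos(theta), r_far * np.sin(theta))
        entry_xy = pos[approach][-1, :2] if approach.any() else np.array(res_xy)
    else:
        stage_z = res_lo + 5.0 if direction == TB else res_hi - 5.0
        entry_xy0 = rng.normal(0.0, 2.0, size=2)
        u = np.clip((times[approach] - t_a) / max(t_start - t_a, 1e-9), 0.0, 1.0)
        zline = stage_z + (entry_z - stage_z) * u
        margin = 0.015
        if direction == TB:
            zline = entry_z + np.maximum(zline - entry_z, margin)
        else:
            zline = entry_z - np.maximum(entry_z - zline, margin)
        pos[approach, 0] = entry_xy0[0]
        pos[approach, 1] = entry_xy0[1]
        pos[approach, 2] = zline
        res_start_z = stage_z
        res_lo_eff, res_hi_eff = res_lo, res_hi
        res_xy = tuple(entry_xy0)
        entry_xy = entry_xy0

    # --- reservoir dwell before the approach
    n_pre = int(pre.sum())
    pre_path = _reservoir_walk(
        rng, n_pre, res_xy, res_start_z, res_lo_eff, res_hi_eff, box, spec.bulk_step
    )
    pos[pre] = pre_path[::-1] if n_pre else pre_path  # walk built backwards from t_a

    # --- transit: linear z between the rings, jittered in-plane
    n_in = int(inside.sum())
    frac = (times[inside] - t_start) / t_dur
    pos[inside, 2] = entry_z + (exit_z - entry_z) * frac
    xy_in = _jittered_radial_walk(rng, n_in, r_inner, entry_xy, spec.jitter)
    pos[inside, :2] = xy_in

    # --- exit descent then far-side reservoir
    exit_xy = xy_in[-1] if n_in else entry_xy
    n_post = int(post.sum())
    depth = post_sign * (2.0 + 25.0 * (times[post] - t_end) / post_ns)
    pos[post, 2] = exit_z + depth
    pos[post, 0] = exit_xy[0]
    pos[post, 1] = exit_xy[1]
    n_far = int(far.sum())
    far_z0 = exit_z + post_sign * 27.0
    far_path = _reservoir_walk(
        rng, n_far, tuple(exit_xy), far_z0, min(out_lo, far_z0), max(out_hi, far_z0),
        box, spec.bulk_step,
    )
    pos[far] = far_path
    return IonTrace(ion_id=ion_id, species=species, times=times, positions=pos)


def generate_run(spec: SyntheticSpec) -> tuple[TrajectoryBundle, GroundTruth]:
    """Generate one synthetic run and its ground-truth event ledger.

    Fully reproducible from ``spec.seed``: one root seed sequence, with a
    deterministic child stream per ion.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_master = np.random.default_rng(ss.spawn(1)[0])
    times = spec.frame_times
    dt_ns = spec.frame_interval / 1000.0
    margin = 2.0 * dt_ns

    gt_events: list[CrossingEvent] = []
    planned: list[tuple[str, int, float, float, bool]] = []
    for (species, direction), model in sorted(
        spec.entry_models.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        if model is None or (isinstance(model, PoissonModel) and model.lam <= 0):
            continue
        # renewal process of start times; draw in blocks until past duration
        starts: list[float] = []
        t = 0.0
        while t < spec.duration:
            block = sample_waiting_times(model, 64, rng_master)
            for w in block:
                t += float(w)
                if t >= spec.duration:
                    break
                starts.append(t)
        for t_start in starts:
            t_dur = 0.0
            while t_dur < spec.min_transit:
                t_dur = float(
                    rng_master.lognormal(
                        *lognormal_params_for_mean(spec.transit_mean, spec.transit_sigma)
                    )
                )
            if t_start + t_dur > spec.duration - margin:
                continue  # would be incomplete: never realized
            draw_lateral = rng_master.uniform() < spec.lateral_fraction
            # a lateral approach needs enough history before the entry for
            # the classifier's look-back window; very early entries stay axial
            lateral = (
                direction == TB
                and species == "K+"
                and draw_lateral
                and t_start > spec.approach_ns + 5.0
            )
            planned.append((species, direction, t_start, t_dur, lateral))

    n_bulk = spec.n_bulk if spec.n_bulk is not None else spec.default_bulk_count()
    n_ions = len(planned) + 2 * n_bulk
    children = ss.spawn(n_ions) if n_ions else []

    traces: list[IonTrace] = []
    k = 0
    for i, (species, direction, t_start, t_dur, lateral) in enumerate(planned):
        rng = np.random.default_rng(children[k]); k += 1
        ion_id = f"{species}:{_DIR_NAME[direction]}:{i}"
        traces.append(
            _permeant_trace(spec, rng, ion_id, species, direction, t_start, t_dur, lateral)
        )
        gt_events.append(
            CrossingEvent(
                ion_id=ion_id,
                species=species,
                direction=direction,
                t_start=t_start,
                t_end=t_start + t_dur,
                pathway="lateral" if lateral else "axial",
            )
        )

    # non-permeant bulk ions, half in each reservoir, both species alternating
    geo = spec.geometry
    box = spec.box
    slabs = (
        (geo.z_top + 4.0, box[2] / 2.0 - 2.0),
        (-box[2] / 2.0 + 2.0, geo.z_bottom - 4.0),
    )
    for j in range(2 * n_bulk):
        rng = np.random.default_rng(children[k]); k += 1
        species = "K+" if j % 2 == 0 else "Cl-"
        z_lo, z_hi = slabs[(j // 2) % 2]
        start_xy = (
            rng.uniform(-box[0] / 2.0 + 2.0, box[0] / 2.0 - 2.0),
            rng.uniform(-box[1] / 2.0 + 2.0, box[1] / 2.0 - 2.0),
        )
        start_z = rng.uniform(z_lo + 1.0, z_hi - 1.0)
        # keep bulk ions out of the counting cylinder's vertical shadow only
        # when between the rings: the slabs already exclude that z range
        path = _reservoir_walk(rng, len(times), start_xy, start_z, z_lo, z_hi, box, spec.bulk_step)
        traces.append(
            IonTrace(ion_id=f"bulk:{species}:{j}", species=species, times=times, positions=path)
        )

    metadata = SystemMetadata(
        box_height=box[2],
        duration=spec.duration,
        frame_interval=spec.frame_interval,
        membrane_voltage=spec.membrane_voltage,
        bulk_concentration=spec.bulk_concentration,
        box_x=box[0],
        box_y=box[1],
    )
    bundle = TrajectoryBundle(
        traces=traces, geometry=spec.geometry, metadata=metadata, frame_times=times
    )
    return bundle, GroundTruth(events=gt_events, entry_models=dict(spec.entry_models))


# ---------------------------------------------------------------------------
# Published per-segment event counts (packaged fixture)


@dataclass(frozen=True)
class SegmentCounts:
    """Printed per-segment event counts at −102 mV (200-ns segments)."""

    segment: str
    tb_k: int
    bt_k: int
    tb_cl: int
    bt_cl: int
    dt: float = 200.0  # ns
    ve: float = -102.0  # mV


_TABLE1_ROWS = [
    ("1", 50, 17, 0, 0),
    ("2", 40, 17, 0, 0),
    ("3", 32, 20, 0, 0),
    ("4", 39, 27, 0, 0),
    ("5", 31, 21, 0, 0),
    ("6.a", 45, 12, 0, 1),
    ("6.b", 45, 16, 0, 0),
    ("7.a", 32, 15, 0, 1),
    ("7.b", 28, 6, 0, 0),
    ("8.a", 40, 23, 0, 0),
    ("8.b", 62, 16, 0, 0),
    ("9.a", 51, 18, 0, 0),
    ("9.b", 43, 13, 0, 1),
    ("10.a", 47, 16, 0, 0),
    ("10.b", 39, 10, 0, 1),
    ("10.c", 62, 13, 1, 1),
    ("10.d", 65, 14, 0, 0),
    ("10.e", 43, 21, 0, 0),
]


def table1_fixture() -> list[SegmentCounts]:
    """The 18 published 200-ns segments of event counts at −102 mV."""
    return [SegmentCounts(*row) for row in _TABLE1_ROWS]
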