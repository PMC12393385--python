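"""Domain types, unit conventions, and trajectory ingestion.

Conventions used throughout the package: right-handed coordinates with the
membrane normal along +z and the extracellular side at larger z; lengths in
Å, times in ns, voltages in mV, currents in pA, conductances in pS; ion
charge in elementary-charge units.

Trajectories enter either from standard MD formats (via MDAnalysis) or from
a plain columnar ion-trace format designed for small, diff-able fixtures:
UTF-8, tab-separated columns ``time_ns  ion_id  species  x  y  z``, ``#``
comment lines, with geometry and system metadata embedded as JSON in header
comments so a bundle round-trips through a single file.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Elementary charge, coulomb.
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Charge (elementary units) of the species the package knows by name.
SPECIES_CHARGE = {"K+": 1, "Na+": 1, "Cl-": -1}

TRACE_FORMAT_MAGIC = "# permkit-ion-traces v1"


class IngestError(ValueError):
    """Raised when a trajectory source cannot be turned into ion traces."""


def charge_of(species: str) -> int:
    """Signed charge in elementary units for a species label ('other' -> 0)."""
    return SPECIES_CHARGE.get(species, 0)


@dataclass
class IonTrace:
    """Per-ion time series of unwrapped coordinates.

    times are strictly increasing (ns); positions is an (n, 3) float array
    in Å, continuity-corrected across periodic boundaries (unwrapped).
    """

    ion_id: str
    species: str
    times: np.ndarray
    positions: np.ndarray
    charge: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.charge is None:
            self.charge = charge_of(self.species)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"non-monotonic time stamps for ion {self.ion_id!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]

    def radial_distance(self, center_xy: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
        """Distance from the (vertical) pore axis at ``center_xy``, Å."""
        d = self.positions[:, :2] - np.asarray(center_xy, dtype=float)
        return np.hypot(d[:, 0], d[:, 1])

    def is_unwrapped(self, box: Sequence[float]) -> bool:
        """True if no consecutive displacement exceeds half a box edge."""
        if len(self.times) < 2:
            return True
        steps = np.abs(np.diff(self.positions, axis=0))
        return bool(np.all(steps < 0.5 * np.asarray(box, dtype=float)))


@dataclass
class ChannelGeometry:
    """Bounded cylinder defining the transmembrane counting region.

    z_top / z_bottom are the boundary-ring planes (Å); for the receptor this
    package was written around these are the centroid z of the backbone
    atoms of the Glu-258 (extracellular) and Glu-237 (intracellular) rings.
    When ``time_varying`` is set, per-frame ring positions may be supplied in
    ``z_top_series`` / ``z_bottom_series`` (aligned with the frame times);
    the scalar fields then hold their time averages.
    """

    z_top: float
    z_bottom: float
    cylinder_radius: float = 17.3
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center_xy: tuple[float, float] = (0.0, 0.0)
    time_varying: bool = False
    z_top_series: np.ndarray | None = None
    z_bottom_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        if not self.z_top > self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if self.z_top_series is not None:
            self.z_top_series = np.asarray(self.z_top_series, dtype=float)
            self.z_bottom_series = np.asarray(self.z_bottom_series, dtype=float)
            if np.any(self.z_top_series <= self.z_bottom_series):
                raise ValueError("z_top must exceed z_bottom in every frame")

    @property
    def length(self) -> float:
        return self.z_top - self.z_bottom

    def boundaries_at(self, frame: int) -> tuple[float, float]:
        """(z_top, z_bottom) for a frame index, honouring time variation."""
        if self.time_varying and self.z_top_series is not None:
            return float(self.z_top_series[frame]), float(self.z_bottom_series[frame])
        return self.z_top, self.z_bottom

    def to_dict(self) -> dict:
        d = {
            "z_top": self.z_top,
            "z_bottom": self.z_bottom,
            "cylinder_radius": self.cylinder_radius,
            "axis": list(self.axis),
            "center_xy": list(self.center_xy),
            "time_varying": self.time_varying,
        }
        if self.z_top_series is not None:
            d["z_top_series"] = [round(v, 4) for v in self.z_top_series]
            d["z_bottom_series"] = [round(v, 4) for v in self.z_bottom_series]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelGeometry":
        kw = dict(d)
        for key in ("axis", "center_xy"):
            if key in kw:
                kw[key] = tuple(kw[key])
        for key in ("z_top_series", "z_bottom_series"):
            if kw.get(key) is not None:
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


@dataclass
class SystemMetadata:
    """Box, field and timing metadata for one run.

    The membrane voltage follows Ve = Lz · EF, with Lz the full box height;
    when both Ve and EF are supplied they must be consistent.
    """

    box_height: float  # Lz, Å
    duration: float  # Δt, ns
    frame_interval: float = 10.0  # ps
    field_strength: float | None = None  # EF, mV/Å
    membrane_voltage: float | None = None  # Ve, mV
    bulk_concentration: float = 150.0  # mM
    box_x: float | None = None
    box_y: float | None = None
    segment: str = "1"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.membrane_voltage is None and self.field_strength is not None:
            self.membrane_voltage = self.box_height * self.field_strength
        elif self.field_strength is None and self.membrane_voltage is not None:
            self.field_strength = self.membrane_voltage / self.box_height
        elif self.membrane_voltage is not None and self.field_strength is not None:
            expect = self.box_height * self.field_strength
            if abs(self.membrane_voltage - expect) > 1e-6 * max(1.0, abs(expect)):
                raise ValueError(
                    f"membrane_voltage {self.membrane_voltage} inconsistent with "
                    f"Lz*EF = {expect}"
                )

    @property
    def box(self) -> tuple[float, float, float]:
        bx = self.box_x if self.box_x is not None else self.box_height
        by = self.box_y if self.box_y is not None else self.box_height
        return (bx, by, self.box_height)

    def to_dict(self) -> dict:
        return {
            "box_height": self.box_height,
            "duration": self.duration,
            "frame_interval": self.frame_interval,
            "field_strength": self.field_strength,
            "membrane_voltage": self.membrane_voltage,
            "bulk_concentration": self.bulk_concentration,
            "box_x": self.box_x,
            "box_y": self.box_y,
            "segment": self.segment,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemMetadata":
        return cls(**dict(d))


@dataclass
class TrajectoryBundle:
    """Ion traces plus geometry and metadata (one analysed run).

    ``water_oxygens`` and ``protein_atoms`` are optional coordinate streams
    used only by the profile calculations; ion-event analysis never needs
    them. All traces share the metadata time base.
    """

    traces: list[IonTrace]
    geometry: ChannelGeometry
    metadata: SystemMetadata
    water_oxygens: np.ndarray | None = None  # (n_frames, n_w, 3)
    protein_atoms: "ProteinCoordinates | None" = None
    frame_times: np.ndarray | None = None

    def select(self, species: str) -> list[IonTrace]:
        return [t for t in self.traces if t.species == species]


@dataclass
class ProteinCoordinates:
    """Per-frame protein coordinates with per-atom annotations.

    coords: (n_frames, n_atoms, 3) Å; elements and residue labels are
    per-atom; ``oxygen_mask`` marks protein oxygens for hydration-shell
    replacement counting.
    """

    coords: np.ndarray
    elements: Sequence[str]
    residue_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]

    @property
    def oxygen_mask(self) -> np.ndarray:
        return np.asarray([e.upper().startswith("O") for e in self.elements])


# ---------------------------------------------------------------------------
# Periodic-boundary unwrapping


def unwrap_positions(positions: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Continuity-correct wrapped coordinates across periodic boundaries.

    Minimum-image rule per axis: each consecutive displacement is shifted by
    integer multiples of the box edge so that it is smaller than half the
    edge, then re-accumulated. Idempotent on already-unwrapped input.
    Orthorhombic boxes only.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    if len(positions) < 2:
        return positions.copy()
    steps = np.diff(positions, axis=0)
    steps -= box * np.round(steps / box)
    out = np.empty_like(positions)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(steps, axis=0)
    return out


# ---------------------------------------------------------------------------
# Columnar ion-trace format


def write_ion_traces(bundle: TrajectoryBundle, path: str | os.PathLike) -> None:
    """Write a bundle to the columnar ion-trace format.

    Times are written to 1e-6 ns and coordinates to 1e-4 Å, the format's
    round-trip tolerances.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TRACE_FORMAT_MAGIC + "\n")
        fh.write("# geometry: " + json.dumps(bundle.geometry.to_dict()) + "\n")
        fh.write("# metadata: " + json.dumps(bundle.metadata.to_dict()) + "\n")
        fh.write("time_ns\tion_id\tspecies\tx\ty\tz\n")
        for tr in bundle.traces:
            for t, (x, y, z) in zip(tr.times, tr.positions):
                fh.write(f"{t:.6f}\t{tr.ion_id}\t{tr.species}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")


def _read_columnar(path: str | os.PathLike) -> TrajectoryBundle:
    geometry = None
    metadata = None
    rows: dict[str, list] = {}
    species_of: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("geometry:"):
                    geometry = ChannelGeometry.from_dict(json.loads(body[len("geometry:"):]))
                elif body.startswith("metadata:"):
                    metadata = SystemMetadata.from_dict(json.loads(body[len("metadata:"):]))
                continue
            if line.startswith("time_ns"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise IngestError(f"malformed ion-trace line: {line!r}")
            t, ion_id, species, x, y, z = parts
            rows.setdefault(ion_id, []).append((float(t), float(x), float(y), float(z)))
            species_of[ion_id] = species
    if geometry is None:
        raise IngestError(f"{path}: no geometry header and no geometry supplied")
    traces = []
    for ion_id, rec in rows.items():
        arr = np.asarray(rec, dtype=float)
        traces.append(
            IonTrace(ion_id=ion_id, species=species_of[ion_id], times=arr[:, 0], positions=arr[:, 1:])
        )
    if metadata is None:
        tmax = max((tr.times[-1] for tr in traces), default=1.0)
        metadata = SystemMetadata(box_height=1.0, duration=float(tmax) or 1.0)
    return TrajectoryBundle(traces=traces, geometry=geometry, metadata=metadata)


# ---------------------------------------------------------------------------
# MD-format ingestion (MDAnalysis behind the scenes)


def _from_mdanalysis(
    universe,
    ion_selections: Mapping[str, str],
    geometry: ChannelGeometry | str = "auto",
    boundary_residues: tuple[int, int] = (258, 237),
    boundary_atoms: str = "name CA",
    time_varying: bool = True,
) -> TrajectoryBundle:
    """Build a TrajectoryBundle from an MDAnalysis Universe.

    ion_selections maps a species label to an MDAnalysis selection string.
    geometry='auto' derives the boundary rings from the per-frame centroid z
    of the ``boundary_atoms`` of the two boundary residues (extracellular
    ring first).
    """
    groups = {}
    for species, sel in ion_selections.items():
        ag = universe.select_atoms(sel)
        if len(ag) == 0:
            raise IngestError(f"selection {sel!r} for species {species!r} matches zero atoms")
        groups[species] = ag

    auto_geometry = isinstance(geometry, str) and geometry == "auto"
    ring_groups = None
    if auto_geometry:
        top_res, bottom_res = boundary_residues
        try:
            ring_top = universe.select_atoms(f"resid {top_res} and {boundary_atoms}")
            ring_bottom = universe.select_atoms(f"resid {bottom_res} and {boundary_atoms}")
        except Exception as exc:  # topology without residue information
            raise IngestError(
                "geometry='auto' but the topology carries no usable boundary "
                f"residues {boundary_residues}: {exc}"
            ) from exc
        if len(ring_top) == 0 or len(ring_bottom) == 0:
            raise IngestError(
                "geometry='auto' but boundary residues "
                f"{boundary_residues} not found in topology; pass an explicit "
                "ChannelGeometry"
            )
        ring_groups = (ring_top, ring_bottom)

    n_frames = len(universe.trajectory)
    times = np.empty(n_frames)
    coords = {sp: np.empty((n_frames, len(ag), 3)) for sp, ag in groups.items()}
    box = None
    z_top_series = np.empty(n_frames)
    z_bottom_series = np.empty(n_frames)
    for i, ts in enumerate(universe.trajectory):
        times[i] = ts.time / 1000.0  # MDAnalysis ps -> ns
        if box is None and ts.dimensions is not None:
            box = tuple(float(v) for v in ts.dimensions[:3])
        for sp, ag in groups.items():
            coords[sp][i] = ag.positions
        if ring_groups is not None:
            z_top_series[i] = ring_groups[0].positions[:, 2].mean()
            z_bottom_series[i] = ring_groups[1].positions[:, 2].mean()

    if len(times) > 1 and not np.all(np.diff(times) > 0):
        if np.allclose(np.diff(times), 0):  # readers without time metadata
            times = np.arange(n_frames, dtype=float) * 1e-2
        else:
            raise IngestError("non-monotonic time stamps in trajectory")

    if auto_geometry:
        geometry = ChannelGeometry(
            z_top=float(z_top_series.mean()),
            z_bottom=float(z_bottom_series.mean()),
            time_varying=time_varying,
            z_top_series=z_top_series if time_varying else None,
            z_bottom_series=z_bottom_series if time_varying else None,
        )

    traces = []
    for sp, arr in coords.items():
        for j in range(arr.shape[1]):
            pos = arr[:, j, :]
            if box is not None:
                pos = unwrap_positions(pos, box)
            traces.append(IonTrace(ion_id=f"{sp}:{j}", species=sp, times=times.copy(), positions=pos))

    lz = box[2] if box is not None else 2.0 * (geometry.z_top - geometry.z_bottom)
    duration = float(times[-1] - times[0]) if n_frames > 1 else 1.0
    frame_interval = float(np.mean(np.diff(times)) * 1000.0) if n_frames > 1 else 10.0
    metadata = SystemMetadata(
        box_height=lz,
        duration=max(duration, 1e-9),
        frame_interval=frame_interval,
        box_x=box[0] if box else None,
        box_y=box[1] if box else None,
    )
    return TrajectoryBundle(traces=traces, geometry=geometry, metadata=metadata, frame_times=times)


def load_ion_traces(
    trajectory_source,
    topology=None,
    *,
    ion_selections: Mapping[str, str] | None = None,
    geometry: ChannelGeometry | str = "auto",
    **kwargs,
) -> TrajectoryBundle:
    """Load ion traces from the columnar format or a standard MD format.

    A path ending in .tsv/.txt/.traces (or any readable columnar file) is
    parsed directly; anything else — a (topology, trajectory) pair or an
    MDAnalysis Universe — goes through MDAnalysis. Traces come back
    unwrapped; geometry is taken from boundary-residue coordinates when
    resolvable, otherwise from the explicit ``geometry`` argument.
    """
    if hasattr(trajectory_source, "select_atoms"):  # a Universe
        if ion_selections is None:
            raise IngestError("ion_selections required for MD-format ingestion")
        return _from_mdanalysis(trajectory_source, ion_selections, geometry, **kwargs)
    src = os.fspath(trajectory_source)
    if topology is None:
        with open(src, encoding="utf-8") as fh:
            first = fh.readline()
        if not first.startswith("#") and not first.startswith("time_ns"):
            raise IngestError(f"{src}: not a columnar ion-trace file and no topology given")
        bundle = _read_columnar(src)
        if isinstance(geometry, ChannelGeometry):
            bundle.geometry = geometry
        return bundle
    import MDAnalysis as mda

    if ion_selections is None:
        raise IngestError("ion_selections required for MD-format ingestion")
    universe = mda.Universe(topology, src)
    return _from_mdanalysis(universe, ion_selections, geometry, **kwargs)
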