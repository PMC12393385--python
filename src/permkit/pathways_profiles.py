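"""Entry-pathway classification and channel-profile observables.

Pathways: an ion can reach the transmembrane pore by descending axially
through the extracellular vestibule or by cutting sideways through a
fenestration in the extracellular wall. An event's entry leg is called
lateral when, within a look-back window before its start, the ion sat
outside the channel-wall radius while at vestibule height — i.e. it crossed
the wall rather than the mouth.

Profiles: per-0.5-Å-bin observables along the pore axis — ion density
normalized to the bulk expectation, a simplified inscribed-sphere pore
radius, first-shell hydration and protein-oxygen replacement counts for K+,
and normalized residue position densities — plus a mean-square-displacement
estimate of the axial diffusion coefficient inside the pore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import ProteinCoordinates, TrajectoryBundle
from .event_detection import BT, TB, EventLedger
from .synthetic_data import AVOGADRO

__all__ = [
    "LateralWindow",
    "PathwayReport",
    "ProfileGrid",
    "classify_pathways",
    "ion_density_profile",
    "pore_radius_profile",
    "hydration_profile",
    "residue_position_density",
    "axial_diffusion",
    "DEFAULT_VDW_RADII",
]

#: van der Waals radii by element, Å.
DEFAULT_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: Free-solution diffusion coefficient of K+ in water, m²/s.
FREE_DIFFUSION_K = 1.96e-9


@dataclass
class LateralWindow:
    """Side-entry detection window above the transmembrane region.

    radial_threshold (Å) is the channel-wall radius an ion must have been
    beyond; (z_low, z_high) bound the vestibule heights at which being
    outside that radius implies a wall crossing; lookback_ns is how far
    before the event start the trace is examined.
    """

    radial_threshold: float = 17.3
    z_low: float = 0.0
    z_high: float = 0.0
    lookback_ns: float = 5.0

    @classmethod
    def from_geometry(cls, geometry, lookback_ns: float = 5.0) -> "LateralWindow":
        return cls(
            radial_threshold=geometry.cylinder_radius,
            z_low=geometry.z_top,
            z_high=geometry.z_top + 40.0,
            lookback_ns=lookback_ns,
        )


@dataclass
class PathwayReport:
    """Lateral/axial partition of an event ledger."""

    lateral: dict[tuple[str, int], int]
    axial: dict[tuple[str, int], int]
    pooled_time_ns: float

    def total(self, key: tuple[str, int]) -> int:
        return self.lateral.get(key, 0) + self.axial.get(key, 0)

    @property
    def lateral_count(self) -> int:
        return sum(self.lateral.values())

    @property
    def lateral_fraction_tb_k(self) -> float:
        n = self.total(("K+", TB))
        return self.lateral.get(("K+", TB), 0) / n if n else 0.0

    @property
    def lateral_fraction_all_k(self) -> float:
        n = self.total(("K+", TB)) + self.total(("K+", BT))
        lat = self.lateral.get(("K+", TB), 0) + self.lateral.get(("K+", BT), 0)
        return lat / n if n else 0.0

    @property
    def lateral_rate_per_us(self) -> float:
        return self.lateral_count / (self.pooled_time_ns / 1000.0)


def classify_pathways(
    ledger: EventLedger,
    bundle: TrajectoryBundle | None = None,
    lateral_window: LateralWindow | None = None,
    pooled_time_ns: float | None = None,
) -> PathwayReport:
    """Label each event's entry leg lateral or axial and tally.

    Only top entries (TB events) can be lateral here: the side openings sit
    in the extracellular wall, and the intracellular portals are out of
    scope. An event whose look-back window would extend before the start of
    its trace is labelled axial with a warning. When ``bundle`` is omitted
    the ledger's existing pathway labels are tallied as-is.
    """
    if bundle is not None and lateral_window is None:
        lateral_window = LateralWindow.from_geometry(bundle.geometry)
    traces = {tr.ion_id: tr for tr in bundle.traces} if bundle is not None else {}

    lateral: dict[tuple[str, int], int] = {}
    axial: dict[tuple[str, int], int] = {}
    for ev in ledger.events:
        label = ev.pathway
        if bundle is not None:
            label = "axial"
            if ev.direction == TB and ev.ion_id in traces:
                tr = traces[ev.ion_id]
                t0 = ev.t_start - lateral_window.lookback_ns
                if t0 < tr.times[0] - 1e-9:
                    warnings.warn(
                        f"look-back for event of ion {ev.ion_id!r} at "
                        f"{ev.t_start:.3f} ns extends before the trajectory "
                        "start; labelled axial",
                        stacklevel=2,
                    )
                else:
                    mask = (tr.times >= t0) & (tr.times < ev.t_start)
                    r = tr.radial_distance()[mask]
                    z = tr.z[mask]
                    hit = (
                        (r > lateral_window.radial_threshold)
                        & (z > lateral_window.z_low)
                        & (z < lateral_window.z_high)
                    )
                    if np.any(hit):
                        label = "lateral"
            ev.pathway = label
        key = (ev.species, ev.direction)
        bucket = lateral if label == "lateral" else axial
        bucket[key] = bucket.get(key, 0) + 1
    if pooled_time_ns is None:
        n_segments = len({ev.segment for ev in ledger.events}) or 1
        pooled_time_ns = ledger.dt * n_segments
    return PathwayReport(lateral=lateral, axial=axial, pooled_time_ns=pooled_time_ns)


@dataclass
class ProfileGrid:
    """Per-bin observables on a regular z grid (0.5-Å bins by default)."""

    z_edges: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])


def _make_edges(z_range: tuple[float, float], bin_width: float) -> np.ndarray:
    lo, hi = z_range
    n = int(np.ceil((hi - lo) / bin_width - 1e-9))
    return lo + bin_width * np.arange(n + 1)


def _stride_indices(bundle: TrajectoryBundle, stride_ps: float) -> np.ndarray:
    step = max(int(round(stride_ps / bundle.metadata.frame_interval)), 1)
    n = len(bundle.traces[0].times) if bundle.traces else 0
    return np.arange(0, n, step)


def ion_density_profile(
    bundle: TrajectoryBundle,
    species: str = "K+",
    stride_ps: float = 100.0,
    z_range: tuple[float, float] | None = None,
    bin_width: float = 0.5,
) -> ProfileGrid:
    """Mean ion count per disk-shaped z bin, normalized to bulk.

    Ions inside the counting radius are binned by z in ``bin_width``-thick
    disks; the per-frame mean count in each disk is divided by the bulk
    expectation c·N_A·V_disk with V_disk = π·r²·bin_width.
    """
    idx = _stride_indices(bundle, stride_ps)
    if len(idx) == 0:
        raise ValueError("no frames to profile")
    geo = bundle.geometry
    if z_range is None:
        z_range = (geo.z_bottom - 30.0, geo.z_top + 40.0)
    edges = _make_edges(z_range, bin_width)
    counts = np.zeros(len(edges) - 1)
    for tr in bundle.select(species):
        r = tr.radial_distance(geo.center_xy)[idx]
        z = tr.z[idx]
        z_in = z[r <= geo.cylinder_radius]
        counts += np.histogram(z_in, bins=edges)[0]
    mean_per_frame = counts / len(idx)
    v_disk_l = np.pi * geo.cylinder_radius**2 * bin_width * 1e-27  # Å^3 -> L
    bulk = bundle.metadata.bulk_concentration * 1e-3 * AVOGADRO * v_disk_l
    grid = ProfileGrid(z_edges=edges)
    grid.columns[f"density_{species}"] = mean_per_frame / bulk
    grid.columns[f"count_{species}"] = mean_per_frame
    return grid


def _inscribed_radius(center: np.ndarray, z: float, atoms: np.ndarray, radii: np.ndarray) -> float:
    d = atoms - np.array([center[0], center[1], z])
    return float(np.min(np.sqrt(np.einsum("ij,ij->i", d, d)) - radii))


def pore_radius_profile(
    protein: ProteinCoordinates,
    vdw_table: dict[str, float] | None = None,
    z_range: tuple[float, float] | None = None,
    bin_width: float = 0.5,
    slab_halfwidth: float = 8.0,
    grid_step: float = 0.1,
    max_steps: int = 400,
    axis_xy: tuple[float, float] = (0.0, 0.0),
) -> ProfileGrid:
    """Simplified inscribed-sphere pore-radius profile.

    At each z level the pore radius is the largest clearance of a sphere
    centred in that plane: max over candidate centres of
    min over atoms of (distance to atom centre − vdW radius). The centre is
    found by a deterministic hill climb on a ``grid_step`` lattice starting
    from the nominal pore axis; per-frame profiles are averaged. Bins with
    no atoms within ``slab_halfwidth`` in z are marked unbounded (NaN).
    """
    vdw_table = vdw_table or DEFAULT_VDW_RADII
    radii_all = np.asarray([vdw_table.get(e.upper()[:1], 1.7) for e in protein.elements])
    coords = protein.coords
    if z_range is None:
        z_all = coords[..., 2]
        z_range = (float(z_all.min()), float(z_all.max()))
    edges = _make_edges(z_range, bin_width)
    centers_z = 0.5 * (edges[:-1] + edges[1:])
    n_frames = coords.shape[0]
    prof = np.full((n_frames, len(centers_z)), np.nan)
    moves = grid_step * np.array(
        [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    )
    for f in range(n_frames):
        frame = coords[f]
        for j, zc in enumerate(centers_z):
            near = np.abs(frame[:, 2] - zc) <= slab_halfwidth
            if not np.any(near):
                continue  # unbounded at this level
            atoms = frame[near]
            radii = radii_all[near]
            center = np.asarray(axis_xy, dtype=float)
            best = _inscribed_radius(center, zc, atoms, radii)
            for _ in range(max_steps):
                cand = center + moves
                vals = [_inscribed_radius(c, zc, atoms, radii) for c in cand]
                k = int(np.argmax(vals))
                if vals[k] <= best:
                    break
                best, center = vals[k], cand[k]
            prof[f, j] = best
    grid = ProfileGrid(z_edges=edges)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        grid.columns["pore_radius"] = np.nanmean(prof, axis=0)
    return grid


def hydration_profile(
    bundle: TrajectoryBundle,
    shell_radius: float = 3.52,
    stride_ps: float = 100.0,
    z_range: tuple[float, float] | None = None,
    bin_width: float = 0.5,
    species: str = "K+",
) -> ProfileGrid:
    """First-shell hydration and protein-oxygen replacement along the pore.

    For every ion of ``species`` inside the counting cylinder, water oxygens
    strictly closer than ``shell_radius`` are counted (the strict inequality
    is a deterministic tie-break; exact-threshold contacts have measure zero
    in real data), and protein oxygens within the same shell are counted as
    replacements. Counts are binned by the ion's z and averaged over
    ion-frames.
    """
    if bundle.water_oxygens is None:
        raise ValueError("bundle has no water-oxygen coordinate stream")
    idx = _stride_indices(bundle, stride_ps)
    geo = bundle.geometry
    if z_range is None:
        z_range = (geo.z_bottom - 10.0, geo.z_top + 40.0)
    edges = _make_edges(z_range, bin_width)
    nbin = len(edges) - 1
    hyd_sum = np.zeros(nbin)
    rep_sum = np.zeros(nbin)
    n_obs = np.zeros(nbin)
    waters = bundle.water_oxygens
    prot = bundle.protein_atoms
    prot_ox = None
    if prot is not None:
        prot_ox = prot.coords[:, prot.oxygen_mask, :]
    for tr in bundle.select(species):
        r = tr.radial_distance(geo.center_xy)
        for f in idx:
            if r[f] > geo.cylinder_radius:
                continue
            p = tr.positions[f]
            b = int(np.floor((p[2] - edges[0]) / bin_width))
            if not 0 <= b < nbin:
                continue
            wf = waters[f if waters.shape[0] > 1 else 0]
            d2 = np.einsum("ij,ij->i", wf - p, wf - p)
            hyd = int(np.count_nonzero(d2 < shell_radius**2))
            rep = 0
            if prot_ox is not None:
                pf = prot_ox[f if prot_ox.shape[0] > 1 else 0]
                d2p = np.einsum("ij,ij->i", pf - p, pf - p)
                rep = int(np.count_nonzero(d2p < shell_radius**2))
            hyd_sum[b] += hyd
            rep_sum[b] += rep
            n_obs[b] += 1
    grid = ProfileGrid(z_edges=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid.columns["hydration"] = np.where(n_obs > 0, hyd_sum / n_obs, np.nan)
        grid.columns["replacement"] = np.where(n_obs > 0, rep_sum / n_obs, np.nan)
    grid.columns["n_observations"] = n_obs
    return grid


def residue_position_density(
    protein: ProteinCoordinates,
    residue_selection: list[str],
    z_range: tuple[float, float] | None = None,
    bin_width: float = 0.5,
) -> ProfileGrid:
    """Normalized z-density of every atom of each selected residue type.

    All atoms (hydrogens included) of all copies of each residue type are
    histogrammed in z over all frames; each type's density integrates to 1.
    """
    if protein.residue_names is None:
        raise ValueError("protein coordinates carry no residue labels")
    names = np.asarray(protein.residue_names)
    if z_range is None:
        z_all = protein.coords[..., 2]
        z_range = (float(z_all.min()) - bin_width, float(z_all.max()) + bin_width)
    edges = _make_edges(z_range, bin_width)
    grid = ProfileGrid(z_edges=edges)
    for res in residue_selection:
        mask = names == res
        if not np.any(mask):
            raise ValueError(f"residue selection {res!r} matches no atoms")
        z = protein.coords[:, mask, 2].ravel()
        dens, _ = np.histogram(z, bins=edges, density=True)
        grid.columns[f"P_{res}"] = dens
    return grid


def axial_diffusion(
    bundle: TrajectoryBundle,
    region: tuple[float, float] | None = None,
    species: str = "K+",
    min_run_frames: int = 10,
    max_lag_frames: int = 20,
    free_reference: float = FREE_DIFFUSION_K,
) -> dict:
    """Axial (1-D) diffusion coefficient from in-region MSD slopes.

    Contiguous residencies of ≥ ``min_run_frames`` frames inside the region
    contribute squared z displacements at lags 1..``max_lag_frames``; the
    MSD–lag line fitted over that window gives D = slope/2. Ballistic
    motion (MSD growing ~quadratically, log-log exponent > 1.5) is flagged
    and no coefficient is reported.

    Returns D in Å²/ns, in 10⁻⁹ m²/s, and as a ratio to ``free_reference``.
    """
    geo = bundle.geometry
    if region is None:
        region = (geo.z_bottom, geo.z_top)
    dt_ns = bundle.metadata.frame_interval / 1000.0
    runs: list[np.ndarray] = []
    for tr in bundle.select(species):
        inside = (
            (tr.z >= region[0])
            & (tr.z <= region[1])
            & (tr.radial_distance(geo.center_xy) <= geo.cylinder_radius)
        )
        # split into maximal contiguous stretches
        boundaries = np.flatnonzero(np.diff(inside.astype(int)))
        start = 0
        for b in np.append(boundaries, len(inside) - 1):
            if inside[start]:
                seg = tr.z[start : b + 1]
                if len(seg) >= min_run_frames:
                    runs.append(seg)
            start = b + 1
    if not runs:
        raise ValueError("no ion resides in the region long enough for an MSD fit")
    lags = np.arange(1, max_lag_frames + 1)
    msd = np.zeros(len(lags))
    nobs = np.zeros(len(lags))
    for seg in runs:
        for i, lag in enumerate(lags):
            if len(seg) > lag:
                d = seg[lag:] - seg[:-lag]
                msd[i] += float(np.sum(d * d))
                nobs[i] += len(d)
    valid = nobs > 0
    lags, msd = lags[valid], msd[valid] / nobs[valid]
    if len(lags) < 3:
        raise ValueError("insufficient lag coverage for an MSD fit")
    alpha = float(np.polyfit(np.log(lags.astype(float)), np.log(msd), 1)[0])
    if alpha > 1.5:
        raise ValueError(
            f"MSD grows as lag^{alpha:.2f}: ballistic/drift-dominated motion, "
            "no diffusion coefficient reported"
        )
    slope = float(np.polyfit(lags * dt_ns, msd, 1)[0])  # Å²/ns
    d_a2ns = slope / 2.0
    d_si = d_a2ns * 1e-11  # 1 Å²/ns = 1e-11 m²/s
    return {
        "D_A2_per_ns": d_a2ns,
        "D_1e-9_m2_per_s": d_si / 1e-9,
        "ratio_to_free": d_si / free_reference,
        "msd_exponent": alpha,
        "n_runs": len(runs),
    }
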