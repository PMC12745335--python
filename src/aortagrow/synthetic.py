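"""Synthetic dissected-aorta scenes, growth fields and cohorts.

Patient imaging is not shipped with this package; instead, every
downstream stage (hemodynamics, wall stress, registration, statistics)
is exercised on synthetic geometries with known ground truth:

* a tube-topology outer wall (straight or arched) with an internal
  dissection flap splitting the cross-section into true and false
  lumens, fenestrations (tears) in the flap, and optional mural
  thrombus in the false lumen;
* follow-up geometries produced by a prescribed circumferential growth
  field, optionally with a rigid perturbation (ground truth for the
  registration stage);
* cohorts of per-region (stress, growth) pairs drawn exactly from the
  random-slope mixed-effects generative model used in the statistics
  stage.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .meshmodel import SolidMesh

__all__ = [
    "PatientRecord",
    "TearSpec",
    "ThrombusSpec",
    "AortaSpec",
    "AortaScene",
    "GrowthField",
    "CohortSpec",
    "SyntheticCohort",
    "make_dissected_aorta",
    "grow_aorta",
    "make_cohort",
    "make_cylinder_fixture",
    "default_stress_generator",
]


# ---------------------------------------------------------------------------
# patient-level scalars
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """Per-patient clinical scalars driving boundary conditions."""

    patient_id: str
    sbp: float                       # systolic brachial pressure, mmHg
    dbp: float                       # diastolic brachial pressure, mmHg
    baseline_date: date
    followup_date: date
    inlet_flow: float | None = None  # systolic flow, L/min
    peak_velocity: float | None = None  # echo peak velocity, m/s
    outlet_areas: tuple[float, ...] = ()  # mm^2
    thrombus_present: bool = False

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError("require sbp > dbp > 0")
        if self.inlet_flow is None and self.peak_velocity is None:
            raise ValueError("either inlet_flow or peak_velocity is required")
        if self.inlet_flow is not None and self.inlet_flow <= 0:
            raise ValueError("inlet_flow must be positive")
        if self.followup_date <= self.baseline_date:
            raise ValueError("followup_date must postdate baseline_date")
        if any(a <= 0 for a in self.outlet_areas):
            raise ValueError("outlet areas must be positive")

    @property
    def followup_years(self) -> float:
        return (self.followup_date - self.baseline_date).days / 365.25


# ---------------------------------------------------------------------------
# geometry specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TearSpec:
    """Circular fenestration in the flap."""

    arclength: float        # mm along the centerline
    chord_frac: float = 0.5  # position across the flap chord in (0, 1)
    radius: float = 5.0      # mm

    def __post_init__(self) -> None:
        if not (0.0 < self.chord_frac < 1.0):
            raise ValueError("chord_frac must be inside (0, 1)")
        if self.radius <= 0:
            raise ValueError("tear radius must be positive")


@dataclass(frozen=True)
class ThrombusSpec:
    """Mural thrombus lining part of the false lumen wall."""

    start: float             # arclength range, mm
    end: float
    depth: float = 5.0       # radial depth into the false lumen, mm
    angle_frac: float = 0.6  # fraction of the false-lumen arc covered
    n_radial: int = 2        # hex layers through the thrombus depth

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("thrombus end must exceed start")
        if self.depth <= 0 or not (0 < self.angle_frac <= 1):
            raise ValueError("invalid thrombus depth or angular extent")


@dataclass(frozen=True)
class AortaSpec:
    """Parameters of the synthetic dissected aorta.

    The default shape is an inverted-U "candy cane": a straight ascending
    segment, a 180-degree arch, and a straight descending segment; the
    left-subclavian surrogate landmark sits at the end of the arch.
    """

    shape: str = "arched"            # "arched" or "straight"
    radius: float = 15.0             # proximal lumen radius, mm
    distal_radius: float | None = None  # taper target; default = radius
    length: float = 200.0            # straight-shape length, mm
    ascending_length: float = 60.0   # arched-shape segments, mm
    arch_radius: float = 35.0
    descending_length: float = 240.0
    n_axial: int = 120               # generator grid resolution
    n_circ: int = 48
    flap_angle: float | None = np.pi  # false-lumen angular span; None = no flap
    flap_center_angle: float = np.pi / 2
    flap_start: float | None = None  # defaults to landmark + 20 mm
    flap_end: float | None = None    # defaults to landmark + 180 mm
    n_chord: int = 11
    tears: tuple[TearSpec, ...] | None = None  # None = default pair, () = none
    thrombus: ThrombusSpec | None = None
    bump_amplitude: float = 0.0      # smooth radius perturbations, mm
    n_bumps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radii and lengths must be positive")
        if self.ascending_length <= 0 or self.descending_length <= 0 or self.arch_radius <= 0:
            raise ValueError("radii and lengths must be positive")
        if self.shape not in ("arched", "straight"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class Outlet:
    """Branch outlet: a point on the wall with a cross-sectional area."""

    arclength: float
    area: float          # mm^2
    position: np.ndarray  # (3,) mm


@dataclass
class FlapSurface:
    """Ruled chord surface splitting the lumen, with tear holes."""

    points: np.ndarray           # (nf_ax, n_chord, 3) mid-surface
    normals: np.ndarray          # (nf_ax, n_chord, 3) unit, toward false lumen
    axial_indices: np.ndarray    # generator-grid stations spanned by the flap
    column_a: int                # wall circ columns of the chord ends
    column_b: int
    false_side_columns: np.ndarray  # wall circ columns on the false-lumen arc
    face_alive: np.ndarray       # (nf_ax-1, n_chord-1) bool, False inside tears
    tears: tuple[TearSpec, ...] = ()

    def triangulated(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangle mesh of the flap with tear faces removed and
        unreferenced vertices dropped (for topology checks and I/O)."""
        nfa, nch = self.points.shape[:2]
        vid = np.arange(nfa * nch).reshape(nfa, nch)
        faces = []
        for j in range(nfa - 1):
            for i in range(nch - 1):
                if not self.face_alive[j, i]:
                    continue
                a, b = vid[j, i], vid[j, i + 1]
                c, d = vid[j + 1, i + 1], vid[j + 1, i]
                faces.append((a, b, c))
                faces.append((a, c, d))
        faces = np.array(faces, dtype=np.int64)
        verts = self.points.reshape(-1, 3)
        used = np.unique(faces)
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return verts[used], remap[faces]


@dataclass
class ThrombusBody:
    """Structured thrombus block attached to the false-lumen wall."""

    columns: np.ndarray        # wall circ columns covered
    axial_indices: np.ndarray  # wall grid stations covered
    depths: np.ndarray         # (n_axial_cov, n_col) mm
    n_radial: int
    points_cache: np.ndarray | None = None

    def depth(self, j_ax: int, i_col: int) -> float:
        a = int(np.searchsorted(self.axial_indices, j_ax))
        b = int(np.searchsorted(self.columns, i_col))
        return float(self.depths[a, b])


@dataclass
class AortaScene:
    """One dissected aorta at one time point.

    ``grid`` is the generator-resolution outer-wall grid (axial stations
    x circumferential nodes); ``grid_centers`` are the analytic
    cross-section centers on the centerline (the generator controls the
    centerline, so no centerline-extraction step is needed).
    """

    centerline: np.ndarray        # (n_s, 3)
    arclengths: np.ndarray        # (n_s,)
    grid: np.ndarray              # (n_axial, n_circ, 3)
    grid_arclengths: np.ndarray   # (n_axial,)
    grid_centers: np.ndarray      # (n_axial, 3)
    landmark_arclength: float
    outlets: list[Outlet] = field(default_factory=list)
    flap: FlapSurface | None = None
    thrombus: ThrombusBody | None = None
    spec: AortaSpec | None = None

    @property
    def total_length(self) -> float:
        return float(self.arclengths[-1])

    @property
    def inlet_radius(self) -> float:
        rel = self.grid[0] - self.grid_centers[0]
        return float(np.linalg.norm(rel, axis=1).mean())

    def section_radii(self) -> np.ndarray:
        """(n_axial, n_circ) node distances to analytic section centers."""
        return np.linalg.norm(self.grid - self.grid_centers[:, None, :], axis=2)

    def flap_chord_fraction(self) -> np.ndarray | None:
        """Per-station false-lumen area fraction estimate (0..1)."""
        if self.flap is None:
            return None
        frac = np.zeros(len(self.grid))
        span = len(self.flap.false_side_columns) / self.grid.shape[1]
        # circular-segment area fraction for the chord subtending the arc
        ang = 2 * np.pi * span
        frac[self.flap.axial_indices] = (ang - np.sin(ang)) / (2 * np.pi)
        return frac

    def outer_trimesh(self):
        """Watertight triangle mesh (side quads + end-cap fans)."""
        import trimesh

        na, nc = self.grid.shape[:2]
        verts = [self.grid.reshape(-1, 3)]
        vid = np.arange(na * nc).reshape(na, nc)
        faces = []
        for j in range(na - 1):
            for i in range(nc):
                i2 = (i + 1) % nc
                a, b = vid[j, i], vid[j, i2]
                c, d = vid[j + 1, i2], vid[j + 1, i]
                faces.append((a, b, c))
                faces.append((a, c, d))
        c0 = na * nc
        c1 = na * nc + 1
        verts.append(self.grid_centers[[0, -1]])
        for i in range(nc):
            i2 = (i + 1) % nc
            faces.append((c0, vid[0, i2], vid[0, i]))       # inlet cap
            faces.append((c1, vid[-1, i], vid[-1, i2]))     # distal cap
        mesh = trimesh.Trimesh(np.vstack(verts), np.array(faces), process=False)
        if mesh.volume < 0:
            mesh.invert()
        return mesh

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AortaScene":
        """Rigidly moved copy (all geometry, including the centerline)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)

        def mv(x):
            return x @ R.T + t

        flap = None
        if self.flap is not None:
            flap = replace(self.flap, points=mv(self.flap.points),
                           normals=self.flap.normals @ R.T)
        thr = None
        if self.thrombus is not None:
            thr = replace(self.thrombus)
        outlets = [Outlet(o.arclength, o.area, mv(o.position)) for o in self.outlets]
        return AortaScene(
            centerline=mv(self.centerline), arclengths=self.arclengths.copy(),
            grid=mv(self.grid), grid_arclengths=self.grid_arclengths.copy(),
            grid_centers=mv(self.grid_centers),
            landmark_arclength=self.landmark_arclength,
            outlets=outlets, flap=flap, thrombus=thr, spec=self.spec,
        )


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------

def _centerline(spec: AortaSpec, step: float = 2.0):
    """Centerline polyline, arclengths and the landmark arclength."""
    if spec.shape == "straight":
        n = max(int(np.ceil(spec.length / step)) + 1, 2)
        z = np.linspace(0.0, spec.length, n)
        pts = np.column_stack([np.zeros(n), np.zeros(n), z])
        s = z.copy()
        landmark = 0.35 * spec.length
        return pts, s, landmark

    la, ra, ld = spec.ascending_length, spec.arch_radius, spec.descending_length
    pts = [np.array([0.0, 0.0, z]) for z in np.arange(0.0, la, step)]
    arc_len = np.pi * ra
    n_arc = max(int(np.ceil(arc_len / step)), 8)
    for phi in np.linspace(0.0, np.pi, n_arc, endpoint=False):
        pts.append(np.array([ra - ra * np.cos(phi), 0.0, la + ra * np.sin(phi)]))
    for z in np.arange(0.0, ld + step / 2, step):
        pts.append(np.array([2 * ra, 0.0, la - z]))
    pts = np.asarray(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    landmark = la + arc_len        # just distal to the arch
    return pts, s, landmark


def _transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents and parallel-transported (e1, e2) section frames."""
    n = len(points)
    tang = np.empty((n, 3))
    tang[:-1] = np.diff(points, axis=0)
    tang[-1] = tang[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    e1 = np.empty((n, 3))
    e2 = np.empty((n, 3))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ tang[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - (ref @ tang[0]) * tang[0]
    e1[0] = v / np.linalg.norm(v)
    e2[0] = np.cross(tang[0], e1[0])
    for i in range(1, n):
        t0, t1 = tang[i - 1], tang[i]
        c = np.cross(t0, t1)
        nc = np.linalg.norm(c)
        if nc < 1e-12:
            e1[i], e2[i] = e1[i - 1], e2[i - 1]
            continue
        axis = c / nc
        cos = np.clip(t0 @ t1, -1.0, 1.0)
        ang = np.arctan2(nc, cos)
        e1[i] = _rodrigues(e1[i - 1], axis, ang)
        e2[i] = np.cross(t1, e1[i])
    return tang, e1, e2


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1.0 - np.cos(angle)))


# ---------------------------------------------------------------------------
# scene generator
# ---------------------------------------------------------------------------

def make_dissected_aorta(spec: AortaSpec = AortaSpec()) -> AortaScene:
    """Generate a dissected-aorta scene from geometric parameters.

    Deterministic for a fixed spec (the spec carries the seed used for
    the optional smooth radius perturbations).
    """
    cl, s_cl, landmark = _centerline(spec)
    total = s_cl[-1]
    s_grid = np.linspace(0.0, total, spec.n_axial)
    centers = np.column_stack([np.interp(s_grid, s_cl, cl[:, k]) for k in range(3)])
    tang, e1c, e2c = _transport_frames(cl)
    e1 = np.column_stack([np.interp(s_grid, s_cl, e1c[:, k]) for k in range(3)])
    e2 = np.column_stack([np.interp(s_grid, s_cl, e2c[:, k]) for k in range(3)])
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    # re-orthogonalize e2 against e1 after interpolation
    e2 -= np.sum(e2 * e1, axis=1, keepdims=True) * e1
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)

    r_distal = spec.distal_radius if spec.distal_radius is not None else spec.radius
    radii = spec.radius + (r_distal - spec.radius) * s_grid / total
    if spec.bump_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        centers_s = rng.uniform(0.15, 0.95, spec.n_bumps) * total
        widths = rng.uniform(0.05, 0.12, spec.n_bumps) * total
        amps = rng.uniform(-1.0, 1.0, spec.n_bumps) * spec.bump_amplitude
        for cs, w, a in zip(centers_s, widths, amps):
            radii = radii + a * np.exp(-0.5 * ((s_grid - cs) / w) ** 2)

    theta = 2.0 * np.pi * np.arange(spec.n_circ) / spec.n_circ
    grid = (centers[:, None, :]
            + radii[:, None, None] * (np.cos(theta)[None, :, None] * e1[:, None, :]
                                      + np.sin(theta)[None, :, None] * e2[:, None, :]))

    flap = _build_flap(spec, grid, s_grid, landmark, theta)
    thrombus = _build_thrombus(spec, flap, s_grid)
    outlets = _default_outlets(spec, grid, s_grid, centers, landmark, radii)

    return AortaScene(
        centerline=cl, arclengths=s_cl, grid=grid, grid_arclengths=s_grid,
        grid_centers=centers, landmark_arclength=landmark,
        outlets=outlets, flap=flap, thrombus=thrombus, spec=spec,
    )


def _build_flap(spec, grid, s_grid, landmark, theta):
    if spec.flap_angle is None:
        return None
    total = s_grid[-1]
    f0 = spec.flap_start if spec.flap_start is not None else min(landmark + 20.0, total * 0.5)
    f1 = spec.flap_end if spec.flap_end is not None else min(landmark + 180.0, total - 15.0)
    if not (0.0 < f0 < f1 < total):
        raise ValueError("flap extent outside the aorta")

    nc = spec.n_circ
    a_ang = spec.flap_center_angle - spec.flap_angle / 2.0
    b_ang = spec.flap_center_angle + spec.flap_angle / 2.0
    col_a = int(np.round(a_ang / (2 * np.pi) * nc)) % nc
    col_b = int(np.round(b_ang / (2 * np.pi) * nc)) % nc
    if col_a == col_b:
        raise ValueError("flap angle too small for the circumferential resolution")
    arc = np.arange(col_a + 1, col_a + 1 + ((col_b - col_a) % nc) - 1)
    false_cols = np.mod(arc, nc)

    ax_idx = np.where((s_grid >= f0) & (s_grid <= f1))[0]
    if len(ax_idx) < 3:
        raise ValueError("flap axial extent too short for the grid resolution")
    A = grid[ax_idx, col_a]           # (nfa, 3)
    B = grid[ax_idx, col_b]
    frac = np.linspace(0.0, 1.0, spec.n_chord)
    points = A[:, None, :] + frac[None, :, None] * (B - A)[:, None, :]

    # unit normal toward the false lumen
    t_axial = np.gradient(points, axis=0)
    t_chord = np.gradient(points, axis=1)
    normals = np.cross(t_chord, t_axial)
    normals /= np.linalg.norm(normals, axis=2, keepdims=True)
    mid_fl = grid[ax_idx[0], false_cols[len(false_cols) // 2]]
    to_fl = mid_fl - points[0, spec.n_chord // 2]
    if normals[0, spec.n_chord // 2] @ to_fl < 0:
        normals = -normals

    face_alive = np.ones((len(ax_idx) - 1, spec.n_chord - 1), dtype=bool)
    tears = spec.tears
    if tears is None:
        # default proximal/distal tears, clear of the flap rim even on
        # coarse axial grids
        spacing = s_grid[1] - s_grid[0]
        margin = max(15.0, 5.0 + 2.5 * spacing)
        tears = (TearSpec(arclength=f0 + margin, radius=5.0),
                 TearSpec(arclength=f1 - margin, radius=5.0))
    chord_len = float(np.linalg.norm(B - A, axis=1).mean())
    for tear in tears:
        if tear.radius >= chord_len / 2.0 or tear.radius >= (f1 - f0) / 2.0:
            raise ValueError("tear larger than the flap extent")
        if not (f0 < tear.arclength < f1):
            raise ValueError("tear strictly inside the flap is required")
        j_t = int(np.argmin(np.abs(s_grid[ax_idx] - tear.arclength)))
        center = points[j_t, int(np.round(tear.chord_frac * (spec.n_chord - 1)))]
        fc = 0.25 * (points[:-1, :-1] + points[1:, :-1] + points[:-1, 1:] + points[1:, 1:])
        inside = np.linalg.norm(fc - center, axis=2) < tear.radius
        if inside[0].any() or inside[-1].any() or inside[:, 0].any() or inside[:, -1].any():
            raise ValueError("tear touches the flap boundary")
        face_alive &= ~inside
    return FlapSurface(points=points, normals=normals, axial_indices=ax_idx,
                       column_a=col_a, column_b=col_b,
                       false_side_columns=false_cols, face_alive=face_alive,
                       tears=tuple(tears))


def _build_thrombus(spec, flap, s_grid):
    if spec.thrombus is None:
        return None
    if flap is None:
        raise ValueError("thrombus requires a false lumen (flap)")
    th = spec.thrombus
    ax = flap.axial_indices[(s_grid[flap.axial_indices] >= th.start)
                            & (s_grid[flap.axial_indices] <= th.end)]
    if len(ax) < 2:
        raise ValueError("thrombus axial extent too short")
    n_cov = max(int(np.round(th.angle_frac * len(flap.false_side_columns))), 2)
    start = (len(flap.false_side_columns) - n_cov) // 2
    cols = np.sort(flap.false_side_columns[start:start + n_cov])
    depths = np.full((len(ax), len(cols)), th.depth)
    return ThrombusBody(columns=cols, axial_indices=ax, depths=depths,
                        n_radial=th.n_radial)


def _default_outlets(spec, grid, s_grid, centers, landmark, radii):
    outlets = []
    if spec.shape == "arched":
        # three arch-branch surrogates proximal to the landmark
        for ds, area in ((-40.0, 60.0), (-25.0, 35.0), (-10.0, 45.0)):
            s = landmark + ds
            j = int(np.argmin(np.abs(s_grid - s)))
            outlets.append(Outlet(float(s_grid[j]), area, grid[j, 0].copy()))
    distal_area = np.pi * radii[-1] ** 2
    outlets.append(Outlet(float(s_grid[-1]), float(distal_area), centers[-1].copy()))
    return outlets


# ---------------------------------------------------------------------------
# growth fields and follow-up geometries
# ---------------------------------------------------------------------------

@dataclass
class GrowthField:
    """Circumferential stretch factor over arclength (and angle).

    ``stretch(s, theta)`` returns the dimensionless stretch applied to a
    cross-section radius; ``duration`` is the elapsed time in years.
    """

    fn: object                  # callable (s, theta) -> stretch
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def stretch(self, s, theta=None):
        th = np.zeros_like(np.asarray(s, dtype=float)) if theta is None else theta
        return np.asarray(self.fn(np.asarray(s, dtype=float), th), dtype=float)

    @classmethod
    def uniform(cls, factor: float, duration: float = 1.0) -> "GrowthField":
        return cls(fn=lambda s, th: np.full_like(np.asarray(s, float), factor),
                   duration=duration)

    @classmethod
    def sigmoid(cls, low: float, high: float, s_mid: float, width: float,
                duration: float = 1.0) -> "GrowthField":
        """Smooth ramp from ``low`` (proximal) to ``high`` (distal)."""
        def fn(s, th):
            return low + (high - low) / (1.0 + np.exp(-(s - s_mid) / width))
        return cls(fn=fn, duration=duration)

    @classmethod
    def from_profile(cls, s_knots, factors, duration: float = 1.0) -> "GrowthField":
        s_knots = np.asarray(s_knots, dtype=float)
        factors = np.asarray(factors, dtype=float)

        def fn(s, th):
            return np.interp(s, s_knots, factors)
        return cls(fn=fn, duration=duration)

    @classmethod
    def from_region_rates(cls, rates_pct_per_year, partition, layer_arclengths,
                          duration: float) -> "GrowthField":
        """Stretch field realizing given descending region growth rates.

        ``rates_pct_per_year`` are circumferential log-strain rates per
        descending region; the stretch is exp(rate/100 * duration),
        interpolated between region-center arclengths (1.0 proximal of
        the landmark region)."""
        rates = np.asarray(rates_pct_per_year, dtype=float)
        centers = []
        for k, reg in enumerate(partition.descending_regions):
            lay = partition.layers(reg)
            centers.append(layer_arclengths[lay].mean())
        centers = np.asarray(centers)
        stretches = np.exp(rates / 100.0 * duration)
        s_knots = np.concatenate([[0.0, centers[0] - 1e-6], centers])
        f_knots = np.concatenate([[1.0, 1.0], stretches])
        return cls.from_profile(s_knots, f_knots, duration=duration)


def grow_aorta(scene: AortaScene, growth: GrowthField,
               rotation: np.ndarray | None = None,
               translation: np.ndarray | None = None) -> AortaScene:
    """Follow-up geometry: scale each cross-section about its center by
    the local stretch factor; optionally apply a rigid perturbation."""
    s = scene.grid_arclengths
    rel = scene.grid - scene.grid_centers[:, None, :]
    theta = 2.0 * np.pi * np.arange(scene.grid.shape[1]) / scene.grid.shape[1]
    sg, tg = np.meshgrid(s, theta, indexing="ij")
    f = growth.stretch(sg, tg)
    if np.any(f <= 0):
        raise ValueError("growth stretch must be positive everywhere")
    grid = scene.grid_centers[:, None, :] + f[:, :, None] * rel

    flap = None
    if scene.flap is not None:
        fl = scene.flap
        s_f = s[fl.axial_indices]
        cen = scene.grid_centers[fl.axial_indices]
        relf = fl.points - cen[:, None, :]
        # flap points scale with the stretch at their own angular position
        ff = growth.stretch(np.repeat(s_f[:, None], fl.points.shape[1], axis=1),
                            np.zeros((len(s_f), fl.points.shape[1])))
        pts = cen[:, None, :] + ff[:, :, None] * relf
        flap = replace(fl, points=pts)

    thr = replace(scene.thrombus) if scene.thrombus is not None else None
    out = [Outlet(o.arclength, o.area, o.position.copy()) for o in scene.outlets]
    grown = AortaScene(
        centerline=scene.centerline.copy(), arclengths=scene.arclengths.copy(),
        grid=grid, grid_arclengths=s.copy(), grid_centers=scene.grid_centers.copy(),
        landmark_arclength=scene.landmark_arclength,
        outlets=out, flap=flap, thrombus=thr, spec=scene.spec,
    )
    if rotation is not None or translation is not None:
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        grown = grown.transformed(R, t)
    return grown


# ---------------------------------------------------------------------------
# cohort generator (random-slope mixed-effects generative model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of the stress -> growth cohort model.

    Region-level growth rate (%/year) is
    ``GR = beta0 + beta1*stress + b0_m + b1_m*stress + eps`` with
    patient-level random effects b0_m ~ N(0, sd_b0^2),
    b1_m ~ N(0, sd_b1^2) and residual eps ~ N(0, sd_eps^2).

    The default effect sizes are the cohort-level estimates this package
    targets: slope 0.095 %/(year*kPa), random-slope SD 0.13, random-
    intercept SD 27.8 %/year over nine patients with 38 regions each.
    """

    n_patients: int = 9
    n_regions: int = 38
    beta0: float = 0.0            # %/year
    beta1: float = 0.095          # %/(year*kPa)
    sd_b0: float = 27.8           # %/year
    sd_b1: float = 0.13           # %/(year*kPa)
    sd_eps: float = 10.0          # %/year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        if min(self.sd_b0, self.sd_b1, self.sd_eps) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SyntheticCohort:
    """Generated cohort table plus the true random effects."""

    table: pd.DataFrame           # patient_id, region, stress_kpa, growth_pct_per_year
    b0: np.ndarray
    b1: np.ndarray
    spec: CohortSpec


def default_stress_generator(rng: np.random.Generator, n: int) -> np.ndarray:
    """Region-averaged maximum-principal stresses (kPa).

    Gamma with mean 300 kPa and SD 150 kPa: wall stress in the dissected
    descending aorta is typically a few hundred kPa, strictly positive
    and right-skewed."""
    shape, scale = 4.0, 75.0
    return rng.gamma(shape, scale, size=n)


def make_cohort(spec: CohortSpec = CohortSpec(),
                stress_generator=default_stress_generator) -> SyntheticCohort:
    """Draw a cohort exactly from the random-slope generative model."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    b0 = rng.normal(0.0, spec.sd_b0, spec.n_patients) if spec.sd_b0 > 0 else np.zeros(spec.n_patients)
    b1 = rng.normal(0.0, spec.sd_b1, spec.n_patients) if spec.sd_b1 > 0 else np.zeros(spec.n_patients)
    for m in range(spec.n_patients):
        stress = np.asarray(stress_generator(rng, spec.n_regions), dtype=float)
        eps = rng.normal(0.0, spec.sd_eps, spec.n_regions) if spec.sd_eps > 0 else np.zeros(spec.n_regions)
        growth = (spec.beta0 + spec.beta1 * stress
                  + b0[m] + b1[m] * stress + eps)
        for i in range(spec.n_regions):
            rows.append((f"P{m + 1}", i + 1, stress[i], growth[i]))
    table = pd.DataFrame(rows, columns=["patient_id", "region",
                                        "stress_kpa", "growth_pct_per_year"])
    return SyntheticCohort(table=table, b0=b0, b1=b1, spec=spec)


# ---------------------------------------------------------------------------
# cylinder fixture
# ---------------------------------------------------------------------------

def make_cylinder_fixture(r: float, t: float, L: float, n_layers: int = 4,
                          n_circ: int = 32, n_axial: int = 20) -> SolidMesh:
    """Hex mesh of a thin cylindrical shell (inner radius r, thickness t).

    Node radial coordinates span [r, r+t]; the inner surface carries the
    load facets (true-lumen label) and the end rings are the default
    fixed node set.  Axis along global z.
    """
    if t >= r:
        raise ValueError("thickness must be smaller than the inner radius")
    if L <= 0 or r <= 0:
        raise ValueError("radius and length must be positive")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")

    nt = n_layers + 1
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    z = np.linspace(0.0, L, n_axial + 1)
    rad = np.linspace(r, r + t, nt)
    # node block (n_axial+1, n_circ, nt)
    R, TH, ZZ = np.meshgrid(rad, theta, z, indexing="ij")  # (nt, nc, na)
    X = (R * np.cos(TH)).transpose(2, 1, 0)
    Y = (R * np.sin(TH)).transpose(2, 1, 0)
    Z = ZZ.transpose(2, 1, 0)
    nodes = np.stack([X, Y, Z], axis=-1)        # (na+1, nc, nt, 3)
    ids = np.arange((n_axial + 1) * n_circ * nt).reshape(n_axial + 1, n_circ, nt)
    from .meshmodel import _hex_block

    wrap = np.concatenate([ids, ids[:, :1]], axis=1)
    hexes = _hex_block(wrap)
    facets, lumen, hints = [], [], []
    for j in range(n_axial):
        for i in range(n_circ):
            i2 = (i + 1) % n_circ
            facets.append((ids[j, i, 0], ids[j, i2, 0], ids[j + 1, i2, 0], ids[j + 1, i, 0]))
            lumen.append(0)
            hints.append((np.cos(theta[i]), np.sin(theta[i]), 0.0))
    fixed = np.unique(np.concatenate([ids[0].ravel(), ids[-1].ravel()]))
    n_el = len(hexes)
    return SolidMesh(
        nodes=nodes.reshape(-1, 3), hexes=hexes,
        material=np.full(n_el, "wall", dtype=object),
        region=np.full(n_el, "tl_wall", dtype=object),
        load_facets=np.array(facets, dtype=np.int64),
        facet_lumen=np.array(lumen, dtype=np.int64),
        facet_hint=np.array(hints, dtype=float),
        fixed_nodes=fixed, grid_shape=(n_axial + 1, n_circ),
    )
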